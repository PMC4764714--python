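"""Synthetic saccade-aligned population spiking data.

The decoding pipeline in this package analyses trial-structured spike
timestamps recorded while a subject makes visually guided saccades.  This
module provides a generative stand-in population with the statistical
structure that analysis assumes:

* a saccade task with 2 orthogonal saccade directions (rightward, downward)
  x 5 initial fixation positions arranged like the 5-face of a die, 10
  degree saccade amplitude;
* tonic eye-position "gain field" firing (rate varies linearly with eye
  position), with a per-neuron temporal offset of the eye-position input
  (negative offsets = predictive inputs, positive = delayed);
* direction-specific peri-saccadic transients (plateau-like enhancement or
  suppression, biphasic modulation, sustained pre/post steps) plus a
  direction-nonspecific peri-saccadic burst;
* inhomogeneous Poisson spiking.

Sessions are emitted already aligned to saccade onset; eye-movement
detection, visual response latency and behavioural errors are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

RIGHTWARD = "rightward"
DOWNWARD = "downward"
DIRECTIONS = (RIGHTWARD, DOWNWARD)

#: identifiers of the peri-saccadic transient basis shapes
TRANSIENT_COMPONENTS = ("plateau", "biphasic", "step", "burst")

DEFAULT_INITIAL_POSITIONS: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.0),
    (-10.0, 10.0),
    (10.0, 10.0),
    (10.0, -10.0),
    (-10.0, -10.0),
)


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and trial structure of the saccade task.

    Defaults reproduce the study design: five initial fixation positions
    arranged like the value 5 on a die, saccades stepping 10 degrees either
    rightward or downward, and an eye trajectory modelled as a scaled
    cumulative Gaussian with mean 25 ms and SD 10 ms relative to saccade
    onset.
    """

    initial_positions: Tuple[Tuple[float, float], ...] = DEFAULT_INITIAL_POSITIONS
    saccade_amplitude: float = 10.0
    directions: Tuple[str, ...] = DIRECTIONS
    fixation_duration: float = 1000.0
    trials_per_condition: int = 20
    saccade_mu: float = 25.0
    saccade_sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.saccade_amplitude <= 0:
            raise ValueError("saccade_amplitude must be positive")
        if self.trials_per_condition < 6:
            raise ValueError("trials_per_condition must be at least 6")
        for d in self.directions:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")

    @property
    def n_conditions(self) -> int:
        return len(self.initial_positions) * len(self.directions)


@dataclass(frozen=True)
class NeuronParams:
    """Generative parameters of one model neuron.

    ``baseline`` is the tonic rate at eye position (0, 0); ``gain_x`` and
    ``gain_y`` are gain-field slopes in spikes/s per degree.  The tonic
    eye-position input is read at ``t - position_input_delay``; a negative
    delay means the tonic input anticipates the eye.  ``transient_amps``
    maps ``(component, direction)`` to a signed amplitude in spikes/s, with
    components drawn from :data:`TRANSIENT_COMPONENTS`, and the whole
    direction-specific transient complex is shifted by ``transient_delay``
    (its own per-neuron temporal offset, independent of the tonic one);
    ``burst_amp`` scales a direction-nonspecific Gaussian bump locked to
    saccade time.
    """

    baseline: float = 20.0
    gain_x: float = 0.0
    gain_y: float = 0.0
    position_input_delay: float = 0.0
    transient_amps: Tuple[Tuple[Tuple[str, str], float], ...] = ()
    transient_delay: float = 0.0
    burst_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        for (comp, direction), _amp in self.transient_amps:
            if comp not in TRANSIENT_COMPONENTS:
                raise ValueError(f"unknown transient component {comp!r}")
            if direction not in DIRECTIONS:
                raise ValueError(f"unknown direction {direction!r}")

    def transient_amp(self, component: str, direction: str) -> float:
        for key, amp in self.transient_amps:
            if key == (component, direction):
                return amp
        return 0.0

    @staticmethod
    def amps_from_dict(d: Dict[str, Dict[str, float]]) -> Tuple:
        """Build the ``transient_amps`` tuple from ``{component: {direction: amp}}``."""
        return tuple(
            ((comp, direction), float(amp))
            for comp, per_dir in d.items()
            for direction, amp in per_dir.items()
        )


@dataclass
class SpikeSession:
    """Trial-aligned spike timestamps with condition labels.

    ``trials`` has one row per trial: ``trial_id``, ``position_index``
    (1-based index into the task's initial positions) and ``direction``.
    ``spikes`` has one row per spike: ``trial_id``, ``neuron_id``,
    ``spike_time_ms`` (relative to saccade onset).  ``ground_truth``
    optionally carries the generating :class:`NeuronParams` so decoding
    results can be scored against truth.
    """

    neurons: List[int]
    trials: pd.DataFrame
    spikes: pd.DataFrame
    time_span: Tuple[float, float]
    task: TaskConfig = field(default_factory=TaskConfig)
    ground_truth: Optional[List[NeuronParams]] = None

    def __post_init__(self) -> None:
        lo, hi = self.time_span
        if len(self.spikes) and (
            self.spikes["spike_time_ms"].min() < lo
            or self.spikes["spike_time_ms"].max() > hi
        ):
            raise ValueError("spike timestamps outside time_span")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def condition_trials(self, position_index: int, direction: str) -> np.ndarray:
        t = self.trials
        mask = (t["position_index"] == position_index) & (t["direction"] == direction)
        return t.loc[mask, "trial_id"].to_numpy()


# ---------------------------------------------------------------------------
# deterministic rate model
# ---------------------------------------------------------------------------

def eye_trajectory(
    direction: str,
    initial_position: Tuple[float, float],
    task: TaskConfig,
    times: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical eye position (degrees) over ``times`` (ms).

    The saccade is a scaled cumulative Gaussian step of the task amplitude,
    rightward along +x or downward along -y, with transition mean
    ``task.saccade_mu`` and SD ``task.saccade_sigma`` relative to saccade
    onset.
    """
    times = np.asarray(times, dtype=float)
    x0, y0 = initial_position
    step = task.saccade_amplitude * norm.cdf(
        (times - task.saccade_mu) / task.saccade_sigma
    )
    if direction == RIGHTWARD:
        return x0 + step, np.full_like(times, y0)
    if direction == DOWNWARD:
        return np.full_like(times, x0), y0 - step
    raise ValueError(f"unknown direction {direction!r}")


def _plateau(t: np.ndarray) -> np.ndarray:
    # smooth plateau: rises near -100 ms, decayed by about +150 ms
    return norm.cdf((t + 80.0) / 25.0) * norm.sf((t - 100.0) / 30.0)


def _biphasic(t: np.ndarray) -> np.ndarray:
    # derivative-of-Gaussian, normalised to unit peak magnitude
    z = (t - 25.0) / 18.0
    return z * np.exp(-0.5 * z * z) / (np.exp(-0.5))


def _step(t: np.ndarray) -> np.ndarray:
    # sustained pre -> post saccadic step, tracking the eye trajectory's pace
    return norm.cdf((t - 25.0) / 10.0)


def _dir_burst(t: np.ndarray) -> np.ndarray:
    # narrow burst for one saccade direction over another
    return np.exp(-0.5 * ((t - 25.0) / 12.0) ** 2)


def _burst(t: np.ndarray) -> np.ndarray:
    # direction-nonspecific peri-saccadic bump
    return np.exp(-0.5 * ((t - 25.0) / 30.0) ** 2)


TRANSIENT_BASIS = {
    "plateau": _plateau,
    "biphasic": _biphasic,
    "step": _step,
    "burst": _dir_burst,
}


def rate_profile(
    neuron: NeuronParams,
    direction: str,
    initial_position: Tuple[float, float],
    task: TaskConfig,
    times: np.ndarray,
) -> np.ndarray:
    """Firing rate (spikes/s) of ``neuron`` over ``times`` for one condition.

    rate(t) = max(0, baseline + gain_x * x(t - delay) + gain_y * y(t - delay)
                     + sum_c amp[c, direction] * basis_c(t - transient_delay)
                     + burst * bump(t))

    The tonic eye-position input and the direction-specific transients each
    carry their own per-neuron temporal offset, while the direction-
    nonspecific burst stays locked to the saccade itself.
    """
    times = np.asarray(times, dtype=float)
    x, y = eye_trajectory(
        direction, initial_position, task, times - neuron.position_input_delay
    )
    rate = neuron.baseline + neuron.gain_x * x + neuron.gain_y * y
    shifted = times - neuron.transient_delay
    for comp, basis in TRANSIENT_BASIS.items():
        amp = neuron.transient_amp(comp, direction)
        if amp:
            rate = rate + amp * basis(shifted)
    if neuron.burst_amp:
        rate = rate + neuron.burst_amp * _burst(times)
    return np.maximum(rate, 0.0)


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

def _draw_spikes(
    rng: np.random.Generator,
    grid: np.ndarray,
    rate: np.ndarray,
) -> np.ndarray:
    """Inhomogeneous Poisson samples by thinning a piecewise-linear intensity."""
    lam_max = float(rate.max())
    if lam_max <= 0.0:
        return np.empty(0)
    span = grid[-1] - grid[0]
    n = rng.poisson(lam_max * span / 1000.0)
    if n == 0:
        return np.empty(0)
    t = rng.uniform(grid[0], grid[-1], size=n)
    lam_t = np.interp(t, grid, rate)
    keep = rng.uniform(0.0, lam_max, size=n) < lam_t
    return np.sort(t[keep])


def simulate_session(
    population: Sequence[NeuronParams],
    task: TaskConfig = TaskConfig(),
    seed: int = 0,
    time_span: Tuple[float, float] = (-900.0, 900.0),
    keep_ground_truth: bool = True,
) -> SpikeSession:
    """Simulate a full saccade-aligned recording session.

    Each trial draws spikes for every neuron from an inhomogeneous Poisson
    process whose intensity is :func:`rate_profile`, by thinning on a 1 ms
    lattice.  Random streams are spawned per trial from ``seed``, so a
    subset of trials is reproducible independently of the rest.
    """
    population = list(population)
    if not population:
        raise ValueError("population must contain at least one neuron")
    grid = np.arange(time_span[0], time_span[1] + 0.5, 1.0)

    # rate profiles cached per (neuron, condition)
    profiles: Dict[Tuple[int, int, str], np.ndarray] = {}
    for j, neuron in enumerate(population):
        for p, pos in enumerate(task.initial_positions, start=1):
            for direction in task.directions:
                profiles[(j, p, direction)] = rate_profile(
                    neuron, direction, pos, task, grid
                )

    trial_rows = []
    trial_id = 0
    conditions = [
        (p, d)
        for p in range(1, len(task.initial_positions) + 1)
        for d in task.directions
    ]
    for p, direction in conditions:
        for _ in range(task.trials_per_condition):
            trial_rows.append((trial_id, p, direction))
            trial_id += 1
    trials = pd.DataFrame(trial_rows, columns=["trial_id", "position_index", "direction"])

    streams = np.random.SeedSequence(seed).spawn(len(trials))
    spike_trials: List[np.ndarray] = []
    spike_neurons: List[np.ndarray] = []
    spike_times: List[np.ndarray] = []
    for (tid, p, direction), ss in zip(trial_rows, streams):
        rng = np.random.default_rng(ss)
        for j in range(len(population)):
            ts = _draw_spikes(rng, grid, profiles[(j, p, direction)])
            if ts.size:
                spike_trials.append(np.full(ts.size, tid, dtype=np.int64))
                spike_neurons.append(np.full(ts.size, j, dtype=np.int64))
                spike_times.append(ts)

    if spike_times:
        spikes = pd.DataFrame(
            {
                "trial_id": np.concatenate(spike_trials),
                "neuron_id": np.concatenate(spike_neurons),
                "spike_time_ms": np.concatenate(spike_times),
            }
        )
    else:
        spikes = pd.DataFrame(
            {
                "trial_id": np.empty(0, dtype=np.int64),
                "neuron_id": np.empty(0, dtype=np.int64),
                "spike_time_ms": np.empty(0, dtype=float),
            }
        )

    return SpikeSession(
        neurons=list(range(len(population))),
        trials=trials,
        spikes=spikes,
        time_span=time_span,
        task=task,
        ground_truth=population if keep_ground_truth else None,
    )


#: default parameter ranges for :func:`sample_population`
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "baseline": (10.0, 40.0),          # spikes/s, uniform
    "gain": (0.0, 1.0),                # spikes/s/deg, normal (mean, sd)
    "delay": (-100.0, 200.0),          # ms, uniform (tonic eye-position input)
    "transient_latency": (-150.0, 250.0),  # ms, uniform (transient complex)
    "transient_plateau": (0.0, 5.0),   # spikes/s, normal (mean, sd)
    "transient_biphasic": (0.0, 30.0),
    "transient_step": (0.0, 10.0),
    "transient_burst": (0.0, 30.0),
    "burst": (0.0, 6.0),               # spikes/s, uniform (nonspecific bump)
}


def sample_population(
    n_neurons: int,
    seed: int = 0,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
) -> List[NeuronParams]:
    """Draw a heterogeneous model population.

    Baselines and nonspecific-burst amplitudes are uniform on their ranges;
    gain-field slopes and transient amplitudes are normal (``ranges`` gives
    (mean, sd), per transient component via ``transient_<component>`` keys).
    The tonic-input delay is uniform on ``ranges['delay']``, by default
    spanning -100..+200 ms so the population supports predictive through
    delayed eye-position read-outs; transient latencies are uniform on
    ``ranges['transient_latency']``, a slightly wider span so peri-saccadic
    modulation covers the whole band with margin.  Direction-specific
    transients dominate the modulation budget (most neurons modulate
    strongly around saccades even when their gain fields are weak), with
    the narrow burst and biphasic shapes carrying the largest amplitudes.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be at least 1")
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    rng = np.random.default_rng(seed)
    population = []
    for _ in range(n_neurons):
        amps = tuple(
            (
                (comp, direction),
                float(rng.normal(*r[f"transient_{comp}"])),
            )
            for comp in TRANSIENT_COMPONENTS
            for direction in DIRECTIONS
        )
        population.append(
            NeuronParams(
                baseline=float(rng.uniform(*r["baseline"])),
                gain_x=float(rng.normal(r["gain"][0], r["gain"][1])),
                gain_y=float(rng.normal(r["gain"][0], r["gain"][1])),
                position_input_delay=float(rng.uniform(*r["delay"])),
                transient_amps=amps,
                transient_delay=float(rng.uniform(*r["transient_latency"])),
                burst_amp=float(rng.uniform(*r["burst"])),
            )
        )
    return population


# ---------------------------------------------------------------------------
# on-disk session format: JSON header + CSV spike table (HDF5 equivalent)
# ---------------------------------------------------------------------------

def _session_header(session: SpikeSession) -> dict:
    header = {
        "format": "gazedecode-session",
        "version": 1,
        "n_neurons": session.n_neurons,
        "time_span": list(session.time_span),
        "task": {
            "initial_positions": [list(p) for p in session.task.initial_positions],
            "saccade_amplitude": session.task.saccade_amplitude,
            "directions": list(session.task.directions),
            "fixation_duration": session.task.fixation_duration,
            "trials_per_condition": session.task.trials_per_condition,
            "saccade_mu": session.task.saccade_mu,
            "saccade_sigma": session.task.saccade_sigma,
        },
    }
    if session.ground_truth is not None:
        header["ground_truth"] = [
            {
                "baseline": n.baseline,
                "gain_x": n.gain_x,
                "gain_y": n.gain_y,
                "position_input_delay": n.position_input_delay,
                "transient_amps": [[list(k), v] for k, v in n.transient_amps],
                "transient_delay": n.transient_delay,
                "burst_amp": n.burst_amp,
            }
            for n in session.ground_truth
        ]
    return header


def _task_from_header(h: dict) -> TaskConfig:
    t = h["task"]
    return TaskConfig(
        initial_positions=tuple(tuple(p) for p in t["initial_positions"]),
        saccade_amplitude=t["saccade_amplitude"],
        directions=tuple(t["directions"]),
        fixation_duration=t["fixation_duration"],
        trials_per_condition=t["trials_per_condition"],
        saccade_mu=t["saccade_mu"],
        saccade_sigma=t["saccade_sigma"],
    )


def _truth_from_header(h: dict) -> Optional[List[NeuronParams]]:
    if "ground_truth" not in h:
        return None
    return [
        NeuronParams(
            baseline=g["baseline"],
            gain_x=g["gain_x"],
            gain_y=g["gain_y"],
            position_input_delay=g["position_input_delay"],
            transient_amps=tuple((tuple(k), v) for k, v in g["transient_amps"]),
            transient_delay=g.get("transient_delay", 0.0),
            burst_amp=g["burst_amp"],
        )
        for g in h["ground_truth"]
    ]


def save_session(session: SpikeSession, prefix: str | Path) -> Tuple[Path, Path]:
    """Write ``<prefix>.json`` (header) and ``<prefix>.csv`` (spike table)."""
    prefix = Path(prefix)
    header_path = prefix.with_suffix(".json")
    spikes_path = prefix.with_suffix(".csv")
    header_path.write_text(json.dumps(_session_header(session), indent=1))
    table = session.spikes.merge(session.trials, on="trial_id")
    table = table[["trial_id", "neuron_id", "position_index", "direction", "spike_time_ms"]]
    table.to_csv(spikes_path, index=False)
    return header_path, spikes_path


def load_session(prefix: str | Path) -> SpikeSession:
    """Load a session written by :func:`save_session`."""
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    table = pd.read_csv(prefix.with_suffix(".csv"))
    trials = (
        table[["trial_id", "position_index", "direction"]]
        .drop_duplicates()
        .sort_values("trial_id")
        .reset_index(drop=True)
    )
    spikes = table[["trial_id", "neuron_id", "spike_time_ms"]].reset_index(drop=True)
    return SpikeSession(
        neurons=list(range(header["n_neurons"])),
        trials=trials,
        spikes=spikes,
        time_span=tuple(header["time_span"]),
        task=_task_from_header(header),
        ground_truth=_truth_from_header(header),
    )


def save_session_hdf5(session: SpikeSession, path: str | Path) -> Path:
    """Single-container HDF5 layout with the same field names as the CSV form."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(_session_header(session))
        g = f.create_group("trials")
        g.create_dataset("trial_id", data=session.trials["trial_id"].to_numpy())
        g.create_dataset("position_index", data=session.trials["position_index"].to_numpy())
        g.create_dataset(
            "direction",
            data=np.array(session.trials["direction"], dtype="S16"),
        )
        s = f.create_group("spikes")
        s.create_dataset("trial_id", data=session.spikes["trial_id"].to_numpy())
        s.create_dataset("neuron_id", data=session.spikes["neuron_id"].to_numpy())
        s.create_dataset("spike_time_ms", data=session.spikes["spike_time_ms"].to_numpy())
    return path


def load_session_hdf5(path: str | Path) -> SpikeSession:
    import h5py

    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        trials = pd.DataFrame(
            {
                "trial_id": f["trials/trial_id"][:],
                "position_index": f["trials/position_index"][:],
                "direction": [d.decode() for d in f["trials/direction"][:]],
            }
        )
        spikes = pd.DataFrame(
            {
                "trial_id": f["spikes/trial_id"][:],
                "neuron_id": f["spikes/neuron_id"][:],
                "spike_time_ms": f["spikes/spike_time_ms"][:],
            }
        )
    return SpikeSession(
        neurons=list(range(header["n_neurons"])),
        trials=trials,
        spikes=spikes,
        time_span=tuple(header["time_span"]),
        task=_task_from_header(header),
        ground_truth=_truth_from_header(header),
    )
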