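"""Firing-rate binning, condition averaging and train/test trial splits.

Spike timestamps are converted to instantaneous firing rates with a 50 ms
counting window stepped in 25 ms increments across -800..+800 ms relative
to saccade onset (65 grid points).  Grid times are window centers and each
window is half-open, ``[t - w/2, t + w/2)``, so boundary spikes are counted
exactly once.  Per-condition trial means are then pooled (unweighted) over
the five initial fixation positions to give one time x neuron design
matrix per saccade direction, ``R_rwd`` and ``R_dwd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthdata import DIRECTIONS, DOWNWARD, RIGHTWARD, SpikeSession


class SpanError(ValueError):
    """Requested analysis span is not covered by the session."""


@dataclass
class RateTensor:
    """Per-trial binned rates: ``rates[trial, time, neuron]`` in spikes/s."""

    times: np.ndarray
    rates: np.ndarray
    trials: pd.DataFrame
    window_ms: float
    step_ms: float

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    def condition_indices(self) -> Dict[Tuple[int, str], np.ndarray]:
        """Row indices into ``rates`` for each (position, direction) condition."""
        out: Dict[Tuple[int, str], np.ndarray] = {}
        grouped = self.trials.reset_index(drop=True).groupby(
            ["position_index", "direction"], sort=True
        )
        for (p, d), g in grouped:
            out[(int(p), str(d))] = g.index.to_numpy()
        return out


@dataclass
class RateMatrices:
    """Trial- and position-averaged design matrices per saccade direction."""

    times: np.ndarray
    R_rwd: np.ndarray  # time x neuron, spikes/s
    R_dwd: np.ndarray

    def __post_init__(self) -> None:
        if self.R_rwd.shape != self.R_dwd.shape:
            raise ValueError("R_rwd and R_dwd must have the same shape")
        if self.R_rwd.shape[0] != len(self.times):
            raise ValueError("row count must match the time grid")

    @property
    def n_neurons(self) -> int:
        return self.R_rwd.shape[1]

    def stacked(self) -> np.ndarray:
        """Both directions concatenated in time (rightward first)."""
        return np.vstack([self.R_rwd, self.R_dwd])


@dataclass
class TrialSplit:
    """Random per-condition partition of trial ids into train and test sets."""

    train: Dict[Tuple[int, str], np.ndarray]
    test: Dict[Tuple[int, str], np.ndarray]
    seed: Optional[int] = None

    @property
    def train_ids(self) -> np.ndarray:
        return np.concatenate(list(self.train.values()))

    @property
    def test_ids(self) -> np.ndarray:
        return np.concatenate(list(self.test.values()))


def default_grid(
    span: Tuple[float, float] = (-800.0, 800.0), step_ms: float = 25.0
) -> np.ndarray:
    return np.arange(span[0], span[1] + step_ms / 2, step_ms)


def bin_rates(
    session: SpikeSession,
    window_ms: float = 50.0,
    step_ms: float = 25.0,
    span: Tuple[float, float] = (-800.0, 800.0),
) -> RateTensor:
    """Bin every trial's spikes into overlapping counting windows.

    The rate at grid time ``t`` is the spike count in ``[t - w/2, t + w/2)``
    divided by the window length.  Raises :class:`SpanError` if any window
    extends beyond the session's recorded time span.
    """
    times = default_grid(span, step_ms)
    lo, hi = session.time_span
    if times[0] - window_ms / 2 < lo or times[-1] + window_ms / 2 > hi:
        raise SpanError(
            f"binning span {span} with window {window_ms} ms exceeds session "
            f"coverage {session.time_span}"
        )

    trials = session.trials.sort_values("trial_id").reset_index(drop=True)
    trial_pos = {tid: i for i, tid in enumerate(trials["trial_id"])}
    n_trials, n_times, n_neurons = len(trials), len(times), session.n_neurons
    counts = np.zeros((n_trials, n_times, n_neurons), dtype=np.float64)

    sp = session.spikes
    if len(sp):
        t = sp["spike_time_ms"].to_numpy(dtype=float)
        rows = sp["trial_id"].map(trial_pos).to_numpy(dtype=np.intp)
        cols = sp["neuron_id"].to_numpy(dtype=np.intp)
        # a window [c - w/2, c + w/2) covers a spike at t iff
        # c in (t - w/2, t + w/2]; the lower bound is strict (half-open
        # window), which floor(.) + 1 realises even on exact lattice hits
        i_lo = np.floor((t - window_ms / 2 - times[0]) / step_ms).astype(np.intp) + 1
        i_hi = np.floor((t + window_ms / 2 - times[0]) / step_ms).astype(np.intp)
        max_cover = int(np.ceil(window_ms / step_ms)) + 1
        for off in range(max_cover):
            idx = i_lo + off
            ok = (idx <= i_hi) & (idx >= 0) & (idx < n_times)
            if ok.any():
                np.add.at(counts, (rows[ok], idx[ok], cols[ok]), 1.0)

    return RateTensor(
        times=times,
        rates=counts / (window_ms / 1000.0),
        trials=trials,
        window_ms=window_ms,
        step_ms=step_ms,
    )


def condition_average(
    tensor: RateTensor,
    trial_ids: Optional[Iterable[int]] = None,
) -> RateMatrices:
    """Average per-trial rates within each condition, then over positions.

    ``trial_ids`` restricts the average to a subset (e.g. one side of a
    :class:`TrialSplit`); every condition must still contribute at least one
    trial.
    """
    weights = _condition_weights(tensor, trial_ids)
    flat = tensor.rates.reshape(tensor.n_trials, -1)
    shape = tensor.rates.shape[1:]
    R = {d: (w @ flat).reshape(shape) for d, w in weights.items()}
    return RateMatrices(times=tensor.times, R_rwd=R[RIGHTWARD], R_dwd=R[DOWNWARD])


def _condition_weights(
    tensor: RateTensor, trial_ids: Optional[Iterable[int]]
) -> Dict[str, np.ndarray]:
    """Averaging weights over trials realising the condition/position means."""
    subset = None if trial_ids is None else set(int(i) for i in trial_ids)
    cond_idx = tensor.condition_indices()
    tid = tensor.trials["trial_id"].to_numpy()
    positions = sorted({p for p, _ in cond_idx})
    weights = {}
    for direction in DIRECTIONS:
        w = np.zeros(tensor.n_trials)
        for p in positions:
            rows = cond_idx.get((p, direction))
            if rows is None:
                raise ValueError(f"no trials for condition ({p}, {direction})")
            if subset is not None:
                rows = rows[np.isin(tid[rows], list(subset))]
            if rows.size == 0:
                raise ValueError(
                    f"condition ({p}, {direction}) has no trials in the subset"
                )
            w[rows] = 1.0 / (len(positions) * rows.size)
        weights[direction] = w
    return weights


def split_trials(
    session: SpikeSession, fraction: float = 0.5, seed: int = 0
) -> TrialSplit:
    """Random per-condition train/test partition.

    With an odd trial count the extra trial goes to the training side
    (favours weight-estimation stability).  Every condition needs at least
    2 trials so both sides are non-empty.
    """
    rng = np.random.default_rng(seed)
    train: Dict[Tuple[int, str], np.ndarray] = {}
    test: Dict[Tuple[int, str], np.ndarray] = {}
    grouped = session.trials.groupby(["position_index", "direction"], sort=True)
    for (p, d), g in grouped:
        ids = np.sort(g["trial_id"].to_numpy())
        if ids.size < 2:
            raise ValueError(f"condition ({p}, {d}) has fewer than 2 trials")
        perm = rng.permutation(ids)
        n_train = int(np.ceil(fraction * ids.size))
        train[(int(p), str(d))] = np.sort(perm[:n_train])
        test[(int(p), str(d))] = np.sort(perm[n_train:])
    return TrialSplit(train=train, test=test, seed=seed)
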