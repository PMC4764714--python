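"""Fixed-weight linear read-out of time-lagged eye-position signals.

Two hypothetical downstream units pool the recorded population with fixed
per-neuron weights to represent the horizontal (X) and vertical (Y) eye
coordinate as a firing rate (1 spike/s = 1 degree):

    X_hat(t) = R(t) . beta_X + c_X        Y_hat(t) = R(t) . beta_Y + c_Y

The weights are estimated by ridge regression against a synthetic
eye-position target -- a scaled cumulative Gaussian whose transition time
can be shifted by a "target lag" to probe predictive (negative lag) and
delayed (positive lag) representations -- and are *fixed across the two
saccade directions*: the rightward and downward design matrices and
targets are concatenated in time and fitted jointly.  Performance is
evaluated in cross-validation over random half/half trial splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .rates import (
    RateMatrices,
    RateTensor,
    TrialSplit,
    _condition_weights,
    bin_rates,
    condition_average,
    default_grid,
    split_trials,
)
from .synthdata import SpikeSession

#: decoded/target channel names: read-out unit x saccade direction
CHANNELS = ("X_rwd", "X_dwd", "Y_rwd", "Y_dwd")


class ZeroVarianceError(ValueError):
    """Total variance of the target is zero; R^2 is undefined."""


@dataclass
class TargetEPS:
    """Synthetic eye-position regression target at a given lag.

    The transition is a cumulative Gaussian with mean ``mu = mu0 + lag``
    and SD ``sigma``; the horizontal channel rises 0 -> amplitude for
    rightward saccades, the vertical channel falls 0 -> -amplitude for
    downward saccades (downward is negative y), and the orthogonal
    channels are identically zero.
    """

    lag: float
    times: np.ndarray
    X_rwd: np.ndarray
    X_dwd: np.ndarray
    Y_rwd: np.ndarray
    Y_dwd: np.ndarray
    mu: float
    sigma: float
    amplitude: float

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def stacked(self, channel: str) -> np.ndarray:
        """Target for one read-out unit, directions concatenated in time."""
        if channel == "X":
            return np.concatenate([self.X_rwd, self.X_dwd])
        if channel == "Y":
            return np.concatenate([self.Y_rwd, self.Y_dwd])
        raise ValueError(f"unknown channel {channel!r}")


@dataclass
class DecoderWeights:
    """Per-neuron pooling weights, fixed across saccade directions."""

    beta_X: np.ndarray
    beta_Y: np.ndarray
    c_X: float
    c_Y: float
    gamma: float
    residual_scale: float  # training residual SD (degrees), pooled channels
    dropped_neurons: Tuple[int, ...] = ()


@dataclass
class DecodedEPS:
    """Cross-validated decoder output: pointwise mean and SD over sets."""

    times: np.ndarray
    mean: Dict[str, np.ndarray]  # keyed by CHANNELS
    sd: Dict[str, np.ndarray]
    n_sets: int
    sets: Optional[np.ndarray] = None      # n_sets x 4 x T, CHANNELS order
    beta_X: Optional[np.ndarray] = None    # n_sets x neurons
    beta_Y: Optional[np.ndarray] = None
    c_X: Optional[np.ndarray] = None
    c_Y: Optional[np.ndarray] = None

    def channel(self, name: str) -> np.ndarray:
        return self.mean[name]


def make_target(
    lag_ms: float,
    amplitude: float = 10.0,
    mu0: float = 25.0,
    sigma: float = 10.0,
    times: Optional[np.ndarray] = None,
) -> TargetEPS:
    """Build the synthetic eye-position target for one lag condition."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if times is None:
        times = default_grid()
    times = np.asarray(times, dtype=float)
    mu = mu0 + lag_ms
    step = amplitude * norm.cdf((times - mu) / sigma)
    zeros = np.zeros_like(times)
    return TargetEPS(
        lag=lag_ms,
        times=times,
        X_rwd=step,
        X_dwd=zeros.copy(),
        Y_rwd=zeros.copy(),
        Y_dwd=-step,
        mu=mu,
        sigma=sigma,
        amplitude=amplitude,
    )


def _ridge_channel(
    Z: np.ndarray, y: np.ndarray, gamma: float
) -> Tuple[np.ndarray, float]:
    """Closed-form ridge with standardized predictors, unpenalized intercept.

    Predictors are z-scored (ddof=1) and the penalty ``gamma`` applies on
    that standardized scale; slopes are rescaled to original units and the
    intercept recovered so predictions are unbiased at the training mean.
    """
    xm = Z.mean(axis=0)
    xs = Z.std(axis=0, ddof=1)
    keep = xs > 0
    beta = np.zeros(Z.shape[1])
    Zs = (Z[:, keep] - xm[keep]) / xs[keep]
    ym = y.mean()
    yc = y - ym
    A = Zs.T @ Zs + gamma * np.eye(Zs.shape[1])
    beta_s = np.linalg.solve(A, Zs.T @ yc)
    beta[keep] = beta_s / xs[keep]
    c = ym - float(xm @ beta)
    return beta, c


def fit_weights(
    R_train: RateMatrices,
    target: TargetEPS,
    gamma: float = 30.0,
    time_mask: Optional[np.ndarray] = None,
) -> DecoderWeights:
    """Estimate pooling weights by ridge regression on the training rates.

    The two directions' design matrices and targets are concatenated in
    time; the X and Y channels are fitted independently with the same
    procedure.  ``time_mask`` (boolean over the grid) optionally restricts
    the rows entering the fit, e.g. to exclude the peri-saccadic epoch.
    Zero-variance neuron columns are dropped with a warning and get zero
    weight.
    """
    Z = R_train.stacked()
    if time_mask is not None:
        time_mask = np.asarray(time_mask, dtype=bool)
        Z = Z[np.concatenate([time_mask, time_mask])]
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 time samples to fit weights")
    dropped = tuple(np.flatnonzero(Z.std(axis=0, ddof=1) == 0).tolist())
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance neuron column(s)",
            stacklevel=2,
        )

    sse = 0.0
    n = 0
    out = {}
    for channel in ("X", "Y"):
        y = target.stacked(channel)
        if time_mask is not None:
            y = y[np.concatenate([time_mask, time_mask])]
        beta, c = _ridge_channel(Z, y, gamma)
        resid = y - (Z @ beta + c)
        sse += float(resid @ resid)
        n += y.size
        out[channel] = (beta, c)
    return DecoderWeights(
        beta_X=out["X"][0],
        beta_Y=out["Y"][0],
        c_X=out["X"][1],
        c_Y=out["Y"][1],
        gamma=gamma,
        residual_scale=float(np.sqrt(sse / n)),
        dropped_neurons=dropped,
    )


def predict(R_test: RateMatrices, w: DecoderWeights) -> Dict[str, np.ndarray]:
    """Apply the read-out to test rates; same weights for both directions."""
    if R_test.n_neurons != w.beta_X.size:
        raise ValueError(
            f"neuron mismatch: {R_test.n_neurons} columns vs "
            f"{w.beta_X.size} weights"
        )
    return {
        "X_rwd": R_test.R_rwd @ w.beta_X + w.c_X,
        "X_dwd": R_test.R_dwd @ w.beta_X + w.c_X,
        "Y_rwd": R_test.R_rwd @ w.beta_Y + w.c_Y,
        "Y_dwd": R_test.R_dwd @ w.beta_Y + w.c_Y,
    }


def cross_validate(
    session: SpikeSession,
    target: TargetEPS,
    gamma: float = 30.0,
    n_sets: int = 1000,
    seed: int = 0,
    fraction: float = 0.5,
    tensor: Optional[RateTensor] = None,
    time_mask: Optional[np.ndarray] = None,
    keep_sets: bool = False,
    keep_weights: bool = True,
) -> DecodedEPS:
    """Cross-validated decoding over repeated random half/half trial splits.

    Each set draws a fresh per-condition train/test partition, estimates
    weights on the trial- and position-averaged training rates and decodes
    the held-out averages; the pointwise mean and SD over sets are
    returned.  ``tensor`` may pass pre-binned per-trial rates to avoid
    re-binning; ``time_mask`` restricts the rows used for weight
    estimation only (prediction always covers the full grid).
    """
    if tensor is None:
        tensor = bin_rates(session, span=(target.times[0], target.times[-1]))
    if not np.array_equal(tensor.times, target.times):
        raise ValueError("rate tensor grid does not match target grid")

    set_seeds = np.random.SeedSequence(seed).generate_state(n_sets) % (2**31 - 1)
    T = len(target.times)
    n_neurons = tensor.rates.shape[2]
    stack = np.empty((n_sets, len(CHANNELS), T))
    bX = np.empty((n_sets, n_neurons))
    bY = np.empty((n_sets, n_neurons))
    cX = np.empty(n_sets)
    cY = np.empty(n_sets)
    flat = tensor.rates.reshape(tensor.n_trials, -1)
    shape = tensor.rates.shape[1:]

    for i, s in enumerate(set_seeds):
        split = split_trials(session, fraction=fraction, seed=int(s))
        Rtr = _average(tensor, flat, shape, split.train_ids)
        Rte = _average(tensor, flat, shape, split.test_ids)
        w = fit_weights(Rtr, target, gamma=gamma, time_mask=time_mask)
        pred = predict(Rte, w)
        for j, ch in enumerate(CHANNELS):
            stack[i, j] = pred[ch]
        bX[i], bY[i], cX[i], cY[i] = w.beta_X, w.beta_Y, w.c_X, w.c_Y

    mean = {ch: stack[:, j].mean(axis=0) for j, ch in enumerate(CHANNELS)}
    sd = {ch: stack[:, j].std(axis=0, ddof=0) for j, ch in enumerate(CHANNELS)}
    return DecodedEPS(
        times=target.times,
        mean=mean,
        sd=sd,
        n_sets=n_sets,
        sets=stack if keep_sets else None,
        beta_X=bX if keep_weights else None,
        beta_Y=bY if keep_weights else None,
        c_X=cX if keep_weights else None,
        c_Y=cY if keep_weights else None,
    )


def _average(tensor, flat, shape, trial_ids) -> RateMatrices:
    weights = _condition_weights(tensor, trial_ids)
    from .synthdata import DOWNWARD, RIGHTWARD

    R = {d: (w @ flat).reshape(shape) for d, w in weights.items()}
    return RateMatrices(times=tensor.times, R_rwd=R[RIGHTWARD], R_dwd=R[DOWNWARD])


def r_squared(
    decoded: DecodedEPS,
    target: TargetEPS,
    window: str = "full",
    peri_halfwidth: float = 100.0,
) -> float:
    """Coefficient of determination pooled over channels and directions.

    ``window='perisaccadic'`` restricts the calculation to times within
    ``peri_halfwidth`` of the *target signal's* transition time (``mu``),
    so lagged targets are scored around their own transition.
    """
    if not np.array_equal(decoded.times, target.times):
        raise ValueError("grids do not match")
    if window == "full":
        mask = np.ones(len(target.times), dtype=bool)
    elif window == "perisaccadic":
        mask = np.abs(target.times - target.mu) <= peri_halfwidth
    else:
        raise ValueError(f"unknown window {window!r}")

    t_all = np.concatenate([target.channel(ch)[mask] for ch in CHANNELS])
    d_all = np.concatenate([decoded.mean[ch][mask] for ch in CHANNELS])
    sst = float(np.sum((t_all - t_all.mean()) ** 2))
    if sst == 0.0:
        raise ZeroVarianceError("target has zero variance in this window")
    sse = float(np.sum((d_all - t_all) ** 2))
    return 1.0 - sse / sst


def fixation_only_mask(
    times: np.ndarray,
    exclusion: float = 100.0,
    saccade_onset: float = 0.0,
    saccade_offset: float = 50.0,
) -> np.ndarray:
    """True for grid rows retained when the peri-saccadic epoch is omitted.

    Rows strictly within ``exclusion`` ms of the saccade interval
    (onset..offset) are removed; ``exclusion=0`` keeps every row.
    """
    times = np.asarray(times, dtype=float)
    dist = np.maximum(
        np.maximum(saccade_onset - times, times - saccade_offset), 0.0
    )
    return dist >= exclusion


def fixation_only_decoder(
    session: SpikeSession,
    gamma: float = 30.0,
    exclusion: float = 100.0,
    target: Optional[TargetEPS] = None,
    n_sets: int = 1000,
    seed: int = 0,
    tensor: Optional[RateTensor] = None,
    **kwargs,
) -> DecodedEPS:
    """Decoder trained on fixation epochs only, predicting the full grid.

    Grid rows within ``exclusion`` ms of the saccade (onset 0 ms to offset
    ~50 ms) are removed from the training design and target; the weights so
    obtained are then applied at every time point.  With peri-saccadic
    transients in the population this yields a damped, late transition.
    """
    if target is None:
        target = make_target(0.0)
    mask = fixation_only_mask(target.times, exclusion=exclusion)
    if mask.sum() < 2:
        raise ValueError("exclusion leaves fewer than 2 grid rows")
    return cross_validate(
        session,
        target,
        gamma=gamma,
        n_sets=n_sets,
        seed=seed,
        tensor=tensor,
        time_mask=mask,
        **kwargs,
    )


@dataclass
class TargetCorrelation:
    """Pairwise similarity of the lagged target signals."""

    lags: np.ndarray
    matrix: np.ndarray  # n_lags x n_lags Pearson r
    mean: float         # over unordered off-diagonal pairs
    min: float
    max: float
    n_pairs: int


def target_correlation(
    lags: Optional[Sequence[float]] = None,
    times: Optional[np.ndarray] = None,
    amplitude: float = 10.0,
    mu0: float = 25.0,
    sigma: float = 10.0,
) -> TargetCorrelation:
    """Mean pairwise Pearson correlation across the lagged targets.

    Each lag's signal is its rightward horizontal channel concatenated with
    its downward vertical channel sign-flipped to the plotted (upward)
    orientation, on the full analysis grid.  With the default nine lags
    (-400..+400 ms in 100 ms steps) this quantifies how similar the
    regression targets are despite their different transition times.
    """
    if lags is None:
        lags = np.arange(-400.0, 401.0, 100.0)
    lags = np.asarray(lags, dtype=float)
    if times is None:
        times = default_grid()
    signals = []
    for lag in lags:
        t = make_target(lag, amplitude=amplitude, mu0=mu0, sigma=sigma, times=times)
        signals.append(np.concatenate([t.X_rwd, -t.Y_dwd]))
    mat = np.corrcoef(np.asarray(signals))
    iu = np.triu_indices(len(lags), k=1)
    vals = mat[iu]
    return TargetCorrelation(
        lags=lags,
        matrix=mat,
        mean=float(vals.mean()),
        min=float(vals.min()),
        max=float(vals.max()),
        n_pairs=len(vals),
    )
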