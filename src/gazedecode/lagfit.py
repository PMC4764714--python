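"""Cumulative-Gaussian parameterization of decoded eye-position signals.

The linear read-out typically produces sigmoid-like transitions between
the pre- and post-saccadic eye positions.  Fitting a cumulative Gaussian
``offset + amplitude * Phi((t - mu) / sigma)`` jointly to the two saccade
channels (the X-unit for rightward saccades and the Y-unit for downward
saccades, the latter entering with negated amplitude) summarizes each
decoded signal with four parameters.  The fitted ``mu`` minus the true
saccade transition time (25 ms) is the *achieved lag*, and the 1st-99th
percentile width of the Gaussian (4.6527 sigma) estimates the represented
saccade duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, t as t_dist

from .decode import (
    DecodedEPS,
    TargetEPS,
    cross_validate,
    make_target,
    r_squared,
)
from .rates import RateTensor, bin_rates
from .synthdata import SpikeSession

#: 1st-to-99th percentile width of a unit Gaussian (= 2 * z_0.99)
DURATION_FACTOR = float(norm.ppf(0.99) - norm.ppf(0.01))

#: transition time of the true (zero-lag) saccade trajectory, ms
TRUE_MU = 25.0

#: SD of the true saccade trajectory, ms
TRUE_SIGMA = 10.0


class FitError(RuntimeError):
    """Sigmoid fit failed to converge from every starting point."""


@dataclass
class SigmoidFit:
    mu: float
    sigma: float
    amplitude: float
    offset: float
    sse: float
    ci_mu: Tuple[float, float]
    ci_sigma: Tuple[float, float]
    reference_mu: float = TRUE_MU
    reference_sigma: float = TRUE_SIGMA

    @property
    def achieved_lag(self) -> float:
        return self.mu - self.reference_mu

    @property
    def duration(self) -> float:
        return DURATION_FACTOR * self.sigma

    @property
    def duration_ratio(self) -> float:
        return self.sigma / self.reference_sigma


def _model(params: np.ndarray, times: np.ndarray, signs: np.ndarray) -> np.ndarray:
    mu, sigma, amp, offset = params
    return offset + signs * amp * norm.cdf((times - mu) / np.abs(sigma))


def _residuals(params, times, signs, values):
    return _model(params, times, signs) - values


def _initial_guesses(
    times: np.ndarray, rwd: np.ndarray
) -> List[np.ndarray]:
    lo = np.median(rwd[: max(3, len(rwd) // 8)])
    hi = np.median(rwd[-max(3, len(rwd) // 8):])
    amp0 = hi - lo
    half = lo + amp0 / 2.0
    crossing = np.flatnonzero(np.diff(np.sign(rwd - half)) != 0)
    mu0 = float(times[crossing[0]]) if crossing.size else float(times[len(times) // 2])
    base = np.array([mu0, TRUE_SIGMA, amp0, lo])
    guesses = [base]
    for d_mu, f_sigma in ((-50.0, 1.0), (50.0, 1.0), (-150.0, 5.0), (150.0, 5.0)):
        g = base.copy()
        g[0] += d_mu
        g[1] *= f_sigma
        guesses.append(g)
    return guesses


def fit_sigmoid_joint(
    xhat_rwd: np.ndarray,
    yhat_dwd: np.ndarray,
    times: np.ndarray,
    reference_mu: float = TRUE_MU,
    reference_sigma: float = TRUE_SIGMA,
) -> SigmoidFit:
    """Joint four-parameter cumulative-Gaussian fit to both saccade channels.

    One shared (mu, sigma, amplitude, offset) is estimated by least squares
    with the residuals of the two channels accumulated; the downward
    channel enters with negated amplitude so a single positive amplitude
    serves both.  Five starting points (half-range crossing plus jittered
    variants) guard against local minima; the best-SSE solution is kept.
    95% confidence intervals for mu and sigma come from the Jacobian at the
    optimum (asymptotic linearization).
    """
    times = np.asarray(times, dtype=float)
    xhat_rwd = np.asarray(xhat_rwd, dtype=float)
    yhat_dwd = np.asarray(yhat_dwd, dtype=float)
    tt = np.concatenate([times, times])
    signs = np.concatenate([np.ones_like(times), -np.ones_like(times)])
    values = np.concatenate([xhat_rwd, yhat_dwd])

    best = None
    for g in _initial_guesses(times, xhat_rwd):
        try:
            res = optimize.least_squares(
                _residuals, g, args=(tt, signs, values), method="lm", max_nfev=5000
            )
        except Exception:
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("cumulative-Gaussian fit did not converge from any start")

    mu, sigma, amp, offset = best.x
    sigma = abs(sigma)
    sse = float(2 * best.cost)
    ci_mu, ci_sigma = _jacobian_ci(best, n_obs=values.size)
    return SigmoidFit(
        mu=float(mu),
        sigma=float(sigma),
        amplitude=float(amp),
        offset=float(offset),
        sse=sse,
        ci_mu=ci_mu,
        ci_sigma=ci_sigma,
        reference_mu=reference_mu,
        reference_sigma=reference_sigma,
    )


def _jacobian_ci(res, n_obs: int, level: float = 0.95):
    dof = max(n_obs - res.x.size, 1)
    s2 = 2 * res.cost / dof
    J = res.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(res.x.size, np.nan)
    q = t_dist.ppf(0.5 + level / 2, dof)
    ci_mu = (float(res.x[0] - q * se[0]), float(res.x[0] + q * se[0]))
    sig = abs(res.x[1])
    ci_sigma = (float(sig - q * se[1]), float(sig + q * se[1]))
    return ci_mu, ci_sigma


def fit_sigmoid_per_set(
    decoded: DecodedEPS, reference: SigmoidFit
) -> pd.DataFrame:
    """Two-parameter (mu, sigma) refits per cross-validation set.

    Amplitude and offset are fixed at the reference fit's values (the fit
    to the mean across sets); non-converging sets are flagged rather than
    excluded silently.  Returns one row per set with columns ``mu``,
    ``sigma`` and ``converged``.
    """
    if decoded.sets is None:
        raise ValueError("DecodedEPS was built without keep_sets=True")
    times = decoded.times
    tt = np.concatenate([times, times])
    signs = np.concatenate([np.ones_like(times), -np.ones_like(times)])
    amp, offset = reference.amplitude, reference.offset

    def resid(p, values):
        return offset + signs * amp * norm.cdf((tt - p[0]) / abs(p[1])) - values

    ix = CHANNEL_INDEX["X_rwd"]
    iy = CHANNEL_INDEX["Y_dwd"]
    rows = []
    for i in range(decoded.n_sets):
        values = np.concatenate([decoded.sets[i, ix], decoded.sets[i, iy]])
        try:
            res = optimize.least_squares(
                resid,
                np.array([reference.mu, reference.sigma]),
                args=(values,),
                method="lm",
                max_nfev=2000,
            )
            rows.append((float(res.x[0]), float(abs(res.x[1])), bool(res.success)))
        except Exception:
            rows.append((np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["mu", "sigma", "converged"])


CHANNEL_INDEX = {"X_rwd": 0, "X_dwd": 1, "Y_rwd": 2, "Y_dwd": 3}


def direction_difference(decoded: DecodedEPS) -> Dict[str, np.ndarray]:
    """Rightward-minus-downward decoded time course per channel.

    Isolates direction-specific dynamics: any drift common to both saccade
    directions (e.g. an oblique anticipatory compromise) cancels.  Values
    are stored physically signed; the vertical channel is sign-flipped only
    at plot time.
    """
    return {
        "dX": decoded.mean["X_rwd"] - decoded.mean["X_dwd"],
        "dY": decoded.mean["Y_rwd"] - decoded.mean["Y_dwd"],
    }


@dataclass
class LagSweepResult:
    """Decoding results and sigmoid parameterizations for every target lag."""

    lags: np.ndarray
    table: pd.DataFrame
    decoded: Dict[float, DecodedEPS]
    fits_raw: Dict[float, SigmoidFit]
    fits_diff: Dict[float, SigmoidFit]
    targets: Dict[float, TargetEPS]


def lag_sweep(
    session: SpikeSession,
    lags: Optional[Sequence[float]] = None,
    gamma: float = 30.0,
    n_sets: int = 1000,
    seed: int = 0,
    tensor: Optional[RateTensor] = None,
    keep_sets: bool = False,
) -> LagSweepResult:
    """Run the full decode -> sigmoid-fit -> goodness-of-fit pipeline per lag.

    For each target lag: build the lagged target, cross-validate the
    decoder, fit the joint sigmoid to the raw mean output and to the
    direction-specific difference, and compute full and peri-saccadic R^2.
    Cross-validation substreams are derived per lag from ``seed``.
    """
    if lags is None:
        lags = np.arange(-400.0, 401.0, 100.0)
    lags = np.asarray(lags, dtype=float)
    if tensor is None:
        tensor = bin_rates(session)

    lag_seeds = np.random.SeedSequence([seed, 7]).generate_state(len(lags)) % (2**31 - 1)
    decoded: Dict[float, DecodedEPS] = {}
    fits_raw: Dict[float, SigmoidFit] = {}
    fits_diff: Dict[float, SigmoidFit] = {}
    targets: Dict[float, TargetEPS] = {}
    rows = []
    for lag, s in zip(lags, lag_seeds):
        target = make_target(lag, times=tensor.times)
        dec = cross_validate(
            session,
            target,
            gamma=gamma,
            n_sets=n_sets,
            seed=int(s),
            tensor=tensor,
            keep_sets=keep_sets,
        )
        raw = fit_sigmoid_joint(dec.mean["X_rwd"], dec.mean["Y_dwd"], dec.times)
        diff = direction_difference(dec)
        # dY rises (0 - (-A*Phi)); negate so it enters as the falling channel
        diff_fit = fit_sigmoid_joint(diff["dX"], -diff["dY"], dec.times)
        r2_full = r_squared(dec, target, window="full")
        r2_peri = r_squared(dec, target, window="perisaccadic")
        decoded[float(lag)] = dec
        fits_raw[float(lag)] = raw
        fits_diff[float(lag)] = diff_fit
        targets[float(lag)] = target
        rows.append(
            {
                "lag": lag,
                "mu": raw.mu,
                "sigma": raw.sigma,
                "achieved_lag": raw.achieved_lag,
                "duration_ms": raw.duration,
                "duration_ratio": raw.duration_ratio,
                "mu_diff": diff_fit.mu,
                "achieved_lag_diff": diff_fit.achieved_lag,
                "duration_ratio_diff": diff_fit.duration_ratio,
                "r2_full": r2_full,
                "r2_peri": r2_peri,
            }
        )
    return LagSweepResult(
        lags=lags,
        table=pd.DataFrame(rows),
        decoded=decoded,
        fits_raw=fits_raw,
        fits_diff=fits_diff,
        targets=targets,
    )
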