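"""How the read-out distributes labor across neurons.

A neuron's "pooling weight" is the average of the absolute values of its
mean (over cross-validation sets) weights onto the X and Y read-out
units, normalized so the pooling weights sum to one across the
population.  Only target lags that the decoder captured well
(peri-saccadic R^2 > 0.75) are summarized.  The histogram of pooling
weights probes sparseness (a bell-like shape means broad pooling); the
per-neuron modulation across lags and the cross-lag correlation of the
weight vectors quantify how much the read-out must change to shift the
represented signal in time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decode import DecodedEPS

#: peri-saccadic R^2 a lag must exceed to enter the weight summaries
ADMISSION_R2 = 0.75


class NoAdmissibleLagsError(ValueError):
    """No target lag passed the goodness-of-fit admission threshold."""


def admissible_lags(
    r2_peri: Dict[float, float], threshold: float = ADMISSION_R2
) -> List[float]:
    """Lags whose peri-saccadic R^2 exceeds ``threshold`` (sorted)."""
    return sorted(lag for lag, r2 in r2_peri.items() if r2 > threshold)


def pooling_weights(
    decoded_by_lag: Dict[float, DecodedEPS],
    r2_peri: Dict[float, float],
    threshold: float = ADMISSION_R2,
) -> pd.DataFrame:
    """Normalized per-neuron pooling weights for each admissible lag.

    Weights are first averaged over cross-validation sets (signed), then
    the per-neuron aggregate ``(|beta_X| + |beta_Y|) / 2`` is normalized
    to unit sum across the population.  Returns neurons x lags.
    """
    lags = admissible_lags(r2_peri, threshold)
    if not lags:
        raise NoAdmissibleLagsError(
            f"no lag has peri-saccadic R^2 > {threshold}"
        )
    cols = {}
    for lag in lags:
        dec = decoded_by_lag[lag]
        if dec.beta_X is None or dec.beta_Y is None:
            raise ValueError("DecodedEPS lacks stored per-set weights")
        mean_bx = dec.beta_X.mean(axis=0)
        mean_by = dec.beta_Y.mean(axis=0)
        agg = (np.abs(mean_bx) + np.abs(mean_by)) / 2.0
        total = agg.sum()
        if total == 0:
            raise ValueError(f"all-zero weights at lag {lag}")
        cols[lag] = agg / total
    return pd.DataFrame(cols)


def weight_histogram(
    pw: pd.DataFrame, bins: int = 20
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of pooling weights per lag; mean and SD of counts across lags.

    Fixed-width bins span [0, max weight] so every lag is binned on the
    same grid.  Returns ``(bin_edges, mean_counts, sd_counts)``.
    """
    top = float(pw.to_numpy().max())
    edges = np.linspace(0.0, top if top > 0 else 1.0, bins + 1)
    counts = np.stack(
        [np.histogram(pw[lag].to_numpy(), bins=edges)[0] for lag in pw.columns]
    )
    return edges, counts.mean(axis=0), counts.std(axis=0, ddof=0)


@dataclass
class ModulationSummary:
    per_neuron_pct: pd.Series
    mean_pct: float
    sem_pct: float
    excluded_neurons: List[int]


def weight_modulation(pw: pd.DataFrame) -> ModulationSummary:
    """Range of each neuron's contribution across lags, as % of its mean.

    ``100 * (max - min) / mean`` per neuron; zero-mean neurons are flagged
    and excluded from the population mean and its standard error.
    """
    if pw.shape[1] < 2:
        raise ValueError("need at least 2 admissible lags")
    vals = pw.to_numpy()
    means = vals.mean(axis=1)
    excluded = np.flatnonzero(means == 0)
    pct = np.full(len(means), np.nan)
    ok = means != 0
    pct[ok] = 100.0 * (vals[ok].max(axis=1) - vals[ok].min(axis=1)) / means[ok]
    series = pd.Series(pct, index=pw.index, name="modulation_pct")
    kept = series.dropna()
    return ModulationSummary(
        per_neuron_pct=series,
        mean_pct=float(kept.mean()),
        sem_pct=float(kept.std(ddof=1) / np.sqrt(len(kept))) if len(kept) > 1 else 0.0,
        excluded_neurons=excluded.tolist(),
    )


@dataclass
class ConsistencySummary:
    corr: pd.DataFrame
    mean_r: float
    sem_r: float
    skipped_pairs: List[Tuple[float, float]]


def weight_consistency(pw: pd.DataFrame) -> ConsistencySummary:
    """Pearson correlation of neuron-contribution vectors between lag pairs.

    Zero-variance vectors make a pair undefined; such pairs are skipped and
    reported.  The mean over the remaining unordered pairs and its standard
    error are returned.
    """
    if pw.shape[1] < 2:
        raise ValueError("need at least 2 admissible lags")
    if pw.shape[0] < 3:
        raise ValueError("need at least 3 neurons")
    lags = list(pw.columns)
    corr = pd.DataFrame(np.eye(len(lags)), index=lags, columns=lags)
    vals, skipped = [], []
    for i in range(len(lags)):
        for j in range(i + 1, len(lags)):
            a = pw[lags[i]].to_numpy()
            b = pw[lags[j]].to_numpy()
            if a.std() == 0 or b.std() == 0:
                corr.iloc[i, j] = corr.iloc[j, i] = np.nan
                skipped.append((lags[i], lags[j]))
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            corr.iloc[i, j] = corr.iloc[j, i] = r
            vals.append(r)
    vals = np.asarray(vals)
    return ConsistencySummary(
        corr=corr,
        mean_r=float(vals.mean()) if vals.size else np.nan,
        sem_r=float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
        skipped_pairs=skipped,
    )
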