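"""PCA of saccade-direction-specific population dynamics.

The differential time course of each neuron (downward-minus-rightward
trial-averaged rate) isolates the direction-dependent part of its
peri-saccadic modulation.  PCA of the resulting time x neuron matrix
yields a small set of canonical modulation shapes (broad enhancement or
suppression, biphasic modulation, sustained pre/post steps) ordered by
explained variance, with neuron-resampling bootstrap standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .rates import RateMatrices


@dataclass
class PCResult:
    components: np.ndarray          # time x k, unit-norm, mutually orthogonal
    scores: np.ndarray              # neuron x k projections
    variance_fraction: np.ndarray   # all components, non-increasing, sums to 1
    n_boot: int = 0
    boot_se: Optional[np.ndarray] = None  # time x k pointwise SE

    @property
    def k(self) -> int:
        return self.components.shape[1]


def differential_timecourses(R: RateMatrices) -> np.ndarray:
    """Downward-minus-rightward rate time course per neuron (time x neuron)."""
    return R.R_dwd - R.R_rwd


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> None:
    # convention: each component's largest-magnitude element is positive
    for j in range(components.shape[1]):
        if components[np.argmax(np.abs(components[:, j])), j] < 0:
            components[:, j] *= -1.0
            scores[:, j] *= -1.0


def pca(D: np.ndarray, k: int = 3, center: bool = True, standardize: bool = False) -> PCResult:
    """PCA of a time x neuron matrix; components are time courses.

    Each neuron column is mean-centered over time (and optionally z-scored)
    before a singular value decomposition.  The first ``k`` unit-norm
    component time courses and per-neuron scores are returned together with
    the variance fractions of *all* components.
    """
    D = np.asarray(D, dtype=float)
    n_times, n_neurons = D.shape
    if k > min(n_times, n_neurons):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(D.shape)}")
    Dc = D - D.mean(axis=0, keepdims=True) if center else D.copy()
    if standardize:
        sd = Dc.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Dc = Dc / sd
    U, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    components = U[:, :k]
    scores = (Vt[:k].T * s[:k])
    _fix_signs(components, scores)
    return PCResult(components=components, scores=scores, variance_fraction=frac)


def _align(ref: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Greedy matching of replicate components to reference by |correlation|.

    Returns the replicate's components permuted/sign-flipped onto the
    reference order (PCA component order and sign are arbitrary under
    resampling).
    """
    k = ref.shape[1]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            c = np.corrcoef(ref[:, i], comp[:, j])[0, 1]
            corr[i, j] = 0.0 if np.isnan(c) else c
    aligned = np.zeros_like(ref)
    free_ref, free_rep = set(range(k)), set(range(k))
    a = np.abs(corr)
    for _ in range(k):
        best, bi, bj = -1.0, None, None
        for i in free_ref:
            for j in free_rep:
                if a[i, j] > best:
                    best, bi, bj = a[i, j], i, j
        sign = 1.0 if corr[bi, bj] >= 0 else -1.0
        aligned[:, bi] = sign * comp[:, bj]
        free_ref.remove(bi)
        free_rep.remove(bj)
    return aligned


def bootstrap_pca(D: np.ndarray, k: int = 3, n_boot: int = 1000, seed: int = 0) -> PCResult:
    """PCA with pointwise standard errors from resampling neurons.

    Neuron columns are resampled with replacement ``n_boot`` times; each
    replicate's components are aligned to the full-sample components
    (greedy |correlation| matching with sign flip) and the pointwise SD
    across replicates is reported as ``boot_se``.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[1] < 2:
        raise ValueError("bootstrap requires at least 2 neurons")
    full = pca(D, k=k)
    rng = np.random.default_rng(seed)
    stack = np.empty((n_boot, D.shape[0], k))
    for b in range(n_boot):
        cols = rng.integers(0, D.shape[1], size=D.shape[1])
        rep = pca(D[:, cols], k=k)
        stack[b] = _align(full.components, rep.components)
    return PCResult(
        components=full.components,
        scores=full.scores,
        variance_fraction=full.variance_fraction,
        n_boot=n_boot,
        boot_se=stack.std(axis=0, ddof=0),
    )
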