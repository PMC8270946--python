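"""Surrogate-based significance, FDR, rank-sum comparisons and ROC analysis.

The null model for decoding significance is the phase-randomized
surrogate: every region keeps its amplitude spectrum, but each positive
frequency bin receives one uniform phase shift shared by all regions
(negative frequencies mirror it so the inverse transform stays real, and
the DC component is untouched). This destroys the time-locked coupling
structure while preserving the autocorrelation introduced by band-pass
filtering, so it tests exactly whether manifold clustering reflects real
synchrony rather than filtering artefacts.

The Monte-Carlo p-value of an observed accuracy a against N_perm
surrogate accuracies is

    p = (#{i : a < a_perm_i} + 1) / (N_perm + 1),

with ties counting in favour of the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datatypes import ManifoldEmbedding, ParcellatedTimeseries


def phase_randomized_surrogate(
    ts: ParcellatedTimeseries, seed: int | np.random.Generator
) -> ParcellatedTimeseries:
    """Phase-randomized surrogate with a common shift across regions.

    Works on the real FFT: bin k > 0 is rotated by phi_k ~ Uniform(0, 2pi)
    identically for every region; for even-length series the Nyquist bin
    (which must remain real) receives a random sign flip instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = ts.n_trs
    spec = np.fft.rfft(ts.data, axis=1)
    n_bins = spec.shape[1]
    rot = np.ones(n_bins, dtype=complex)
    even = T % 2 == 0
    top = n_bins - 1 if even else n_bins
    rot[1:top] = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, size=top - 1))
    if even:
        rot[-1] = rng.choice([-1.0, 1.0])
    surr = np.fft.irfft(spec * rot[None, :], n=T, axis=1)
    return ParcellatedTimeseries(
        data=surr,
        tr_seconds=ts.tr_seconds,
        region_ids=list(ts.region_ids),
        band=ts.band,
    )


def monte_carlo_pvalue(a: float, a_perm: np.ndarray) -> float:
    """Permutation p-value; ties (a >= a_perm) do not count against a."""
    ens = np.asarray(a_perm, dtype=float)
    if ens.size == 0:
        raise ValueError("surrogate ensemble is empty")
    return (np.count_nonzero(a < ens) + 1) / (ens.size + 1)


def fdr_correct(
    pvalues: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, rejection flags at ``alpha``).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for samples of at most 10 without ties; otherwise the normal
    approximation with tie correction. Two identical constant samples
    yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass
class ROCResult:
    """Threshold-sweep ROC curve along one embedding dimension."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    dimension_index: int = 0
    flipped: bool = False  # True if scores were negated to make AUC >= 0.5


def roc_curve(
    scores: np.ndarray, labels: np.ndarray, direction: str = "auto"
) -> ROCResult:
    """ROC by exhaustive threshold sweep along a scalar score.

    Thresholds are all midpoints between consecutive sorted unique scores
    plus -inf/+inf; a point is called positive when score >= threshold.
    With ``direction="auto"`` the score orientation giving AUC >= 0.5 is
    chosen and recorded in ``flipped``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    def sweep(sc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        uniq = np.unique(sc)
        mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
        # descending thresholds: predictions (score >= threshold) accumulate,
        # so tpr and fpr are non-decreasing by construction
        thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
        pred = sc[None, :] >= thresholds[:, None]
        tpr = (pred & y[None, :]).sum(axis=1) / n_pos
        fpr = (pred & ~y[None, :]).sum(axis=1) / n_neg
        auc = float(np.trapezoid(tpr, fpr))
        return thresholds, tpr, fpr, auc

    thresholds, tpr, fpr, auc = sweep(s)
    flipped = False
    if direction == "auto" and auc < 0.5:
        thresholds, tpr, fpr, auc = sweep(-s)
        flipped = True
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, flipped=flipped)


def best_dimension_roc(
    embedding: ManifoldEmbedding | np.ndarray,
    labels: np.ndarray,
    stage_a: str,
    stage_b: str,
    dims_to_scan: int = 3,
) -> ROCResult:
    """ROC per embedding dimension; the max-AUC dimension wins (lowest-index
    tie-break). ``dimension_index`` is 1-based, matching "dimension 1..d"."""
    coords = embedding.coords if isinstance(embedding, ManifoldEmbedding) else np.asarray(embedding)
    if dims_to_scan > coords.shape[1]:
        raise ValueError("dims_to_scan exceeds the embedding dimension")
    labels = np.asarray(labels, dtype=object)
    mask = (labels == stage_a) | (labels == stage_b)
    if not mask.any():
        raise ValueError("neither stage present in labels")
    y = labels[mask] == stage_a
    best: ROCResult | None = None
    for dim in range(dims_to_scan):
        res = roc_curve(coords[mask, dim], y)
        res.dimension_index = dim + 1
        if best is None or res.auc > best.auc:
            best = res
    assert best is not None
    return best


@dataclass
class SignificanceResult:
    """Observed accuracy vs a surrogate null ensemble."""

    accuracy: float
    surrogate_accuracies: np.ndarray
    pvalue: float
    qvalue: float | None = None
    n_perm: int = 0

    def __post_init__(self) -> None:
        self.surrogate_accuracies = np.asarray(self.surrogate_accuracies, dtype=float)
        self.n_perm = int(self.surrogate_accuracies.size)


def significance_from_ensemble(
    accuracy: float, surrogate_accuracies: np.ndarray
) -> SignificanceResult:
    p = monte_carlo_pvalue(accuracy, surrogate_accuracies)
    return SignificanceResult(
        accuracy=accuracy, surrogate_accuracies=surrogate_accuracies, pvalue=p
    )
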