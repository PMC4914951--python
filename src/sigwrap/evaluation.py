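"""Quality metrics for feature selections and PLS-DA model significance.

Stability follows the resampled-signature protocol: the dataset is split
into 10 overlapping subsets, each holding 90% of the samples (complements
of a seeded stratified 10-fold partition), the selector runs on each, and
stability is the mean chance-adjusted Lustgarten similarity over the 45
signature pairs.  The accuracy/stability trade-off ("performance") is their
harmonic mean.

Model-level significance of a PLS-DA fit uses response permutation: the
full fit (including automatic component selection) is repeated on permuted
class labels and the p-value is the proportion of permuted cumulative Q2Y
values reaching the observed one (ties count, the conservative reading).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import BinaryLabels, FeatureTable, SelectionConfig
from .pls import fit_plsda

__all__ = [
    "StabilityReport",
    "PermutationTestResult",
    "lustgarten_similarity",
    "harmonic_performance",
    "signature_stability",
    "q2y_permutation_test",
]


@dataclass
class StabilityReport:
    signatures: list[tuple[str, ...]]
    similarity: np.ndarray            # n_subsets x n_subsets, diagonal 1
    stability: float                  # mean of the strict upper triangle
    accuracy: float | None = None
    performance: float | None = None


@dataclass
class PermutationTestResult:
    q2y: float
    r2y_cum: float
    q2y_perm: np.ndarray
    p_value: float
    n_perm: int


def lustgarten_similarity(
    a: Sequence[str], b: Sequence[str], p: int
) -> float:
    """Chance-adjusted similarity of two feature sets from a p-feature universe.

    S(a, b) = (|a & b| - |a||b|/p) / (min(|a|, |b|) - max(0, |a| + |b| - p)).
    Values lie in [-1, 1]; 0 when either set is empty or the denominator
    vanishes (both sets full or degenerate).
    """
    if p <= 0:
        raise ValueError("the feature universe must be non-empty")
    sa, sb = set(a), set(b)
    if not sa or not sb:
        return 0.0
    inter = len(sa & sb)
    expected = len(sa) * len(sb) / p
    denom = min(len(sa), len(sb)) - max(0, len(sa) + len(sb) - p)
    if denom == 0:
        return 0.0
    return (inter - expected) / denom


def harmonic_performance(accuracy: float, stability: float) -> float:
    """Harmonic mean of accuracy and stability; 0 when the sum vanishes."""
    s = accuracy + stability
    if s == 0:
        return 0.0
    return 2.0 * accuracy * stability / s


def _stratified_fold_assignment(
    y01: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    fold = np.empty(len(y01), dtype=int)
    offset = 0
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y01 == cls))
        for pos, i in enumerate(idx):
            fold[i] = (offset + pos) % k
        offset += len(idx)
    return fold


def signature_stability(
    table: FeatureTable,
    labels: BinaryLabels,
    selector: Callable[[FeatureTable, BinaryLabels, int], Sequence[str]],
    config: SelectionConfig,
    n_subsets: int = 10,
    accuracy: float | None = None,
) -> StabilityReport:
    """Stability of ``selector`` over 90%-sample subsets.

    ``selector(table, labels, seed)`` returns a feature id collection.  The
    subsets are the complements of a seeded stratified ``n_subsets``-fold
    partition, so each holds (1 - 1/n_subsets) of the samples with both
    classes present.  When ``accuracy`` is given, the report also carries
    the harmonic-mean performance.
    """
    if table.n < n_subsets:
        raise ValueError(f"need at least {n_subsets} samples")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    fold = _stratified_fold_assignment(labels.as_binary(), n_subsets, rng)
    signatures: list[tuple[str, ...]] = []
    for f in range(n_subsets):
        keep = np.flatnonzero(fold != f)
        sub_t = table.take_samples(keep)
        sub_l = labels.take(keep)
        sig = tuple(selector(sub_t, sub_l, int(rng.integers(2**31 - 1))))
        signatures.append(sig)
    m = len(signatures)
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = lustgarten_similarity(
                signatures[i], signatures[j], table.p
            )
    upper = sim[np.triu_indices(m, k=1)]
    stability = float(upper.mean())
    perf = None if accuracy is None else harmonic_performance(accuracy, stability)
    return StabilityReport(
        signatures=signatures,
        similarity=sim,
        stability=stability,
        accuracy=accuracy,
        performance=perf,
    )


def q2y_permutation_test(
    table: FeatureTable,
    labels: BinaryLabels,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Response-permutation significance of the PLS-DA cumulative Q2Y."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    model = fit_plsda(table, labels, seed=int(rng.integers(2**31 - 1)))
    observed = model.q2y_cum
    r2y_cum = float(np.sum(model.r2y)) if model.informative else float(model.r2y[0])
    perms = np.empty(n_perm)
    label_arr = np.asarray(labels.labels)
    for i in range(n_perm):
        shuffled = label_arr[rng.permutation(labels.n)]
        perm_labels = BinaryLabels(tuple(shuffled), positive_level=labels.positive_level)
        perm_model = fit_plsda(table, perm_labels, seed=int(rng.integers(2**31 - 1)))
        perms[i] = perm_model.q2y_cum
    p_value = float(np.mean(perms >= observed))
    return PermutationTestResult(
        q2y=observed, r2y_cum=r2y_cum, q2y_perm=perms, p_value=p_value, n_perm=n_perm
    )
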