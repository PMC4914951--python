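"""Synthetic and semi-synthetic datasets with known ground truth.

``generate_planted`` draws Gaussian log-intensity-like feature tables with
a controllable number of class-discriminant features at a stated
standardized effect size, optionally with an equicorrelated feature block
(shared latent factor).  ``spike_semisynthetic`` implements the spiking
construction: purge every univariately significant feature from a base
table, then amplify a single surviving feature in one class by the largest
factor that keeps it undetected by univariate testing at the given FDR —
producing a target only a multivariate selector should find.
``sensitivity_specificity`` scores repeated selection runs against the
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import BinaryLabels, FeatureTable
from .selection import TierTable

__all__ = [
    "PlantedSpec",
    "SpikeSpec",
    "generate_planted",
    "spike_semisynthetic",
    "sensitivity_specificity",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for a planted-signal table.

    n_per_class
        Samples in each of the two balanced classes.
    p
        Total number of features.
    n_informative
        Number of class-discriminant features (the first ones unless
        ``informative_ids`` is given).
    effect
        Standardized mean shift d: informative features are raised by
        d * sd in the positive class.
    sd
        Within-class standard deviation of every feature.
    rho
        Equicorrelation of the leading ``corr_block`` features (shared
        latent factor); 0 disables it.
    baseline
        Common mean added to every feature (useful when downstream steps
        expect positive intensities).
    """

    n_per_class: int
    p: int
    n_informative: int = 0
    informative_ids: tuple[int, ...] | None = None
    effect: float = 0.0
    sd: float = 1.0
    rho: float = 0.0
    corr_block: int = 0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2 or self.p < 1:
            raise ValueError("need n_per_class >= 2 and p >= 1")
        if self.effect < 0 or self.sd <= 0:
            raise ValueError("effect must be >= 0 and sd > 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        ids = self.informative_ids
        if ids is None:
            ids = tuple(range(self.n_informative))
        ids = tuple(int(i) for i in ids)
        if any(i < 0 or i >= self.p for i in ids):
            raise ValueError("informative ids out of range")
        object.__setattr__(self, "informative_ids", ids)
        object.__setattr__(self, "n_informative", len(ids))


def generate_planted(
    spec: PlantedSpec,
) -> tuple[FeatureTable, BinaryLabels, tuple[str, ...]]:
    """Draw a planted-signal dataset; a pure function of the spec."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    values = rng.normal(0.0, 1.0, size=(n, spec.p))
    if spec.corr_block > 1 and spec.rho > 0:
        b = min(spec.corr_block, spec.p)
        z = rng.normal(0.0, 1.0, size=n)
        values[:, :b] = np.sqrt(spec.rho) * z[:, None] + np.sqrt(1 - spec.rho) * values[:, :b]
    values = spec.baseline + spec.sd * values
    y01 = np.repeat([0, 1], spec.n_per_class)
    for j in spec.informative_ids:
        values[y01 == 1, j] += spec.effect * spec.sd
    width = len(str(spec.p))
    feature_ids = tuple(f"f{j + 1:0{width}d}" for j in range(spec.p))
    sample_ids = tuple(f"s{i + 1:03d}" for i in range(n))
    labels = BinaryLabels(
        tuple("class1" if c else "class0" for c in y01), positive_level="class1"
    )
    table = FeatureTable(values, sample_ids, feature_ids)
    truth = tuple(feature_ids[j] for j in spec.informative_ids)
    return table, labels, truth


@dataclass(frozen=True)
class SpikeSpec:
    """Recipe for the semi-synthetic spiking construction."""

    table: FeatureTable
    labels: BinaryLabels
    fdr: float = 0.05
    target: str | None = None
    factor_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")
        if self.factor_max <= 1.0:
            raise ValueError("factor_max must exceed 1")


def _bh_adjusted(table: FeatureTable, labels: BinaryLabels) -> np.ndarray:
    """BH-adjusted two-sided Wilcoxon rank-sum p-values, one per feature."""
    y01 = labels.as_binary()
    a = table.values[y01 == 1]
    b = table.values[y01 == 0]
    pvals = np.empty(table.p)
    for j in range(table.p):
        if np.ptp(table.values[:, j]) == 0.0:
            pvals[j] = 1.0
            continue
        pvals[j] = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
    return stats.false_discovery_control(pvals, method="bh")


def _with_target_scaled(
    table: FeatureTable, y01: np.ndarray, col: int, factor: float
) -> FeatureTable:
    values = table.values.copy()
    values[y01 == 1, col] *= factor
    return FeatureTable(values, table.sample_ids, table.feature_ids)


def spike_semisynthetic(
    spec: SpikeSpec,
) -> tuple[FeatureTable, BinaryLabels, str, float]:
    """Build a table whose only class signal is a sub-detection-limit spike.

    Steps: (i) drop every feature significant by rank-sum testing at
    BH-FDR <= ``spec.fdr``; (ii) pick a surviving target; (iii) bisect the
    largest factor in (1, factor_max] such that multiplying the target's
    intensities in the positive class leaves its BH-adjusted p-value above
    the FDR level; apply it.  Returns (table, labels, target id, factor).
    """
    table, labels = spec.table, spec.labels
    adj = _bh_adjusted(table, labels)
    survivors = [table.feature_ids[j] for j in range(table.p) if adj[j] > spec.fdr]
    if len(survivors) < 10:
        raise ValueError(
            f"only {len(survivors)} features survive the significance purge; "
            "need at least 10"
        )
    from .core import restrict_features

    purged = restrict_features(table, survivors)
    rng = np.random.default_rng(spec.seed)
    if spec.target is None:
        target = survivors[int(rng.integers(len(survivors)))]
    else:
        target = str(spec.target)
        if target not in survivors:
            raise ValueError(f"target {target!r} did not survive the purge")
    col = purged.feature_ids.index(target)
    y01 = labels.as_binary()

    def undetected(factor: float) -> bool:
        scaled = _with_target_scaled(purged, y01, col, factor)
        return _bh_adjusted(scaled, labels)[col] > spec.fdr

    lo, hi = 1.0, spec.factor_max
    if undetected(hi):
        factor = hi
    else:
        if not undetected(1.0 + 1e-9):
            raise ValueError(
                f"no admissible factor > 1 for target {target!r}; "
                "try a different target"
            )
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if undetected(mid):
                lo = mid
            else:
                hi = mid
        factor = lo
    spiked = _with_target_scaled(purged, y01, col, factor)
    return spiked, labels, target, factor


def sensitivity_specificity(
    runs: Sequence[TierTable], truth_ids: Sequence[str]
) -> tuple[float, float]:
    """Score repeated selection runs against known informative features.

    Sensitivity: fraction of runs in which *every* truth feature appears in
    the union of the classifiers' S signatures.  Specificity: one minus the
    mean fraction of non-truth features entering that union, averaged over
    runs.
    """
    if not runs:
        raise ValueError("need at least one run")
    truth = set(truth_ids)
    hits = 0
    false_fracs = []
    for run in runs:
        union = set(run.signature_union())
        if truth and truth <= union:
            hits += 1
        non_truth = [f for f in run.feature_ids if f not in truth]
        if non_truth:
            false_fracs.append(len(union - truth) / len(non_truth))
        else:
            false_fracs.append(0.0)
    sensitivity = hits / len(runs)
    specificity = 1.0 - float(np.mean(false_fracs))
    return sensitivity, specificity
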