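"""Comparator selectors: VIP filtering and recursive feature elimination.

Both reuse the same classifiers, ranking metrics and bootstrap/OOB
machinery as the main selection engine, so differences in selected sets
reflect the selection strategies, not the models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifiers import rank_features
from .core import BinaryLabels, FeatureTable, SelectionConfig, restrict_features
from .pls import fit_plsda, vip
from .selection import _fit_bootstraps, aggregate_ranks

__all__ = ["RfeTrace", "vip_filter", "rfe_size_schedule", "rfe_select"]


@dataclass
class RfeTrace:
    """Accuracy trajectory of recursive feature elimination.

    ``sizes`` decrease strictly to 1; ``selected_ids`` is the surviving set
    at the size with the best mean OOB balanced accuracy (ties favour the
    smaller size)."""

    sizes: list[int]
    accuracies: list[float]
    feature_sets: list[tuple[str, ...]]
    selected_size: int
    selected_ids: tuple[str, ...]


def vip_filter(
    table: FeatureTable,
    labels: BinaryLabels,
    threshold: float = 1.0,
    seed: int = 0,
) -> tuple[str, ...]:
    """Keep the features whose PLS-DA VIP reaches ``threshold`` (>=).

    The documented presets are 1 and 1.5.  A non-informative PLS model (no
    admissible component) yields an empty selection with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    model = fit_plsda(table, labels, seed=seed)
    if not model.informative:
        warnings.warn(
            "PLS-DA model is non-informative (no admissible component); "
            "VIP filter returns no features",
            stacklevel=2,
        )
        return ()
    v = vip(model)
    return tuple(f for f, x in zip(table.feature_ids, v) if x >= threshold)


def rfe_size_schedule(p: int) -> list[int]:
    """Feature-set sizes visited by RFE: drop max(1, floor(0.2 p)) per step."""
    if p < 1:
        raise ValueError("p must be >= 1")
    sizes = [p]
    while sizes[-1] > 1:
        drop = max(1, int(np.floor(0.2 * sizes[-1])))
        sizes.append(sizes[-1] - drop)
    return sizes


def rfe_select(
    table: FeatureTable,
    labels: BinaryLabels,
    method: str,
    config: SelectionConfig,
) -> RfeTrace:
    """Recursive feature elimination with bootstrap evaluation.

    At each size: fit ``config.boot`` bootstrap models on the surviving
    features, record the mean OOB balanced accuracy, aggregate the
    per-bootstrap ranks by the median, and drop the worst-ranked 20%
    (at least one feature).  Bootstraps are redrawn at every iteration.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    current = table.feature_ids
    sizes: list[int] = []
    accuracies: list[float] = []
    feature_sets: list[tuple[str, ...]] = []
    while True:
        sub = restrict_features(table, current)
        fits = _fit_bootstraps(sub, labels, method, config, rng)
        acc = float(np.mean([f.accuracy for f in fits]))
        sizes.append(sub.p)
        accuracies.append(acc)
        feature_sets.append(current)
        if sub.p == 1:
            break
        final_ranks = aggregate_ranks(np.vstack([f.ranks for f in fits]))
        drop = max(1, int(np.floor(0.2 * sub.p)))
        order = np.argsort(final_ranks)  # best first
        current = tuple(sub.feature_ids[j] for j in order[: sub.p - drop])
    # best mean accuracy; ties -> smallest size (scan from the end)
    best = len(sizes) - 1
    for i in range(len(sizes) - 2, -1, -1):
        if accuracies[i] > accuracies[best]:
            best = i
    return RfeTrace(
        sizes=sizes,
        accuracies=accuracies,
        feature_sets=feature_sets,
        selected_size=sizes[best],
        selected_ids=feature_sets[best],
    )
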