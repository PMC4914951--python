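"""Signature selection by bootstrap, rank aggregation, permutation
significance and half-interval search.

One selection *round* consists of three steps:

1. *Resampling* — ``boot`` stratified bootstrap resamples; each trains a
   classifier, which is evaluated on its out-of-bag (OOB) samples by
   balanced accuracy.  No further model is ever fitted in the round.
2. *Ranking* — per-bootstrap feature ranks are aggregated by the median and
   re-ranked into a final rank vector (1 = most important).
3. *Significance of ranked tails* — the tail subset S_f = {features with
   rank >= rank(f)} is declared significant when permuting its intensities
   in the OOB sets degrades the accuracy in more than (1 - alpha) of the
   bootstraps.  A half-interval search over rank positions finds the
   boundary rank f_ns: the most important feature whose tail is *not*
   significant.

The dataset is restricted to the significant head (rank < f_ns) and the
round repeats until a round finds its whole incoming feature set
significant (that set is the signature S) or until no feature survives
(S is empty).  When a round finds nothing significant, the dataset is
halved to the most important features, which are *not* registered as
significant.  Features discarded on the way out are graded into tiers A
(last round) through E (everything earlier).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classifiers import TrainedClassifier, fit_classifier, metric_to_ranks, rank_features
from .core import (
    BinaryLabels,
    FeatureTable,
    SelectionConfig,
    restrict_features,
    validate_dataset,
)

__all__ = [
    "BootstrapSplit",
    "BootstrapFit",
    "SearchStep",
    "RoundResult",
    "MethodResult",
    "TierTable",
    "bootstrap_splits",
    "balanced_accuracy",
    "aggregate_ranks",
    "permute_subset",
    "subset_significance",
    "half_interval_core",
    "half_interval_search",
    "selection_round",
    "run_selection",
    "run_all",
]

logger = logging.getLogger(__name__)

TIER_LETTERS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class BootstrapSplit:
    """Stratified bootstrap resample: in-bag (train) and out-of-bag (test)
    sample indices.  Train has exactly n draws with replacement, stratified
    within class; test is every sample absent from train and always
    contains both classes."""

    train: np.ndarray
    test: np.ndarray


@dataclass
class BootstrapFit:
    """One trained bootstrap model with its OOB evaluation material."""

    split: BootstrapSplit
    model: TrainedClassifier
    ranks: np.ndarray
    accuracy: float
    test_values: np.ndarray      # OOB rows, training feature order
    test_truth: tuple[str, ...]  # OOB class labels


@dataclass(frozen=True)
class SearchStep:
    """One probe of the half-interval search."""

    candidate_rank: int
    proportion: float
    significant: bool


@dataclass
class RoundResult:
    significant_ids: tuple[str, ...]
    registered: bool
    fits: list[BootstrapFit]
    final_ranks: np.ndarray
    trace: list[SearchStep]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.fits]))


@dataclass
class RoundRecord:
    feature_ids: tuple[str, ...]
    registered: bool
    significant_ids: tuple[str, ...]
    discarded_ids: tuple[str, ...]
    mean_accuracy: float
    trace: list[SearchStep]


@dataclass
class MethodResult:
    """Outcome of the full iterative selection for one classifier."""

    method: str
    signature: tuple[str, ...]            # tier S, ordered by final rank
    tiers: dict[str, str]                 # feature id -> tier letter (S, A..E)
    converged: bool
    rounds: list[RoundRecord]
    accuracies: dict[str, float | None]   # "full" / "S" / "AS" mean OOB accuracy
    final_model: TrainedClassifier | None

    @property
    def signature_with_a(self) -> tuple[str, ...]:
        extra = tuple(f for f, t in self.tiers.items() if t == "A")
        return self.signature + extra


@dataclass
class TierTable:
    """Merged per-method tier assignments and final models."""

    feature_ids: tuple[str, ...]
    results: dict[str, MethodResult]
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(self.results)

    def tier(self, method: str, feature_id: str) -> str:
        return self.results[method].tiers.get(feature_id, "-")

    def signature_union(self) -> tuple[str, ...]:
        union = set()
        for res in self.results.values():
            union.update(res.signature)
        return tuple(f for f in self.feature_ids if f in union)

    def signature_intersection(self) -> tuple[str, ...]:
        sets = [set(res.signature) for res in self.results.values()]
        if not sets:
            return ()
        inter = set.intersection(*sets)
        return tuple(f for f in self.feature_ids if f in inter)


# ---------------------------------------------------------------------------
# step 1: resampling


def bootstrap_splits(
    labels: BinaryLabels,
    boot: int,
    seed: int | np.random.Generator,
    max_retries: int = 100,
) -> list[BootstrapSplit]:
    """Draw ``boot`` stratified bootstrap train/OOB splits.

    A draw whose OOB set is empty or single-class is redrawn (bounded
    retries) since balanced accuracy is undefined there.
    """
    if boot < 2:
        raise ValueError("boot must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y01 = labels.as_binary()
    class_idx = [np.flatnonzero(y01 == c) for c in (0, 1)]
    n = labels.n
    splits: list[BootstrapSplit] = []
    for _ in range(boot):
        for attempt in range(max_retries + 1):
            train = np.concatenate(
                [rng.choice(idx, size=len(idx), replace=True) for idx in class_idx]
            )
            test = np.setdiff1d(np.arange(n), train)
            if len(test) > 0 and len(set(y01[test])) == 2:
                break
        else:
            raise RuntimeError(
                f"could not draw a two-class out-of-bag set in {max_retries} tries; "
                "the dataset is too small or too imbalanced"
            )
        splits.append(BootstrapSplit(train=train, test=test))
    return splits


def balanced_accuracy(
    truth: Sequence[str], predicted: Sequence[str], positive_level: str
) -> float:
    """(sensitivity + specificity) / 2; robust to class imbalance."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    if len(truth) == 0:
        raise ValueError("empty truth vector")
    pos = [t == positive_level for t in truth]
    n_pos = sum(pos)
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both classes")
    tp = sum(1 for t, pr, is_p in zip(truth, predicted, pos) if is_p and pr == t)
    tn = sum(1 for t, pr, is_p in zip(truth, predicted, pos) if not is_p and pr == t)
    return 0.5 * (tp / n_pos + tn / n_neg)


# ---------------------------------------------------------------------------
# step 2: rank aggregation


def aggregate_ranks(rank_matrix: np.ndarray) -> np.ndarray:
    """Median-aggregate per-bootstrap ranks into a final rank permutation.

    Per-feature medians are re-ranked; median ties break by mean rank,
    then by feature index.
    """
    rank_matrix = np.asarray(rank_matrix, dtype=float)
    if rank_matrix.ndim != 2:
        raise ValueError("rank matrix must be 2-dimensional (boot x p)")
    medians = np.median(rank_matrix, axis=0)
    means = rank_matrix.mean(axis=0)
    p = rank_matrix.shape[1]
    order = np.lexsort((np.arange(p), means, medians))
    final = np.empty(p, dtype=int)
    final[order] = np.arange(1, p + 1)
    return final


# ---------------------------------------------------------------------------
# step 3: permutation significance and half-interval search


def permute_subset(
    test: FeatureTable, subset: Sequence[str], rng: np.random.Generator
) -> FeatureTable:
    """Independently shuffle each subset feature's values across the test
    samples; features outside the subset are untouched."""
    values = test.values.copy()
    index = {f: j for j, f in enumerate(test.feature_ids)}
    for fid in subset:
        j = index[str(fid)]
        values[:, j] = values[rng.permutation(test.n), j]
    return FeatureTable(values, test.sample_ids, test.feature_ids)


def _permuted_values(
    values: np.ndarray, cols: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = values.copy()
    n = values.shape[0]
    for j in cols:
        out[:, j] = out[rng.permutation(n), j]
    return out


def subset_significance(
    fits: Sequence[BootstrapFit],
    subset: Sequence[str],
    alpha: float,
    rng: np.random.Generator,
    positive_level: str,
) -> tuple[bool, float]:
    """Permutation test of one feature subset across all bootstraps.

    For each bootstrap the subset's intensities are freshly permuted in the
    OOB set and the stored model re-predicts (no refitting).  The subset is
    *not* significant when the proportion of bootstraps with
    accuracy_perm >= accuracy exceeds ``alpha`` (strict), i.e. significant
    iff proportion <= alpha.
    """
    if not fits:
        raise ValueError("no bootstrap fits")
    feature_ids = fits[0].model.feature_ids
    index = {f: j for j, f in enumerate(feature_ids)}
    cols = np.array([index[str(f)] for f in subset], dtype=int)
    non_drop = 0
    for fit in fits:
        perm = _permuted_values(fit.test_values, cols, rng)
        pred = fit.model.predict_values(perm)
        acc_perm = balanced_accuracy(fit.test_truth, pred, positive_level)
        if acc_perm >= fit.accuracy:
            non_drop += 1
    proportion = non_drop / len(fits)
    return proportion <= alpha, proportion


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def half_interval_core(
    p: int, test_rank: Callable[[int], tuple[bool, float]]
) -> tuple[int, list[SearchStep]]:
    """Half-interval search for the boundary rank f_ns.

    ``test_rank(r)`` reports whether the tail subset {rank >= r} is
    significant.  The first candidate is rank 1 (permute everything); when
    the tail at rank f is significant the search moves toward
    less-important features (midpoint of f and l), otherwise toward
    more-important ones (midpoint of h and f), with h / l the last
    significant / non-significant candidates (sentinels 0 and p+1).
    Midpoints round half away from zero and clamp to the open interval
    (h, l).  Returns (f_ns, trace); f_ns = p + 1 means every tail tested
    significant.
    """
    if p < 1:
        raise ValueError("need at least one rank position")
    h, l = 0, p + 1
    trace: list[SearchStep] = []
    candidate = 1  # first probe permutes the full feature set
    while h + 1 < l:
        significant, proportion = test_rank(candidate)
        trace.append(SearchStep(candidate, proportion, significant))
        if significant:
            h = candidate
        else:
            l = candidate
        candidate = _round_half_away((h + l) / 2.0)
        candidate = min(max(candidate, h + 1), l - 1)
    return l, trace


def half_interval_search(
    fits: Sequence[BootstrapFit],
    final_ranks: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    positive_level: str,
) -> tuple[tuple[str, ...], list[SearchStep]]:
    """Run the search on real bootstrap fits.

    Returns the round's significant feature set — the features with rank
    strictly below the boundary f_ns, ordered by rank — and the search
    trace.  The set is empty when even the full-set permutation does not
    degrade accuracy.
    """
    feature_ids = fits[0].model.feature_ids
    final_ranks = np.asarray(final_ranks)
    p = len(feature_ids)
    order = np.argsort(final_ranks)  # feature indices by increasing rank

    def test_rank(r: int) -> tuple[bool, float]:
        tail = [feature_ids[j] for j in order[r - 1 :]]
        significant, proportion = subset_significance(
            fits, tail, alpha, rng, positive_level
        )
        logger.info(
            "  candidate rank %d (|S_f|=%d): proportion=%.4f -> %s",
            r,
            len(tail),
            proportion,
            "significant" if significant else "not significant",
        )
        return significant, proportion

    f_ns, trace = half_interval_core(p, test_rank)
    selected = tuple(feature_ids[j] for j in order[: f_ns - 1])
    return selected, trace


# ---------------------------------------------------------------------------
# one round, the iterative engine, and the multi-method wrapper


def _fit_bootstraps(
    table: FeatureTable,
    labels: BinaryLabels,
    method: str,
    config: SelectionConfig,
    rng: np.random.Generator,
) -> list[BootstrapFit]:
    splits = bootstrap_splits(labels, config.boot, rng)
    fits: list[BootstrapFit] = []
    for split in splits:
        train_t = table.take_samples(split.train)
        train_l = labels.take(split.train)
        model = fit_classifier(
            method,
            train_t,
            train_l,
            seed=int(rng.integers(2**31 - 1)),
            n_trees=config.n_trees,
            svm_cost=config.svm_cost,
        )
        test_values = table.values[split.test]
        test_truth = tuple(labels.labels[i] for i in split.test)
        pred = model.predict_values(test_values)
        acc = balanced_accuracy(test_truth, pred, labels.positive_level)
        fits.append(
            BootstrapFit(
                split=split,
                model=model,
                ranks=rank_features(model),
                accuracy=acc,
                test_values=test_values,
                test_truth=test_truth,
            )
        )
    return fits


def selection_round(
    table: FeatureTable,
    labels: BinaryLabels,
    method: str,
    config: SelectionConfig,
    rng: np.random.Generator,
) -> RoundResult:
    """One pass of steps 1-3 on the current feature set.

    When nothing is significant, the ceil(p/2) most important features are
    returned unregistered (the backward halving of the search space).
    """
    if table.p < 1:
        raise ValueError("selection round needs at least one feature")
    fits = _fit_bootstraps(table, labels, method, config, rng)
    rank_matrix = np.vstack([f.ranks for f in fits])
    final_ranks = aggregate_ranks(rank_matrix)
    significant, trace = half_interval_search(
        fits, final_ranks, config.alpha, rng, labels.positive_level
    )
    if significant:
        return RoundResult(significant, True, fits, final_ranks, trace)
    keep = int(np.ceil(table.p / 2))
    order = np.argsort(final_ranks)
    half = tuple(table.feature_ids[j] for j in order[:keep])
    return RoundResult(half, False, fits, final_ranks, trace)


def _mean_oob_accuracy(
    table: FeatureTable,
    labels: BinaryLabels,
    method: str,
    config: SelectionConfig,
    rng: np.random.Generator,
) -> float:
    """Mean OOB balanced accuracy over ``config.boot`` fresh bootstraps."""
    fits = _fit_bootstraps(table, labels, method, config, rng)
    return float(np.mean([f.accuracy for f in fits]))


def _assign_tiers(
    signature: Sequence[str], discards: Sequence[Sequence[str]]
) -> dict[str, str]:
    tiers = {f: "S" for f in signature}
    for age, discarded in enumerate(reversed(discards)):
        letter = TIER_LETTERS[min(age, len(TIER_LETTERS) - 1)]
        for f in discarded:
            tiers[f] = letter
    return tiers


def run_selection(
    table: FeatureTable,
    labels: BinaryLabels,
    method: str,
    config: SelectionConfig,
) -> MethodResult:
    """Iterate selection rounds to convergence for one classifier.

    Convergence: a round registers its whole incoming feature set as
    significant (that set is the signature S) or the candidate set empties
    (S is empty).  A non-significant single remaining feature terminates
    with an empty signature.  ``config.max_rounds`` is a safety net only.
    """
    table, labels = validate_dataset(table, labels)
    method_index = {"plsda": 0, "rf": 1, "svm": 2}[method]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, method_index]))

    current = table.feature_ids
    discards: list[tuple[str, ...]] = []
    records: list[RoundRecord] = []
    converged = False
    signature: tuple[str, ...] = ()

    for round_no in range(1, config.max_rounds + 1):
        sub = restrict_features(table, current)
        logger.info(
            "%s round %d: %d candidate features", method, round_no, sub.p
        )
        result = selection_round(sub, labels, method, config, rng)
        kept = result.significant_ids
        discarded = tuple(f for f in current if f not in set(kept))
        records.append(
            RoundRecord(
                feature_ids=current,
                registered=result.registered,
                significant_ids=kept if result.registered else (),
                discarded_ids=discarded,
                mean_accuracy=result.mean_accuracy,
                trace=result.trace,
            )
        )
        if result.registered and not discarded:
            signature = kept
            converged = True
            break
        if not result.registered and not discarded:
            # single remaining feature tested non-significant: nothing left
            discards.append(current)
            records[-1].discarded_ids = current
            signature = ()
            converged = True
            break
        discards.append(discarded)
        current = kept
        if not current:  # defensive; kept is non-empty by construction
            signature = ()
            converged = True
            break
    else:
        warnings.warn(
            f"{method}: selection did not converge in {config.max_rounds} rounds",
            stacklevel=2,
        )
        signature = ()

    tiers = _assign_tiers(signature, discards)

    acc_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, method_index, 1])
    )
    accuracies: dict[str, float | None] = {
        "full": _mean_oob_accuracy(table, labels, method, config, acc_rng),
        "S": None,
        "AS": None,
    }
    tier_a = tuple(f for f in table.feature_ids if tiers.get(f) == "A")
    sig_ordered = tuple(f for f in signature)
    if sig_ordered:
        accuracies["S"] = _mean_oob_accuracy(
            restrict_features(table, sig_ordered), labels, method, config, acc_rng
        )
    s_plus_a = sig_ordered + tier_a
    if s_plus_a:
        accuracies["AS"] = _mean_oob_accuracy(
            restrict_features(table, s_plus_a), labels, method, config, acc_rng
        )

    final_model = None
    if sig_ordered:
        final_model = fit_classifier(
            method,
            restrict_features(table, sig_ordered),
            labels,
            seed=int(acc_rng.integers(2**31 - 1)),
            n_trees=config.n_trees,
            svm_cost=config.svm_cost,
        )

    return MethodResult(
        method=method,
        signature=sig_ordered,
        tiers=tiers,
        converged=converged,
        rounds=records,
        accuracies=accuracies,
        final_model=final_model,
    )


def run_all(
    table: FeatureTable, labels: BinaryLabels, config: SelectionConfig
) -> TierTable:
    """Run the selection independently for every configured classifier.

    Each method gets its own seed stream; a failure in one method is
    recorded and does not abort the others.
    """
    table, labels = validate_dataset(table, labels)
    results: dict[str, MethodResult] = {}
    errors: dict[str, str] = {}
    for method in config.methods:
        try:
            results[method] = run_selection(table, labels, method, config)
        except Exception as exc:  # noqa: BLE001 - isolate per-method failures
            logger.exception("method %s failed", method)
            errors[method] = f"{type(exc).__name__}: {exc}"
    return TierTable(feature_ids=table.feature_ids, results=results, errors=errors)
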