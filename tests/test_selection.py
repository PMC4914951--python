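"""Selection engine: resampling, rank aggregation, permutation
significance, half-interval search, and the iterative rounds."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigwrap import (
    BinaryLabels,
    FeatureTable,
    PlantedSpec,
    SelectionConfig,
    aggregate_ranks,
    balanced_accuracy,
    bootstrap_splits,
    generate_planted,
    half_interval_core,
    permute_subset,
    run_all,
    run_selection,
    selection_round,
    subset_significance,
)
from _helpers import injected_fits as _injected_fits, scan_oracle as _scan_oracle


class TestBootstrapSplits:
    def test_reproducible(self):
        labels = BinaryLabels(("a",) * 10 + ("b",) * 10)
        a = bootstrap_splits(labels, 10, seed=3)
        b = bootstrap_splits(labels, 10, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.train, y.train)
            np.testing.assert_array_equal(x.test, y.test)

    def test_train_is_stratified_and_full_size(self):
        labels = BinaryLabels(("a",) * 12 + ("b",) * 8)
        for split in bootstrap_splits(labels, 20, seed=0):
            assert len(split.train) == 20
            assert sum(1 for i in split.train if labels.labels[i] == "a") == 12

    def test_oob_contains_both_classes(self):
        labels = BinaryLabels(("a",) * 5 + ("b",) * 5)
        for split in bootstrap_splits(labels, 50, seed=1):
            oob = {labels.labels[i] for i in split.test}
            assert oob == {"a", "b"}

    def test_oob_fraction_matches_bootstrap_expectation(self):
        n = 200
        labels = BinaryLabels(("a",) * 100 + ("b",) * 100)
        splits = bootstrap_splits(labels, 50, seed=2)
        frac = np.mean([len(s.test) / n for s in splits])
        assert abs(frac - (1 - 1 / n) ** n) < 0.03


class TestBalancedAccuracy:
    def test_perfect_and_constant(self):
        truth = ("a", "a", "b", "b", "b")
        assert balanced_accuracy(truth, truth, "b") == 1.0
        assert balanced_accuracy(truth, ("b",) * 5, "b") == 0.5
        assert balanced_accuracy(truth, ("a",) * 5, "b") == 0.5

    def test_mixture(self):
        # sensitivity 0.8, specificity 0.6 -> 0.7
        truth = ("b",) * 5 + ("a",) * 5
        pred = ("b",) * 4 + ("a",) + ("a",) * 3 + ("b",) * 2
        assert balanced_accuracy(truth, pred, "b") == pytest.approx(0.7)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            balanced_accuracy(("a", "a"), ("a", "b"), "b")

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=6))
    def test_matches_sklearn_on_all_small_vectors(self, pairs):
        truth = tuple("b" if t else "a" for t, _ in pairs)
        pred = tuple("b" if p else "a" for _, p in pairs)
        if len(set(truth)) < 2:
            return
        from sklearn.metrics import balanced_accuracy_score

        ours = balanced_accuracy(truth, pred, "b")
        ref = balanced_accuracy_score(truth, pred)
        assert ours == pytest.approx(ref)


class TestAggregateRanks:
    def test_hand_example(self):
        ranks = np.array([[1, 2, 3], [1, 3, 2], [2, 1, 3]])
        np.testing.assert_array_equal(aggregate_ranks(ranks), [1, 2, 3])

    def test_single_row_identity(self):
        row = np.array([[3, 1, 2, 4]])
        np.testing.assert_array_equal(aggregate_ranks(row), [3, 1, 2, 4])

    def test_full_tie_breaks_by_index(self):
        ranks = np.array([[1, 2], [2, 1]])
        np.testing.assert_array_equal(aggregate_ranks(ranks), [1, 2])

    def test_matches_explicit_sort_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            boot, p = int(rng.integers(2, 6)), int(rng.integers(2, 7))
            mat = np.vstack([rng.permutation(p) + 1 for _ in range(boot)])
            med = np.median(mat, axis=0)
            mean = mat.mean(axis=0)
            order = sorted(range(p), key=lambda j: (med[j], mean[j], j))
            expected = np.empty(p, dtype=int)
            for r, j in enumerate(order, start=1):
                expected[j] = r
            np.testing.assert_array_equal(aggregate_ranks(mat), expected)

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            aggregate_ranks(np.array([1, 2, 3]))


class TestPermuteSubset:
    def _table(self, n=6, p=4, seed=0):
        rng = np.random.default_rng(seed)
        return FeatureTable(
            rng.normal(size=(n, p)),
            tuple(f"s{i}" for i in range(n)),
            tuple(f"f{j}" for j in range(p)),
        )

    def test_empty_subset_is_identity(self):
        table = self._table()
        out = permute_subset(table, [], np.random.default_rng(0))
        np.testing.assert_array_equal(out.values, table.values)

    def test_single_sample_unchanged(self):
        table = self._table(n=1)
        out = permute_subset(table, ["f0", "f2"], np.random.default_rng(0))
        np.testing.assert_array_equal(out.values, table.values)

    def test_columns_are_rearrangements_and_others_untouched(self):
        table = self._table()
        out = permute_subset(table, ["f1"], np.random.default_rng(5))
        assert sorted(out.values[:, 1]) == sorted(table.values[:, 1])
        for j in (0, 2, 3):
            np.testing.assert_array_equal(out.values[:, j], table.values[:, j])

    def test_input_never_mutated(self):
        table = self._table()
        before = table.values.copy()
        permute_subset(table, list(table.feature_ids), np.random.default_rng(1))
        np.testing.assert_array_equal(table.values, before)




class TestSubsetSignificance:
    def test_threshold_arithmetic_at_default_alpha(self):
        rng = np.random.default_rng(0)
        sig, prop = subset_significance(
            _injected_fits(48, 2), ["f1"], 0.05, rng, positive_level="b"
        )
        assert prop == pytest.approx(0.04)
        assert sig
        sig, prop = subset_significance(
            _injected_fits(47, 3), ["f1"], 0.05, rng, positive_level="b"
        )
        assert prop == pytest.approx(0.06)
        assert not sig

    def test_all_non_drops_not_significant(self):
        rng = np.random.default_rng(0)
        sig, prop = subset_significance(
            _injected_fits(0, 10), ["f1"], 0.05, rng, positive_level="b"
        )
        assert prop == 1.0 and not sig

    def test_all_drops_significant(self):
        rng = np.random.default_rng(0)
        sig, prop = subset_significance(
            _injected_fits(10, 0), ["f1"], 0.05, rng, positive_level="b"
        )
        assert prop == 0.0 and sig




class TestHalfIntervalSearch:
    @pytest.mark.parametrize("p", [4, 8, 16])
    def test_matches_exhaustive_scan_on_monotone_oracles(self, p):
        rng = np.random.default_rng(123)
        for _ in range(50):
            boundary = int(rng.integers(0, p + 1))  # tails at ranks <= boundary significant
            oracle = lambda r, b=boundary: r <= b
            f_ns, trace = half_interval_core(p, lambda r: (oracle(r), 0.0))
            assert f_ns == _scan_oracle(p, oracle)
            candidates = [s.candidate_rank for s in trace]
            assert len(set(candidates)) == len(candidates)
            assert all(1 <= c <= p for c in candidates)
            assert candidates[0] == 1  # first probe permutes everything

    def test_all_significant_returns_full_set(self):
        f_ns, _ = half_interval_core(8, lambda r: (True, 0.0))
        assert f_ns == 9

    def test_candidate_sequence_follows_halving_pattern(self):
        # p = 16: full set significant, then rank 9 (worst 50%) and rank 5
        # (worst 75%) both not significant
        seen = []

        def probe(r):
            seen.append(r)
            return r <= 1, 0.0

        half_interval_core(16, probe)
        assert seen[:3] == [1, 9, 5]

    def test_search_never_tests_more_than_log_candidates(self):
        for p in (4, 16):
            for b in range(p + 1):
                _, trace = half_interval_core(p, lambda r, b=b: (r <= b, 0.0))
                assert len(trace) <= int(np.ceil(np.log2(p))) + 2


class TestRounds:
    def test_single_significant_feature_round(self):
        rng = np.random.default_rng(0)
        spec = PlantedSpec(n_per_class=12, p=1, n_informative=1, effect=3.0, seed=1)
        table, labels, _ = generate_planted(spec)
        cfg = SelectionConfig(boot=15, seed=0)
        res = selection_round(table, labels, "plsda", cfg, rng)
        assert res.registered
        assert res.significant_ids == table.feature_ids

    def test_noise_round_returns_unregistered_half(self):
        rng = np.random.default_rng(1)
        spec = PlantedSpec(n_per_class=15, p=9, effect=0.0, seed=5)
        table, labels, _ = generate_planted(spec)
        cfg = SelectionConfig(boot=15, seed=0)
        res = selection_round(table, labels, "svm", cfg, rng)
        if not res.registered:
            assert len(res.significant_ids) == 5  # ceil(9 / 2)

    def test_planted_signal_recovered_and_restriction_helps(self, planted_separable):
        table, labels, truth = planted_separable
        cfg = SelectionConfig(boot=20, seed=3, methods=("plsda",))
        res = run_selection(table, labels, "plsda", cfg)
        assert truth[0] in res.signature
        assert res.accuracies["S"] >= res.accuracies["full"]
        assert res.tiers[truth[0]] == "S"

    def test_tier_letters_are_reverse_chronological(self, planted_separable):
        table, labels, _ = planted_separable
        cfg = SelectionConfig(boot=20, seed=3)
        res = run_selection(table, labels, "plsda", cfg)
        discard_rounds = [r for r in res.rounds if r.discarded_ids]
        letters = [
            {res.tiers[f] for f in r.discarded_ids} for r in discard_rounds
        ]
        expected = ["E"] * max(0, len(discard_rounds) - 4) + list(
            "DCBA"[-min(4, len(discard_rounds)) :]
        )
        assert [s.pop() for s in letters] == expected

    def test_run_all_merges_methods_and_is_deterministic(self, planted_separable):
        table, labels, truth = planted_separable
        cfg = SelectionConfig(boot=15, seed=9, methods=("plsda", "svm"))
        a = run_all(table, labels, cfg)
        b = run_all(table, labels, cfg)
        assert set(a.methods) == {"plsda", "svm"}
        for m in a.methods:
            assert a.results[m].signature == b.results[m].signature
            assert a.results[m].accuracies == b.results[m].accuracies
        assert truth[0] in a.signature_union()

    def test_models_fitted_once_per_round(self, planted_separable, monkeypatch):
        # the efficiency contract: significance probes re-predict but never refit
        import sigwrap.selection as sel

        table, labels, _ = planted_separable
        calls = {"n": 0}
        real = sel.fit_classifier

        def counting(*args, **kwargs):
            calls["n"] += 1
            return real(*args, **kwargs)

        monkeypatch.setattr(sel, "fit_classifier", counting)
        cfg = SelectionConfig(boot=10, seed=2)
        res = run_selection(table, labels, "plsda", cfg)
        n_rounds = len(res.rounds)
        n_acc = sum(1 for v in res.accuracies.values() if v is not None)
        expected = cfg.boot * (n_rounds + n_acc) + (1 if res.final_model else 0)
        assert calls["n"] == expected
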