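"""Shared test utilities: injected bootstrap records and brute-force oracles."""

import numpy as np

from sigwrap.selection import BootstrapFit, BootstrapSplit


class StubModel:
    """Injected classifier with a frozen prediction, for significance tests."""

    def __init__(self, feature_ids, prediction):
        self.feature_ids = feature_ids
        self._prediction = tuple(prediction)

    def predict_values(self, values):
        return self._prediction


def injected_fits(n_drop, n_non_drop):
    """Bootstrap records where permutation visibly drops accuracy in exactly
    ``n_drop`` bootstraps and leaves it intact in the other ``n_non_drop``."""
    feature_ids = ("f1",)
    truth = ("a", "b")
    values = np.zeros((2, 1))
    split = BootstrapSplit(train=np.array([0, 1]), test=np.array([0, 1]))

    def fit(prediction, accuracy):
        return BootstrapFit(
            split=split,
            model=StubModel(feature_ids, prediction),
            ranks=np.array([1]),
            accuracy=accuracy,
            test_values=values,
            test_truth=truth,
        )

    fits = [fit(("b", "a"), 0.5) for _ in range(n_drop)]        # acc_perm = 0 < 0.5
    fits += [fit(("a", "b"), 0.5) for _ in range(n_non_drop)]   # acc_perm = 1 >= 0.5
    return fits


def scan_oracle(p, is_significant):
    """Exhaustive linear scan for the boundary rank: the smallest rank whose
    tail subset is not significant (p + 1 when every tail is significant)."""
    for r in range(1, p + 1):
        if not is_significant(r):
            return r
    return p + 1
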