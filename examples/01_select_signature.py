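"""Discover a molecular signature on a planted-signal peak table.

Builds a 40-sample, 100-feature table where a single feature separates the
two classes (3-sd mean shift), runs the selection with all three wrapped
classifiers, and prints each classifier's signature with the balanced
accuracies of the full and restricted models.
"""

from sigwrap import PlantedSpec, SelectionConfig, generate_planted, run_all

table, labels, truth = generate_planted(
    PlantedSpec(n_per_class=20, p=100, n_informative=1, effect=3.0, seed=7)
)
print(f"dataset: {table.n} samples x {table.p} features; planted: {truth[0]}")

tiers = run_all(table, labels, SelectionConfig(seed=11))

for method, res in tiers.results.items():
    sig = ", ".join(res.signature) if res.signature else "(empty)"
    acc = res.accuracies
    s_acc = "na" if acc["S"] is None else f"{acc['S']:.3f}"
    print(
        f"{method:>5s}: S = {sig:<12s} accuracy full={acc['full']:.3f} S={s_acc}"
    )

print(f"union of signatures: {', '.join(tiers.signature_union())}")
# A signature containing only the planted feature, with the restricted
# model clearly more accurate than the 100-feature model, shows the
# permutation criterion isolating the real signal from the noise floor.
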