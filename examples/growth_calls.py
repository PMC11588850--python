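"""From kinetic phenotyping plates to binary growth calls and substrate PCA.

Each well's opacity trace is Savitzky-Golay smoothed; its maximum is
z-tested (one-sided) against the negative-control wells with Bonferroni
correction.  Calls across strains are compared per nutrient category, and
PCA of the binary call matrix shows which substrate classes separate the
strains.
"""

from trn_adapt import plates as plt
from trn_adapt import synthetic as syn

study = syn.simulate_study(syn.archetype_spec(seed=1))
matrix = plt.GrowthCallMatrix.from_plates(study.plates)

print("growth calls per strain (of", matrix.calls.shape[1], "substrates):")
for strain, n in matrix.calls.sum(axis=1).items():
    print(f"  {strain}: {int(n)}")

comp = plt.compare_calls(matrix.calls.loc["wt"], matrix.calls.loc["tf004_ko"],
                         matrix.conditions)
print(f"\nwt -> tf004_ko: gained {len(comp['gained'])}, lost {len(comp['lost'])}")
for cat, pct in sorted(comp["loss_percent_by_category"].items()):
    print(f"  {cat}-source conditions lost: {pct:.1f}%")

scores, loadings, var_frac = plt.pca_binary(matrix.calls)
print(f"\nPC1 explains {100 * var_frac[0]:.1f}% of call variance; "
      f"strain scores:")
print(scores["PC1"].round(2).to_string())
# A high category loss percentage means the knockout-evolved strain
# abandoned substrates of that nutrient class relative to wildtype.
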