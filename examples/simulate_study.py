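"""Generate a synthetic knockout-adaptation study and inspect its ground truth.

The archetype study contains four regulator knockouts, one per adaptation
category: an inactive regulator that recovers (i), an active one that
recovers without regulator-specific mutations (ii), one that recovers via a
planted convergent mutation inside its own regulon (iii), and a hub
regulator that never recovers (iv).
"""

from trn_adapt import synthetic as syn

study = syn.simulate_study(syn.archetype_spec(seed=1))

print(f"TRN: {len(study.trn.records)} regulatory edges, "
      f"{len(study.trn.regulators)} regulators")
print(f"expression: {study.expression.values.shape[0]} genes x "
      f"{study.expression.values.shape[1]} samples "
      f"({len(study.expression.reference_ids)} reference)")
print(f"mutation records: {len(study.mutations.records)}")
print("ground-truth categories:", study.ground_truth.true_category)
for ko, genes in study.ground_truth.true_convergent_genes.items():
    if genes:
        print(f"  planted convergent mutation for {ko}: {sorted(genes)}")
# The categories above are what the analysis pipeline must recover from the
# generated data alone; the convergent genes are planted in >= 2 lineages.
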