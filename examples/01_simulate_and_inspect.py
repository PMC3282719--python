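"""Generate the default synthetic multi-cell-line study and look inside it.

The generator draws a 27-cell-line panel (5 pluripotent P, 4 multipotent M,
15 unipotent/differentiated U/D, 3 cancer C) over 2,000 genes on 4
chromosomes.  Every gene in every line carries a hidden chromatin state
(1 = null, 2 = non-active, 3 = active) and a 5-mark score vector emitted from
that state.  The hidden truth (hotspot genes, planted domains, regulatory
modules) is returned alongside the data so downstream methods can be scored.
"""

from chromstage import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=0))

print("cell lines by class:")
print(ds.metadata["label"].value_counts().to_string(), end="\n\n")

print("annotation (first genes):")
print(ds.annotation.head(3).to_string(index=False), end="\n\n")

print("true-state composition per class (fraction of gene/line pairs):")
for cls in ("P", "M", "U/D", "C"):
    lines = ds.metadata.loc[ds.metadata["label"] == cls, "cell_line"]
    sub = ds.true_states[lines]
    fr = sub.stack().value_counts(normalize=True).sort_index()
    print(f"  {cls:>4}: " + "  ".join(f"state {s}: {f:.3f}" for s, f in fr.items()))
print()

truth = ds.truth
print(f"hotspot genes: {len(truth['hotspot_genes'])}")
print(f"planted domains: {truth['planted_domains']}")
print(f"modules: {{name: size}} = { {k: len(v) for k, v in ds.modules.items()} }")
print(f"cancer-private non-active genes: {len(truth['cancer_private_genes'])}")

print("\nmean score per mark in each true state (pooled over lines):")
import numpy as np
for s, name in ((1, "null"), (2, "nonactive"), (3, "active")):
    mask = ds.true_states.to_numpy() == s
    means = [ds.gene_scores.values[:, j, :][mask].mean()
             for j in range(len(ds.gene_scores.marks))]
    row = "  ".join(f"{m}:{v:5.2f}" for m, v in zip(ds.gene_scores.marks, means))
    print(f"  {name:>9}  {row}")
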