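"""Bin-level preprocessing: reads -> 100 bp counts -> RPM -> repeat filter ->
1 kb merge -> gene scores -> peaks -> bivalent genes.

This walks the low-level path a real ChIP-seq experiment would take.  We
simulate raw read positions for one cell line, then run the exact chain of
transformations the pipeline applies before any model sees the data.
"""

import numpy as np

from chromstage import SimConfig, simulate_dataset
from chromstage.simulate import simulate_bin_reads
from chromstage.binning import (
    bin_reads, drop_empty, filter_repeats, merge_bins, normalize_rpm,
)
from chromstage.gene_scores import (
    bivalent_genes, call_peaks, genes_from_annotation, score_genes,
)

cfg = SimConfig(n_genes=300, n_chromosomes=2, seed=0,
                domain_spec=[], module_size=20, n_cancer_private=10)
ds = simulate_dataset(cfg)

line = "P01"
marks = ["H3K4me3", "H3K27me3"]
reads, _, _, repeats, chrom_sizes = simulate_bin_reads(
    cfg, ds, cell_lines=[line], marks=marks, seed=0)

print(f"simulated reads per track: "
      f"{ {k: len(v) for k, v in reads.items()} }")

bm = bin_reads(reads, chrom_sizes, bin_size=100)
print(f"100 bp bins: {bm.n_bins}")

bm = normalize_rpm(bm)
bm = filter_repeats(bm, repeats)
print(f"bins removed by the >=50% repeat-overlap filter: {len(bm.removed_bins)}")

bm = drop_empty(merge_bins(bm, target=1000))
print(f"non-empty 1 kb bins after merging: {bm.n_bins}")

genes = genes_from_annotation(ds.annotation)
track_names = {m: f"{line}|{m}" for m in marks}
scores = score_genes(genes, bm, "H3K4me3",
                     columns={m: t for m, t in track_names.items()})
print(f"\npromoter-score table ({scores.shape[0]} genes x {scores.shape[1]} tracks):")
print(scores.head(3).round(3).to_string())

k4_peaks = call_peaks(bm, track_names["H3K4me3"])
k27_peaks = call_peaks(bm, track_names["H3K27me3"])
print(f"\nH3K4me3 peak bins: {len(k4_peaks)}, H3K27me3 peak bins: {len(k27_peaks)}")

biv = bivalent_genes(k4_peaks, k27_peaks, bm.bins, genes)
print(f"bivalent genes (both peaks in the +/-2 kb promoter): {len(biv)}")
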