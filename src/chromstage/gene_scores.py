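"""Gene-level summary scores per histone mark, peak calling and bivalent genes.

For promoter-associated marks (H3K4me1, H3K4me3, H3K9ac, H3K27me3) the gene
score is the mean normalized signal over the [-2 kb, +2 kb] window around the
transcription start site.  H3K36me3 accumulates over transcribed gene bodies,
peaking over the 80-95% stretch of the coding region, so its score averages
over that stretch instead.

Bivalent genes carry both the activating H3K4me3 and the repressive H3K27me3
at their promoter: a 1 kb bin is bivalent when it lies in the peak set of both
marks, and a gene is bivalent when its promoter window overlaps at least one
bivalent bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binning import BinMatrix, InputError

PROMOTER_FLANK = 2_000
K36_LO, K36_HI = 0.80, 0.95
BODY_MARK = "H3K36me3"


@dataclass
class GeneModel:
    """One gene: RefSeq-like coordinates, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(f"bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise InputError(f"{self.gene_id}: txStart must be < txEnd")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start

    def promoter(self, flank: int = PROMOTER_FLANK):
        return self.tss - flank, self.tss + flank

    def k36_region(self, lo: float = K36_LO, hi: float = K36_HI):
        """The lo-hi stretch of the CDS, measured from the 5' end on either strand.

        Fractional positions are rounded down to integer bp.
        """
        L = self.cds_end - self.cds_start
        if self.strand == "+":
            return self.cds_start + int(lo * L), self.cds_start + int(hi * L)
        return self.cds_end - int(hi * L), self.cds_end - int(lo * L)


def genes_from_annotation(annotation: pd.DataFrame) -> list:
    """Build GeneModel objects; keeps the longest transcript per gene_id."""
    ann = annotation.copy()
    ann["_len"] = ann["txEnd"] - ann["txStart"]
    ann = ann.sort_values("_len", ascending=False).drop_duplicates("gene_id")
    ann = ann.sort_index()
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.txStart), int(r.txEnd),
                  int(r.cdsStart), int(r.cdsEnd))
        for r in ann.itertuples()
    ]


def _window_mean(track: BinMatrix, column: str, chrom: str, lo: int, hi: int,
                 weighted: bool = True) -> float:
    """Overlap-fraction-weighted mean of bin values over [lo, hi)."""
    mask = (track.bins["chrom"] == chrom).to_numpy()
    if not mask.any():
        raise InputError(f"chromosome {chrom!r} absent from track")
    bs = track.bins["start"].to_numpy()[mask]
    be = track.bins["end"].to_numpy()[mask]
    v = track.values[column].to_numpy()[mask]
    ov = np.clip(np.minimum(be, hi) - np.maximum(bs, lo), 0, None)
    sel = ov > 0
    if not sel.any():
        return np.nan
    if weighted:
        w = ov[sel] / (be[sel] - bs[sel])
    else:
        w = np.ones(np.count_nonzero(sel))
    return float(np.sum(w * v[sel]) / np.sum(w))


def promoter_score(gene: GeneModel, track: BinMatrix, column: str,
                   flank: int = PROMOTER_FLANK, weighted: bool = True) -> float:
    """Mean signal over the +/- ``flank`` window around the TSS.

    Windows truncated at a chromosome edge are averaged over the covered part
    (a warning is emitted).
    """
    lo, hi = gene.tss - flank, gene.tss + flank
    if lo < 0:
        warnings.warn(f"{gene.gene_id}: promoter truncated at chromosome start")
        lo = 0
    return _window_mean(track, column, gene.chrom, lo, hi, weighted)


def body_score_k36(gene: GeneModel, track: BinMatrix, column: str,
                   lo: float = K36_LO, hi: float = K36_HI,
                   weighted: bool = True) -> float:
    """Mean signal over the 80-95% stretch of the coding region (strand-aware).

    Returns NaN for non-coding genes (no CDS to measure over).
    """
    if not gene.coding:
        warnings.warn(f"{gene.gene_id}: non-coding, H3K36me3 body score undefined")
        return np.nan
    a, b = gene.k36_region(lo, hi)
    return _window_mean(track, column, gene.chrom, a, b, weighted)


def repeat_excluded_genes(genes: list, removed_bins: pd.DataFrame,
                          bin_size: int = 100, flank: int = PROMOTER_FLANK,
                          max_removed_frac: float = 0.5) -> set:
    """Genes whose promoter lost more than ``max_removed_frac`` of its bins to
    repeat filtering; these are excluded from downstream gene-level analysis."""
    excluded = set()
    by_chrom = {c: sub for c, sub in removed_bins.groupby("chrom", sort=False)}
    for g in genes:
        lo, hi = max(g.tss - flank, 0), g.tss + flank
        n_bins = max((hi - lo) // bin_size, 1)
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        n_removed = int(np.count_nonzero((s < hi) & (e > lo)))
        if n_removed > max_removed_frac * n_bins:
            excluded.add(g.gene_id)
    return excluded


def score_genes(genes: list, track: BinMatrix, mark: str,
                columns: dict | None = None, flank: int = PROMOTER_FLANK,
                weighted: bool = True) -> pd.DataFrame:
    """Gene x track score table for one mark over every track column.

    ``columns`` optionally maps output column names to track column names;
    by default every column of the track is scored under its own name.
    """
    columns = columns or {c: c for c in track.tracks}
    out = {}
    for out_name, col in columns.items():
        vals = []
        for g in genes:
            if mark == BODY_MARK:
                vals.append(body_score_k36(g, track, col, weighted=weighted))
            else:
                vals.append(promoter_score(g, track, col, flank=flank, weighted=weighted))
        out[out_name] = vals
    return pd.DataFrame(out, index=[g.gene_id for g in genes])


# ---------------------------------------------------------------------------
# peak calling (simplified bin-level Poisson caller) and bivalent genes
# ---------------------------------------------------------------------------

def call_peaks(track: BinMatrix, column: str, fdr: float = 0.05,
               min_background: float = 0.25) -> np.ndarray:
    """Bin indices called as peaks for one track.

    Each bin's value (rounded to a count) is tested against a Poisson
    background whose rate is the median bin value (floored at
    ``min_background`` so all-background tracks stay calibrated); p-values are
    Benjamini-Hochberg corrected and bins with q <= ``fdr`` are peaks.
    """
    v = track.values[column].to_numpy(float)
    if track.n_bins < 100:
        raise InputError("peak calling needs at least 100 bins")
    if not np.any(v > 0):
        return np.array([], dtype=int)
    lam = max(float(np.median(v)), min_background)
    counts = np.round(v).astype(int)
    p = stats.poisson.sf(counts - 1, lam)
    reject, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return np.flatnonzero(reject)


def bivalent_genes(k4me3_peaks: np.ndarray, k27me3_peaks: np.ndarray,
                   bins: pd.DataFrame, genes: list,
                   flank: int = PROMOTER_FLANK) -> set:
    """Genes whose promoter overlaps a bin in both marks' peak sets.

    Both peak index arrays must refer to the same bin grid (``bins``).
    """
    shared = np.intersect1d(k4me3_peaks, k27me3_peaks)
    if shared.size == 0:
        return set()
    bchrom = bins["chrom"].to_numpy()[shared]
    bs = bins["start"].to_numpy()[shared]
    be = bins["end"].to_numpy()[shared]
    out = set()
    for g in genes:
        lo, hi = max(g.tss - flank, 0), g.tss + flank
        hit = (bchrom == g.chrom) & (bs < hi) & (be > lo)
        if hit.any():
            out.add(g.gene_id)
    return out
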