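"""Bin-level preprocessing of ChIP-seq read positions.

The pipeline tiles each chromosome into 100 bp bins, counts reads per bin,
normalizes each track to reads per million (RPM) so cell lines are comparable,
removes bins that overlap known repetitive regions by 50% or more, merges the
survivors into 1 kb regions, and finally drops 1 kb regions with no signal in
any track.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Raised on malformed or out-of-bounds input data."""


@dataclass
class BinMatrix:
    """Ordered genomic bins with per-track signal.

    ``bins`` holds (chrom, start, end) rows sorted by (chrom, start),
    non-overlapping; ``values`` is a DataFrame aligned row-for-row with
    ``bins``, one column per track ("cell_line|mark"); ``library_sizes``
    records total mapped reads per track (used for RPM normalization).
    ``removed_bins`` keeps provenance of repeat-filtered bins.
    """

    bins: pd.DataFrame
    values: pd.DataFrame
    library_sizes: pd.Series
    removed_bins: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def __post_init__(self):
        if len(self.bins) != len(self.values):
            raise InputError("bins and values must have the same number of rows")
        self.bins = self.bins.reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def tracks(self) -> list:
        return list(self.values.columns)

    def copy(self) -> "BinMatrix":
        return BinMatrix(self.bins.copy(), self.values.copy(),
                         self.library_sizes.copy(), self.removed_bins.copy())


def _sort_key(bins: pd.DataFrame):
    return bins.sort_values(["chrom", "start"], kind="stable").index


def bin_reads(reads: dict, chrom_sizes: dict, bin_size: int = 100) -> BinMatrix:
    """Count reads per fixed-width bin for every track.

    ``reads`` maps track name to a DataFrame with columns (chrom, pos); a read
    at position p falls in the bin [k*bin_size, (k+1)*bin_size) containing p.
    Every chromosome in ``chrom_sizes`` is tiled completely.
    """
    chroms = sorted(chrom_sizes)
    n_bins_per = {c: int(np.ceil(chrom_sizes[c] / bin_size)) for c in chroms}
    offsets, off = {}, 0
    rows = []
    for c in chroms:
        offsets[c] = off
        starts = np.arange(n_bins_per[c]) * bin_size
        rows.append(pd.DataFrame(
            {"chrom": c, "start": starts,
             "end": np.minimum(starts + bin_size, chrom_sizes[c])}))
        off += n_bins_per[c]
    bins = pd.concat(rows, ignore_index=True)
    n_total = off

    values = {}
    lib = {}
    for track, df in reads.items():
        counts = np.zeros(n_total, dtype=np.int64)
        for c, sub in df.groupby("chrom", sort=False):
            if c not in chrom_sizes:
                raise InputError(f"read on unknown chromosome {c!r}")
            pos = sub["pos"].to_numpy()
            if pos.size and (pos.min() < 0 or pos.max() >= chrom_sizes[c]):
                raise InputError(f"read position outside chromosome {c!r}")
            idx = offsets[c] + pos // bin_size
            counts += np.bincount(idx, minlength=n_total)
        values[track] = counts
        lib[track] = int(counts.sum())
    values_df = pd.DataFrame(values, index=bins.index)
    return BinMatrix(bins, values_df, pd.Series(lib, dtype=float))


def normalize_rpm(bm: BinMatrix, library_sizes: pd.Series | None = None) -> BinMatrix:
    """Scale each track to reads per million mapped reads.

    By default the matrix's stored library sizes (total mapped reads, counted
    before any filtering) are used; pass ``library_sizes`` to override, e.g.
    to renormalize with post-filter totals.
    """
    lib = bm.library_sizes if library_sizes is None else library_sizes
    out = bm.values.astype(float).copy()
    for track in bm.tracks:
        size = float(lib[track])
        if size <= 0:
            raise InputError(f"track {track!r} has zero library size; cannot compute RPM")
        out[track] = bm.values[track] * (1e6 / size)
    return BinMatrix(bm.bins.copy(), out, lib.astype(float), bm.removed_bins.copy())


def _merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    merged = []
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def filter_repeats(bm: BinMatrix, repeats: pd.DataFrame,
                   min_overlap_frac: float = 0.5) -> BinMatrix:
    """Drop bins whose repeat overlap is at least ``min_overlap_frac`` of their width.

    Overlapping repeat intervals are unioned first, so multiple repeats hitting
    one bin have their overlaps summed.  Removed bins are recorded in
    ``removed_bins`` for provenance (gene-level repeat exclusion needs them).
    """
    merged = _merge_intervals(repeats)
    overlap = np.zeros(bm.n_bins)
    bstart = bm.bins["start"].to_numpy()
    bend = bm.bins["end"].to_numpy()
    bchrom = bm.bins["chrom"].to_numpy()
    for chrom, sub in merged.groupby("chrom", sort=False):
        mask = bchrom == chrom
        if not mask.any():
            continue
        bs, be = bstart[mask], bend[mask]
        ov = np.zeros(bs.size)
        for s, e in zip(sub["start"], sub["end"]):
            ov += np.clip(np.minimum(be, e) - np.maximum(bs, s), 0, None)
        overlap[mask] = ov
    width = bend - bstart
    drop = overlap >= min_overlap_frac * width
    removed = pd.concat([bm.removed_bins, bm.bins[drop]], ignore_index=True)
    removed = removed.drop_duplicates().reset_index(drop=True)
    return BinMatrix(bm.bins[~drop].reset_index(drop=True),
                     bm.values[~drop].reset_index(drop=True),
                     bm.library_sizes.copy(), removed)


def merge_bins(bm: BinMatrix, target: int = 1000, agg: str = "sum") -> BinMatrix:
    """Merge fine bins into ``target``-width regions aligned to the target grid.

    The merged value is the sum (default) of surviving constituent bins, with
    no rescaling for repeat-filtered constituents, so total signal mass is
    conserved exactly; ``agg="mean"`` averages the survivors instead.
    """
    if agg not in ("sum", "mean"):
        raise InputError("agg must be 'sum' or 'mean'")
    key = pd.DataFrame({
        "chrom": bm.bins["chrom"],
        "start": (bm.bins["start"] // target) * target,
    })
    grouped = pd.concat([key, bm.values], axis=1).groupby(["chrom", "start"], sort=True)
    out_vals = grouped.sum() if agg == "sum" else grouped.mean()
    out_bins = out_vals.index.to_frame(index=False)
    out_bins["end"] = out_bins["start"] + target
    return BinMatrix(out_bins, out_vals.reset_index(drop=True),
                     bm.library_sizes.copy(), bm.removed_bins.copy())


def drop_empty(bm: BinMatrix) -> BinMatrix:
    """Remove bins with zero signal in every track."""
    keep = (bm.values != 0).any(axis=1).to_numpy()
    return BinMatrix(bm.bins[keep].reset_index(drop=True),
                     bm.values[keep].reset_index(drop=True),
                     bm.library_sizes.copy(), bm.removed_bins.copy())
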