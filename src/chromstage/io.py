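"""Plain-text readers and writers for the pipeline's on-disk formats.

Everything is TSV, BED (0-based half-open) or JSON; gene-set files are one
gene id per line.  These are thin pandas wrappers kept in one place so the
on-disk layout stays consistent between the CLI, the pipeline and the tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneScoreArray, SyntheticDataset

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd"]


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bed(intervals: pd.DataFrame, path, extra_cols=()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=list(names),
                       usecols=range(len(names)))


def write_gene_list(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path) -> list:
    text = Path(path).read_text().strip()
    return text.split("\n") if text else []


def write_scores(scores: GeneScoreArray, outdir) -> None:
    """One genes x cell-lines TSV per mark."""
    outdir = Path(outdir)
    for mark in scores.marks:
        write_tsv(scores.frame(mark), outdir / f"scores_{mark}.tsv")


def read_scores(outdir, marks) -> GeneScoreArray:
    outdir = Path(outdir)
    frames = [read_tsv(outdir / f"scores_{m}.tsv") for m in marks]
    genes = list(frames[0].index)
    lines = list(frames[0].columns)
    values = np.stack([f.to_numpy(float) for f in frames], axis=1)
    return GeneScoreArray(values, genes, list(marks), lines)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Serialize a synthetic dataset: metadata, annotation, truth, scores, modules."""
    outdir = Path(outdir)
    write_tsv(ds.metadata, outdir / "metadata.tsv", index=False)
    write_tsv(ds.annotation, outdir / "annotation.tsv", index=False)
    write_tsv(ds.true_states, outdir / "true_states.tsv")
    write_scores(ds.gene_scores, outdir)
    for name, genes in ds.modules.items():
        write_gene_list(genes, outdir / f"module_{name}.txt")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
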