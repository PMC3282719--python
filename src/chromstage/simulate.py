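"""Synthetic multi-cell-line histone-modification datasets.

Generates gene-level score matrices (and optionally bin-level read data) for a
panel of cell lines spanning the differentiation classes P (pluripotent),
M (multipotent), U/D (unipotent or terminally differentiated) and C (cancer),
with the statistical structure the downstream analysis assumes:

* three latent chromatin states per gene per cell line -- null (code 1),
  non-active (code 2, high H3K27me3) and active (code 3, high active marks) --
  with Markov-dependent runs along gene order within each chromosome;
* a configurable subset of "hotspot" genes whose state distribution depends on
  the differentiation class of the cell line;
* planted multi-gene same-state runs (chromatin domains) shared by all lines;
* regulatory-module gene sets (Core / PRC / MYC) whose non-active fraction
  separates the differentiation classes;
* cancer lines that behave like U/D lines plus a private gene set switched to
  the non-active state.

Observed gene-level scores are drawn per state from diagonal-Gaussian emission
profiles (one mean/sd per state per mark) and truncated at zero, since
read-derived scores are non-negative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Integer state coding used throughout the package.
STATE_NULL, STATE_NONACTIVE, STATE_ACTIVE = 1, 2, 3
STATE_NAMES = {STATE_NULL: "null", STATE_NONACTIVE: "nonactive", STATE_ACTIVE: "active"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}

DEFAULT_MARKS = ("H3K4me1", "H3K4me3", "H3K9ac", "H3K36me3", "H3K27me3")

# Per-state emission profiles in RPM-like units, rows ordered (null, nonactive,
# active), columns in DEFAULT_MARKS order.  The active state carries the four
# active marks, the non-active state carries H3K27me3 with a moderate H3K4me3
# component (bivalent-like promoters), the null state carries nothing.
DEFAULT_EMISSION_MEANS = np.array(
    [
        [0.20, 0.20, 0.20, 0.20, 0.30],  # null
        [0.80, 1.50, 0.80, 0.40, 5.00],  # nonactive
        [3.00, 8.00, 6.00, 5.00, 0.50],  # active
    ]
)
DEFAULT_EMISSION_SDS = np.array(
    [
        [0.20, 0.20, 0.20, 0.20, 0.25],
        [0.40, 0.70, 0.40, 0.30, 1.50],
        [1.00, 2.00, 1.50, 1.50, 0.40],
    ]
)

DEFAULT_TRANSITION = np.array(
    [
        [0.80, 0.10, 0.10],
        [0.10, 0.80, 0.10],
        [0.10, 0.10, 0.80],
    ]
)
DEFAULT_INITIAL = np.array([1 / 3, 1 / 3, 1 / 3])

# Class-conditional state probabilities for hotspot genes, over
# (null, nonactive, active), in two biologically distinct groups:
# "stem-repressed" genes (developmental regulators) are Polycomb-silenced
# (non-active) in pluripotent and multipotent cells and drift to the null
# state on terminal differentiation; "lineage-priming" genes are switched on
# (active) specifically in multipotent progenitors.  Each rule is
# (fraction of hotspot genes, {class: state probabilities}).
DEFAULT_HOTSPOT_RULES = [
    (0.6, {
        "P": (0.05, 0.85, 0.10),
        "M": (0.20, 0.70, 0.10),
        "U/D": (0.85, 0.10, 0.05),
    }),
    (0.4, {
        "P": (0.60, 0.25, 0.15),
        "M": (0.10, 0.15, 0.75),
        "U/D": (0.70, 0.20, 0.10),
    }),
]

# Per-module, per-class probability that a module gene is in the non-active
# state.  Core-module genes are active in stem cells and shut down on
# differentiation; PRC (Polycomb-target) genes show the opposite trend; the
# MYC module varies little across classes.
DEFAULT_MODULE_SPEC = {
    "Core": {"P": 0.05, "M": 0.45, "U/D": 0.85},
    "PRC": {"P": 0.80, "M": 0.50, "U/D": 0.25},
    "MYC": {"P": 0.10, "M": 0.15, "U/D": 0.25},
}


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class BinSimParams:
    """Geometry and rates for the bin-level read simulation."""

    bin_size: int = 100
    gene_spacing: int = 6_000          # bp between consecutive gene starts
    gene_length: int = 2_000           # bp, txStart..txEnd
    background_rate: float = 0.05      # expected reads per bin, background
    reads_per_score: float = 2.0       # extra expected reads per bin per score unit
    repeat_fraction: float = 0.02      # fraction of each chromosome covered by repeats
    library_scale: float = 1.0         # multiplies every rate (library size knob)


@dataclass
class SimConfig:
    """Complete description of one synthetic study.

    Defaults reproduce the study design of the analysis this package
    implements: 5 marks over 24 normal cell lines (5 pluripotent, 4
    multipotent, 15 unipotent/differentiated) plus 3 cancer lines.
    """

    n_per_class: dict = field(default_factory=lambda: {"P": 5, "M": 4, "U/D": 15})
    n_cancer: int = 3
    n_genes: int = 2_000
    n_chromosomes: int = 4
    marks: tuple = DEFAULT_MARKS
    emission_means: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION_MEANS.copy())
    emission_sds: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION_SDS.copy())
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    initial: np.ndarray = field(default_factory=lambda: DEFAULT_INITIAL.copy())
    hotspot_fraction: float = 0.25
    hotspot_rules: list = field(default_factory=lambda: [(f, dict(d)) for f, d in DEFAULT_HOTSPOT_RULES])
    background_flip: float = 0.08   # per-line, per-gene chance a background gene deviates from consensus
    # planted same-state gene runs shared by every cell line: (state name, run length)
    domain_spec: list = field(
        default_factory=lambda: [("nonactive", 30), ("active", 30), ("null", 30)]
    )
    module_spec: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MODULE_SPEC.items()})
    module_size: int = 50
    n_cancer_private: int = 40         # genes forced non-active in cancer lines only
    bin_sim: BinSimParams = field(default_factory=BinSimParams)
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        K, M = 3, len(self.marks)
        means = np.asarray(self.emission_means, float)
        sds = np.asarray(self.emission_sds, float)
        if means.shape != (K, M) or sds.shape != (K, M):
            raise ConfigError(
                f"emission profiles must be {K}x{M}; got {means.shape} and {sds.shape}"
            )
        if not np.all(sds > 0):
            raise ConfigError("emission sds must be strictly positive")
        trans = np.asarray(self.transition, float)
        if trans.shape != (K, K):
            raise ConfigError(f"transition matrix must be {K}x{K}")
        if not np.allclose(trans.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("transition rows must sum to 1")
        if not np.allclose(np.sum(self.initial), 1.0, atol=1e-9):
            raise ConfigError("initial distribution must sum to 1")
        if not (0.0 <= self.hotspot_fraction <= 1.0):
            raise ConfigError("hotspot_fraction must be in [0, 1]")
        for name, n in self.n_per_class.items():
            if n <= 0:
                raise ConfigError(f"class {name!r} must have a positive count")
        if self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise ConfigError("n_genes and n_chromosomes must be positive")
        if not (0.0 <= self.background_flip <= 1.0):
            raise ConfigError("background_flip must be in [0, 1]")
        total = 0.0
        for frac, rule in self.hotspot_rules:
            total += frac
            for probs in rule.values():
                if len(probs) != K or abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigError("hotspot class probabilities must be length-3 simplexes")
        if self.hotspot_rules and abs(total - 1.0) > 1e-9:
            raise ConfigError("hotspot rule fractions must sum to 1")

    def n_normal(self) -> int:
        return sum(self.n_per_class.values())


@dataclass
class SyntheticDataset:
    """One simulated study: metadata, annotation, truth and observed scores."""

    metadata: pd.DataFrame          # cell_line, label (P/M/U-D/C)
    annotation: pd.DataFrame        # gene_id, chrom, strand, txStart, txEnd, cdsStart, cdsEnd
    true_states: pd.DataFrame       # genes x cell lines, integer codes 1/2/3
    gene_scores: "GeneScoreArray"
    modules: dict                   # module name -> list of gene ids
    truth: dict                     # planted hotspot/domain/cancer-private bookkeeping
    config: SimConfig


class GeneScoreArray:
    """Gene-level scores for every (gene, mark, cell line) triple.

    Thin wrapper over a dense ndarray of shape (n_genes, n_marks, n_lines)
    keeping the axis labels together; `.frame(mark)` gives the genes x lines
    DataFrame for one mark.
    """

    def __init__(self, values: np.ndarray, genes, marks, cell_lines):
        values = np.asarray(values, float)
        if values.shape != (len(genes), len(marks), len(cell_lines)):
            raise ValueError("score array shape does not match axis labels")
        self.values = values
        self.genes = list(genes)
        self.marks = list(marks)
        self.cell_lines = list(cell_lines)

    def frame(self, mark: str) -> pd.DataFrame:
        j = self.marks.index(mark)
        return pd.DataFrame(self.values[:, j, :], index=self.genes, columns=self.cell_lines)

    def line_matrix(self, cell_line: str) -> np.ndarray:
        """n_genes x n_marks score matrix for one cell line."""
        j = self.cell_lines.index(cell_line)
        return self.values[:, :, j]

    def __eq__(self, other):
        return (
            isinstance(other, GeneScoreArray)
            and self.genes == other.genes
            and self.marks == other.marks
            and self.cell_lines == other.cell_lines
            and np.array_equal(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def _make_metadata(config: SimConfig) -> pd.DataFrame:
    rows = []
    for cls in ("P", "M", "U/D"):
        for i in range(config.n_per_class.get(cls, 0)):
            rows.append((f"{cls.replace('/', '')}{i + 1:02d}", cls))
    for i in range(config.n_cancer):
        rows.append((f"C{i + 1:02d}", "C"))
    return pd.DataFrame(rows, columns=["cell_line", "label"])


def _make_annotation(config: SimConfig) -> pd.DataFrame:
    p = config.bin_sim
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    gid = 0
    for c in range(config.n_chromosomes):
        for i in range(per_chrom[c]):
            tx_start = 1_000 + i * p.gene_spacing
            tx_end = tx_start + p.gene_length
            cds_start, cds_end = tx_start + 200, tx_end - 200
            strand = "+" if (gid % 2 == 0) else "-"
            rows.append((f"G{gid:05d}", f"chr{c + 1}", strand, tx_start, tx_end, cds_start, cds_end))
            gid += 1
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd"]
    )


def _place_planted_domains(config: SimConfig, annotation: pd.DataFrame) -> list:
    """Deterministic placement of planted runs: (chrom, start_idx, end_idx, state_code)."""
    placed = []
    chrom_groups = {c: idx.to_numpy() for c, idx in annotation.groupby("chrom").groups.items()}
    chroms = sorted(chrom_groups, key=lambda c: int(c[3:]))
    cursor = {c: 10 for c in chroms}
    for r, (state_name, length) in enumerate(config.domain_spec):
        chrom = chroms[r % len(chroms)]
        idx = chrom_groups[chrom]
        start = cursor[chrom]
        if start + length > len(idx):
            raise ConfigError(
                f"planted domain of length {length} does not fit on {chrom}"
            )
        placed.append((chrom, int(idx[start]), int(idx[start + length - 1]), STATE_CODES[state_name]))
        cursor[chrom] = start + length + 20
    return placed


def _markov_path(n: int, initial: np.ndarray, transition: np.ndarray, rng) -> np.ndarray:
    """State-index path (0-based over null/nonactive/active order)."""
    cum_init = np.cumsum(initial)
    cum_trans = np.cumsum(transition, axis=1)
    path = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    path[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, n):
        path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t], side="right")
    return path


def simulate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Draw one complete synthetic dataset.

    Per cell line and per chromosome, gene states follow the configured Markov
    chain, except hotspot and module genes (class-dependent categorical draws)
    and planted domain runs (forced to their planted state in every line).
    Scores are then drawn per state from the emission profiles and truncated
    at zero.  The same config (including seed) always produces the identical
    dataset.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    metadata = _make_metadata(config)
    annotation = _make_annotation(config)
    n_genes = len(annotation)
    gene_ids = annotation["gene_id"].tolist()
    lines = metadata["cell_line"].tolist()
    labels = metadata["label"].tolist()

    planted = _place_planted_domains(config, annotation)
    domain_mask = np.zeros(n_genes, dtype=bool)
    for _, i0, i1, _ in planted:
        domain_mask[i0 : i1 + 1] = True

    free = np.flatnonzero(~domain_mask)
    n_hot = int(round(config.hotspot_fraction * n_genes))
    if n_hot + config.module_size * len(config.module_spec) + config.n_cancer_private > len(free):
        raise ConfigError("not enough genes for hotspots, modules and cancer-private set")
    chosen = rng.choice(free, size=n_hot + config.module_size * len(config.module_spec)
                        + config.n_cancer_private, replace=False)
    hot_idx = np.sort(chosen[:n_hot])
    # split hotspot genes into the configured rule groups
    rule_sizes = [int(round(f * n_hot)) for f, _ in config.hotspot_rules]
    if rule_sizes:
        rule_sizes[-1] = n_hot - sum(rule_sizes[:-1])
    rule_groups = []
    pos = 0
    for size in rule_sizes:
        rule_groups.append(hot_idx[pos : pos + size])
        pos += size
    off = n_hot
    module_idx = {}
    for name in config.module_spec:
        module_idx[name] = np.sort(chosen[off : off + config.module_size])
        off += config.module_size
    cancer_private_idx = np.sort(chosen[off:])

    module_names = list(config.module_spec)

    chrom_of = annotation["chrom"].to_numpy()
    chrom_bounds = []
    start = 0
    for c in range(config.n_chromosomes):
        size = np.count_nonzero(chrom_of == f"chr{c + 1}")
        chrom_bounds.append((start, start + size))
        start += size

    means = np.asarray(config.emission_means, float)
    sds = np.asarray(config.emission_sds, float)
    n_marks = len(config.marks)

    states = np.empty((n_genes, len(lines)), dtype=np.int64)
    scores = np.empty((n_genes, n_marks, len(lines)))

    def _module_state(frac_nonactive: float, n: int) -> np.ndarray:
        """Non-active w.p. f; otherwise active vs null 70/30."""
        u = rng.random(n)
        v = rng.random(n)
        out = np.where(u < frac_nonactive, 1, np.where(v < 0.7, 2, 0))
        return out

    # one consensus epigenome shared by every line: most genes keep the same
    # state across cell types, as in real panels
    consensus = np.empty(n_genes, dtype=np.int64)
    for (lo, hi) in chrom_bounds:
        consensus[lo:hi] = _markov_path(hi - lo, config.initial, config.transition, rng)

    for j, (line, label) in enumerate(zip(lines, labels)):
        eff_class = "U/D" if label == "C" else label
        path = consensus.copy()
        # line-specific deviations from the consensus
        if config.background_flip > 0:
            flip = rng.random(n_genes) < config.background_flip
            shift = rng.integers(1, 3, size=n_genes)
            path = np.where(flip, (path + shift) % 3, path)
        # class-dependent hotspot states, per rule group
        for (_, rule), idx in zip(config.hotspot_rules, rule_groups):
            probs = np.asarray(rule[eff_class])
            path[idx] = rng.choice(3, size=len(idx), p=probs)
        # module genes
        for m, name in enumerate(module_names):
            idx = module_idx[name]
            path[idx] = _module_state(config.module_spec[name][eff_class], len(idx))
        # planted domain runs override everything
        for _, i0, i1, code in planted:
            path[i0 : i1 + 1] = code - 1
        if label == "C":
            path[cancer_private_idx] = 1  # non-active
        states[:, j] = path + 1  # to integer codes

        eps = rng.standard_normal((n_genes, n_marks))
        scores[:, :, j] = np.maximum(0.0, means[path] + sds[path] * eps)

    truth = {
        "hotspot_genes": [gene_ids[i] for i in hot_idx],
        "hotspot_index": hot_idx,
        "hotspot_rule_groups": rule_groups,
        "planted_domains": planted,
        "cancer_private_genes": [gene_ids[i] for i in cancer_private_idx],
        "module_index": module_idx,
    }
    modules = {name: [gene_ids[i] for i in idx] for name, idx in module_idx.items()}

    return SyntheticDataset(
        metadata=metadata,
        annotation=annotation,
        true_states=pd.DataFrame(states, index=gene_ids, columns=lines),
        gene_scores=GeneScoreArray(scores, gene_ids, list(config.marks), lines),
        modules=modules,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# bin-level read simulation
# ---------------------------------------------------------------------------

def simulate_bin_reads(config: SimConfig, dataset: SyntheticDataset,
                       cell_lines=None, marks=None, seed: int | None = None):
    """Simulate raw read positions and 100 bp bin counts from gene scores.

    Poisson counts per bin with rate ``background_rate`` plus, inside each
    gene's promoter (or 80-95% CDS stretch for H3K36me3), an increment
    proportional to that gene's score.  Also plants repeat intervals covering
    roughly ``repeat_fraction`` of each chromosome.

    Returns ``(reads, counts, bins, repeats, chrom_sizes)`` where *reads* maps
    track name ("cell_line|mark") to a DataFrame of (chrom, pos), *counts* is
    the bins x tracks count DataFrame and *repeats* a BED-like DataFrame.
    """
    p = config.bin_sim
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    ann = dataset.annotation
    cell_lines = list(cell_lines) if cell_lines is not None else list(dataset.gene_scores.cell_lines)
    marks = list(marks) if marks is not None else list(config.marks)

    per_chrom = ann.groupby("chrom", sort=False)
    chrom_sizes = {}
    for chrom, sub in per_chrom:
        last = int(sub["txEnd"].max()) + p.gene_spacing
        chrom_sizes[chrom] = int(np.ceil(last / p.bin_size)) * p.bin_size

    # bin grid
    bin_rows = []
    for chrom in chrom_sizes:
        n_bins = chrom_sizes[chrom] // p.bin_size
        starts = np.arange(n_bins) * p.bin_size
        bin_rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + p.bin_size}))
    bins = pd.concat(bin_rows, ignore_index=True)

    # per-gene signal windows (bin index ranges within each chromosome)
    chrom_offset = {}
    off = 0
    for chrom in chrom_sizes:
        chrom_offset[chrom] = off
        off += chrom_sizes[chrom] // p.bin_size
    n_total_bins = off

    def gene_window(row, mark):
        if mark == "H3K36me3":
            L = row.cdsEnd - row.cdsStart
            if row.strand == "+":
                lo = row.cdsStart + int(0.80 * L)
                hi = row.cdsStart + int(0.95 * L)
            else:
                hi = row.cdsEnd - int(0.80 * L)
                lo = row.cdsEnd - int(0.95 * L)
        else:
            tss = row.txStart if row.strand == "+" else row.txEnd
            lo, hi = tss - 2_000, tss + 2_000
        lo = max(lo, 0)
        b0 = chrom_offset[row.chrom] + lo // p.bin_size
        b1 = chrom_offset[row.chrom] + max((hi - 1) // p.bin_size + 1, lo // p.bin_size + 1)
        return b0, b1

    gene_pos = {g: i for i, g in enumerate(dataset.gene_scores.genes)}
    reads, counts = {}, {}
    for line in cell_lines:
        jl = dataset.gene_scores.cell_lines.index(line)
        for mark in marks:
            jm = dataset.gene_scores.marks.index(mark)
            rate = np.full(n_total_bins, p.background_rate * p.library_scale)
            for row in ann.itertuples():
                s = dataset.gene_scores.values[gene_pos[row.gene_id], jm, jl]
                if s <= 0:
                    continue
                b0, b1 = gene_window(row, mark)
                rate[b0:b1] += p.reads_per_score * p.library_scale * s / max(b1 - b0, 1)
            c = rng.poisson(rate)
            track = f"{line}|{mark}"
            counts[track] = c
            # uniform positions within each bin for the drawn counts
            rep = np.repeat(np.arange(n_total_bins), c)
            offs = rng.integers(0, p.bin_size, size=rep.size)
            starts = bins["start"].to_numpy()[rep] + offs
            reads[track] = pd.DataFrame({"chrom": bins["chrom"].to_numpy()[rep], "pos": starts})

    counts_df = pd.DataFrame(counts)
    counts_df.index = bins.index

    # planted repeats: evenly spaced intervals covering ~repeat_fraction per chromosome
    rep_rows = []
    for chrom, size in chrom_sizes.items():
        n_rep = max(1, int(config.bin_sim.repeat_fraction * size / 500))
        step = size // (n_rep + 1)
        for i in range(n_rep):
            s = (i + 1) * step
            rep_rows.append((chrom, s, min(s + 500, size)))
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end"])

    return reads, counts_df, bins, repeats, chrom_sizes


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable view of a SimConfig."""
    d = dataclasses.asdict(config)
    for key in ("emission_means", "emission_sds", "transition", "initial"):
        d[key] = np.asarray(d[key]).tolist()
    d["marks"] = list(d["marks"])
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key in ("emission_means", "emission_sds", "transition", "initial"):
        if key in d:
            d[key] = np.asarray(d[key], float)
    if "marks" in d:
        d["marks"] = tuple(d["marks"])
    if "bin_sim" in d and isinstance(d["bin_sim"], dict):
        d["bin_sim"] = BinSimParams(**d["bin_sim"])
    return SimConfig(**d)
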