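"""End-to-end orchestration: simulate -> HMM -> domains -> hotspots -> classify.

One `PipelineConfig` drives every stage; all randomness flows from a single
root seed through named substreams, and a `RunManifest` (JSON) records the
config snapshot, seeds, thresholds and output-file digests so a run can be
reproduced or resumed.  Stages write their outputs into a fixed directory
layout; with ``resume=True`` a stage whose outputs already exist is loaded
from disk instead of recomputed, which yields byte-identical final results.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import differential as diff
from . import domains as dom
from . import hmm as hm
from . import io as cio
from .simulate import SimConfig, config_to_dict, simulate_dataset

log = logging.getLogger("chromstage")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    training_chrom: str = "chr1"
    n_states: int = 3
    gap_B: int = 100
    gap_kmax: int = 8
    run_gap: bool = False          # gap model selection is a diagnostic; K fixed at 3
    domain_n_perm: int = 1000
    domain_fdr: float = 0.05
    persistence: int = 22
    min_domain_lines: int = 2
    hotspot_n_perm: int = 10_000
    hotspot_fdr: float = 0.05
    svm_C: float = 1.0
    logit_ridge: float = 0.1
    seed: int = 0

    def substream(self, name: str) -> int:
        """Stable per-stage seed derived from the root seed."""
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Run every stage, returning the manifest dict (also written to disk).

    Stage order: simulate -> hmm (fit + decode) -> domains -> differential
    (hotspots) -> classify.  A stage failure propagates with the stage name
    in the log; earlier outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "sim": config_to_dict(config.sim),
            "training_chrom": config.training_chrom,
            "n_states": config.n_states,
            "domain_n_perm": config.domain_n_perm,
            "domain_fdr": config.domain_fdr,
            "persistence": config.persistence,
            "min_domain_lines": config.min_domain_lines,
            "hotspot_n_perm": config.hotspot_n_perm,
            "hotspot_fdr": config.hotspot_fdr,
            "svm_C": config.svm_C,
            "logit_ridge": config.logit_ridge,
            "seed": config.seed,
        },
        "stages": {},
        "outputs": {},
    }

    # -- stage: simulate ----------------------------------------------------
    sim_dir = outdir / "simulated"
    if resume and (sim_dir / "true_states.tsv").exists():
        log.info("simulate: resuming from %s", sim_dir)
        metadata = pd.read_csv(sim_dir / "metadata.tsv", sep="\t")
        annotation = pd.read_csv(sim_dir / "annotation.tsv", sep="\t")
        scores = cio.read_scores(sim_dir, config.sim.marks)
        modules = {
            p.stem.removeprefix("module_"): cio.read_gene_list(p)
            for p in sorted(sim_dir.glob("module_*.txt"))
        }
    else:
        log.info("simulate: drawing synthetic dataset (seed=%d)", config.sim.seed)
        ds = simulate_dataset(config.sim)
        cio.write_dataset(ds, sim_dir)
        metadata, annotation = ds.metadata, ds.annotation
        scores, modules = ds.gene_scores, ds.modules
    modules = {k: modules[k] for k in sorted(modules)}   # stable order across resume
    manifest["stages"]["simulate"] = {"seed": config.sim.seed}

    normal = metadata[metadata["label"] != "C"]
    cancer = metadata[metadata["label"] == "C"]

    # -- stage: hmm ---------------------------------------------------------
    model_path = outdir / "model.json"
    states_path = outdir / "states.tsv"
    if resume and model_path.exists() and states_path.exists():
        log.info("hmm: resuming")
        model = hm.StateHMM.from_json(model_path)
        states = cio.read_tsv(states_path)
    else:
        hmm_seed = config.substream("hmm")
        if config.run_gap:
            pooled = scores.values.transpose(0, 2, 1).reshape(-1, len(scores.marks))
            gap = hm.gap_select_k(pooled, range(1, config.gap_kmax + 1),
                                  B=config.gap_B, seed=config.substream("gap"))
            manifest["stages"]["gap"] = {"chosen_k": gap.chosen_k,
                                         "gap": gap.gap.tolist()}
            log.info("gap statistic selects K=%d", gap.chosen_k)
        log.info("hmm: fitting per-line models on %s", config.training_chrom)
        model = hm.fit_common_model(scores, annotation,
                                    training_chrom=config.training_chrom,
                                    K=config.n_states, seed=hmm_seed)
        model.to_json(model_path)
        states = hm.decode_states(model, scores, annotation)
        cio.write_tsv(states, states_path)
    manifest["stages"]["hmm"] = {"K": config.n_states, "labels": model.labels,
                                 "training_chrom": config.training_chrom}

    # -- stage: domains -----------------------------------------------------
    summary_path = outdir / "domain_genes.tsv"
    if resume and summary_path.exists():
        log.info("domains: resuming")
        domain_summary = cio.read_tsv(summary_path)
        cutoffs = cio.read_json(outdir / "domain_cutoffs.json")
    else:
        log.info("domains: permutation size cutoffs (%d perms)", config.domain_n_perm)
        blocks = dom.call_domains(states, annotation, model=model, scores=scores,
                                  n_perm=config.domain_n_perm, fdr=config.domain_fdr,
                                  seed=config.substream("domains"))
        cutoffs = blocks.pop("_cutoffs")
        summary = dom.summarize_domain_genes(
            blocks, list(states.index), min_lines=config.min_domain_lines,
            persistence=config.persistence)
        domain_summary = summary.table
        cio.write_tsv(domain_summary, summary_path)
        cio.write_json(cutoffs, outdir / "domain_cutoffs.json")
        _write_domain_beds(blocks, annotation, states, outdir / "domains")
    manifest["stages"]["domains"] = {
        "n_perm": config.domain_n_perm, "fdr": config.domain_fdr,
        "cutoffs": cutoffs,
        "n_domain_associated": int(domain_summary["domain_associated"].sum()),
        "n_persistent": int(domain_summary["persistent"].sum()),
    }

    # -- stage: differential (hotspots) -------------------------------------
    hotspot_path = outdir / "hotspots.tsv"
    if resume and hotspot_path.exists():
        log.info("differential: resuming")
        hot_table = cio.read_tsv(hotspot_path)
    else:
        log.info("differential: permutation ANOVA on states (%d perms)",
                 config.hotspot_n_perm)
        hot_table, hot_summary = diff.hotspot_genes(
            states[normal["cell_line"]], normal["label"].to_numpy(),
            n_perm=config.hotspot_n_perm, q=config.hotspot_fdr,
            seed=config.substream("hotspots"))
        cio.write_tsv(hot_table, hotspot_path)
        cio.write_tsv(hot_summary, outdir / "hotspot_states_by_class.tsv")
    manifest["stages"]["differential"] = {
        "n_perm": config.hotspot_n_perm, "fdr": config.hotspot_fdr,
        "n_hotspots": int(hot_table["significant"].sum()),
    }

    # -- stage: classify ----------------------------------------------------
    class_seed = config.substream("classify")
    Xn = states[normal["cell_line"]].T
    yn = normal["label"].to_numpy()
    reports = {}
    for kernel in ("linear", "radial"):
        rep = cls.loocv_svm(Xn, yn, kernel=kernel, C=config.svm_C,
                            seed=class_seed, representation="state")
        reports[kernel] = rep
        cio.write_tsv(rep.to_frame(), outdir / f"loocv_state_{kernel}.tsv", index=False)
    cancer_calls = {}
    if len(cancer):
        Xc = states[cancer["cell_line"]].T
        for kernel in ("linear", "radial"):
            cancer_calls[kernel] = cls.classify_new_lines(
                Xn, yn, Xc, kernel=kernel, C=config.svm_C, seed=class_seed).to_dict()
    fracs, frac_report = cls.module_fractions(states, modules)
    cio.write_tsv(fracs, outdir / "module_fractions.tsv")
    logit = cls.fit_module_logit(fracs.loc[normal["cell_line"]], yn,
                                 ridge=config.logit_ridge)
    logit_pred = cls.classify_module_logit(logit, fracs)
    cio.write_tsv(logit_pred.to_frame("predicted"), outdir / "module_logit_calls.tsv")
    _, leaves, flat = cls.hierarchical_cluster_cell_lines(states)
    cio.write_tsv(flat.to_frame("cluster"), outdir / "hierarchical_clusters.tsv")
    manifest["stages"]["classify"] = {
        "null_model_accuracy": cls.null_model_accuracy(yn),
        "loocv_accuracy": {k: r.accuracy for k, r in reports.items()},
        "cancer_calls": cancer_calls,
        "module_logit_train_accuracy": 100.0 * float(
            (logit_pred.loc[normal["cell_line"]].to_numpy() == yn).mean()),
        "leaf_order": leaves,
    }

    # -- manifest -----------------------------------------------------------
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _digest(p)
    cio.write_json(manifest, outdir / "manifest.json")
    return manifest


def _write_domain_beds(blocks_per_line: dict, annotation: pd.DataFrame,
                       states: pd.DataFrame, outdir: Path) -> None:
    """Significant domains as BED: span of first to last gene, name=state, score=size."""
    from .simulate import STATE_NAMES
    ann = annotation.set_index("gene_id")
    starts = ann["txStart"].loc[states.index].to_numpy()
    ends = ann["txEnd"].loc[states.index].to_numpy()
    outdir.mkdir(parents=True, exist_ok=True)
    for line, blocks in blocks_per_line.items():
        sig = blocks[blocks["significant"]]
        rows = [{"chrom": b.chrom,
                 "start": int(starts[b.start_idx]),
                 "end": int(ends[b.end_idx]),
                 "name": STATE_NAMES[int(b.state)],
                 "score": int(b.size)} for b in sig.itertuples()]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
        safe = line.replace("/", "-")
        df.to_csv(outdir / f"{safe}.bed", sep="\t", header=False, index=False)
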