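"""Run the full pipeline end to end and read its manifest.

Equivalent to `chromstage run --out out/ --seed 0 --n-genes 600` from the
shell.  Every stage writes plain-text outputs under the output directory and
the manifest records config, per-stage summaries and SHA-256 digests of every
file, so a rerun with the same config is byte-identical and a run can be
resumed with `resume=True`.
"""

import json
import tempfile
from pathlib import Path

from chromstage import SimConfig
from chromstage.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    sim=SimConfig(n_genes=600, seed=0),
    domain_n_perm=300,
    hotspot_n_perm=2000,
    seed=0,
)

outdir = Path(tempfile.mkdtemp(prefix="chromstage_"))
manifest = run_pipeline(cfg, outdir)

print(f"\noutputs under {outdir}:")
for name in sorted(manifest["outputs"]):
    print(f"  {name}")

print("\nstage summaries:")
print(json.dumps(manifest["stages"], indent=2, default=str))
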