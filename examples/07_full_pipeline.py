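"""Run the whole analysis end-to-end from a single config.

Stages: simulate -> filter -> merge -> orthomap -> contract -> stats ->
famloss -> report. Outputs (FASTA/GFF3/TSV/JSON plus report.md and a
manifest with the config hash) land in the run directory; rerunning with
the same config reproduces them exactly.

Equivalent CLI: synshrink run --seed 1 --n-genes 60 --out runs/demo
"""

from pathlib import Path

from synshrink import PipelineConfig, run_pipeline

out = run_pipeline(PipelineConfig(seed=1, n_genes=60, n_contigs=4), "runs/demo")
print((Path(out) / "report.md").read_text())
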