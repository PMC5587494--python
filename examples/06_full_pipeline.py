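"""Run the whole pipeline on a synthetic study and print the report.

simulate -> isotope assignment -> condition/timing prep -> two-tier
refueling selection -> transient-CJS stopover estimation. Equivalent to
`warblerstop run-all --seed 1 --out out/`.
"""

from pathlib import Path

from warblerstop import PipelineConfig, SimulationConfig, run_pipeline

outdir = Path("example_pipeline_output")
cfg = PipelineConfig(outdir=outdir, seed=1, simulate=SimulationConfig(seed=1))
report = run_pipeline(cfg)

print(report.report_path.read_text())
print(f"(per-stage tables written under {outdir}/)")
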