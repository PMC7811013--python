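"""Run the full pipeline into an output directory and render the report.

Stages: simulate (tables, images, genotypes) -> traits (NIfTI -> 10-trait
TSV) -> longitudinal -> genetics -> cross-sectional, with a manifest that
makes re-runs no-ops while inputs are unchanged.

Equivalent shell command:  msqmri run --seed 6 --outdir out/demo
"""

from msqmri import CohortConfig, render_report, run_pipeline

manifest = run_pipeline(CohortConfig(seed=6), "out/pipeline_demo")
print("stages completed:", ", ".join(manifest.stages))

text, summary = render_report("out/pipeline_demo")
print(text[:1500])
# report.md / report.json in the output directory aggregate the per-trait
# decomposition, cross-tissue correlations, and genetic-scan summaries.
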