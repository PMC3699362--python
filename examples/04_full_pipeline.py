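"""The whole analysis in one call.

Generates a complete synthetic study (tree, outlines, landmarks for 37
taxa x 2 wings), then runs every stage — per-specimen RSM, joint GPA
with sliding semilandmarks, species means, size regressions, shape
scores, MANCOVA, coloration-group GLM, independent contrasts and the
phylogenetic ANOVA — and prints the consolidated report. Rerunning with
the same seeds reproduces every number bit for bit.
"""

import wingshape as ws

config = ws.RunConfig(
    simulation=ws.SimulationSpec(seed=1),
    output_dir="scratch/pipeline_demo",
    n_sim=1000,
    seed=0,
)
result = ws.run_pipeline(config)
print(result.report_text)
print("result tables written to", config.output_dir)
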