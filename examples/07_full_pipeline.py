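"""End-to-end pipeline run with a consolidated report.

Runs simulate -> QC -> clonality -> signatures -> scores -> screen ->
composition -> survival under one global seed and prints the
ground-truth comparison section of report.json.
"""

import json
import warnings

import immunosift as ims

warnings.filterwarnings("ignore", category=UserWarning)

config = ims.RunConfig(
    outdir="scratch/example_run",
    seed=7,
    synthetic={"cells_per_clone_per_timepoint": 100, "n_genes": 600},
    n_permutations=2000,
)
report = ims.run_pipeline(config)

print("ground-truth comparison:")
print(json.dumps(report["ground_truth_comparison"], indent=2, sort_keys=True))
print(f"\noutputs written to {config.outdir} ({len(report['outputs'])} files, checksummed)")
print()
print("Jaccard values compare detected core/recurrent gene sets with the")
print("planted truth; the screen and survival entries confirm the planted")
print("strongest guide ranks first and the planted hazard difference is seen.")
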