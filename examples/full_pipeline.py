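"""Run the whole pipeline — simulate, preprocess, analyze, test, report.

Uses a reduced problem size (3 subjects, 10 channels) so the example
finishes in well under a minute; the written tables live in
``example_output/`` and every table header carries the config hash and seed.
"""

import json
from pathlib import Path

from mvfeeg import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulation=SimulationConfig(
        n_subjects=3, n_runs=2, trials_per_run=12,
        channels=("C3", "FC1", "FC5", "CP1", "CP5", "C4", "FC2", "FC6", "CP2", "CP6"),
        n_left_handed=1,
    ),
    seed=11,
)

outdir = Path("example_output")
state = run_pipeline(config, outdir)

report = json.loads((outdir / "report.json").read_text())
print("tables written to", outdir, "->", sorted(p.name for p in outdir.iterdir()))
print("\ntrial accounting (per subject):")
for row in report["trial_counts"]:
    print(" ", row)
print("\nlatency summary:")
for row in report["lt_summary"]:
    print(f"  {row['condition']}: {row['mean_s']:.2f} +- {row['sd_s']:.2f} s")
print("\nalpha/beta ERD window means at C3/C4 (%):")
for row in report["erd_window_means"]:
    print(f"  {row['channel']} {row['band']:>5} {row['condition']}: {row['erd_pct']:6.1f}")
print("\nsignificant contrasts:", len(report["significant_contrasts"]))
print("\nRe-running with the same seed reproduces every table byte for byte;"
      " trial counts mirror the artifact/no-pedal exclusion rules.")
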