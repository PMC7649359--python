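"""Recover a planted event-related desynchronization from synthetic EEG.

Plants a 50% alpha-power reduction (amplitude factor sqrt(0.5)) at channel
C3 from the moment of embodiment (pedal press) onward, runs the
preprocessing chain, and compares the estimated ERD against the analytic
ground truth (a^2 - 1) * 100 = -50%.
"""

import math

from mvfeeg import (
    LatencyModel,
    SimulationConfig,
    SpectralParams,
    compute_erd,
    compute_topography,
    epoch_recording,
    generate_dataset,
    select_embodiment_epochs,
)

a = math.sqrt(0.5)
conds = ("NV", "CV", "IV")
config = SimulationConfig(
    n_subjects=1, n_runs=1, trials_per_run=240, n_left_handed=0,
    channels=("C3", "C4", "FC1", "FC2", "CP1", "CP2"),
    erd_depth={(c, "C3", "alpha"): a for c in conds},
    latency={c: LatencyModel(2.0, 0.5, 0.05) for c in conds},
    seed=3,
)
experiment = generate_dataset(config)

epochs = epoch_recording(experiment.recordings[(0, 0)], experiment.events)
epochs = select_embodiment_epochs(epochs)  # [pedal, pedal + 4 s) windows
params = SpectralParams()

curve = compute_erd(epochs, params, "C3", "alpha")
print(f"planted ERD at C3 (alpha): {(a * a - 1) * 100:.1f}%")
print(f"estimated ERD (time-mean): {curve.values.mean():.1f}%  "
      f"over {len(curve.times)} sliding windows")

topo = compute_topography(epochs, params, "alpha")
print("\nper-channel alpha ERD/ERS (%):")
for ch, v in zip(topo.channels, topo.values):
    print(f"  {ch:>4}: {v:7.1f}")
print("\nOnly the planted channel shows a deep power loss; the unattenuated"
      " channels sit near 0%, i.e. no change against the pre-go baseline.")
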