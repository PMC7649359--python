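"""Phase-lag-index networks and weighted graph metrics.

Couples C3 and FC1 with a fixed pi/4 phase lag in the synthetic EEG, builds
the 8-26 Hz PLI network, thresholds it across the sparsity sweep, and
prints the weighted clustering coefficient and shortest path length.
"""

import math

from mvfeeg import (
    Coupling,
    LatencyModel,
    SimulationConfig,
    compute_pli,
    epoch_recording,
    generate_dataset,
    metric_sweep,
    select_embodiment_epochs,
)

conds = ("NV", "CV", "IV")
config = SimulationConfig(
    n_subjects=1, n_runs=1, trials_per_run=60, n_left_handed=0,
    channels=("C3", "FC1", "FC5", "CP1", "CP5", "C4", "FC2", "FC6", "CP2", "CP6"),
    coupling=(Coupling("C3", "FC1", math.pi / 4, 8.0),),
    latency={c: LatencyModel(2.0, 0.5, 0.0) for c in conds},
    seed=5,
)
experiment = generate_dataset(config)
epochs = select_embodiment_epochs(
    epoch_recording(experiment.recordings[(0, 0)], experiment.events)
)

graph = compute_pli(epochs, band=(8.0, 26.0))
i, j = graph.labels.index("C3"), graph.labels.index("FC1")
print(f"PLI(C3, FC1) with planted pi/4 lag: {graph.weights[i, j]:.3f}")
others = [graph.weights[a, b] for a in range(10) for b in range(a + 1, 10)
          if {a, b} != {i, j}]
print(f"median PLI of uncoupled pairs:      {sorted(others)[len(others) // 2]:.3f}")

print("\nmetric sweep over the sparsity grid (fraction of retained edges):")
print(metric_sweep(graph).to_string(index=False))
print("\nThe coupled pair carries a PLI near 1 (a consistent nonzero phase"
      " lag) while uncoupled pairs stay near 0. On this 10-electrode demo"
      " the standard sparsity grid keeps only 5-9 edges, so the thresholded"
      " graph has no triangles (wCC 0) and is partly disconnected (flagged;"
      " wsPL averages the connected pairs only) - on the full 32-channel"
      " montage the same grid keeps 50-99 edges.")
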