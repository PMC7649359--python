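"""Score the embodiment questionnaire and run the nonparametric battery.

Generates questionnaire ratings for 12 subjects (ownership and location
rated higher under vibration by construction), summarizes them per
statement, and applies the Friedman test with Wilcoxon signed-rank
post-hocs (Bonferroni over the three condition pairs).
"""

from mvfeeg import (
    SimulationConfig,
    eq_matrix,
    friedman,
    generate_dataset,
    score_eq,
    wilcoxon_posthoc,
)

conds = ("NV", "CV", "IV")
config = SimulationConfig(n_subjects=12, n_runs=1, trials_per_run=3,
                          channels=("C3", "C4"), n_left_handed=2, seed=17)
eq = generate_dataset(config).eq

summary = score_eq(eq)
print("medians per condition and statement:")
print(summary.pivot(index="statement_id", columns="condition", values="median"))

print("\nFriedman + Wilcoxon post-hocs per statement:")
for st in ("L-1", "O-1", "A-2", "D-1"):
    m = eq_matrix(eq, st, conds)
    f = friedman(m, conds)
    line = f"  {st}: chi2={f.statistic:5.2f} p={f.p:.3f}"
    if f.p < 0.05:
        posthoc = wilcoxon_posthoc(m, conds)
        sig = [r.contrast for r in posthoc if r.p_adj < 0.05]
        line += f"  significant contrasts: {sig}"
    print(line)
print("\nStatements with the largest planted condition effects (ownership)"
      " reach significance with vibration-vs-none contrasts; statements"
      " rated equally under every condition (A-2, D-1) do not, and at 12"
      " subjects the weaker planted effects may stay below threshold.")
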