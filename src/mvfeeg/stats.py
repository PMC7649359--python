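"""The repeated-measures statistical battery.

Assumption checks (Shapiro-Wilk, Levene), a one-way within-subject ANOVA
with subject as random factor plus Bonferroni-corrected paired contrasts,
pointwise (time- or time-frequency-resolved) p-value maps, the Friedman
test, and Wilcoxon signed-rank post-hocs for the questionnaire. All tests
are two-sided at alpha = 0.05 unless stated otherwise.

The ANOVA uses the classical within-subject sum-of-squares decomposition
(subject, condition, residual); with condition fixed and subject random,
the condition F is MS_condition / MS_residual on (k-1, (n-1)(k-1)) degrees
of freedom. Pointwise maps report uncorrected per-bin p values, matching
how per-bin post-hoc maps are conventionally displayed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache as _lru_cache

import numpy as np
from scipy import stats as sps

DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (("CV", "NV"), ("IV", "NV"), ("IV", "CV"))


@dataclass
class TestResult:
    """One test outcome: statistic, degrees of freedom, raw and adjusted p."""

    test: str
    statistic: float
    p: float
    df: tuple[float, ...] | None = None
    p_adj: float | None = None
    adjustment: str | None = None
    contrast: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0 <= self.p <= 1 + 1e-12:
            raise ValueError(f"p value {self.p} outside [0, 1]")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p over m comparisons: min(1, p * m)."""
    return min(1.0, p * m)


def check_assumptions(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """Shapiro-Wilk normality per group and Levene homogeneity across groups.

    Reported but not gating: downstream tests run regardless of the outcome.
    """
    out = []
    for label, x in groups.items():
        x = np.asarray(x, dtype=float)
        if len(x) < 3:
            raise ValueError(f"group {label!r} needs at least 3 observations")
        if np.ptp(x) == 0:
            raise ValueError(f"Shapiro-Wilk undefined for constant sample {label!r}")
        w, p = sps.shapiro(x)
        out.append(TestResult("shapiro-wilk", float(w), float(p), contrast=label))
    if len(groups) >= 2:
        stat, p = sps.levene(*[np.asarray(v, float) for v in groups.values()])
        out.append(TestResult("levene", float(stat), float(p),
                              contrast="+".join(groups)))
    return out


def _as_matrix(values: np.ndarray, conditions: tuple[str, ...]) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim < 2 or x.shape[1] != len(conditions):
        raise ValueError("values must be subjects x conditions (x bins)")
    if x.shape[0] < 2:
        raise ValueError("at least 2 subjects required")
    if not np.isfinite(x).all():
        raise ValueError("missing cell in the subject x condition design")
    return x


def rm_anova(values: np.ndarray, conditions: tuple[str, ...]) -> TestResult:
    """One-way within-subject ANOVA (condition fixed, subject random).

    ``values`` is a complete subjects x conditions matrix. Identical
    conditions give F = 0, p = 1.
    """
    x = _as_matrix(values, conditions)
    f, p, df = _rm_anova_core(x)
    return TestResult("rm-anova", float(f), float(p), df=df,
                      contrast="|".join(conditions))


def _rm_anova_core(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Within-subject decomposition; x is (subjects, conditions, *bins)."""
    n, k = x.shape[0], x.shape[1]
    grand = x.mean(axis=(0, 1))
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum(axis=0)
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum(axis=0)
    ss_tot = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_subj - ss_cond, 0.0)
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    # guard numerically-zero effects (identical conditions) against 0/0
    tiny = 1e-12 * np.maximum(ss_tot, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df_cond) / (ss_err / df_err)
    f = np.where(ss_cond <= tiny, 0.0, f)
    p = np.where(ss_cond <= tiny, 1.0, sps.f.sf(f, df_cond, df_err))
    return f, p, (df_cond, df_err)


def paired_posthoc(
    values: np.ndarray,
    conditions: tuple[str, ...],
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> list[TestResult]:
    """Bonferroni-corrected paired t contrasts between condition pairs."""
    x = _as_matrix(values, conditions)
    m = len(pairs)
    out = []
    for a, b in pairs:
        d = x[:, conditions.index(a)] - x[:, conditions.index(b)]
        if np.ptp(d) == 0:
            t, p = (0.0, 1.0) if d[0] == 0 else (np.inf * np.sign(d[0]), 0.0)
        else:
            t, p = sps.ttest_rel(x[:, conditions.index(a)], x[:, conditions.index(b)])
        out.append(TestResult(
            "paired-t", float(t), float(p), df=(len(d) - 1,),
            p_adj=bonferroni(float(p), m), adjustment=f"bonferroni(m={m})",
            contrast=f"{a} vs {b}",
        ))
    return out


@dataclass
class PValueMap:
    """Per-bin p values on the input grid, for the omnibus test and each
    Bonferroni-adjusted pairwise contrast."""

    times: np.ndarray
    omnibus_p: np.ndarray
    contrasts: dict[str, np.ndarray]  # contrast label -> adjusted p per bin
    alpha: float = 0.05

    def significant_spans(self, contrast: str) -> list[tuple[float, float]]:
        """Contiguous time spans where the contrast's p < alpha."""
        sig = self.contrasts[contrast] < self.alpha
        spans = []
        in_run, t0 = False, 0.0
        for t, s in zip(self.times, sig):
            if s and not in_run:
                in_run, t0 = True, t
            elif not s and in_run:
                in_run = False
                spans.append((t0, t))
        if in_run:
            spans.append((t0, float(self.times[-1])))
        return spans


def pointwise_map(
    values: np.ndarray,
    conditions: tuple[str, ...],
    times: np.ndarray,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    alpha: float = 0.05,
) -> PValueMap:
    """rm-ANOVA plus post-hoc contrasts applied independently at each bin.

    ``values`` is subjects x conditions x bins (bins may be a flattened
    time-frequency grid); p values are per-bin, uncorrected across bins.
    """
    x = _as_matrix(values, conditions)
    if x.ndim != 3 or x.shape[2] != len(times):
        raise ValueError("values must be subjects x conditions x bins matching times")
    _, omni_p, _ = _rm_anova_core(x)
    n = x.shape[0]
    m = len(pairs)
    contrasts = {}
    for a, b in pairs:
        d = x[:, conditions.index(a), :] - x[:, conditions.index(b), :]
        mean, sd = d.mean(axis=0), d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t = np.where((mean == 0) & (sd == 0), 0.0, t)
        p = 2.0 * sps.t.sf(np.abs(t), n - 1)
        contrasts[f"{a} vs {b}"] = np.minimum(1.0, p * m)
    return PValueMap(times=np.asarray(times), omnibus_p=omni_p,
                     contrasts=contrasts, alpha=alpha)


@_lru_cache(maxsize=32)
def _friedman_exact_dist(n: int) -> tuple[tuple[float, float], ...]:
    """Exact null distribution of the Friedman statistic for k = 3 blocks.

    Each subject contributes a uniformly random permutation of the ranks
    (1, 2, 3); the joint distribution of the column rank sums is built by
    dynamic programming. Returns (statistic, probability) pairs.
    """
    from itertools import permutations

    perms = list(permutations((1, 2, 3)))
    dist: dict[tuple[int, int, int], float] = {(0, 0, 0): 1.0}
    for _ in range(n):
        new: dict[tuple[int, int, int], float] = {}
        for (a, b, c), p in dist.items():
            for r in perms:
                key = (a + r[0], b + r[1], c + r[2])
                new[key] = new.get(key, 0.0) + p / 6.0
        dist = new
    out: dict[float, float] = {}
    for (a, b, c), p in dist.items():
        s = round((a * a + b * b + c * c) / n - 12.0 * n, 9)
        out[s] = out.get(s, 0.0) + p
    return tuple(sorted(out.items()))


_EXACT_FRIEDMAN_MAX_N = 25


def friedman(values: np.ndarray, conditions: tuple[str, ...]) -> TestResult:
    """Friedman test on a complete subjects x conditions block.

    Mid-ranks handle ties within a subject's row, with the standard tie
    correction of the statistic; fully tied data give statistic 0 and p = 1.
    For three conditions without within-row ties and up to 25 subjects the
    p value comes from the exact permutation null with the mid-p convention
    (P(S > s) + P(S = s)/2), which keeps the realized test size at the
    nominal level despite the statistic's discreteness; otherwise the
    chi-square approximation with k - 1 degrees of freedom is used.
    """
    x = _as_matrix(values, conditions)
    n, k = x.shape
    ranks = sps.rankdata(x, axis=1)
    rsum = ranks.sum(axis=0)
    s = ((rsum - n * (k + 1) / 2.0) ** 2).sum()
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie += float((counts**3 - counts).sum())
    corr = 1.0 - tie / (n * k * (k * k - 1))
    if corr <= 0:  # every row fully tied
        return TestResult("friedman", 0.0, 1.0, df=(k - 1,), contrast="|".join(conditions))
    stat = 12.0 * s / (n * k * (k + 1)) / corr
    if k == 3 and tie == 0.0 and n <= _EXACT_FRIEDMAN_MAX_N:
        p_gt = p_eq = 0.0
        for sv, pv in _friedman_exact_dist(n):
            if sv > stat + 1e-9:
                p_gt += pv
            elif abs(sv - stat) <= 1e-9:
                p_eq += pv
        return TestResult("friedman-exact-midp", float(stat), float(p_gt + 0.5 * p_eq),
                          df=(k - 1,), contrast="|".join(conditions))
    return TestResult("friedman", float(stat), float(sps.chi2.sf(stat, k - 1)),
                      df=(k - 1,), contrast="|".join(conditions))


def wilcoxon_posthoc(
    values: np.ndarray,
    conditions: tuple[str, ...],
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> list[TestResult]:
    """Wilcoxon signed-rank contrasts with Bonferroni adjustment.

    Zero differences are excluded; mid-ranks handle tied magnitudes. The
    exact null distribution is used for n <= 25 without ties, the normal
    approximation with continuity correction otherwise. All differences zero
    in a contrast is an error.
    """
    x = _as_matrix(values, conditions)
    m = len(pairs)
    out = []
    for a, b in pairs:
        d = x[:, conditions.index(a)] - x[:, conditions.index(b)]
        nz = d[d != 0]
        if len(nz) == 0:
            raise ValueError(f"all differences zero in contrast {a} vs {b}")
        has_ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
        res = sps.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                           alternative="two-sided", method=method)
        out.append(TestResult(
            f"wilcoxon-{method}", float(res.statistic), float(res.pvalue),
            p_adj=bonferroni(float(res.pvalue), m), adjustment=f"bonferroni(m={m})",
            contrast=f"{a} vs {b}",
        ))
    return out
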