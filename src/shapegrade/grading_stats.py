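"""Grading statistics: regression, ANOVA, pairwise tests, ROC and cutoffs.

The pairwise tests default to Welch (unequal-variance) two-tailed t-tests;
pooled-variance is available. Pairwise p-values are reported raw (no
multiplicity correction) with optional Holm adjustment. AUROC confidence
intervals default to a seeded stratified bootstrap; DeLong is available.
ROC direction is always explicit, never inferred from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_COLUMNS = ("surface_regularity", "sphericity", "flatness", "elongation")

LOWER_IS_POSITIVE = "lower_is_positive"
HIGHER_IS_POSITIVE = "higher_is_positive"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
        }


@dataclass
class GroupComparison:
    f_statistic: float
    anova_p: float
    pairwise: dict  # {(g_i, g_j): {"t": ..., "p": ...}}
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "anova_p": self.anova_p,
            "degenerate": self.degenerate,
            "pairwise": {
                f"{a}v{b}": dict(v) for (a, b), v in self.pairwise.items()
            },
        }


@dataclass
class RocResult:
    direction: str
    points: list  # [(threshold, sensitivity, specificity), ...]
    auroc: float
    ci95: tuple[float, float]
    p_value: float
    all_tied: bool = False

    def as_dict(self) -> dict:
        return {
            "direction": self.direction,
            "auroc": self.auroc,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "all_tied": self.all_tied,
            "points": [list(p) for p in self.points],
        }


@dataclass
class CutoffResult:
    threshold: float
    comparison: str  # "<" or ">"
    sensitivity: float
    specificity: float
    criterion: str = "youden"
    youden_j: float = 0.0
    informative: bool = True

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "comparison": self.comparison,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "criterion": self.criterion,
            "youden_j": self.youden_j,
            "informative": self.informative,
        }


def fit_linear(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the two-sided zero-slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA (F, p).

    Zero within-group variance with unequal means returns (inf, 0.0) — the
    degenerate perfect-separation convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def pairwise_t(groups: dict, variant: str = "welch") -> dict:
    """Two-tailed t-tests for every pair of groups.

    ``groups`` maps a label (e.g. WHO grade) to its values. Welch by
    default; ``variant='pooled'`` uses the equal-variance test. p-values
    are raw; use :func:`holm_adjust` for multiplicity control.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant}")
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k} has n={len(v)} < 2")
    out = {}
    for a, b in combinations(sorted(groups), 2):
        t, p = stats.ttest_ind(
            np.asarray(groups[a], dtype=float),
            np.asarray(groups[b], dtype=float),
            equal_var=(variant == "pooled"),
        )
        out[(a, b)] = {"t": float(t), "p": float(p)}
    return out


def holm_adjust(pairwise: dict) -> dict:
    """Holm step-down adjusted copies of the pairwise p-values."""
    keys = sorted(pairwise, key=lambda k: pairwise[k]["p"])
    m = len(keys)
    adj, running = {}, 0.0
    for i, k in enumerate(keys):
        running = max(running, min(1.0, (m - i) * pairwise[k]["p"]))
        adj[k] = {**pairwise[k], "p_holm": running}
    return adj


def _auroc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(tie), via midranks (O(n log n))."""
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_curve(
    scores,
    labels,
    direction: str = LOWER_IS_POSITIVE,
    n_boot: int = 2000,
    ci_method: str = "bootstrap",
    seed: int = 0,
) -> RocResult:
    """Threshold sweep, AUROC, 95% CI and Mann-Whitney p-value.

    With ``lower_is_positive`` a case is called positive when its score is
    <= the threshold. The sweep visits every unique score; trapezoidal
    AUROC over the resulting points equals the Mann-Whitney estimate with
    ties counted 1/2. CI by stratified bootstrap (percentile, seeded) or
    DeLong.
    """
    if direction not in (LOWER_IS_POSITIVE, HIGHER_IS_POSITIVE):
        raise ValueError(f"unknown direction {direction!r}")
    if ci_method not in ("bootstrap", "delong"):
        raise ValueError(f"ci_method must be 'bootstrap' or 'delong', got {ci_method}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    pos, neg = scores[labels], scores[~labels]
    # effective scores: higher = more positive
    sgn = -1.0 if direction == LOWER_IS_POSITIVE else 1.0
    epos, eneg = sgn * pos, sgn * neg

    all_tied = np.ptp(scores) == 0
    thresholds = np.unique(scores)
    if direction == LOWER_IS_POSITIVE:
        # sweep from most to least stringent: low thresholds first
        points = [
            (float(t), float((pos <= t).mean()), float((neg > t).mean()))
            for t in thresholds
        ]
    else:
        points = [
            (float(t), float((pos >= t).mean()), float((neg < t).mean()))
            for t in thresholds[::-1]
        ]

    auroc = 0.5 if all_tied else _auroc_mann_whitney(epos, eneg)

    if all_tied:
        p_value = 1.0
    else:
        p_value = float(
            stats.mannwhitneyu(epos, eneg, alternative="two-sided").pvalue
        )

    if ci_method == "delong":
        ci = _delong_ci(epos, eneg, auroc)
    else:
        rng = np.random.default_rng(seed)
        n_pos, n_neg = len(epos), len(eneg)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            bp = epos[rng.integers(0, n_pos, n_pos)]
            bn = eneg[rng.integers(0, n_neg, n_neg)]
            boots[i] = _auroc_mann_whitney(bp, bn)
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))

    return RocResult(
        direction=direction,
        points=points,
        auroc=float(auroc),
        ci95=ci,
        p_value=p_value,
        all_tied=bool(all_tied),
    )


def _delong_ci(epos: np.ndarray, eneg: np.ndarray, auroc: float) -> tuple[float, float]:
    """DeLong structural-components variance and normal-approximation CI."""
    m, n = len(epos), len(eneg)
    v10 = np.array([((x > eneg).sum() + 0.5 * (x == eneg).sum()) / n for x in epos])
    v01 = np.array([((epos > y).sum() + 0.5 * (epos == y).sum()) / m for y in eneg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return (max(0.0, auroc - half), min(1.0, auroc + half))


def select_cutoff(roc: RocResult, criterion: str = "youden") -> CutoffResult:
    """Operating point maximizing Youden's J = sens + spec - 1.

    Ties break toward higher specificity. The reported threshold is the
    midpoint between the selected unique score and its neighbor on the
    negative side, so a strict comparison reproduces the operating numbers.
    """
    if criterion != "youden":
        raise ValueError(f"unknown criterion {criterion!r}")
    pts = roc.points
    best_i, best_j, best_spec = 0, -math.inf, -1.0
    for i, (_, sens, spec) in enumerate(pts):
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and spec > best_spec):
            best_i, best_j, best_spec = i, j, spec
    thr, sens, spec = pts[best_i]
    uniq = sorted({p[0] for p in pts})
    k = uniq.index(thr)
    if roc.direction == LOWER_IS_POSITIVE:
        if k + 1 < len(uniq):
            thr_rep = 0.5 * (uniq[k] + uniq[k + 1])
        else:
            thr_rep = uniq[k] + 0.5 * (uniq[-1] - uniq[0] or 1.0) / max(len(uniq) - 1, 1)
        comparison = "<"
    else:
        if k - 1 >= 0:
            thr_rep = 0.5 * (uniq[k - 1] + uniq[k])
        else:
            thr_rep = uniq[k] - 0.5 * (uniq[-1] - uniq[0] or 1.0) / max(len(uniq) - 1, 1)
        comparison = ">"
    return CutoffResult(
        threshold=float(thr_rep),
        comparison=comparison,
        sensitivity=float(sens),
        specificity=float(spec),
        criterion=criterion,
        youden_j=float(best_j),
        informative=bool(best_j > 1e-12),
    )


# ROC contrasts reported per feature: positive class and which grades enter.
ROC_CONTRASTS = {
    "1v3": (lambda g: g == 3, lambda g: g != 2),
    "12v3": (lambda g: g == 3, lambda g: True),
    "1v23": (lambda g: g >= 2, lambda g: True),
}


def run_grading_analysis(
    cohort: pd.DataFrame,
    ttest_variant: str = "welch",
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    holm: bool = False,
) -> dict:
    """Full grading report for a cohort table.

    ``cohort`` needs columns who_grade, mitotic_rate and the four feature
    columns. For each feature: OLS regression against mitotic rate,
    one-way ANOVA across grades, the three pairwise tests, three ROC
    contrasts (1 vs 3, {1,2} vs 3, 1 vs {2,3}; positive = higher grade,
    lower score = positive), and Youden cutoffs for grade-1 and grade-3
    identification.
    """
    required = {"who_grade", "mitotic_rate", *FEATURE_COLUMNS}
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise ValueError(f"cohort table is missing columns: {', '.join(missing)}")
    grades = cohort["who_grade"].astype(int)
    present = sorted(grades.unique())
    if present != [1, 2, 3]:
        raise ValueError(f"cohort must contain grades 1, 2 and 3; found {present}")
    counts = grades.value_counts()
    if (counts < 2).any():
        raise ValueError("insufficient group sizes: every grade needs >= 2 cases")

    report: dict = {"n_per_grade": {int(g): int(counts[g]) for g in present}, "features": {}}
    for feat in FEATURE_COLUMNS:
        vals = cohort[feat].astype(float).to_numpy()
        groups = {g: vals[grades.to_numpy() == g] for g in (1, 2, 3)}
        reg = fit_linear(cohort["mitotic_rate"].astype(float).to_numpy(), vals)
        f_stat, anova_p = anova_oneway([groups[1], groups[2], groups[3]])
        pw = pairwise_t(groups, variant=ttest_variant)
        if holm:
            pw = holm_adjust(pw)
        comparison = GroupComparison(
            f_statistic=f_stat,
            anova_p=anova_p,
            pairwise=pw,
            degenerate=math.isinf(f_stat),
        )
        rocs, cutoffs = {}, {}
        for name, (is_pos, in_scope) in ROC_CONTRASTS.items():
            sel = grades.map(in_scope).to_numpy()
            roc = roc_curve(
                vals[sel],
                grades[sel].map(is_pos).to_numpy(),
                direction=LOWER_IS_POSITIVE,
                n_boot=n_boot,
                ci_method=ci_method,
                seed=seed,
            )
            rocs[name] = roc
        # grade-3 identification: {1,2} vs 3, lower score calls grade 3
        cutoffs["grade3"] = select_cutoff(rocs["12v3"])
        # grade-1 identification: 1 vs {2,3}, higher score calls grade 1
        roc_g1 = roc_curve(
            vals,
            (grades == 1).to_numpy(),
            direction=HIGHER_IS_POSITIVE,
            n_boot=n_boot,
            ci_method=ci_method,
            seed=seed,
        )
        cutoffs["grade1"] = select_cutoff(roc_g1)
        report["features"][feat] = {
            "group_means": {g: float(groups[g].mean()) for g in (1, 2, 3)},
            "regression_vs_mitotic": reg.as_dict(),
            "group_comparison": comparison.as_dict(),
            "roc": {name: r.as_dict() for name, r in rocs.items()},
            "cutoffs": {k: v.as_dict() for k, v in cutoffs.items()},
        }
    return report
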