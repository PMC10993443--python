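"""Bivariate screening of candidate determinants of child undernutrition.

Each candidate variable is screened against each Z-score outcome with the
test matched to its type:

* continuous — Pearson or Spearman correlation.  The historical choice was a
  visual scatterplot check; here a deterministic surrogate decides: Pearson
  only if *both* variables pass D'Agostino's K² normality test at α = 0.05,
  Spearman otherwise (overridable per variable).  A correlation is
  *reportable* when |r| ≥ 0.10 and p < 0.05.
* dichotomous — independent-samples t test.  The folded F test (ratio of the
  larger to the smaller sample variance) decides at α = 0.05 between the
  pooled and the Welch–Satterthwaite branch.
* categorical — one-way fixed-effects ANOVA (general-linear-model F test on
  possibly unbalanced data) with R² = SS_between / SS_total and the
  lowest-mean level reported.
* effect modification — a two-way model with main effects plus interaction;
  the interaction-block F decides (p < 0.05) whether one variable modifies
  the other's association.

No multiple-testing correction is applied at this stage — screening is
deliberately permissive, and downstream model selection does the pruning.
Continuous variables also get categorical versions via :func:`categorize`,
with the built-in cut-point schemes used throughout the analysis; the
categorical version is screened first and the continuous original is kept
only if the categorical one shows no significant association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
REPORTABLE_R = 0.10


@dataclass
class CorrelationResult:
    variable: str
    method: str                       # "pearson" | "spearman"
    r: float
    ci95: tuple[float, float]
    p: float
    n: int
    reportable: bool = field(init=False)
    ci_sign_consistent: bool = field(init=False)

    def __post_init__(self) -> None:
        self.reportable = (abs(self.r) >= REPORTABLE_R) and (self.p < ALPHA)
        lo, hi = self.ci95
        # a CI that excludes the point estimate signals a transcription error
        self.ci_sign_consistent = lo <= self.r <= hi


@dataclass
class TTestResult:
    variable: str
    group_labels: tuple
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    diff_means: float                 # mean(group0) − mean(group1)
    folded_f: float
    folded_f_p: float
    variance_equal: bool
    branch: str                       # "pooled" | "satterthwaite"
    t: float
    p: float
    n: tuple[int, int]


@dataclass
class AnovaResult:
    variable: str
    levels: list
    F: float
    p: float
    r_square: float
    lowest_mean_level: object
    n: int


@dataclass
class InteractionResult:
    variables: tuple[str, str]
    interaction_F: float
    interaction_p: float
    modifies: bool
    dropped_cells: list = field(default_factory=list)


def choose_method(x, y, alpha: float = ALPHA) -> str:
    """Deterministic Pearson-vs-Spearman rule via D'Agostino K² normality.

    Pearson only when both samples look Normal at ``alpha``; Spearman
    otherwise.  The decision is invariant under affine rescaling of either
    variable (K² depends only on standardized moments).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 8 or len(y) < 8:
        raise ValueError("normality surrogate needs n >= 8 in both samples")
    for name, arr in (("x", x), ("y", y)):
        if np.ptp(arr) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")
    px = stats.normaltest(x).pvalue
    py = stats.normaltest(y).pvalue
    return "pearson" if (px >= alpha and py >= alpha) else "spearman"


def correlate(x, y, method: str, variable: str = "") -> CorrelationResult:
    """Correlation with Fisher-z 95% CI and the |r| ≥ 0.10 & p < 0.05 flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 8:
        raise ValueError("need n >= 8 for a stable correlation screen")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance sample; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(r)
    # Fisher z interval (for Spearman this is the standard large-sample
    # approximation on the rank correlation)
    if abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    else:
        lo = hi = r
    return CorrelationResult(
        variable=variable, method=method, r=r, ci95=(float(lo), float(hi)),
        p=float(p), n=n,
    )


def folded_f_test(a, b) -> tuple[float, float]:
    """Variance-ratio pre-test: F = larger s² / smaller s², two-sided p.

    The numerator degrees of freedom belong to the larger-variance sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va >= vb:
        f, df1, df2 = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, df1, df2 = vb / va if va > 0 else np.inf, len(b) - 1, len(a) - 1
    p = min(2.0 * stats.f.sf(f, df1, df2), 1.0) if np.isfinite(f) else 0.0
    return float(f), float(p)


def ttest_dichotomous(z, g, variable: str = "", alpha: float = ALPHA) -> TTestResult:
    """Two-group comparison with the folded-F pooled/Satterthwaite switch.

    ``diff_means`` is mean(group of the smaller label) − mean(group of the
    larger label), with labels sorted ascending.
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(g)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"grouping variable must have exactly 2 levels, got {labels}")
    a = z[g == labels[0]]
    b = z[g == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if (np.var(a, ddof=1) == 0 and len(a) < 3) or (np.var(b, ddof=1) == 0 and len(b) < 3):
        raise ValueError("zero-variance group too small for a variance pre-test")
    f, f_p = folded_f_test(a, b)
    equal = f_p >= alpha
    branch = "pooled" if equal else "satterthwaite"
    t, p = stats.ttest_ind(a, b, equal_var=equal)
    return TTestResult(
        variable=variable,
        group_labels=(labels[0], labels[1]),
        group_means=(float(np.mean(a)), float(np.mean(b))),
        group_sds=(float(np.std(a, ddof=1)), float(np.std(b, ddof=1))),
        diff_means=float(np.mean(a) - np.mean(b)),
        folded_f=f,
        folded_f_p=f_p,
        variance_equal=equal,
        branch=branch,
        t=float(t),
        p=float(p),
        n=(len(a), len(b)),
    )


def anova_categorical(z, levels, variable: str = "") -> AnovaResult:
    """One-way fixed-effects F test on (possibly unbalanced) level groups."""
    z = np.asarray(z, dtype=float)
    levels = np.asarray(levels)
    uniq = pd.unique(levels)
    groups = [z[levels == lv] for lv in uniq]
    groups = [(lv, grp) for lv, grp in zip(uniq, groups) if len(grp) > 0]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two non-empty levels")
    n = len(z)
    k = len(groups)
    grand = np.mean(z)
    ss_total = float(np.sum((z - grand) ** 2))
    ss_between = float(sum(len(grp) * (np.mean(grp) - grand) ** 2 for _, grp in groups))
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        F = 0.0 if ss_between <= 0 else np.inf
        p = 1.0 if ss_between <= 0 else 0.0
    else:
        F = (ss_between / (k - 1)) / (ss_within / (n - k))
        p = float(stats.f.sf(F, k - 1, n - k))
    r_square = ss_between / ss_total if ss_total > 0 else 0.0
    lowest = min(groups, key=lambda t: np.mean(t[1]))[0]
    return AnovaResult(
        variable=variable, levels=[lv for lv, _ in groups], F=float(F), p=float(p),
        r_square=float(r_square), lowest_mean_level=lowest, n=n,
    )


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Reference-coded dummies (level 0 dropped)."""
    out = np.zeros((len(codes), n_levels - 1))
    for lv in range(1, n_levels):
        out[:, lv - 1] = codes == lv
    return out


def interaction_screen(z, v1, v2, variables: tuple[str, str] = ("v1", "v2")) -> InteractionResult:
    """Partial-F test of the v1×v2 interaction in a two-way linear model.

    Both variables are treated as categorical (continuous candidates are
    categorized first).  Interaction cells unobserved in the data are dropped
    from the interaction block and reported in ``dropped_cells``.  Symmetric
    in its two variables.
    """
    z = np.asarray(z, dtype=float)
    c1, lv1 = pd.factorize(np.asarray(v1))
    c2, lv2 = pd.factorize(np.asarray(v2))
    n = len(z)
    main = np.column_stack([
        np.ones(n), _dummies(c1, len(lv1)), _dummies(c2, len(lv2)),
    ])
    inter_cols = []
    dropped = []
    for i in range(1, len(lv1)):
        for j in range(1, len(lv2)):
            col = ((c1 == i) & (c2 == j)).astype(float)
            if col.any():
                inter_cols.append(col)
            else:
                dropped.append((lv1[i], lv2[j]))
    if not inter_cols:
        return InteractionResult(variables=variables, interaction_F=0.0,
                                 interaction_p=1.0, modifies=False,
                                 dropped_cells=dropped)
    full = np.column_stack([main] + inter_cols)
    sse_r, rank_r = _sse(main, z)
    sse_f, rank_f = _sse(full, z)
    df_inter = rank_f - rank_r
    df_resid = n - rank_f
    if df_inter <= 0 or df_resid <= 0 or sse_f <= 0:
        F, p = (0.0, 1.0) if sse_r - sse_f <= 1e-12 * max(sse_r, 1.0) else (np.inf, 0.0)
    else:
        F = ((sse_r - sse_f) / df_inter) / (sse_f / df_resid)
        F = max(float(F), 0.0)
        p = float(stats.f.sf(F, df_inter, df_resid))
    return InteractionResult(
        variables=variables, interaction_F=float(F), interaction_p=float(p),
        modifies=p < ALPHA, dropped_cells=dropped,
    )


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


# ---------------------------------------------------------------------------
# Categorization schemes

#: Built-in cut-point schemes.  Bins are left-open/right-closed:
#: a cut-point belongs to the lower class.
SCHEMES: dict[str, tuple[list[float], list[str]]] = {
    "household_size": ([5, 10], ["0–5", "6–10", ">10"]),
    "altitude": ([800, 1000, 1200],
                 ["<=800", "800–1000", "1000–1200", ">1200"]),
    "population_density": ([50, 500], ["<=50", "50–500", ">500"]),
    "slope": ([8, 16, 30], ["<8", "8–16", "16–30", ">30"]),
}


def categorize(x, scheme, labels: list[str] | None = None) -> pd.Categorical:
    """Ordered categorical version of a continuous variable.

    ``scheme`` is a built-in name (see :data:`SCHEMES`), ``"quartiles"``,
    ``"agricultural_land"`` (0 → no land, then <3 ha vs ≥3 ha), or an
    explicit list of strictly increasing interior cut-points.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    if isinstance(scheme, str) and scheme == "quartiles":
        return pd.qcut(x, 4, labels=["Q1", "Q2", "Q3", "Q4"], duplicates="drop")
    if isinstance(scheme, str) and scheme == "agricultural_land":
        labs = ["no land", "<3 ha", ">=3 ha"]
        out = pd.Series(pd.Categorical([None] * len(x), categories=labs, ordered=True))
        out[x == 0] = "no land"
        out[(x > 0) & (x < 3)] = "<3 ha"
        out[x >= 3] = ">=3 ha"
        return pd.Categorical(out, categories=labs, ordered=True)
    if isinstance(scheme, str):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown categorization scheme {scheme!r}")
        cuts, labels = SCHEMES[scheme]
    else:
        cuts = list(scheme)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cut-points must be strictly increasing")
    edges = [-np.inf] + list(cuts) + [np.inf]
    if labels is not None and len(labels) != len(edges) - 1:
        raise ValueError("need one label per class")
    return pd.cut(x, bins=edges, labels=labels, right=True)
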