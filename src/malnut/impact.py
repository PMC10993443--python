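"""Quasi-experimental comparison of Z-score changes across district groups.

Intervention exposure is defined at district level (intent-to-treat): every
child in an intervention ("JP") district counts as exposed.  For each
outcome the evaluation compares the change in mean Z-score between baseline
and endline waves in JP districts against the same change in non-JP
districts:

* absolute change   Δ  = mean(endline) − mean(baseline)
* relative change %    = 100 · Δ / |mean(baseline)|
* impact              = Δ(JP) − Δ(non-JP)   (positive = JP improved more)

Because the district groups start from unequal baselines, the same contrast
is repeated within strata of the determinant variables (the same stratum
definition in both groups and both waves), approximating exchangeable
comparison groups.  Strata in which either side has fewer than 50 children
at baseline or endline are flagged as too small to report reliably.

Report tables render Z-score changes with two implied decimal places
(+0.37 → "37") and impact differences with one decimal on that scale,
rounding half-up; machine-readable output always carries full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anthro import round_half_up
from .screen import TTestResult, ttest_dichotomous

#: Minimum per-cell sample size below which a stratum is flagged unreliable.
SMALL_STRATUM_N = 50


@dataclass
class GroupChange:
    """Baseline→endline change of one exposure group in one stratum."""

    exposure: str                       # "JP" | "non-JP"
    stratum: str                        # "overall" or "variable=level"
    n_baseline: int
    n_endline: int
    mean_baseline: float
    mean_endline: float
    abs_change: float = field(init=False)
    rel_change_pct: float | None = field(init=False)
    small_stratum: bool = field(init=False)

    def __post_init__(self) -> None:
        self.abs_change = self.mean_endline - self.mean_baseline
        if self.mean_baseline == 0:
            self.rel_change_pct = None   # undefined denominator, flagged
        else:
            self.rel_change_pct = 100.0 * self.abs_change / abs(self.mean_baseline)
        self.small_stratum = min(self.n_baseline, self.n_endline) < SMALL_STRATUM_N


@dataclass
class ImpactRow:
    outcome: str
    stratum: str
    jp: GroupChange
    nonjp: GroupChange
    impact_abs: float = field(init=False)
    se_impact: float | None = None      # descriptive aid, not in source tables
    reliable: bool = field(init=False)

    def __post_init__(self) -> None:
        self.impact_abs = self.jp.abs_change - self.nonjp.abs_change
        self.reliable = not (self.jp.small_stratum or self.nonjp.small_stratum)


@dataclass
class BaselineComparison:
    outcome: str
    wave: str
    diff_means: float                   # JP − non-JP
    ci95: tuple[float, float]
    p: float
    ttest: TTestResult


def impact_from_changes(jp_change: float, nonjp_change: float) -> float:
    """Difference-of-changes impact from two group changes (JP − non-JP)."""
    return jp_change - nonjp_change


def relative_change_pct(mean_baseline: float, abs_change: float) -> float:
    """Relative change with |baseline mean| as denominator."""
    if mean_baseline == 0:
        raise ZeroDivisionError("relative change undefined at zero baseline mean")
    return 100.0 * abs_change / abs(mean_baseline)


def _wave_labels(records: pd.DataFrame, wave_col: str) -> tuple[str, str]:
    waves = sorted(records[wave_col].astype(str).unique())
    if len(waves) != 2:
        raise ValueError(f"need exactly two waves, found {waves}")
    return waves[0], waves[1]


def group_change(
    records: pd.DataFrame,
    outcome: str,
    exposed: bool,
    stratum: str = "overall",
    stratum_mask: pd.Series | None = None,
    jp_col: str = "jp",
    wave_col: str = "wave",
) -> GroupChange:
    """Baseline/endline means and change for one exposure group."""
    baseline, endline = _wave_labels(records, wave_col)
    sel = records[jp_col].astype(bool) == bool(exposed)
    if stratum_mask is not None:
        sel &= stratum_mask.reindex(records.index, fill_value=False)
    sub = records.loc[sel].dropna(subset=[outcome])
    b = sub.loc[sub[wave_col].astype(str) == baseline, outcome]
    e = sub.loc[sub[wave_col].astype(str) == endline, outcome]
    if len(b) == 0 or len(e) == 0:
        raise ValueError(
            f"empty {'baseline' if len(b) == 0 else 'endline'} cell for "
            f"exposure={'JP' if exposed else 'non-JP'}, stratum={stratum!r}"
        )
    return GroupChange(
        exposure="JP" if exposed else "non-JP",
        stratum=stratum,
        n_baseline=len(b),
        n_endline=len(e),
        mean_baseline=float(b.mean()),
        mean_endline=float(e.mean()),
    )


def _impact_se(records, outcome, jp_col, wave_col) -> float:
    """Independent-samples SE of the difference of changes (descriptive)."""
    baseline, endline = _wave_labels(records, wave_col)
    var = 0.0
    for exposed in (True, False):
        for wave in (baseline, endline):
            sel = (records[jp_col].astype(bool) == exposed) & (
                records[wave_col].astype(str) == wave
            )
            vals = records.loc[sel, outcome].dropna()
            if len(vals) < 2:
                return float("nan")
            var += float(vals.var(ddof=1)) / len(vals)
    return float(np.sqrt(var))


def impact_row(
    records: pd.DataFrame,
    outcome: str,
    stratum: str = "overall",
    stratum_mask: pd.Series | None = None,
    jp_col: str = "jp",
    wave_col: str = "wave",
) -> ImpactRow:
    sub = records if stratum_mask is None else records.loc[
        stratum_mask.reindex(records.index, fill_value=False)
    ]
    row = ImpactRow(
        outcome=outcome,
        stratum=stratum,
        jp=group_change(records, outcome, True, stratum, stratum_mask,
                        jp_col, wave_col),
        nonjp=group_change(records, outcome, False, stratum, stratum_mask,
                           jp_col, wave_col),
    )
    row.se_impact = _impact_se(sub.dropna(subset=[outcome]), outcome, jp_col, wave_col)
    return row


def impact_table(
    records: pd.DataFrame,
    outcome: str,
    strata: list[str] | None = None,
    jp_col: str = "jp",
    wave_col: str = "wave",
) -> list[ImpactRow]:
    """Overall impact row plus one row per level of each stratum variable."""
    if jp_col not in records.columns:
        raise KeyError(f"exposure column {jp_col!r} absent from records")
    rows = [impact_row(records, outcome, "overall", None, jp_col, wave_col)]
    for var in strata or []:
        if var not in records.columns:
            raise KeyError(f"stratification covariate {var!r} absent from records")
        levels = [lv for lv in pd.unique(records[var]) if pd.notna(lv)]
        try:
            levels = sorted(levels)
        except TypeError:
            levels = sorted(levels, key=str)
        for lv in levels:
            mask = records[var] == lv
            try:
                rows.append(
                    impact_row(records, outcome, f"{var}={lv}", mask,
                               jp_col, wave_col)
                )
            except ValueError:
                # an empty exposure×wave cell: stratum cannot be contrasted
                continue
    return rows


def baseline_endline_tests(
    records: pd.DataFrame,
    outcome: str,
    jp_col: str = "jp",
    wave_col: str = "wave",
) -> dict[str, BaselineComparison]:
    """JP − non-JP difference of means per wave (pooled/Welch per folded F)."""
    out = {}
    for wave in _wave_labels(records, wave_col):
        sub = records[records[wave_col].astype(str) == wave].dropna(subset=[outcome])
        g = sub[jp_col].astype(bool)
        if g.all() or (~g).all():
            raise ValueError(f"wave {wave!r} lacks one exposure group")
        # ttest_dichotomous orders groups by sorted label: False (non-JP)
        # first — flip sign so the contrast reads JP − non-JP.
        res = ttest_dichotomous(sub[outcome].to_numpy(), g.to_numpy(),
                                variable=f"{outcome}@{wave}")
        diff = -res.diff_means
        se, dfree = _diff_se_df(res)
        half = float(stats.t.ppf(0.975, dfree)) * se
        out[wave] = BaselineComparison(
            outcome=outcome, wave=wave, diff_means=diff,
            ci95=(diff - half, diff + half), p=res.p, ttest=res,
        )
    return out


def _diff_se_df(res: TTestResult) -> tuple[float, float]:
    """SE and df of the mean difference, matching the chosen t-test branch."""
    (n1, n2), (s1, s2) = res.n, res.group_sds
    if res.branch == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        return float(np.sqrt(sp2 * (1 / n1 + 1 / n2))), float(n1 + n2 - 2)
    v1, v2 = s1**2 / n1, s2**2 / n2
    dfree = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(np.sqrt(v1 + v2)), float(dfree)


def format_change(value: float, implied_decimals: int = 2) -> str:
    """Render a Z-score change with implied decimals: +0.37 → "37".

    Scaling happens in decimal space so a printed 0.575 rounds half-up to
    58 rather than tripping over its binary representation.
    """
    from decimal import ROUND_HALF_UP, Decimal
    v = Decimal(repr(float(value))).scaleb(implied_decimals).quantize(
        Decimal(1), rounding=ROUND_HALF_UP)
    return f"{'−' if v < 0 else ''}{abs(int(v))}"


def format_impact(value: float, implied_decimals: int = 2) -> str:
    """Impact differences keep one decimal on the implied-decimal scale."""
    from decimal import ROUND_HALF_UP, Decimal
    v = Decimal(repr(float(value))).scaleb(implied_decimals).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    s = f"{abs(v)}".rstrip("0").rstrip(".")
    return f"{'−' if v < 0 else ''}{s or '0'}"


def format_table(rows: list[ImpactRow], implied_decimals: int = 2) -> str:
    """Paper-style text table; unreliable (small-stratum) rows marked with *."""
    lines = [
        f"{'stratum':<28} {'noJP abs':>9} {'noJP %':>7} {'JP abs':>9} "
        f"{'JP %':>7} {'impact':>8}",
    ]
    for r in rows:
        mark = "" if r.reliable else "*"
        def pct(g):
            return ("–" if g.rel_change_pct is None
                    else f"{int(round_half_up(g.rel_change_pct, 0))}")
        lines.append(
            f"{r.stratum + mark:<28} "
            f"{format_change(r.nonjp.abs_change, implied_decimals):>9} "
            f"{pct(r.nonjp):>7} "
            f"{format_change(r.jp.abs_change, implied_decimals):>9} "
            f"{pct(r.jp):>7} "
            f"{format_impact(r.impact_abs, implied_decimals):>8}"
        )
    lines.append("* at least one group below "
                 f"{SMALL_STRATUM_N} children; too small to report reliably")
    return "\n".join(lines)


def table_to_frame(rows: list[ImpactRow]) -> pd.DataFrame:
    """Full-precision machine table."""
    recs = []
    for r in rows:
        recs.append({
            "outcome": r.outcome,
            "stratum": r.stratum,
            "nonjp_n_baseline": r.nonjp.n_baseline,
            "nonjp_n_endline": r.nonjp.n_endline,
            "nonjp_mean_baseline": r.nonjp.mean_baseline,
            "nonjp_mean_endline": r.nonjp.mean_endline,
            "nonjp_abs_change": r.nonjp.abs_change,
            "nonjp_rel_change_pct": r.nonjp.rel_change_pct,
            "jp_n_baseline": r.jp.n_baseline,
            "jp_n_endline": r.jp.n_endline,
            "jp_mean_baseline": r.jp.mean_baseline,
            "jp_mean_endline": r.jp.mean_endline,
            "jp_abs_change": r.jp.abs_change,
            "jp_rel_change_pct": r.jp.rel_change_pct,
            "impact_abs": r.impact_abs,
            "se_impact": r.se_impact,
            "reliable": r.reliable,
        })
    return pd.DataFrame(recs)
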