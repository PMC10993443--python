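"""Undernutrition classification, prevalence and missingness accounting.

Child nutritional status is summarized by three WHO-reference Z-scores:
height-for-age (HAZ, stunting), weight-for-age (WAZ, underweight) and
weight-for-height (WHZ, wasting).  A child fails a criterion when the score
is strictly below −2.0 SD.  The composite index of anthropometric failure
(CIAF) used here is the binary "any failure" indicator: at least one of the
three flags set.

Because about 2.3% of children in a well-nourished reference population fall
below −2 SD by natural variation alone, the *excess* prevalence subtracts
that constant (floored at zero).  Report-level percentages round half-up;
underlying values are always carried at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

#: Z-score threshold below which a child is classified as failing (strict).
Z_CUTOFF = -2.0

#: Prevalence (%) of each anthropometric failure expected in a well-fed
#: population from natural variation alone.
NATURAL_PREVALENCE_PCT = 2.3

OUTCOMES = ("haz", "waz", "whz")
CONDITIONS = {"stunted": "haz", "underweight": "waz", "wasted": "whz"}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (so 58.75 → 59 at zero decimals, not 58)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PrevalenceSummary:
    """Per-wave anthropometric summary over complete cases."""

    wave: str
    n: int
    mean: dict = field(default_factory=dict)           # outcome -> mean
    sd: dict = field(default_factory=dict)             # outcome -> SD
    prevalence: dict = field(default_factory=dict)     # condition -> percent
    excess: dict = field(default_factory=dict)         # condition -> percent
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "wave": self.wave,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "prevalence_pct": self.prevalence,
            "excess_prevalence_pct": self.excess,
            "notes": self.notes,
        }


def classify(haz: float, waz: float, whz: float) -> dict:
    """Failure flags for one child; all three Z-scores must be present.

    The inequality is strict: a score of exactly −2.0 does not fail.
    """
    scores = (haz, waz, whz)
    if any(s is None or not np.isfinite(s) for s in scores):
        raise ValueError(
            "classify requires all three Z-scores; records with missing "
            "anthropometry must be excluded upstream"
        )
    flags = {
        "stunted": haz < Z_CUTOFF,
        "underweight": waz < Z_CUTOFF,
        "wasted": whz < Z_CUTOFF,
    }
    flags["ciaf"] = any(flags.values())
    return flags


def classify_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify` over complete cases of a record table."""
    complete = records.dropna(subset=list(OUTCOMES))
    out = pd.DataFrame(index=complete.index)
    for cond, col in CONDITIONS.items():
        out[cond] = complete[col] < Z_CUTOFF
    out["ciaf"] = out[list(CONDITIONS)].any(axis=1)
    return out


def excess_prevalence(prevalence_pct: float) -> float:
    """Observed prevalence minus the 2.3% natural background, floored at 0."""
    if not 0.0 <= prevalence_pct <= 100.0:
        raise ValueError("prevalence must be a percentage in [0, 100]")
    return max(prevalence_pct - NATURAL_PREVALENCE_PCT, 0.0)


def summarize(records: pd.DataFrame, wave: str, wave_col: str = "wave") -> PrevalenceSummary:
    """Means, SDs and (excess) prevalences for one survey wave.

    Statistics are over complete cases (all three Z-scores present); SDs are
    sample SDs (ddof=1).
    """
    in_wave = records[records[wave_col].astype(str) == str(wave)]
    complete = in_wave.dropna(subset=list(OUTCOMES))
    if len(complete) == 0:
        raise ValueError(f"no complete records in wave {wave!r}")
    flags = classify_frame(complete)
    n = len(complete)
    summary = PrevalenceSummary(wave=str(wave), n=n)
    for outcome in OUTCOMES:
        vals = complete[outcome].to_numpy(dtype=float)
        summary.mean[outcome] = float(np.mean(vals))
        summary.sd[outcome] = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    for cond in list(CONDITIONS) + ["ciaf"]:
        pct = 100.0 * float(flags[cond].sum()) / n
        summary.prevalence[cond] = pct
        summary.excess[cond] = excess_prevalence(pct)
    summary.notes.append(
        "excess prevalence = prevalence − 2.3 (natural background), floored "
        "at 0; percentages rounded half-up only at report time"
    )
    return summary


def missingness_report(records: pd.DataFrame, wave: str, wave_col: str = "wave") -> dict:
    """Total/complete counts and the missing-data percentage for one wave."""
    in_wave = records[records[wave_col].astype(str) == str(wave)]
    total = len(in_wave)
    if total == 0:
        raise ValueError(f"no records in wave {wave!r}")
    complete = int(len(in_wave.dropna(subset=list(OUTCOMES))))
    missing_pct = 100.0 * (total - complete) / total
    return {
        "wave": str(wave),
        "total": total,
        "complete": complete,
        "missing_pct": missing_pct,
        "missing_pct_1dp": round_half_up(missing_pct, 1),
    }


def missingness_pct(total: int, complete: int) -> float:
    """Missing-data percentage from raw counts (one-decimal report rounding
    is left to the caller via :func:`round_half_up`)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * (total - complete) / total
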