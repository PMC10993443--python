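"""Backward p-value selection and subsampling stability selection.

The explanatory models are ordinary least-squares regressions of a Z-score
outcome on screened candidate effects.  Selection proceeds in two layers:

1. :func:`backward_select` — traditional backwards elimination: repeatedly
   drop the single worst effect with p ≥ ``alpha_stay`` (default 0.05) until
   every remaining effect is significant.  Categorical variables enter as
   reference-coded dummy levels and individual levels leave the model
   independently of their parent variable ("split" semantics).
2. :func:`stability_select` — the backward procedure is repeated on
   ``n_resamples`` (default 100) subsets, each a randomly drawn
   ``fraction`` (default 75%) of the rows drawn *without* replacement.
   Each effect's selection frequency is recorded; effects selected in fewer
   than ``retain`` (default 20%) of the subsets are dropped, and an averaged
   model is built by averaging each surviving effect's estimates over the
   subset models in which it appeared.

Averaged p-values are deliberately not produced (averaging p-values across
models is not meaningful); the stability output is frequencies plus averaged
estimates.  :func:`compare_models` checks that the single full-data model
does not deviate from the averaged one by more than twice the resampling SD
of each estimate — the robustness verdict.

A hard sample-size floor of ``min_obs_per_effect`` (default 10, i.e. at
least ten observations per candidate effect) guards against overfitted
specifications and is enforced before any fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats


class RankDeficiencyError(ValueError):
    """Raised when the design matrix is collinear; names the offending effects."""

    def __init__(self, effects):
        self.effects = list(effects)
        super().__init__(
            "design matrix is rank deficient; collinear effects: "
            + ", ".join(self.effects)
        )


@dataclass
class ModelSpec:
    """Candidate-effect specification for one outcome.

    ``categorical`` maps each classification variable to its reference
    level (omitted from the design); every other observed level becomes an
    independently removable effect named ``"var[level]"``.
    """

    outcome: str
    continuous: list = field(default_factory=list)
    categorical: dict = field(default_factory=dict)
    alpha_stay: float = 0.05
    min_obs_per_effect: int = 10

    def columns(self) -> list:
        return [self.outcome] + list(self.continuous) + list(self.categorical)


@dataclass
class FittedModel:
    outcome: str
    effects: list
    coefficients: dict
    std_errors: dict
    pvalues: dict
    intercept: float
    r_square: float
    adjusted_r_square: float
    n: int
    notes: list = field(default_factory=list)


@dataclass
class StabilityModel:
    outcome: str
    n_resamples: int
    n_failed: int
    selection_frequency: dict          # effect -> fraction of successful resamples
    averaged_coefficients: dict        # effect -> mean estimate where selected
    estimate_sd: dict                  # effect -> SD of estimates where selected
    retained: dict                     # effect -> selection_frequency >= retain
    retain_threshold: float
    resample_log: list                 # per resample: sorted list of selected effects


def effect_name(variable: str, level=None) -> str:
    return variable if level is None else f"{variable}[{level}]"


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Design matrix (intercept first) and effect names from a record table.

    Rows with missing values in any used column are dropped (complete-case).
    """
    cols = spec.columns()
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise KeyError(f"columns absent from data: {missing_cols}")
    df = data[cols].dropna()
    y = df[spec.outcome].to_numpy(dtype=float)
    parts = [np.ones((len(df), 1))]
    names: list[str] = []
    for var in spec.continuous:
        parts.append(df[var].to_numpy(dtype=float)[:, None])
        names.append(effect_name(var))
    for var, ref in spec.categorical.items():
        # levels compare as strings so CSV round trips (int vs str codes)
        # cannot silently orphan the reference level
        col = df[var].astype(str)
        ref = str(ref)
        levels = sorted(lv for lv in col.unique() if lv != ref)
        if ref not in set(col.unique()):
            warnings.warn(
                f"reference level {ref!r} of {var!r} unobserved in data",
                stacklevel=2,
            )
        for lv in levels:
            parts.append((col == lv).to_numpy(dtype=float)[:, None])
            names.append(effect_name(var, lv))
    X = np.hstack(parts)
    return X, y, names


def _collinear_columns(X: np.ndarray, names: list) -> list:
    """Identify dependent columns via pivoted QR (intercept excluded)."""
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    bad = sorted(piv[rank:])
    return [names[i - 1] for i in bad if i >= 1]


def _fit_matrix(X: np.ndarray, y: np.ndarray, names: list):
    """OLS with classical t-based p-values; raises on rank deficiency."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} too small for {p - 1} effects plus intercept")
    xtx = X.T @ X
    try:
        c, low = linalg.cho_factor(xtx)
    except np.linalg.LinAlgError:
        raise RankDeficiencyError(_collinear_columns(X, names) or ["<unknown>"])
    # Cholesky can succeed on near-singular matrices; double-check conditioning
    if np.linalg.cond(xtx) > 1e12:
        bad = _collinear_columns(X, names)
        if bad:
            raise RankDeficiencyError(bad)
    beta = linalg.cho_solve((c, low), X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df_resid = n - p
    sigma2 = sse / df_resid
    xtx_inv_diag = np.diag(linalg.cho_solve((c, low), np.eye(p)))
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_diag, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else r2
    return beta, se, pvals, r2, adj


def _as_model(outcome, beta, se, pvals, r2, adj, n, names, notes=None) -> FittedModel:
    return FittedModel(
        outcome=outcome,
        effects=list(names),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        std_errors={nm: float(s) for nm, s in zip(names, se[1:])},
        pvalues={nm: float(p) for nm, p in zip(names, pvals[1:])},
        intercept=float(beta[0]),
        r_square=float(r2),
        adjusted_r_square=float(adj),
        n=int(n),
        notes=list(notes or []),
    )


def fit_linear(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Least-squares fit of the full candidate model (no selection)."""
    if not spec.continuous and not spec.categorical:
        raise ValueError("model specification has no candidate effects")
    X, y, names = build_design(data, spec)
    beta, se, pvals, r2, adj = _fit_matrix(X, y, names)
    return _as_model(spec.outcome, beta, se, pvals, r2, adj, len(y), names)


def _backward_matrix(X, y, names, alpha_stay):
    """Backwards elimination on a pre-built design; returns fit of survivors.

    Removal order: worst (largest) p ≥ alpha first; exact p ties break on
    lexicographically smallest effect name.  Returns (fit tuple, kept names,
    notes).
    """
    active = list(range(1, X.shape[1]))  # column indices of live effects
    notes = []
    while True:
        cols = [0] + active
        sub_names = [names[i - 1] for i in active]
        beta, se, pvals, r2, adj = _fit_matrix(X[:, cols], y, sub_names)
        if not active:
            break
        eff_p = pvals[1:]
        over = [(p, sub_names[k], k) for k, p in enumerate(eff_p) if not p < alpha_stay]
        if not over:
            break
        over.sort(key=lambda t: (-t[0], t[1]))
        _, drop_name, drop_k = over[0]
        del active[drop_k]
        notes.append(f"dropped {drop_name} (p={over[0][0]:.4g})")
        if not active:
            notes.append("all effects removed; intercept-only model returned")
            warnings.warn(
                "backward selection removed every effect; intercept-only model",
                stacklevel=3,
            )
            beta, se, pvals, r2, adj = _fit_matrix(X[:, [0]], y, [])
            return (beta, se, pvals, r2, adj), [], notes
    return (beta, se, pvals, r2, adj), [names[i - 1] for i in active], notes


def backward_select(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Backwards p-value elimination with split categorical levels.

    Enforces the sample-size floor n ≥ ``min_obs_per_effect`` × (#effects)
    on the initial candidate set.
    """
    X, y, names = build_design(data, spec)
    _check_floor(len(y), len(names), spec.min_obs_per_effect)
    (beta, se, pvals, r2, adj), kept, notes = _backward_matrix(
        X, y, names, spec.alpha_stay
    )
    return _as_model(spec.outcome, beta, se, pvals, r2, adj, len(y), kept, notes)


def _check_floor(n, n_effects, min_obs):
    if n_effects and n < min_obs * n_effects:
        raise ValueError(
            f"only {n} observations for {n_effects} candidate effects; "
            f"need at least {min_obs} per effect ({min_obs * n_effects})"
        )


def apply_retention(selection_frequency: dict, retain: float) -> dict:
    """Retention rule: keep an effect iff selected in at least ``retain`` of
    the resamples (so 20/100 survives a 0.20 threshold, 19/100 does not)."""
    return {nm: f >= retain for nm, f in selection_frequency.items()}


def stability_select(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_resamples: int = 100,
    fraction: float = 0.75,
    retain: float = 0.20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> StabilityModel:
    """Subsampling stability selection around :func:`backward_select`.

    Each resample draws ``fraction`` of the rows without replacement,
    independently of the others; membership is recorded in the resample log
    for audit.  Retention uses ``selection_frequency >= retain`` — an effect
    selected in exactly 20 of 100 subsets is retained, one selected in 19
    is dropped.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not 0 <= retain <= 1:
        raise ValueError("retain must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    X, y, names = build_design(data, spec)
    n = len(y)
    m = int(np.floor(fraction * n))
    _check_floor(m, len(names), spec.min_obs_per_effect)
    estimates: dict[str, list[float]] = {nm: [] for nm in names}
    log: list = []
    n_failed = 0
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                (beta, _, _, _, _), kept, _ = _backward_matrix(
                    X[idx], y[idx], names, spec.alpha_stay
                )
        except (RankDeficiencyError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            log.append(None)
            continue
        for nm, b in zip(kept, beta[1:]):
            estimates[nm].append(float(b))
        log.append(sorted(kept))
    if n_failed > 0.1 * n_resamples:
        raise RuntimeError(
            f"{n_failed}/{n_resamples} resample fits failed (>10%); aborting"
        )
    ok = n_resamples - n_failed
    freq = {nm: len(v) / ok for nm, v in estimates.items()}
    return StabilityModel(
        outcome=spec.outcome,
        n_resamples=ok,
        n_failed=n_failed,
        selection_frequency=freq,
        averaged_coefficients={
            nm: float(np.mean(v)) for nm, v in estimates.items() if v
        },
        estimate_sd={
            nm: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            for nm, v in estimates.items() if v
        },
        retained=apply_retention(freq, retain),
        retain_threshold=retain,
        resample_log=log,
    )


def compare_models(main: FittedModel, stability: StabilityModel) -> dict:
    """Per-effect main-vs-averaged comparison and a robustness verdict.

    An effect is flagged when |main − averaged| exceeds twice the resampling
    SD of its estimate.  Verdict "robust" when nothing is flagged.
    """
    if main.outcome != stability.outcome:
        raise ValueError("models describe different outcomes")
    common = [e for e in main.effects if e in stability.averaged_coefficients]
    if not common and main.effects:
        raise ValueError("main and stability models share no effects")
    rows = []
    for e in common:
        diff = main.coefficients[e] - stability.averaged_coefficients[e]
        sd = stability.estimate_sd.get(e, 0.0)
        flagged = abs(diff) > 2.0 * sd if sd > 0 else abs(diff) > 0
        rows.append({
            "effect": e,
            "main": main.coefficients[e],
            "averaged": stability.averaged_coefficients[e],
            "difference": diff,
            "resample_sd": sd,
            "flagged": bool(flagged),
        })
    verdict = "robust" if not any(r["flagged"] for r in rows) else "unstable"
    return {"effects": rows, "verdict": verdict}
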