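"""Least-squares core, backwards elimination and stability selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from malnut import modelsel
from malnut.modelsel import (
    FittedModel,
    ModelSpec,
    RankDeficiencyError,
    StabilityModel,
    apply_retention,
    backward_select,
    compare_models,
    fit_linear,
    stability_select,
)


def make_data(rng, n=200, betas=(1.0, -0.5), noise=1.0):
    df = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(len(betas))})
    df["y"] = 2.0 + sum(b * df[f"x{i}"] for i, b in enumerate(betas))
    df["y"] += noise * rng.normal(size=n)
    return df


def spec_for(df, outcome="y"):
    return ModelSpec(outcome=outcome,
                     continuous=[c for c in df.columns if c.startswith("x")])


class TestFitLinear:
    def test_noise_free_recovery(self, rng):
        df = make_data(rng, n=50, noise=0.0)
        fit = fit_linear(df, spec_for(df))
        assert fit.intercept == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["x0"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["x1"] == pytest.approx(-0.5, abs=1e-10)
        assert fit.r_square == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self, rng):
        df = make_data(rng, n=20)
        fit = fit_linear(df, spec_for(df))
        X = np.column_stack([np.ones(20), df.x0, df.x1])
        beta = np.linalg.solve(X.T @ X, X.T @ df.y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.coefficients["x0"] == pytest.approx(beta[1], rel=1e-10)
        assert fit.coefficients["x1"] == pytest.approx(beta[2], rel=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        df = make_data(rng, n=120, betas=(0.7, 0.0, -1.2))
        fit = fit_linear(df, spec_for(df))
        X = sm.add_constant(df[["x0", "x1", "x2"]].to_numpy())
        ref = sm.OLS(df.y.to_numpy(), X).fit()
        for k, name in enumerate(["x0", "x1", "x2"], start=1):
            assert fit.coefficients[name] == pytest.approx(ref.params[k], rel=1e-9)
            assert fit.pvalues[name] == pytest.approx(ref.pvalues[k], rel=1e-6)
        assert fit.adjusted_r_square == pytest.approx(ref.rsquared_adj, rel=1e-9)

    def test_adjusted_r_square_below_r_square(self, rng):
        df = make_data(rng)
        fit = fit_linear(df, spec_for(df))
        assert fit.adjusted_r_square <= fit.r_square

    def test_collinear_effects_named(self, rng):
        df = make_data(rng)
        df["x_dup"] = df["x0"] * 2.0
        with pytest.raises(RankDeficiencyError) as exc:
            fit_linear(df, spec_for(df))
        assert any("x" in e for e in exc.value.effects)

    def test_categorical_reference_coding(self, rng):
        n = 300
        lv = rng.choice(["A", "B", "C"], size=n)
        df = pd.DataFrame({"g": lv})
        df["y"] = 1.0 + 2.0 * (lv == "B") + 0.0 * (lv == "C")
        spec = ModelSpec(outcome="y", categorical={"g": "A"})
        fit = fit_linear(df, spec)
        assert fit.coefficients["g[B]"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["g[C]"] == pytest.approx(0.0, abs=1e-10)

    def test_no_candidates_rejected(self, rng):
        df = make_data(rng)
        with pytest.raises(ValueError, match="no candidate"):
            fit_linear(df, ModelSpec(outcome="y"))


class TestBackwardSelect:
    def test_fixed_point_when_all_significant(self, rng):
        df = make_data(rng, n=2000, betas=(1.0, -0.8), noise=0.5)
        full = fit_linear(df, spec_for(df))
        assert all(p < 0.05 for p in full.pvalues.values())
        sel = backward_select(df, spec_for(df))
        assert sel.effects == full.effects
        for e in full.effects:
            assert sel.coefficients[e] == pytest.approx(full.coefficients[e],
                                                        rel=1e-12)

    def test_noise_effects_removed(self, rng):
        df = make_data(rng, n=2000, betas=(1.0, 0.0, 0.0, 0.0), noise=1.0)
        sel = backward_select(df, spec_for(df))
        assert "x0" in sel.effects

    def test_noise_retention_near_alpha(self):
        """One true effect + five noise effects: each noise effect survives
        with probability ≈ α."""
        rng = np.random.default_rng(31)
        reps = 200
        noise_kept = 0
        true_kept = 0
        for _ in range(reps):
            df = make_data(rng, n=2000,
                           betas=(0.5, 0.0, 0.0, 0.0, 0.0, 0.0), noise=1.0)
            sel = backward_select(df, spec_for(df))
            true_kept += "x0" in sel.effects
            noise_kept += sum(f"x{i}" in sel.effects for i in range(1, 6))
        assert true_kept == reps
        rate = noise_kept / (5 * reps)
        assert rate < 0.12          # ≈ 0.05 expected, generous ceiling

    def test_split_level_semantics(self, rng):
        """Level C may leave the model while predictive level B stays."""
        n = 600
        lv = rng.choice(["A", "B", "C"], size=n)
        df = pd.DataFrame({"g": lv})
        # noise centered within each level so the C contrast is exactly null
        noise = 0.3 * rng.normal(size=n)
        for level in "ABC":
            noise[lv == level] -= noise[lv == level].mean()
        df["y"] = 1.0 * (lv == "B") + noise
        sel = backward_select(df, ModelSpec(outcome="y", categorical={"g": "A"}))
        assert "g[B]" in sel.effects
        assert "g[C]" not in sel.effects

    def test_all_removed_gives_intercept_only(self, rng):
        df = make_data(rng, n=500, betas=(0.0,), noise=1.0)
        df["y"] = rng.normal(size=500)      # no signal at all
        with pytest.warns(UserWarning, match="intercept-only"):
            sel = backward_select(df, spec_for(df))
        assert sel.effects == []

    def test_sample_size_floor_enforced(self, rng):
        df = make_data(rng, n=15, betas=(1.0, 1.0))
        spec = spec_for(df)
        spec.min_obs_per_effect = 10
        with pytest.raises(ValueError, match="at least 10 per effect"):
            backward_select(df, spec)


class TestStability:
    def test_retention_boundary(self):
        freq = {"a": 0.19, "b": 0.20, "c": 1.0}
        retained = apply_retention(freq, 0.20)
        assert retained == {"a": False, "b": True, "c": True}

    def test_zero_noise_full_selection(self, rng):
        df = make_data(rng, n=400, betas=(1.0, -0.5), noise=1e-8)
        stab = stability_select(df, spec_for(df), n_resamples=20, seed=1)
        assert stab.selection_frequency == {"x0": 1.0, "x1": 1.0}
        assert stab.averaged_coefficients["x0"] == pytest.approx(1.0, abs=1e-6)
        assert stab.averaged_coefficients["x1"] == pytest.approx(-0.5, abs=1e-6)

    def test_reproducible_given_seed(self, rng):
        df = make_data(rng, n=500, betas=(0.3, 0.05), noise=1.0)
        a = stability_select(df, spec_for(df), n_resamples=30, seed=42)
        b = stability_select(df, spec_for(df), n_resamples=30, seed=42)
        assert a.selection_frequency == b.selection_frequency
        assert a.resample_log == b.resample_log

    def test_resample_log_records_membership(self, rng):
        df = make_data(rng, n=300, betas=(2.0,), noise=0.5)
        stab = stability_select(df, spec_for(df), n_resamples=10, seed=3)
        assert len(stab.resample_log) == 10
        assert all(log == ["x0"] for log in stab.resample_log)

    def test_invalid_fraction_rejected(self, rng):
        df = make_data(rng)
        with pytest.raises(ValueError):
            stability_select(df, spec_for(df), fraction=1.5, seed=0)


class TestCompareModels:
    def test_zero_noise_verdict_robust(self, rng):
        df = make_data(rng, n=400, betas=(1.0, -0.5), noise=1e-8)
        main = backward_select(df, spec_for(df))
        stab = stability_select(df, spec_for(df), n_resamples=20, seed=5)
        rep = compare_models(main, stab)
        assert rep["verdict"] == "robust"
        assert all(abs(r["difference"]) < 1e-6 for r in rep["effects"])

    def test_injected_instability_flagged(self):
        main = FittedModel(
            outcome="y", effects=["u"], coefficients={"u": 0.5},
            std_errors={"u": 0.1}, pvalues={"u": 0.01}, intercept=0.0,
            r_square=0.1, adjusted_r_square=0.1, n=100)
        stab = StabilityModel(
            outcome="y", n_resamples=100, n_failed=0,
            selection_frequency={"u": 0.25},
            averaged_coefficients={"u": -0.4},   # sign-flipped average
            estimate_sd={"u": 0.2},
            retained={"u": True}, retain_threshold=0.2, resample_log=[])
        rep = compare_models(main, stab)
        assert rep["effects"][0]["flagged"]
        assert rep["verdict"] == "unstable"

    def test_different_outcomes_rejected(self, rng):
        df = make_data(rng)
        main = fit_linear(df, spec_for(df))
        stab = stability_select(df, spec_for(df), n_resamples=5, seed=0)
        stab.outcome = "other"
        with pytest.raises(ValueError):
            compare_models(main, stab)


def test_synthetic_bundle_recovery():
    """Generating effects well above the noise floor are always retained.

    Uses a dedicated low-noise bundle so retention reflects the machinery
    rather than borderline power; full-scale power is exercised in the
    acceptance suite.
    """
    from malnut.synthetic import GenConfig, generate_bundle
    cfg = GenConfig(
        n_children_per_wave=800, n_districts=4, jp_district_ids={0, 1},
        raster_extent=(-9.5, -8.5, 124.0, 126.0), resolution_arcsec=600,
        noise_sd={"haz": 0.5, "waz": 0.5, "whz": 0.5}, seed=19)
    data = generate_bundle(cfg).records
    data = data[data.wave == "2009"].dropna(subset=["haz"])
    spec = ModelSpec(outcome="haz",
                     continuous=["female", "hungry_season", "noise1"],
                     categorical={"age_years": "0"})
    stab = stability_select(data, spec, n_resamples=30, seed=9)
    for effect in ("female", "hungry_season", "age_years[1]", "age_years[2]",
                   "age_years[3]", "age_years[4]"):
        assert stab.retained[effect], effect
    assert set(stab.selection_frequency) == {
        "female", "hungry_season", "noise1",
        "age_years[1]", "age_years[2]", "age_years[3]", "age_years[4]"}
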