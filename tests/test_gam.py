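import json

import numpy as np
import pandas as pd
import pytest

from lexcontext.gam import (
    FitResult,
    ModelSpec,
    RandomIntercept,
    RandomSlope,
    SmoothTerm,
    TensorTerm,
    bootstrap_ci,
    build_design,
    crs_basis,
    crs_knots,
    fit_model,
    fit_penalized,
    frequency_model_spec,
    linear_partial_stub,
    quadratic_test_spec,
    significance_stars,
    superlinearity_test,
    surprisal_model_spec,
)
from lexcontext.synth import GenerativeEffectSpec, generate_participants, sample_modeling_frame


def _frame(n, seed=0, slope=5.0, noise=0.0, curvature=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "surp": rng.gamma(4.0, 2.0, n),
            "participant_id": rng.choice([f"p{i}" for i in range(10)], n),
        }
    )
    df["tf"] = 100.0 + slope * df["surp"] + curvature * df["surp"] ** 2
    if noise:
        df["tf"] += rng.normal(0, noise, n)
    return df


class TestBasis:
    def test_k4_spline_has_3_columns_after_constraint(self):
        df = _frame(100)
        design = build_design(ModelSpec("tf", (SmoothTerm("surp", 4),)), df)
        assert design.blocks[0].size == 3

    def test_random_effect_block_has_identity_penalty(self):
        df = _frame(200)
        design = build_design(ModelSpec("tf", (RandomIntercept(),)), df)
        b = design.blocks[0]
        assert b.size == 10
        assert np.array_equal(b.penalties[0], np.eye(10))

    def test_tensor_block_kronecker_dimension(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"freq": rng.gamma(4, 2, 300), "len": rng.uniform(1, 12, 300)})
        df["tf"] = 100.0
        design = build_design(ModelSpec("tf", (TensorTerm("freq", "len", 5, 5),)), df)
        assert design.blocks[0].size == 25 - 1  # one sum-to-zero constraint

    def test_partition_of_unity(self):
        knots = np.linspace(0, 10, 8)
        X = crs_basis(np.linspace(-2, 12, 50), knots)
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_few_distinct_values_reduce_k_with_warning(self):
        x = np.tile(np.arange(5.0), 40)
        with pytest.warns(UserWarning, match="reducing basis dimension"):
            knots = crs_knots(x, 10)
        assert len(knots) == 5

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            crs_knots(np.ones(50), 5)

    def test_missing_variable_rejected(self):
        df = _frame(50)
        with pytest.raises(KeyError, match="missing"):
            build_design(ModelSpec("tf", (SmoothTerm("nope", 4),)), df)


class TestFitOracles:
    def test_lambda_zero_equals_unpenalized_least_squares(self):
        df = _frame(500, noise=25.0, seed=2)
        design = build_design(ModelSpec("tf", (SmoothTerm("surp", 8),)), df)
        fit = fit_penalized(design, df["tf"], fixed_lambdas={"s(surp)": 0.0})
        beta_ols, *_ = np.linalg.lstsq(design.X, df["tf"].to_numpy(), rcond=None)
        assert np.abs(fit.beta - beta_ols).max() < 1e-8

    def test_lambda_infinity_collapses_to_line(self):
        df = _frame(500, noise=25.0, seed=3)
        design = build_design(ModelSpec("tf", (SmoothTerm("surp", 10),)), df)
        fit = fit_penalized(design, df["tf"], fixed_lambdas={"s(surp)": 1e10})
        xs = np.linspace(df["surp"].min(), df["surp"].max(), 40)
        pe = fit.partial_effect("surp", xs)
        resid = pe - np.polyval(np.polyfit(xs, pe, 1), xs)
        assert np.abs(resid).max() < 1e-4

    def test_noiseless_linear_data_recovers_slope(self):
        df = _frame(3000, slope=5.0, noise=0.0)
        fit = fit_model(ModelSpec("tf", (SmoothTerm("surp", 20),)), df)
        lo, hi = df["surp"].quantile([0.05, 0.95])
        pe = fit.partial_effect("surp", np.array([lo, hi]))
        slope = (pe[1] - pe[0]) / (hi - lo)
        assert slope == pytest.approx(5.0, abs=0.05)

    def test_linear_generative_slopes_recovered_within_5pct(self):
        # full benchmark model on noiseless linear data at large n
        profiles = generate_participants(0, 25, random_effect_sds={}, seed=11)
        rng = np.random.default_rng(12)
        n = 50_000
        ann = pd.DataFrame(
            {
                "surp": rng.gamma(4, 2, n),
                "freq": rng.gamma(5, 1.5, n),
                "len": rng.integers(1, 13, n).astype(float),
            }
        )
        ann["prev_surp"] = np.roll(ann["surp"], 1)
        ann["prev_freq"] = np.roll(ann["freq"], 1)
        ann["prev_len"] = np.roll(ann["len"], 1)
        eff = GenerativeEffectSpec(
            effects={"surp": (5.0,), "freq": (3.0,), "len": (2.0,)},
            spillover={"surp": 1.0, "freq": 0.0, "len": 0.0},
            noise_sd=0.0,
        )
        df = sample_modeling_frame(ann, profiles, n, eff, seed=13)
        fit = fit_model(frequency_model_spec("tf"), df, keep_cov=False)
        for var, true_slope in (("surp", 5.0), ("freq", 3.0), ("len", 2.0)):
            lo, hi = df[var].quantile([0.1, 0.9])
            pe = fit.partial_effect(var, np.array([lo, hi]))
            slope = (pe[1] - pe[0]) / (hi - lo)
            assert slope == pytest.approx(true_slope, rel=0.05)

    def test_gcv_criterion_also_recovers_slope(self):
        df = _frame(1500, slope=5.0, noise=20.0, seed=5)
        fit = fit_model(ModelSpec("tf", (SmoothTerm("surp", 10),)), df, criterion="gcv")
        assert fit.criterion == "gcv"
        lo, hi = df["surp"].quantile([0.1, 0.9])
        pe = fit.partial_effect("surp", np.array([lo, hi]))
        assert (pe[1] - pe[0]) / (hi - lo) == pytest.approx(5.0, abs=0.3)


@pytest.fixture(scope="module")
def fitted():
    df = _frame(2000, slope=4.0, noise=20.0, seed=7)
    spec = ModelSpec("tf", (SmoothTerm("surp", 12), RandomIntercept()))
    design = build_design(spec, df)
    fit = fit_penalized(design, df["tf"])
    return df, design, fit


class TestFitInvariants:
    def test_spline_partial_effect_centered(self, fitted):
        df, design, fit = fitted
        vals = fit.partial_effect("surp", df["surp"].to_numpy())
        assert abs(vals.sum()) < 1e-8 * len(df)

    def test_prediction_decomposes_into_terms(self, fitted):
        df, design, fit = fitted
        recon = fit.beta[0] + sum(
            design.X[:, b.sl] @ fit.beta[b.sl] for b in design.blocks
        )
        assert np.abs(recon - fit.fitted).max() < 1e-8

    def test_criterion_recorded(self, fitted):
        _, _, fit = fitted
        assert fit.criterion == "reml"
        assert np.isfinite(fit.criterion_value)

    def test_json_round_trip_preserves_evaluator(self, fitted):
        df, _, fit = fitted
        clone = FitResult.from_json(fit.to_json())
        g = np.linspace(0, 15, 7)
        assert np.allclose(
            clone.partial_effect("surp", g), fit.partial_effect("surp", g)
        )
        assert clone.lambdas == fit.lambdas

    def test_benchmark_model_specs_match_printed_formulas(self):
        s1 = surprisal_model_spec("tf")
        labels1 = [t.label for t in s1.terms]
        assert labels1 == [
            "s(surp)", "s(prev_surp)", "te(freq,len)", "te(prev_freq,prev_len)",
            "re(participant_id)", "re(participant_id,surp)", "re(participant_id,freq*len)",
        ]
        assert all(t.k == 20 for t in s1.terms if isinstance(t, SmoothTerm))
        s2 = frequency_model_spec("gd")
        labels2 = [t.label for t in s2.terms]
        assert labels2 == [
            "s(surp)", "s(prev_surp)", "s(freq)", "s(prev_freq)", "s(len)", "s(prev_len)",
            "re(participant_id)", "re(participant_id,surp)",
            "re(participant_id,freq)", "re(participant_id,len)",
        ]


class TestSuperlinearity:
    def test_strong_curvature_detected_with_sign(self, small_annotations, small_profiles):
        eff = GenerativeEffectSpec(
            effects={"surp": (5.0,), "freq": (3.0, 1.0), "len": (2.0,)}, noise_sd=40.0
        )
        df = sample_modeling_frame(small_annotations, small_profiles, 8000, eff, seed=21)
        res = superlinearity_test(df, "freq", "tf")
        assert res.p_value < 0.001
        assert res.quadratic_coef > 0
        assert res.stars == "***"

    def test_surprisal_variant_uses_surprisal_model_base(self, small_annotations, small_profiles):
        eff = GenerativeEffectSpec(noise_sd=40.0)
        df = sample_modeling_frame(small_annotations, small_profiles, 4000, eff, seed=22)
        res = superlinearity_test(df, "surp", "tf")
        spec = quadratic_test_spec("surp")
        labels = [t.label for t in spec.terms]
        assert "poly(surp,2)" in labels and "te(freq,len)" in labels
        assert "re(participant_id,surp^2)" in labels
        assert 0.0 <= res.p_value <= 1.0

    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "(.)"


class TestBootstrap:
    def test_same_seed_identical_bands(self, small_annotations, small_profiles):
        eff = GenerativeEffectSpec(noise_sd=25.0)
        df = sample_modeling_frame(small_annotations, small_profiles, 1500, eff, seed=31)
        spec = ModelSpec("tf", (SmoothTerm("surp", 8),))
        grid = np.linspace(2, 10, 9)
        b1 = bootstrap_ci(df, spec, "surp", grid, B=12, seed=99)
        b2 = bootstrap_ci(df, spec, "surp", grid, B=12, seed=99)
        assert np.array_equal(b1["lower"], b2["lower"])
        assert np.array_equal(b1["upper"], b2["upper"])

    def test_degenerate_data_gives_zero_width_band(self, small_annotations, small_profiles):
        eff = GenerativeEffectSpec(
            effects={"surp": (5.0,), "freq": (0.0,), "len": (0.0,)},
            spillover={}, noise_sd=0.0,
        )
        profiles = generate_participants(0, 8, random_effect_sds={}, seed=32)
        df = sample_modeling_frame(small_annotations, profiles, 1200, eff, seed=33)
        spec = ModelSpec("tf", (SmoothTerm("surp", 8),))
        grid = np.linspace(3, 9, 7)
        # anchored bands: replicate centering constants depend on the resampled
        # rows, so only the anchored effect is invariant on degenerate data;
        # the width bound is set by float64 solve noise on ~100 ms responses
        band = bootstrap_ci(df, spec, "surp", grid, B=10, seed=1, anchor="zero")
        assert np.max(band["upper"] - band["lower"]) < 1e-4

    def test_pointwise_coverage_of_linear_truth(self, small_annotations):
        # scaled-down coverage study: linear effect, anchored bands vs b*x
        rng = np.random.default_rng(44)
        spec = ModelSpec("tf", (SmoothTerm("surp", 8), RandomIntercept()))
        eff = GenerativeEffectSpec(
            effects={"surp": (5.0,), "freq": (0.0,), "len": (0.0,)},
            spillover={}, noise_sd=25.0,
        )
        x0 = 6.0  # mid-grid point
        hits, n_data = 0, 25
        for r in range(n_data):
            profiles = generate_participants(
                0, 10, random_effect_sds={"intercept": 15.0}, seed=100 + r
            )
            df = sample_modeling_frame(small_annotations, profiles, 800, eff, seed=200 + r)
            band = bootstrap_ci(
                df, spec, "surp", np.array([x0]), B=49, seed=300 + r, anchor="zero"
            )
            if band["lower"][0] <= 5.0 * x0 <= band["upper"][0]:
                hits += 1
        # binomial(25, 0.95) central range; failure here signals badly
        # miscalibrated bands rather than sampling noise
        assert hits >= 20
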