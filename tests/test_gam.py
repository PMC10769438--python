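import numpy as np
import pandas as pd
import pytest

from bitescape import GAMSpec, SmoothSpec, fit_gam, select_models, tps_basis
from bitescape.errors import ValidationError
from bitescape.gam import _tps_kernel


def plane_data(rng, n=300, noise=0.3):
    g = rng.uniform(1, 8, n)
    jp = rng.uniform(1, 9, n)
    y = 1.0 + 0.5 * g - 0.3 * jp + rng.normal(0, noise, n)
    return pd.DataFrame({"g": g, "jp": jp, "length_mm": y})


def ols_predict(df, response="length_mm", covars=("g", "jp")):
    X = np.column_stack([np.ones(len(df))] + [df[c] for c in covars])
    beta, *_ = np.linalg.lstsq(X, df[response].to_numpy(), rcond=None)
    return X @ beta


class TestTPSBasis:
    def test_kernel_zero_at_origin(self):
        assert _tps_kernel(np.array([0.0]), 2)[0] == 0.0
        assert _tps_kernel(np.array([0.0]), 1)[0] == 0.0

    def test_affine_function_unpenalized(self, rng):
        pts = rng.uniform(0, 10, (40, 2))
        B, S = tps_basis(pts, 12)
        coef = np.zeros(12)
        coef[-3:] = [1.0, 2.0, -0.5]  # constant + linear terms only
        assert coef @ S @ coef == pytest.approx(0.0, abs=1e-10)

    def test_penalty_psd_small_case(self, rng):
        pts = rng.uniform(0, 5, (8, 2))
        _, S = tps_basis(pts, 8)
        assert np.linalg.eigvalsh(S).min() >= -1e-10

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValidationError):
            tps_basis(pts, 8)

    def test_k_bounds_enforced(self, rng):
        pts = rng.uniform(0, 1, (20, 2))
        with pytest.raises(ValidationError):
            tps_basis(pts, 4)  # below null space + 2
        with pytest.raises(ValidationError):
            tps_basis(pts, 21)  # above n


class TestFit:
    def test_plane_data_matches_ols_oracle(self, rng):
        df = plane_data(rng, n=300, noise=0.3)
        spec = GAMSpec("length_mm", factors=(), smooths=(SmoothSpec(("g", "jp"), k=30),))
        fit = fit_gam(spec, df)
        oracle = ols_predict(df)
        se = 0.3 / np.sqrt(len(df))
        rms = np.sqrt(np.mean((fit.fitted_values - oracle) ** 2))
        assert rms < 2 * 0.3  # well within the noise scale
        # REML shrinks the wiggly part nearly away on linear truth
        assert fit.edf_by_term["s(g,jp)"] < 8.0

    def test_lambda_inf_reproduces_ols_exactly(self, rng):
        df = plane_data(rng)
        spec = GAMSpec("length_mm", factors=(), smooths=(SmoothSpec(("g", "jp"), k=30),))
        fit = fit_gam(spec, df, lambda_overrides={"s(g,jp)": np.inf})
        oracle = ols_predict(df)
        assert np.abs(fit.fitted_values - oracle).max() < 1e-6

    def test_noiseless_quadratic_nearly_interpolated(self, rng):
        n = 400
        g = rng.uniform(1, 8, n)
        jp = rng.uniform(1, 9, n)
        y = 2 + 0.3 * (g - 4) ** 2 + 0.2 * (jp - 5) ** 2
        df = pd.DataFrame({"g": g, "jp": jp, "length_mm": y})
        spec = GAMSpec("length_mm", factors=(), smooths=(SmoothSpec(("g", "jp"), k=30),))
        fit = fit_gam(spec, df)
        assert fit.deviance_explained >= 0.999

    def test_constant_response_null_fit(self, rng):
        df = plane_data(rng, n=100)
        df["length_mm"] = 3.14
        spec = GAMSpec("length_mm", factors=(), smooths=(SmoothSpec(("g", "jp"), k=20),))
        fit = fit_gam(spec, df)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-8)

    def test_edf_within_bounds(self, default_dataset):
        from bitescape import kinematic_table

        tab = kinematic_table(default_dataset)
        spec = GAMSpec(
            "length_mm",
            ("species", "strike_type"),
            ("ja", "rs", "ttpg"),
            (SmoothSpec(("g", "jp"), k=30),),
        )
        fit = fit_gam(spec, tab)
        # null space contributes 2 linear columns; wiggly part k - 3
        assert 2.0 <= fit.edf_by_term["s(g,jp)"] <= 29.0
        assert 0.0 <= fit.deviance_explained <= 1.0

    def test_prediction_consistent_with_fitted_values(self, rng):
        df = plane_data(rng, n=150)
        df["species"] = np.where(df.index % 2 == 0, "generalist", "scale_eater")
        spec = GAMSpec(
            "length_mm", ("species",), smooths=(SmoothSpec(("g", "jp"), k=20),)
        )
        fit = fit_gam(spec, df)
        pred = fit.predict(df)
        assert np.abs(pred - fit.fitted_values).max() < 1e-8

    def test_variable_cannot_be_linear_and_smooth(self):
        with pytest.raises(ValidationError):
            GAMSpec("length_mm", linear=("g",), smooths=(SmoothSpec(("g", "jp")),))

    def test_shrinkage_can_remove_smooth(self, rng):
        # pure-noise response: the double penalty shrinks the term away
        df = plane_data(rng, n=200)
        df["length_mm"] = rng.normal(0, 1, 200)
        spec = GAMSpec(
            "length_mm",
            factors=(),
            smooths=(SmoothSpec(("g", "jp"), k=20, shrinkage=True),),
        )
        fit = fit_gam(spec, df)
        assert fit.edf_by_term["s(g,jp)"] < 2.0


class TestSelection:
    def test_duplicate_candidates_tie(self, rng):
        df = plane_data(rng)
        spec = GAMSpec("length_mm", factors=(), smooths=(SmoothSpec(("g", "jp"), k=20),))
        table = select_models([spec, spec], df)
        np.testing.assert_allclose(table["delta_aic"], 0.0, atol=1e-6)

    def test_failure_flagged_not_fatal(self, rng):
        df = plane_data(rng)
        good = GAMSpec("length_mm", factors=(), smooths=(SmoothSpec(("g", "jp"), k=20),))
        bad = GAMSpec("length_mm", factors=("missing_factor",))
        table = select_models([good, bad], df).set_index("model")
        assert table.loc[good.label, "error"] == ""
        assert table.loc[bad.label, "error"] != ""

    def test_interaction_surface_beats_additive(self, default_dataset):
        from bitescape import kinematic_table

        tab = kinematic_table(default_dataset)
        inter = GAMSpec(
            "length_mm",
            ("species", "strike_type"),
            ("ja", "rs", "ttpg"),
            (SmoothSpec(("g", "jp"), k=30),),
        )
        addit = GAMSpec(
            "length_mm",
            ("species", "strike_type"),
            ("ja", "rs", "ttpg"),
            (SmoothSpec(("g",), k=10), SmoothSpec(("jp",), k=10)),
        )
        table = select_models([inter, addit], tab).set_index("model")
        assert table.loc[addit.label, "aic"] - table.loc[inter.label, "aic"] > 2.0

    def test_packaged_candidates_cover_seven_shapes(self):
        from bitescape.gam import candidate_models

        for resp in ("length_mm", "volume_mm3"):
            cands = candidate_models(resp)
            assert len(cands) == 7
            assert sum(
                any(len(s.variables) == 2 for s in c.smooths) for c in cands
            ) == 4  # bivariate surface present in four shapes
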