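"""AICc, Akaike weights, candidate enumeration, OLS fits, model averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warblerstop.modelselect import (
    ModelSpec,
    SelectionTable,
    aicc,
    akaike_weights,
    build_design,
    enumerate_candidate_models,
    fit_linear_model,
    model_average,
)


class TestAICc:
    def test_hand_value(self):
        assert aicc(-50, 3, 20) == pytest.approx(107.5)

    def test_large_n_limit(self):
        aic = -2 * (-50) + 2 * 3
        assert aicc(-50, 3, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_boundary_correction(self):
        # k = n-2 makes the correction 2k(k+1)
        k, n = 8, 10
        assert aicc(0, k, n) == pytest.approx(2 * k + 2 * k * (k + 1))

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            aicc(-50, 10, 11)


class TestWeights:
    def test_examples(self):
        _, w = akaike_weights([100.0, 102.0])
        assert np.allclose(w, [0.7311, 0.2689], atol=1e-4)
        _, w = akaike_weights([0.0, 2.0, 4.0])
        assert np.allclose(w, [0.6652, 0.2447, 0.0900], atol=1e-4)

    def test_single_model(self):
        _, w = akaike_weights([123.4])
        assert w == pytest.approx([1.0])

    @given(st.lists(st.floats(0, 500), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_weights_sum_to_one(self, vals):
        delta, w = akaike_weights(vals)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert delta.min() == 0.0


class TestEnumeration:
    def test_four_mains_gives_fifteen_plus_null(self):
        specs = enumerate_candidate_models(["a", "b", "c", "d"])
        assert len(specs) == 16
        assert sum(1 for s in specs if not s.terms) == 1  # exactly one null

    def test_single_main(self):
        specs = enumerate_candidate_models(["a"])
        assert {s.name for s in specs} == {"null", "a"}

    def test_hierarchy_two_mains(self):
        specs = enumerate_candidate_models(["a", "b"], [("a", "b")])
        names = {s.name for s in specs}
        assert names == {"null", "a", "b", "a + b", "a + b + a:b"}

    def test_biological_tier_count_is_144(self):
        specs = enumerate_candidate_models(
            ["destination", "timing", "condition", "age", "sex"],
            [
                ("destination", "timing"),
                ("destination", "age"),
                ("destination", "sex"),
                ("timing", "age"),
                ("timing", "sex"),
            ],
            always_include=("ln_bleedtime",),
        )
        assert len(specs) == 144
        # null has no extras; every other model carries the always-include term
        nulls = [s for s in specs if not s.terms]
        assert len(nulls) == 1
        assert all("ln_bleedtime" in s.terms for s in specs if s.terms)

    def test_unknown_interaction_parent(self):
        with pytest.raises(ValueError):
            enumerate_candidate_models(["a"], [("a", "zzz")])


class TestLinearModel:
    def test_normal_equations_oracle(self, rng):
        """Coefficients match the closed-form normal-equations solution."""
        data = pd.DataFrame(
            {
                "y": [1.1, 1.9, 3.2, 3.9, 5.1],
                "x": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        fit = fit_linear_model(data, "y", ModelSpec(mains=("x",)))
        X = np.column_stack([np.ones(5), data["x"]])
        beta = np.linalg.solve(X.T @ X, X.T @ data["y"])
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_intercept_only_is_mean(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 6.0]})
        fit = fit_linear_model(data, "y", ModelSpec())
        assert fit.params["Intercept"] == pytest.approx(data["y"].mean())

    def test_exact_fit_flagged(self):
        data = pd.DataFrame({"y": [2.0, 4.0, 6.0, 8.0, 10.0],
                             "x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        with pytest.warns(UserWarning, match="zero residual variance"):
            fit = fit_linear_model(data, "y", ModelSpec(mains=("x",)))
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.sigma2_ml == 0.0

    def test_random_designs_match_lstsq(self, rng):
        for _ in range(5):
            n = 30
            data = pd.DataFrame(
                {
                    "y": rng.normal(size=n),
                    "x1": rng.normal(size=n),
                    "x2": rng.normal(size=n),
                }
            )
            fit = fit_linear_model(data, "y", ModelSpec(mains=("x1", "x2")))
            X = np.column_stack([np.ones(n), data["x1"], data["x2"]])
            beta, *_ = np.linalg.lstsq(X, data["y"].to_numpy(), rcond=None)
            assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_categorical_reference_level(self):
        data = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 5.5, 4.5],
                "sex": ["F", "M"] * 4,
            }
        )
        fit = fit_linear_model(data, "y", ModelSpec(mains=("sex",)))
        assert "sex[M]" in fit.params.index  # F is the reference

    def test_rank_deficiency_error(self):
        data = pd.DataFrame({"y": [1.0] * 6, "x": [2.0] * 6})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear_model(data, "y", ModelSpec(mains=("x",)))


class TestModelAverage:
    def _table(self, rng):
        n = 40
        data = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
            }
        )
        data["y"] = 1.0 + 0.5 * data["x1"] + rng.normal(size=n) * 0.3
        specs = enumerate_candidate_models(["x1", "x2"])
        return SelectionTable([fit_linear_model(data, "y", s) for s in specs])

    def test_hand_formula(self):
        """Unconditional SE on the printed two-model example."""
        betas = np.array([1.0, 1.5])
        ses = np.array([0.2, 0.3])
        w = np.array([0.6, 0.4])
        bbar = float(w @ betas)
        use = float(w @ np.sqrt(ses**2 + (betas - bbar) ** 2))
        assert bbar == pytest.approx(1.2)
        assert use == pytest.approx(0.3394, abs=2e-4)

    def test_term_in_every_model(self, rng):
        table = self._table(rng)
        # average over only the models containing x1 equals each coefficient
        # when they are all identical; here just check w_plus bounds
        avg = model_average(table, "x1")
        est = avg["x1"]
        assert 0 < est.w_plus <= 1.0
        assert est.estimate == pytest.approx(0.5, abs=0.2)

    def test_absent_term_error(self, rng):
        table = self._table(rng)
        with pytest.raises(ValueError):
            model_average(table, "zzz")

    def test_weights_renormalized_subset(self, rng):
        table = self._table(rng)
        top = table.top_set(4.0)
        avg_all = model_average(table, "x1")
        avg_top = model_average(table, "x1", subset=top)
        # w_plus is over the full candidate set in both calls
        assert avg_all["x1"].w_plus == pytest.approx(avg_top["x1"].w_plus)


class TestDesign:
    def test_interaction_columns(self):
        data = pd.DataFrame(
            {
                "destination": ["southeast", "boreal", "boreal", "southeast"],
                "timing": ["early", "middle", "late", "late"],
            }
        )
        X = build_design(
            data, ModelSpec(("destination", "timing"), (("destination", "timing"),))
        )
        assert "destination[boreal]:timing[middle]" in X.columns
        assert "destination[boreal]:timing[late]" in X.columns
        assert X["Intercept"].eq(1.0).all()
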