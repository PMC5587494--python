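"""Transient-CJS likelihood, fitting, and derived stopover quantities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warblerstop.cjs import (
    CJSModelSpec,
    CaptureHistory,
    cjs_history_logprob,
    cjs_neg_loglik,
    collapse_histories,
    enumerate_history_probs,
    expected_stopover_duration,
    fit_cjs,
    histories_frame,
    transient_probability,
    _per_individual_loglik,
)
from warblerstop.synth import simulate_histories


class TestCollapse:
    def _detections(self, days, bird="b1"):
        return pd.DataFrame({"bird_id": bird, "day": days})

    def test_single_capture(self):
        [h] = collapse_histories(self._detections([100]))
        assert "".join(map(str, h.detections)) == "100000000"

    def test_offset_placement(self):
        [h] = collapse_histories(self._detections([100, 101, 103]))
        assert "".join(map(str, h.detections)) == "110100000"

    def test_span_overflow_warns(self):
        with pytest.warns(UserWarning, match="beyond occasion"):
            [h] = collapse_histories(self._detections([100, 120]))
        assert "".join(map(str, h.detections)) == "100000000"

    def test_history_must_start_detected(self):
        with pytest.raises(ValueError):
            CaptureHistory("b1", [0, 1, 0])


class TestLikelihood:
    @pytest.mark.parametrize(
        "hist,phis,ps,prob",
        [
            ([1, 1], [0.5], [0.5], 0.25),          # phi*p
            ([1, 0], [0.5], [0.5], 0.75),          # 1 - phi*p
            ([1, 0, 1], [0.6, 0.6], [0.5, 0.5], 0.09),  # phi(1-p)phi p
        ],
    )
    def test_hand_products(self, hist, phis, ps, prob):
        assert cjs_history_logprob(hist, phis, ps) == pytest.approx(np.log(prob))

    @pytest.mark.parametrize("T", [2, 3, 4])
    @pytest.mark.parametrize(
        "phi1,phi2,p",
        [(0.35, 0.75, 0.4), (0.9, 0.2, 0.85), (0.5, 0.5, 0.5)],
    )
    def test_outcome_probabilities_sum_to_one(self, T, phi1, phi2, p):
        probs = enumerate_history_probs(T, phi1, phi2, p)
        assert len(probs) == 2 ** (T - 1)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-10)

    @given(
        st.floats(0.05, 0.95), st.floats(0.05, 0.95), st.floats(0.05, 0.95)
    )
    @settings(deadline=None, max_examples=30)
    def test_probability_sum_property(self, phi1, phi2, p):
        probs = enumerate_history_probs(4, phi1, phi2, p)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-10)

    def test_vectorized_matches_scalar(self, rng):
        """The batched likelihood equals the per-history recursion."""
        det = simulate_histories(50, 0.4, 0.7, 0.5, 6, rng)
        phi1 = np.full(50, 0.42)
        phi2 = np.full(50, 0.71)
        p = np.full(50, 0.33)
        batch = _per_individual_loglik(det, phi1, phi2, p)
        for i in range(50):
            phis = np.array([0.42] + [0.71] * 4)
            ps = np.full(5, 0.33)
            assert batch[i] == pytest.approx(
                cjs_history_logprob(det[i], phis, ps), abs=1e-10
            )

    def test_non_finite_params_rejected(self, rng):
        det = simulate_histories(5, 0.0, 0.5, 0.5, 3, rng)
        X = np.ones((5, 1))
        with pytest.raises(ValueError):
            cjs_neg_loglik(np.array([np.nan, 0.0, 0.0]), det, X, X, X)


class TestFit:
    def test_fixed_p_one_closed_form(self, rng):
        """With perfect detection, the MLEs are observed survival fractions."""
        det = simulate_histories(800, 0.3, 0.6, 1.0, 5, rng)
        cov = pd.DataFrame({"bird_id": [str(i) for i in range(800)]})
        fit = fit_cjs((det, cov), CJSModelSpec(fix_p=1.0), n_starts=2, seed=0)
        phi1_hat = fit.real_params()[0][0]
        phi2_hat = fit.real_params()[1][0]
        # observed fractions: survivors of interval 1; pooled later intervals
        s1 = det[:, 1].mean()
        alive = det[:, 1:].astype(bool)
        num = den = 0
        for t in range(1, 4):
            den += alive[:, t - 1].sum()
            num += (alive[:, t - 1] & alive[:, t]).sum()
        assert phi1_hat == pytest.approx(s1, abs=1e-4)
        assert phi2_hat == pytest.approx(num / den, abs=1e-4)

    def test_recovery_within_two_se(self, rng):
        from scipy.special import logit

        tau = 1 - 0.35 / 0.75
        det = simulate_histories(1000, tau, 0.75, 0.4, 9, rng)
        cov = pd.DataFrame({"bird_id": [str(i) for i in range(1000)]})
        fit = fit_cjs((det, cov), CJSModelSpec(), seed=0)
        truth = np.array([logit(0.35), logit(0.75), logit(0.4)])
        se = np.sqrt(np.diag(fit.vcov))
        assert np.all(np.abs(fit.beta - truth) <= 2 * se)


class TestDerived:
    @pytest.mark.parametrize(
        "phi,days",
        [(0.5, 1.4427), (np.exp(-1), 1.0), (0.699, 2.7926)],
    )
    def test_duration_values(self, phi, days):
        dur, _ = expected_stopover_duration(phi)
        assert dur == pytest.approx(days, abs=1e-3)

    def test_duration_se_delta_method(self):
        dur, se = expected_stopover_duration(0.7, se=0.05)
        expect = 0.05 / (0.7 * np.log(0.7) ** 2)
        assert se == pytest.approx(expect)

    @given(st.floats(0.02, 0.97))
    @settings(deadline=None, max_examples=50)
    def test_duration_strictly_increasing(self, phi):
        d1, _ = expected_stopover_duration(phi)
        d2, _ = expected_stopover_duration(phi + 0.02)
        assert d2 > d1

    def test_duration_domain(self):
        with pytest.raises(ValueError):
            expected_stopover_duration(1.0)
        with pytest.raises(ValueError):
            expected_stopover_duration(0.0)

    def test_transient_examples(self):
        pct, _, clamped = transient_probability(0.35, 0.70)
        assert pct == pytest.approx(50.0)
        assert not clamped
        pct, _, _ = transient_probability(0.7, 0.7)
        assert pct == 0.0

    def test_transient_delta_se_hand_oracle(self):
        cov = np.diag([0.001, 0.001])
        pct, se, _ = transient_probability(0.35, 0.70, cov)
        grad = np.array([-1 / 0.7, 0.35 / 0.49])
        expect = np.sqrt(grad @ cov @ grad) * 100
        assert se == pytest.approx(expect)
        assert se == pytest.approx(5.0508, abs=1e-3)

    def test_transient_clamped(self):
        pct, _, clamped = transient_probability(0.9, 0.7)
        assert clamped and pct == 0.0


class TestModelSelection:
    def test_single_candidate_equals_its_estimate(self, rng):
        from warblerstop.cjs import stopover_model_selection

        det = simulate_histories(400, 0.3, 0.7, 0.5, 9, rng)
        cov = pd.DataFrame(
            {
                "bird_id": [str(i) for i in range(400)],
                "destination": ["southeast", "boreal"] * 200,
            }
        )
        res = stopover_model_selection(
            (det, cov), [()], phi1_terms=(), p_terms=(), seed=0
        )
        fit = res.fits[0]
        all_row = res.estimates[res.estimates["group"] == "all"].iloc[0]
        phi2_hat = fit.real_params()[1].mean()
        dur, _ = expected_stopover_duration(phi2_hat)
        assert all_row["duration_days"] == pytest.approx(dur, abs=1e-9)

    def test_group_transient_ranking_recovered(self, rng):
        from warblerstop.cjs import stopover_model_selection

        n = 1000
        dest = np.array(["southeast", "boreal"])[np.arange(n) % 2]
        tau = np.where(dest == "boreal", 0.5, 0.1)
        det = simulate_histories(n, tau, 0.7, 0.4, 9, rng)
        cov = pd.DataFrame({"bird_id": [str(i) for i in range(n)],
                            "destination": dest})
        res = stopover_model_selection(
            (det, cov), [(), ("destination",)], phi1_terms=("destination",),
            p_terms=(), seed=0,
        )
        est = res.estimates.set_index("group")
        assert (
            est.loc["destination=boreal", "transient_pct"]
            > est.loc["destination=southeast", "transient_pct"]
        )
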