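import numpy as np
import pytest
from scipy import optimize

import ascotval as av
from ascotval.anchoring import AnchoredLinearRegression, fit_anchoring
from ascotval.states import BEST_STATE
from ascotval.tto import StateValueObservation


def _observations(tariff, values_by_state):
    return [
        StateValueObservation(av.parse_state(s), v, 100, 0.05)
        for s, v in values_by_state.items()
    ]


class TestAnchoredRegression:
    def test_exact_fit_recovers_slope_and_unit_r_squared(self):
        anchor_x = 6.778
        x = np.linspace(0.5, anchor_x, 12)
        y = 1.0 + 0.2 * (x - anchor_x)  # line through (anchor_x, 1), slope 0.2
        reg = AnchoredLinearRegression(anchor_x=anchor_x, anchor_y=1.0).fit(x, y)
        assert reg.slope_ == pytest.approx(0.2, abs=1e-14)
        assert reg.r_squared_ == pytest.approx(1.0, abs=1e-12)
        assert reg.slope_ * anchor_x + reg.intercept_ == pytest.approx(1.0, abs=1e-14)

    def test_constraint_holds_on_noisy_fits(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            anchor_x = float(rng.uniform(3, 8))
            x = rng.uniform(0, anchor_x, size=30)
            y = 1 + rng.normal(-0.3, 0.2) * (x - anchor_x) + rng.normal(0, 0.1, 30)
            reg = AnchoredLinearRegression(anchor_x=anchor_x).fit(x, y)
            assert reg.slope_ * anchor_x + reg.intercept_ == pytest.approx(
                1.0, abs=1e-12
            )

    def test_matches_search_oracle_over_the_one_parameter_family(self):
        """Constrained least squares equals a direct numeric minimisation of
        SSE over the slope (lines through the anchor form a 1-parameter
        family)."""
        rng = np.random.default_rng(1)
        for trial in range(5):
            anchor_x = float(rng.uniform(4, 8))
            x = rng.uniform(0, anchor_x, size=25)
            y = rng.normal(0, 0.5, size=25) + 0.15 * x - 0.4
            reg = AnchoredLinearRegression(anchor_x=anchor_x).fit(x, y)

            def sse(a):
                return np.sum((y - (a * x + 1 - a * anchor_x)) ** 2)

            oracle = optimize.minimize_scalar(sse, bounds=(-5, 5), method="bounded",
                                              options={"xatol": 1e-12})
            assert reg.slope_ == pytest.approx(oracle.x, abs=1e-6)

    def test_residuals_orthogonal_to_centred_predictor(self):
        rng = np.random.default_rng(2)
        anchor_x = 6.0
        x = rng.uniform(0, anchor_x, 40)
        y = rng.normal(0, 1, 40)
        reg = AnchoredLinearRegression(anchor_x=anchor_x).fit(x, y)
        resid = y - reg.predict(x)
        assert resid @ (x - anchor_x) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            AnchoredLinearRegression(anchor_x=1.0).fit([2.0, 2.0, 2.0], [0, 1, 2])


class TestFitAnchoring:
    def test_anchor_state_maps_to_one_on_exact_data(self, jp):
        bws_max = av.latent_bws_score(BEST_STATE, jp)
        states = ["11111111", "21212121", "33333333", "44444444", "12341234"]
        values = {
            s: 1 + 0.2 * (av.latent_bws_score(av.parse_state(s), jp) - bws_max)
            for s in states
        }
        fit = fit_anchoring(_observations(jp, values), jp)
        assert av.apply_anchoring(fit, BEST_STATE, jp) == pytest.approx(1.0, abs=1e-12)
        assert fit.conv.slope == pytest.approx(0.2, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_published_conversions_reproduce_printed_extremes(self, jp, uk):
        worst = av.scqaly_score(av.parse_state("44444444"), jp, av.JP_CONVERSION)
        assert round(worst, 2) == -0.38
        best_uk = av.scqaly_score(BEST_STATE, uk, av.UK_CONVERSION)
        assert round(best_uk, 2) == 1.00

    def test_too_few_observations_rejected(self, jp):
        with pytest.raises(ValueError):
            fit_anchoring(_observations(jp, {"11111111": 1.0}), jp)

    def test_slope_recovery_on_synthetic_study(self):
        """64-state study with truth slope 0.25 and noise 0.1: the
        constrained estimator lands within 0.02 of the true slope."""
        truth_tariff = av.SyntheticTruth.default(seed=0).implied_tariff()
        bws_max = av.latent_bws_score(BEST_STATE, truth_tariff)
        truth = av.SyntheticTruth.default(
            seed=21,
            true_conversion=av.ConversionParams(0.25, 1 - 0.25 * bws_max),
            tto_noise_sd=0.1,
        )
        from ascotval.synthetic import make_bws_design, simulate_tto

        blocks = make_bws_design(64, 8, seed=21)
        responses = simulate_tto(truth, blocks, 1050, seed=22)
        obs, _ = av.state_means(responses)
        fit = fit_anchoring(obs, truth_tariff)
        assert abs(fit.conv.slope - 0.25) < 0.02
        assert fit.conv.slope * fit.bws_max + fit.conv.intercept == pytest.approx(
            1.0, abs=1e-12
        )
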