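import math

import numpy as np
import pytest

import ascotval as av
from ascotval.coding import ChoiceOccasion, code_row
from ascotval.estimation import (
    BestWorstMNL,
    BestWorstMixedLogit,
    IdentifiabilityError,
    occasion_logprob,
)


def _occasion(alternatives, chosen, sign=+1):
    return ChoiceOccasion(
        respondent_id=1, task_index=1,
        occasion="best" if sign > 0 else "worst",
        sign=sign, alternatives=tuple(alternatives), chosen=chosen,
    )


class TestOccasionLogprob:
    def test_two_equal_alternatives(self):
        occ = _occasion([("food", 4), ("control", 4)], "food")
        beta = np.zeros(31)
        assert occasion_logprob(occ, beta) == pytest.approx(math.log(0.5))

    def test_eight_equal_alternatives(self):
        alts = [(d.name, 4) for d in av.DOMAINS]
        occ = _occasion(alts, "dignity")
        assert occasion_logprob(occ, np.zeros(31)) == pytest.approx(math.log(1 / 8))

    def test_matches_brute_force_softmax_on_three_item_toy(self):
        """Direct enumeration oracle: compute exp(sign*V) for each
        alternative from first principles and normalise."""
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.5, size=31)
        alts = [("food", 1), ("safety", 2), ("occupation", 3)]
        for sign in (+1, -1):
            v = {
                name: float(code_row(name, lvl, 1) @ beta) for name, lvl in alts
            }
            weights = {n: math.exp(sign * u) for n, u in v.items()}
            total = sum(weights.values())
            for chosen in v:
                occ = _occasion(alts, chosen, sign)
                expected = math.log(weights[chosen] / total)
                assert occasion_logprob(occ, beta) == pytest.approx(
                    expected, abs=1e-10
                )

    def test_probabilities_normalise_over_alternatives(self, small_study):
        rng = np.random.default_rng(4)
        beta = rng.normal(0, 1, size=31)
        for resp in small_study["bws"][:5]:
            for occ in av.explode(resp):
                total = sum(
                    math.exp(
                        occasion_logprob(
                            _occasion(occ.alternatives, name, occ.sign), beta
                        )
                    )
                    for name, _ in occ.alternatives
                )
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_with_negated_utilities_is_equivariant(self):
        rng = np.random.default_rng(8)
        beta = rng.normal(0, 0.7, size=31)
        alts = [("food", 1), ("control", 2), ("dignity", 4), ("safety", 3)]
        for chosen in ("food", "dignity"):
            plus = occasion_logprob(_occasion(alts, chosen, +1), beta)
            minus = occasion_logprob(_occasion(alts, chosen, -1), -beta)
            assert plus == pytest.approx(minus, abs=1e-12)

    def test_overflow_guard_for_large_utilities(self):
        beta = np.zeros(31)
        beta[0] = 650.0  # X1 column
        alts = [("accommodation", 4), ("control", 4)]
        lp = occasion_logprob(_occasion(alts, "accommodation"), beta)
        assert np.isfinite(lp)
        assert lp == pytest.approx(0.0, abs=1e-12)


class TestMNL:
    def test_fitted_loglik_beats_null_and_gradient_vanishes(self, small_choice_long):
        est = BestWorstMNL().fit(small_choice_long)
        null_ll = est.loglik(small_choice_long, beta=np.zeros(31))
        assert est.loglik_ > null_ll
        assert est.gradient_max_ / est.n_occasions_ < 1e-5

    def test_replicating_every_respondent_leaves_estimates_unchanged(
        self, small_study, small_choice_long
    ):
        doubled = [r for r in small_study["bws"]] + [
            av.BwsResponse(
                r.respondent_id + 10000, r.profile, r.picks, r.task_index,
                r.total_bws_minutes,
            )
            for r in small_study["bws"]
        ]
        est1 = BestWorstMNL().fit(small_choice_long)
        est2 = BestWorstMNL().fit(av.responses_to_long(doubled))
        assert np.allclose(est1.coef_, est2.coef_, atol=1e-7)

    def test_single_response_is_unidentified(self, small_study):
        long = av.responses_to_long(small_study["bws"][:1])
        with pytest.raises(IdentifiabilityError):
            BestWorstMNL().fit(long)

    def test_coefficient_table_round_trips_vectors(self, small_choice_long):
        est = BestWorstMNL().fit(small_choice_long)
        table = est.coefficient_table_
        assert np.allclose(table.coef_vector(), est.coef_)
        assert np.allclose(table.se_vector(), est.se_)


class TestMixedLogit:
    def test_one_draw_zero_scale_collapses_to_mnl(self, small_choice_long):
        mnl = BestWorstMNL().fit(small_choice_long)
        mx = BestWorstMixedLogit(n_draws=1, seed=0)
        ll = mx.loglik(small_choice_long, beta=mnl.coef_, mixing_sd=np.zeros(7))
        assert ll == pytest.approx(mnl.loglik_, abs=1e-9)

    def test_likelihood_invariant_to_row_order_with_shared_seed(
        self, small_choice_long
    ):
        mx = BestWorstMixedLogit(n_draws=25, seed=3)
        beta = np.linspace(-0.5, 0.5, 31)
        sd = np.full(7, 0.3)
        ll1 = mx.loglik(small_choice_long, beta=beta, mixing_sd=sd)
        shuffled = small_choice_long.sample(
            frac=1.0, random_state=5
        ).reset_index(drop=True)
        ll2 = mx.loglik(shuffled, beta=beta, mixing_sd=sd)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    @pytest.mark.parametrize("scheme, factor", [("respondent", 1),
                                                ("respondent_by_sign", 2)])
    def test_cluster_schemes_build_expected_cluster_counts(
        self, small_choice_long, scheme, factor
    ):
        from ascotval.estimation import _compile

        data = _compile(small_choice_long, scheme)
        assert data.n_clusters == data.n_respondents * factor

    def test_lognormal_likelihood_is_finite_and_seeded(self, small_choice_long):
        mx = BestWorstMixedLogit(distribution="lognormal", n_draws=10, seed=1)
        beta = np.concatenate([np.full(7, -0.5), np.linspace(0, 2, 24)])
        ll1 = mx.loglik(small_choice_long, beta=beta, mixing_sd=np.full(7, 0.2))
        ll2 = mx.loglik(small_choice_long, beta=beta, mixing_sd=np.full(7, 0.2))
        assert np.isfinite(ll1)
        assert ll1 == ll2
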