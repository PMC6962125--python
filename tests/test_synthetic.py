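import numpy as np
import pytest

import ascotval as av
from ascotval.states import DOMAINS
from ascotval.synthetic import (
    DesignError,
    SyntheticTruth,
    gumbel_choice,
    make_bws_design,
    simulate_tto,
    write_study,
)

_NAMES = [d.name for d in DOMAINS]


def _flat_truth(**kwargs):
    """All item utilities zero (complete indifference)."""
    return SyntheticTruth(
        true_domain_constants={n: 0.0 for n in _NAMES if n != "control"},
        true_level_effects={(n, q): 0.0 for n in _NAMES for q in (1, 2, 3)},
        **kwargs,
    )


class TestDesign:
    @pytest.mark.parametrize("n_profiles, n_blocks", [(32, 4), (64, 8)])
    def test_block_structure_and_level_balance(self, n_profiles, n_blocks):
        design = make_bws_design(n_profiles, n_blocks, seed=5)
        assert len(design) == n_blocks
        assert all(len(b) == n_profiles // n_blocks for b in design)
        flat = [s for b in design for s in b]
        assert len({str(s) for s in flat}) == n_profiles
        levels = np.array([s.levels_by_position for s in flat])
        for pos in range(8):
            counts = np.bincount(levels[:, pos], minlength=5)[1:]
            assert np.all(counts == n_profiles // 4)

    def test_seed_determinism(self):
        a = make_bws_design(32, 4, seed=9)
        b = make_bws_design(32, 4, seed=9)
        assert [[str(s) for s in blk] for blk in a] == [
            [str(s) for s in blk] for blk in b
        ]

    def test_infeasible_requests_rejected(self):
        with pytest.raises(DesignError):
            make_bws_design(30, 4, seed=0)
        with pytest.raises(DesignError):
            make_bws_design(10, 5, seed=0)


class TestSimulateBws:
    def test_dominant_item_chosen_best_almost_always(self):
        truth = _flat_truth(seed=0)
        truth.true_domain_constants["food"] = 10.0
        design = make_bws_design(32, 4, seed=0)
        responses = av.simulate_bws(truth, design, n_respondents=250, seed=1)
        best = [r.picks[0] for r in responses]
        # softmax bound: P(best=food) >= e^10 / (e^10 + 7) > 0.999
        assert len(best) == 2000
        assert np.mean([b == "food" for b in best]) >= 0.99

    def test_indifference_gives_uniform_best_shares(self):
        truth = _flat_truth(seed=0)
        design = make_bws_design(32, 4, seed=2)
        responses = av.simulate_bws(truth, design, n_respondents=250, seed=3)
        best = np.array([r.picks[0] for r in responses])
        freq = np.array([(best == n).mean() for n in _NAMES])
        mc_3se = 3 * np.sqrt(0.125 * 0.875 / len(best))
        assert np.all(np.abs(freq - 0.125) < mc_3se + 1e-9)

    def test_each_respondent_answers_their_whole_block(self, small_study):
        counts = {}
        for r in small_study["bws"]:
            counts[r.respondent_id] = counts.get(r.respondent_id, 0) + 1
        assert set(counts.values()) == {8}

    def test_best_choice_frequencies_match_conditional_logit_on_toy(self):
        """First-choice shares over 3 items with utilities (1, 0, -1)
        converge to the closed-form softmax probabilities."""
        v = np.array([1.0, 0.0, -1.0])
        expected = np.exp(v) / np.exp(v).sum()
        rng = np.random.default_rng(11)
        n = 20000
        picks = np.array([gumbel_choice(v, +1, rng) for _ in range(n)])
        freq = np.bincount(picks, minlength=3) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freq - expected) < 3 * se + 1e-12)


class TestSimulateTto:
    def _conv_truth(self, intercept, noise=0.0, **kw):
        # slope 0 makes every state's true value equal the intercept
        return av.SyntheticTruth.default(
            true_conversion=av.ConversionParams(0.0, intercept),
            tto_noise_sd=noise,
            seed=0,
            **kw,
        )

    @pytest.mark.parametrize(
        "true_value, wtd, answer",
        [(0.75, False, 7.5), (-0.5, True, 5.0), (-1.4, True, 0.0)],
    )
    def test_noiseless_answers_invert_the_scoring_formulas(
        self, true_value, wtd, answer
    ):
        truth = self._conv_truth(true_value)
        [resp] = simulate_tto(truth, [av.parse_state("11111111")], 1, seed=0)
        assert resp.wtd_flag is wtd
        assert resp.answer_years == pytest.approx(answer)

    def test_state_means_converge_to_clamped_truth(self):
        truth = av.SyntheticTruth.default(seed=6, tto_noise_sd=0.1)
        block = make_bws_design(8, 1, seed=6)[0]
        responses = simulate_tto(truth, [block], 500, seed=7, answer_grid=0.0)
        observations, _ = av.state_means(responses)
        tariff = truth.implied_tariff()
        for obs in observations:
            v = float(
                truth.true_conversion.apply(av.latent_bws_score(obs.state, tariff))
            )
            v = min(1.0, max(-1.0, v))
            se = obs.sd / np.sqrt(obs.n_respondents)
            assert abs(obs.mean_tto - v) < 2 * se + 1e-9

    def test_seed_determinism_byte_identical_outputs(self, tmp_path):
        truth = av.SyntheticTruth.default(seed=13)
        for d in ("a", "b"):
            _, _, bws, tto = av.simulate_study(truth, n_respondents=20)
            write_study(tmp_path / d, truth, bws, tto)
        for name in ("bws_responses.csv", "tto_responses.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestTruthValidation:
    def test_mixing_sd_requires_distribution(self):
        with pytest.raises(ValueError, match="mixing_sd"):
            _flat_truth(mixing_sd={"food": 0.5}, mixing_distribution="none", seed=0)

    def test_implied_tariff_uses_pipeline_rescaling(self):
        truth = av.SyntheticTruth.default(seed=0)
        tariff = truth.implied_tariff()
        assert tariff.weight("control", 1) == 1.0
        assert tariff.weight("control", 4) == 0.0
        # matches the published tariff within printed rounding
        jp = av.jp_tariff()
        diffs = [
            abs(tariff.weight(d.name, q) - jp.weight(d.name, q))
            for d in DOMAINS
            for q in (1, 2, 3, 4)
        ]
        assert max(diffs) <= 0.001
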