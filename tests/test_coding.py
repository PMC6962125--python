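import numpy as np
import pandas as pd
import pytest

import ascotval as av
from ascotval.coding import (
    DESIGN_COLUMNS,
    BwsResponse,
    code_row,
    explode,
    filter_respondents,
    responses_to_long,
)
from ascotval.states import DOMAINS, parse_state

_P = {d.name: d.p_index for d in DOMAINS}


def _random_response(rng, rid=1, task=1):
    profile = av.AscotState(tuple(int(q) for q in rng.integers(1, 5, size=8)))
    picks = tuple(rng.choice([d.name for d in DOMAINS], size=4, replace=False))
    return BwsResponse(rid, profile, picks, task, 10.0)


def _oracle_row(domain_name, level, sign):
    """Independent re-coding straight from the rule text: the domain
    indicator X_p (absent for control, p=5) and the level indicator X_pq
    (absent for level 4) are set to +1 for best-side picks and -1 for
    worst-side picks; everything else is 0."""
    row = dict.fromkeys(DESIGN_COLUMNS, 0.0)
    p = _P[domain_name]
    if p != 5:
        row[f"X{p}"] = float(sign)
    if level in (1, 2, 3):
        row[f"X{p}{level}"] = float(sign)
    return np.array([row[c] for c in DESIGN_COLUMNS])


class TestExplode:
    def test_shrinking_alternative_sets(self):
        rng = np.random.default_rng(0)
        occasions = explode(_random_response(rng))
        assert [len(o.alternatives) for o in occasions] == [8, 7, 6, 5]
        assert sum(len(o.alternatives) for o in occasions) == 26
        assert [o.sign for o in occasions] == [1, -1, 1, -1]

    def test_sequential_removal_in_pick_order(self):
        profile = parse_state("12341234")
        picks = ("occupation", "food", "control", "dignity")
        occasions = explode(BwsResponse(1, profile, picks, 1, 9.0))
        worst_names = [d for d, _ in occasions[1].alternatives]
        assert "occupation" not in worst_names
        second_best_names = [d for d, _ in occasions[2].alternatives]
        assert set(second_best_names).isdisjoint({"occupation", "food"})
        assert [o.chosen for o in occasions] == list(picks)

    def test_regrouping_recovers_pick_sequence(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            resp = _random_response(rng)
            assert tuple(o.chosen for o in explode(resp)) == resp.picks

    def test_duplicate_picks_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            BwsResponse(
                1, parse_state("11111111"),
                ("food", "food", "control", "dignity"), 1, 9.0,
            )

    def test_eight_tasks_give_32_occasions(self, small_study):
        by_resp = {}
        for r in small_study["bws"]:
            by_resp.setdefault(r.respondent_id, []).append(r)
        tasks = by_resp[1]
        assert len(tasks) == 8
        assert sum(len(explode(r)) for r in tasks) == 32


class TestCodeRow:
    def test_thirty_one_columns(self):
        assert len(DESIGN_COLUMNS) == 31
        assert len(code_row("food", 2, 1)) == 31

    @pytest.mark.parametrize(
        "domain, level, sign, nonzero",
        [
            ("occupation", 1, +1, {"X8": 1.0, "X81": 1.0}),
            ("control", 4, -1, {}),
            ("safety", 2, -1, {"X2": -1.0, "X22": -1.0}),
            ("control", 2, +1, {"X52": 1.0}),
            ("cleanliness", 4, +1, {"X4": 1.0}),
        ],
    )
    def test_coding_rule(self, domain, level, sign, nonzero):
        row = code_row(domain, level, sign)
        got = {
            c: v for c, v in zip(DESIGN_COLUMNS, row) if v != 0
        }
        assert got == nonzero

    def test_agrees_with_independent_oracle_on_random_responses(self):
        rng = np.random.default_rng(7)
        responses = [_random_response(rng, rid=i, task=1) for i in range(100)]
        long = responses_to_long(responses)
        X = long[list(DESIGN_COLUMNS)].to_numpy()
        expected = np.array(
            [
                _oracle_row(r.alt_domain, r.alt_level, r.sign)
                for r in long.itertuples()
            ]
        )
        assert np.array_equal(X, expected)

    def test_row_has_at_most_two_nonzeros_equal_to_sign(self, small_choice_long):
        X = small_choice_long[list(DESIGN_COLUMNS)].to_numpy()
        nnz = (X != 0).sum(axis=1)
        assert nnz.max() <= 2
        signs = small_choice_long["sign"].to_numpy()
        assert np.all((X == 0) | (X == signs[:, None]))


class TestFilters:
    def _tables(self):
        bws = pd.DataFrame(
            {"respondent_id": [1, 2, 3], "total_bws_minutes": [4.4, 4.5, 12.0]}
        )
        tto = pd.DataFrame(
            {"respondent_id": [1, 2, 3], "total_tto_minutes": [5.0, 4.9, 30.0]}
        )
        return bws, tto

    def test_strict_thresholds_and_phase_independence(self):
        bws, tto = self._tables()
        bws_f, tto_f, report = filter_respondents(bws, tto)
        # 4.4 < 4.5 excluded from BWS; 4.5 retained (strict <)
        assert report["excluded_bws_ids"] == [1]
        # 5.0 retained (strict <); 4.9 excluded from TTO only
        assert report["excluded_tto_ids"] == [2]
        assert set(bws_f["respondent_id"]) == {2, 3}
        assert set(tto_f["respondent_id"]) == {1, 3}

    def test_zero_thresholds_exclude_nobody(self):
        bws, tto = self._tables()
        _, _, report = filter_respondents(bws, tto, 0.0, 0.0)
        assert report["n_excluded_bws"] == 0
        assert report["n_excluded_tto"] == 0

    def test_negative_times_rejected(self):
        bws, tto = self._tables()
        bws.loc[0, "total_bws_minutes"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            filter_respondents(bws, tto)
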