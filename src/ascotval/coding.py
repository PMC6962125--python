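"""Explosion and sign coding of sequential best-worst responses.

Each best-worst task shows one 8-domain profile and asks for four sequential
picks: best (from 8 domains), worst (from the remaining 7), second-best
(from 6), second-worst (from 5).  Under the exploded rank-ordered logit each
pick is one conditional-logit choice occasion over the domains still on the
table, so a single task yields four occasions with 8+7+6+5 = 26 alternative
rows.

The linear index has 31 parameters: 7 domain constants X_p (control, p = 5,
is the reference) and 24 level effects X_pq for levels q in {1,2,3} (level 4
is the reference).  An alternative "domain p at level q" is coded with its
domain indicator and level indicator set to +1 on best/second-best
occasions and to -1 on worst/second-worst occasions, so that a worst pick
is the maximum of negated utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import DOMAIN_BY_NAME, DOMAINS, AscotState

__all__ = [
    "OCCASIONS",
    "DESIGN_COLUMNS",
    "BwsResponse",
    "TtoResponse",
    "ChoiceOccasion",
    "explode",
    "code_row",
    "responses_to_long",
    "filter_respondents",
    "BWS_MIN_MINUTES",
    "TTO_MIN_MINUTES",
]

# occasion name, sign, number of alternatives on the table
OCCASIONS: tuple[tuple[str, int, int], ...] = (
    ("best", +1, 8),
    ("worst", -1, 7),
    ("second_best", +1, 6),
    ("second_worst", -1, 5),
)

BWS_MIN_MINUTES = 4.5
TTO_MIN_MINUTES = 5.0

_DOMAIN_PS = tuple(p for p in range(1, 9) if p != 5)  # control is reference
DESIGN_COLUMNS: tuple[str, ...] = tuple(
    [f"X{p}" for p in _DOMAIN_PS]
    + [f"X{p}{q}" for p in range(1, 9) for q in (1, 2, 3)]
)
assert len(DESIGN_COLUMNS) == 31

_P_TO_NAME = {d.p_index: d.name for d in DOMAINS}
_NAME_TO_P = {d.name: d.p_index for d in DOMAINS}


@dataclass(frozen=True)
class BwsResponse:
    """One respondent's four sequential picks on one profile."""

    respondent_id: int
    profile: AscotState
    picks: tuple[str, str, str, str]  # best, worst, second_best, second_worst
    task_index: int
    total_bws_minutes: float

    def __post_init__(self) -> None:
        if len(set(self.picks)) != 4:
            raise ValueError(f"picks must be 4 distinct domains, got {self.picks}")
        unknown = [d for d in self.picks if d not in DOMAIN_BY_NAME]
        if unknown:
            raise ValueError(f"unknown domains in picks: {unknown}")


@dataclass(frozen=True)
class TtoResponse:
    """One respondent's cTTO indifference answer on one state.

    ``wtd_flag`` marks a worse-than-dead valuation (lead-time arm);
    ``answer_years`` is the marked point on the 0..10 bar.
    """

    respondent_id: int
    state: AscotState
    wtd_flag: bool
    answer_years: float
    total_tto_minutes: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.answer_years <= 10.0:
            raise ValueError(
                f"answer_years must be in [0, 10], got {self.answer_years}"
            )


@dataclass(frozen=True)
class ChoiceOccasion:
    """One conditional-logit choice occasion from an exploded task."""

    respondent_id: int
    task_index: int
    occasion: str  # "best" | "worst" | "second_best" | "second_worst"
    sign: int  # +1 best-side, -1 worst-side
    alternatives: tuple[tuple[str, int], ...]  # (domain name, level in profile)
    chosen: str  # domain name

    def __post_init__(self) -> None:
        names = [d for d, _ in self.alternatives]
        if len(set(names)) != len(names):
            raise ValueError("duplicate alternatives in occasion")
        if self.chosen not in names:
            raise ValueError(f"chosen domain {self.chosen!r} not among alternatives")


def explode(response: BwsResponse) -> list[ChoiceOccasion]:
    """Four choice occasions with shrinking alternative sets (8, 7, 6, 5)."""
    remaining = [d.name for d in DOMAINS]
    occasions = []
    for (occ_name, sign, size), pick in zip(OCCASIONS, response.picks):
        if len(remaining) != size:
            raise AssertionError("sequential removal out of sync")
        occasions.append(
            ChoiceOccasion(
                respondent_id=response.respondent_id,
                task_index=response.task_index,
                occasion=occ_name,
                sign=sign,
                alternatives=tuple(
                    (name, response.profile.level(name)) for name in remaining
                ),
                chosen=pick,
            )
        )
        remaining.remove(pick)
    return occasions


def code_row(domain_name: str, level: int, sign: int) -> np.ndarray:
    """Sign-coded 31-entry design row for one alternative.

    The domain indicator (omitted for control) and the level indicator
    (omitted for level 4) are both set to ``sign``; everything else is 0.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"level must be in 1..4, got {level}")
    if sign not in (-1, 1):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    p = _NAME_TO_P[domain_name]
    row = np.zeros(len(DESIGN_COLUMNS))
    if p != 5:
        row[DESIGN_COLUMNS.index(f"X{p}")] = sign
    if level != 4:
        row[DESIGN_COLUMNS.index(f"X{p}{level}")] = sign
    return row


def responses_to_long(responses: Iterable[BwsResponse]) -> pd.DataFrame:
    """Long-format choice table: one row per (occasion x alternative).

    Columns: respondent_id, task, occasion, sign, alt_domain, alt_level,
    chosen (0/1), then the 31 sign-coded design columns.  This is the input
    to the choice estimators and the layout of the choice-data CSV.
    """
    recs: list[dict] = []
    for resp in responses:
        for occ in explode(resp):
            for name, level in occ.alternatives:
                recs.append(
                    {
                        "respondent_id": occ.respondent_id,
                        "task": occ.task_index,
                        "occasion": occ.occasion,
                        "sign": occ.sign,
                        "alt_domain": name,
                        "alt_level": level,
                        "chosen": int(name == occ.chosen),
                    }
                )
    df = pd.DataFrame.from_records(recs)
    if df.empty:
        raise ValueError("no responses to code")
    # vectorised sign coding of the 31 columns
    p = df["alt_domain"].map(_NAME_TO_P).to_numpy()
    q = df["alt_level"].to_numpy()
    sign = df["sign"].to_numpy()
    X = np.zeros((len(df), len(DESIGN_COLUMNS)))
    col_index = {c: j for j, c in enumerate(DESIGN_COLUMNS)}
    dom_mask = p != 5
    dom_cols = np.array([col_index.get(f"X{pp}", -1) for pp in range(9)])
    X[np.arange(len(df))[dom_mask], dom_cols[p[dom_mask]]] = sign[dom_mask]
    lev_mask = q != 4
    lev_cols = np.full((9, 5), -1, dtype=int)
    for pp in range(1, 9):
        for qq in (1, 2, 3):
            lev_cols[pp, qq] = col_index[f"X{pp}{qq}"]
    X[np.arange(len(df))[lev_mask], lev_cols[p[lev_mask], q[lev_mask]]] = sign[
        lev_mask
    ]
    return pd.concat([df, pd.DataFrame(X, columns=list(DESIGN_COLUMNS))], axis=1)


def filter_respondents(
    bws_table: pd.DataFrame,
    tto_table: pd.DataFrame,
    bws_min_minutes: float = BWS_MIN_MINUTES,
    tto_min_minutes: float = TTO_MIN_MINUTES,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the phase-specific response-time exclusions.

    Respondents whose total BWS time is strictly below ``bws_min_minutes``
    leave the BWS analysis set; strictly below ``tto_min_minutes`` leaves
    the TTO analysis set.  The filters are independent: a respondent can be
    excluded from one phase and retained in the other.  Returns the two
    filtered tables and an exclusion report.
    """
    for table, col in (
        (bws_table, "total_bws_minutes"),
        (tto_table, "total_tto_minutes"),
    ):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
        if (table[col] < 0).any():
            raise ValueError(f"negative times in {col!r}")

    bws_bad = bws_table.loc[
        bws_table["total_bws_minutes"] < bws_min_minutes, "respondent_id"
    ].unique()
    tto_bad = tto_table.loc[
        tto_table["total_tto_minutes"] < tto_min_minutes, "respondent_id"
    ].unique()
    report = {
        "bws_threshold_minutes": bws_min_minutes,
        "tto_threshold_minutes": tto_min_minutes,
        "n_respondents_bws": int(bws_table["respondent_id"].nunique()),
        "n_respondents_tto": int(tto_table["respondent_id"].nunique()),
        "n_excluded_bws": int(len(bws_bad)),
        "n_excluded_tto": int(len(tto_bad)),
        "excluded_bws_ids": sorted(int(i) for i in bws_bad),
        "excluded_tto_ids": sorted(int(i) for i in tto_bad),
    }
    return (
        bws_table[~bws_table["respondent_id"].isin(bws_bad)].reset_index(drop=True),
        tto_table[~tto_table["respondent_id"].isin(tto_bad)].reset_index(drop=True),
        report,
    )
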