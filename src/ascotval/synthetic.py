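"""Synthetic BWS and cTTO survey data with the study's statistical structure.

The generator emulates the valuation-study design: 1050 respondents; a
best-worst phase with 4 blocks x 8 profiles drawn from a 32-profile
level-balanced design; a cTTO phase with 8 blocks x 8 states drawn from 64
states.  Sequential picks come from latent item utilities
``beta_p + beta_pq`` plus fresh Gumbel noise per choice occasion (the
data-generating assumption that matches the exploded-logit likelihood),
with optional normal or log-normal respondent heterogeneity on the domain
constants.  cTTO indifference answers come from a true linear map of the
latent tariff score plus Gaussian noise, floored at -1 (the lead-time
floor), and snapped to a 0.5-year answer grid.

Response-time fields are log-normal with defaults matched to the observed
response-time distributions (BWS: median 9.6 min, IQR 7.3-12.7; cTTO:
median 10.1, IQR 7.6-13.3), which places roughly 3% of BWS times under the
4.5-min exclusion threshold and 5% of cTTO times under 5.0 min.

Output tables (``bws_responses.csv``, ``tto_responses.csv``) columns:

* BWS: respondent_id, task_index, profile (8-digit string), best, worst,
  second_best, second_worst (domain names), total_bws_minutes
* TTO: respondent_id, state (8-digit string), wtd_flag (0/1),
  answer_years, total_tto_minutes

plus a ``truth.json`` sidecar with every true parameter and the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import BwsResponse, TtoResponse
from .coefficients import CoefficientTable, published_mnl_coefficients
from .rescaling import weights_from_coefficients
from .states import DOMAINS, DOMAINS_IN_POSITION_ORDER, AscotState, parse_state
from .tariffs import JP_CONVERSION, ConversionParams, WeightTable, latent_bws_score

__all__ = [
    "SyntheticTruth",
    "DesignError",
    "make_bws_design",
    "simulate_bws",
    "simulate_tto",
    "simulate_study",
    "sequential_picks",
    "gumbel_choice",
    "bws_frame",
    "tto_frame",
    "bws_from_frame",
    "tto_from_frame",
    "write_study",
]

_DOMAIN_NAMES = tuple(d.name for d in DOMAINS)
_NONREF = tuple(n for n in _DOMAIN_NAMES if n != "control")

# log-normal response-time parameters matched to the observed medians/IQRs
BWS_TIME_MU, BWS_TIME_SIGMA = math.log(9.6), 0.411
TTO_TIME_MU, TTO_TIME_SIGMA = math.log(10.1), 0.414


class DesignError(ValueError):
    """Infeasible design request (balance or divisibility constraints)."""


@dataclass
class SyntheticTruth:
    """True parameters of a simulated valuation study.

    ``true_domain_constants`` maps the 7 non-reference domain names to
    beta_p (control is 0); ``true_level_effects`` maps (domain, q<=3) to
    beta_pq (level 4 is 0).  With ``mixing_distribution="normal"`` the
    domain constant of a respondent is beta_p + mixing_sd_p * eta; with
    ``"lognormal"`` it is exp(beta_p + mixing_sd_p * eta).  The cTTO arm
    generates answers from ``true_conversion`` applied to the latent score
    under the tariff implied by these coefficients (the same rescaling the
    analysis pipeline applies), plus N(0, tto_noise_sd) noise.
    """

    true_domain_constants: dict[str, float]
    true_level_effects: dict[tuple[str, int], float]
    mixing_sd: dict[str, float] = field(default_factory=dict)
    mixing_distribution: str = "none"  # none | normal | lognormal
    true_conversion: ConversionParams = JP_CONVERSION
    tto_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.true_domain_constants) != set(_NONREF):
            raise ValueError("true_domain_constants must cover the 7 non-reference domains")
        if set(self.true_level_effects) != {(n, q) for n in _DOMAIN_NAMES for q in (1, 2, 3)}:
            raise ValueError("true_level_effects must cover all 24 (domain, q<=3) cells")
        if self.mixing_distribution not in ("none", "normal", "lognormal"):
            raise ValueError(f"unknown mixing distribution {self.mixing_distribution!r}")
        if self.mixing_distribution == "none" and any(
            v != 0 for v in self.mixing_sd.values()
        ):
            raise ValueError("mixing_sd must be all zero when distribution is 'none'")
        if any(v < 0 for v in self.mixing_sd.values()):
            raise ValueError("mixing_sd entries must be nonnegative")
        if self.tto_noise_sd < 0:
            raise ValueError("tto_noise_sd must be nonnegative")

    @classmethod
    def from_coefficients(
        cls, coefs: CoefficientTable, **kwargs
    ) -> "SyntheticTruth":
        return cls(
            true_domain_constants={n: coefs.beta(n) for n in _NONREF},
            true_level_effects={
                (n, q): coefs.beta(n, q) for n in _DOMAIN_NAMES for q in (1, 2, 3)
            },
            **kwargs,
        )

    @classmethod
    def default(cls, seed: int = 0, **kwargs) -> "SyntheticTruth":
        """Study conditions: the published Japanese MNL coefficients as truth."""
        return cls.from_coefficients(
            published_mnl_coefficients(), seed=seed, **kwargs
        )

    def coefficient_table(self) -> CoefficientTable:
        return CoefficientTable(
            domain_constants={
                n: (self.true_domain_constants[n], float("nan")) for n in _NONREF
            },
            level_effects={
                k: (v, float("nan")) for k, v in self.true_level_effects.items()
            },
            model_id="truth",
        )

    def implied_tariff(self) -> WeightTable:
        """Tariff from the true coefficients by the pipeline's own rescaling."""
        return weights_from_coefficients(self.coefficient_table(), label="truth")

    def mean_item_utilities(self) -> np.ndarray:
        """(8, 4) mean item utilities, rows in p-index order 1..8."""
        out = np.zeros((8, 4))
        for d in DOMAINS:
            bp = self.true_domain_constants.get(d.name, 0.0)
            for q in (1, 2, 3, 4):
                bpq = self.true_level_effects.get((d.name, q), 0.0)
                out[d.p_index - 1, q - 1] = bp + bpq
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_domain_constants": self.true_domain_constants,
                "true_level_effects": {
                    f"{n}:{q}": v for (n, q), v in self.true_level_effects.items()
                },
                "mixing_sd": self.mixing_sd,
                "mixing_distribution": self.mixing_distribution,
                "true_conversion": {
                    "slope": self.true_conversion.slope,
                    "intercept": self.true_conversion.intercept,
                    "label": self.true_conversion.label,
                },
                "tto_noise_sd": self.tto_noise_sd,
                "seed": self.seed,
            },
            indent=2,
        )


def make_bws_design(
    n_profiles: int, n_blocks: int, seed: int = 0
) -> list[list[AscotState]]:
    """Level-balanced random profile design split into blocks.

    Each domain's levels appear ``n_profiles/4`` times across the design
    (so every level of every domain appears at least once), profiles are
    distinct, and generation is seed-deterministic.  The published studies
    drew their profiles from an unpublished fractional-factorial design;
    this balanced random design is the stand-in with the same marginal
    level balance.
    """
    if n_profiles % n_blocks != 0:
        raise DesignError(
            f"n_profiles={n_profiles} not divisible by n_blocks={n_blocks}"
        )
    if n_profiles % 4 != 0 or n_profiles < 4:
        raise DesignError("n_profiles must be a positive multiple of 4")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(1, 5), n_profiles // 4)
    for _ in range(1000):
        cols = [rng.permutation(base) for _ in range(8)]
        levels = np.stack(cols, axis=1)
        if len({tuple(row) for row in levels}) == n_profiles:
            break
    else:  # pragma: no cover - vanishingly unlikely for feasible requests
        raise DesignError("could not draw distinct level-balanced profiles")
    states = [AscotState(tuple(int(q) for q in row)) for row in levels]
    per_block = n_profiles // n_blocks
    return [states[b * per_block : (b + 1) * per_block] for b in range(n_blocks)]


def gumbel_choice(utilities: np.ndarray, sign: int, rng: np.random.Generator) -> int:
    """Index of the pick: argmax of sign * V + fresh Gumbel noise."""
    return int(np.argmax(sign * np.asarray(utilities) + rng.gumbel(size=len(utilities))))


def sequential_picks(
    utilities: np.ndarray, rng: np.random.Generator
) -> tuple[int, int, int, int]:
    """Best / worst / second-best / second-worst indices from 8 utilities.

    Fresh Gumbel draws per occasion, matching the exploded likelihood's
    independence assumption.
    """
    remaining = list(range(len(utilities)))
    picks = []
    for sign in (+1, -1, +1, -1):
        u = np.asarray(utilities)[remaining]
        picks.append(remaining.pop(gumbel_choice(u, sign, rng)))
    return tuple(picks)


def _respondent_item_utilities(
    truth: SyntheticTruth, rng: np.random.Generator
) -> np.ndarray:
    """(8, 4) item utilities for one respondent (p-index rows)."""
    mean = truth.mean_item_utilities()
    if truth.mixing_distribution == "none":
        return mean
    util = mean.copy()
    for d in DOMAINS:
        if d.name == "control":
            continue
        s = truth.mixing_sd.get(d.name, 0.0)
        eta = rng.standard_normal()
        bp = truth.true_domain_constants[d.name]
        if truth.mixing_distribution == "normal":
            bp_r = bp + s * eta
        else:  # lognormal: bp is the log-scale location
            bp_r = math.exp(bp + s * eta)
        for q in (1, 2, 3, 4):
            util[d.p_index - 1, q - 1] = bp_r + truth.true_level_effects.get(
                (d.name, q), 0.0
            )
    return util


def simulate_bws(
    truth: SyntheticTruth,
    design: list[list[AscotState]],
    n_respondents: int,
    seed: int | None = None,
) -> list[BwsResponse]:
    """Simulate sequential best-worst responses for ``n_respondents``.

    Respondent r gets design block ``r % n_blocks``; each respondent
    answers every profile of their block (8 tasks in the study design).
    """
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_blocks = len(design)
    responses = []
    p_of = {d.name: d.p_index for d in DOMAINS}
    names = _DOMAIN_NAMES
    for r in range(n_respondents):
        util_items = _respondent_item_utilities(truth, rng)
        block = design[r % n_blocks]
        minutes = float(rng.lognormal(BWS_TIME_MU, BWS_TIME_SIGMA))
        for t, profile in enumerate(block, start=1):
            v = np.array(
                [util_items[p_of[n] - 1, profile.level(n) - 1] for n in names]
            )
            picks = sequential_picks(v, rng)
            responses.append(
                BwsResponse(
                    respondent_id=r + 1,
                    profile=profile,
                    picks=tuple(names[i] for i in picks),
                    task_index=t,
                    total_bws_minutes=minutes,
                )
            )
    return responses


def simulate_tto(
    truth: SyntheticTruth,
    states: list[list[AscotState]] | list[AscotState],
    n_respondents: int,
    seed: int | None = None,
    answer_grid: float = 0.5,
) -> list[TtoResponse]:
    """Simulate cTTO indifference answers.

    The true value of a state is the truth conversion applied to its latent
    score under the truth-implied tariff; the observed value adds
    N(0, tto_noise_sd) noise and is clamped to [-1, 1] (the lead-time
    design floors valuations at -1).  Values >= 0 produce a conventional
    (better-than-dead) answer x = 10v; values < 0 a lead-time
    (worse-than-dead) answer y = 10(v + 1).  Answers snap to
    ``answer_grid`` years.
    """
    if not states:
        raise ValueError("states must be non-empty")
    blocks: list[list[AscotState]]
    if isinstance(states[0], AscotState):
        blocks = [list(states)]  # type: ignore[arg-type]
    else:
        blocks = [list(b) for b in states]  # type: ignore[union-attr]
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    tariff = truth.implied_tariff()
    true_value = {
        str(s): float(truth.true_conversion.apply(latent_bws_score(s, tariff)))
        for block in blocks
        for s in block
    }
    responses = []
    for r in range(n_respondents):
        block = blocks[r % len(blocks)]
        minutes = float(rng.lognormal(TTO_TIME_MU, TTO_TIME_SIGMA))
        for state in block:
            v = true_value[str(state)]
            if truth.tto_noise_sd > 0:
                v += float(rng.normal(0.0, truth.tto_noise_sd))
            v = min(1.0, max(-1.0, v))
            wtd = v < 0
            answer = 10.0 * (v + 1.0) if wtd else 10.0 * v
            if answer_grid > 0:
                answer = round(answer / answer_grid) * answer_grid
            answer = min(10.0, max(0.0, answer))
            responses.append(
                TtoResponse(
                    respondent_id=r + 1,
                    state=state,
                    wtd_flag=bool(wtd),
                    answer_years=float(answer),
                    total_tto_minutes=minutes,
                )
            )
    return responses


def simulate_study(
    truth: SyntheticTruth,
    n_respondents: int = 1050,
    n_bws_profiles: int = 32,
    n_bws_blocks: int = 4,
    n_tto_states: int = 64,
    n_tto_blocks: int = 8,
    answer_grid: float = 0.5,
):
    """Full study: designs plus BWS and cTTO response sets.

    Seeds for the design, BWS and TTO stages are spawned from
    ``truth.seed`` so each stage is independently reproducible.
    """
    ss = np.random.SeedSequence(truth.seed)
    s_design, s_design2, s_bws, s_tto = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    bws_design = make_bws_design(n_bws_profiles, n_bws_blocks, seed=s_design)
    tto_design = make_bws_design(n_tto_states, n_tto_blocks, seed=s_design2)
    bws = simulate_bws(truth, bws_design, n_respondents, seed=s_bws)
    tto = simulate_tto(truth, tto_design, n_respondents, seed=s_tto,
                       answer_grid=answer_grid)
    return bws_design, tto_design, bws, tto


# ----------------------------------------------------------------------
# tabular round trips


def bws_frame(responses: list[BwsResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in responses],
            "task_index": [r.task_index for r in responses],
            "profile": [str(r.profile) for r in responses],
            "best": [r.picks[0] for r in responses],
            "worst": [r.picks[1] for r in responses],
            "second_best": [r.picks[2] for r in responses],
            "second_worst": [r.picks[3] for r in responses],
            "total_bws_minutes": [r.total_bws_minutes for r in responses],
        }
    )


def bws_from_frame(df: pd.DataFrame) -> list[BwsResponse]:
    return [
        BwsResponse(
            respondent_id=int(r.respondent_id),
            profile=parse_state(str(r.profile)),
            picks=(str(r.best), str(r.worst), str(r.second_best), str(r.second_worst)),
            task_index=int(r.task_index),
            total_bws_minutes=float(r.total_bws_minutes),
        )
        for r in df.itertuples()
    ]


def tto_frame(responses: list[TtoResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in responses],
            "state": [str(r.state) for r in responses],
            "wtd_flag": [int(r.wtd_flag) for r in responses],
            "answer_years": [r.answer_years for r in responses],
            "total_tto_minutes": [r.total_tto_minutes for r in responses],
        }
    )


def tto_from_frame(df: pd.DataFrame) -> list[TtoResponse]:
    return [
        TtoResponse(
            respondent_id=int(r.respondent_id),
            state=parse_state(str(r.state)),
            wtd_flag=bool(r.wtd_flag),
            answer_years=float(r.answer_years),
            total_tto_minutes=float(r.total_tto_minutes),
        )
        for r in df.itertuples()
    ]


def write_study(
    outdir: str | Path,
    truth: SyntheticTruth,
    bws: list[BwsResponse],
    tto: list[TtoResponse],
) -> dict[str, Path]:
    """Write bws_responses.csv, tto_responses.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bws": outdir / "bws_responses.csv",
        "tto": outdir / "tto_responses.csv",
        "truth": outdir / "truth.json",
    }
    bws_frame(bws).to_csv(paths["bws"], index=False)
    tto_frame(tto).to_csv(paths["tto"], index=False)
    paths["truth"].write_text(truth.to_json())
    return paths
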