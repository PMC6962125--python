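"""Converting cTTO responses to state-level utility observations.

A conventional (better-than-dead) answer of x years maps to a utility of
x/10 in [0, 1]; a lead-time (worse-than-dead) answer of y years maps to
y/10 - 1 in [-1, 0].  The two branches meet at dead (0), and the lead-time
design floors the scale at -1.  State values are the unweighted means of
retained responses per state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import TtoResponse
from .states import AscotState, parse_state

__all__ = ["StateValueObservation", "tto_score", "state_means"]


@dataclass(frozen=True)
class StateValueObservation:
    """Mean observed utility of one state over retained respondents."""

    state: AscotState
    mean_tto: float
    n_respondents: int
    sd: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.mean_tto <= 1.0:
            raise ValueError(f"mean_tto out of [-1, 1]: {self.mean_tto}")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")


def tto_score(response: TtoResponse) -> float:
    """Utility of one cTTO answer: x/10 if better than dead, y/10 - 1 if worse."""
    if not 0.0 <= response.answer_years <= 10.0:
        raise ValueError(f"answer_years out of [0, 10]: {response.answer_years}")
    if response.wtd_flag:
        return response.answer_years / 10.0 - 1.0
    return response.answer_years / 10.0


def state_means(
    responses: list[TtoResponse] | pd.DataFrame,
    expected_states: list[AscotState] | None = None,
) -> tuple[list[StateValueObservation], dict]:
    """Per-state mean/SD/n of cTTO utilities, plus a distribution summary.

    ``responses`` may be response objects or the tto_responses.csv layout.
    States in ``expected_states`` with no retained responses are reported
    in the summary under ``states_without_responses`` rather than silently
    dropped.  The summary also carries min, max, median of the state means
    and the count of states valued worse than dead (mean < 0).
    """
    if isinstance(responses, pd.DataFrame):
        df = responses.copy()
        df["state"] = df["state"].astype(str)
        df["score"] = np.where(
            df["wtd_flag"].astype(bool),
            df["answer_years"] / 10.0 - 1.0,
            df["answer_years"] / 10.0,
        )
        if ((df["answer_years"] < 0) | (df["answer_years"] > 10)).any():
            raise ValueError("answer_years out of [0, 10] in response table")
    else:
        df = pd.DataFrame(
            {
                "state": [str(r.state) for r in responses],
                "score": [tto_score(r) for r in responses],
            }
        )
    grouped = df.groupby("state")["score"].agg(["mean", "std", "count"])
    observations = [
        StateValueObservation(
            state=parse_state(state),
            mean_tto=float(row["mean"]),
            n_respondents=int(row["count"]),
            sd=float(row["std"]) if row["count"] > 1 else 0.0,
        )
        for state, row in grouped.iterrows()
    ]
    means = grouped["mean"].to_numpy()
    missing: list[str] = []
    if expected_states is not None:
        missing = sorted(
            {str(s) for s in expected_states} - set(grouped.index.astype(str))
        )
    summary = {
        "n_states": int(len(observations)),
        "min_mean": float(means.min()),
        "max_mean": float(means.max()),
        "median_mean": float(np.median(means)),
        "n_states_worse_than_dead": int((means < 0).sum()),
        "states_without_responses": missing,
    }
    return observations, summary


def observations_frame(observations: list[StateValueObservation]) -> pd.DataFrame:
    """state_values.csv layout: state, mean, sd, n."""
    return pd.DataFrame(
        {
            "state": [str(o.state) for o in observations],
            "mean": [o.mean_tto for o in observations],
            "sd": [o.sd for o in observations],
            "n": [o.n_respondents for o in observations],
        }
    )
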