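"""Tariffs (value sets) and SC-QALY scoring.

A tariff is a table of 32 preference weights, one per (domain, level),
rescaled so that "Control over daily life" level 1 = 1 and level 4 = 0.
The *latent BWS score* of a state is the sum of the eight applicable
weights; a linear conversion, estimated against composite time trade-off
(cTTO) valuations, maps that latent score onto the SC-QALY scale where the
best state scores 1 and dead scores 0.

The published Japanese and UK SCT4 tariffs and their conversion parameters
(JP: SC-QALY = 0.221 x latent - 0.496; UK: 0.203 x latent - 0.466) ship as
packaged data, stored to the 3 decimals at which they were published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .states import (
    DOMAIN_BY_NAME,
    DOMAINS_IN_POSITION_ORDER,
    AscotState,
    state_level_matrix,
)

__all__ = [
    "WeightTable",
    "ConversionParams",
    "TariffIntegrityError",
    "load_tariff",
    "jp_tariff",
    "uk_tariff",
    "JP_CONVERSION",
    "UK_CONVERSION",
    "latent_bws_score",
    "scqaly_score",
    "latent_scores_all_states",
]


class TariffIntegrityError(KeyError):
    """A tariff is missing a (domain, level) entry or is malformed."""


@dataclass(frozen=True)
class WeightTable:
    """32 preference weights: one per (domain name, level)."""

    weights: dict[tuple[str, int], float]
    label: str = ""

    def weight(self, domain: str, level: int) -> float:
        try:
            return self.weights[(domain, level)]
        except KeyError:
            raise TariffIntegrityError(
                f"tariff {self.label!r} has no weight for ({domain}, level {level})"
            ) from None

    def validate(self) -> None:
        expected = {
            (d.name, q) for d in DOMAINS_IN_POSITION_ORDER for q in (1, 2, 3, 4)
        }
        if set(self.weights) != expected:
            raise TariffIntegrityError(
                f"tariff {self.label!r} must have exactly the 32 (domain, level) "
                f"entries; missing {sorted(expected - set(self.weights))}, "
                f"extra {sorted(set(self.weights) - expected)}"
            )

    def weight_matrix(self) -> np.ndarray:
        """(8, 4) array of weights, rows in state-string position order."""
        self.validate()
        return np.array(
            [
                [self.weight(d.name, q) for q in (1, 2, 3, 4)]
                for d in DOMAINS_IN_POSITION_ORDER
            ]
        )

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        rows = [
            {"domain_name": d.name, "level": q, "weight": self.weight(d.name, q)}
            for d in DOMAINS_IN_POSITION_ORDER
            for q in (1, 2, 3, 4)
        ]
        df = pd.DataFrame(rows)
        if decimals is not None:
            df["weight"] = df["weight"].round(decimals)
        return df

    def to_csv(self, path: str | Path | IO[str], decimals: int | None = 3) -> None:
        self.to_frame(decimals=decimals).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "WeightTable":
        weights = {
            (str(r.domain_name), int(r.level)): float(r.weight)
            for r in df.itertuples()
        }
        table = cls(weights, label=label)
        table.validate()
        return table


def load_tariff(path: str | Path | IO[str], label: str = "") -> WeightTable:
    """Read a tariff from a delimited text file (domain_name, level, weight)."""
    return WeightTable.from_frame(pd.read_csv(path), label=label or str(path))


@dataclass(frozen=True)
class ConversionParams:
    """Linear map from latent BWS score to the SC-QALY scale."""

    slope: float
    intercept: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("conversion parameters must be finite")

    def apply(self, latent: float | np.ndarray) -> float | np.ndarray:
        return self.slope * latent + self.intercept


def _packaged(name: str, label: str) -> WeightTable:
    with resources.files("ascotval.data").joinpath(name).open("r") as fh:
        return load_tariff(fh, label=label)


def jp_tariff() -> WeightTable:
    """Published Japanese SCT4 tariff (3-decimal printed weights)."""
    return _packaged("tariff_jp.csv", "JP")


def uk_tariff() -> WeightTable:
    """Published UK SCT4 tariff (3-decimal printed weights)."""
    return _packaged("tariff_uk.csv", "UK")


JP_CONVERSION = ConversionParams(0.221, -0.496, "JP")
UK_CONVERSION = ConversionParams(0.203, -0.466, "UK")


def latent_bws_score(state: AscotState, tariff: WeightTable) -> float:
    """Sum over the 8 domains of the tariff weight at the state's level."""
    return float(
        sum(tariff.weight(name, level) for name, level in state.levels.items())
    )


def scqaly_score(
    state: AscotState, tariff: WeightTable, conv: ConversionParams
) -> float:
    """SC-QALY score: the linear conversion applied to the latent score."""
    return float(conv.apply(latent_bws_score(state, tariff)))


def latent_scores_all_states(tariff: WeightTable) -> np.ndarray:
    """Latent BWS scores of all 65,536 states, in enumeration order."""
    W = tariff.weight_matrix()  # (8 positions, 4 levels)
    levels = state_level_matrix()  # (65536, 8), values 1..4
    return W[np.arange(8), levels - 1].sum(axis=1)


def monotone_in_levels(tariff: WeightTable) -> bool:
    """True if weights are non-increasing in level within every domain."""
    W = tariff.weight_matrix()
    return bool(np.all(np.diff(W, axis=1) <= 0))
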