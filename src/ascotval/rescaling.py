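"""Item coefficients and rescaling to the published weight scale.

A fitted 31-parameter table yields 32 *item coefficients* — one per
(domain, level) — as the sum of the domain constant and the level effect,
value(p, q) = beta_p + beta_pq, with both reference terms fixed at 0 so the
control-level-4 item is exactly 0.  A linear transformation then pins
control level 1 to 1 and control level 4 to 0:

    weight(p, q) = (value(p, q) - value(control, 4))
                   / (value(control, 1) - value(control, 4))

Because value(control, 4) = 0 by construction this reduces to division by
the control level-1 item coefficient.  The result is a tariff
(:class:`~ascotval.tariffs.WeightTable`) on the published scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coefficients import CoefficientTable
from .states import DOMAINS_IN_POSITION_ORDER
from .tariffs import WeightTable

__all__ = ["ItemCoefficient", "item_coefficients", "rescale", "weights_from_coefficients"]


@dataclass(frozen=True)
class ItemCoefficient:
    """Logit-scale value of one (domain, level) item: beta_p + beta_pq."""

    domain: str
    level: int
    value: float


def item_coefficients(coefs: CoefficientTable) -> list[ItemCoefficient]:
    """All 32 item coefficients, in state-string domain order."""
    return [
        ItemCoefficient(d.name, q, coefs.beta(d.name) + coefs.beta(d.name, q))
        for d in DOMAINS_IN_POSITION_ORDER
        for q in (1, 2, 3, 4)
    ]


def rescale(items: list[ItemCoefficient], label: str = "") -> WeightTable:
    """Rescale 32 item coefficients so control L1 = 1 and control L4 = 0."""
    by_key = {(it.domain, it.level): it.value for it in items}
    if len(by_key) != 32:
        raise ValueError(f"expected 32 distinct items, got {len(by_key)}")
    top = by_key[("control", 1)]
    bottom = by_key[("control", 4)]
    denom = top - bottom
    if denom == 0:
        raise ZeroDivisionError(
            "degenerate scale: control level-1 and level-4 items are equal"
        )
    weights = {k: (v - bottom) / denom for k, v in by_key.items()}
    return WeightTable(weights, label=label)


def weights_from_coefficients(
    coefs: CoefficientTable, label: str = ""
) -> WeightTable:
    """Coefficient table -> tariff in one step (compose the two maps)."""
    return rescale(item_coefficients(coefs), label=label)
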