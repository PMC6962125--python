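"""Anchoring latent BWS scores to the SC-QALY scale.

The map f(x) = a*x + b from latent tariff scores to mean cTTO utilities is
a least-squares line constrained so that the best state [11111111] maps
exactly to 1 (the definition of the top of the SC-QALY scale).  With the
anchor point (x*, 1), the constrained problem has one free parameter and a
closed form:

    a = sum_i (TTO_i - 1)(BWS_i - x*) / sum_i (BWS_i - x*)^2,   b = 1 - a*x*

State means enter unweighted, one observation per state.  R-squared is
1 - SSR/SST with SST about the mean of the observed values; because the
fit is constrained this can in principle be negative for pathological
data, and the squared Pearson correlation between fitted and observed
values is reported alongside.  The slope's standard error comes from the
one-free-parameter delta method, SE(a)^2 = sigma^2 / sum(BWS_i - x*)^2
with sigma^2 = SSR/(n-1); b = 1 - a*x* inherits SE(b) = |x*| SE(a).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .states import BEST_STATE, AscotState
from .tariffs import ConversionParams, WeightTable, latent_bws_score, scqaly_score
from .tto import StateValueObservation

__all__ = ["AnchoringFit", "AnchoredLinearRegression", "fit_anchoring", "apply_anchoring"]


@dataclass(frozen=True)
class AnchoringFit:
    """Result of the constrained anchoring regression."""

    conv: ConversionParams
    r_squared: float
    slope_t: float
    intercept_t: float
    n_states: int
    bws_max: float  # latent score of the best state under the fit tariff
    fitted_vs_observed_r2: float = float("nan")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "slope": self.conv.slope,
                "intercept": self.conv.intercept,
                "r_squared": self.r_squared,
                "slope_t": self.slope_t,
                "intercept_t": self.intercept_t,
                "n_states": self.n_states,
                "bws_max": self.bws_max,
                "fitted_vs_observed_r2": self.fitted_vs_observed_r2,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


class AnchoredLinearRegression(BaseEstimator, RegressorMixin):
    """Least-squares line constrained through a fixed anchor point.

    Parameters
    ----------
    anchor_x, anchor_y : float
        The point the line must pass through.  In the valuation pipeline
        this is (latent score of the best state, 1).

    Attributes
    ----------
    slope_, intercept_ : float
        The fitted line; ``intercept_ = anchor_y - slope_ * anchor_x``
        holds to machine precision.
    r_squared_ : float
        1 - SSR/SST with SST about the observed mean.
    slope_se_, slope_t_, intercept_se_, intercept_t_ : float
        Delta-method uncertainty of the single free parameter.
    """

    def __init__(self, anchor_x: float = 0.0, anchor_y: float = 1.0):
        self.anchor_x = anchor_x
        self.anchor_y = anchor_y

    def fit(self, X, y) -> "AnchoredLinearRegression":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if len(x) < 2 or np.ptp(x) == 0:
            raise ValueError(
                "degenerate regression: need >= 2 distinct predictor values"
            )
        dx = x - self.anchor_x
        dy = y - self.anchor_y
        denom = float(dx @ dx)
        a = float(dx @ dy) / denom
        b = self.anchor_y - a * self.anchor_x

        resid = y - (a * x + b)
        ssr = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        sigma2 = ssr / max(len(x) - 1, 1)  # one free parameter
        se_a = float(np.sqrt(sigma2 / denom))

        self.slope_ = a
        self.intercept_ = b
        self.r_squared_ = 1.0 - ssr / sst if sst > 0 else float("nan")
        self.slope_se_ = se_a
        self.slope_t_ = a / se_a if se_a > 0 else float("inf")
        self.intercept_se_ = abs(self.anchor_x) * se_a
        self.intercept_t_ = (
            b / self.intercept_se_ if self.intercept_se_ > 0 else float("inf")
        )
        fitted = a * x + b
        if np.ptp(fitted) > 0 and np.ptp(y) > 0:
            self.fitted_vs_observed_r2_ = float(np.corrcoef(fitted, y)[0, 1] ** 2)
        else:
            self.fitted_vs_observed_r2_ = float("nan")
        self.n_obs_ = len(x)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_


def fit_anchoring(
    observations: list[StateValueObservation],
    tariff: WeightTable,
    label: str = "anchored",
) -> AnchoringFit:
    """Fit the constrained map from latent scores to mean cTTO utilities.

    The anchor is (latent score of [11111111] under ``tariff``, 1).
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 state observations")
    bws_max = latent_bws_score(BEST_STATE, tariff)
    x = np.array([latent_bws_score(o.state, tariff) for o in observations])
    y = np.array([o.mean_tto for o in observations])
    reg = AnchoredLinearRegression(anchor_x=bws_max, anchor_y=1.0).fit(x, y)
    return AnchoringFit(
        conv=ConversionParams(reg.slope_, reg.intercept_, label),
        r_squared=reg.r_squared_,
        slope_t=reg.slope_t_,
        intercept_t=reg.intercept_t_,
        n_states=len(observations),
        bws_max=bws_max,
        fitted_vs_observed_r2=reg.fitted_vs_observed_r2_,
    )


def apply_anchoring(fit: AnchoringFit, state: AscotState, tariff: WeightTable) -> float:
    """SC-QALY score of a state under the fitted conversion."""
    return scqaly_score(state, tariff, fit.conv)
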