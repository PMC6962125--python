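"""The 31-parameter coefficient table of the best-worst utility model.

The linear index has a constant beta_p for each domain except control
(p = 5, reference) and a level effect beta_pq for each domain at levels
q in {1,2,3} (level 4 reference): 7 + 24 = 31 parameters.  A table carries
estimates, standard errors, and the fit metadata needed to reproduce it.

The Japanese conditional-logit (MNL) estimates published for SCT4 ship as
packaged data (``published_mnl_coefficients``); they are the input of the
published-tariff regression test and of pipeline truth scenarios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import DESIGN_COLUMNS
from .states import DOMAINS, DOMAIN_BY_NAME

__all__ = ["CoefficientTable", "published_mnl_coefficients"]

_NAME_TO_P = {d.name: d.p_index for d in DOMAINS}
_P_TO_NAME = {d.p_index: d.name for d in DOMAINS}


@dataclass
class CoefficientTable:
    """Estimates and SEs for the 31 utility parameters, plus metadata.

    ``domain_constants`` maps domain name (control excluded) to
    (estimate, se); ``level_effects`` maps (domain name, level q<=3) to
    (estimate, se).  ``mixing_sd`` is populated by mixed-logit fits with
    the estimated scale of each random domain constant.
    """

    domain_constants: dict[str, tuple[float, float]]
    level_effects: dict[tuple[str, int], tuple[float, float]]
    model_id: str = "mnl"  # mnl | mixed_normal | mixed_lognormal
    cluster_scheme: str = "respondent"  # respondent | respondent_by_sign
    log_likelihood: float = float("nan")
    n_draws: int = 0
    seed: int | None = None
    mixing_sd: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected_doms = {d.name for d in DOMAINS} - {"control"}
        if set(self.domain_constants) != expected_doms:
            raise ValueError(
                "domain_constants must cover the 7 non-reference domains; "
                f"got {sorted(self.domain_constants)}"
            )
        expected_levels = {(d.name, q) for d in DOMAINS for q in (1, 2, 3)}
        if set(self.level_effects) != expected_levels:
            raise ValueError("level_effects must cover all 24 (domain, q<=3) cells")

    def beta(self, domain: str, level: int | None = None) -> float:
        """beta_p (level None) or beta_pq; references return 0."""
        if level is None:
            if domain == "control":
                return 0.0
            return self.domain_constants[domain][0]
        if level == 4:
            return 0.0
        return self.level_effects[(domain, level)][0]

    def coef_vector(self) -> np.ndarray:
        """Estimates ordered as the 31 design columns."""
        return np.array([self._by_column(c)[0] for c in DESIGN_COLUMNS])

    def se_vector(self) -> np.ndarray:
        return np.array([self._by_column(c)[1] for c in DESIGN_COLUMNS])

    def _by_column(self, col: str) -> tuple[float, float]:
        p = int(col[1])
        name = _P_TO_NAME[p]
        if len(col) == 2:
            return self.domain_constants[name]
        return self.level_effects[(name, int(col[2]))]

    @classmethod
    def from_vectors(
        cls, estimates: np.ndarray, ses: np.ndarray, **meta
    ) -> "CoefficientTable":
        if len(estimates) != 31 or len(ses) != 31:
            raise ValueError("expected 31 estimates and 31 SEs")
        by_col = dict(zip(DESIGN_COLUMNS, zip(estimates, ses)))
        domain_constants = {
            _P_TO_NAME[int(c[1])]: (float(e), float(s))
            for c, (e, s) in by_col.items()
            if len(c) == 2
        }
        level_effects = {
            (_P_TO_NAME[int(c[1])], int(c[2])): (float(e), float(s))
            for c, (e, s) in by_col.items()
            if len(c) == 3
        }
        return cls(domain_constants, level_effects, **meta)

    def to_frame(self) -> pd.DataFrame:
        """Long layout: term (domain/level), domain_name, level, estimate, se."""
        rows = []
        for d in DOMAINS:
            if d.name == "control":
                continue
            e, s = self.domain_constants[d.name]
            rows.append(
                {"term": "domain", "domain_name": d.name, "level": None,
                 "estimate": e, "se": s}
            )
        for d in DOMAINS:
            for q in (1, 2, 3):
                e, s = self.level_effects[(d.name, q)]
                rows.append(
                    {"term": "level", "domain_name": d.name, "level": q,
                     "estimate": e, "se": s}
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "CoefficientTable":
        domain_constants = {}
        level_effects = {}
        for r in df.itertuples():
            if r.term == "domain":
                domain_constants[str(r.domain_name)] = (float(r.estimate), float(r.se))
            elif r.term == "level":
                level_effects[(str(r.domain_name), int(r.level))] = (
                    float(r.estimate),
                    float(r.se),
                )
            else:
                raise ValueError(f"unknown term {r.term!r}")
        return cls(domain_constants, level_effects, **meta)

    def save(self, csv_path: str | Path) -> None:
        """Write the table as CSV with a JSON metadata sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "model_id": self.model_id,
            "cluster_scheme": self.cluster_scheme,
            "log_likelihood": self.log_likelihood,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "mixing_sd": {k: list(v) for k, v in self.mixing_sd.items()},
        }
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "CoefficientTable":
        csv_path = Path(csv_path)
        meta_path = csv_path.with_suffix(".json")
        meta: dict = {}
        if meta_path.exists():
            raw = json.loads(meta_path.read_text())
            meta = {
                "model_id": raw.get("model_id", "mnl"),
                "cluster_scheme": raw.get("cluster_scheme", "respondent"),
                "log_likelihood": raw.get("log_likelihood", float("nan")),
                "n_draws": raw.get("n_draws", 0),
                "seed": raw.get("seed"),
                "mixing_sd": {
                    k: tuple(v) for k, v in raw.get("mixing_sd", {}).items()
                },
            }
        return cls.from_frame(pd.read_csv(csv_path), **meta)


def published_mnl_coefficients() -> CoefficientTable:
    """The published Japanese SCT4 conditional-logit estimates."""
    with resources.files("ascotval.data").joinpath(
        "coefficients_mnl_jp.csv"
    ).open("r") as fh:
        return CoefficientTable.from_frame(pd.read_csv(fh), model_id="mnl")
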