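"""End-to-end valuation-study pipeline.

Stage order mirrors the study: simulate (or load) survey data -> apply
response-time exclusions -> explode and sign-code the BWS picks -> estimate
the choice model -> rescale coefficients to a tariff -> score the cTTO arm
-> anchor latent scores to the SC-QALY scale -> compare against a
reference tariff.  Every artifact is written to the run directory along
with a manifest (config echo, derived stage seeds, file hashes) so a rerun
with the same config is byte-identical.

The single config seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``; stage k's seed is the first
31-bit word of spawn child k, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anchoring import fit_anchoring
from .coding import filter_respondents, responses_to_long
from .coefficients import CoefficientTable, published_mnl_coefficients
from .comparison import compare_tariffs
from .estimation import BestWorstMNL, BestWorstMixedLogit
from .rescaling import weights_from_coefficients
from .synthetic import (
    SyntheticTruth,
    bws_from_frame,
    make_bws_design,
    simulate_bws,
    simulate_tto,
    tto_from_frame,
    write_study,
)
from .tariffs import (
    JP_CONVERSION,
    UK_CONVERSION,
    ConversionParams,
    jp_tariff,
    uk_tariff,
)
from .tto import observations_frame, state_means

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("design_bws", "design_tto", "simulate_bws", "simulate_tto", "estimate")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML/JSON loadable)."""

    seed: int = 1
    mode: str = "full"  # full | published_comparison
    n_respondents: int = 1050
    n_bws_profiles: int = 32
    n_bws_blocks: int = 4
    n_tto_states: int = 64
    n_tto_blocks: int = 8
    model: str = "mnl"  # mnl | mixed_normal | mixed_lognormal
    cluster_scheme: str = "respondent"
    n_draws: int = 500
    bws_min_minutes: float = 4.5
    tto_min_minutes: float = 5.0
    tto_answer_grid: float = 0.5
    tto_noise_sd: float = 0.1
    mixing_distribution: str = "none"
    mixing_sd: dict = field(default_factory=dict)
    true_slope: float = 0.221
    true_intercept: float = -0.496
    compare_to: str = "uk"  # uk | jp | none
    write_choice_data: bool = False

    def validate(self) -> None:
        if self.mode not in ("full", "published_comparison"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.model not in ("mnl", "mixed_normal", "mixed_lognormal"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.compare_to not in ("uk", "jp", "none"):
            raise ValueError(f"unknown compare_to {self.compare_to!r}")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(_STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    bws_csv: str | Path | None = None,
    tto_csv: str | Path | None = None,
) -> dict:
    """Run the configured study; returns the manifest (also written to disk).

    With ``bws_csv``/``tto_csv`` the survey data are loaded instead of
    simulated (the simulate stage is skipped and the truth sidecar is not
    written).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log: list[str] = []
    artifacts: dict[str, Path] = {}

    def note(msg: str) -> None:
        log.append(msg)

    if config.mode == "published_comparison":
        report = compare_tariffs(
            jp_tariff(), JP_CONVERSION, uk_tariff(), UK_CONVERSION
        )
        path = outdir / "comparison_summary.json"
        report.to_json(path)
        artifacts["comparison_summary"] = path
        note("published-tariff comparison only; no estimation stages")
        return _finish(config, seeds, outdir, artifacts, log)

    truth = SyntheticTruth.from_coefficients(
        published_mnl_coefficients(),
        mixing_distribution=config.mixing_distribution,
        mixing_sd=dict(config.mixing_sd),
        true_conversion=ConversionParams(
            config.true_slope, config.true_intercept, "truth"
        ),
        tto_noise_sd=config.tto_noise_sd,
        seed=config.seed,
    )

    # --- stage: survey data (simulate or load)
    if bws_csv is None and tto_csv is None:
        bws_design = make_bws_design(
            config.n_bws_profiles, config.n_bws_blocks, seed=seeds["design_bws"]
        )
        tto_design = make_bws_design(
            config.n_tto_states, config.n_tto_blocks, seed=seeds["design_tto"]
        )
        bws = simulate_bws(
            truth, bws_design, config.n_respondents, seed=seeds["simulate_bws"]
        )
        tto = simulate_tto(
            truth, tto_design, config.n_respondents, seed=seeds["simulate_tto"],
            answer_grid=config.tto_answer_grid,
        )
        paths = write_study(outdir, truth, bws, tto)
        artifacts.update(
            {"bws_responses": paths["bws"], "tto_responses": paths["tto"],
             "truth": paths["truth"]}
        )
        note(f"simulated {len(bws)} BWS and {len(tto)} cTTO responses "
             f"({config.n_respondents} respondents)")
    elif bws_csv is not None and tto_csv is not None:
        bws = bws_from_frame(pd.read_csv(bws_csv))
        tto = tto_from_frame(pd.read_csv(tto_csv))
        note(f"loaded {len(bws)} BWS and {len(tto)} cTTO responses")
    else:
        raise ValueError("provide both bws_csv and tto_csv, or neither")

    # --- stage: exclusions
    from .synthetic import bws_frame, tto_frame

    bws_tab, tto_tab, report = filter_respondents(
        bws_frame(bws), tto_frame(tto),
        bws_min_minutes=config.bws_min_minutes,
        tto_min_minutes=config.tto_min_minutes,
    )
    (outdir / "exclusions.json").write_text(json.dumps(report, indent=2))
    artifacts["exclusions"] = outdir / "exclusions.json"
    note(
        f"excluded {report['n_excluded_bws']} BWS and "
        f"{report['n_excluded_tto']} cTTO respondents by response time"
    )

    # --- stage: code + estimate
    choice_long = responses_to_long(bws_from_frame(bws_tab))
    if config.write_choice_data:
        p = outdir / "choice_data.csv"
        choice_long.to_csv(p, index=False)
        artifacts["choice_data"] = p
    if config.model == "mnl":
        est = BestWorstMNL().fit(choice_long)
    else:
        est = BestWorstMixedLogit(
            distribution=config.model.removeprefix("mixed_"),
            cluster_scheme=config.cluster_scheme,
            n_draws=config.n_draws,
            seed=seeds["estimate"],
        ).fit(choice_long)
    table: CoefficientTable = est.coefficient_table_
    table.save(outdir / "coefficients.csv")
    artifacts["coefficients"] = outdir / "coefficients.csv"
    note(
        f"fitted {config.model} on {est.n_occasions_} occasions from "
        f"{est.n_respondents_} respondents; LL = {est.loglik_:.1f}"
    )

    # --- stage: rescale to a tariff
    tariff = weights_from_coefficients(table, label="estimated")
    tariff.to_csv(outdir / "weights.csv", decimals=None)
    artifacts["weights"] = outdir / "weights.csv"

    # --- stage: TTO state values
    observations, tto_summary = state_means(tto_frame(tto_from_frame(tto_tab)))
    observations_frame(observations).to_csv(
        outdir / "state_values.csv", index=False
    )
    (outdir / "tto_summary.json").write_text(json.dumps(tto_summary, indent=2))
    artifacts["state_values"] = outdir / "state_values.csv"
    artifacts["tto_summary"] = outdir / "tto_summary.json"
    note(
        f"{tto_summary['n_states']} state values; "
        f"{tto_summary['n_states_worse_than_dead']} worse than dead"
    )

    # --- stage: anchor
    anchor = fit_anchoring(observations, tariff, label="estimated")
    anchor.to_json(outdir / "anchoring.json")
    artifacts["anchoring"] = outdir / "anchoring.json"
    note(
        f"anchoring slope {anchor.conv.slope:.4f}, intercept "
        f"{anchor.conv.intercept:.4f}, R^2 {anchor.r_squared:.3f}"
    )

    # --- stage: compare
    if config.compare_to != "none":
        ref_tariff = uk_tariff() if config.compare_to == "uk" else jp_tariff()
        ref_conv = UK_CONVERSION if config.compare_to == "uk" else JP_CONVERSION
        report_cmp = compare_tariffs(tariff, anchor.conv, ref_tariff, ref_conv)
        report_cmp.to_json(outdir / "comparison_summary.json")
        artifacts["comparison_summary"] = outdir / "comparison_summary.json"
        note(
            f"vs {config.compare_to.upper()}: {report_cmp.pct_b_higher:.1f}% of "
            f"states score higher under the reference tariff"
        )

    return _finish(config, seeds, outdir, artifacts, log)


def _finish(
    config: PipelineConfig,
    seeds: dict[str, int],
    outdir: Path,
    artifacts: dict[str, Path],
    log: list[str],
) -> dict:
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "log": log,
        "artifacts": {
            k: {"path": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
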