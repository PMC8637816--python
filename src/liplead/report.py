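"""Pipeline assembly: run every analysis stage and write a report bundle.

The full pipeline mirrors the study's workflow: descriptive statistics of
the concentration panel → regulatory limit check → deterministic ingestion
risk at the panel mean → zero-inflated lognormal fit → Monte Carlo risk
percentiles → Adult Lead Model scenario grid with maternal inputs → child
lip-balm intake and multi-media uptake. Every numeric output is traceable
through the JSON manifest (parameters, seeds, package version).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .bloodlead import (
    AGE_BANDS,
    ALMParams,
    ChildExposureParams,
    child_lip_intake,
    child_media_uptake,
    maternal_inputs,
    scenario_table,
)
from .errors import LipLeadError, ParameterError
from .ingestion import ExposureParams, assess
from .montecarlo import McConfig, fit_concentration_distribution, probabilistic_risk
from .panel import SamplePanel, check_limit, read_panel, summarize_panel, write_panel
from .simulate import PanelSpec, generate_panel

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("liplead")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one concentration source must be given: a panel CSV path or a
    synthetic panel spec.
    """

    output_dir: str
    panel_path: str | None = None
    synthetic: PanelSpec | None = None
    mc: McConfig = field(default_factory=McConfig)
    alm: ALMParams = field(default_factory=ALMParams)
    limit_mg_per_kg: float = 10.0
    rounding: str = "paper_emulation"

    def __post_init__(self) -> None:
        if (self.panel_path is None) == (self.synthetic is None):
            raise ParameterError(
                "exactly one of panel_path or synthetic must be provided"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw: Mapping[str, Any] = yaml.safe_load(fh)
        kwargs: dict[str, Any] = {"output_dir": raw["output_dir"]}
        if "panel_path" in raw:
            kwargs["panel_path"] = raw["panel_path"]
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            if "n_per_category" in syn:
                syn["n_per_category"] = tuple(syn["n_per_category"])
            kwargs["synthetic"] = PanelSpec(**syn)
        if "mc" in raw:
            mc = dict(raw["mc"])
            if "percentiles" in mc:
                mc["percentiles"] = tuple(mc["percentiles"])
            kwargs["mc"] = McConfig(**mc)
        if "alm" in raw:
            kwargs["alm"] = ALMParams(**raw["alm"])
        for key in ("limit_mg_per_kg", "rounding"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _load_panel(cfg: RunConfig) -> SamplePanel:
    if cfg.panel_path is not None:
        return read_panel(cfg.panel_path)
    return generate_panel(cfg.synthetic)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.output_dir``.

    Returns the manifest dict; raises on stage failure with the stage named
    in the message. Partially written outputs are flagged in the manifest.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "liplead",
        "version": __version__,
        "config": {
            "panel_path": cfg.panel_path,
            "synthetic": None if cfg.synthetic is None else {
                "n_per_category": list(cfg.synthetic.n_per_category),
                "p_zero": cfg.synthetic.p_zero,
                "mu": cfg.synthetic.mu,
                "sigma": cfg.synthetic.sigma,
                "price_bins": list(cfg.synthetic.price_bins),
                "seed": cfg.synthetic.seed,
            },
            "mc": {"n_iter": cfg.mc.n_iter, "seed": cfg.mc.seed,
                   "percentiles": list(cfg.mc.percentiles)},
            "alm": cfg.alm.to_dict(),
            "limit_mg_per_kg": cfg.limit_mg_per_kg,
            "rounding": cfg.rounding,
        },
        "stages": {},
        "outputs": [],
    }

    def _stage(name: str):
        def wrap(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
            except Exception as exc:
                manifest["stages"][name] = f"failed: {exc}"
                _write_manifest(out, manifest, partial=True)
                raise LipLeadError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    state: dict[str, Any] = {}

    @_stage("load_panel")
    def _():
        state["panel"] = _load_panel(cfg)
        if cfg.synthetic is not None:
            write_panel(state["panel"], out / "panel.csv")
            manifest["outputs"].append("panel.csv")

    @_stage("summarize")
    def _():
        summary = summarize_panel(state["panel"])
        summary.to_csv(out / "summary.csv")
        manifest["outputs"].append("summary.csv")
        state["summary"] = summary

    @_stage("limit_check")
    def _():
        lc = check_limit(state["panel"], cfg.limit_mg_per_kg)
        pd.DataFrame(
            {"sample_id": list(lc.flags), "exceeds_limit": list(lc.flags.values())}
        ).to_csv(out / "limit_check.csv", index=False)
        manifest["outputs"].append("limit_check.csv")
        manifest["limit_verdict"] = lc.verdict

    @_stage("deterministic_risk")
    def _():
        mean_c = state["summary"].groups["total"].mean
        rows = [
            assess(mean_c, p).to_dict()
            for p in (ExposureParams.average_user(), ExposureParams.high_user())
        ]
        pd.DataFrame(rows).to_csv(out / "deterministic_risk.csv", index=False)
        manifest["outputs"].append("deterministic_risk.csv")

    @_stage("fit")
    def _():
        fit = fit_concentration_distribution(state["panel"].values)
        state["fit"] = fit
        manifest["fit"] = {
            "p_zero": fit.p_zero, "mu": fit.mu, "sigma": fit.sigma,
            "method": fit.method, "n_fit": fit.n_fit,
        }

    @_stage("monte_carlo")
    def _():
        summary = probabilistic_risk(state["fit"], cfg=cfg.mc)
        summary.to_csv(out / "mc_percentiles.csv")
        (out / "mc_percentiles.json").write_text(summary.to_json())
        manifest["outputs"] += ["mc_percentiles.csv", "mc_percentiles.json"]

    @_stage("blood_lead")
    def _():
        grid = scenario_table(cfg.alm, rounding=cfg.rounding)
        grid.to_csv(out / "bll_grid.csv")
        manifest["outputs"].append("bll_grid.csv")
        manifest["maternal_inputs"] = maternal_inputs(grid)

    @_stage("child_uptake")
    def _():
        lip_mean = state["summary"].groups.get("lip_balm")
        conc = lip_mean.mean if lip_mean else 0.0
        rows = []
        for band in AGE_BANDS:
            p = ChildExposureParams.for_age_band(band, lipbalm_conc=conc)
            rows.append(child_media_uptake(p).to_dict())
        pd.DataFrame(rows).to_csv(out / "child_uptake.csv", index=False)
        manifest["outputs"].append("child_uptake.csv")
        manifest["child_lip_intake_ug_per_d"] = {
            "average": child_lip_intake(conc, 0.02578),
            "high": child_lip_intake(conc, 0.14902),
        }

    _write_manifest(out, manifest, partial=False)
    return manifest


def _write_manifest(out: Path, manifest: dict, partial: bool) -> None:
    manifest["partial"] = partial
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
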