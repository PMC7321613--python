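"""End-to-end orchestration: retention tables in, analysis bundle out.

``run_all`` executes the stages in order — input (read or simulate),
lipophilicity fits, van't Hoff fits with linearity gating, pair selectivity,
descriptor cross-correlation, activity models — collecting every gate
decision in a log and stamping the bundle with provenance (config hash,
seed, package version). The same config always yields the same bundle.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import (
    ActivityClassifier,
    ActivityRegressor,
    build_feature_table,
    estimate_threshold,
    split_activity,
)
from .correlation import cross_correlate
from .exceptions import LipothermError
from .io import measurements_to_frame, read_activity_table, read_descriptor_table, read_retention_table
from .lipophilicity import SoczewinskiModel
from .selectivity import CompoundPair, SelectivityModel, delta_delta_g
from .simulate import generate_activity, generate_cohort, generate_descriptors
from .thermodynamics import VantHoffModel, gibbs_free_energy

__all__ = ["DEFAULT_CONFIG", "run_all", "write_bundle", "config_hash"]

DEFAULT_CONFIG = {
    "seed": 1,
    "n_compounds": 14,
    "noise_sd": 0.01,
    "t_ref": 293.15,
    "phi_ref": 0.15,
    "vant_hoff_r2_gate": 0.9,
    "selectivity_r2_gate": 0.97,
    "ed50_threshold": 350.0,
    "classifier_family": "penalized_logistic",
    "regressor_family": "penalized_regression",
    "selection_method": "none",
    "n_repeats": 10,
    "inputs": None,  # dict of file paths to analyse real tables instead of simulating
}


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except LipothermError as exc:
                raise LipothermError(f"[stage {name}] {exc}") from exc

        return wrapper

    return deco


def run_all(config: dict | None = None) -> dict:
    """Run every stage; returns the report bundle as a dict of artifacts."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    log: list[str] = []
    bundle: dict = {"config": cfg, "log": log}

    # --- input stage -------------------------------------------------------
    measurements, descriptors, activity, pairs, truth = _load_inputs(cfg, log)
    if measurements.empty or measurements["compound_id"].nunique() == 0:
        raise LipothermError("[stage io] empty compound list; nothing to analyse")
    bundle["n_compounds"] = int(measurements["compound_id"].nunique())

    # --- lipophilicity -----------------------------------------------------
    iso = measurements[measurements["temperature"] == cfg["t_ref"]]
    lipo = _fit_lipo(iso)
    bundle["lipophilicity"] = lipo.to_frame()
    for mod in sorted(iso["modifier"].unique()):
        fit = lipo.similarity_regression(mod)
        log.append(f"similarity log_kw~S ({mod}): R^2 = {fit.r2:.4f}, n = {fit.n}")
    bundle["lipo_results"] = lipo

    # --- thermodynamics ----------------------------------------------------
    vh_data = measurements[measurements["phi"] == cfg["phi_ref"]]
    thermo = _fit_thermo(vh_data, cfg["vant_hoff_r2_gate"])
    bundle["thermodynamics"] = thermo.to_frame(cfg["t_ref"])
    for r in thermo.results:
        if not r.linear_ok:
            log.append(
                f"van't Hoff gate failed: {r.compound_id}/{r.modifier} "
                f"R^2 = {r.fit.r2:.3f} <= {cfg['vant_hoff_r2_gate']}"
            )
    bundle["thermo_results"] = thermo

    # --- selectivity -------------------------------------------------------
    if pairs:
        sel = _fit_selectivity(vh_data, pairs, cfg["selectivity_r2_gate"])
        bundle["selectivity"] = sel.to_frame()
        for r in sel.results:
            if not r.linear_ok:
                log.append(
                    f"selectivity gate failed: {r.pair.id_low}/{r.pair.id_high} "
                    f"({r.modifier}) R^2 = {r.fit.r2:.3f} <= {cfg['selectivity_r2_gate']}"
                )
        bundle["delta_delta_g"] = _ddg_table(thermo, pairs, cfg["t_ref"])

    # --- descriptor correlation -------------------------------------------
    params = build_feature_table(lipo, thermo, t_ref=cfg["t_ref"])
    if descriptors is not None:
        corr = cross_correlate(params, descriptors)
        bundle["correlation"] = corr
    bundle["features"] = params

    # --- activity models ---------------------------------------------------
    if activity is not None:
        bundle.update(_activity_stage(params, activity, cfg, log))
    if truth is not None:
        bundle["truth"] = truth
    return bundle


@_stage("io")
def _load_inputs(cfg, log):
    inputs = cfg.get("inputs")
    truth = None
    if inputs:
        measurements = measurements_to_frame(
            read_retention_table(inputs["retention"], inputs.get("dialect"))
        )
        descriptors = (
            read_descriptor_table(inputs["descriptors"]) if inputs.get("descriptors") else None
        )
        activity = (
            read_activity_table(inputs["activity"]) if inputs.get("activity") else None
        )
        pairs = [
            CompoundPair(p["id_low"], p["id_high"], p.get("label", ""))
            for p in inputs.get("pairs", [])
        ]
        log.append(f"read {len(measurements)} measurements from {inputs['retention']}")
    else:
        measurements, truth = generate_cohort(
            n_compounds=cfg["n_compounds"],
            noise_sd=cfg["noise_sd"],
            seed=cfg["seed"],
            t_ref=cfg["t_ref"],
            phi_ref=cfg["phi_ref"],
        )
        descriptors = generate_descriptors(truth)
        activity = generate_activity(truth)
        pairs = truth.pairs
        log.append(
            f"simulated cohort: {cfg['n_compounds']} compounds, seed {cfg['seed']}, "
            f"noise sd {cfg['noise_sd']} on log10 k"
        )
    return measurements, descriptors, activity, pairs, truth


@_stage("lipophilicity")
def _fit_lipo(iso):
    return SoczewinskiModel(iso).fit()


@_stage("thermodynamics")
def _fit_thermo(vh_data, gate):
    return VantHoffModel(vh_data, r2_gate=gate).fit()


@_stage("selectivity")
def _fit_selectivity(vh_data, pairs, gate):
    return SelectivityModel(vh_data, pairs, r2_gate=gate).fit()


def _ddg_table(thermo, pairs, t_ref):
    rows = []
    for pair in pairs:
        for mod in ("MeOH", "ACN"):
            try:
                g1 = gibbs_free_energy(thermo.get(pair.id_low, mod), t_ref, allow_nonlinear=True)
                g2 = gibbs_free_energy(thermo.get(pair.id_high, mod), t_ref, allow_nonlinear=True)
            except KeyError:
                continue
            rows.append(
                {
                    "id_low": pair.id_low,
                    "id_high": pair.id_high,
                    "difference_label": pair.difference_label,
                    "modifier": mod,
                    "ddG_kJ_mol": delta_delta_g(g1, g2),
                }
            )
    return pd.DataFrame(rows)


@_stage("activity")
def _activity_stage(params, activity, cfg, log):
    shared = params.index.intersection(activity.index)
    feats = params.loc[shared].dropna(axis=1)
    ed50 = activity.loc[shared, "ed50"]
    threshold = estimate_threshold(ed50, fallback=cfg["ed50_threshold"])
    labels, counts = split_activity(ed50, threshold)
    log.append(f"ED50 threshold {threshold:.1f} mg/kg; class counts {counts}")
    out = {"ed50_threshold": threshold, "class_counts": counts}
    if min(counts.values()) >= 2:
        clf = ActivityClassifier(
            feats,
            labels,
            cfg["classifier_family"],
            selection_method=cfg["selection_method"],
            n_repeats=cfg["n_repeats"],
            seed=cfg["seed"],
        ).fit()
        out["classifier_report"] = clf
    else:
        log.append("degenerate labelling: classifier skipped")
    reg = ActivityRegressor(
        feats,
        ed50,
        cfg["regressor_family"],
        selection_method=cfg["selection_method"],
        n_repeats=cfg["n_repeats"],
        seed=cfg["seed"],
    ).fit()
    out["regressor_report"] = reg
    return out


def write_bundle(bundle: dict, outdir) -> None:
    """Serialize the bundle: CSV per table, JSON for reports and provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("lipophilicity", "thermodynamics", "selectivity", "delta_delta_g", "features"):
        if name in bundle:
            bundle[name].to_csv(outdir / f"{name}.csv", index=name == "features")
    if "correlation" in bundle:
        corr = bundle["correlation"]
        corr.r2.to_csv(outdir / "correlation.csv")
        (outdir / "correlation.json").write_text(json.dumps(corr.to_dict(), indent=2))
    reports = {}
    for key in ("classifier_report", "regressor_report"):
        if key in bundle:
            reports[key] = bundle[key].to_dict()
    if reports:
        (outdir / "activity_models.json").write_text(json.dumps(reports, indent=2))
    if "truth" in bundle:
        (outdir / "truth.json").write_text(
            json.dumps(bundle["truth"].to_dict(), indent=2, default=float)
        )
    cfg = bundle["config"]
    provenance = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg.get("seed"),
        "version": __version__,
        "log": bundle["log"],
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
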