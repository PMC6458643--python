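"""End-to-end study replica on a synthetic cohort.

Stages, in order:

1. **generate** — synthetic cohort (centrelines + waveforms + covariates);
2. **filter** — exclude residual re-coarctation, coarctation index < 0.7;
3. **shape** — resample to 100 points, scale to the population mean length,
   generalised-Procrustes registration, separate curvature/radius PCA
   (first 5 components), per-subject weights and geometry indices;
4. **haemodynamics** — central SBP calibration, vascular resistance, total
   arterial compliance, QA-loop wave speed, wave-intensity FCW/BCW;
5. **associations** — univariable correlation table, gothic-arch logistic
   regression on curvature weights, multivariable regression of BCW on the
   associated radius components;
6. **model1d** — ±2SD proto-aorta simulations of selected radius components;
7. **report** — tables and a manifest tying every output to config + seed.

All randomness flows through the single seed in the config, so a rerun with
the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, hemodynamics, io, shape, synthetic
from .model1d import run_proto_aorta_experiment

__all__ = ["default_config", "run_all"]


def default_config() -> dict:
    """Study-replica configuration (60 subjects, 5 PCs, 3 radius-PC protos)."""
    return {
        "seed": 0,
        "cohort": {"n_subjects": 60, "mode_sd": {}},
        "filter": {"min_coarctation_index": 0.7},
        "shape": {"n_points": 100, "n_components": 5},
        "hemodynamics": {"wia_convention": "increments"},
        "model1d": {"enabled": True, "pcs": [1, 2, 3], "dx": 0.8,
                    "n_beats": 12, "pp_tol": 2e-3},
    }


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def run_all(config: dict | None = None, out_dir: str | Path = "results",
            write_cohort_files: bool = False) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Writes ``report.json``, ``table1.csv``, ``weights.csv``, ``haemo.csv``,
    ``exclusions.csv``, proto-aorta WIA table and ``manifest.json`` under
    ``out_dir``.  Any stage failure aborts with the stage name; the manifest
    lists the stages that completed.
    """
    cfg = default_config()
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and key in cfg:
                cfg[key].update(val)
            else:
                cfg[key] = val
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg, "config_hash": _config_hash(cfg), "seed": cfg["seed"],
        "version": __version__, "stages": [], "outputs": {},
    }

    def stage(name: str):
        manifest["stages"].append({"name": name, "t_start": time.time()})
        return name

    def stage_done(**info) -> None:
        manifest["stages"][-1]["duration_s"] = round(
            time.time() - manifest["stages"][-1].pop("t_start"), 3)
        manifest["stages"][-1].update(info)

    try:
        # 1. generate ------------------------------------------------------
        stage("generate")
        ccfg = synthetic.default_cohort_config(
            n_subjects=cfg["cohort"]["n_subjects"], seed=cfg["seed"])
        for mode_id, sd in cfg["cohort"].get("mode_sd", {}).items():
            matched = [d for d in ccfg.population.mode_defs
                       if d.mode_id == mode_id]
            if not matched:
                raise ValueError(f"unknown generator mode {mode_id!r}")
            matched[0].sd = float(sd)
        records, truth = synthetic.generate_cohort(ccfg)
        if write_cohort_files:
            io.write_cohort(records, truth, out / "cohort")
        stage_done(n_subjects=len(records))

        # 2. filter --------------------------------------------------------
        stage("filter")
        threshold = cfg["filter"]["min_coarctation_index"]
        kept, excluded = [], []
        for rec in records:
            ci = shape.geometry_indices(rec.centreline).coarctation_index
            if ci < threshold:
                excluded.append({"id": rec.subject_id,
                                 "coarctation_index": ci,
                                 "rule": f"coarctation_index < {threshold}"})
            else:
                kept.append(rec)
        pd.DataFrame(excluded, columns=["id", "coarctation_index", "rule"]) \
            .to_csv(out / "exclusions.csv", index=False, float_format="%.9g")
        stage_done(n_excluded=len(excluded), n_kept=len(kept))

        # 3. shape ---------------------------------------------------------
        stage("shape")
        n_points = cfg["shape"]["n_points"]
        n_comp = cfg["shape"]["n_components"]
        resampled = [shape.resample_centreline(r.centreline, n_points)
                     for r in kept]
        mean_len = float(np.mean([c.length for c in resampled]))
        scaled = [shape.normalise_length(c, mean_len) for c in resampled]
        reference = shape.build_reference(scaled)
        registered = [shape.rigid_register(c, reference) for c in scaled]
        mean_rad = float(np.mean([c.radius.mean() for c in resampled]))
        rad_scaled = [shape.normalise_radius(c, mean_rad) for c in resampled]
        curv_model = shape.fit_shape_model(registered, "curvature", n_comp)
        rad_model = shape.fit_shape_model(rad_scaled, "radius", n_comp)
        io.save_shape_model(curv_model, out / "model_curvature.json")
        io.save_shape_model(rad_model, out / "model_radius.json")
        weights = pd.DataFrame({"id": [r.subject_id for r in kept]})
        for i in range(curv_model.n_components):
            weights[f"pc_curvature_{i+1}"] = curv_model.subject_weights[:, i]
        for i in range(rad_model.n_components):
            weights[f"pc_radius_{i+1}"] = rad_model.subject_weights[:, i]
        indices = [shape.geometry_indices(r.centreline) for r in kept]
        weights["coarctation_index"] = [g.coarctation_index for g in indices]
        weights["arch_index"] = [g.arch_index for g in indices]
        weights.to_csv(out / "weights.csv", index=False, float_format="%.9g")
        stage_done(mean_length_mm=mean_len, mean_radius_mm=mean_rad,
                   curvature_variance=curv_model.variance_fraction.tolist(),
                   radius_variance=rad_model.variance_fraction.tolist())

        # 4. haemodynamics -------------------------------------------------
        stage("haemodynamics")
        conv = cfg["hemodynamics"]["wia_convention"]
        haemo = pd.DataFrame([vars(hemodynamics.subject_summary(r, conv))
                              for r in kept])
        haemo = haemo.rename(columns={"subject_id": "id"})
        haemo.to_csv(out / "haemo.csv", index=False, float_format="%.9g")
        stage_done(taci_mean=float(haemo["taci"].mean()),
                   c_sbp_mean=float(haemo["c_sbp"].mean()))

        # 5. associations --------------------------------------------------
        stage("associations")
        covar = pd.DataFrame([{"id": r.subject_id, "p_sbp": r.p_sbp,
                               "lvmi": r.lvmi, "lvef": r.lvef,
                               "gothic": int(r.gothic)} for r in kept])
        merged = weights.merge(haemo, on="id").merge(covar, on="id")
        merged.to_csv(out / "merged.csv", index=False, float_format="%.9g")
        tab1 = association.table1(merged)
        tab1.to_csv(out / "table1.csv", float_format="%.9g")
        gothic_fit = association.logistic(
            merged["gothic"].to_numpy(),
            merged[[f"pc_curvature_{i+1}" for i in range(n_comp)]].to_numpy())
        bcw_x = merged[[f"pc_radius_{i}" for i in (1, 2, 3)]].to_numpy()
        bcw_fit = association.ols_multi(bcw_x, merged["bcw_area"].to_numpy())
        stage_done(n_log_transformed=len(tab1.attrs["log_transformed"]),
                   bcw_r2=bcw_fit.r_squared)

        # 6. model1d -------------------------------------------------------
        proto_table = None
        if cfg["model1d"]["enabled"]:
            stage("model1d")
            m1 = cfg["model1d"]
            proto_table = run_proto_aorta_experiment(
                rad_model, pcs=list(m1["pcs"]), weights=(-1.0, 0.0, 1.0),
                dx=m1["dx"], n_beats=m1["n_beats"], pp_tol=m1["pp_tol"])
            proto_table.to_csv(out / "proto_wia.csv", index=False,
                               float_format="%.9g")
            stage_done(larger_bcw_weight=proto_table.attrs["larger_bcw_weight"])

        # 7. report --------------------------------------------------------
        stage("report")
        report = {
            "n_subjects": len(records),
            "n_excluded": len(excluded),
            "curvature_variance_pct":
                (100 * curv_model.variance_fraction).round(1).tolist(),
            "radius_variance_pct":
                (100 * rad_model.variance_fraction).round(1).tolist(),
            "haemo_means": {k: float(haemo[k].mean()) for k in
                            ("co", "r", "tac", "taci", "wave_speed",
                             "fcw_area", "bcw_area", "c_sbp", "c_pp")},
            "gothic_logistic": {
                "coefficients": gothic_fit.coefficients.tolist(),
                "p_values": gothic_fit.p_values.tolist(),
                "converged": gothic_fit.converged,
            },
            "bcw_on_radius_pcs": {
                "r_squared": bcw_fit.r_squared,
                "p_overall": bcw_fit.p_overall,
                "coefficients": bcw_fit.coefficients.tolist(),
            },
            "table1_significant_cells": int(
                (tab1[[c for c in tab1.columns if c.endswith("_p")]]
                 < tab1.attrs["significance_level"]).to_numpy().sum()),
        }
        if proto_table is not None:
            report["proto_larger_bcw_weight"] = {
                str(k): v for k, v in
                proto_table.attrs["larger_bcw_weight"].items()}
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True,
                       default=_json_default))
        stage_done()
    except Exception as err:
        failed = manifest["stages"][-1]["name"] if manifest["stages"] else "?"
        completed = [s["name"] for s in manifest["stages"][:-1]]
        raise RuntimeError(
            f"pipeline stage {failed!r} failed after {completed}: {err}"
        ) from err

    manifest["outputs"] = {p.name: str(p) for p in sorted(out.glob("*"))
                           if p.is_file()}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_json_default))
    return manifest
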