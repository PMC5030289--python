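"""End-to-end orchestration: synthetic data -> two-stage fit -> experiments.

A single structured configuration (YAML-compatible dict) drives the
whole analysis; every output directory gets a manifest recording the
config hash and seeds so runs are traceable and exactly repeatable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .experiments import run_oblique_sun, run_vertical_sun
from .geometry import CoralModelParams, fitting_params, make_medium
from .inverse import (ForwardProfileModel, MeasurementSeries,
                      extract_skeleton_properties, extract_tissue_properties)
from .io import write_fit_json, write_measurement_csv
from .synth import SyntheticConfig, generate_measurement
from .transport import SourceSpec

__all__ = ["default_config", "load_config", "config_hash",
           "run_full_analysis"]


def default_config() -> dict:
    """Baseline configuration for the full synthetic-data analysis."""
    return {
        "media": {
            "skeleton_truth": {"mu_a": 0.01, "mu_s_prime": 3.4},
            "tissue_truth": {"mu_a": 1.8, "mu_s_prime": 10.0},
            "g": 0.9,
            "n": 1.38,
        },
        "geometry": {
            "wall_thickness": 3.0, "corallite_width": 10.0,
            "corallite_depth": 8.0, "tissue_thickness": 2.0,
        },
        "source": {"kind": "disk", "diameter_mm": 2.05,
                   "profile": "gaussian", "wavelength_nm": 636.0},
        "synth": {"radii_mm": [2, 5, 8, 11, 14, 17, 20],
                  "K_true": 1e4, "cv": 0.05,
                  "n_replicates_skeleton": 15, "n_replicates_coral": 13,
                  "n_photons": 1_000_000},
        "fit": {"mu_a_fixed_skeleton": 0.01,
                "photons_per_eval_skeleton": 400_000,
                "photons_per_eval_coral": 200_000,
                "max_iter": 200},
        "experiments": {"n_photons": 1_000_000, "run": True},
        "execution": {"seed": 0, "out_dir": "results"},
    }


def load_config(path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _media_from_config(cfg: dict):
    m = cfg["media"]
    skel = make_medium(g=m["g"], n=m["n"], **m["skeleton_truth"])
    tis = make_medium(g=m["g"], n=m["n"], **m["tissue_truth"])
    return skel, tis


def run_full_analysis(cfg: dict | None = None, out_dir=None,
                      measurements: dict[str, MeasurementSeries] | None = None,
                      ) -> dict:
    """Synthetic (or supplied) measurements -> skeleton fit -> tissue fit
    -> illumination experiments; returns the report bundle.

    ``measurements`` may supply real data series under keys 'skeleton'
    and 'coral' (schema identical to the synthetic CSV); each stage
    that completes has its outputs written before any later stage can
    fail.
    """
    cfg = cfg or default_config()
    seed = int(cfg["execution"]["seed"])
    out = Path(out_dir or cfg["execution"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    skel_truth, tissue_truth = _media_from_config(cfg)
    geom = CoralModelParams(**cfg["geometry"])
    fit_geom = fitting_params()
    source = SourceSpec(**cfg["source"])
    synth = cfg["synth"]
    fit_cfg = cfg["fit"]
    radii = tuple(float(r) for r in synth["radii_mm"])

    bundle: dict = {"config_hash": config_hash(cfg), "seed": seed,
                    "version": __version__}

    # --- stage 0: measurements ---
    if measurements is None:
        measurements = {}
        for stage, n_rep in (("skeleton", synth["n_replicates_skeleton"]),
                             ("coral", synth["n_replicates_coral"])):
            sc = SyntheticConfig(
                stage=stage, skeleton=skel_truth,
                tissue=tissue_truth if stage == "coral" else None,
                params=geom, source=source, radii_mm=radii,
                K_true=synth["K_true"], cv=synth["cv"], n_replicates=n_rep,
                n_photons=synth["n_photons"], seed=seed)
            measurements[stage] = generate_measurement(sc)
            write_measurement_csv(measurements[stage],
                                  out / f"measurement_{stage}.csv")

    # --- stage 1: skeleton fit ---
    fw_s = ForwardProfileModel(
        "skeleton", measurements["skeleton"].radii_mm, params=fit_geom,
        source=source, n_photons=fit_cfg["photons_per_eval_skeleton"],
        seed=seed + 1)
    skel_fit = extract_skeleton_properties(
        measurements["skeleton"], forward=fw_s,
        mu_a_fixed=fit_cfg["mu_a_fixed_skeleton"],
        max_iter=fit_cfg["max_iter"])
    write_fit_json(skel_fit, out / "fit_skeleton.json")
    bundle["skeleton_fit"] = skel_fit.as_dict()
    skel_fitted = make_medium(fit_cfg["mu_a_fixed_skeleton"],
                              skel_fit.mu_s_prime,
                              g=cfg["media"]["g"], n=cfg["media"]["n"])

    # --- stage 2: tissue fit ---
    fw_c = ForwardProfileModel(
        "coral", measurements["coral"].radii_mm, params=fit_geom,
        skeleton=skel_fitted, source=source,
        n_photons=fit_cfg["photons_per_eval_coral"], seed=seed + 2)
    tissue_fit = extract_tissue_properties(
        measurements["coral"], skeleton_props=skel_fitted,
        skeleton_fit=skel_fit, forward=fw_c, max_iter=fit_cfg["max_iter"])
    write_fit_json(tissue_fit, out / "fit_tissue.json")
    bundle["tissue_fit"] = tissue_fit.as_dict()
    tissue_fitted = make_medium(tissue_fit.mu_a, tissue_fit.mu_s_prime,
                                g=cfg["media"]["g"], n=cfg["media"]["n"])

    # --- stage 3: illumination experiments at the fitted properties ---
    if cfg["experiments"]["run"]:
        n_ph = cfg["experiments"]["n_photons"]
        vert = run_vertical_sun(tissue=tissue_fitted, skeleton=skel_fitted,
                                n_photons=n_ph, seed=seed + 3)
        obl = run_oblique_sun(tissue=tissue_fitted, skeleton=skel_fitted,
                              n_photons=n_ph, seed=seed + 4)
        obl_nt = run_oblique_sun(tissue=tissue_fitted, skeleton=skel_fitted,
                                 skeleton_mode="tissue-replaced",
                                 n_photons=n_ph, seed=seed + 4)
        bundle["vertical_sun"] = vert.as_dict()
        bundle["oblique_sun"] = obl.as_dict()
        bundle["oblique_sun_tissue_replaced"] = obl_nt.as_dict()

    manifest = {"config": cfg, "config_hash": bundle["config_hash"],
                "seed": seed, "version": __version__}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    (out / "report.json").write_text(
        json.dumps(bundle, indent=2, default=_json_default))
    return bundle


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return str(o)
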