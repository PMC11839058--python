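"""End-to-end orchestration.

``run_pipeline`` wires the stages together: synthetic-cortex generation
(or ingestion of a prepared profile table in real-data mode), an
equivolume phantom self-check, the geodesic S-A axis, per-parcel and
per-depth-bin smooth trajectory fits with FDR-controlled age effects,
derivative-band plateau detection, depth/group ANOVAs and the 4:1
cross-species comparison.  Outputs are flat, diffable CSV files plus a
``summary.json`` and a run log; identical configs (and seeds) produce
byte-identical tables.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import axis as axis_mod
from . import compare, gam, maps, plateau, synthetic

DEFAULT_CONFIG = {
    "mode": "synthetic",
    "n_parcels": 60,
    "k_depth_bins": 5,
    "parcel_grid": [6, 10],
    "mesh_block": 5,  # vertices per parcel block side
    "n_subjects_human": 150,
    "growth_origin": 5.5,  # human age at which synthetic growth begins
    "macaque": {"n_subjects": 34, "n_sessions": 5},
    "cluster_fraction": 0.1,
    "smooth_k": 3,
    "grid_points": 200,
    "n_draws": 10000,
    "level": 0.95,
    "fdr_alpha": 0.05,
    "species_scaling": {"factor": 4.0, "human_baseline_age": 4.0, "macaque_baseline_age": 1.0},
    "seeds": {"cohort": 11, "kmeans": 13, "band": 17},
    "phantom": {"inner_radius": 10.0, "outer_radius": 12.0, "voxel_size": 0.1},
    "paths": {},  # real mode: profiles, mesh, vertex_labels, external_axis
}

_REQUIRED_REAL_PATHS = ("profiles", "mesh", "vertex_labels")


def load_config(path) -> dict:
    path = str(path)
    with open(path) as fh:
        if path.endswith((".yaml", ".yml")):
            import yaml

            user = yaml.safe_load(fh)
        else:
            user = json.load(fh)
    return validate_config(user or {})


def validate_config(user: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys and
    (in real mode) naming any missing path field."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config field {key!r}")
        if isinstance(cfg[key], dict) and not isinstance(value, dict):
            raise ValueError(f"config field {key!r} must be a mapping")
        if isinstance(cfg[key], dict):
            for sub, sval in value.items():
                if key != "paths" and sub not in cfg[key]:
                    raise ValueError(f"unknown config field {key}.{sub}")
                cfg[key][sub] = sval
        else:
            cfg[key] = value
    if cfg["mode"] not in ("synthetic", "real"):
        raise ValueError("mode must be 'synthetic' or 'real'")
    if cfg["mode"] == "real":
        for field in _REQUIRED_REAL_PATHS:
            if field not in cfg["paths"]:
                raise ValueError(f"real-data mode requires config field paths.{field}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _fit_units(table, k, grid_points, n_draws, level, band_seed, random_intercepts, log):
    """Fit full+reduced models per unit of a long table grouped by `keys`,
    returning (effects table, fits dict, bands dict)."""
    rows = []
    fits = {}
    bands = {}
    for unit, sub in table:
        df = pd.DataFrame(
            {
                "age": sub["age"].to_numpy(),
                "value": sub["ratio"].to_numpy(),
                "sex": sub["sex"].to_numpy(),
                "subject": sub["subject_id"].to_numpy(),
            }
        )
        full = gam.fit_gam(df, k=k, random_intercepts=random_intercepts)
        red = gam.fit_gam(df, k=k, random_intercepts=random_intercepts, include_age=False)
        grid = gam.default_age_grid(full, grid_points)
        eff = gam.age_effect(full, red, grid)
        band = plateau.derivative_band(full, grid, n_draws=n_draws, level=level, seed=band_seed)
        p_age, flag = plateau.plateau_age(band)
        fits[unit] = full
        bands[unit] = band
        rows.append(
            {
                "unit": unit,
                "r2_partial": eff.r2_partial,
                "sign": eff.sign,
                "p": eff.p_value,
                "mean_slope": eff.mean_slope,
                "edf": full.edf_fixed,
                "lambda": full.lam.get("smooth", float("nan")),
                "plateau_age": p_age,
                "flag": flag,
            }
        )
    effects = pd.DataFrame(rows)
    effects["q"] = gam.fdr_correct(effects["p"])
    log(f"fitted {len(effects)} units (random_intercepts={random_intercepts})")
    return effects, fits, bands


def group_mean_tables(ratios: pd.DataFrame, axis_map: pd.DataFrame) -> dict:
    """Per-subject group-averaged trajectory tables for species comparison.

    Units are the three S-A groups (all depth bins averaged) plus the
    deepest and most superficial bins (all parcels averaged) -- the
    averaged trajectories carry far less noise than single parcels while
    the cross-species time-compression identity is preserved exactly.
    """
    merged = ratios.merge(axis_map[["parcel", "group"]], on="parcel")
    units = {f"axis_{g}": sub for g, sub in merged.groupby("group", sort=True, observed=True)}
    deep, sup = ratios["depth_bin"].min(), ratios["depth_bin"].max()
    units["depth_deep"] = ratios[ratios["depth_bin"] == deep]
    if sup != deep:
        units["depth_superficial"] = ratios[ratios["depth_bin"] == sup]
    out = {}
    for name, sub in units.items():
        out[name] = (
            sub.groupby(["subject_id", "age", "sex"], sort=True)["ratio"]
            .mean()
            .reset_index()
        )
    return out


def run_pipeline(config: dict | None = None, out_dir="results") -> dict:
    """Run the full pipeline and write the result bundle to ``out_dir``.

    Returns the summary dict (also written to ``summary.json``).  The
    bundle is ``axis.csv``, ``profiles.csv``, ``effects.csv``,
    ``plateaus.csv``, ``summary.json`` and ``run.log``.
    """
    cfg = validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg, stage=[0]):
        stage[0] += 1
        log_lines.append(f"[{stage[0]:02d}] {msg}")

    log(f"config hash {config_hash(cfg)}; seeds {cfg['seeds']}")
    summary = {"config_hash": config_hash(cfg), "seeds": cfg["seeds"]}

    K = cfg["k_depth_bins"]
    n_parcels = cfg["n_parcels"]
    try:
        if cfg["mode"] == "synthetic":
            # --- stage: phantom equivolume self-check ---------------------
            ph = cfg["phantom"]
            ribbon = synthetic.make_phantom_ribbon(
                "annulus", ph["inner_radius"], ph["outer_radius"], ph["voxel_size"]
            )
            bins = maps.assign_depth_bins(ribbon, K)
            counts = np.bincount(bins[bins > 0], minlength=K + 1)[1:]
            summary["phantom_bin_counts"] = counts.tolist()
            summary["phantom_bin_imbalance"] = float(
                np.max(np.abs(counts - counts.mean()) / counts.mean())
            )
            log(f"phantom annulus K={K}: max bin imbalance "
                f"{summary['phantom_bin_imbalance']:.4f}")

            # --- stage: mesh + geodesic axis ------------------------------
            pr, pc = cfg["parcel_grid"]
            if pr * pc != n_parcels:
                raise ValueError("parcel_grid must multiply to n_parcels")
            b = cfg["mesh_block"]
            mesh = synthetic.make_grid_mesh(pr * b, pc * b, 1.0, parcel_grid=(pr, pc))
            # association seeds = highest parcel ids = last block column
            seed_parcels = range(n_parcels - pr, n_parcels)
            seeds = axis_mod.select_seed_nodes(
                mesh, seed_parcels, cfg["cluster_fraction"], seed=cfg["seeds"]["kmeans"]
            )
            axis_map = axis_mod.build_axis_map(mesh, seeds)
            log(f"axis: {len(axis_map)} parcels from {len(seeds)} seed vertices")

            # --- stage: cohorts -------------------------------------------
            cohort_h, ratios_h, truth_h = synthetic.simulate_cohort(
                cfg["n_subjects_human"], n_parcels, K,
                seed=cfg["seeds"]["cohort"],
                growth_origin=cfg["growth_origin"],
            )
            cohort_m, ratios_m, truth_m = synthetic.simulate_cohort(
                cfg["macaque"]["n_subjects"],
                n_parcels,
                K,
                species="macaque",
                species_scale=cfg["species_scaling"]["factor"],
                n_sessions=cfg["macaque"]["n_sessions"],
                seed=cfg["seeds"]["cohort"] + 1,
                growth_origin=cfg["growth_origin"],
            )
            ratios = pd.concat([ratios_h, ratios_m], ignore_index=True)
            truth = pd.concat(
                [truth_h.assign(species="human"), truth_m.assign(species="macaque")],
                ignore_index=True,
            )
            truth.to_csv(out / "ground_truth.csv", index=False)
            log(f"cohorts: {len(cohort_h)} human rows, {len(cohort_m)} macaque rows")
        else:
            from . import io as io_mod

            paths = cfg["paths"]
            ratios = pd.read_csv(paths["profiles"])
            needed = {"subject_id", "age", "sex", "species", "parcel", "depth_bin", "ratio"}
            missing = needed - set(ratios.columns)
            if missing:
                raise ValueError(f"profiles table missing columns {sorted(missing)}")
            if "session" not in ratios.columns:
                ratios["session"] = 1
            mesh = io_mod.load_mesh(paths["mesh"], vertex_parcel=paths["vertex_labels"])
            seed_parcels = paths.get("seed_parcels")
            if seed_parcels is None:
                raise ValueError("real-data mode requires config field paths.seed_parcels")
            seeds = axis_mod.select_seed_nodes(
                mesh, seed_parcels, cfg["cluster_fraction"], seed=cfg["seeds"]["kmeans"]
            )
            axis_map = axis_mod.build_axis_map(mesh, seeds)
            ratios_h = ratios[ratios["species"] == "human"]
            ratios_m = ratios[ratios["species"] == "macaque"]
            log("real-data mode: profiles and mesh ingested")

        if "external_axis" in cfg["paths"]:
            ext = pd.read_csv(cfg["paths"]["external_axis"]).set_index("parcel").iloc[:, 0]
            rho, p = axis_mod.validate_axis(axis_map, ext)
            summary["external_axis_spearman"] = {"rho": rho, "p": p}
            log(f"external axis check: spearman rho {rho:.3f}")

        # --- stage: trajectory fits ---------------------------------------
        kws = dict(
            k=cfg["smooth_k"],
            grid_points=cfg["grid_points"],
            n_draws=cfg["n_draws"],
            level=cfg["level"],
            band_seed=cfg["seeds"]["band"],
            log=log,
        )
        # per-parcel (depth-averaged) human fits
        parcel_mean_h = (
            ratios_h.groupby(["subject_id", "age", "sex", "session", "parcel"], sort=True)[
                "ratio"
            ]
            .mean()
            .reset_index()
        )
        eff_h, fits_h, bands_h = _fit_units(
            parcel_mean_h.groupby("parcel", sort=True), random_intercepts=False, **kws
        )
        # per parcel x depth human fits
        eff_hd, fits_hd, _ = _fit_units(
            ratios_h.groupby(["parcel", "depth_bin"], sort=True), random_intercepts=False, **kws
        )
        # per-parcel macaque fits (longitudinal: subject random intercepts)
        have_macaque = len(ratios_m) > 0
        if have_macaque:
            parcel_mean_m = (
                ratios_m.groupby(["subject_id", "age", "sex", "session", "parcel"], sort=True)[
                    "ratio"
                ]
                .mean()
                .reset_index()
            )
            eff_m, fits_m, bands_m = _fit_units(
                parcel_mean_m.groupby("parcel", sort=True), random_intercepts=True, **kws
            )

        # --- stage: axis-level summaries ----------------------------------
        slopes_h = eff_h.rename(columns={"unit": "parcel", "mean_slope": "slope"})[
            ["parcel", "slope"]
        ]
        summary["slope_vs_axis_human"] = gam.slope_vs_axis(slopes_h, axis_map)
        depth_slopes = eff_hd.copy()
        depth_slopes[["parcel", "depth_bin"]] = pd.DataFrame(
            depth_slopes["unit"].tolist(), index=depth_slopes.index
        )
        wide = depth_slopes.pivot(index="parcel", columns="depth_bin", values="mean_slope")
        deep, sup = wide.columns.min(), wide.columns.max()
        summary["deeper_steeper_fraction"] = float((wide[deep] > wide[sup]).mean())
        diff = (wide[deep] - wide[sup]).rename("slope").reset_index()
        summary["depth_slope_diff_vs_axis"] = gam.slope_vs_axis(diff, axis_map)
        summary["depth_slope_anova"] = compare.depth_slope_anova(
            depth_slopes.rename(columns={"mean_slope": "slope"})[
                ["parcel", "depth_bin", "slope"]
            ],
            axis_map,
        )
        log(f"deeper-steeper fraction {summary['deeper_steeper_fraction']:.3f}")

        # --- stage: plateau summaries --------------------------------------
        groups = axis_map.rename(columns={"parcel": "unit"})[["unit", "group"]]
        elig_h = pd.DataFrame(
            {"unit": eff_h["unit"], "eligible": eff_h["q"] <= cfg["fdr_alpha"]}
        )
        summary["plateau_human"] = plateau.plateau_summary(
            eff_h[["unit", "plateau_age", "flag"]], groups, elig_h
        )
        if have_macaque:
            elig_m = pd.DataFrame(
                {"unit": eff_m["unit"], "eligible": eff_m["q"] <= cfg["fdr_alpha"]}
            )
            summary["plateau_macaque"] = plateau.plateau_summary(
                eff_m[["unit", "plateau_age", "flag"]], groups, elig_m
            )
            log(
                "plateau ANOVA F: human "
                f"{summary['plateau_human']['anova_F']:.3f}, macaque "
                f"{summary['plateau_macaque']['anova_F']:.3f}"
            )

        # --- stage: cross-species scaling ----------------------------------
        if have_macaque:
            sc = compare.SpeciesScaling(**cfg["species_scaling"])
            s_hat = compare.estimate_scaling(
                group_mean_tables(ratios_h, axis_map),
                group_mean_tables(ratios_m, axis_map),
            )
            summary["species_scaling_estimate"] = float(s_hat)
            check = {}
            for name, fits, base in (
                ("human", fits_h, sc.human_baseline_age),
                ("macaque", fits_m, sc.macaque_baseline_age),
            ):
                fit0 = fits[sorted(fits)[0]]
                # configured baseline clipped into the observed range
                base_eff = min(max(base, fit0.age_range[0]), fit0.age_range[1])
                adj = compare.baseline_adjust(fit0, base_eff, ages=np.array([base_eff]))
                check[name] = {"baseline_age": base_eff, "adjusted_value": float(adj[0])}
            summary["baseline_adjusted_at_baseline"] = check
            log(f"species scaling estimate {s_hat:.3f}")

        # --- stage: outputs -------------------------------------------------
        axis_map.rename(columns={"distance": "distance_mm"}).to_csv(
            out / "axis.csv", index=False
        )
        ratios.to_csv(out / "profiles.csv", index=False)
        eff_all = [
            eff_h.rename(columns={"unit": "parcel"}).assign(species="human", depth_bin="all")
        ]
        eff_all.append(depth_slopes.assign(species="human", depth_bin=lambda d: d["depth_bin"].astype(str)).drop(columns=["unit"]))
        if have_macaque:
            eff_all.append(
                eff_m.rename(columns={"unit": "parcel"}).assign(
                    species="macaque", depth_bin="all"
                )
            )
        effects = pd.concat(eff_all, ignore_index=True)
        effects.to_csv(out / "effects.csv", index=False)
        plate = effects[["species", "parcel", "depth_bin", "plateau_age", "flag"]]
        plate.to_csv(out / "plateaus.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log("bundle written")
    except Exception as exc:
        log_lines.append(f"[FAIL] stage error: {type(exc).__name__}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
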