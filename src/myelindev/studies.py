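"""Ground-truth validation studies.

Each function runs one self-contained recovery or calibration study on
synthetic data with known ground truth and returns a dict of summary
numbers.  These are the quantitative checks behind the package's claims:
equivolume geometry against closed forms, geodesic distances against an
exhaustive shortest-path oracle, null calibration of the age-effect test,
FDR control, plateau-age recovery, hierarchy/depth structure recovery
end-to-end, and cross-species time-compression recovery.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq

from . import axis as axis_mod
from . import compare, gam, maps, pipeline, plateau, synthetic

HUMAN_RANGE = (5.0, 35.0)


def equivolume_annulus_study(inner=10.0, outer=12.0, voxel=0.1) -> dict:
    """Annulus phantom: K=2 boundary vs sqrt((r_in^2+r_out^2)/2); K=6 balance."""
    ribbon = synthetic.make_phantom_ribbon("annulus", inner, outer, voxel)
    radius = ribbon._coord()
    bins2 = maps.assign_depth_bins(ribbon, 2)
    analytic = math.sqrt((inner**2 + outer**2) / 2)
    b_low = radius[bins2 == 1].max()
    b_high = radius[bins2 == 2].min()
    boundary_err = max(abs(b_low - analytic), abs(b_high - analytic))
    bins6 = maps.assign_depth_bins(ribbon, 6)
    counts = np.bincount(bins6[bins6 > 0], minlength=7)[1:]
    dev = np.max(np.abs(counts - counts.mean())) / counts.mean()
    return {
        "boundary_radius_mm": float((b_low + b_high) / 2),
        "boundary_error_voxels": float(boundary_err / voxel),
        "k6_max_bin_deviation": float(dev),
    }


def equivolume_rho_oracle_study(n_cases: int = 100, seed: int = 0) -> dict:
    """Closed-form rho(alpha) vs numerical inversion of the volume integral."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        aw, ap = rng.uniform(0.2, 5.0, 2)
        alpha = rng.uniform(0.001, 0.999)
        col = maps.EquivolumeColumn(aw, ap)
        total, _ = quad(lambda t: aw + t * (ap - aw), 0, 1)

        def cum(rho):
            v, _ = quad(lambda t: aw + t * (ap - aw), 0, rho)
            return v / total - alpha

        oracle = brentq(cum, 0.0, 1.0, xtol=1e-13)
        worst = max(worst, abs(float(maps.equivolume_rho(col, alpha)) - oracle))
    return {"max_abs_error": worst, "n_cases": n_cases}


def geodesic_oracle_study(n_meshes: int = 50, max_vertices: int = 200, seed: int = 0) -> dict:
    """Multi-source distances vs exhaustive networkx Dijkstra on random meshes."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_meshes):
        rows = int(rng.integers(2, 15))
        cols = int(rng.integers(2, max(3, max_vertices // rows)))
        mesh = synthetic.make_grid_mesh(rows, cols, 1.0)
        mesh.vertices = mesh.vertices + rng.normal(0, 0.2, mesh.vertices.shape)
        n_seed = int(rng.integers(1, 4))
        seeds = rng.choice(mesh.n_vertices, size=min(n_seed, mesh.n_vertices), replace=False)
        d = axis_mod.geodesic_distance(mesh, seeds)
        g = nx.Graph()
        for tri in mesh.triangles:
            for i, j in ((0, 1), (1, 2), (2, 0)):
                w = float(np.linalg.norm(mesh.vertices[tri[i]] - mesh.vertices[tri[j]]))
                g.add_edge(int(tri[i]), int(tri[j]), weight=w)
        lengths = nx.multi_source_dijkstra_path_length(g, set(int(s) for s in seeds))
        oracle = np.array([lengths[v] for v in range(mesh.n_vertices)])
        worst = max(worst, float(np.max(np.abs(d - oracle))))
    grid = synthetic.make_grid_mesh(10, 10, 1.0)
    worked = float(axis_mod.geodesic_distance(grid, [0])[3 * 10 + 4])
    return {"max_abs_diff": worst, "grid_worked_value": worked, "n_meshes": n_meshes}


def null_space_study(n: int = 80, seed: int = 0) -> dict:
    """Constants and lines reproduced exactly at lambda in {0, 1, 1e6}."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*HUMAN_RANGE, n)
    worst = 0.0
    for lam in (0.0, 1.0, 1e6):
        for y in (np.full(n, 3.7), 2.0 + 0.5 * ages):
            fit = gam.fit_gam(pd.DataFrame({"age": ages, "value": y}), lam=lam)
            worst = max(worst, float(np.max(np.abs(fit.predict(ages) - y))))
    return {"max_abs_error": worst}


def type_i_fdr_study(
    n_parcels: int = 200,
    n_reps: int = 100,
    n_subjects: int = 50,
    frac_null: float = 0.9,
    alpha: float = 0.05,
    q_level: float = 0.05,
    seed: int = 0,
) -> dict:
    """Null calibration of the age-effect test and BH-FDR control.

    Per replicate, ``frac_null`` of the parcels are pure noise (+ sex
    effect) and the rest follow a saturating growth curve.  The type-I
    rate is the rejection fraction among null parcels at ``alpha``; the
    false-discovery proportion is averaged over replicates at
    ``q_level`` after BH correction within each replicate.
    """
    lo, hi = HUMAN_RANGE
    n_alt = int(round(n_parcels * (1 - frac_null)))
    growth = synthetic.GrowthParams(1.5, 0.3, rate=np.log(100) / 15.0, sex_effect=0.05)
    null_rej = 0
    null_total = 0
    fdps = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        ages = rng.uniform(lo, hi, n_subjects)
        sex = rng.choice(["F", "M"], n_subjects)
        sexc = np.where(sex == "M", 0.5, -0.5)
        ps = np.empty(n_parcels)
        is_null = np.ones(n_parcels, dtype=bool)
        is_null[:n_alt] = False
        for parcel in range(n_parcels):
            mean = 1.5 if is_null[parcel] else synthetic.growth_curve(growth, ages)
            y = mean + growth.sex_effect * sexc + rng.normal(0, 0.06, n_subjects)
            df = pd.DataFrame({"age": ages, "value": y, "sex": sex})
            full = gam.fit_gam(df)
            red = gam.fit_gam(df, include_age=False)
            eff = gam.age_effect(full, red, np.linspace(ages.min(), ages.max(), 50))
            ps[parcel] = eff.p_value
        null_rej += int(np.sum(ps[is_null] < alpha))
        null_total += int(is_null.sum())
        qs = gam.fdr_correct(ps)
        disc = qs <= q_level
        fdps.append(np.sum(disc & is_null) / max(disc.sum(), 1))
    return {
        "null_rejection_rate": null_rej / null_total,
        "false_discovery_proportion": float(np.mean(fdps)),
        "n_tests": null_total,
        "n_reps": n_reps,
    }


def plateau_recovery_study(
    n_reps: int = 100,
    n_subjects: int = 150,
    onset_frac: float = 0.25,
    noise_frac: float = 0.10,
    n_draws: int = 10000,
    seed: int = 0,
) -> dict:
    """Plateau-age recovery and monotone-growth specificity.

    Saturating trajectories with plateau onset at ``onset_frac`` of the
    age-range width (the derivative decays to 1% of its initial value by
    that age); recovery = detected plateau within +/-15% of the range
    width.  Controls are strictly increasing linear trajectories, which
    should be declared no-plateau.
    """
    lo, hi = HUMAN_RANGE
    width = hi - lo
    amplitude = 0.6
    params = synthetic.GrowthParams(1.2, amplitude, rate=np.log(100) / (onset_frac * width))
    true_onset = params.plateau_onset
    hits = 0
    detected = []
    controls_ok = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        ages = rng.uniform(lo, hi, n_subjects)
        y = synthetic.growth_curve(params, ages) + rng.normal(
            0, noise_frac * amplitude, n_subjects
        )
        fit = gam.fit_gam(pd.DataFrame({"age": ages, "value": y}))
        grid = gam.default_age_grid(fit)
        band = plateau.derivative_band(fit, grid, n_draws=n_draws, seed=seed + rep)
        a_star, flag = plateau.plateau_age(band)
        if np.isfinite(a_star) and abs(a_star - true_onset) <= 0.15 * width:
            hits += 1
        detected.append(a_star)
        # monotone control: linear growth well clear of zero derivative
        y_lin = 1.2 + 0.02 * ages + rng.normal(0, noise_frac * amplitude, n_subjects)
        fit_l = gam.fit_gam(pd.DataFrame({"age": ages, "value": y_lin}))
        band_l = plateau.derivative_band(
            fit_l, gam.default_age_grid(fit_l), n_draws=n_draws, seed=seed + rep
        )
        _, flag_l = plateau.plateau_age(band_l)
        controls_ok += flag_l == plateau.FLAG_ABSENT
    return {
        "recovery_rate": hits / n_reps,
        "control_no_plateau_rate": controls_ok / n_reps,
        "true_onset": float(true_onset),
        "median_detected": float(np.nanmedian(detected)),
        "n_reps": n_reps,
    }


def hierarchy_depth_study(seed: int = 0, out_dir=None) -> dict:
    """End-to-end structure recovery on the default synthetic cortex.

    Runs the full pipeline (60 parcels x 5 depth bins) and checks (i) the
    Spearman correlation between true plateau-onset order and recovered
    plateau-age order across parcels and (ii) the fraction of parcels
    whose deepest bin has a steeper mean slope than the most superficial.
    """
    cfg = {"seeds": {"cohort": seed + 11, "kmeans": seed + 13, "band": seed + 17}}
    ctx = tempfile.TemporaryDirectory() if out_dir is None else None
    out = Path(out_dir) if out_dir is not None else Path(ctx.name)
    try:
        summary = pipeline.run_pipeline(cfg, out_dir=out)
        eff = pd.read_csv(out / "effects.csv")
        truth = pd.read_csv(out / "ground_truth.csv")
    finally:
        if ctx is not None:
            ctx.cleanup()
    hp = eff[(eff["species"] == "human") & (eff["depth_bin"] == "all")].copy()
    hp["parcel"] = hp["parcel"].astype(int)
    onset = truth[truth["species"] == "human"].groupby("parcel")["plateau_onset"].mean()
    merged = hp.merge(onset.rename("true_onset"), left_on="parcel", right_index=True)
    ranked = merged[np.isfinite(merged["plateau_age"])]
    rho, _ = stats.spearmanr(ranked["true_onset"], ranked["plateau_age"])
    return {
        "plateau_order_spearman": float(rho),
        "n_ranked": int(len(ranked)),
        "deeper_steeper_fraction": float(summary["deeper_steeper_fraction"]),
        "slope_vs_axis_r2": float(summary["slope_vs_axis_human"]["r2_smooth"]),
    }


def scaling_recovery_study(n_reps: int = 20, true_factor: float = 4.0, seed: int = 0) -> dict:
    """Recovery of the species time-compression factor over replicates.

    Simulates paired human/macaque arms (true factor 4), estimates s per
    replicate from group-averaged trajectories and summarizes by the
    median (single-replicate identifiability is weak under the realistic
    window overlap; see the methods note).  Also verifies that
    baseline-adjusted trajectories vanish at the baseline exactly.
    """
    estimates = []
    for rep in range(n_reps):
        rep_seed = seed + 1000 * rep
        tables = {}
        for species, n, ns in (("human", 150, 1), ("macaque", 34, 5)):
            _, ratios, _ = synthetic.simulate_cohort(
                n, 60, 5, species=species, species_scale=true_factor,
                n_sessions=ns, seed=rep_seed,
                growth_origin=pipeline.DEFAULT_CONFIG["growth_origin"],
            )
            ratios = ratios.copy()
            ratios["grp"] = pd.cut(ratios["parcel"], 3, labels=["S", "M", "A"])
            axis_like = pd.DataFrame(
                {"parcel": np.arange(60), "group": pd.cut(np.arange(60), 3,
                 labels=["sensorimotor", "middle", "association"])}
            )
            tables[species] = pipeline.group_mean_tables(ratios, axis_like)
        estimates.append(compare.estimate_scaling(tables["human"], tables["macaque"]))
    estimates = np.array(estimates)

    # baseline-adjust exactness on one fitted trajectory per species
    fit_h = gam.fit_gam(tables["human"]["depth_deep"].rename(columns={"ratio": "value"}))
    fit_m = gam.fit_gam(tables["macaque"]["depth_deep"].rename(columns={"ratio": "value"}))
    sc = compare.SpeciesScaling(factor=true_factor)
    base_h = max(sc.human_baseline_age, fit_h.age_range[0])
    resid = max(
        abs(compare.baseline_adjust(fit_h, base_h, ages=np.array([base_h]))[0]),
        abs(compare.baseline_adjust(fit_m, sc.macaque_baseline_age,
                                    ages=np.array([sc.macaque_baseline_age]))[0]),
    )
    return {
        "median_s_hat": float(np.median(estimates)),
        "mean_s_hat": float(np.mean(estimates)),
        "in_band_fraction": float(np.mean((estimates >= 3.5) & (estimates <= 4.5))),
        "baseline_adjust_max_residual": float(resid),
        "n_reps": n_reps,
    }


def determinism_study(out_root, seed: int = 0) -> dict:
    """Two CLI pipeline runs with an identical config: byte-identical CSVs."""
    import subprocess
    import sys
    import json as _json

    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    cfg = {
        "n_parcels": 12,
        "parcel_grid": [3, 4],
        "mesh_block": 4,
        "n_subjects_human": 40,
        "macaque": {"n_subjects": 12, "n_sessions": 5},
        "n_draws": 2000,
        "phantom": {"inner_radius": 10.0, "outer_radius": 12.0, "voxel_size": 0.25},
        "seeds": {"cohort": seed + 1, "kmeans": seed + 2, "band": seed + 3},
    }
    cfg_path = out_root / "config.json"
    cfg_path.write_text(_json.dumps(cfg))
    for run in ("run_a", "run_b"):
        subprocess.run(
            [sys.executable, "-m", "myelindev.cli", "run", "--config", str(cfg_path),
             "--out-dir", str(out_root / run)],
            check=True, capture_output=True,
        )
    identical = True
    for name in ("axis.csv", "profiles.csv", "effects.csv", "plateaus.csv", "summary.json"):
        a = (out_root / "run_a" / name).read_bytes()
        b = (out_root / "run_b" / name).read_bytes()
        identical &= a == b
    return {"byte_identical": int(identical)}
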