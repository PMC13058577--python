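"""End-to-end pipeline orchestration and candidate-set intersection.

A single YAML config drives the stages simulate → freqs → reduce → fit →
offset → revorate → map (each toggleable); every stage writes plain CSV/JSON
artifacts into the output directory and the run manifest records seeds,
versions, input digests and per-stage outputs so a rerun with the same
config is bit-identical (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grids import ClimateGrid
from .landscape import cluster_landscape, rgb_projection
from .offset import offset_series
from .poolfreq import counts_to_freqs, filter_chain
from .predictors import pcnm_vectors, pearson_prune
from .rates import (DEFAULT_BASELINE_MIDPOINT, DEFAULT_PERIOD_MIDPOINTS,
                    classify_series, discrete_revorate)
from .synthdata import (make_climate_grid, project_climate,
                        sample_populations, simulate_pool_counts)
from .turnover import TurnoverForest

__all__ = ["intersect_candidates", "run_pipeline", "default_config",
           "validate_config"]

log = logging.getLogger("revokit")


def intersect_candidates(named_sets: dict) -> pd.DataFrame:
    """Exclusive-combination counts over named candidate-locus sets.

    For every non-empty subset S of method names, counts the loci belonging
    to exactly the methods in S (the numbers behind an UpSet plot). Counts
    over all combinations sum to the size of the union.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 named sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate method names")
    membership: dict = {}
    for name in names:
        for locus in named_sets[name]:
            membership.setdefault(locus, set()).add(name)
    counts: dict[tuple, int] = {}
    for methods in membership.values():
        key = tuple(sorted(methods))
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(sorted(names), r):
            rows.append({"methods": "&".join(combo),
                         "n_methods": r,
                         "exclusive_count": counts.get(combo, 0)})
    return pd.DataFrame(rows)


def default_config() -> dict:
    return {
        "outdir": "revokit_run",
        "seed": 0,
        "stages": ["simulate", "freqs", "reduce", "fit", "offset",
                   "revorate", "map"],
        "simulate": {
            "nx": 20, "ny": 20, "smoothness": 4.0,
            "predictors": ["bio_temp", "bio_seasonality", "bio_precip"],
            "n_pops": 40, "n_loci": 500, "frac_adaptive": 0.1,
            "slope_range": [4.0, 8.0], "pool_size_diploid": 25,
            "mean_coverage": 25.0,
            "periods": ["p1", "p2", "p3", "p4"],
            "trend": {"bio_temp": [0.5, 0.5, 0.5, 0.5],
                      "bio_seasonality": [0.1, 0.1, 0.1, 0.1],
                      "bio_precip": [-0.3, -0.3, -0.3, -0.3]},
            "trend_noise_sd": 0.02,
        },
        "freqs": {"min_cov": 3, "pop_missing_max": 0.70,
                  "locus_missing_max_pops": 1},
        "reduce": {"r_max": 0.8, "pcnm": True},
        "fit": {"n_trees": 200, "bins": 200, "r2_min": 0.1},
        "revorate": {"baseline_midpoint": DEFAULT_BASELINE_MIDPOINT,
                     "midpoints": list(DEFAULT_PERIOD_MIDPOINTS)},
        "map": {"k_range": [2, 3, 4, 5], "n_restarts": 10},
    }


def validate_config(config: dict) -> dict:
    """Merge with defaults; unknown keys are errors (fail fast)."""
    defaults = default_config()
    merged = {}
    unknown = set(config) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, dval in defaults.items():
        val = config.get(key, dval)
        if isinstance(dval, dict) and isinstance(val, dict):
            bad = set(val) - set(dval)
            if bad:
                raise ValueError(f"unknown keys under {key!r}: {sorted(bad)}")
            merged[key] = {**dval, **val}
        else:
            merged[key] = val
    bad_stages = set(merged["stages"]) - set(defaults["stages"])
    if bad_stages:
        raise ValueError(f"unknown stages: {sorted(bad_stages)}")
    return merged


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    manifest = {"version": __version__, "seed": seed, "stages": stages,
                "config": cfg, "artifacts": {}, "timings": {},
                "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    state: dict = {}

    def record(stage: str, name: str, path: Path) -> None:
        manifest["artifacts"].setdefault(stage, {})[name] = str(path)

    def run_stage(stage, fn):
        t0 = time.time()
        log.info("stage %s starting (seed=%d)", stage, seed)
        try:
            fn()
        except Exception:
            log.error("stage %s failed", stage)
            raise RuntimeError(f"stage {stage!r} failed") from None
        manifest["timings"][stage] = round(time.time() - t0, 3)
        log.info("stage %s done in %.2fs", stage, manifest["timings"][stage])

    if "simulate" in stages:
        def _simulate():
            sim = cfg["simulate"]
            grid = make_climate_grid(sim["nx"], sim["ny"], sim["predictors"],
                                     sim["smoothness"], seed)
            slices = project_climate(grid, sim["periods"], sim["trend"],
                                     sim["trend_noise_sd"], seed + 1)
            pops = sample_populations(grid, sim["n_pops"], seed + 2)
            counts, truth = simulate_pool_counts(
                pops, sim["n_loci"], sim["frac_adaptive"],
                sim["slope_range"], sim["pool_size_diploid"],
                sim["mean_coverage"], seed + 3)
            truth.trend = dict(sim["trend"])
            state.update(grid=grid, slices=slices, pops=pops, counts=counts,
                         truth=truth)
            grid.to_csv(outdir / "climate_baseline.csv")
            record("simulate", "climate_baseline", outdir / "climate_baseline.csv")
            long = pd.concat([s.to_long() for s in slices])
            long.to_csv(outdir / "climate_slices.csv", index=False)
            record("simulate", "climate_slices", outdir / "climate_slices.csv")
            pops.to_csv(outdir / "populations.csv")
            record("simulate", "populations", outdir / "populations.csv")
            truth.to_json(outdir / "truth.json")
            record("simulate", "truth", outdir / "truth.json")
        run_stage("simulate", _simulate)

    if "freqs" in stages:
        def _freqs():
            fq = cfg["freqs"]
            fm = counts_to_freqs(state["counts"], min_cov=fq["min_cov"])
            filtered, report = filter_chain(
                fm, pop_missing_max=fq["pop_missing_max"],
                locus_missing_max_pops=fq["locus_missing_max_pops"])
            state["freqs"] = filtered
            filtered.to_csv(outdir / "frequencies.csv")
            record("freqs", "frequencies", outdir / "frequencies.csv")
            report.to_json(outdir / "filter_report.json")
            record("freqs", "filter_report", outdir / "filter_report.json")
        run_stage("freqs", _freqs)

    if "reduce" in stages:
        def _reduce():
            rd = cfg["reduce"]
            pops = state["pops"].loc[state["freqs"].populations]
            env = pops.drop(columns=["cell", "x", "y"])
            retained = pearson_prune(env, r_max=rd["r_max"])
            env_red = env[retained]
            if rd["pcnm"]:
                basis = pcnm_vectors(pops[["x", "y"]])
                spatial = basis.select_half()
            else:
                spatial = pd.DataFrame(index=env.index)
            state["env"] = env_red
            state["spatial"] = spatial
            table = pd.concat([env_red, spatial], axis=1)
            table.to_csv(outdir / "predictors.csv")
            record("reduce", "predictors", outdir / "predictors.csv")
        run_stage("reduce", _reduce)

    if "fit" in stages:
        def _fit():
            ft = cfg["fit"]
            predictors = pd.concat([state["env"], state["spatial"]], axis=1)
            model = TurnoverForest(state["freqs"], predictors,
                                   n_trees=ft["n_trees"], n_bins=ft["bins"],
                                   spatial=list(state["spatial"].columns))
            results = model.fit(seed=seed + 4)
            state["results"] = results
            results.to_json(outdir / "turnover_model.json")
            record("fit", "turnover_model", outdir / "turnover_model.json")
            results.importance.to_csv(outdir / "importance.csv")
            record("fit", "importance", outdir / "importance.csv")
            cands = sorted(results.candidate_loci(ft["r2_min"]))
            (outdir / "gf_candidates.txt").write_text(
                "\n".join(cands) + ("\n" if cands else ""))
            record("fit", "gf_candidates", outdir / "gf_candidates.txt")
        run_stage("fit", _fit)

    if "offset" in stages:
        def _offset():
            results = state["results"]
            pops = state["pops"].loc[state["freqs"].populations]
            env_now = pops.drop(columns=["cell", "x", "y"])
            cells = pops["cell"].to_numpy()
            env_by_slice = {}
            for s in state["slices"]:
                sub = s.values.loc[cells]
                sub.index = env_now.index
                env_by_slice[s.label] = sub
            surf = offset_series(results, env_now, env_by_slice)
            state["offsets"] = surf
            surf.to_csv(outdir / "offsets.csv")
            record("offset", "offsets", outdir / "offsets.csv")
        run_stage("offset", _offset)

    if "revorate" in stages:
        def _revorate():
            rv = cfg["revorate"]
            series = discrete_revorate(state["offsets"].offsets,
                                       rv["midpoints"],
                                       rv["baseline_midpoint"])
            regimes = classify_series(series)
            series.to_csv(outdir / "rates.csv")
            record("revorate", "rates", outdir / "rates.csv")
            regimes.to_csv(outdir / "regimes.csv", index_label="unit")
            record("revorate", "regimes", outdir / "regimes.csv")
            state["rates"] = series
        run_stage("revorate", _revorate)

    if "map" in stages:
        def _map():
            mp = cfg["map"]
            results = state["results"]
            grid = state["grid"]
            transformed, _ = results.transform(
                grid.values, predictors=results.climate_predictors)
            rgb = rgb_projection(transformed)
            clusters = cluster_landscape(rgb, k_range=mp["k_range"],
                                         seed=seed + 5,
                                         n_restarts=mp["n_restarts"])
            out = pd.concat([grid.coords(), rgb.rgb,
                             clusters.labels.rename("cluster")], axis=1)
            out.to_csv(outdir / "landscape_map.csv", index_label="cell")
            record("map", "landscape_map", outdir / "landscape_map.csv")
            manifest["chosen_k"] = clusters.chosen_k
        run_stage("map", _map)

    manifest["input_digests"] = {
        name: _digest(Path(p))
        for stage in manifest["artifacts"].values()
        for name, p in stage.items()
        if Path(p).suffix in {".csv", ".txt", ".json"}
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
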