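"""One reproducible run of the whole spatial analysis chain.

Stages, in analysis order: simulate (or load) the survey; aggregate to
cluster features; build spatial weights; global Moran's I (analytic +
permutation); Gi* hotspot classification; Bernoulli spatial scan; OLS
exploratory search with the full diagnostic battery; GWR on the best model;
AICc model comparison.  Everything is driven by one config and one seed;
artifacts (CSV tables, GeoJSON layers, a JSON report) land in the output
directory and a repeated run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, cluster_stats, geo, gwr, regression, scan, synthetic
from .weights import build_weights

log = logging.getLogger("spatepi.pipeline")


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class PipelineConfig:
    # inputs: either paths or a simulation config
    individuals_csv: str | None = None
    locations_path: str | None = None
    simulate: bool = True
    n_clusters: int = 300
    seed: int = 0
    # analysis settings
    covariates: list = field(default_factory=lambda: [
        "community_poverty", "contraceptive_nonuse",
        "traditional_contraceptive", "secondary_education"])
    weights_method: str = "distance_band"
    weights_band_km: float | None = None      # None -> minimum connecting band
    row_standardize: bool = True
    moran_permutations: int = 999
    hotspot_thresholds: tuple = (1.645, 1.96, 2.576)
    scan_max_fraction: float = 0.5
    scan_reps: int = 999
    gwr_kernel: str = "bisquare"
    gwr_adaptive: bool = True
    exploratory_max_size: int = 4
    out_dir: str = "spatepi_run"

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["hotspot_thresholds"] = list(d["hotspot_thresholds"])
        return d

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.hotspot_thresholds = tuple(cfg.hotspot_thresholds)
        return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Range checks; returns a list of problems (empty means valid)."""
    problems = []
    if not 0 < config.scan_max_fraction <= 0.5:
        problems.append(
            f"scan_max_fraction={config.scan_max_fraction}: the scan window "
            f"may cover at most 50% of the population")
    if config.scan_reps < 99:
        problems.append(f"scan_reps={config.scan_reps} < 99")
    if config.moran_permutations < 99:
        problems.append(f"moran_permutations={config.moran_permutations} < 99")
    t = config.hotspot_thresholds
    if not (len(t) == 3 and t[0] < t[1] < t[2]):
        problems.append(f"hotspot_thresholds={t} not strictly increasing")
    if config.seed < 0:
        problems.append(f"seed={config.seed} must be nonnegative")
    if config.n_clusters <= 0:
        problems.append(f"n_clusters={config.n_clusters} must be positive")
    if not config.simulate:
        for label, p in (("individuals_csv", config.individuals_csv),
                         ("locations_path", config.locations_path)):
            if p is None:
                problems.append(f"{label} required when simulate is off")
    return problems


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig, write_artifacts: bool = True) -> dict:
    """Execute every stage; returns the machine-readable run report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)

    t0 = _stage("input")
    if config.simulate:
        sim = synthetic.dhs_like_config(seed=config.seed,
                                        n_clusters=config.n_clusters)
        individuals, locations = synthetic.simulate_survey(sim)
    else:
        individuals = pd.read_csv(config.individuals_csv)
        locations = geo.read_locations(config.locations_path)

    _stage("aggregate")
    covs = [c for c in config.covariates if c in individuals.columns]
    feats = aggregation.build_cluster_features(individuals, locations,
                                               covariates=covs)
    regional = aggregation.regional_summary(individuals)

    _stage("weights")
    lon, lat = feats["lon"].to_numpy(), feats["lat"].to_numpy()
    ids = feats["cluster_id"].to_numpy()
    y = feats["outcome_proportion"].to_numpy()
    W = build_weights(lon, lat, ids=ids, method=config.weights_method,
                      param=config.weights_band_km,
                      row_standardize=config.row_standardize)
    W_star = build_weights(lon, lat, ids=ids, method=config.weights_method,
                           param=config.weights_band_km, include_self=True)

    _stage("moran")
    mor = cluster_stats.morans_i(y, W)
    mor.p_permutation = cluster_stats.moran_permutation(
        y, W, n_perm=config.moran_permutations, seed=config.seed)

    _stage("hotspots")
    gi = cluster_stats.getis_ord_gistar(y, W_star)
    cat_counts = pd.Series(gi.category).value_counts().to_dict()

    _stage("scan")
    clusters = scan.scan_mc(
        lon, lat, feats["cases"].to_numpy(), feats["population"].to_numpy(),
        ids=ids, max_fraction=config.scan_max_fraction,
        n_reps=config.scan_reps, seed=config.seed)

    _stage("ols")
    X_pool = feats[covs]
    search = regression.exploratory_search(
        X_pool, y, W, max_size=min(config.exploratory_max_size, len(covs)))
    if len(search):
        best = list(search.iloc[0]["predictors"])
    else:
        best = covs  # no subset passed every gate; report the full model
    ols_res = regression.fit_ols(feats[best], y)

    _stage("gwr")
    bw, _trace = gwr.select_bandwidth(
        feats[best], y, lon, lat, kernel=config.gwr_kernel,
        adaptive=config.gwr_adaptive)
    gwr_res = gwr.fit_gwr(feats[best], y, lon, lat, bw,
                          kernel=config.gwr_kernel,
                          adaptive=config.gwr_adaptive)

    verdict = gwr.compare_models(ols_res.aicc, gwr_res.aicc,
                                 labels=("ols", "gwr"))

    report = {
        "config": config.to_dict(),
        "n_clusters": int(len(feats)),
        "n_individuals": int(len(individuals)),
        "moran": {
            "I": mor.I, "expected_I": mor.expected_I, "z": mor.z,
            "p_analytic": mor.p_analytic, "p_permutation": mor.p_permutation,
        },
        "hotspots": {k: int(v) for k, v in sorted(cat_counts.items())},
        "scan": [dataclasses.asdict(c) for c in clusters],
        "ols": {
            "predictors": best,
            "all_gates_passed": bool(len(search)),
            "coefficients": json.loads(
                ols_res.coefficient_table().to_json(orient="records")),
            "diagnostics": {
                "n": ols_res.n, "r2": ols_res.r2, "adj_r2": ols_res.adj_r2,
                "aicc": ols_res.aicc,
                "joint_f": ols_res.f_stat, "joint_f_p": ols_res.f_p,
                "joint_wald": ols_res.wald_stat, "joint_wald_p": ols_res.wald_p,
                "koenker_bp": ols_res.koenker_stat, "koenker_p": ols_res.koenker_p,
                "jarque_bera": ols_res.jb_stat, "jarque_bera_p": ols_res.jb_p,
            },
        },
        "gwr": gwr_res.summary(),
        "model_comparison": {
            "aicc_ols": ols_res.aicc, "aicc_gwr": gwr_res.aicc,
            "delta": abs(ols_res.aicc - gwr_res.aicc), "preferred": verdict,
        },
    }
    log.info("pipeline done in %.1fs", time.time() - t0)

    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        feats.to_csv(out / "cluster_features.csv", index=False)
        regional.to_csv(out / "regional_summary.csv", index=False)
        geo.write_geojson(geo.points_to_geojson(feats), out / "cluster_features.geojson")
        hot = feats[["cluster_id", "lon", "lat"]].copy()
        hot["z"], hot["p"], hot["category"] = gi.z, gi.p, gi.category
        geo.write_geojson(geo.points_to_geojson(hot), out / "hotspots.geojson")
        for name, layer in gwr.coefficient_surfaces(gwr_res, lon, lat, ids).items():
            geo.write_geojson(layer, out / f"gwr_surface_{name}.geojson")
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2, allow_nan=True,
                       default=_json_default) + "\n")
    return report
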