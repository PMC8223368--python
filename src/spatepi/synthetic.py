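"""Synthetic DHS-like surveys with known spatial structure.

The generator emulates a two-stage cluster survey of teenagers: cluster
(enumeration-area) GPS points scattered over a bounding box, a handful of
teenagers per cluster, a binary pregnancy-like outcome drawn from an
individual-level logistic model whose intercept and covariate effects are
spatial surfaces, binary community covariates, log-normal sampling weights
rescaled to mean one, and the DHS confidentiality displacement of cluster
coordinates (urban points jittered up to 2 km, rural up to 5 km).  Because
every surface is known, downstream stages (hotspots, scan, OLS, GWR) can be
tested against ground truth.

All randomness flows from a single seed through named ``SeedSequence``
spawns, so identical (config, seed) pairs reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weights import EARTH_RADIUS_KM, haversine_km

#: Ethiopia-like bounding box (lon_min, lat_min, lon_max, lat_max), degrees
DEFAULT_DOMAIN = (33.0, 3.4, 48.0, 14.9)

#: urban share of enumeration areas in the emulated sampling frame (202/645)
DEFAULT_URBAN_FRACTION = 202 / 645


@dataclass
class SurfaceSpec:
    """A real-valued surface over the spatial domain.

    kinds
    -----
    constant        params: value
    linear-gradient params: base, slope=(per-deg-lon, per-deg-lat),
                    origin=(lon0, lat0) (default (0, 0))
    gaussian-bump   params: amplitude, center=(lon, lat), scale_km, base=0
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __call__(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if self.kind == "constant":
            return np.full(np.broadcast(lon, lat).shape, float(self.params["value"]))
        if self.kind == "linear-gradient":
            a, b = self.params["slope"]
            lon0, lat0 = self.params.get("origin", (0.0, 0.0))
            return (self.params.get("base", 0.0)
                    + a * (lon - lon0) + b * (lat - lat0))
        if self.kind == "gaussian-bump":
            clon, clat = self.params["center"]
            d = haversine_km(lon, lat, clon, clat)
            scale = float(self.params["scale_km"])
            return (self.params.get("base", 0.0)
                    + self.params["amplitude"] * np.exp(-0.5 * (d / scale) ** 2))
        raise ValueError(f"unknown surface kind {self.kind!r}")


@dataclass
class SimulationConfig:
    n_clusters: int = 617
    teens_per_cluster: tuple = (2, 10)        # inclusive range, or an int
    spatial_domain: tuple = DEFAULT_DOMAIN
    intercept_surface: SurfaceSpec = field(
        default_factory=lambda: SurfaceSpec("constant", {"value": -1.9}))
    covariate_effects: list = field(default_factory=list)   # (name, SurfaceSpec)
    covariate_prevalence: dict = field(default_factory=dict)  # name -> p or SurfaceSpec
    weight_sigma: float = 0.25                # log-normal sigma; mean rescaled to 1
    urban_fraction: float = DEFAULT_URBAN_FRACTION
    displacement: bool = True
    seed: int = 0

    def validate(self):
        lo, la, hi, ha = self.spatial_domain
        if self.n_clusters <= 0:
            raise ValueError("n_clusters must be positive")
        if hi <= lo or ha <= la:
            raise ValueError("degenerate bounding box")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValueError("urban_fraction outside [0, 1]")
        for name, p in self.covariate_prevalence.items():
            if not isinstance(p, SurfaceSpec) and not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        for name, _ in self.covariate_effects:
            if name not in self.covariate_prevalence:
                raise ValueError(f"covariate {name!r} has an effect but no prevalence")


_STREAMS = ("locations", "urban", "teens", "covariates", "outcome",
            "weights", "split", "displacement")


def _rngs(seed):
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _region_label(lon, lat, domain):
    """Coarse 3 x 2 grid of region labels over the bounding box."""
    lo, la, hi, ha = domain
    cx = np.minimum((np.asarray(lon) - lo) / (hi - lo) * 3, 2.999).astype(int)
    cy = np.minimum((np.asarray(lat) - la) / (ha - la) * 2, 1.999).astype(int)
    idx = cy * 3 + cx + 1
    return np.array([f"region_{i}" for i in idx])


def simulate_survey(config: SimulationConfig):
    """Draw one survey; returns (individual table, cluster location table).

    Individuals: cluster_id, region, weight, births_before_19,
    currently_pregnant, outcome, one 0/1 column per covariate.
    Locations: cluster_id, lon, lat, urban (coordinates displaced when
    ``config.displacement`` is on; the raw coordinates used to generate the
    data are in lon_true/lat_true).
    """
    config.validate()
    rng = _rngs(config.seed)
    nc = config.n_clusters
    lo, la, hi, ha = config.spatial_domain

    lon = rng["locations"].uniform(lo, hi, nc)
    lat = rng["locations"].uniform(la, ha, nc)
    urban = rng["urban"].random(nc) < config.urban_fraction

    tpc = config.teens_per_cluster
    if np.isscalar(tpc):
        n_teens = np.full(nc, int(tpc))
    else:
        n_teens = rng["teens"].integers(int(tpc[0]), int(tpc[1]) + 1, nc)
    total = int(n_teens.sum())
    cluster_of = np.repeat(np.arange(nc), n_teens)

    cov_names = list(config.covariate_prevalence)
    covs = {}
    for name in cov_names:
        p = config.covariate_prevalence[name]
        pv = p(lon, lat) if isinstance(p, SurfaceSpec) else np.full(nc, float(p))
        pv = np.clip(pv, 0.0, 1.0)
        covs[name] = (rng["covariates"].random(total) < pv[cluster_of]).astype(int)

    eta = config.intercept_surface(lon, lat)[cluster_of]
    for name, surf in config.covariate_effects:
        eta = eta + surf(lon, lat)[cluster_of] * covs[name]
    p_outcome = 1.0 / (1.0 + np.exp(-eta))
    outcome = (rng["outcome"].random(total) < p_outcome).astype(int)

    # split the composite outcome into its two source flags: a positive is
    # currently pregnant (no birth yet) ~15% of the time, else a past birth
    currently = (rng["split"].random(total) < 0.15).astype(int) * outcome
    births = outcome * (1 - currently)

    w = rng["weights"].lognormal(0.0, config.weight_sigma, total)
    w = w / w.mean()

    individuals = pd.DataFrame({
        "cluster_id": cluster_of,
        "region": _region_label(lon, lat, config.spatial_domain)[cluster_of],
        "weight": w,
        "births_before_19": births,
        "currently_pregnant": currently,
        "outcome": outcome,
        **{name: covs[name] for name in cov_names},
    })

    out_lon, out_lat = lon, lat
    if config.displacement:
        out_lon, out_lat = _displace(lon, lat, urban,
                                     rng["displacement"])
    locations = pd.DataFrame({
        "cluster_id": np.arange(nc),
        "lon": out_lon,
        "lat": out_lat,
        "urban": urban.astype(int),
        "lon_true": lon,
        "lat_true": lat,
    })
    return individuals, locations


def _displace(lon, lat, urban, rng, urban_max_km=2.0, rural_max_km=5.0):
    n = lon.size
    max_d = np.where(urban, urban_max_km, rural_max_km)
    d = rng.uniform(0.0, 1.0, n) * max_d
    bearing = rng.uniform(0.0, 2.0 * np.pi, n)
    # exact great-circle destination on the sphere
    phi1 = np.radians(lat)
    lmb1 = np.radians(lon)
    delta = d / EARTH_RADIUS_KM
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta)
                     + np.cos(phi1) * np.sin(delta) * np.cos(bearing))
    lmb2 = lmb1 + np.arctan2(
        np.sin(bearing) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    return np.degrees(lmb2), np.degrees(phi2)


def apply_displacement(locations: pd.DataFrame, urban_flags=None,
                       seed: int | None = None) -> pd.DataFrame:
    """DHS confidentiality displacement of cluster coordinates.

    Urban points move a uniform random distance in (0, 2] km, rural points
    in (0, 5] km, at a uniform random bearing.  Returns a new table; the
    input is untouched.
    """
    if urban_flags is None:
        urban_flags = locations["urban"].to_numpy()
    urban_flags = np.asarray(urban_flags).astype(bool)
    if len(urban_flags) != len(locations):
        raise ValueError(f"{len(urban_flags)} urban flags for "
                         f"{len(locations)} locations")
    rng = np.random.default_rng(seed)
    out = locations.copy()
    new_lon, new_lat = _displace(locations["lon"].to_numpy(dtype=float),
                                 locations["lat"].to_numpy(dtype=float),
                                 urban_flags, rng)
    out["lon"] = new_lon
    out["lat"] = new_lat
    return out


def true_coefficient_field(config: SimulationConfig, locations) -> pd.DataFrame:
    """Evaluate every configured surface at every cluster location."""
    lon = np.asarray(locations["lon"], dtype=float)
    lat = np.asarray(locations["lat"], dtype=float)
    out = {"cluster_id": np.asarray(locations["cluster_id"]),
           "intercept": config.intercept_surface(lon, lat)}
    for name, surf in config.covariate_effects:
        out[name] = surf(lon, lat)
    return pd.DataFrame(out)


def dhs_like_config(seed: int = 0, n_clusters: int = 617) -> SimulationConfig:
    """Study-conditions default: four community covariates with spatially
    varying effects over an Ethiopia-like domain.

    Covariates mirror the community variables used for teenage pregnancy:
    poverty (two lowest wealth quintiles), contraceptive non-use,
    traditional contraceptive use and secondary education; the south-east of
    the domain carries elevated baseline risk so hotspot and scan stages
    have a planted signal.
    """
    lo, la, hi, ha = DEFAULT_DOMAIN
    return SimulationConfig(
        n_clusters=n_clusters,
        intercept_surface=SurfaceSpec(
            "gaussian-bump",
            {"amplitude": 1.2, "center": (44.0, 7.0), "scale_km": 400.0,
             "base": -2.2}),
        covariate_effects=[
            ("community_poverty",
             SurfaceSpec("linear-gradient",
                         {"base": 0.8, "slope": (0.04, 0.0),
                          "origin": ((lo + hi) / 2, (la + ha) / 2)})),
            ("contraceptive_nonuse", SurfaceSpec("constant", {"value": 0.9})),
            ("traditional_contraceptive", SurfaceSpec("constant", {"value": 0.5})),
            ("secondary_education",
             SurfaceSpec("linear-gradient",
                         {"base": -0.7, "slope": (0.0, -0.03),
                          "origin": ((lo + hi) / 2, (la + ha) / 2)})),
        ],
        covariate_prevalence={
            "community_poverty": 0.4,
            "contraceptive_nonuse": 0.65,
            "traditional_contraceptive": 0.1,
            "secondary_education": 0.25,
        },
        seed=seed,
    )
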