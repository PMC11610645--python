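"""One-call orchestration of the full analysis.

``run(config)`` executes simulate → buffers → scale scan → protection-zone
comparison → nitrate models → final presence model → sampled-vs-random
site comparison, writing every table as CSV plus text reports and a
manifest, all reproducible from the single master seed.

Per-stage seeds are derived from the master seed by a fixed counter
scheme, ``SeedSequence([master, stage_index])``, so any stage can be
rerun in isolation; the manifest records every derived seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, scale_scan, site_stats, spatial
from .buffers import compute_proportions_table
from .errors import ConfigurationError
from .rasters import CLASS_CODES, write_ascii_grid, write_class_map
from .site_stats import forest_agriculture_gradient
from .synthetic import (
    LandscapeConfig,
    TruthConfig,
    generate_dem,
    generate_landuse,
    place_sites,
    simulate_covariates,
    simulate_nitrate,
    simulate_presence,
    simulate_protection_zones,
)

log = logging.getLogger(__name__)

#: stage name -> index in the seed-derivation scheme
STAGES = ("landscape", "sites", "presence", "nitrate", "zones", "covariates",
          "scan", "random_sites")


def stage_seed(master: int, stage: str) -> int:
    """Derived per-stage seed: ``SeedSequence([master, stage_index])``."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything one end-to-end synthetic run needs."""

    out_dir: str = "stygoscale_run"
    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    sizes: tuple = (50, 100, 200, 400, 600, 800, 1000)
    buffer_types: tuple = ("round", "catchment")
    drop_m: float = 5.0
    gap_m: float = 50.0
    scan_classes: tuple = ("forest", "pasture", "crop")
    scan_frac: float = 0.7
    scan_reps: int = 1000
    model_size: float = 600.0
    model_buffer_type: str = "catchment"
    nitrate_fraction: float = 0.5
    n_random_sites: int | None = None
    scale_interval: tuple | None = None
    write_rasters: bool = False

    def validate(self) -> None:
        self.landscape.validate()
        self.truth.validate()
        if not self.sizes:
            raise ConfigurationError("at least one buffer size required")
        if self.model_size not in self.sizes:
            raise ConfigurationError("model_size must be one of the scan sizes")
        if not 0 < self.scan_frac < 1:
            raise ConfigurationError("scan_frac must lie in (0, 1)")
        if not 0 <= self.nitrate_fraction <= 1:
            raise ConfigurationError("nitrate_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "landscape" in raw:
            raw["landscape"] = LandscapeConfig(**raw["landscape"])
        if "truth" in raw:
            raw["truth"] = TruthConfig(**raw["truth"])
        for key in ("sizes", "buffer_types", "scan_classes", "scale_interval"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("sizes", "buffer_types", "scan_classes", "scale_interval"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # identical science, different folder: same hash
    canonical = json.dumps(d, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of the key results.

    Writes to ``config.out_dir``: ``sites.csv``, ``proportions.csv``,
    ``scan.csv``, ``profile.csv``, ``zone_summary.txt``,
    ``nitrate_models.csv`` + report, ``presence_model.txt`` + CSV,
    ``site_comparison.csv``, and ``manifest.json``.  Identical configs
    yield byte-identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.seed
    seeds = {stage: stage_seed(master, stage) for stage in STAGES}
    results: dict = {}

    # --- stage 1: landscape -------------------------------------------
    landscape = dataclasses.replace(config.landscape, seed=seeds["landscape"])
    dem = generate_dem(landscape)
    landuse = generate_landuse(landscape)
    if config.write_rasters:
        write_ascii_grid(dem, out / "dem.asc")
        write_ascii_grid(landuse, out / "landuse.asc", fmt="%d")
        write_class_map({v: k for k, v in CLASS_CODES.items()},
                        out / "landuse_classes.txt")

    # --- stage 2: sites and responses ---------------------------------
    truth = dataclasses.replace(config.truth, seed=seeds["presence"])
    margin = max(max(config.sizes), truth.true_scale) + landscape.resolution
    sites = place_sites(truth.n_sites, dem, truth.min_spacing,
                        seed=seeds["sites"], edge_margin=margin)
    sites = simulate_presence(sites, dem, landuse, truth)
    nit_truth = dataclasses.replace(truth, seed=seeds["nitrate"])
    nitrate = simulate_nitrate(sites, dem, landuse, nit_truth)
    rng_nit = np.random.default_rng(seeds["nitrate"])
    has_nitrate = rng_nit.uniform(size=len(sites)) < config.nitrate_fraction
    sites["nitrate_mg_l"] = np.where(
        has_nitrate, nitrate["nitrate_mg_l"].to_numpy(), np.nan)
    sites["zone_extent_m"] = simulate_protection_zones(
        len(sites), truth.zone_median, truth.zone_log_sd, seed=seeds["zones"])
    covariates = simulate_covariates(sites, seed=seeds["covariates"])
    site_cols = ["site_id", "x", "y", "elevation_m", "presence",
                 "nitrate_mg_l", "zone_extent_m"]
    sites[site_cols].to_csv(out / "sites.csv", index=False)

    # --- stage 3: buffers ---------------------------------------------
    proportions = compute_proportions_table(
        sites, dem, landuse, sizes=config.sizes,
        buffer_types=config.buffer_types, drop_m=config.drop_m,
        gap_m=config.gap_m)
    proportions.to_csv(out / "proportions.csv", index=False)

    # --- stage 4: scale scan ------------------------------------------
    cells = scale_scan.scan(
        sites, proportions, sizes=config.sizes,
        buffer_types=config.buffer_types, classes=config.scan_classes,
        frac=config.scan_frac, reps=config.scan_reps, seed=seeds["scan"])
    cells.to_csv(out / "scan.csv", index=False)
    if len(config.sizes) >= 2:
        peak, profile = scale_scan.peak_scale(cells)
    else:  # a single-size run has nothing to rank
        peak = float(config.sizes[0])
        grp = cells.groupby("size_m")["pseudo_r2"]
        profile = pd.DataFrame({
            "size_m": list(grp.groups), "mean_r2": grp.mean().to_numpy(),
            "sd_of_mean": (grp.std(ddof=1) / np.sqrt(grp.count())).to_numpy(),
            "n_combos": grp.count().to_numpy()})
    profile.to_csv(out / "profile.csv", index=False)
    results["peak_scale_m"] = float(peak)

    # --- stage 5: protection zones ------------------------------------
    if config.scale_interval is not None:
        interval = config.scale_interval
    else:
        # sizes whose mean pseudo-R2 is within 90% of the peak value
        near = profile[profile["mean_r2"] >= 0.9 * profile["mean_r2"].max()]
        interval = (float(near["size_m"].min()), float(near["size_m"].max()))
    zs = scale_scan.zone_summary(sites["zone_extent_m"].to_numpy(), interval)
    with open(out / "zone_summary.txt", "w") as fh:
        fh.write(f"n_zones {zs.n_zones}\n")
        fh.write(f"median_extent_m {zs.median_extent:.1f}\n")
        fh.write(f"scale_interval_m {interval[0]:.0f} {interval[1]:.0f}\n")
        fh.write(f"fraction_below_interval {zs.fraction_below:.3f}\n")
        fh.write(f"fold_range {zs.fold_range[0]:.2f} {zs.fold_range[1]:.2f}\n")
    results["zone_summary"] = zs
    results["scale_interval"] = interval

    # --- stage 6: nitrate models --------------------------------------
    nitrate_fits = spatial.nitrate_models(
        sites, proportions, size=config.model_size,
        buffer_type=config.model_buffer_type)
    nit_rows = []
    for cls, fit in nitrate_fits.items():
        row = fit.terms.loc[cls]
        nit_rows.append({
            "class": cls, "estimate": row.estimate, "se": row.se,
            "ci_low": row.ci_low, "ci_high": row.ci_high, "p": row.p,
            "nu": fit.matern.nu, "rho": fit.matern.rho,
            "lambda": fit.matern.lam, "n": fit.n_obs,
            "converged": fit.converged,
        })
    pd.DataFrame(nit_rows).to_csv(out / "nitrate_models.csv", index=False)
    with open(out / "nitrate_models.txt", "w") as fh:
        for cls, fit in nitrate_fits.items():
            fh.write(spatial.format_fit_report(
                fit, f"Nitrate ~ {cls} (Gamma, log link)") + "\n\n")
    results["nitrate_fits"] = nitrate_fits

    # --- stage 7: final presence model --------------------------------
    prop_model = proportions[
        (proportions["size_m"] == config.model_size)
        & (proportions["buffer_type"] == config.model_buffer_type)
    ].pivot(index="site_id", columns="class", values="proportion")
    grad = forest_agriculture_gradient(
        prop_model["forest"], prop_model["pasture"], prop_model["crop"])
    cov = covariates.set_index("site_id")
    cov.insert(0, "land_use", pd.Series(grad, index=prop_model.index))
    cov = cov.dropna(subset=["land_use"]).reset_index()
    selected, trace, full = spatial.final_presence_model(sites, cov)
    with open(out / "presence_model.txt", "w") as fh:
        fh.write(spatial.format_fit_report(
            selected, "Amphipod presence (binomial, logit) - selected model"))
        fh.write("\n\nBackward-AIC elimination trace:\n")
        for step in trace:
            fh.write(f"  step {step['step']}: dropped={step['dropped']} "
                     f"AIC={step['aic']:.2f} terms={step['terms']}\n")
    selected.terms.to_csv(out / "presence_model.csv")
    results["presence_fit"] = selected
    results["presence_trace"] = trace

    # --- stage 8: sampled-vs-random comparison ------------------------
    n_random = config.n_random_sites or len(sites)
    bounds = (dem.origin_x + margin, dem.origin_y + margin,
              dem.origin_x + dem.width - margin,
              dem.origin_y + dem.height - margin)
    random_sites = site_stats.generate_random_sites(
        bounds, n_random, seed=seeds["random_sites"])
    random_props = compute_proportions_table(
        random_sites, dem, landuse, sizes=(config.model_size,),
        buffer_types=(config.model_buffer_type,), drop_m=config.drop_m,
        gap_m=config.gap_m)
    sampled_props = proportions[
        (proportions["size_m"] == config.model_size)
        & (proportions["buffer_type"] == config.model_buffer_type)
    ]
    comparison = site_stats.compare_compositions(sampled_props, random_props)
    comparison.to_csv(out / "site_comparison.csv", index=False)
    results["comparison"] = comparison

    # --- manifest ------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stage_seeds": seeds,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
        "peak_scale_m": results["peak_scale_m"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
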