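"""Synthetic landscapes, sites, and responses with known ground truth.

Every downstream stage (buffers, scale scan, spatial models, site
comparison) is exercised on landscapes generated here, so the true scale
of effect, the true regression slopes, and the true protection-zone
distribution are all known quantities.

Landscapes are Gaussian random fields: smoothed white noise with a
Gaussian kernel whose bandwidth (in meters) sets the spatial correlation
length.  The land-use mosaic slices a second, independent field at rank
quantiles matching the requested class proportions, which yields
contiguous patches with exactly controlled composition.

Responses follow the generative models of the analysis itself:

* presence/absence — Bernoulli with logit probability linear in the
  forest percentage within the buffer of the *true* radius and type;
* nitrate — Gamma with log-link mean linear in crop and forest
  percentages;
* protection-zone extents — log-normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .buffers import BufferSpec, extract_proportions, make_buffer
from .errors import ConfigurationError, GenerationError
from .rasters import CLASS_CODES, CLASSES, Raster

log = logging.getLogger(__name__)

#: Default land-use composition of the synthetic mosaic (fractions).
DEFAULT_PROPORTIONS = {
    "forest": 0.30,
    "pasture": 0.20,
    "crop": 0.20,
    "construction": 0.15,
    "other": 0.15,
}


@dataclass
class LandscapeConfig:
    """Geometry and texture of one synthetic landscape.

    The default grid is 1500 x 1500 cells at 10 m resolution (15 x 15 km),
    large enough that multi-kilometer buffers fit around interior sites.
    """

    nx: int = 1500
    ny: int = 1500
    resolution: float = 10.0
    dem_amplitude: float = 50.0
    dem_corr_length: float = 1000.0
    landuse_corr_length: float = 200.0
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    seed: int = 0

    def validate(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.dem_corr_length <= 0 or self.landuse_corr_length <= 0:
            raise ConfigurationError("correlation lengths must be positive")
        if set(self.class_proportions) != set(CLASSES):
            raise ConfigurationError(
                f"class_proportions must cover exactly {CLASSES}"
            )
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class proportions sum to {total}, not 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ConfigurationError("class proportions must be non-negative")


@dataclass
class TruthConfig:
    """Ground truth of the simulated study.

    ``true_scale`` and ``true_buffer_type`` define the buffer whose forest
    percentage drives presence.  Logit slopes are per percentage point of
    coverage; nitrate slopes likewise, on the log scale.  Zone extents are
    log-normal with the given median; ``zone_log_sd`` 0.46 places about
    two thirds of extents below 400 m when the median is 327 m.
    """

    true_scale: float = 600.0
    true_buffer_type: str = "catchment"
    beta0: float = -2.5
    beta_forest: float = 0.06
    nitrate_intercept: float = math.log(15.0)
    nitrate_beta_crop: float = 0.015
    nitrate_beta_forest: float = -0.0070
    nitrate_shape: float = 5.0
    zone_median: float = 327.0
    zone_log_sd: float = 0.46
    n_sites: int = 300
    min_spacing: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 10:
            raise ConfigurationError("n_sites must be at least 10")
        if self.zone_median <= 0:
            raise ConfigurationError("zone_median must be positive")
        if self.nitrate_shape <= 0:
            raise ConfigurationError("Gamma shape must be positive")
        if self.true_buffer_type not in ("round", "catchment"):
            raise ConfigurationError("true_buffer_type must be round or catchment")


def _gaussian_field(ny, nx, sigma_cells, rng):
    """Unit-variance Gaussian random field via kernel-smoothed white noise."""
    noise = rng.standard_normal((ny, nx))
    if sigma_cells > 0:
        fieldv = ndimage.gaussian_filter(noise, sigma_cells, mode="wrap")
    else:
        fieldv = noise
    sd = fieldv.std()
    if sd > 0:
        fieldv = (fieldv - fieldv.mean()) / sd
    return fieldv


def generate_dem(cfg: LandscapeConfig) -> Raster:
    """Spatially autocorrelated elevation surface.

    Elevations are a Gaussian random field scaled to ``dem_amplitude``
    (the field's standard deviation in meters) with correlation length set
    by ``dem_corr_length``.  ``dem_amplitude=0`` gives a flat raster.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    sigma = cfg.dem_corr_length / cfg.resolution
    fieldv = _gaussian_field(cfg.ny, cfg.nx, sigma, rng)
    return Raster(fieldv * cfg.dem_amplitude, cfg.resolution)


#: Quantile-band order of the mosaic slicing, from low to high field value.
#: Forest sits at one end and the agricultural classes (pasture, crop) at
#: the other, so agriculture jointly displaces forest across the mosaic —
#: the forest-agriculture opposition that structures real extraction-site
#: landscapes (and the ternary gradient built on it).
BAND_ORDER = ("forest", "other", "construction", "pasture", "crop")


def generate_landuse(cfg: LandscapeConfig) -> Raster:
    """5-class land-use mosaic with controlled composition and patch size.

    An independent Gaussian field is sliced at rank quantiles (band order
    :data:`BAND_ORDER`) so the realized class fractions match
    ``class_proportions`` to within one cell.  Patch diameter scales with
    ``landuse_corr_length``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    sigma = cfg.landuse_corr_length / cfg.resolution
    fieldv = _gaussian_field(cfg.ny, cfg.nx, sigma, rng)
    flat = fieldv.ravel()
    order = np.argsort(flat, kind="stable")
    ncells = flat.size
    fracs = np.array([cfg.class_proportions[c] for c in BAND_ORDER])
    bounds = np.round(np.cumsum(fracs) * ncells).astype(int)
    codes = np.empty(ncells, dtype=np.uint8)
    start = 0
    for cls, stop in zip(BAND_ORDER, bounds):
        codes[order[start:stop]] = CLASS_CODES[cls]
        start = stop
    codes[order[start:]] = CLASS_CODES[BAND_ORDER[-1]]  # rounding remainder
    return Raster(codes.reshape(cfg.ny, cfg.nx), cfg.resolution)


def place_sites(
    n: int,
    dem: Raster,
    min_spacing: float = 200.0,
    seed: int = 0,
    edge_margin: float | None = None,
    max_tries: int = 200,
) -> pd.DataFrame:
    """Random site locations with a minimum pairwise spacing.

    Sites snap to cell centers; elevation is the DEM value at the cell.
    When feasible, all sites keep ``edge_margin`` meters (one largest
    buffer radius) from the grid edge; otherwise sites near the edge are
    flagged ``edge_flag=True``.  Raises :class:`GenerationError` when the
    packing is infeasible after bounded retries.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    if edge_margin is None:
        edge_margin = 0.0
    margin = edge_margin
    # feasibility heuristic: each site excludes a disk of radius spacing/2
    usable_w = dem.width - 2 * margin
    usable_h = dem.height - 2 * margin
    if usable_w <= 0 or usable_h <= 0 or (
        n * math.pi * (min_spacing / 2) ** 2 > 0.7 * usable_w * usable_h
    ):
        log.warning("edge margin %g m infeasible for %d sites; flagging instead",
                    margin, n)
        margin = 0.0
        usable_w, usable_h = dem.width, dem.height

    xs, ys = [], []
    for _ in range(max_tries):
        need = n - len(xs)
        if need == 0:
            break
        cand_x = rng.uniform(dem.origin_x + margin,
                             dem.origin_x + dem.width - margin, size=4 * need)
        cand_y = rng.uniform(dem.origin_y + margin,
                             dem.origin_y + dem.height - margin, size=4 * need)
        for x, y in zip(cand_x, cand_y):
            # snap to cell center
            row, col = dem.cell_at(x, y)
            x, y = dem.cell_center(row, col)
            x, y = float(x), float(y)
            if xs:
                d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
                if min_spacing > 0 and d2.min() < min_spacing**2:
                    continue
                if d2.min() == 0.0:  # same cell twice
                    continue
            xs.append(x)
            ys.append(y)
            if len(xs) == n:
                break
    if len(xs) < n:
        raise GenerationError(
            f"could not place {n} sites with spacing {min_spacing} m "
            f"after {max_tries} rounds (placed {len(xs)})"
        )
    xs = np.array(xs)
    ys = np.array(ys)
    rows_cols = [dem.cell_at(x, y) for x, y in zip(xs, ys)]
    elev = np.array([dem.values[r, c] for r, c in rows_cols])
    edge_flag = (
        (xs - dem.origin_x < edge_margin)
        | (dem.origin_x + dem.width - xs < edge_margin)
        | (ys - dem.origin_y < edge_margin)
        | (dem.origin_y + dem.height - ys < edge_margin)
    )
    return pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n)],
            "x": xs,
            "y": ys,
            "elevation_m": elev,
            "edge_flag": edge_flag,
        }
    )


def true_buffer_forest_pct(sites, dem, landuse, truth: TruthConfig) -> np.ndarray:
    """Forest percentage (0-100) within each site's true-scale buffer.

    Sites whose true buffer leaves the raster get NaN.
    """
    spec = BufferSpec(truth.true_scale, truth.true_buffer_type)
    out = np.full(len(sites), np.nan)
    for i, site in enumerate(sites.itertuples(index=False)):
        region = make_buffer(site.x, site.y, spec, dem, site_id=site.site_id)
        if region.truncated:
            continue
        out[i] = extract_proportions(region, landuse).forest * 100.0
    return out


def simulate_presence(sites, dem, landuse, truth: TruthConfig) -> pd.DataFrame:
    """Bernoulli presence with logit-linear dependence on true-buffer forest %.

    Returns a copy of ``sites`` with columns ``forest_pct_true`` and
    ``presence``; sites whose true buffer leaves the raster are excluded
    (with a logged count).
    """
    truth.validate()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 4]))
    forest_pct = true_buffer_forest_pct(sites, dem, landuse, truth)
    keep = ~np.isnan(forest_pct)
    if (~keep).any():
        log.warning("%d sites dropped: true buffer leaves the raster",
                    int((~keep).sum()))
    out = sites.loc[keep].copy().reset_index(drop=True)
    fp = forest_pct[keep]
    eta = truth.beta0 + truth.beta_forest * fp
    p = 1.0 / (1.0 + np.exp(-eta))
    out["forest_pct_true"] = fp
    out["presence"] = (rng.uniform(size=len(out)) < p).astype(int)
    return out


def simulate_nitrate(sites, dem, landuse, truth: TruthConfig) -> pd.DataFrame:
    """Gamma-distributed nitrate (mg/L) with log-link land-use dependence.

    mean = exp(intercept + beta_crop * crop% + beta_forest * forest%) over
    the true-scale buffer; draws are Gamma(shape, scale=mean/shape).
    """
    truth.validate()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 5]))
    spec = BufferSpec(truth.true_scale, truth.true_buffer_type)
    crop_pct = np.full(len(sites), np.nan)
    forest_pct = np.full(len(sites), np.nan)
    for i, site in enumerate(sites.itertuples(index=False)):
        region = make_buffer(site.x, site.y, spec, dem, site_id=site.site_id)
        if region.truncated:
            continue
        props = extract_proportions(region, landuse)
        crop_pct[i] = props.crop * 100.0
        forest_pct[i] = props.forest * 100.0
    keep = ~np.isnan(crop_pct)
    out = sites.loc[keep].copy().reset_index(drop=True)
    mean = np.exp(
        truth.nitrate_intercept
        + truth.nitrate_beta_crop * crop_pct[keep]
        + truth.nitrate_beta_forest * forest_pct[keep]
    )
    out["crop_pct_true"] = crop_pct[keep]
    out["forest_pct_true"] = forest_pct[keep]
    out["nitrate_mg_l"] = rng.gamma(truth.nitrate_shape,
                                    mean / truth.nitrate_shape)
    return out


def simulate_protection_zones(
    n: int, zone_median: float = 327.0, zone_log_sd: float = 0.46, seed: int = 0
) -> np.ndarray:
    """Log-normal protection-zone extents (m) with the given median."""
    if zone_median <= 0:
        raise ConfigurationError("zone_median must be positive")
    if zone_log_sd < 0:
        raise ConfigurationError("zone_log_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    return np.exp(rng.normal(math.log(zone_median), zone_log_sd, size=n))


def simulate_covariates(sites: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Synthetic environmental covariates for the final presence model.

    Stand-ins for the study's altitude, aquifer-distance, and glaciation
    covariates: altitude is the site elevation; the others are noise with
    realistic marginals (log-normal distances in m, a binary glaciation
    indicator, a positive glacier-cover time in ka).  None of them affect
    the simulated presence, so a correct selection keeps only land use.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    n = len(sites)
    return pd.DataFrame(
        {
            "site_id": sites["site_id"].to_numpy(),
            "altitude": sites["elevation_m"].to_numpy() + 700.0,
            "dist_karst": np.exp(rng.normal(8.0, 1.0, n)),
            "dist_unconsolidated": np.exp(rng.normal(6.0, 1.0, n)),
            "glaciation_lgm": rng.integers(0, 2, n).astype(float),
            "glacier_cover_ka": rng.uniform(0.0, 60.0, n),
        }
    )
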