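"""Round and topography-restricted catchment buffers.

Two buffer families are constructed around each drinking-water extraction
site:

* **round** — all cells whose centers lie within a radius of the site;
* **catchment** — the subset of the round buffer approximating the surface
  drainage area: cells no more than ``drop_m`` (default 5 m) below the
  site's elevation that are connected to the site, where connectivity
  bridges gaps of up to ``gap_m`` (default 50 m, Euclidean cell-center
  distance).  Delineation is region growing from the site cell, implemented
  as masked binary propagation with a disk structuring element of radius
  ``gap_m``.

Land-use proportions are then tallied per buffer over the 5 canonical
classes (forest, pasture, crop, construction, other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ExtractionError, GeometryError
from .rasters import CLASSES, Raster

log = logging.getLogger(__name__)

#: Buffer radii (m) used in the multi-scale scan.
DEFAULT_SIZES = (10, 20, 50, 100, 200, 400, 600, 800, 1000, 2000, 3000, 4000, 5000)

BUFFER_TYPES = ("round", "catchment")


@dataclass(frozen=True)
class BufferSpec:
    """One buffer definition: radius, type, and catchment thresholds."""

    size: float
    buffer_type: str = "round"
    drop_m: float = 5.0
    gap_m: float = 50.0

    def __post_init__(self):
        if self.size <= 0:
            raise GeometryError("buffer size must be positive")
        if self.buffer_type not in BUFFER_TYPES:
            raise GeometryError(f"unknown buffer type {self.buffer_type!r}")
        if self.drop_m < 0 or self.gap_m < 0:
            raise GeometryError("drop_m and gap_m must be non-negative")


@dataclass
class BufferRegion:
    """The set of raster cells assigned to one (site, size, type) buffer.

    ``rows``/``cols`` index into the full raster.  ``truncated`` is set when
    the requested radius extends beyond the raster bounds; the caller
    decides whether to drop the site at that size.
    """

    site_id: object
    spec: BufferSpec
    rows: np.ndarray
    cols: np.ndarray
    resolution: float
    truncated: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def area(self) -> float:
        """Region area in square meters."""
        return self.n_cells * self.resolution**2

    def cell_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass
class LandUseProportions:
    """Per-class cell fractions over one buffer region; sums to 1."""

    forest: float
    pasture: float
    crop: float
    construction: float
    other: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CLASSES}


def _window_mask(site_x, site_y, size, raster):
    """Boolean in-circle mask on the raster window covering the circle.

    Returns ``(r0, c0, mask, site_rc, truncated)`` where ``mask`` is the
    center-in-circle test on the window and ``site_rc`` is the site cell in
    window coordinates.
    """
    res = raster.resolution
    row_s, col_s = raster.cell_at(site_x, site_y)
    half = int(np.ceil(size / res)) + 1
    r0, r1 = row_s - half, row_s + half + 1
    c0, c1 = col_s - half, col_s + half + 1
    truncated = (
        site_x - size < raster.origin_x
        or site_x + size > raster.origin_x + raster.width
        or site_y - size < raster.origin_y
        or site_y + size > raster.origin_y + raster.height
    )
    r0c, r1c = max(r0, 0), min(r1, raster.ny)
    c0c, c1c = max(c0, 0), min(c1, raster.nx)
    rows = np.arange(r0c, r1c)
    cols = np.arange(c0c, c1c)
    cx, _ = raster.cell_center(np.zeros_like(cols), cols)
    _, cy = raster.cell_center(rows, np.zeros_like(rows))
    dist2 = (cy[:, None] - site_y) ** 2 + (cx[None, :] - site_x) ** 2
    mask = dist2 <= size**2
    # The site's own cell belongs to every buffer, even when a degenerate
    # radius leaves its center outside the circle.
    mask[row_s - r0c, col_s - c0c] = True
    return r0c, c0c, mask, (row_s - r0c, col_s - c0c), truncated


def make_round_buffer(site_x, site_y, size, raster, site_id=None) -> BufferRegion:
    """All cells whose centers lie within ``size`` m of the site."""
    r0, c0, mask, _, truncated = _window_mask(site_x, site_y, size, raster)
    rr, cc = np.nonzero(mask)
    if truncated:
        log.warning("round buffer (site=%s, size=%g) truncated at raster edge",
                    site_id, size)
    return BufferRegion(
        site_id=site_id,
        spec=BufferSpec(size, "round"),
        rows=rr + r0,
        cols=cc + c0,
        resolution=raster.resolution,
        truncated=truncated,
    )


def _gap_structure(gap_m: float, resolution: float, connectivity: int = 8):
    """Disk structuring element of radius ``gap_m`` in cell units.

    With ``gap_m == 0`` the element degenerates to the plain 4- or
    8-neighborhood chosen by ``connectivity``.
    """
    if gap_m == 0:
        if connectivity == 4:
            return ndimage.generate_binary_structure(2, 1)
        return ndimage.generate_binary_structure(2, 2)
    k = int(np.floor(gap_m / resolution))
    di = np.arange(-k, k + 1)
    dist = np.hypot(di[:, None], di[None, :]) * resolution
    return dist <= gap_m


def delineate_catchment_buffer(
    site_x,
    site_y,
    size,
    dem: Raster,
    drop_m: float = 5.0,
    gap_m: float = 50.0,
    site_id=None,
    connectivity: int = 8,
) -> BufferRegion:
    """Topography-restricted buffer approximating the drainage area.

    Within the round buffer, keep cells with elevation at least
    ``site_elevation - drop_m``, then grow a region from the site cell
    joining qualifying cells within ``gap_m`` of the current region
    (cell-center Euclidean distance); everything not reached is discarded
    as not draining toward the site.  ``drop_m=inf`` recovers the round
    buffer; ``gap_m=inf`` keeps every qualifying cell regardless of
    adjacency.
    """
    r0, c0, mask, (sr, sc), truncated = _window_mask(site_x, site_y, size, dem)
    window = dem.values[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
    site_elev = window[sr, sc]
    qualifying = mask & (window >= site_elev - drop_m)
    qualifying[sr, sc] = True  # site cell included unconditionally
    if np.isinf(gap_m):
        region = qualifying
    else:
        seed = np.zeros_like(qualifying)
        seed[sr, sc] = True
        structure = _gap_structure(gap_m, dem.resolution, connectivity)
        region = ndimage.binary_propagation(seed, structure=structure,
                                            mask=qualifying)
    rr, cc = np.nonzero(region)
    spec = BufferSpec(size, "catchment", drop_m=drop_m, gap_m=gap_m)
    return BufferRegion(
        site_id=site_id,
        spec=spec,
        rows=rr + r0,
        cols=cc + c0,
        resolution=dem.resolution,
        truncated=truncated,
    )


def make_buffer(site_x, site_y, spec: BufferSpec, dem: Raster, site_id=None):
    """Dispatch on :attr:`BufferSpec.buffer_type`."""
    if spec.buffer_type == "round":
        return make_round_buffer(site_x, site_y, spec.size, dem, site_id=site_id)
    return delineate_catchment_buffer(
        site_x, site_y, spec.size, dem,
        drop_m=spec.drop_m, gap_m=spec.gap_m, site_id=site_id,
    )


def extract_proportions(region: BufferRegion, landuse: Raster) -> LandUseProportions:
    """Per-class cell fractions of the land-use raster over a buffer region."""
    if region.n_cells == 0:
        raise ExtractionError("empty buffer region")
    codes = np.asarray(landuse.values[region.rows, region.cols]).astype(np.int64)
    if codes.min() < 0 or codes.max() >= len(CLASSES):
        bad = sorted(set(codes[(codes < 0) | (codes >= len(CLASSES))].tolist()))
        from .errors import ClassificationError

        raise ClassificationError(f"unmapped land-use codes in region: {bad}", bad)
    counts = np.bincount(codes, minlength=len(CLASSES))
    fracs = counts / counts.sum()
    return LandUseProportions(*fracs.tolist())


def compute_proportions_table(
    sites: pd.DataFrame,
    dem: Raster,
    landuse: Raster,
    sizes=DEFAULT_SIZES,
    buffer_types=BUFFER_TYPES,
    drop_m: float = 5.0,
    gap_m: float = 50.0,
) -> pd.DataFrame:
    """Long-format land-use proportions per (site, size, buffer type, class).

    Sites whose buffer at a given size leaves the raster are excluded from
    that size with a logged warning.  Columns: ``site_id, size_m,
    buffer_type, class, proportion``.
    """
    if not dem.same_grid(landuse):
        raise GeometryError("DEM and land-use rasters are on different grids")
    records = []
    n_dropped = 0
    for site in sites.itertuples(index=False):
        for size in sizes:
            for btype in buffer_types:
                spec = BufferSpec(size, btype, drop_m=drop_m, gap_m=gap_m)
                region = make_buffer(site.x, site.y, spec, dem, site_id=site.site_id)
                if region.truncated:
                    n_dropped += 1
                    continue
                props = extract_proportions(region, landuse)
                for cls, frac in props.as_dict().items():
                    records.append((site.site_id, size, btype, cls, frac))
    if n_dropped:
        log.warning("%d (site, size, type) buffers left the raster and were dropped",
                    n_dropped)
    return pd.DataFrame(
        records, columns=["site_id", "size_m", "buffer_type", "class", "proportion"]
    )
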