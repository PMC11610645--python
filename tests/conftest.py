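"""Shared fixtures and independent oracles.

The oracles here deliberately take a different computational route from
the package (exhaustive enumeration, pairwise-distance graphs, generic
numerical likelihood maximization) so agreement is evidence, not
tautology.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from stygoscale.rasters import Raster
from stygoscale.synthetic import LandscapeConfig, TruthConfig


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------
def catchment_oracle(site_x, site_y, size, dem, drop_m=5.0, gap_m=50.0):
    """Brute-force catchment delineation.

    Enumerates qualifying cells over the whole raster, builds the full
    pairwise gap_m-adjacency graph, and takes the connected component
    containing the site cell.
    """
    rs, cs = dem.cell_at(site_x, site_y)
    rows, cols = np.meshgrid(np.arange(dem.ny), np.arange(dem.nx), indexing="ij")
    cx, cy = dem.cell_center(rows.ravel(), cols.ravel())
    in_circle = (cx - site_x) ** 2 + (cy - site_y) ** 2 <= size**2
    qualifies = dem.values.ravel() >= dem.values[rs, cs] - drop_m
    keep = in_circle & qualifies
    keep[rs * dem.nx + cs] = True  # site cell always in
    idx = np.nonzero(keep)[0]
    pts = np.column_stack([cx[idx], cy[idx]])
    D = cdist(pts, pts)
    adj = csr_matrix(D <= gap_m)
    _, labels = connected_components(adj, directed=False)
    site_pos = np.searchsorted(idx, rs * dem.nx + cs)
    members = idx[labels == labels[site_pos]]
    return {(int(i // dem.nx), int(i % dem.nx)) for i in members}


def logit_glm_oracle(x, y):
    """Independent Bernoulli log-likelihood maximizer (generic optimizer)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def nll(b):
        eta = b[0] + b[1] * x
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = optimize.minimize(nll, [0.0, 0.0], method="BFGS",
                            options={"gtol": 1e-12})
    res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14})
    return res.x, -res.fun


def wilcoxon_enumeration_oracle(a, b):
    """Exact two-sided rank-sum p by exhausting all rank assignments."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    n1 = len(a)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}  # tie-free only
    obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2  # observed U of a
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(c + 1 for c in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_low = np.mean(us <= obs)
    p_high = np.mean(us >= obs)
    return min(1.0, 2.0 * min(p_low, p_high))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------
@pytest.fixture(scope="session")
def small_landscape():
    cfg = LandscapeConfig(nx=500, ny=500, seed=11)
    return cfg


@pytest.fixture(scope="session")
def small_study():
    """An 80-site study on a 5x5 km landscape, 4 scan sizes."""
    from stygoscale.experiments import make_study

    sites, proportions, dem, landuse, truth = make_study(
        seed=11,
        landscape=LandscapeConfig(nx=500, ny=500),
        truth=TruthConfig(n_sites=80, min_spacing=100),
        sizes=(100, 200, 400, 600),
        with_nitrate=True,
    )
    return {"sites": sites, "proportions": proportions, "dem": dem,
            "landuse": landuse, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_dem_factory():
    """Rough 50x50 DEMs at 10 m resolution with ridges and valleys."""

    def make(seed):
        r = np.random.default_rng(seed)
        base = r.normal(0, 8, (50, 50)).cumsum(axis=0) / 3
        return Raster(base, 10.0)

    return make
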