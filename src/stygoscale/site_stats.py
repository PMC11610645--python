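"""Sampled-vs-random site comparison and composition summaries.

Drinking-water extraction sites are not placed at random: their land-use
surroundings are compared against randomly distributed reference sites
(stratified so an oversampled sub-region keeps its share), class by
class, with Wilcoxon rank-sum tests and Bonferroni correction.  The
forest-agriculture gradient and ternary (barycentric) coordinates
summarize each site's composition over the three major classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .errors import GenerationError, StygoscaleError

log = logging.getLogger(__name__)


def _as_geometry(region) -> BaseGeometry:
    if isinstance(region, BaseGeometry):
        return region
    xmin, ymin, xmax, ymax = region
    return box(xmin, ymin, xmax, ymax)


def _largest_remainder_quotas(n: int, fractions: dict) -> dict:
    """Integer quotas per stratum summing exactly to n."""
    names = list(fractions)
    raw = np.array([fractions[k] * n for k in names])
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(names, base.tolist()))


def generate_random_sites(region, n: int, strata: dict | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Uniform random reference sites, optionally stratified by sub-region.

    ``region`` is a shapely geometry or ``(xmin, ymin, xmax, ymax)``.
    ``strata`` maps stratum name to ``(geometry, fraction)``; fractions
    must sum to 1 and quotas use largest-remainder rounding.  Without
    strata a single stratum covering ``region`` is used.
    """
    rng = np.random.default_rng(seed)
    if strata is None:
        strata = {"all": (region, 1.0)}
    fracs = {k: f for k, (_, f) in strata.items()}
    total = sum(fracs.values())
    if abs(total - 1.0) > 1e-9:
        raise GenerationError(f"stratum fractions sum to {total}, not 1")
    quotas = _largest_remainder_quotas(n, fracs)
    records = []
    idx = 0
    for name, (geom, _) in strata.items():
        geom = _as_geometry(geom)
        if geom.is_empty or geom.area <= 0:
            raise GenerationError(f"stratum {name!r} has empty geometry")
        want = quotas[name]
        xmin, ymin, xmax, ymax = geom.bounds
        got = 0
        tries = 0
        while got < want:
            tries += 1
            if tries > 1000 * max(want, 1):
                raise GenerationError(f"rejection sampling stalled in {name!r}")
            x = rng.uniform(xmin, xmax)
            y = rng.uniform(ymin, ymax)
            if geom.contains(Point(x, y)):
                records.append((f"R{idx:04d}", x, y, name))
                idx += 1
                got += 1
    return pd.DataFrame(records, columns=["site_id", "x", "y", "stratum"])


def wilcoxon_rank_sum(a, b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples have n <= 12 and no
    ties, and the normal approximation with tie and continuity correction
    otherwise.  Returns ``(U statistic of the first sample, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StygoscaleError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (a.size <= 12 and b.size <= 12) and not has_ties
    res = mannwhitneyu(a, b, alternative="two-sided",
                       method="exact" if exact else "asymptotic",
                       use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: ``min(1, m * p)`` per p-value."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StygoscaleError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise StygoscaleError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def significance_label(p: float) -> str:
    """Star convention: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_compositions(
    sampled_props: pd.DataFrame,
    random_props: pd.DataFrame,
    classes=("forest", "pasture", "crop", "construction"),
) -> pd.DataFrame:
    """Per-class comparison of land use at sampled vs random sites.

    Both inputs are long-format proportion tables (``site_id, class,
    proportion``) already restricted to one buffer size and type.  Per
    class, the per-site proportions are compared across the two groups
    with a Wilcoxon rank-sum test; p-values are Bonferroni-adjusted over
    the ``len(classes)`` tests.  Cumulated percentages (total coverage
    share per class across all sites of a group) are reported for display.
    """
    rows = []
    for cls in classes:
        a = sampled_props.loc[sampled_props["class"] == cls, "proportion"]
        b = random_props.loc[random_props["class"] == cls, "proportion"]
        if a.empty or b.empty:
            raise StygoscaleError(f"no proportions for class {cls!r}")
        stat, p = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
        rows.append({
            "class": cls,
            "sampled_pct": 100.0 * a.mean(),
            "random_pct": 100.0 * b.mean(),
            "statistic": stat,
            "p_raw": p,
        })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bonferroni(out["p_raw"].to_numpy(), len(classes))
    out["significance"] = [significance_label(p) for p in out["p_adjusted"]]
    return out


def forest_agriculture_gradient(forest, pasture, crop):
    """Forest share (0-100) of the combined forest+pasture+crop coverage.

    The vertical axis of the ternary plot: 100 * forest / (forest +
    pasture + crop).  All-zero inputs are undefined (NaN, logged) — such a
    site is excluded from the gradient model.
    """
    forest = np.asarray(forest, dtype=float)
    pasture = np.asarray(pasture, dtype=float)
    crop = np.asarray(crop, dtype=float)
    total = forest + pasture + crop
    bad = total <= 0
    if np.any(bad):
        log.warning("%d sites with zero forest+pasture+crop: gradient undefined",
                    int(np.sum(bad)))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, 100.0 * forest / total)
    return out if out.ndim else float(out)


def ternary_coordinates(forest, pasture, crop):
    """Barycentric (forest, pasture, crop) triple normalized to sum 1."""
    forest = np.asarray(forest, dtype=float)
    pasture = np.asarray(pasture, dtype=float)
    crop = np.asarray(crop, dtype=float)
    total = forest + pasture + crop
    if np.any(total <= 0):
        raise StygoscaleError("ternary coordinates undefined for all-zero input")
    return np.stack([forest / total, pasture / total, crop / total], axis=-1)
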