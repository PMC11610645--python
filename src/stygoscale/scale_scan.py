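"""Multi-scale GLM scan scored by McFadden's pseudo-R².

One binomial (logit) GLM is fit per combination of buffer size, buffer
type, and land-use class, with amphipod presence/absence as the response
and the percentage coverage (0-100) of the class as the single covariate.
Each fit is scored by McFadden's pseudo-R² = 1 - deviance/null deviance;
its uncertainty is the SD of the pseudo-R² over repeated 70% subsamples.
The scale of effect is the buffer size maximizing the mean pseudo-R²
across class x buffer-type combinations, and is finally compared against
the distribution of groundwater protection-zone extents.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateResponseError, FitError, StygoscaleError

log = logging.getLogger(__name__)

#: logit-scale coefficient magnitude beyond which a fit is treated as
#: separated (non-converged).
SEPARATION_BOUND = 15.0


@dataclass
class GLMFit:
    """One binomial logit GLM: presence ~ percentage coverage."""

    intercept: float
    slope: float
    slope_se: float
    deviance: float
    null_deviance: float
    converged: bool
    n: int


@dataclass
class ZoneSummary:
    """Protection-zone extents against the identified scale interval."""

    median_extent: float
    fraction_below: float
    fold_range: tuple[float, float]
    n_zones: int


def fit_binomial_glm(x, y, maxiter: int = 100, tol: float = 1e-10) -> GLMFit:
    """ML fit (IRLS) of presence ~ coverage%, with honest convergence flag.

    ``x`` is percentage coverage (0-100); the slope is per percentage
    point.  A single-class response raises
    :class:`DegenerateResponseError`; complete separation is reported via
    ``converged=False`` (coefficients beyond +-15 on the logit scale).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise FitError("x and y lengths differ")
    if len(y) < 10:
        raise FitError(f"need at least 10 observations, got {len(y)}")
    if y.min() == y.max():
        raise DegenerateResponseError("response contains a single class")
    X = np.column_stack([np.ones_like(x), x])
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter, tol=tol)
    params = np.asarray(res.params)
    separated = np.abs(params).max() > SEPARATION_BOUND
    converged = bool(res.converged) and not separated
    return GLMFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        slope_se=float(np.asarray(res.bse)[1]),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        converged=converged,
        n=len(y),
    )


def mcfadden_pseudo_r2(deviance: float, null_deviance: float) -> float:
    """McFadden's pseudo-R² = 1 - deviance/null deviance, clipped to [0, 1]."""
    if null_deviance <= 0:
        raise StygoscaleError("null deviance must be positive")
    r2 = 1.0 - deviance / null_deviance
    if r2 < 0:
        if r2 < -1e-8:
            log.warning("negative pseudo-R2 (%.3g) clipped to 0", r2)
        r2 = 0.0
    return min(r2, 1.0)


def subsample_r2_sd(
    x,
    y,
    frac: float = 0.7,
    reps: int = 1000,
    seed: int = 0,
    max_redraws: int | None = None,
) -> float:
    """SD of pseudo-R² over repeated subsampling without replacement.

    Each of ``reps`` subsamples keeps ``floor(frac * n)`` sites; subsamples
    with a single-class response are redrawn (count logged).  The SD uses
    denominator ``reps - 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    m = int(np.floor(frac * n))
    if m < 10:
        raise StygoscaleError(f"subsample size {m} too small (need >= 10)")
    if reps < 2:
        raise StygoscaleError("need at least 2 subsampling repetitions")
    if max_redraws is None:
        max_redraws = 100 * reps
    rng = np.random.default_rng(seed)
    r2s = np.empty(reps)
    redraws = 0
    for i in range(reps):
        while True:
            idx = rng.choice(n, size=m, replace=False)
            ys = y[idx]
            if ys.min() != ys.max():
                break
            redraws += 1
            if redraws > max_redraws:
                raise StygoscaleError("too many degenerate subsamples")
        fit = fit_binomial_glm(x[idx], ys)
        r2s[i] = mcfadden_pseudo_r2(fit.deviance, fit.null_deviance)
    if redraws:
        log.info("redrew %d degenerate subsamples", redraws)
    return float(np.std(r2s, ddof=1))


def scan(
    sites: pd.DataFrame,
    proportions: pd.DataFrame,
    sizes=None,
    buffer_types=("round", "catchment"),
    classes=("forest", "pasture", "crop"),
    frac: float = 0.7,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One GLM per (buffer size, buffer type, land-use class).

    ``proportions`` is the long-format table from
    :func:`stygoscale.buffers.compute_proportions_table`; ``sites`` must
    carry ``site_id`` and ``presence``.  ``reps=0`` skips the subsampling
    SD (NaN).  Missing combinations are skipped with a warning.  Returns
    one row per scan cell: ``size_m, buffer_type, class, slope, slope_se,
    pseudo_r2, pseudo_r2_sd, n, converged``.
    """
    if sizes is None:
        sizes = sorted(proportions["size_m"].unique())
    presence = sites.set_index("site_id")["presence"]
    # independent per-cell subsampling seeds, stable in cell order
    ss = np.random.SeedSequence(seed)
    cells = [(s, b, c) for s in sizes for b in buffer_types for c in classes]
    child_seeds = ss.generate_state(len(cells))
    rows = []
    grouped = proportions.groupby(["size_m", "buffer_type", "class"])
    for (size, btype, cls), cell_seed in zip(cells, child_seeds):
        try:
            sub = grouped.get_group((size, btype, cls))
        except KeyError:
            log.warning("no proportions for (%s, %s, %s); skipped", size, btype, cls)
            continue
        sub = sub.set_index("site_id")["proportion"]
        common = sub.index.intersection(presence.index)
        xpct = sub.loc[common].to_numpy() * 100.0
        yv = presence.loc[common].to_numpy()
        fit = fit_binomial_glm(xpct, yv)
        r2 = mcfadden_pseudo_r2(fit.deviance, fit.null_deviance)
        sd = (
            subsample_r2_sd(xpct, yv, frac=frac, reps=reps,
                            seed=int(cell_seed % 2**31))
            if reps
            else np.nan
        )
        rows.append(
            (size, btype, cls, fit.slope, fit.slope_se, r2, sd, fit.n,
             fit.converged)
        )
    return pd.DataFrame(
        rows,
        columns=["size_m", "buffer_type", "class", "slope", "slope_se",
                 "pseudo_r2", "pseudo_r2_sd", "n", "converged"],
    )


def peak_scale(scan_cells: pd.DataFrame):
    """Scale of effect: buffer size maximizing the mean pseudo-R².

    The mean is taken over the class x buffer-type combinations at each
    size, with the SD of the mean (across-combination SD / sqrt(k))
    attached for plotting.  Ties break toward the smallest size.  Returns
    ``(best_size, profile)`` where ``profile`` has columns ``size_m,
    mean_r2, sd_of_mean, n_combos``.
    """
    if len(scan_cells) == 0:
        raise StygoscaleError("empty scan")
    grp = scan_cells.groupby("size_m")["pseudo_r2"]
    profile = pd.DataFrame(
        {
            "mean_r2": grp.mean(),
            "sd_of_mean": grp.std(ddof=1) / np.sqrt(grp.count()),
            "n_combos": grp.count(),
        }
    ).reset_index()
    profile = profile.sort_values("size_m", kind="stable").reset_index(drop=True)
    if len(profile) < 2:
        raise StygoscaleError("need at least 2 sizes to locate a peak")
    best = profile.loc[profile["mean_r2"].idxmax(), "size_m"]  # first max wins
    return best, profile


def zone_summary(zone_extents, scale_interval=(400.0, 1000.0)) -> ZoneSummary:
    """Protection-zone extents vs the identified scale-of-effect interval.

    Reports the median extent, the fraction of zones smaller than the
    interval's lower edge, and how many fold the interval is relative to
    the median (low/median, high/median).
    """
    extents = np.asarray(zone_extents, dtype=float)
    if extents.size == 0:
        raise StygoscaleError("no zone extents given")
    if np.any(extents <= 0):
        raise StygoscaleError("zone extents must be positive")
    low, high = scale_interval
    if low > high:
        raise StygoscaleError("scale interval must have low <= high")
    med = float(np.median(extents))
    return ZoneSummary(
        median_extent=med,
        fraction_below=float(np.mean(extents < low)),
        fold_range=(low / med, high / med),
        n_zones=int(extents.size),
    )
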