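"""Isolation-by-distance regression on individual pairwise genetic distances.

Genetic distance between individuals follows Rousset's â logic: an
identity-probability contrast between the two genomes of an individual
(within, Qw) and across the pair (between, Qb), accumulated as a
ratio-of-sums over loci, analogous to FST/(1-FST) for individual pairs.
Under limited dispersal the expectation of â increases linearly with
geographic distance in a 1D habitat and with log-distance in 2D, with slope
1/NS where NS is Wright's neighborhood size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "IbDFit",
    "genetic_distance_matrix",
    "pair_locus_components",
    "geographic_distance_matrix",
    "ibd_regression",
    "slope_ci_bootstrap",
    "mantel_permutation_p",
]


@dataclass
class IbDFit:
    """Fitted isolation-by-distance regression.

    ``slope`` has units of genetic distance per meter (1D model) or per
    log-meter (2D model).  ``ci_low``/``ci_high`` are 95% percentile locus
    bootstrap bounds (None until computed); ``p_value`` is a one-tailed
    Mantel-style permutation probability (None until computed).
    """

    model: str
    slope: float
    intercept: float
    n_pairs: int
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_pairs": self.n_pairs,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
        }


def _identity_components(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample arrays used by the â estimator: p (alt dosage/2), hom flag, mask."""
    ok = gm.calls != MISSING
    g = np.where(ok, gm.calls, 0).astype(np.float64)
    p = g / 2.0
    hom = (gm.calls != 1) & ok
    return p, hom.astype(np.float64), ok.astype(np.float64)


def genetic_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise â-style genetic distance matrix.

    For pair (i, j), with per-locus Qw = mean homozygosity of the two
    individuals and Qb = identity probability of two alleles drawn one from
    each individual, ``d_ij = sum_l (Qw - Qb) / sum_l (1 - Qw)`` over loci
    non-missing in both.  Pairs whose denominator is zero (both individuals
    homozygous at every shared locus) are NaN.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p, hom, m = _identity_components(gm)
    pm = p * m
    hm = hom * m
    # sum_l M_i M_j * f(i,j) expanded into matrix products:
    shared = m @ m.T
    sum_hom = hm @ m.T
    qw_sum = 0.5 * (sum_hom + sum_hom.T)
    # Qb = 1 - p_i - p_j + 2 p_i p_j
    sum_p = pm @ m.T
    qb_sum = shared - sum_p - sum_p.T + 2.0 * (pm @ pm.T)
    num = qw_sum - qb_sum
    den = shared - qw_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    n_undef = int(np.sum(~np.isfinite(d[np.triu_indices(gm.n_samples, 1)])))
    if n_undef:
        logger.info("genetic_distance_matrix: %d undefined pairs", n_undef)
    return d


def pair_locus_components(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair, per-locus numerator/denominator of the â ratio-of-sums.

    Returns ``(num, den, pair_index)`` where num/den have shape
    ``(n_pairs, n_loci)`` (NaN where either member is missing) and
    pair_index is the ``(i, j)`` array from ``np.triu_indices``.  Memory is
    O(n_pairs * n_loci); intended for locus-bootstrap at analysis scales.
    """
    p, hom, m = _identity_components(gm)
    iu = np.triu_indices(gm.n_samples, k=1)
    pi, pj = p[iu[0]], p[iu[1]]
    qw = 0.5 * (hom[iu[0]] + hom[iu[1]])
    qb = 1.0 - pi - pj + 2.0 * pi * pj
    ok = (m[iu[0]] * m[iu[1]]) > 0
    num = np.where(ok, qw - qb, np.nan)
    den = np.where(ok, 1.0 - qw, np.nan)
    return num, den, np.stack(iu)


def geographic_distance_matrix(st: SampleTable, mode: str = "haversine") -> np.ndarray:
    """Pairwise geographic distances in meters.

    ``haversine`` uses latitude/longitude on a sphere of mean radius
    6,371,000 m; ``planar`` uses Euclidean distance on x/y columns (meters).
    """
    df = st.df
    if mode == "haversine":
        for col in ("latitude", "longitude"):
            if col not in df.columns or df[col].isna().any():
                bad = df.index[df[col].isna()].tolist() if col in df.columns else df.index.tolist()
                raise ValueError(f"missing {col} for samples {bad}")
        lat = np.radians(df["latitude"].to_numpy(float))
        lon = np.radians(df["longitude"].to_numpy(float))
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    elif mode == "planar":
        for col in ("x", "y"):
            if col not in df.columns or df[col].isna().any():
                bad = df.index[df[col].isna()].tolist() if col in df.columns else df.index.tolist()
                raise ValueError(f"missing {col} for samples {bad}")
        xy = df[["x", "y"]].to_numpy(float)
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))
    raise ValueError(f"unknown mode {mode!r}")


def _pair_arrays(
    gdist: np.ndarray, xdist: np.ndarray, model: str, min_distance: float
) -> tuple[np.ndarray, np.ndarray]:
    if gdist.shape != xdist.shape:
        raise ValueError("distance matrices not conformable")
    iu = np.triu_indices(gdist.shape[0], k=1)
    g = gdist[iu]
    x = xdist[iu]
    keep = np.isfinite(g) & np.isfinite(x) & (x >= min_distance)
    g, x = g[keep], x[keep]
    if model == "2D":
        x = np.log(x)
    elif model != "1D":
        raise ValueError(f"model must be '1D' or '2D', got {model!r}")
    return g, x


def ibd_regression(
    gdist: np.ndarray,
    xdist: np.ndarray,
    model: str = "2D",
    min_distance: float = 1.0,
) -> IbDFit:
    """OLS of pairwise genetic distance on (log-)geographic distance.

    Unordered pairs enter once; pairs closer than ``min_distance`` (guards
    log(0) in the 2D model) or with undefined genetic distance are excluded.
    """
    g, x = _pair_arrays(gdist, xdist, model, min_distance)
    if g.size < 3:
        raise ValueError(f"only {g.size} usable pairs; need >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in geographic distances")
    res = stats.linregress(x, g)
    return IbDFit(model=model, slope=float(res.slope),
                  intercept=float(res.intercept), n_pairs=int(g.size))


def slope_ci_bootstrap(
    gm: GenotypeMatrix,
    xdist: np.ndarray,
    model: str = "2D",
    min_distance: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """95% percentile CI on the IbD slope by bootstrap over loci.

    Loci are resampled with replacement; pairwise genetic distances and the
    slope are recomputed per replicate from the cached per-locus components
    of the ratio-of-sums.  Replicates with degenerate distance matrices are
    skipped; more than 10% failures is an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    num, den, iu = pair_locus_components(gm)
    x = xdist[iu[0], iu[1]]
    keep_x = np.isfinite(x) & (x >= min_distance)
    xm = np.log(x[keep_x]) if model == "2D" else x[keep_x]
    num, den = num[keep_x], den[keep_x]
    num0, den0 = np.nan_to_num(num), np.nan_to_num(den)
    L = num.shape[1]
    # multinomial counts of each locus per replicate -> matrix-product bootstrap
    counts = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T.astype(np.float64)
    bnum = num0 @ counts
    bden = den0 @ counts
    slopes = []
    failures = 0
    for r in range(n_boot):
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(bden[:, r] > 0, bnum[:, r] / bden[:, r], np.nan)
        ok = np.isfinite(d)
        if ok.sum() < 3 or np.ptp(xm[ok]) == 0:
            failures += 1
            continue
        res = stats.linregress(xm[ok], d[ok])
        slopes.append(res.slope)
    if failures > 0.1 * n_boot:
        raise ValueError(f"{failures}/{n_boot} bootstrap replicates failed")
    if failures:
        logger.info("slope_ci_bootstrap: skipped %d degenerate replicates", failures)
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_slope_draws(
    gm: GenotypeMatrix,
    xdist: np.ndarray,
    model: str = "2D",
    min_distance: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Raw locus-bootstrap slope replicates (for uncertainty propagation)."""
    rng = np.random.default_rng(seed)
    num, den, iu = pair_locus_components(gm)
    x = xdist[iu[0], iu[1]]
    keep_x = np.isfinite(x) & (x >= min_distance)
    xm = np.log(x[keep_x]) if model == "2D" else x[keep_x]
    num0 = np.nan_to_num(num[keep_x])
    den0 = np.nan_to_num(den[keep_x])
    L = num0.shape[1]
    counts = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T.astype(np.float64)
    bnum, bden = num0 @ counts, den0 @ counts
    out = []
    for r in range(n_boot):
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(bden[:, r] > 0, bnum[:, r] / bden[:, r], np.nan)
        ok = np.isfinite(d)
        if ok.sum() >= 3 and np.ptp(xm[ok]) > 0:
            out.append(stats.linregress(xm[ok], d[ok]).slope)
    return np.asarray(out)


def mantel_permutation_p(
    gdist: np.ndarray,
    xdist: np.ndarray,
    model: str = "2D",
    min_distance: float = 1.0,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """One-tailed permutation p-value for the IbD slope.

    Sample locations are permuted jointly (rows and columns of the
    geographic matrix) and the slope recomputed; p = (1 + #{slope_perm >=
    slope_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    obs = ibd_regression(gdist, xdist, model, min_distance).slope
    n = gdist.shape[0]
    # ties (e.g. exactly zero slopes) count as >= up to fp round-off
    tol = 1e-12 * max(1.0, abs(obs))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = xdist[np.ix_(perm, perm)]
        try:
            s = ibd_regression(gdist, xp, model, min_distance).slope
        except ValueError:
            continue
        if s >= obs - tol:
            count += 1
    return (1 + count) / (n_perm + 1)
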