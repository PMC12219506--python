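"""Conversion of isolation-by-distance slopes into dispersal quantities.

Under Rousset's regression framework the slope *b* of pairwise genetic
distance on distance (1D habitat) or log-distance (2D) estimates the
reciprocal of Wright's neighborhood size NS.  Combined with a population
density D (individuals per meter or per square meter), the per-generation
axial dispersal distance sigma follows from

    2D:  sigma = 1 / sqrt(4 * pi * D * b)        NS = 4 * pi * D * sigma^2
    1D:  sigma = 1 / sqrt(4 * D * b)             NS = 4 * D * sigma^2

so that NS = 1/b in both geometries.  The dispersal neighborhood is the
disc of radius 2*sigma, and an indicative Laplace kernel calibrated to
sigma has mean dispersal distance sigma/sqrt(2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DensityEstimate",
    "DispersalEstimate",
    "LaplaceKernel",
    "sigma_from_slope",
    "neighborhood_size",
    "neighborhood_radius",
    "laplace_kernel",
    "census_density",
    "effective_density",
    "propagate_sigma",
    "lognormal_slope_draws",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (summary-output convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class DensityEstimate:
    """Population density: census (counted colonies) or effective (from Ne).

    ``value`` is colonies/m^2 for the 2D model or colonies/m for 1D.
    ``draws`` is an optional pool of plausible values for Monte-Carlo
    propagation (e.g. site bootstrap or per-population densities).
    """

    kind: str  # "census" | "effective"
    model: str  # "1D" | "2D"
    value: float
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("density must be positive")
        if self.draws is not None:
            self.draws = np.asarray(self.draws, dtype=float)
            if (self.draws <= 0).any():
                raise ValueError("all density draws must be positive")


@dataclass
class LaplaceKernel:
    """Isotropic per-axis Laplace dispersal kernel calibrated to sigma.

    pdf(x) = 1/(sigma*sqrt(2)) * exp(-sqrt(2)*|x|/sigma) on the real line;
    the mean dispersal distance E|x| equals sigma/sqrt(2).
    """

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self._dist = stats.laplace(loc=0.0, scale=self.sigma / math.sqrt(2.0))

    def pdf(self, x):
        return self._dist.pdf(x)

    def cdf(self, x):
        return self._dist.cdf(x)

    @property
    def mean_distance(self) -> float:
        return self.sigma / math.sqrt(2.0)

    def quantile(self, q):
        """Quantile of the signed displacement (closed form via scipy)."""
        return self._dist.ppf(q)

    def distance_quantile(self, q):
        """Quantile of |x|, the dispersal distance (exponential with rate sqrt(2)/sigma)."""
        return stats.expon(scale=self.sigma / math.sqrt(2.0)).ppf(q)


@dataclass
class DispersalEstimate:
    """Point estimates and (optionally) propagated uncertainty summaries.

    ``radius = 2*sigma`` is the neighborhood radius;
    ``kernel_mean_distance = sigma/sqrt(2)``.  ``summaries`` holds
    ``{quantity: {"median": ..., "iqr": (lo, hi)}}`` when Monte-Carlo
    propagated; ``n_modes`` counts density modes of the sigma distribution.
    """

    sigma: float
    ns: float
    radius: float
    kernel_mean_distance: float
    summaries: dict = field(default_factory=dict)
    n_modes: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sigma_m": self.sigma,
            "neighborhood_size": self.ns,
            "radius_m": self.radius,
            "kernel_mean_distance_m": self.kernel_mean_distance,
            "sigma_m_2sf": round_sig(self.sigma),
            "summaries": self.summaries,
            "n_modes": self.n_modes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def sigma_from_slope(b: float, density: DensityEstimate | float, model: str = "2D") -> float:
    """Axial dispersal distance (m) from IbD slope and density.

    2D: sigma = 1/sqrt(4*D*b*pi); 1D: sigma = 1/sqrt(4*D*b).
    """
    if b <= 0:
        raise ValueError("no IbD signal; sigma undefined for slope <= 0")
    d = density.value if isinstance(density, DensityEstimate) else float(density)
    if d <= 0:
        raise ValueError("density must be positive")
    if isinstance(density, DensityEstimate) and density.model != model:
        raise ValueError(f"density is {density.model} but model is {model}")
    if model == "2D":
        return 1.0 / math.sqrt(4.0 * d * b * math.pi)
    if model == "1D":
        return 1.0 / math.sqrt(4.0 * d * b)
    raise ValueError(f"model must be '1D' or '2D', got {model!r}")


def neighborhood_size(
    b: float | None = None,
    density: DensityEstimate | float | None = None,
    sigma: float | None = None,
    model: str = "2D",
) -> float:
    """Neighborhood size NS: effective breeders within radius 2*sigma.

    Two equivalent entry points: from the slope (NS = 1/b) or from density
    and sigma (NS = 4*pi*D*sigma^2 in 2D, 4*D*sigma^2 in 1D).
    """
    if b is not None:
        if b <= 0:
            raise ValueError("no IbD signal; NS undefined for slope <= 0")
        return 1.0 / b
    if density is None or sigma is None:
        raise ValueError("provide either b, or density and sigma")
    d = density.value if isinstance(density, DensityEstimate) else float(density)
    if model == "2D":
        return 4.0 * math.pi * d * sigma ** 2
    if model == "1D":
        return 4.0 * d * sigma ** 2
    raise ValueError(f"model must be '1D' or '2D', got {model!r}")


def neighborhood_radius(sigma: float) -> float:
    """Radius 2*sigma beyond which populations are effectively isolated."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 2.0 * sigma


def laplace_kernel(sigma: float) -> LaplaceKernel:
    return LaplaceKernel(sigma)


def census_density(
    counts,
    areas,
    taxon_fraction=None,
    model: str = "2D",
    strip_width: float | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DensityEstimate:
    """Census density from per-site colony counts.

    Per-site density = count * taxon_fraction / area; the 2D value is the
    median across sites, with draws from a site-level bootstrap (medians of
    resampled site sets).  For the 1D model the areal density is multiplied
    by ``strip_width`` (meters of habitat strip), an explicit configuration
    choice.
    """
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if (areas <= 0).any():
        raise ValueError("site area must be positive")
    frac = np.ones_like(counts) if taxon_fraction is None else np.asarray(taxon_fraction, float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("taxon_fraction must be in [0, 1]")
    per_site = counts * frac / areas
    scale = 1.0
    if model == "1D":
        if strip_width is None or strip_width <= 0:
            raise ValueError("1D census density requires a positive strip_width")
        scale = strip_width
    rng = np.random.default_rng(seed)
    k = len(per_site)
    draws = np.median(per_site[rng.integers(0, k, size=(n_boot, k))], axis=1) * scale
    draws = draws[draws > 0]
    return DensityEstimate(kind="census", model=model,
                           value=float(np.median(per_site) * scale), draws=draws)


def effective_density(ne, extent, model: str = "2D") -> DensityEstimate:
    """Effective density from per-population Ne and habitat extent.

    With lists, the per-population densities form the draw pool and the
    value is their median (so one outlier population shows up as a second
    mode downstream rather than being averaged away).
    """
    ne = np.atleast_1d(np.asarray(ne, dtype=float))
    extent = np.atleast_1d(np.asarray(extent, dtype=float))
    if (ne <= 0).any() or (extent <= 0).any():
        raise ValueError("ne and extent must be positive")
    dens = ne / extent
    return DensityEstimate(kind="effective", model=model,
                           value=float(np.median(dens)), draws=dens)


def lognormal_slope_draws(
    median: float, ci_low: float, ci_high: float, n: int = 10000,
    seed: int | None = None,
) -> np.ndarray:
    """Slope draws from a lognormal matched to a median and 95% CI.

    Used when only summary statistics of the slope bootstrap are available;
    the log-scale sd is the average implied by the two CI bounds at z=1.96.
    """
    if not (0 < ci_low <= median <= ci_high):
        raise ValueError("require 0 < ci_low <= median <= ci_high")
    mu = math.log(median)
    z = stats.norm.ppf(0.975)
    sd = 0.5 * ((math.log(ci_high) - mu) / z + (mu - math.log(ci_low)) / z)
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=max(sd, 1e-12), size=n)


def _count_modes(x: np.ndarray) -> int:
    """Number of modes of the KDE of log(x) on a fixed grid."""
    lx = np.log(x)
    if np.ptp(lx) < 1e-9:
        return 1
    kde = stats.gaussian_kde(lx)
    grid = np.linspace(lx.min() - 0.5, lx.max() + 0.5, 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    # suppress negligible bumps below 5% of the peak
    return max(1, int(np.sum(interior & (dens[1:-1] > 0.05 * dens.max()))))


def propagate_sigma(
    b_draws,
    density: DensityEstimate,
    model: str = "2D",
    n_mc: int = 10000,
    seed: int | None = None,
) -> DispersalEstimate:
    """Monte-Carlo propagation of slope and density uncertainty into sigma.

    Each iteration draws a slope and a density independently (with
    replacement from their draw pools), computes sigma, NS, the
    neighborhood radius and the Laplace-kernel mean distance, and the
    median and IQR of each are reported.  Non-positive slope draws are
    rejected (more than 50% rejections is an error).  The number of modes
    of the sigma distribution is reported since a multimodal density pool
    (one outlier population) produces a multimodal sigma.
    """
    b_draws = np.asarray(b_draws, dtype=float)
    if b_draws.size == 0:
        raise ValueError("b_draws is empty")
    n_rej = int((b_draws <= 0).sum())
    if n_rej > 0.5 * b_draws.size:
        raise ValueError(f"{n_rej}/{b_draws.size} non-positive slope draws rejected")
    b_draws = b_draws[b_draws > 0]
    rng = np.random.default_rng(seed)
    b = rng.choice(b_draws, size=n_mc, replace=True)
    pool = density.draws if density.draws is not None and density.draws.size else np.array([density.value])
    d = rng.choice(pool, size=n_mc, replace=True)
    geo = 4.0 * math.pi if model == "2D" else 4.0
    sigma = 1.0 / np.sqrt(geo * d * b)
    ns = 1.0 / b
    radius = 2.0 * sigma
    kern = sigma / math.sqrt(2.0)

    def summ(x):
        q25, q50, q75 = np.percentile(x, [25, 50, 75])
        return {"median": float(q50), "iqr": (float(q25), float(q75))}

    summaries = {
        "sigma": summ(sigma),
        "ns": summ(ns),
        "radius": summ(radius),
        "kernel_mean_distance": summ(kern),
    }
    med_sigma = summaries["sigma"]["median"]
    return DispersalEstimate(
        sigma=med_sigma,
        ns=summaries["ns"]["median"],
        radius=2.0 * med_sigma,
        kernel_mean_distance=med_sigma / math.sqrt(2.0),
        summaries=summaries,
        n_modes=_count_modes(sigma),
    )


def read_density_csv(path: str | Path, model: str = "2D",
                     strip_width: float | None = None,
                     seed: int | None = None) -> DensityEstimate:
    """Load a ``densities.csv`` (site, count, area_m2, taxon_fraction)."""
    df = pd.read_csv(path)
    frac = df["taxon_fraction"] if "taxon_fraction" in df.columns else None
    return census_density(df["count"], df["area_m2"], frac, model=model,
                          strip_width=strip_width, seed=seed)


def read_ne_csv(path: str | Path, model: str = "2D") -> DensityEstimate:
    """Load a ``ne.csv`` (population, ne, extent) into an effective density."""
    df = pd.read_csv(path)
    return effective_density(df["ne"], df["extent"], model=model)
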