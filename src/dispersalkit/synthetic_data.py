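"""Forward-in-time generators with known ground truth.

Three generators cover the pipeline's inputs:

* :func:`simulate_spatial` — individuals in a continuous 1D or 2D habitat
  with local mating and a controlled parent-offspring dispersal kernel of
  axial standard deviation ``sigma_true``; produces genotype data whose
  pairwise genetic distance grows with (log-)distance at a slope set by
  sigma and density.
* :func:`simulate_two_demes` — two Wright-Fisher demes diverging from a
  common ancestral pool while exchanging migrants at asymmetric rates.
* :func:`inject_artifacts` — plants near-duplicate (clonal) samples and
  random missingness, returning the planted truth for detector tests.

The simulations are forward rather than coalescent so that the realized
per-generation parent-offspring displacement is directly measurable and
equals the configured kernel parameter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable

__all__ = [
    "SpatialSimConfig",
    "TwoDemeConfig",
    "simulate_spatial",
    "simulate_two_demes",
    "simulate_wright_fisher",
    "inject_artifacts",
]


@dataclass
class SpatialSimConfig:
    """Continuous-space simulation settings.

    ``extent`` is the habitat side (2D, meters) or line length (1D);
    ``sigma_true`` the axial dispersal standard deviation per generation;
    ``kernel`` the per-axis dispersal draw (``gaussian`` or ``laplace``);
    ``mutation_rate`` the symmetric per-allele-copy flip probability per
    generation; ``boundary`` is ``reflect`` (bounded reef) or ``torus``.
    """

    model: str = "2D"
    extent: float = 500.0
    n_individuals: int = 500
    sigma_true: float = 20.0
    kernel: str = "gaussian"
    n_loci: int = 300
    mutation_rate: float = 1e-4
    n_generations: int = 100
    seed: int = 0
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.model not in ("1D", "2D"):
            raise ValueError("model must be '1D' or '2D'")
        if self.kernel not in ("gaussian", "laplace"):
            raise ValueError("kernel must be 'gaussian' or 'laplace'")
        if self.boundary not in ("reflect", "torus"):
            raise ValueError("boundary must be 'reflect' or 'torus'")
        for name in ("extent", "n_individuals", "sigma_true", "n_loci", "n_generations"):
            if getattr(self, name) < 0 or (name != "sigma_true" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")

    @property
    def density(self) -> float:
        """True density: individuals per m^2 (2D) or per m (1D)."""
        dims = 2 if self.model == "2D" else 1
        return self.n_individuals / self.extent ** dims


@dataclass
class TwoDemeConfig:
    """Two-deme divergence-with-migration settings.

    ``m12`` is the per-generation probability that a gamete in deme 1 comes
    from a deme-2 parent (migration INTO 1), and symmetrically for ``m21``.
    """

    ne1: int = 200
    ne2: int = 200
    m12: float = 0.0
    m21: float = 0.0
    n_loci: int = 1000
    n_generations: int = 200
    sample1: int = 20
    sample2: int = 20
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.m12 < 1 and 0 <= self.m21 < 1):
            raise ValueError("migration rates must be in [0, 1)")
        if self.ne1 < 2 or self.ne2 < 2:
            raise ValueError("deme sizes must be >= 2")


def _kernel_draw(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Per-axis dispersal displacement with standard deviation sigma."""
    return rng.normal(0.0, sigma, size=size)


def _kernel_draw_laplace(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    return rng.laplace(0.0, sigma / np.sqrt(2.0), size=size)


def _fold_boundary(x: np.ndarray, extent: float, boundary: str) -> np.ndarray:
    if boundary == "torus":
        return np.mod(x, extent)
    # reflect: fold the real line onto [0, extent]
    period = 2.0 * extent
    x = np.mod(x, period)
    return np.where(x > extent, period - x, x)


def _transmit(rng: np.random.Generator, parent_calls: np.ndarray,
              mutation_rate: float) -> np.ndarray:
    """One gamete per row: Bernoulli(g/2) alt allele, then symmetric mutation."""
    allele = rng.random(parent_calls.shape) < parent_calls / 2.0
    if mutation_rate > 0:
        flip = rng.random(parent_calls.shape) < mutation_rate
        allele = allele ^ flip
    return allele


def simulate_spatial(
    cfg: SpatialSimConfig,
    sample_size: int | None = None,
) -> tuple[GenotypeMatrix, SampleTable, dict]:
    """Run the continuous-space forward simulation.

    Each generation every one of N offspring picks a mother uniformly, is
    born at the mother's position plus a per-axis kernel draw (reflected or
    wrapped at the habitat edge), and picks a father with probability
    proportional to the kernel density at his distance from the offspring's
    natal position (selfing allowed, matching a hermaphroditic coral).
    Loci are unlinked (one per contig), biallelic, initialized at frequency
    0.5 in Hardy-Weinberg proportions, and mutate symmetrically.

    Returns ``(genotypes, sample_table, truth)`` for a random sample of
    ``sample_size`` final-generation individuals (all when None); ``truth``
    records the configuration, true density and the realized axial
    parent-offspring displacement standard deviation of the final
    generation.
    """
    if cfg.sigma_true >= cfg.extent:
        warnings.warn("sigma_true >= extent: expect panmixia, no IbD signal")
    rng = np.random.default_rng(cfg.seed)
    N, L = cfg.n_individuals, cfg.n_loci
    dims = 2 if cfg.model == "2D" else 1
    pos = rng.uniform(0, cfg.extent, size=(N, dims))
    calls = rng.binomial(1, 0.5, size=(N, L)) + rng.binomial(1, 0.5, size=(N, L))
    calls = calls.astype(np.int8)
    draw = _kernel_draw if cfg.kernel == "gaussian" else _kernel_draw_laplace

    disp_sq_sum = 0.0
    disp_n = 0
    for gen in range(cfg.n_generations):
        mothers = rng.integers(0, N, size=N)
        step = (
            draw(rng, cfg.sigma_true, (N, dims))
            if cfg.sigma_true > 0
            else np.zeros((N, dims))
        )
        natal = _fold_boundary(pos[mothers] + step, cfg.extent, cfg.boundary)
        # father ~ kernel density around the natal position
        diff = natal[:, None, :] - pos[None, :, :]
        if cfg.boundary == "torus":
            diff = diff - cfg.extent * np.round(diff / cfg.extent)
        d2 = (diff ** 2).sum(axis=2)
        if cfg.sigma_true > 0:
            if cfg.kernel == "gaussian":
                logw = -d2 / (2.0 * cfg.sigma_true ** 2)
            else:
                logw = -np.sqrt(2.0) * np.sqrt(d2) / cfg.sigma_true
            w = np.exp(logw - logw.max(axis=1, keepdims=True))
        else:
            w = (d2 == d2.min(axis=1, keepdims=True)).astype(float)
        cw = np.cumsum(w, axis=1)
        u = rng.random(N) * cw[:, -1]
        fathers = np.clip((cw < u[:, None]).sum(axis=1), 0, N - 1)
        g_m = _transmit(rng, calls[mothers], cfg.mutation_rate)
        g_f = _transmit(rng, calls[fathers], cfg.mutation_rate)
        calls = (g_m.astype(np.int8) + g_f.astype(np.int8))
        if gen == cfg.n_generations - 1:
            # realized per-axis parent-offspring displacement (mother side)
            disp = natal - pos[mothers]
            disp_sq_sum += float((disp ** 2).sum())
            disp_n += disp.size
        pos = natal

    realized_sd = float(np.sqrt(disp_sq_sum / disp_n)) if disp_n else 0.0
    if sample_size is not None and sample_size < N:
        pick = rng.choice(N, size=sample_size, replace=False)
    else:
        pick = np.arange(N)
    samples = [f"ind{i:04d}" for i in range(len(pick))]
    loci = [(f"ctg{j:05d}", 1, "A", "T") for j in range(L)]
    gm = GenotypeMatrix(samples=samples, loci=loci, calls=calls[pick])
    meta = pd.DataFrame(
        {
            "population": "sim",
            "site": "sim",
            "x": pos[pick, 0],
            "y": pos[pick, 1] if dims == 2 else 0.0,
            "depth": 0.0,
        },
        index=pd.Index(samples, name="sample"),
    )
    st = SampleTable(meta)
    truth = {
        "model": cfg.model,
        "sigma_true": cfg.sigma_true,
        "density": cfg.density,
        "extent": cfg.extent,
        "n_individuals": N,
        "n_loci": L,
        "n_generations": cfg.n_generations,
        "kernel": cfg.kernel,
        "seed": cfg.seed,
        "realized_axial_sd": realized_sd,
    }
    return gm, st, truth


def simulate_two_demes(
    cfg: TwoDemeConfig,
) -> tuple[GenotypeMatrix, dict[str, list[str]], dict]:
    """Two Wright-Fisher demes with asymmetric gamete migration.

    Both demes start from one ancestral pool (per-locus frequencies drawn
    Uniform(0.1, 0.9), Hardy-Weinberg genotypes) and then drift for
    ``n_generations`` while each gamete in deme i is drawn from the other
    deme with probability m_i.  Returns sampled genotypes, a population
    map, and the ground-truth parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    p0 = rng.uniform(0.1, 0.9, size=L)
    demes = [
        (rng.random((n, L)) < p0).astype(np.int8) + (rng.random((n, L)) < p0).astype(np.int8)
        for n in (cfg.ne1, cfg.ne2)
    ]
    mig = (cfg.m12, cfg.m21)
    for _ in range(cfg.n_generations):
        new = []
        for d, (n, m) in enumerate(zip((cfg.ne1, cfg.ne2), mig)):
            other = 1 - d
            gametes = []
            for _side in range(2):
                from_other = rng.random(n) < m
                idx_local = rng.integers(0, demes[d].shape[0], size=n)
                idx_other = rng.integers(0, demes[other].shape[0], size=n)
                parents = np.where(from_other[:, None],
                                   demes[other][idx_other],
                                   demes[d][idx_local])
                gametes.append(_transmit(rng, parents, cfg.mutation_rate))
            new.append((gametes[0].astype(np.int8) + gametes[1].astype(np.int8)))
        demes = new
    s1 = rng.choice(cfg.ne1, size=min(cfg.sample1, cfg.ne1), replace=False)
    s2 = rng.choice(cfg.ne2, size=min(cfg.sample2, cfg.ne2), replace=False)
    calls = np.vstack([demes[0][s1], demes[1][s2]])
    names1 = [f"d1_{i:03d}" for i in range(len(s1))]
    names2 = [f"d2_{i:03d}" for i in range(len(s2))]
    loci = [(f"ctg{j:05d}", 1, "A", "T") for j in range(L)]
    gm = GenotypeMatrix(samples=names1 + names2, loci=loci, calls=calls)
    popmap = {"deme1": names1, "deme2": names2}
    truth = {
        "ne1": cfg.ne1, "ne2": cfg.ne2, "m12": cfg.m12, "m21": cfg.m21,
        "n_generations": cfg.n_generations, "seed": cfg.seed,
        "ancestral_freqs": "uniform(0.1, 0.9)",
    }
    return gm, popmap, truth


def simulate_wright_fisher(
    ne: int,
    n_loci: int,
    n_generations: int,
    sample_size: int,
    seed: int = 0,
    init_freq: float = 0.5,
) -> GenotypeMatrix:
    """Single closed Wright-Fisher population (for LD-based Ne recovery).

    Individual-based transmission generates the drift LD between unlinked
    loci that the LD method measures; loci sit on separate contigs.
    """
    rng = np.random.default_rng(seed)
    calls = (
        (rng.random((ne, n_loci)) < init_freq).astype(np.int8)
        + (rng.random((ne, n_loci)) < init_freq).astype(np.int8)
    )
    for _ in range(n_generations):
        g1 = _transmit(rng, calls[rng.integers(0, ne, size=ne)], 0.0)
        g2 = _transmit(rng, calls[rng.integers(0, ne, size=ne)], 0.0)
        calls = g1.astype(np.int8) + g2.astype(np.int8)
    pick = rng.choice(ne, size=min(sample_size, ne), replace=False)
    samples = [f"wf{i:03d}" for i in range(len(pick))]
    loci = [(f"ctg{j:05d}", 1, "A", "T") for j in range(n_loci)]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls[pick])


def inject_artifacts(
    gm: GenotypeMatrix,
    clone_pairs: int = 0,
    discordance: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict]:
    """Append near-duplicate samples and sprinkle missing calls.

    Each planted clone copies a distinct existing sample and perturbs each
    call to a different genotype value with probability ``discordance``;
    afterwards random calls across the whole matrix are set MISSING at
    ``missing_rate``.  Returns the augmented matrix and a provenance map of
    the planted truths.
    """
    if not (0 <= discordance < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    if clone_pairs > gm.n_samples:
        raise ValueError("more clone pairs than source samples")
    rng = np.random.default_rng(seed)
    sources = rng.choice(gm.n_samples, size=clone_pairs, replace=False)
    rows = [gm.calls]
    names = list(gm.samples)
    planted = []
    for s in sources:
        dup = gm.calls[s].copy()
        if discordance > 0:
            hit = (rng.random(gm.n_loci) < discordance) & (dup != MISSING)
            shift = rng.integers(1, 3, size=gm.n_loci)
            dup = np.where(hit, (dup + shift) % 3, dup).astype(np.int8)
        rows.append(dup[None, :])
        clone_name = f"{gm.samples[s]}_clone"
        names.append(clone_name)
        planted.append({"source": gm.samples[s], "clone": clone_name})
    calls = np.vstack(rows)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)
    out = GenotypeMatrix(samples=names, loci=list(gm.loci), calls=calls)
    provenance = {
        "clone_pairs": planted,
        "discordance": discordance,
        "missing_rate": missing_rate,
        "seed": seed,
    }
    return out, provenance


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float) + "\n")
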