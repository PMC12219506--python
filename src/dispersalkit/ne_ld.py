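"""Contemporary effective population size from linkage disequilibrium.

In a closed population of effective size Ne, drift generates association
between unlinked loci with expectation E[r^2] ~ 1/(3Ne) plus a sampling
term that depends only on the number of genotyped individuals S.  Burrows'
composite disequilibrium makes r^2 computable from unphased genotypes.
The Ne back-calculation uses the published random-mating LD-method
constants: for S >= 30, E[r^2_sample] = 1/S + 3.19/S^2 and

    Ne = (1/3 + sqrt(1/9 - 2.76 r^2')) / (2 r^2'),   r^2' = r^2 - E[r^2_sample]

and for S < 30 the small-sample polynomial E[r^2_sample] = 0.0018 +
0.907/S + 4.44/S^2 with Ne = (0.308 + sqrt(0.308^2 - 2.08 r^2'))/(2 r^2').
Non-positive r^2' (no drift signal above sampling noise) yields an
infinite estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["NeEstimate", "burrows_r2", "ne_from_r2", "estimate_ne"]


@dataclass
class NeEstimate:
    ne: float  # math.inf when no drift signal
    r2_mean: float
    r2_sample_expectation: float
    n_pairs: int
    maf_cutoff: float
    s_harmonic: float


def _pair_iter_blocks(keep_contig: np.ndarray) -> np.ndarray:
    """Boolean (L, L) matrix marking cross-contig locus pairs."""
    same = keep_contig[:, None] == keep_contig[None, :]
    return ~same


def burrows_r2(
    gm: GenotypeMatrix,
    pop: list[str] | None = None,
    maf_cutoff: float = 0.02,
    cross_contig_only: bool = True,
) -> tuple[float, int, float]:
    """Weighted mean Burrows' composite r^2 across qualifying locus pairs.

    For loci A, B with alt-dosage genotypes g_A, g_B the composite
    disequilibrium is estimated as
    ``delta = (n/(n-1)) * (mean(g_A g_B)/2 - 2 p_A p_B)`` over individuals
    called at both loci, and
    ``r^2 = delta^2 / [(p_A(1-p_A) + D_A)(p_B(1-p_B) + D_B)]`` where
    ``D_A = P_AA - p_A^2`` is the within-locus Hardy-Weinberg disequilibrium
    (Weir's recommended denominator, as used by the published LD method; it
    reduces to p(1-p)q(1-q) under Hardy-Weinberg proportions).
    Pairs are restricted to loci on different contigs (proxy for unlinked)
    unless ``cross_contig_only`` is False; the mean is weighted by the
    pairwise sample size.

    Returns ``(r2_mean, n_pairs, s_harmonic)`` where s_harmonic is the
    harmonic mean pairwise sample size.
    """
    if pop is not None:
        lookup = {s: i for i, s in enumerate(gm.samples)}
        idx = np.array([lookup[s] for s in pop])
        calls = gm.calls[idx]
    else:
        calls = gm.calls
    ok = calls != MISSING
    n_called = ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (maf >= maf_cutoff) & (n_called >= 2)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 loci pass the MAF cutoff")
    calls = calls[:, keep]
    ok = ok[:, keep]
    contigs = np.array([gm.loci[i][0] for i in np.flatnonzero(keep)])
    L = calls.shape[1]

    g = np.where(ok, calls, 0).astype(np.float64)
    okf = ok.astype(np.float64)
    hom = ((calls == 2) & ok).astype(np.float64)
    n_pair = okf.T @ okf  # pairwise complete sample sizes
    sum_ab = (g.T @ g) / 2.0  # sum over i of g_A g_B / 2
    sum_a = g.T @ okf  # sum of g_A over individuals called at both
    sum_hom = hom.T @ okf  # count of alt homozygotes over the same set
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = sum_a / (2.0 * n_pair)  # pairwise allele freq of A (rows) given B
        p_b = p_a.T
        mean_ab = sum_ab / n_pair
        delta = mean_ab - 2.0 * p_a * p_b
        corr = n_pair / np.maximum(n_pair - 1.0, 1e-12)
        delta = delta * corr
        d_hw_a = sum_hom / n_pair - p_a ** 2  # within-locus HW disequilibrium
        term_a = p_a * (1 - p_a) + d_hw_a
        denom = term_a * term_a.T
        r2 = np.where(denom > 0, delta ** 2 / denom, np.nan)

    pairmask = np.triu(np.ones((L, L), dtype=bool), k=1)
    if cross_contig_only:
        pairmask &= _pair_iter_blocks(contigs)
    pairmask &= np.isfinite(r2) & (n_pair >= 2)
    if not pairmask.any():
        raise ValueError("no qualifying locus pairs")
    w = n_pair[pairmask]
    vals = r2[pairmask]
    r2_mean = float((vals * w).sum() / w.sum())
    s_harm = float(len(w) / (1.0 / w).sum())
    return r2_mean, int(pairmask.sum()), s_harm


def ne_from_r2(r2_mean: float, s_harmonic: float,
               n_pairs: int = 0, maf_cutoff: float = 0.02) -> NeEstimate:
    """Effective size from mean composite r^2 and harmonic mean sample size."""
    if s_harmonic >= 30:
        e_sample = 1.0 / s_harmonic + 3.19 / s_harmonic ** 2
        k1, k2 = 1.0 / 3.0, 2.76
    else:
        e_sample = 0.0018 + 0.907 / s_harmonic + 4.44 / s_harmonic ** 2
        k1, k2 = 0.308, 2.08
    r2p = r2_mean - e_sample
    if r2p <= 0:
        ne = math.inf
    else:
        disc = k1 ** 2 - k2 * r2p
        if disc < 0:
            logger.warning("ne_from_r2: negative discriminant; Ne -> infinite")
            ne = math.inf
        else:
            ne = (k1 + math.sqrt(disc)) / (2.0 * r2p)
            if ne <= 0:
                ne = math.inf
    return NeEstimate(ne=ne, r2_mean=r2_mean, r2_sample_expectation=e_sample,
                      n_pairs=n_pairs, maf_cutoff=maf_cutoff,
                      s_harmonic=s_harmonic)


def estimate_ne(
    gm: GenotypeMatrix,
    pop: list[str] | None = None,
    maf_cutoff: float = 0.02,
    cross_contig_only: bool = True,
) -> NeEstimate:
    """Convenience wrapper: Burrows r^2 then the LD-method Ne."""
    r2_mean, n_pairs, s_harm = burrows_r2(gm, pop, maf_cutoff, cross_contig_only)
    return ne_from_r2(r2_mean, s_harm, n_pairs=n_pairs, maf_cutoff=maf_cutoff)
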