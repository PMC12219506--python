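"""Joint allele-frequency spectra and diffusion-parameter conversion.

The two-population folded joint allele-frequency spectrum (JAFS) is the 2D
histogram of minor-allele counts across population pairs; singleton and
doubleton cells (combined minor count 1 or 2) are masked because low-count
variants are enriched for sequencing error.  Fitted diffusion-model
parameters (theta, nu1, nu2, M12, M21, T in units of the ancestral
population) are converted into natural units with a per-base per-generation
mutation rate mu, callable sequence length L and generation time g:

    Nref = theta / (4 mu L)      Ne_i = nu_i * Nref
    m_ij = M_ij / (2 Nref)       Nem_ij = Ne_i * m_ij
    T_years = 2 * Nref * T * g

Index convention: 12 denotes migration INTO population 1 from population 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_MU = 1.2e-8  # per base per generation, Acroporidae sequence-divergence estimate
DEFAULT_GEN_TIME = 3.0  # years

__all__ = [
    "FoldedJAFS",
    "DemographicEstimates",
    "build_folded_jafs",
    "convert_params",
    "migrants_per_generation",
    "convert_params_table",
]


@dataclass
class FoldedJAFS:
    """Folded two-population joint allele-frequency spectrum.

    ``counts[i, j]`` is the (possibly fractional, under projection) number
    of SNPs with minor-allele count i in population 1 and j in population
    2; ``mask`` is True for excluded cells (low combined counts and the
    un-populated half beyond the fold).
    """

    counts: np.ndarray
    mask: np.ndarray
    n1: int
    n2: int

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def unmasked_total(self) -> float:
        return float(self.counts[~self.mask].sum())

    def to_tsv(self, path: str | Path) -> None:
        base = Path(path)
        pd.DataFrame(self.counts).to_csv(base, sep="\t", header=False, index=False)
        pd.DataFrame(self.mask.astype(int)).to_csv(
            base.with_suffix(base.suffix + ".mask"), sep="\t", header=False, index=False
        )


@dataclass
class DemographicEstimates:
    nref: float
    ne1: float
    ne2: float
    m12: float
    m21: float
    nem12: float
    nem21: float
    t_years: float
    mu: float
    L: float
    g: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _project_weights(k: int, c: int, m: int) -> np.ndarray:
    """Hypergeometric weights P(j alt copies | subsample m of k with c alt)."""
    j = np.arange(m + 1, dtype=float)
    with np.errstate(invalid="ignore"):
        lw = (
            gammaln(c + 1) - gammaln(j + 1) - gammaln(c - j + 1)
            + gammaln(k - c + 1) - gammaln(m - j + 1) - gammaln(k - c - (m - j) + 1)
            - (gammaln(k + 1) - gammaln(m + 1) - gammaln(k - m + 1))
        )
    valid = (j <= c) & ((m - j) <= (k - c))
    w = np.where(valid, np.exp(lw), 0.0)
    return w


def build_folded_jafs(
    gm: GenotypeMatrix,
    pop1: list[str],
    pop2: list[str],
    mask_low: int = 2,
    projection: tuple[int, int] | None = None,
) -> FoldedJAFS:
    """Fold a SNP matrix into a masked two-population JAFS.

    Without projection, SNPs with any missing call in either population are
    dropped; with ``projection=(n1, n2)`` (diploid sizes) each SNP is
    hypergeometrically projected down to 2*n1 and 2*n2 gene copies and
    contributes fractional weight.  Folding is on the combined minor
    allele; a site at exactly 50% combined frequency is assigned to the
    lexicographically lower cell of its fold pair.  Cells with combined
    count <= ``mask_low`` are masked, as are fold-redundant cells.
    """
    if set(pop1) & set(pop2):
        raise ValueError("populations must be disjoint")
    lookup = {s: i for i, s in enumerate(gm.samples)}
    i1 = np.array([lookup[s] for s in pop1])
    i2 = np.array([lookup[s] for s in pop2])
    if projection is None:
        n1, n2 = len(pop1), len(pop2)
    else:
        n1, n2 = projection
    k1, k2 = 2 * n1, 2 * n2
    unfolded = np.zeros((k1 + 1, k2 + 1))
    n_used = 0
    for j in range(gm.n_loci):
        if gm.invariant_flag[j]:
            continue
        c1_col = gm.calls[i1, j]
        c2_col = gm.calls[i2, j]
        ok1, ok2 = c1_col != MISSING, c2_col != MISSING
        kk1, kk2 = 2 * int(ok1.sum()), 2 * int(ok2.sum())
        c1 = int(c1_col[ok1].sum())
        c2 = int(c2_col[ok2].sum())
        if projection is None:
            if kk1 != k1 or kk2 != k2:
                continue
            unfolded[c1, c2] += 1.0
        else:
            if kk1 < k1 or kk2 < k2:
                continue
            w = np.outer(_project_weights(kk1, c1, k1), _project_weights(kk2, c2, k2))
            unfolded += w
        n_used += 1
    if unfolded.sum() == 0:
        warnings.warn("monomorphic input: empty spectrum")
    # fold on the combined minor allele: cell (a, b) and its complement
    # (k1-a, k2-b) collapse onto whichever has the smaller combined count;
    # exact-half ties go to the lexicographically lower cell of the pair
    counts = np.zeros_like(unfolded)
    S = k1 + k2
    keepable = np.zeros(unfolded.shape, dtype=bool)
    for a in range(k1 + 1):
        for b in range(k2 + 1):
            fa, fb = k1 - a, k2 - b
            if a + b < fa + fb or (a + b == fa + fb and (a, b) <= (fa, fb)):
                keepable[a, b] = True
                counts[a, b] = unfolded[a, b]
                if (a, b) != (fa, fb):
                    counts[a, b] += unfolded[fa, fb]
    comb = np.add.outer(np.arange(k1 + 1), np.arange(k2 + 1))
    mask = (comb <= mask_low) | ~keepable
    logger.info("build_folded_jafs: %d SNPs used", n_used)
    return FoldedJAFS(counts=counts, mask=mask, n1=n1, n2=n2)


def convert_params(
    theta: float,
    nu1: float,
    nu2: float,
    M12: float,
    M21: float,
    T: float,
    mu: float = DEFAULT_MU,
    L: float = 0.0,
    g: float = DEFAULT_GEN_TIME,
) -> DemographicEstimates:
    """Convert scaled diffusion parameters to natural units.

    ``L`` is the callable sequence length in bases (the all-sites span the
    SNPs were ascertained from, not the SNP count).
    """
    if L <= 0:
        raise ValueError("callable length L must be positive")
    for name, v in [("theta", theta), ("nu1", nu1), ("nu2", nu2), ("mu", mu), ("g", g)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if M12 < 0 or M21 < 0 or T < 0:
        raise ValueError("M12, M21, T must be non-negative")
    nref = theta / (4.0 * mu * L)
    ne1 = nu1 * nref
    ne2 = nu2 * nref
    m12 = M12 / (2.0 * nref)
    m21 = M21 / (2.0 * nref)
    return DemographicEstimates(
        nref=nref, ne1=ne1, ne2=ne2, m12=m12, m21=m21,
        nem12=ne1 * m12, nem21=ne2 * m21,
        t_years=2.0 * nref * T * g, mu=mu, L=L, g=g,
    )


def migrants_per_generation(ne_recipient: float, m: float) -> float:
    """Gene flow Nem: migrant individuals per generation into the recipient."""
    if ne_recipient <= 0 or m < 0:
        raise ValueError("require ne_recipient > 0 and m >= 0")
    return ne_recipient * m


def convert_params_table(
    params: pd.DataFrame | str | Path,
    mu: float = DEFAULT_MU,
    g: float = DEFAULT_GEN_TIME,
) -> pd.DataFrame:
    """Convert a fitted-parameter table (columns theta, nu1, nu2, M12, M21,
    T, L, optionally 'pair') into natural units, one row per pair."""
    if not isinstance(params, pd.DataFrame):
        params = pd.read_csv(params)
    rows = []
    for _, r in params.iterrows():
        est = convert_params(r["theta"], r["nu1"], r["nu2"], r["M12"], r["M21"],
                             r["T"], mu=mu, L=r["L"], g=g)
        row = est.to_dict()
        if "pair" in params.columns:
            row["pair"] = r["pair"]
        rows.append(row)
    return pd.DataFrame(rows)
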