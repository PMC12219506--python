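"""Within-population diversity and pairwise differentiation.

Nucleotide diversity (pi) is computed from all-sites data (variant plus
invariant) because omitting monomorphic sites inflates per-base diversity;
windows are combined as a ratio of summed pairwise differences to summed
comparisons, which makes the combined value invariant to the window
partition.  Expected heterozygosity and FIS use only loci fully called
within the population.  Allelic richness and private alleles are rarefied
to a standardized number of gene copies g.  Pairwise FST is the
Weir-Cockerham (1984) theta as a multi-locus ratio of sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityReport",
    "pi_windowed",
    "he_fis",
    "allelic_richness",
    "private_alleles",
    "pairwise_fst",
    "diversity_table",
]


@dataclass
class DiversityReport:
    population: str
    n: int
    pi: float
    he: float
    fis: float | None
    ar_g: float
    pa_g: float
    g: int


def _pop_index(gm: GenotypeMatrix, pop: list[str]) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(gm.samples)}
    missing = [s for s in pop if s not in lookup]
    if missing:
        raise KeyError(f"samples not in matrix: {missing}")
    return np.array([lookup[s] for s in pop], dtype=int)


def _site_diffs_comps(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pairwise allele differences and comparisons.

    With k non-missing allele copies of which a are the alternate allele,
    the number of differing unordered copy pairs is a*(k-a) and the number
    of comparisons is k*(k-1)/2.
    """
    ok = calls != MISSING
    a = np.where(ok, calls, 0).sum(axis=0).astype(np.int64)
    k = 2 * ok.sum(axis=0).astype(np.int64)
    diffs = a * (k - a)
    comps = k * (k - 1) // 2
    return diffs, comps


def pi_windowed(
    gm: GenotypeMatrix, pop: list[str], window: int = 1000
) -> tuple[pd.DataFrame, float]:
    """Windowed and combined nucleotide diversity from an all-sites matrix.

    Returns ``(per_window, combined)``: per-window pi = sum(diffs)/sum(comps)
    within each ``window``-bp bin per contig (NaN when a window has no
    comparisons), and the combined count-weighted pi over all sites.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    idx = _pop_index(gm, pop)
    diffs, comps = _site_diffs_comps(gm.calls[idx])
    contigs = np.array([l[0] for l in gm.loci])
    pos = np.array([l[1] for l in gm.loci], dtype=np.int64)
    win_start = ((pos - 1) // window) * window + 1
    df = pd.DataFrame({"contig": contigs, "window_start": win_start,
                       "diffs": diffs, "comps": comps})
    agg = df.groupby(["contig", "window_start"], sort=True).sum().reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["pi"] = np.where(agg["comps"] > 0, agg["diffs"] / agg["comps"], np.nan)
    agg["n_sites"] = df.groupby(["contig", "window_start"], sort=True).size().values
    total_comps = int(comps.sum())
    combined = float(diffs.sum() / total_comps) if total_comps > 0 else float("nan")
    return agg[["contig", "window_start", "n_sites", "diffs", "comps", "pi"]], combined


def he_fis(
    gm: GenotypeMatrix, pop: list[str], unbiased: bool = False
) -> tuple[float, float | None]:
    """Expected heterozygosity over all sites and population-level FIS.

    Only loci with no missing calls within the population are used.  Per
    site He = 1 - sum_k p_k^2 (times 2n/(2n-1) if ``unbiased``); ``he`` is
    the mean over all retained sites, invariant sites contributing zero.
    FIS = 1 - mean(Ho)/mean(He) over variant sites with He > 0; None when
    no such site exists.
    """
    idx = _pop_index(gm, pop)
    calls = gm.calls[idx]
    full = ~(calls == MISSING).any(axis=0)
    if not full.any():
        raise ValueError("no fully-called loci in population")
    calls = calls[:, full]
    n = len(idx)
    p = calls.sum(axis=0) / (2.0 * n)
    he_site = 2.0 * p * (1.0 - p)
    if unbiased:
        he_site *= (2.0 * n) / (2.0 * n - 1.0)
    ho_site = (calls == 1).mean(axis=0)
    he = float(he_site.mean())
    seg = he_site > 0
    if not seg.any():
        return he, None
    fis = 1.0 - float(ho_site[seg].mean()) / float(he_site[seg].mean())
    return he, fis


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    """log C(n, k) elementwise, -inf where n < k."""
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(n - k + 1) - gammaln(k + 1)
    return np.where(n >= k, out, -np.inf)


def _absence_prob(n_total: np.ndarray, n_allele: np.ndarray, g: int) -> np.ndarray:
    """P(allele absent from a subsample of g copies) = C(N-Nk, g)/C(N, g)."""
    return np.exp(_log_comb(n_total - n_allele, g) - _log_comb(n_total, g))


def _allele_counts(gm: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (total copies N, alt copies Nk) within the sample subset."""
    calls = gm.calls[idx]
    ok = calls != MISSING
    alt = np.where(ok, calls, 0).sum(axis=0).astype(np.int64)
    total = 2 * ok.sum(axis=0).astype(np.int64)
    return total, alt


def allelic_richness(gm: GenotypeMatrix, pop: list[str], g: int) -> float:
    """Mean rarefied allelic richness at g gene copies.

    Per locus AR = sum over alleles of the probability that the allele
    appears in a random subsample of g copies; loci with fewer than g
    called copies are dropped (logged).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    idx = _pop_index(gm, pop)
    total, alt = _allele_counts(gm, idx)
    ok = total >= g
    if not ok.any():
        raise ValueError(f"no locus has >= {g} called copies")
    dropped = int((~ok).sum())
    if dropped:
        logger.info("allelic_richness: dropped %d loci with < g copies", dropped)
    total, alt = total[ok], alt[ok]
    ar = (1.0 - _absence_prob(total, alt, g)) + (1.0 - _absence_prob(total, total - alt, g))
    return float(ar.mean())


def private_alleles(
    gm: GenotypeMatrix, pops: dict[str, list[str]], g: int
) -> dict[str, float]:
    """Rarefied private allelic richness per population at g gene copies.

    The contribution of allele k at a locus to population j is the
    probability of appearing in a g-copy subsample from j times the
    probability of being absent from g-copy subsamples of every other
    population; values are summed over loci and alleles.  Loci with fewer
    than g copies in any population are dropped.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    names = list(pops)
    totals, alts = {}, {}
    ok = np.ones(gm.n_loci, dtype=bool)
    for name in names:
        t, a = _allele_counts(gm, _pop_index(gm, pops[name]))
        totals[name], alts[name] = t, a
        ok &= t >= g
    if not ok.any():
        raise ValueError(f"no locus has >= {g} copies in every population")
    out: dict[str, float] = {}
    for name in names:
        total = 0.0
        for allele in ("alt", "ref"):
            counts = {
                p: (alts[p][ok] if allele == "alt" else totals[p][ok] - alts[p][ok])
                for p in names
            }
            present = 1.0 - _absence_prob(totals[name][ok], counts[name], g)
            absent_others = np.ones(int(ok.sum()))
            for other in names:
                if other != name:
                    absent_others = absent_others * _absence_prob(
                        totals[other][ok], counts[other], g
                    )
            total += float((present * absent_others).sum())
        out[name] = total
    return out


def _wc_components(
    calls1: np.ndarray, calls2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components (a, a+b+c)."""
    r = 2
    comps_a = []
    comps_abc = []
    for j in range(calls1.shape[1]):
        cols = []
        for calls in (calls1, calls2):
            col = calls[:, j]
            col = col[col != MISSING]
            cols.append(col)
        n_i = np.array([len(c) for c in cols], dtype=float)
        if (n_i < 1).any() or n_i.sum() < 3:
            comps_a.append(0.0)
            comps_abc.append(0.0)
            continue
        p_i = np.array([c.sum() / (2 * len(c)) for c in cols])
        h_i = np.array([(c == 1).mean() for c in cols])
        nbar = n_i.mean()
        if nbar <= 1:
            comps_a.append(0.0)
            comps_abc.append(0.0)
            continue
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        if nc <= 0:
            comps_a.append(0.0)
            comps_abc.append(0.0)
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        comps_a.append(a)
        comps_abc.append(a + b + c)
    return np.asarray(comps_a), np.asarray(comps_abc)


def pairwise_fst(gm: GenotypeMatrix, pops: dict[str, list[str]]) -> pd.DataFrame:
    """Pairwise Weir-Cockerham theta between populations.

    Multi-locus ratio of sums of the variance components; negative
    estimates are reported as computed.
    """
    names = list(pops)
    if len(names) < 2:
        raise ValueError("need >= 2 populations")
    idx = {p: _pop_index(gm, pops[p]) for p in names}
    for p in names:
        if len(idx[p]) < 2:
            raise ValueError(f"population {p!r} has < 2 samples")
        if (gm.calls[idx[p]] == MISSING).all():
            raise ValueError(f"population {p!r} has no non-missing calls")
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, p1 in enumerate(names):
        for p2 in names[i + 1:]:
            a, abc = _wc_components(gm.calls[idx[p1]], gm.calls[idx[p2]])
            denom = abc.sum()
            theta = float(a.sum() / denom) if denom != 0 else float("nan")
            mat.loc[p1, p2] = mat.loc[p2, p1] = theta
    return mat


def diversity_table(
    allsites: GenotypeMatrix,
    pops: dict[str, list[str]],
    window: int = 1000,
    min_n: int = 8,
    g: int | None = None,
) -> pd.DataFrame:
    """Per-population diversity summary (pi, He, FIS, AR, PA).

    Populations with fewer than ``min_n`` samples are excluded.  The
    rarefaction size defaults to ``2 * (smallest included n - 1)`` gene
    copies.
    """
    included = {p: s for p, s in pops.items() if len(s) >= min_n}
    if len(included) < 1:
        raise ValueError(f"no population has >= {min_n} samples")
    if g is None:
        g = 2 * (min(len(s) for s in included.values()) - 1)
    variant = allsites.variant_only()
    pa = (
        private_alleles(variant, included, g) if len(included) >= 2
        else {p: float("nan") for p in included}
    )
    rows = []
    for p, samples in included.items():
        _, pi = pi_windowed(allsites, samples, window=window)
        he, fis = he_fis(allsites, samples)
        ar = allelic_richness(variant, samples, g)
        rows.append(DiversityReport(population=p, n=len(samples), pi=pi, he=he,
                                    fis=fis, ar_g=ar, pa_g=pa[p], g=g))
    return pd.DataFrame([r.__dict__ for r in rows])
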