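"""Genotype input, filtering, clone detection and linkage pruning.

The central container is :class:`GenotypeMatrix`: a samples x loci matrix of
diploid alternate-allele counts (0/1/2, or -1 for missing) for biallelic
sites, optionally carrying per-call read depths and a per-locus flag marking
invariant (monomorphic) sites from an all-sites VCF.

The filtering cascade mirrors common RAD-seq practice for clonal marine
invertebrates: per-call depth bounds, per-site missingness, minor allele
count (MAC) and frequency (MAF) thresholds, per-sample missingness, removal
of clonal replicates by allelic similarity, and variance-inflation-factor
(VIF) pruning of physically linked SNPs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SampleTable",
    "ClonalReport",
    "read_genotypes",
    "write_vcf",
    "filter_sites",
    "filter_samples",
    "allelic_similarity",
    "detect_clones",
    "prune_linked",
]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-loci diploid genotype matrix.

    Attributes
    ----------
    samples
        Ordered sample identifiers.
    loci
        Ordered ``(contig, position, ref, alt)`` tuples; position is 1-based.
        Invariant sites carry ``alt == "."``.
    calls
        ``(n_samples, n_loci)`` int8 array of alternate-allele counts in
        {0, 1, 2}, with :data:`MISSING` (-1) for no-calls.
    depths
        Optional ``(n_samples, n_loci)`` int32 array of read depths
        (-1 where unknown).
    invariant_flag
        Boolean per-locus array; True where the site has no observed
        alternate allele.
    """

    samples: list[str]
    loci: list[tuple[str, int, str, str]]
    calls: np.ndarray
    depths: np.ndarray | None = None
    invariant_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        valid = np.isin(self.calls, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("calls must be in {0,1,2} or MISSING (-1)")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int32)
            if self.depths.shape != self.calls.shape:
                raise ValueError("depths shape mismatch")
        if self.invariant_flag is None:
            with np.errstate(invalid="ignore"):
                self.invariant_flag = ~(self.calls > 0).any(axis=0)
        self.invariant_flag = np.asarray(self.invariant_flag, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_missingness(self) -> np.ndarray:
        """Fraction of missing calls per sample."""
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask.mean(axis=1)

    def site_missingness(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return self.missing_mask.mean(axis=0)

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            loci=list(self.loci),
            calls=self.calls[index],
            depths=None if self.depths is None else self.depths[index],
            invariant_flag=self.invariant_flag.copy(),
        )

    def take_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in index],
            calls=self.calls[:, index],
            depths=None if self.depths is None else self.depths[:, index],
            invariant_flag=self.invariant_flag[index],
        )

    def variant_only(self) -> "GenotypeMatrix":
        return self.take_loci(np.flatnonzero(~self.invariant_flag))

    def alt_counts(self) -> np.ndarray:
        """Per-site alternate allele count over non-missing calls."""
        c = np.where(self.calls == MISSING, 0, self.calls)
        return c.sum(axis=0)

    def called_copies(self) -> np.ndarray:
        """Per-site number of non-missing allele copies (2 per called sample)."""
        return 2 * (~self.missing_mask).sum(axis=0)

    # -- TSV round trip ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write samples-as-rows TSV with 0/1/2/NA values."""
        cols = [f"{c}:{p}:{r}:{a}" for c, p, r, a in self.loci]
        df = pd.DataFrame(
            np.where(self.calls == MISSING, np.nan, self.calls),
            index=self.samples,
            columns=cols,
        )
        df.to_csv(path, sep="\t", na_rep="NA", index_label="sample",
                  float_format="%.0f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        loci = []
        for col in df.columns:
            contig, pos, ref, alt = col.rsplit(":", 3)
            loci.append((contig, int(pos), ref, alt))
        calls = df.to_numpy(dtype=float)
        calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
        return cls(samples=list(df.index.astype(str)), loci=loci, calls=calls)


class SampleTable:
    """Per-sample spatial and population metadata.

    Wraps a :class:`pandas.DataFrame` indexed by sample id with columns
    ``population``, ``site``, ``latitude``, ``longitude``, ``depth`` and
    (optionally, for planar-coordinate data) ``x``/``y`` in meters.
    """

    REQUIRED = ("population", "site")

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if "latitude" in df.columns:
            lat = df["latitude"].dropna()
            if ((lat < -90) | (lat > 90)).any():
                raise ValueError("latitude outside [-90, 90]")
        if "longitude" in df.columns:
            lon = df["longitude"].dropna()
            if ((lon < -180) | (lon > 180)).any():
                raise ValueError("longitude outside [-180, 180]")
        self.df = df

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleTable":
        df = pd.read_csv(path)
        id_col = "sample" if "sample" in df.columns else df.columns[0]
        return cls(df.set_index(id_col))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="sample")

    @property
    def samples(self) -> list[str]:
        return list(self.df.index.astype(str))

    def subset(self, samples: Iterable[str]) -> "SampleTable":
        return SampleTable(self.df.loc[list(samples)])

    def populations(self) -> dict[str, list[str]]:
        """Mapping of population label -> sample ids."""
        out: dict[str, list[str]] = {}
        for sid, pop in self.df["population"].items():
            out.setdefault(str(pop), []).append(str(sid))
        return out

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ClonalReport:
    """Clonal (near-identical multilocus genotype) pairs and removals."""

    pairs: list[tuple[str, str, float]]
    threshold: float
    removed: list[str]
    similarity_histogram: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "pairs": [
                {"a": a, "b": b, "similarity": round(s, 10)}
                for a, b, s in self.pairs
            ],
            "removed": self.removed,
            "similarity_histogram": [round(s, 10) for s in self.similarity_histogram],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, mode: str = "variant") -> GenotypeMatrix:
    """Read a VCF (optionally gzipped) into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF 4.x file with diploid genotypes.
    mode
        ``"variant"`` keeps biallelic SNP records only; ``"all-sites"``
        additionally keeps monomorphic (invariant) records, flagged in
        ``invariant_flag``.  Indels and multi-allelic records are excluded
        in both modes.
    """
    from cyvcf2 import VCF

    if mode not in ("variant", "all-sites"):
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read VCF: {path}")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    loci: list[tuple[str, int, str, str]] = []
    calls_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    n_excluded = 0
    have_depth = False
    for rec in vcf:
        alts = [a for a in rec.ALT if a not in (".", "<NON_REF>")]
        if len(alts) > 1:
            n_excluded += 1
            continue
        ref = rec.REF
        alt = alts[0] if alts else "."
        if len(ref) != 1 or (alt != "." and len(alt) != 1):
            n_excluded += 1  # indel or complex allele
            continue
        if alt == "." and mode == "variant":
            continue
        ploidies = {len([a for a in g[:-1] if a is not None]) for g in rec.genotypes}
        ploidies.discard(0)
        if ploidies - {2}:
            raise ValueError(
                f"non-diploid call at {rec.CHROM}:{rec.POS} (ploidy {ploidies})"
            )
        # gts012: 0/1/2 = alt count, 3 = missing
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        if alt == ".":
            g[g > 0] = 0  # no alt allele exists at an invariant site
        calls_rows.append(g)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            have_depth = True
            d = np.asarray(dp, dtype=np.int32).reshape(-1)
            d[d < 0] = -1
        else:
            d = np.full(len(samples), -1, dtype=np.int32)
        depth_rows.append(d)
        loci.append((rec.CHROM, rec.POS, ref, alt))
    if n_excluded:
        logger.info("read_genotypes: excluded %d multiallelic/indel records", n_excluded)
    calls = (
        np.array(calls_rows, dtype=np.int8).T
        if calls_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depths = (
        np.array(depth_rows, dtype=np.int32).T
        if (depth_rows and have_depth)
        else None
    )
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls, depths=depths)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 representation of *gm* (uncompressed text)."""
    path = Path(path)
    contigs = []
    for c, *_ in gm.loci:
        if c not in contigs:
            contigs.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dispersalkit\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (contig, pos, ref, alt) in enumerate(gm.loci):
            gts = "\t".join(gt_strings[int(g)] for g in gm.calls[:, j])
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------


def filter_sites(
    gm: GenotypeMatrix,
    mac_min: int = 3,
    depth_min: int = 5,
    depth_max: int = 100,
    max_site_missing: float = 0.5,
    maf_min: float = 0.01,
    apply_to_invariant: bool = False,
) -> GenotypeMatrix:
    """Apply per-call depth and per-site MAC/MAF/missingness filters.

    Order is fixed: depth (call-level) -> missingness -> MAC -> MAF.
    MAC/MAF count the *minor* allele over non-missing calls; an exact 50%
    frequency passes.  Invariant sites (all-sites input) are exempt from
    MAC/MAF unless ``apply_to_invariant``.
    """
    for name, v in [("mac_min", mac_min), ("depth_min", depth_min),
                    ("depth_max", depth_max), ("max_site_missing", max_site_missing),
                    ("maf_min", maf_min)]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    calls = gm.calls.copy()
    if gm.depths is not None:
        known = gm.depths >= 0
        bad = known & ((gm.depths < depth_min) | (gm.depths > depth_max))
        calls[bad] = MISSING
        logger.info("filter_sites: %d calls set MISSING by depth", int(bad.sum()))
    work = replace(gm, calls=calls, depths=gm.depths,
                   invariant_flag=gm.invariant_flag.copy())

    miss = work.site_missingness()
    keep = miss <= max_site_missing
    n_miss = int((~keep).sum())

    alt = work.alt_counts()
    copies = work.called_copies()
    minor = np.minimum(alt, copies - alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        mfreq = np.where(copies > 0, minor / np.maximum(copies, 1), 0.0)
    variant = ~work.invariant_flag if not apply_to_invariant else np.ones(work.n_loci, bool)
    fail_mac = variant & (minor < mac_min)
    fail_maf = variant & (mfreq < maf_min)
    n_mac = int((keep & fail_mac).sum())
    keep &= ~fail_mac
    n_maf = int((keep & fail_maf).sum())
    keep &= ~fail_maf
    logger.info(
        "filter_sites: dropped %d missingness, %d MAC, %d MAF; %d/%d sites kept",
        n_miss, n_mac, n_maf, int(keep.sum()), gm.n_loci,
    )
    if not keep.any():
        raise ValueError("no sites survive filtering")
    return work.take_loci(np.flatnonzero(keep))


def filter_samples(gm: GenotypeMatrix, max_sample_missing: float = 0.3) -> GenotypeMatrix:
    """Drop samples whose missing-call fraction *exceeds* the threshold."""
    if not 0 <= max_sample_missing <= 1:
        raise ValueError("max_sample_missing must be in [0, 1]")
    miss = gm.sample_missingness()
    keep = np.flatnonzero(miss <= max_sample_missing)
    if keep.size == 0:
        raise ValueError("all samples removed by missingness filter")
    if keep.size < gm.n_samples:
        dropped = [gm.samples[i] for i in np.flatnonzero(miss > max_sample_missing)]
        logger.info("filter_samples: removed %s", dropped)
    return gm.take_samples(keep)


# ---------------------------------------------------------------------------
# Clone detection
# ---------------------------------------------------------------------------


def allelic_similarity(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise allelic similarity matrix.

    Per locus scored in both samples: 1 for identical genotypes, 0.5 when
    sharing exactly one allele, 0 otherwise — i.e. ``1 - |g_i - g_j| / 2``
    for alt-dosage genotypes.  Pair value is the mean over jointly
    non-missing loci; NaN when no locus is shared.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = gm.calls.astype(np.float64)
    ok = gm.calls != MISSING
    n = gm.n_samples
    sim = np.ones((n, n))
    for i in range(n):
        shared = ok[i] & ok[i + 1:]
        diff = np.abs(g[i] - g[i + 1:]) / 2.0
        score = np.where(shared, 1.0 - diff, 0.0).sum(axis=1)
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(cnt > 0, score / np.maximum(cnt, 1), np.nan)
        sim[i, i + 1:] = row
        sim[i + 1:, i] = row
    return sim


def detect_clones(
    sim: np.ndarray,
    samples: Sequence[str],
    missingness: np.ndarray,
    threshold: float = 0.99,
) -> ClonalReport:
    """Find clonal groups (connected components of pairs >= threshold).

    Within each group every member except the one with the least missing
    data is flagged for removal.
    """
    n = len(samples)
    pairs = []
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            s = sim[i, j]
            if np.isfinite(s) and s >= threshold:
                pairs.append((samples[i], samples[j], float(s)))
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    removed = []
    for members in groups.values():
        if len(members) < 2:
            continue
        keep = min(members, key=lambda i: (missingness[i], i))
        removed.extend(samples[i] for i in members if i != keep)
    upper = sim[np.triu_indices(n, k=1)]
    hist = sorted(float(s) for s in upper if np.isfinite(s))
    return ClonalReport(pairs=pairs, threshold=threshold,
                        removed=sorted(removed), similarity_histogram=hist)


# ---------------------------------------------------------------------------
# VIF pruning of linked loci
# ---------------------------------------------------------------------------


def _vif_scores(x: np.ndarray) -> np.ndarray:
    """VIF per column of a mean-imputed genotype block.

    VIF_j = 1/(1 - R^2_j) from OLS of column j on the others (least-squares
    pseudoinverse, so rank-deficient blocks are handled without ridge terms);
    monomorphic columns have VIF 1 by convention.
    """
    n, k = x.shape
    xc = x - x.mean(axis=0)
    sstot = (xc ** 2).sum(axis=0)
    vif = np.ones(k)
    if k < 2:
        return vif
    for j in range(k):
        if sstot[j] <= 1e-12:
            continue
        others = np.delete(xc, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, xc[:, j], rcond=None)
        resid = xc[:, j] - others @ beta
        r2 = 1.0 - (resid ** 2).sum() / sstot[j]
        r2 = min(max(r2, 0.0), 1.0)
        vif[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vif


def prune_linked(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_max: float = 2.0,
) -> GenotypeMatrix:
    """Sliding-window VIF pruning of linked loci (PLINK ``--indep`` style).

    Within each window of ``window`` loci (advanced by ``step``), the locus
    with the highest VIF is removed iteratively until all VIF <= ``vif_max``.
    Missing calls are mean-imputed per locus for the regression only.
    Removals are permanent across windows.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    order = sorted(range(gm.n_loci), key=lambda i: (gm.loci[i][0], gm.loci[i][1]))
    g = gm.calls[:, order].astype(np.float64)
    g[gm.calls[:, order] == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    imputed = np.where(np.isnan(g), col_mean, g)

    alive = np.ones(len(order), dtype=bool)
    start = 0
    while start < len(order):
        idx = [i for i in range(start, min(start + window, len(order))) if alive[i]]
        while len(idx) >= 2:
            vif = _vif_scores(imputed[:, idx])
            worst = int(np.argmax(vif))
            if vif[worst] <= vif_max:
                break
            alive[idx[worst]] = False
            idx.pop(worst)
        if start + window >= len(order):
            break
        start += step
    kept_sorted = [order[i] for i in range(len(order)) if alive[i]]
    kept = sorted(kept_sorted)  # restore original locus order
    logger.info("prune_linked: %d/%d loci retained", len(kept), gm.n_loci)
    return gm.take_loci(kept)
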