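# Methods

## The inference chain

`dispersalkit` estimates how far individuals of a sessile, continuously
distributed species move per generation, and how much gene flow connects
distant populations, from genotype data alone. The chain is:

1. filter genotypes (call depth, site/sample missingness, MAC, MAF),
   remove clonal replicates, prune linked SNPs;
2. regress Rousset's-â individual genetic distances on (log-)geographic
   distance to obtain the IbD slope *b*;
3. combine *b* with a density estimate to obtain the axial dispersal
   distance σ, neighborhood size NS, neighborhood radius 2σ and a Laplace
   dispersal kernel, with Monte-Carlo uncertainty propagation;
4. summarize within-population diversity (π with invariant sites, He,
   FIS, rarefied allelic richness/private alleles), pairwise
   Weir–Cockerham FST, and LD-based contemporary Ne;
5. convert fitted two-population diffusion parameters into natural units
   (Ne, m, Nem, years).

## Genetic distance (Rousset's â form)

For a pair of diploids (i, j) at locus *l*, let Qw(l) be the mean
within-individual allele identity (1 for a homozygote, 0 for a
heterozygote, averaged over the two individuals) and Qb(l) the probability
that one allele drawn from each individual is identical
(p_i·p_j + (1−p_i)(1−p_j) for alt dosages p = g/2). The distance is the
ratio of sums over jointly called loci

    d_ij = Σ_l (Qw − Qb) / Σ_l (1 − Qw),

an individual-pair analogue of FST/(1−FST). Pairs whose denominator is
zero (both individuals homozygous at every shared locus) are undefined and
excluded with a logged count. The estimator is a module boundary: an
ANOVA-based alternative can be substituted without touching the
regression, and the σ/NS conversions consume only the slope.

Under IbD theory E[d] increases linearly with distance in a 1D habitat and
with log distance in 2D, with slope 1/NS. The regression is ordinary least
squares over unordered pairs; pairs closer than `min_distance` (default
1 m, guarding log 0) are excluded. Significance comes from a Mantel-style
permutation of sample locations (one-tailed, (1+k)/(n_perm+1)), not from
OLS standard errors, because pairs sharing an individual are not
independent. The 95% CI on the slope is a percentile bootstrap over loci:
the ratio-of-sums structure lets replicates be recomputed from cached
per-pair, per-locus components with one matrix product per batch.

## Dispersal conversions

With density D (individuals/m² in 2D, individuals/m in 1D):

    σ = 1/√(4πDb)  (2D)        σ = 1/√(4Db)   (1D)
    NS = 4πDσ²     (2D)        NS = 4Dσ²      (1D)   — both equal 1/b

The identity NS·b = 1 is property-tested for every draw. The neighborhood
radius is 2σ: populations separated by more than 2σ receive too few
migrants to be demographically coupled. The indicative kernel is Laplace,
pdf(x) = exp(−√2|x|/σ)/(σ√2), whose mean dispersal distance is σ/√2.

Census density is the median of per-site count·taxon_fraction/area, with
uncertainty from a site-level bootstrap of that median. Effective density
is per-population Ne/extent; the per-population values themselves form the
Monte-Carlo draw pool (median as point value), so a single outlier
population appears downstream as a second mode of σ rather than being
averaged away — the propagation reports the mode count of the σ
distribution (KDE on log σ, peaks above 5% of the maximum) for exactly
this reason. 1D census density is areal density times an explicit
`strip_width` (meters of habitat strip); linear density is a modeling
abstraction and the width is a configuration knob, not a claim.

Monte-Carlo propagation draws slope and density independently (slope draws
either raw locus-bootstrap replicates or, when only summaries exist, a
lognormal matched to the median and 95% CI at z = 1.96), rejects
non-positive slopes (> 50% rejection is an error), and reports median and
IQR of σ, NS, radius, and kernel mean. Summary output rounds to 2
significant figures; JSON keeps full precision.

## Diversity

π uses all-sites input (variant plus invariant) because dropping
monomorphic sites inflates per-base diversity. Per site, with k called
allele copies of which a are alternate: diffs = a(k−a), comps = k(k−1)/2;
windowed π is Σdiffs/Σcomps per window and the combined value is the same
ratio over all sites, which makes it invariant to the window partition
(verified at windows 13/100/∞). He is the naive 1−Σp² per site averaged
over all loci fully called within the population (an unbiased 2n/(2n−1)
flag exists, default off); FIS is the population-level ratio
1 − mean(Ho)/mean(He) over segregating sites, avoiding per-site 0/0.
Rarefied allelic richness at g gene copies is the expected allele count of
a g-copy subsample (hypergeometric closed form); private alleles multiply
the presence probability in the focal population by absence probabilities
everywhere else, summed over loci and alleles. Both equal exhaustive
subsample enumeration for N ≤ 8 in the tests. g defaults to
2·(smallest included n − 1), and populations below `min_n` (default 8) are
excluded. FST is the Weir–Cockerham (1984) two-population θ as a
multi-locus ratio of sums; negative estimates are reported, not clamped.

## LD-based contemporary Ne

Burrows' composite disequilibrium between loci A and B is estimated from
unphased genotypes as Δ̂ = (n/(n−1))(mean(g_A g_B)/2 − 2p_A p_B) over
individuals called at both loci, and
r² = Δ̂²/[(p_A(1−p_A)+D_A)(p_B(1−p_B)+D_B)], where D_A = P_AA − p_A² is
the within-locus Hardy–Weinberg disequilibrium. The HW-adjusted
denominator is the published LD method's form; it reduces to p(1−p)q(1−q)
under HW proportions, and in Wright–Fisher recovery runs it centers the
estimator where the bare product is biased upward. Pairs are restricted to
cross-contig loci (a proxy for "unlinked"), the mean r² is weighted by
pairwise sample size, and the harmonic mean pairwise n gives S. For
S ≥ 30: E[r²_sample] = 1/S + 3.19/S² and
Ne = (1/3 + √(1/9 − 2.76·r²′))/(2r²′) with r²′ = r² − E[r²_sample]; for
S < 30 the published small-sample constants (0.0018 + 0.907/S + 4.44/S²;
0.308, 2.08) are used. r²′ ≤ 0 (no drift signal above sampling noise)
yields an infinite estimate, as does a negative discriminant. The default
MAF cutoff is 0.02.

## Demographic conversion and JAFS

Scaled parameters are converted with Nref = θ/(4μL), Ne_i = ν_i·Nref,
m = M/(2Nref) (M is in units of 2·Nref migrants), Nem = Ne·m,
T_years = 2·Nref·T·g. Index 12 means migration INTO population 1 from
population 2. Defaults: μ = 1.2×10⁻⁸ per base per generation (a coral
sequence-divergence estimate) and g = 3 years. L must be the callable
all-sites span the SNPs were ascertained from, not the SNP count.
Scale-consistency (doubling μ halves sizes and times, doubles m, leaves
Nem fixed) and the natural→scaled→natural round trip are asserted
numerically. The folded JAFS counts each complete (or hypergeometrically
projected) SNP at its minor-allele cell pair; a site at exactly half
frequency folds to the lexicographically lower cell, and cells with
combined minor count ≤ 2 are masked (low-count variants are enriched for
sequencing error).

## Synthetic data

The spatial simulator is forward-in-time and individual-based so that the
controlled quantity — the per-axis parent-offspring displacement sd — is
directly measurable (it is reported as `realized_axial_sd`). Each
offspring takes a uniformly chosen mother, a natal position displaced by a
per-axis kernel draw (Gaussian or Laplace, axial sd σ_true), and a father
chosen with probability proportional to the kernel density at his distance
from the natal position; selfing is allowed (hermaphroditic corals).
Boundaries reflect by default (a bounded reef; slight edge-density bias),
with a torus option. Loci are unlinked, biallelic, initialized at
frequency 0.5 in HW proportions, and mutate symmetrically per transmitted
copy. Defaults (N = 500, extent 500 m, 300 loci, 100 generations,
μ = 10⁻⁴) give neighborhood sizes in the tens-to-hundreds range where the
IbD method is used in practice; the recovery tests use N = 800,
extent 350 m, 250 loci, 80 generations, 80 sampled individuals, sizes
chosen so a full 20-run panel completes in about a minute while still
recovering σ within a factor of two in ≥ 80% of runs.

The two-deme simulator draws both demes from one ancestral frequency pool
(Uniform(0.1, 0.9) per locus) and then drifts them with per-gamete
migration m12/m21. At symmetric equilibrium the Weir–Cockerham θ between
the two demes is compared against the pairwise coalescent expectation
FST = 1/(1+8Nm) (derived from T_between − T_within = 1/(2m) for two demes;
cross-checked against an independent coalescent simulation during
development). The LD-Ne panel uses a single closed Wright–Fisher
population run 80 generations from frequency 0.5 — drift LD between
unlinked loci equilibrates within a few generations, and longer runs only
lose polymorphic loci absent mutation.

What the generators do not emulate: real missingness structure (depth- and
locus-correlated rather than uniform), sequencing/genotyping error,
overlapping generations, selection, habitat patchiness, and oceanographic
asymmetry. Passing recovery tests therefore demonstrates correctness of
the estimators under the models' own assumptions, not robustness to every
property of empirical RAD data.

## Numerical and design choices

* Filter order is fixed and logged: per-call depth → site missingness →
  MAC → MAF; sample filter afterwards; site filters are re-applied after
  clone removal (allele counts change) with both counts logged. MAC/MAF
  count the minor allele; exact 50% frequency passes.
* Clone groups are resolved as connected components of pairs at ≥ the
  similarity threshold (default 0.99); within each group every member but
  the least-missing one is removed. The sorted similarity histogram is
  returned so a distribution break can be inspected, but the operative
  rule is the fixed threshold.
* VIF pruning mean-imputes missing calls, uses a least-squares
  pseudoinverse (rank-deficient windows need no ridge term), defines the
  VIF of a monomorphic locus as 1, and removes the highest-VIF locus
  (first index on ties) iteratively per window; removals are permanent
  across windows.
* Permutation p-values count ties (slope differences below 1e-12 relative)
  as exceedances, so degenerate zero-slope configurations give p = 1
  rather than fp-noise-dependent values.
* Geographic distances: haversine on a sphere of radius 6,371,000 m, or
  planar Euclidean on x/y meters (used by the simulators).
* Pipeline outputs use fixed float formatting and sorted JSON keys, so two
  runs with the same config and seed are byte-identical.

## Known limitations

* The â estimator is the identity-probability form; it matches the
  FST/(1−FST) logic but is not numerically identical to every published
  implementation. Acceptance-level conversions consume slopes, which are
  estimator-consistent.
* The slope bootstrap resamples loci; it does not reproduce any particular
  ABC bootstrap scheme.
* Census/effective density procedures are simple medians with bootstrap or
  per-population pools; site-weighting schemes beyond that are out of
  scope.
* The diffusion model itself (spectrum solve, optimization) is out of
  scope: the conversion consumes already-fitted parameters.
* LD-Ne assumes random mating and unlinked loci; pooling structured
  samples produces mixture LD and downward-biased Ne, as the literature
  warns.
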