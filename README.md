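# dispersalkit

Dispersal-distance and gene-flow inference for continuously distributed,
sessile marine populations (corals in particular), from SNP genotypes of
georeferenced individuals.

Many reef organisms disperse only as larvae, so the spatial scale of
demographic connectivity is invisible to direct observation. Two genetic
signals recover it at complementary scales:

* **Isolation by distance (IbD).** Under limited dispersal, the genetic
  distance between pairs of individuals increases with geographic distance.
  Using Rousset's â (an individual-pair analogue of FST/(1−FST)) regressed
  on distance (1D habitat) or log-distance (2D), the slope *b* estimates
  1/NS, the reciprocal of Wright's neighborhood size. With a population
  density *D* the per-generation axial dispersal distance follows:

  σ = 1/√(4πDb) (2D),  σ = 1/√(4Db) (1D),  NS = 4πDσ² = 1/b

  The dispersal neighborhood is a circle of radius 2σ, and a Laplace kernel
  calibrated to σ has mean dispersal distance σ/√2.

* **Demographic modeling.** Between distant populations, fitted two-deme
  diffusion parameters (θ, ν₁, ν₂, M₁₂, M₂₁, T) convert into long-term
  effective sizes, per-generation migrant fractions m, and gene flow
  Nem = Ne·m, via Nref = θ/(4μL), m = M/(2Nref), T_years = 2·Nref·T·g.

Around these two cores the package provides the supporting chain: VCF
filtering (depth, MAC, MAF, missingness), clone detection by allelic
similarity, VIF-based linkage pruning, within-population diversity with
invariant sites (windowed π, He, FIS, rarefied allelic richness and
private alleles), pairwise Weir–Cockerham FST, LD-based contemporary Ne
(Burrows' composite r²), folded joint allele-frequency spectra with
low-count masking, and forward spatial/two-deme simulators with known
ground truth for validation.

## Worked example

Dispersal quantities from a published-scale IbD fit — a 2D slope with median
0.0032 (95% CI 0.0021–0.0041) per log-meter against a census density of
0.046 colonies/m²:

```python
import dispersalkit as dk
from dispersalkit import dispersal as dp

draws = dp.lognormal_slope_draws(0.0032, 0.0021, 0.0041, n=20000, seed=17)
dens  = dp.DensityEstimate("census", "2D", 0.046)
est   = dp.propagate_sigma(draws, dens, model="2D", n_mc=20000, seed=17)
print(round(est.sigma, 1), round(est.ns), round(est.radius, 1),
      round(est.kernel_mean_distance, 1))
```

prints

```
23.2 312 46.5 16.4
```

i.e. a median axial dispersal distance of ~23 m per generation, a
neighborhood of ~312 effective breeders within a 46.5 m radius, and a
Laplace-kernel mean dispersal distance of ~16.4 m. An organism with these
numbers recruits almost entirely within its natal reef.

End-to-end on synthetic data with known truth:

```python
from dispersalkit import synthetic_data as sd, ibd, dispersal

cfg = sd.SpatialSimConfig(model="2D", extent=350, n_individuals=800,
                          sigma_true=20, n_loci=250, n_generations=80,
                          mutation_rate=1e-3, seed=1)
gm, st, truth = sd.simulate_spatial(cfg, sample_size=80)
g = ibd.genetic_distance_matrix(gm)
x = ibd.geographic_distance_matrix(st, mode="planar")
fit = ibd.ibd_regression(g, x, "2D")
print(dispersal.sigma_from_slope(fit.slope, truth["density"], "2D"))
```

recovers σ within a factor of two of the configured 20 m (13.3 m for this
seed).

A `dispersalkit` console command exposes each stage (`filter`, `ibd`,
`sigma`, `diversity`, `ne`, `demog convert`, `simulate`, `run`); see
`dispersalkit --help`. `dispersalkit run --config run.yaml` executes the
whole chain and writes a reproducibility manifest.

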