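# occabund

Macroscale species abundance estimation from replicated detection–nondetection
data, with neutral-theory metacommunity inference.

## The problem

Vegetation surveys and similar programmes record only whether each species
was seen in each sampling plot — not how many individuals were present. Yet
regional conservation assessment needs *abundance*: how many individuals of
each species occur in each grid cell, how much area each species occupies,
and how diverse each cell's community is. `occabund` is for ecologists and
biodiversity modellers who have (i) plot-level binary detection records with
known plot areas, (ii) per-cell habitat areas and environmental covariates,
and (iii) patchy independent knowledge of cell-level presence or absence
(specimens, range maps, checklists), and who want cell-level abundance with
honest uncertainty.

## The model

Assuming individuals of species *i* follow a homogeneous Poisson point
process of density *d_ij* within the habitat of cell *j*, a plot of area
*a_jk* detects the species with probability

```
p_ijk = 1 − exp(−z_ij d_ij a_jk),        y_ijk ~ Bernoulli(p_ijk)
```

where *z_ij* ~ Bernoulli(ψ_ij) is the latent cell-level occupancy (zero
inflation). Both `log d` and `logit ψ` carry covariates (standardised AET
and HII plus their interaction) and crossed Gaussian random effects for
species, cells (correlated across the two predictors, correlation ρ) and
species×cell. Auxiliary occurrence records fix *z_ij* where it is known;
elsewhere *z* is marginalised exactly. Random effects are integrated out by
a joint Laplace approximation (adaptive Gauss–Hermite where the structure
factorises), maximising the marginal likelihood. Derived estimators then
give per-cell richness, abundance vectors, Shannon entropy, per-species
regional abundance and area of occupancy, with parametric-bootstrap
standard errors.

Aggregating abundances over biogeographic regions yields metacommunity
species-abundance distributions (SADs), to which the package fits three
speciation variants of the unified neutral theory of biodiversity — point
mutation (Ewens sampling formula), random fission, and protracted speciation
(difference logseries on Preston octaves) — plus a Poisson-lognormal
baseline, compares them by composite-likelihood AIC and Akaike weights, and
converts the fitted fundamental biodiversity number θ into a speciation rate
ν and an average species lifetime L in generations. See `docs/methods.md`
for formulas, defaults and numerical choices.

## Worked example

```python
import occabund as ob

# simulate a survey: 30 species, 50 cells, 10 plots per cell
cfg = ob.SimulationConfig(n_species=30, n_cells=50, plots_per_cell=10, seed=42)
ds = ob.simulate_dataset(cfg)

fit = ob.fit(ds.data)                      # integrated zero-inflated model
print(f"loglik {fit.loglik:.1f}, mu = {fit.params.mu:.2f} "
      f"(+/- {2*fit.se['mu']:.2f}), true {cfg.true_params.mu:.2f}")

total = ob.cell_abundance(fit, ds.cells).sum()
print(f"estimated total abundance {total:,.0f} vs true {ds.truth['N'].sum():,.0f}")

sad = ob.MetacommunitySAD(ob.estimate_abundance(fit, ds.cells).to_numpy())
pms = ob.fit_pms(sad)
print(f"PMS: theta = {pms.theta:.1f}, nu = {pms.nu:.2e}, lifetime = {pms.lifetime:.1f} generations")
```

Output:

```
loglik -3833.8, mu = 7.44 (+/- 0.40), true 7.60
estimated total abundance 137,258,472 vs true 110,866,486
PMS: theta = 1.6, nu = 1.18e-08, lifetime = 18.3 generations
```

The fitted density intercept recovers the generating value within its
confidence interval; the total abundance estimate lands within ~25% of the
simulated truth (dominated by a few high-density species-cell draws); and
the Ewens fit converts the SAD's diversity into a per-generation speciation
rate and a mean species lifetime.

A command-line interface mirrors the library
(`occabund simulate|fit|predict|cv|derive|bootstrap|untb|run|validate`);
`occabund run --config examples/pipeline.yaml --out out/` executes the whole
pipeline and writes a manifest with file hashes and seeds.

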