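# popfba — population flux balance analysis

Single-cell imaging shows that genetically identical yeast cells grow at
very different rates: a broad shoulder of slow growers and a sharp peak
of fast ones. `popfba` explains such heterogeneity mechanistically. It
builds an in-silico population by sampling each cell's enzyme copy
numbers from measured single-cell distributions (with the correlations
that co-regulation imposes), converts every sampled copy number into a
flux capacity on a genome-scale metabolic model, and solves a
parsimonious flux balance problem per cell. The package is aimed at
systems biologists doing constraint-based modeling who want
population-level predictions — growth-rate distributions, overflow
(Crabtree) metabolism, bimodal nutrient usage — rather than a single
"average cell" flux state.

## The model

For each cell, every measured enzyme contributes a capacity constraint

    v_max = N_copy · k_cat · c ,      c = 3600 / (2.0·10⁻¹¹ g × 6.02·10²⁰ mmol⁻¹)
                                        ≈ 3.0·10⁻⁷ s cell⁻¹ mmol gDwt⁻¹ hr⁻¹

where `N_copy` is the sampled copy number and `k_cat` the turnover
number. Gene–protein–reaction rules combine per-gene capacities into
per-reaction bounds: minimum over AND (complex subunits), sum over OR
(isozymes); an unmeasured isozyme leaves the reaction at the default
bound of 1000 mmol gDwt⁻¹ hr⁻¹. The cell's fluxes `v` then solve

    max  v_biomass   s.t.  S·v = 0,  lb ≤ v ≤ ub        (FBA)
    min  Σ|v|        s.t.  v_biomass ≥ μ*               (pFBA)

Copy numbers are sampled with a Gaussian copula: single-cell abundances
are gamma-distributed (shape k, scale θ, fluorescence units), converted
to copies through the power-law calibration `p = a·f^b` (a = 2.87,
b = 1.5577, floored at 2.87 copies), and correlated on the latent normal
scale using the Cholesky factor of a gene–gene Pearson matrix estimated
from quantile-normalized expression arrays — so every protein keeps its
measured marginal exactly.

Because literature turnover numbers are unreliable, two repair
strategies are included: an iterative *doubling* procedure (simulate a
small batch, find the reaction whose capacity binds most often, double
the responsible enzyme's k_cat, repeat until the batch reaches a target
mean growth rate) and a *micro genetic algorithm* that searches binary
keep-or-lift-to-38,000 s⁻¹ choices against a target growth-rate
histogram.

## Worked example

The package ships a generator for a ~20-reaction toy network that
distills the Crabtree mechanism: high-yield respiration is capped by a
~100-copy electron-transport subunit, so constrained cells overflow to
ethanol even with oxygen available.

```python
import numpy as np
from popfba import fba
from popfba.population import bound_uptake_fraction, simulate_population
from popfba.sampling import sample_population
from popfba.synthetic import (ToyModelConfig, make_toy_medium,
                              make_toy_model, make_toy_proteomics)

cfg = ToyModelConfig()
model = make_toy_model(cfg)
prot = make_toy_proteomics(model, cfg, seed=1)
medium = make_toy_medium(cfg)

print(f"unconstrained FBA: mu = {fba(model).growth_rate:.2f} /hr, "
      f"ethanol flux = {fba(model).flux('EX_etoh'):.2f}")

cells = sample_population(500, prot.marginals, prot.corr, prot.cal, seed=7)
pop = simulate_population(model, cells, prot.true_kcats, medium)
mu = pop.growth_rates[pop.feasible]
etoh = pop.flux_column("EX_etoh")[pop.feasible]
print(f"population of {pop.n_cells} cells: mean mu = {mu.mean():.3f} /hr "
      f"(range {mu.min():.3f}-{mu.max():.3f})")
print(f"fraction secreting ethanol: {np.mean(etoh > 1e-6):.3f}")
aa = bound_uptake_fraction(pop, "EX_aa", medium)
print(f"amino-acid uptake: {aa.fraction_at_max:.2f} at max, "
      f"{aa.fraction_basal:.2f} basal, bimodal={aa.bimodal}")
```

prints

```
unconstrained FBA: mu = 2.62 /hr, ethanol flux = -0.00
population of 500 cells: mean mu = 0.536 /hr (range 0.161-0.688)
fraction secreting ethanol: 1.000
amino-acid uptake: 0.67 at max, 0.30 basal, bimodal=True
```

Read top to bottom this is the package's story: without enzyme
constraints the LP respires (no ethanol, implausibly fast growth at
2.6 hr⁻¹); with sampled proteomics constraints every cell ferments,
growth rates spread over 0.16–0.69 hr⁻¹ with a fast glucose-limited
peak, and the amino acid is taken up either at its full 0.78 mmol gDwt⁻¹
hr⁻¹ cap or at a basal rate — almost never in between — depending on
which enzyme bound caps glycolysis in that cell.

The same workflow is scriptable from a shell: `popfba make-toy`,
`censor`, `calibrate`, `correlate`, `sample`, `simulate`,
`relax-double`, `relax-ga`, `analyze` (see `popfba --help`).

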