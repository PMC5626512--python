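# Methods

This note documents the models and procedures `popfba` implements, the
assumptions they make, the defaults and why, and what the synthetic
fixtures do and do not establish.

## Proteomics preprocessing

Input is a gamma distribution (shape k, scale θ, fluorescence A.U.) per
protein per timepoint, as produced by automated deconvolution of
single-cell fluorescence from autofluorescence. Deconvolution failures
yield near-degenerate "spikes" that must be censored before sampling.
The pipeline applies six filters in a fixed order: (1) proteins missing
any of the `required_timepoints` (default 18) raw measurements are
dropped — this is a raw-data completeness check, which is why the
idempotence of the pipeline is stated with respect to the later filters;
(2) distributions with sd < 0.1 A.U. are spikes; (3) per protein,
distributions whose mean or sd falls outside the Tukey fences
(1.5 × IQR beyond the quartiles, type-7/linear-interpolation quantiles
so the filter is bit-reproducible) are outliers; (4) proteins with fewer
than 3 survivors are dropped; (5) proteins whose CV-of-means or
CV-of-sds is not strictly below 0.5 are irreproducible across time;
(6) proteins with pooled mean fluorescence below 7.98 A.U. sit below the
instrument's reliability threshold.

Survivors are pooled into one sampling marginal per protein by averaging
the per-timepoint means and variances and refitting a gamma by method of
moments (shape = m²/v, scale = v/m). How the surviving per-timepoint
fits should be combined is genuinely open; moment pooling was chosen
because the censoring pipeline quality-controls exactly those two
moments, so they are the statistics the data can support.

Fluorescence converts to absolute copies through `p = a·f^b`, fitted by
OLS on the log-log scale to paired mass-spectrometry counts ×
media-expression ratios. The floor equals `a` (the count at f = 1):
sub-unit fluorescence is unreliable, so no sampled count may fall below
it, and the floor is re-applied after any media rescaling.

## Correlated sampling

Expression arrays are quantile normalized (each array's order statistics
replaced by across-array means; ties get the mean of their tied target
values), probes of one gene averaged, and gene–gene Pearson correlations
computed across arrays. Finite-sample correlation matrices assembled
this way are routinely indefinite, so eigenvalues are clipped at 1e-8
and the matrix rescaled to unit diagonal before Cholesky factorization;
the factorization is verified to reproduce the repaired matrix to 1e-8.

Counts are sampled with a Gaussian copula (NORTA): z = L·ε on the latent
normal scale, u = Φ(z), f = F⁻¹_gamma(u) per protein, then the
calibration. The correlation is imposed on the *latent* scale — the
realized Pearson correlation of the gamma counts is slightly attenuated
— because exact preservation of the measured marginals is the primary
contract; the attenuation is measured in the test suite via the
closed-form Spearman relation 6/π·arcsin(ρ/2). Proteins without
correlation data are sampled independently. One Philox stream per seed,
fully vectorized, makes populations bit-reproducible; reproducibility
is asserted by test, and parallel per-cell streams were deliberately
not implemented since population generation is a negligible fraction of
runtime next to the per-cell LPs.

## Enzyme-capacity constraints

`v_max = N_copy · k_cat · c` with c = 3600/(2.0·10⁻¹¹ × 6.02·10²⁰) ≈
2.99·10⁻⁷ s cell⁻¹ mmol gDwt⁻¹ hr⁻¹ computed from first principles
(seconds per hour, haploid dry mass, particles per mmol), never stored
as a rounded literal. GPR combination: AND → minimum over *measured*
subunits (a measured subunit is a valid ceiling even when its partners
are unmeasured; an entirely unmeasured complex imposes nothing); OR →
sum of isozyme capacities, but any unmeasured isozyme leaves the
reaction at the default bound of 1000 mmol gDwt⁻¹ hr⁻¹ since the missing
enzyme could carry arbitrary flux. An enzyme catalyzing several
reactions contributes its full pool to each — copies are not partitioned
across reactions or compartments, for lack of localization data.
Capacities are applied symmetrically to reversible reactions
(ub = min(ub, v_max), lb = max(lb, −v_max)), with an upper-bound-only
switch, because the same enzyme pool carries either direction.

Turnover numbers: per gene, the largest wild-type S. cerevisiae value;
failing that the largest value from any mutant or species; failing that
38,000 s⁻¹ (the largest wild-type yeast k_cat on record) — a
deliberately minimally-constraining policy. Before any relaxation, all
subunits of a complex are raised to the within-complex maximum
(transitively, to a fixpoint): a complex turns over as one unit, so a
lower subunit value is most plausibly a measurement gap.

Media are maps exchange → maximum uptake magnitude; uptake is negative
flux, so listed exchanges get lb = −magnitude and unlisted ones are
closed for uptake while secretion stays free. Knockouts zero every
reaction whose GPR evaluates false without the deleted genes.

## FBA, pFBA, FVA

All flux problems are LPs behind a single solver contract with two
backends: HiGHS (scipy) as default and GLPK (optlang) as an independent
cross-check; fixtures assert both give the same optimum. pFBA fixes
biomass ≥ fraction·μ* (inequality, slack 1e-9, to avoid infeasibility at
the vertex), splits each flux into non-negative forward/backward parts
and minimizes their sum. FVA minimizes/maximizes each flux at a growth
fraction, optionally with the pFBA total flux pinned (Σ|v| ≤ total +
1e-6; the slack is visible as a ≤2e-6 leak in otherwise-excluded
branches and the tests state it as such). pFBA's stage-2 LP can itself
be degenerate; the package returns the solver's vertex and relies on FVA
for robustness statements. Infeasible cells are flagged with μ = 0,
never dropped silently; analytics exclude them with a logged count.

Correctness is established against brute-force vertex enumeration of the
flux polytope on ≤12-reaction fixtures (each vertex fixes n − rank(S)
fluxes at bounds and solves the balance equations); on the irreversible
fixtures the total flux is linear on the optimal face, so pFBA's optimum
is also vertex-attained and enumerable.

## Relaxation of turnover numbers

*Doubling*: each iteration simulates a fresh seeded batch (seed + i, so
the stopping rule is not fit to one population; default 400 cells),
tallies which protein-derived bounds each cell's optimum sits on
(|v| ≥ (1−1e-6)·v_max, ignoring no-op bounds ≥ 1000), and doubles the
k_cat behind the most frequently binding reaction — the single gene, the
highest-mean-count isozyme branch of an OR, or all subunits of an AND at
once. Ties break to the lexicographically smallest reaction id for
determinism. The loop stops when the batch mean growth reaches the
target; if no bound is ever active while the target is unmet the medium,
not the proteome, is limiting, and the procedure says so. The log
replays exactly onto the initial table.

*Micro-GA*: genomes are bit vectors over candidate genes (0 = curated
k_cat, 1 = lift to 38,000 s⁻¹), population 10, elitism, binary
tournament selection, uniform crossover, no mutation, and a restart that
re-randomizes everyone but the elite when the population's mean bit
similarity to the elite reaches 95%. Fitness is −Σ(p−q)² between
normalized growth histograms (50 bins on [0, 0.7] hr⁻¹, covering the
observed 0–0.57 range; mass outside the range is penalized, not
renormalized away). Every genome is evaluated on the same seeded cell
batch so comparisons are paired, which also makes fitness cacheable and
the elite trace exactly non-decreasing. These operator choices are the
package's own where the formalism leaves them open.

## Population analytics

Growth histograms are density-normalized over a fixed range (default
[0, 0.7] hr⁻¹, 50 bins). PCA runs on growth-normalized fluxes (each
cell's vector divided by its μ) of a seeded random subset of feasible
cells, centered but *not* rescaled per reaction — the components should
reflect absolute flux reallocation between pathways, not per-reaction
z-scores — and columns constant up to solver jitter (std ≤ 1e-9 relative)
are dropped. Flux comparisons report per-reaction population means and
their RMSD against a user-supplied reference map. Uptake-bound analysis
classifies cells as saturated (≥ (1−tol) of the medium cap) or basal
(≤ 10% of the cap, configurable) and flags bimodality when both groups
exceed 5% with at most 5% in between.

## The synthetic generator: what it emulates, and what passing tests show

`make_toy_model` builds a ~20-reaction network with explicit ATP/ADP and
NADH/NAD currency metabolites (conservation of both moieties is asserted
at build time): glucose transport (single-gene GPR), lumped glycolysis
(two-subunit AND complex; 2 ATP + 2 NADH per glucose), a fermentation
branch (isozyme OR; redox-neutral, ethanol out), lumped TCA + electron
transport (4 NADH per pyruvate, 2 ATP per NADH) whose complex contains a
~97-copies-per-cell subunit, a capped amino-acid uptake (0.78 mmol
gDwt⁻¹ hr⁻¹) feeding an energy-yielding catabolic shortcut, a biomass
reaction consuming pyruvate, ATP and NADH, and ATP-wasting decoy
reactions that are provably zero-flux at any optimum. Respiration
yields 24 ATP per glucose versus 2 for fermentation, so the
unconstrained optimum respires; the low-copy respiratory subunit is what
tips sampled cells into overflow metabolism. Biomass stoichiometry is
scaled so population growth rates land in the 0–0.7 hr⁻¹ window of the
default histogram.

`make_toy_proteomics` supplies gamma marginals (CVs 0.1–1.0, means
echoing real yeast abundance scales), a block correlation structure
(positive within the fermentative and respiratory gene sets, negative
between them), a turnover table with deliberately under-estimated
("planted") entries plus the clean table, and noiseless power-law
calibration rows that refit exactly. Two minimal chain fixtures carry
planted defects for the relaxation algorithms: a transporter k_cat
100-fold low (so recovery takes exactly ⌈log₂ 100⌉ = 7 doublings, with
the stopping target computed at run time from a clean-table batch), and
a two-enzyme chain with both k_cats 1000-fold low among 12 candidate
genes (so the micro-GA must lift exactly those two, while decoy bits are
fitness-neutral and accumulate as degenerate supersets).

What the fixtures do *not* emulate: proteome scale. With 14 proteins,
every constraint is individually load-bearing, so "drop a random half of
the constraints and the histogram survives" — which holds for a
real proteome where only a small minority of hundreds of measured
enzymes ever bind — is false here: dropping the one respiration-limiting
subunit unleashes respiration, and dropping a single isozyme of an OR
pair uncaps its reaction entirely by the missing-isozyme rule. The
omission test therefore drops the designed half of the constraints that
the mechanism predicts to be redundant (complex subunits whose partner
remains measured, never-binding capacities, decoys) and verifies the
histogram is unchanged; the general random-omission robustness should be
read as a statement about proteome-scale redundancy, not about minimal
fixtures. Likewise, absolute growth rates, doubling tallies and RMSD
values from genome-scale studies on the real datasets are out of reach
of these fixtures; the tests establish the algorithms' contracts, not
those numbers.

## Numerical choices and degenerate inputs

- Mass-balance residual tolerance 1e-6; bound violations 1e-6.
- Growth pin slack 1e-9; FVA total-flux pin slack 1e-6.
- Active-bound detection: relative tolerance 1e-6.
- PSD repair eigenvalue floor 1e-8; Cholesky verified to 1e-8.
- Copula u clipped to [1e-15, 1−1e-15] before the gamma quantile.
- Zero-variance genes in correlation estimation get ρ = 0 with a logged
  warning; empty media make FBA infeasible or zero-growth, reported as
  status, never an exception; an all-infeasible GA population scores −∞.
- Problem sizes in the test suite (2,000-cell populations, 400-cell
  doubling batches, 40-cell GA fitness evaluations over 25 generations,
  n = 5·10⁴ copula checks) were chosen so the whole suite runs in about
  six minutes on one CPU while keeping Monte-Carlo standard errors well
  inside every asserted tolerance.

## Known limitations

- Biomass composition is constant across the population; real
  composition shifts with growth rate.
- GFP-fusion stability bias in the underlying proteomics is not
  modeled, nor is signal deconvolution (both upstream of the inputs).
- Enzyme pools are shared across compartments and reactions; no
  thermodynamic or loopless constraints.
- The Pearson-on-latent-scale choice attenuates realized count
  correlations (quantified in tests); rank-based alternatives were not
  pursued.
- pFBA alternate optima are resolved by the solver's vertex choice;
  conclusions about individual fluxes should be backed by FVA.
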