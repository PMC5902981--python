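# Methods

## Model overview

`edsim` simulates a closed breeding population with discrete,
non-overlapping generations. Two traits are carried per animal:

* a **polygenic trait**, represented directly by its true breeding value
  (TBV) under the infinitesimal model — no markers or genome are
  simulated; and
* a **monogenic trait**, a single biallelic locus unlinked to the
  polygenic background, stored as the count `G ∈ {0, 1, 2}` of desired
  alleles (think polledness in cattle: dominant desired phenotype needs
  `G ≥ 1`; a recessive trait needs `G = 2`).

Founders draw `TBV ~ N(0, 1)`; the founder genetic variance defines the
unit of scale throughout. Offspring receive

```
TBV = ½ TBV_sire + ½ TBV_dam + m,   m ~ N(0, ½(1 − ½(F_sire + F_dam)))
```

The Mendelian-sampling variance is expressed on the founder scale and
shrinks only with parental pedigree inbreeding `F`, not with the Bulmer
reduction of between-family variance — directional selection therefore
erodes genetic variance to an equilibrium rather than to zero.

Genomic prediction is emulated with a pseudo-EBV,

```
EBV = r² (TBV + PE),   PE ~ N(0, (1 − r²)/r²),
```

which has reliability (squared accuracy) `r²` in the founder population.
The PE variance stays fixed on the founder scale across generations; as
genetic variance shrinks under selection, realized accuracy drifts
slightly below `√r²`. The alternative — rescaling PE variance by the
current genetic variance each generation — would keep reliability exactly
constant; we use the fixed-scale form as the plainer reading of the
definition and because the difference at `r² = 0.5` is small (equilibrium
accuracy 0.65 instead of 0.71).

## Selection and mating

Each generation the `n_sires` males and `n_dams` females with the highest
index `I = b1·EBV + b2·G` are kept (truncation selection within sex; exact
ties broken toward the lower animal id for determinism — ties have
probability ~0 with continuous EBV). `b1` is fixed at 1. `b2 = 0` is pure
genomic selection; `b2 = 0.5` gives the monogenic locus a moderate weight
(about 0.75 equilibrium-EBV standard deviations per allele); `b2 = 1000`
is an ordinary numeric weight so large that `G` dominates any realistic
EBV, implementing "maximal emphasis" without a special lexicographic rule.

One sire is assigned to each dam uniformly at random **with replacement**
(a sire can serve many dams or none); a balanced, near-equal-usage
assignment is available behind `balanced_matings` for sensitivity checks
but is not the default. Every mating produces exactly `n_off_per_mating`
zygotes; sexes are Bernoulli(0.5) with no balancing. If editing mortality
or sex-ratio fluctuation ever left fewer candidates of a sex than parents
required, the replicate aborts with an explicit error (astronomically
unlikely at the default sizes).

A replicate runs `n_burnin_generations` (default 5) rounds of selection on
EBV alone — generations −5 … 0 — bringing variance and response to Bulmer
equilibrium, then `n_selection_generations` (default 20) rounds of index
selection with optional editing. Generation 0 is the reference cohort for
all comparisons.

## Genome editing

Editing is applied to zygotes during reproduction; parent genotypes never
change. With `edit_fraction = f`, `round(f · n_dams)` matings are flagged
per generation (half-up rounding; 10% of 2000 matings = 200). Only
matings whose parents jointly carry fewer than 4 desired alleles are
eligible; among them the flagging order is (1) smallest parental
desired-allele count, (2) highest parent-average index, (3) lowest dam id
(deterministic tie-break).

Every zygote of a flagged mating is subjected to the procedure and counted
as one procedure. Each undesired allele converts independently with
probability `k`; the zygote survives with probability `s` regardless of
edit success (the risk attaches to undergoing the procedure). Setting
`k = s = 0.2` reproduces a realistic low efficiency: one live, fully
edited offspring per 25 subjected heterozygous zygotes.

Whether zygotes already homozygous for the desired allele are subjected is
a genuine modelling choice. We calibrated both conventions against the
published scenario totals this simulator is designed to reproduce:
family-level subjection (all zygotes of a flagged mating) matches the
reported cumulative procedure counts within ~2% across all four editing
scenarios, and exactly reproduces the 10,000 procedures over five
generations of the zero-weight editing scenario (200 matings × 10 zygotes
× 5 generations), while carrier-only subjection undercounts by 15–20%.
Family-level subjection is therefore the default; `subject_noncarriers =
False` switches to carrier-only subjection (fewer procedures, and no
survival risk for already-desirable zygotes). Mosaicism and off-target
damage are not modelled as distinct states; they are absorbed into the
survival probability `s`.

## Inbreeding

Inbreeding is exact pedigree inbreeding with founders assumed unrelated
and non-inbred. Because parents come only from the immediately preceding
generation, the additive-relationship matrix is propagated among the
~`n_sires + n_dams` selected parents each generation:

```
a(x, y) = ¼ (a(sx, sy) + a(sx, dy) + a(dx, sy) + a(dx, dy)),  x ≠ y
a(x, x) = 1 + ½ a(sx, dx)
```

and a candidate's `F` is half its parents' relationship. This is
algebraically identical to the classic tabular method over the full
(~500,000-animal) pedigree — the test suite verifies exact agreement on
complete simulated pedigrees — at a per-generation cost of one ~2100²
matrix instead of a full-pedigree pass.

## Evaluation metrics

* **Time to fixation**: first generation whose candidate cohort has
  desired-allele frequency exactly 1.0; replicate averages exclude
  replicates in which the allele was lost to drift (frequency 0 at the
  end). Under editing the allele is always re-introduced, so editing
  scenarios always fix.
* **Loss in months**: `(mean TBV_scenario − mean TBV_baseline) / R_eq ×
  interval`, where the baseline is the `b2 = 0` genomic-selection scenario
  run on the same seeds, `R_eq` is the baseline's replicate-mean response
  at generation 0, and the interval defaults to 24 months.
* **Loss in genetic-dispersion units**: the same TBV difference divided by
  the baseline's generation-0 equilibrium genetic variance (≈ 0.73), used
  directly as the divisor in the summary tables for comparability with
  the published tabulations; the audit column `sd_loss_sqrt_*` also
  reports the conventional division by √variance.
* **Cumulative benefit**: percentage of all animals born in generations
  1…horizon with the desired phenotype (`G ≥ 1` dominant, `G = 2`
  recessive), evaluated at horizons 5 and 20.
* **Breakeven editing cost**: percentage-point gain in desired-phenotype
  animals over the baseline × animals born over the horizon × per-animal
  saving (default €10, e.g. dehorning avoided) ÷ total editing
  procedures.

Equilibrium response and variance are estimated from the baseline run at
generation 0 in every experiment, never hard-coded.

## Randomness and reproducibility

Each replicate owns one `numpy` PCG64 stream seeded `base_seed + i`; the
per-generation draw order (mate assignment, Mendelian-sampling normals,
genotype transmission, edit conversions, edit survival, sexes, EBV of
survivors) is fixed, so a `(spec, seed)` pair reproduces trajectories
bit-for-bit. Scenario comparisons (months-loss, extra inbreeding,
breakeven) run all scenarios on the **same** seed set: the burn-in phase
is then identical across scenarios and the contrasts are paired, which
removes the shared burn-in noise from the differences.

## Problem sizes and Monte-Carlo error

Published-scale runs use the full 20,000-candidate design. The acceptance
script uses 30 replicates per scenario and the acceptance tests 20
(versus 50 in the original evaluations), which we chose as the point
where every targeted mean is resolved to within a few percent. The
months-loss contrast at generation 20 is the noisiest quantity: its
per-replicate standard deviation is ~5 months (20 generations of
independent Mendelian-sampling drift in cohort means), so even paired
30-replicate estimates carry a standard error near one month. The
drift-loss rate check runs the 19 main-design scenarios at 4 replicates
each, enough to detect gross departures from the ~1.5% loss rate but not
to resolve it finely.

## What the simulator does not capture

* No explicit genomes, markers, linkage or genomic relationships; genomic
  selection enters only through the pseudo-EBV reliability, so
  marker-specific phenomena (e.g. hitch-hiking around the edited locus)
  are outside scope.
* Overlapping generations, unequal parental contributions,
  optimal-contribution selection and mating plans other than uniform
  random assignment are not modelled; absolute inbreeding rates are
  accordingly low (~0.25%/generation at the default design).
* The monogenic locus has no effect on the polygenic trait and no
  fitness effect of its own.
* Costs and benefits are linear head-counts; no discounting or gene-flow
  weighting.

Passing tests therefore demonstrate fidelity of the selection-genetics
machinery (selection response, drift, inbreeding, Mendelian transmission,
editing arithmetic) under these idealizations — not predictions for any
particular real breeding program.

## Known calibration notes

With moderate index weight and no editing (`b2 = 0.5`, GS-only), the
simulated allele frequency rises faster than the published trajectories
(fixation near generation 11 versus the reported 17–19), while the same
scenario's months-loss, and all editing-scenario procedure counts,
fixation times and inbreeding levels, agree with the published values
within Monte-Carlo error. The published account of this scenario is also
internally inconsistent (17 versus 19 generations in different places), so
the package reports its own estimate rather than calibrating to either
printed number. Editing-scenario fixation times trend ~½–1 generation
earlier than the printed integers at equal procedure totals.
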