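# Methods

This note documents the models, conventions, and numerical choices behind
`granulefate`, and what the synthetic-data generator does and does not
emulate.

## Pharmaceutical quantification and removal

Calibration is an ordinary-least-squares line of peak area on nominal
concentration; standards prepared in different solvents are pooled into one
fit (a `solvent` column is retained so stratified fits remain possible).
Quantified concentrations below zero (area under the intercept) are clipped
to 0 and flagged `below_range`, mirroring a limit-of-quantification regime;
the LOQ (default 10 μg/L) is a pipeline parameter carried in the config.

Spike recovery is `(prespike − unspiked)/(postspike − unspiked)` on the
concentration scale. Recoveries above 1 are real (matrix enhancement) and
are propagated unclipped; correction divides by recovery, and recoveries
are validated to lie in (0, 2].

Percent removal is a per-timepoint mass balance on influent and effluent
*concentrations*, treating per-cycle influent and effluent volumes as equal
(SBR fill/decant volumes are assumed matched; no volume terms are modeled).
This makes the sign convention exact: effluent at twice influent is −100 %.
Timepoints with non-positive influent are flagged undefined (NaN), not
dropped. Total-nitrogen removal sums the three as-N species per phase
before the balance.

Solid-phase concentrations convert an extract concentration to μg per g dry
granules: `conc · V_extract / dry_weight` with the extract volume in liters.

## Suspect screening

Theoretical m/z values come from an embedded, versioned table of standard
atomic weights and most-abundant-isotope masses, so screening results are
bit-stable across environments. The default adduct is [M+H]⁺ (positive ion
mode); [M+Na]⁺ and [M−H]⁻ are available.

The reporting filter is applied exactly as stated: the *magnitude* of the
signed ppm error must be strictly `< 5`, and S/N must be `>= 10`
(inclusive). Peaks lacking a usable parent-standard area are flagged
un-normalizable rather than silently dropped. Corrected peak areas use the
literal printed forms; multiplying the aqueous area by the concentration
factor is arguably aggressive dimensionally, so a `divide_by_cf` switch is
provided but defaults off. Non-detections in product time series are
explicit gaps, never zeros — an absent peak is not a measured zero.

The built-in compound database carries the three parents and eight
degradation products. Diclofenac's parent formula is C14H11Cl2NO2
(MW ≈ 296.1); its mono-hydroxylated product DCF1 is C14H11Cl2NO3. Sources
occasionally print the hydroxylated formula for the parent; the database
keeps the pair consistent with the parent's quoted molecular weight.

## Active-community calling

Ratios are computed on rarefied **relative abundances**, which equals the
rarefied count ratio when depths are equal and remains comparable when DNA
and cDNA depths differ. The default rarefaction depth is the minimum
library total across both pools (per-pool overrides available).

Per trial: a ZOTU with rarefied cDNA > 0 and rarefied DNA = 0 is a phantom
and receives ratio 100 (substitution applied per trial, before averaging);
a ZOTU absent from both rarefied libraries contributes no value to that
trial. The across-trial mean is taken over trials in which the ZOTU had a
value (an `absent_as_zero` mode exists behind a flag). Activity is called
on the mean: `active ⇔ mean_ratio ≥ threshold` (default 1). Structural
phantoms — zero DNA reads in the whole unrarefied sample but positive cDNA
— are assigned mean ratio 100 outright, so they are active at every depth
and seed.

Active-community relative abundances divide each active ZOTU's unrarefied
DNA reads by the active set's total DNA reads; phantom taxa are included
with their DNA reads, which for structural phantoms are zero (no
pseudo-counts are invented — a phantom can be active yet contribute zero
abundance). Samples with no active ZOTU, or an active set with zero reads,
yield a flagged all-NaN composition. Diversity is observed richness plus
Shannon entropy with natural log, from DNA reads.

Seeding: a master seed spawns one child stream per (sample, trial) via
`numpy.random.SeedSequence`, so per-sample results are independent of
processing order.

## Community response

The response ratio uses the symmetric difference-over-sum form
`(b − a)/(b + a)`: it is the standard bounded response statistic whose
range and endpoint interpretations (±1 = appearance/disappearance) match
the intended use. The neutral band is inclusive (|rr| ≤ 0.5), making the
three categories an exact partition with deterministic boundaries. The
0.1 % abundance filter is "exceeds at **either** timepoint" (strict >), so
taxa that appear or vanish — the most interesting responders — are
retained. Response ratios are computed on active-community relative
abundances (an assumption; whole-community abundances of active ZOTUs are
an alternative reading).

Vector fitting regresses the centered variable on centered ordination
scores; the arrow is the normalized coefficient vector, r² the fraction of
variance explained, and p a permutation test
`(1 + #{r²_perm ≥ r²_obs})/(1 + n_perm)`. This reproduces vegan `envfit`
r² and arrows to ~1e-6 (cross-checked in the test suite via Rscript).
NMDS is deliberately not implemented; ordination coordinates are an input.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: two 3.4 L
SBRs over 80 days, the test reactor dosed at ~150 μg/L each of DCF, ERY,
and GEM; a removal phase (days 0–12) with per-compound removal fractions
{DCF 0.50, ERY 0.18, GEM 0.40} (peak removals of roughly this size are what
such exposures report); a desorption spike (days 12–23) with effluent at
`desorption_multiplier × influent` (default 2.0, i.e. −100 % removal); and
negligible removal after day 23. Solid-phase concentrations rise during
phase 1 and decay thereafter. Raw aqueous/solid measurements are distorted
by realistic extraction recoveries (aqueous 0.97/1.17/0.98, solid
0.75/0.56/0.68) so the correction stage has real work to do. Measurement
noise is multiplicative lognormal with CV 0.10 by default (reported spreads
for such measurements are ~10–20 %); `noise_cv=0` gives exact noise-free
constructions used by round-trip tests. Degradation-product peaks are
emitted only on days the product is truly present, with small (|ppm| ≤ 4)
mass errors and S/N 15–60; optional decoy peaks are constructed to fail
exactly one filter rule.

Community samples draw a latent composition per sample from a Dirichlet
(base Dirichlet(5) over ZOTUs, overdispersion 300) and sample DNA and cDNA
counts multinomially at the configured depths (default 20 000). Truly
active taxa have cDNA concentration 3× their DNA share, inactive taxa
0.3×; phantom taxa have structurally zero DNA concentration (an
`undersampled_phantoms` option makes them merely rare instead). The test
reactor adds a deterministic time drift to a few active taxa (decliners and
bloomers) so response ratios are non-trivial; the control reactor has no
pharmaceutical effect. Conventional analytes follow configurable removal
trajectories (test-reactor nitrogen ~0.70 with a brief recovery peaking at
0.93 mid-phase, phosphate ~0.63, DOC 0.92 in both reactors).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing error and chimeras (counts are drawn
from the true composition), compositional correlations between taxa beyond
the Dirichlet, reverse-transcription bias in cDNA yields, chromatographic
co-elution or matrix effects beyond a scalar recovery, and reactor
hydraulics (no ASM-style kinetics; phase trajectories are imposed, not
emergent). Parameter-recovery results (e.g. caller sensitivity/specificity
≥ 0.9) are statements about this generative model at the stated depths.

## Problem sizes and determinism

The test suite and acceptance checks run at deliberately desk-scale sizes:
communities of 24–150 ZOTUs, 1–4 samples per reactor, depths 2 000–50 000,
100 rarefaction trials, 199–999 permutations; the full default pipeline run
(60 ZOTUs, 16 samples, depth 20 000, 100 trials) completes in seconds.
Every random draw descends from a single seed; the pipeline manifest hashes
every output table, and reruns with an identical configuration are
hash-identical.

## Known limitations

* The mass balance has no volume or inventory terms; removal is a
  concentration ratio.
* Corrected peak areas are relative proxies; no absolute product
  quantification is attempted (by design).
* The phantom substitution value (100) is a convention, not an estimate;
  mean ratios near the threshold are sensitive to depth and trial count.
* `fit_environment` reports raw permutation p-values with no
  multiple-testing correction across variables.
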