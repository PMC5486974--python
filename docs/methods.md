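# Methods

## The model

`stimcnv` models environmentally stimulated copy number variation (CNV) at
tandem gene arrays in budding yeast, with the copper-inducible *CUP1* array
as the reference system. The biological picture is: each repeat unit carries
a bidirectional promoter next to a replication fork stalling (RFS) site.
Inducing the promoter drives a cryptic unstable transcript (CUT) through the
RFS site; transcription across the stalled fork promotes its collapse, the
fork restarts by break-induced replication (BIR), and the restarted,
low-processivity fork template-switches between repeat copies, changing the
copy number of the array. H3K56 acetylation (written by Rtt109, erased by
Hst3/Hst4, raised globally by nicotinamide) reduces BIR fork processivity
and is required for the stimulated pathway.

The package decomposes this into four layers, each independently testable:

1. **Activity map** (`locus_activity`): environment × locus × genotype →
   (sense activity `t_sense`, antisense/CUT activity `t_anti`, acetylation
   `A`), all in [0, 1].
2. **Rate law** (`stimulated_cnv_rate`): per-allele per-division CNV
   probability.
3. **Outcome scheme** (`enumerate_switch_outcomes`, `sample_cnv_event`):
   what a CNV event does to the copy number.
4. **Population layer** (`population`): who divides, who dies, and where
   events accumulate, for the four assay designs (mother-enrichment cohort,
   batch outgrowth, competition, growth curves).

## Rate law: form and rationale

```
rate = fork_stability_modifier · b + r_max · (1 − exp(−κ · t_anti · H(A)))
H(A) = A^h / (A^h + K^h)
```

The functional form is a design choice of this package, not a fitted
mechanistic law: no published rate equation exists for this pathway. It was
chosen as the minimal smooth form that reproduces four qualitative contrasts
at once:

* a silent promoter (`t_anti = 0`) is never stimulated, whatever the
  acetylation state — nicotinamide alone does nothing to a glucose-repressed
  galactose promoter;
* an induced promoter with basal acetylation is strongly stimulated —
  copper alone suffices at *CUP1*;
* removing the acetyltransferase (`A = 0`, so `H(A) = 0` exactly) collapses
  the rate to the basal term `fork_stability_modifier · b` — the rtt109Δ
  gate is exact, not approximate;
* because `t_anti` and `H(A)` multiply *inside* a saturating exponential,
  either channel saturates the stimulated term when the other is high, so
  the nicotinamide effect vanishes at saturating induction while the two
  contributions are additive in the intermediate regime.

The transcription drive is the antisense activity `t_anti` (transcription
through the RFS site), since stimulation tracks bidirectional/antisense
firing rather than sense mRNA output; `t_sense` is carried in the state for
reporting but unused by the default rate law, because the data do not
separate an independent sense contribution. For galactose- and
formaldehyde-inducible constructs the promoter is treated as symmetric
(`t_sense = t_anti`).

Default parameters (`RateParams`): `b = 0.0015` per allele per division,
`r_max = 0.05`, `κ = 8`, `ac_K = 0.3`, `ac_h = 2`. These were calibrated
once against the cohort arithmetic of the copper experiment: an untreated
diploid cohort (two ~13-copy alleles, ~12 divisions in 24 h) should show a
few percent deviating alleles, and a 1 mM copper cohort (~8 divisions)
should show roughly an order of magnitude more. With these defaults the
simulated per-division rates are ≈ 0.004 (untreated) and ≈ 0.05 (1 mM
copper), which integrate to ≈ 5% and ≈ 30% deviating alleles over the assay
window — the observed regime.

## Activity map

Hill responses with unit-bearing constants (`ActivityParams`): copper
half-induction 0.3 mM (h = 2), galactose half-induction at carbon fraction
0.2 (h = 2), formaldehyde half-induction 0.7 mM with a sharp exponent
(h = 6) to mirror the narrow 0.9–1.0 mM growth/no-growth window of the
3x*SFA1* system. Nicotinamide acts twice, separably: it raises `t_anti` at
the endogenous copper promoter (loss of promoter directionality; Hill with
K = 1 mM) and ramps acetylation linearly to `A = 1` at 5 mM (the assay
concentration; full HDAC inhibition). The two effects are independent
because the directionality effect is observed even in rtt109Δ cells, where
the acetylation channel is closed. The uninduced copper promoter keeps a
small antisense floor (`antisense_floor = 0.01`); basal acetylation is
`a0 = 0.4`. rrp6Δ (stabilised CUTs) affects only reported CUT abundance in
synthetic expression output, never the rate — the mutant is a detection
tool, not a pathway component.

## Template-switch outcome scheme

`SwitchScheme` models an event as `n_switches` successive template switches,
each independently "forward" (towards the array end, net copy loss,
`delta_forward = −1`) with probability `p_forward = ½` or "backward"
(re-replication, net gain, `delta_backward = +1`). Exhaustive enumeration of
the 2^n ordered paths gives the outcome distribution; classes follow the
sign of the net delta, with zero-net paths scored as `zero_net_class`. The
default (n = 2, zero-net = contraction) yields paths {FF: −2, FB: 0, BF: 0,
BB: +2} and the 3:1 contraction:amplification bias characteristic of the
mechanism. This default is the *minimal* parameterisation producing 3:1; it
is not unique (e.g. asymmetric per-switch magnitudes with sign-based
classification also produce 3:1), so every element of the scheme is
configurable rather than hard-coded.

Sampling (`sample_cnv_event`) clips contractions at the floor
`min_copies − copies`. The default floor is 1 (a single-copy allele has no
nonallelic homologous template and can neither contract further nor seed an
event — `copies = 1` always returns no-event); setting `min_copies = 0`
permits whole-array loss, as seen in pol32Δ backgrounds. A contraction
clipped all the way to zero net change is suppressed rather than reported
as a spurious neutral event.

## Population layer

**Fitness.** Copper inhibition is `I = c^h / (c^h + (K0 + k_copy·n)^h)`
with `n` the cell's total array copies across alleles: protection is linear
in copy number (each repeat adds metallothionein dosage), giving
half-inhibition at `K0 + k_copy·n` mM. Division time is
`1/(mu_max·(1 − I))` hours. Death is a per-division probability
`p_death · I^dh/(I^dh + death_threshold^dh)` — a graded Hill hazard with
half-maximum at `death_threshold = 0.6` — plus a copper-independent
baseline `p_death_base = 0.01` per division (replicative attrition over the
24 h window). A graded hazard was used instead of a hard threshold because
a single step probability cannot simultaneously produce moderate viability
loss in the high-copy cohort at 1 mM (I ≈ 0.33) and near-total growth
suppression of 3-copy cells at 0.75 mM (I ≈ 0.69); the Hill form does both
with one parameter set.

Defaults (`mu_max = 0.5`/h, `K0 = 0.385` mM, `k_copy = 0.0383` mM/copy,
`hill_h = 2`, `death_h = 4`, `p_death = 0.95`) were calibrated jointly,
once, to the printed phenotypes: ≈ 12 divisions per 24 h without copper vs
≈ 8 with 1 mM for the high-copy diploid; ≈ 89% untreated vs ≈ 40% treated
cohort viability; GI50 ≈ 0.5 mM for untreated 3-copy cells; slow growth at
0.3 mM and full inhibition at 0.75 mM for 3-copy cells. Whether treated
cells are lost by death or arrest is not distinguished by the data; the
simulator models loss as death and exposes the probabilities.

**Cohort assay** (`run_mep_cohort`): founders are simulated independently
on their own division clocks (asynchronous, wall-time-bounded — copper
slows division, so generation-synchronous stepping would misrepresent the
24 h window). Daughters are discarded: the assay runs in β-estradiol, where
newborn cells are inviable (escape probability `p_esc`, default 0 — the
leakiness of the system is not quantified). Each division gives each allele
one CNV draw; a mutated allele segregates to mother or daughter with
probability ½ (sister-chromatid ambiguity; the data do not resolve it), so
only half of all events remain in the assayed cohort.

**Batch/competition** (`run_batch_culture`, `run_competition`): a shared
vectorised engine with discrete time steps of `0.25/mu_max` hours; each
cell divides within a step with probability `1 − exp(−mu·(1 − I)·dt)`,
dividing mothers draw CNV events and die with the per-division hazard.
Runs stop after the requested number of population doublings. Populations
above `population_cap` (default 10⁵ agents) are randomly down-sampled with
a tracked scale factor — a pure desk-scale approximation that preserves
expected allele frequencies but truncates rare-lineage dynamics.

**Growth curves** (`simulate_growth_curve`): biomass per copy-number class
integrated deterministically (Euler, 0.02 h substeps) under logistic
capacity, with net per-class rate `mu_i·(1 + log2(1 − p_death,i))` (each
division multiplies a lineage by `2(1 − p_death)`); additive Gaussian
measurement noise on OD. CNV during the curve itself is not modelled — the
curve reflects the seeded composition, which is sufficient for the
kinetics estimators the package tests. OD mapping: blank 0.05, capacity
1.2 OD₆₆₀, inoculum 1:1000 of saturation.

## Inference procedures

**Cohort rate test** (`cohort_rate_test`). The verbal description of the
published normalisation admits several readings; the implementation pins
the only internally consistent "conservative" one: background rate
`r = events_u / (alleles_u / v_u)` — events per *starting-cohort* allele,
i.e. cells lost during the window are assumed event-free; treated starting
alleles `N_t = alleles_t / v_t`; `E = r·N_t`; `O = events_t`; two-cell
goodness of fit `χ² = (O−E)²/E + ((N_t−O)−(N_t−E))²/(N_t−E)` with 1 df.
On the printed cohort counts this procedure yields p ≈ 7×10⁻²¹ for CNV
events and ≈ 3×10⁻⁷ for amplifications — much smaller than the printed
1.1×10⁻⁷ and 0.028, which could not be reproduced under any single reading
of the normalisation; the package reports its pinned procedure's outputs
and does not force agreement. The fold estimator reports the raw
per-recovered-allele rate ratio `(events_t/alleles_t)/(events_u/alleles_u)`
(10.1 on the printed counts); the printed "9-fold" equals the ratio of the
*rounded* percentages (27/3) and is not a ratio this package computes.
Note also that 31/112 = 27.7% rounds to 28%, not the printed 27%, under
half-up rounding; the discrepancy is documented, not replicated. The test's
χ² p-value is cross-checked in the suite against the exact binomial null of
the same statistic by Monte-Carlo.

**Percentages and band tables.** `percent_deviating` takes counts, a
per-allele copy-number list, or a band table (probe-corrected,
intensity-weighted); printed-style percentages round half *up* to the
nearest integer. `probe_correct` divides band intensity by probe-binding
sites and renormalises — amplified alleles bind proportionally more probe,
so raw intensity overstates their molar share. `percent_low_copy` reports
corrected mass at ≤ 3 copies (multiple-contraction products).

**Kinetics.** `smooth_curve` is a centred 9-point moving average (the
plate-reader smoothing convention); edge handling — truncated one-sided
windows — is this package's choice, as is making the width configurable.
`max_growth_rate` takes central finite differences of the smoothed curve;
on a noiseless logistic sampled every 15 min the estimate is biased low by
≈ (μ·Δt_window)²-order smoothing loss, ≈ 1.3% at μ = 0.35/h — within the
2% accuracy the suite asserts. `dose_response` integrates AUC by trapezoid
over concentration and interpolates GI50 linearly at the 50%-of-zero-dose
crossing (the published estimator is unstated); a never-crossing series is
right-censored at the maximum concentration and flagged.

**Delegations.** ANOVA/t-test group comparisons used around these readouts
are deliberately not reimplemented; the package emits the tidy per-gene /
per-culture tables such routines consume. χ² tail probabilities come from
`scipy.stats`; smoothing from pandas rolling windows.

## Genomics

Coordinates are 0-based half-open internally; GFF3 is converted on read.
The upstream window is measured from the CDS start (1 kb, strand-aware,
clamped at position 0) — whether the original classification measured from
the CDS start or an annotated TSS is ambiguous, so CDS start is pinned and
the window size configurable. A gene is γH2A iff ≥ 1 peak with fold
enrichment ≥ 2 overlaps the window by ≥ 1 bp (no overlap-fraction rule is
published, so the minimal criterion is used). Expression normalisation is
`log2((count + 1) / CDS_kb)` per gene, then one additive constant per
dataset so the dataset median equals 9 exactly (the correction is iterated
so the equality is exact even when the median is the floating-point
midpoint of a central pair); the pseudocount of 1 for zero counts is this
package's choice. The ~7% genome-wide γH2A gene fraction depends on the
real ChIP-seq data and peak caller and is a qualitative check on real
inputs only — never a fixture target.

## Synthetic data

Generators are pure functions of (parameters, seed) and write the same
formats the parsers read. Defaults encode the study conditions: diploid
cohorts with 13/14-copy parental alleles, viabilities (0.40 treated, 0.89
untreated), planted event rates 0.027/0.27 (the observed per-recovered-
allele fractions, 10-fold apart); growth curves of 72 h at 15-min sampling
with logistic rate 0.35/h, capacity 1.2 OD, noise SD 0.005; genome fixtures
of 100 genes on two chromosomes with 10 planted γH2A genes and a −2 log2
expression shift. Gene spacing (5 kb) guarantees two 1-kb upstream windows
never share an intergenic gap, so planted classifications are exactly
recoverable.

What the generators deliberately do *not* emulate: selection during the
cohort window (rates are planted per-window, not per-division), Southern
band blur and partial digestion, alignment/peak-calling noise in the
genome fixture, and plate-position effects in growth curves. Passing
recovery tests on these fixtures therefore demonstrates the correctness of
the estimators and classifiers under their stated model, not robustness to
every artefact of real gels and sequencing.

## Numerical choices and degenerate inputs

* Event streams, cohorts and fixtures are bit-reproducible from
  (config, seed); all randomness flows through `numpy.random.Generator`.
* Empty cohort (`n_start = 0`): empty table, viability NaN.
* Batch extinction is reported in the result, not raised.
* A χ² test with zero expected events raises `UndefinedTestError`;
  viability 0 is rejected at construction.
* `percent_deviating` rounding: half-up (`floor(x + 0.5)`).
* Growth-curve integration uses 0.02 h Euler substeps — refining further
  changes the simulated max rate by < 0.1%.
* Scheme enumeration is cached per scheme (frozen dataclass), so repeated
  event sampling does not re-enumerate.

## Problem sizes

The shipped tests and acceptance checks run cohorts of 120–500 founders,
batch cultures of a few hundred founders capped at 10⁵ agents, 20-seed
competition panels and 10⁵-draw Monte-Carlo comparisons; these sizes give
standard errors comfortably inside every asserted tolerance while keeping
the whole suite in the seconds-to-minutes range on a laptop.

## Known limitations

* The rate law and fitness model are phenomenological; their parameters
  are calibrated to printed summary phenotypes, not fitted to raw data.
* No sequence-level junction modelling, no DNA-repair kinetics, no
  extrachromosomal-circle amplification (negligible for *CUP1*), no
  chromatin state beyond the scalar `A`.
* Diploids carry two independent alleles; inter-homolog recombination is
  not modelled.
* No spatial structure, mating, or cell-cycle phase resolution.
* The CLI consumes derived files (peak calls, annotations, count tables);
  alignment and peak calling are upstream tools' work and are consumed,
  not re-implemented.
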