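# Methods

## The two-state conversion model

A PEV locus is modeled as a two-state Markov chain per cell generation:
active (A) with probability `c_as` of converting to silent at each
division, silent (S) with probability `c_sa` of converting to active.
Both coefficients are probabilities (fractions in [0, 1], percent only at
I/O boundaries) and are independent of each other and of the current
population composition. The population-level active fraction obeys

    Y_A[n] = Y_A[n-1] − Y_A[n-1]·c_as + (1 − Y_A[n-1])·c_sa,

an affine recurrence whose solution is geometric relaxation to
`Y* = c_sa/(c_sa + c_as)` with retention factor `λ = 1 − c_sa − c_as`
(`closed_form` is verified against literal iteration to 1e-12 over 500
generations in the test suite, not taken on faith). When both rates are
zero every composition is frozen: `closed_form` returns `y0`, and only
`equilibrium()` raises ("no unique equilibrium"). When `c_sa + c_as > 1`
the model is still well defined but `λ < 0`, so the approach alternates
around `Y*`; constructing such rates emits a warning since measured
switching rates sum well below 1.

**"Equilibrium reached"** is operationalized as: both the all-silent
(`y0 = 0`) and all-active (`y0 = 1`) trajectories are within 2 percentage
points (0.02 absolute) of `Y*`. The first-passage generation is computed
by inverting the exact geometric decay
(`n = ⌈ln(tol/|y0 − Y*|)/ln λ⌉`, with an iterative fallback for `λ ≤ 0`)
and cross-checked against brute-force iteration in the tests. This
convention reproduces, as bounds, all the canonical generation counts for
the five reference scenarios (16 ≤ 20 at 15%/6%; 34 ≤ 40 at 7%/3%;
25 < 30 at 15%/0.01%; 10 ≤ 10 at 15%/15%; 160 ≥ 100 at 1%/1%).

Generations are integer division steps. Fractional generation numbers
(as produced by OD600 ratios, `log2(OD_f/OD_i)`) are accepted by the
closed form as geometric interpolation.

## Branching mini-culture simulation

The single-cell assay is simulated as a synchronous branching process:
each generation every cell divides into two daughters, and each daughter
independently converts with its state's coefficient. Per-daughter
independence is the minimal mechanism whose expectation reproduces the
population recurrence exactly; whether real conversions affect one or
both sister loci per division is not resolved by population data, and
the model deliberately does not distinguish these cases. The population
is tracked as exact (active, silent) counts via paired binomial draws —
distributionally identical to per-cell agents (verified against a
literal agent simulation at ≤64 cells in the tests) but O(generations)
instead of O(cells), so 40-generation lineages are instantaneous.

Not modeled: cell death, state-dependent division times, and well
cross-contamination (sonication before seeding is treated as perfect
dispersal). Founder states are Bernoulli draws; the default founder
probability is the equilibrium `Y*` of the supplied rates (0.5 for
symmetric rates) because the seeding culture has grown unselected for
many generations — it is overridable when the seeding mixture is known.
Per-clone randomness derives from
`SeedSequence(master_seed, spawn_key=(1, clone_index))`, a stable,
platform-independent scheme, so panels reproduce bit-for-bit.

With symmetric 7%/7% rates over 15 generations, 50-clone panels spread
over a narrow mid band (roughly 35–65% active); at 1%/1% most clones
stay near their founder's state and the sorted profile is two-phase with
modes near `closed_form(0) = 0.13` and `closed_form(1) = 0.87`. The
`mid_band_fraction` summary (share of clones in [0.25, 0.75]) separates
the two regimes.

## Rate estimation

`ConversionRateEstimator` minimizes the unweighted sum of squared
residuals between observed %FOA-resistant fractions and the closed-form
silenced fraction `1 − Y_A(n)`, fitted jointly over both selection
origins (`y0 = 0` for FOA-established cultures, `y0 = 1` for
ura-established ones). %FOA^R is identified with the silenced fraction
and %URA+ with the active fraction — perfect selection, no
plating-efficiency correction; observed ratios above 1 (counting noise)
are clamped to 1 for fitting only. Unweighted least squares is the
simplest objective consistent with jointly plotted dual-origin fits;
no weighting scheme is attempted.

The search is a 24×24 log-spaced grid over the box [1e-5, 0.5] per rate
(covering all reported telomeric and mating-locus rates, 0.0006–0.15,
while excluding the degenerate boundary) followed by Nelder–Mead
refinement from the 4 best grid cells (`xatol` 1e-12); ties between
equal optima prefer the smaller `c_as`. Data spanning fewer than two
distinct generations are rejected ("insufficient time resolution");
a single selection origin is allowed but recorded as a warning.
Plateau-only data (all observations within 2 points of one value) set
`identifiable_ = False`: such data constrain only the ratio
`c_sa/(c_sa + c_as)`, not the individual rates.

**Bootstrap intervals** are case-resampling percentile intervals:
time points are resampled with replacement within each course, the model
is refitted, and the 2.5–97.5 percentiles of B = 200 refits are
reported. Refits start a Nelder–Mead search from the full-data point
estimate rather than repeating the global grid scan — the resampled
objective is a small perturbation of the original, and the shortcut
changes coverage by less than the Monte-Carlo noise (checked against
full global refits). Percentile case-resampling intervals need a
reasonable number of points per course to reach near-nominal coverage:
at ~11 points per course their realized coverage is in the low 80s
percent, at ~26 points per course it exceeds 90%. The coverage test
therefore samples generations 0–50 in steps of 2. Degenerate resamples
(fewer than two distinct generations) fall back to the point estimate.

**Equilibrium diagnostic.** A single-time-point pair of %FOA^R values
from the two initial selections is labeled `at_equilibrium` when they
agree within 0.15 (absolute), else `selection_dependent`. The 0.15
default cleanly separates published wild-type-like strains (deltas
≤ ~0.1) from hysteretic slow-switching mutants (deltas ~0.9); it is
configurable.

**Scenario classification** compares two fitted rate pairs by fold
change with a default threshold of 3×: both rates down → gain of
stability; both up → loss of stability; `c_sa` up alone → loss of
silencing; `c_as` up alone → gain of silencing; otherwise unchanged.
Qualitative contrasts in this assay family span 2–10×, so 3 is a
middle-of-the-road default (configurable); point estimates are
classified as-is, with bootstrap intervals reported alongside rather
than folded into a test.

## Synthetic assay data

The generators emulate the statistical structure the analysis assumes,
not the biology of the assays:

- **Plating counts** — each plate (non-selective, SC-ura, SC/FOA)
  receives an independent serial-dilution aliquot, so counts are
  independent Poisson draws with means `m`, `m·Y_A`, `m·(1 − Y_A)`;
  reported fractions are count ratios (the non-selective count is
  redrawn until positive). Default `m = 200` colonies per plate, a
  typical countable density. Ratios occasionally exceed 100%, matching
  real plating tables; stored fractions are truncated at the container's
  documented 120% ceiling (the truncation binds with probability
  < 1e-2 per point at the default density).
- **FACS wells** — observed %GFP+ is `Binomial(n_events, p)/n_events`
  with 10,000 events per well and an optional autofluorescence
  false-positive floor (default 0).
- **Mutation-driven FOA resistance is omitted**: forward-mutation rates
  (≤1e-6 per generation) are three to four orders below epigenetic
  switching (1e-2–1e-3) and invisible at these sample sizes.

Every generator is a pure function of (parameters, seed). What passing
tests on these data do **not** show: robustness to plating-efficiency
differences between media, to FOA escapers or reporter loss, to
generation-dependent (aging) rates — the late-generation collapse of
FOA resistance seen in some long CAF-I-mutant cultures is outside the
model — or to correlated noise between plates from a shared aliquot.

## Problem sizes

The test suite and acceptance script use desk-scale experiments chosen
to make Monte-Carlo noise small relative to the asserted tolerances:
2000 clones for law-of-large-numbers checks, 5000 replicates for the
agent-oracle comparison at ≤64 cells, 25 datasets × 500 expected
colonies for noisy rate recovery (relative tolerance 20%), 50 datasets
× B = 200 for bootstrap coverage, and 1000 randomized rate pairs × up
to 500 generations for the closed-form/iteration identity.
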