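# Methods

## The population model

We model an X-linked meiotic driver in a dioecious population with discrete,
non-overlapping generations. The driving X chromosome (X') biases its own
transmission through males: an X'Y male produces X'-bearing functional sperm
at frequency *t* (the **drive strength**), while XY males segregate 0.5/0.5.
Since X-bearing sperm sire daughters, *t* is also the expected female fraction
among a driver male's progeny. *t* = 0.5 is the Mendelian control; drive
proper is 0.5 < *t* ≤ 1.

Two further parameters shape the demography:

| symbol | meaning | default | constraint |
|---|---|---|---|
| *z* | offspring per reproducing female (reproduction index) | 2 | *z* ≥ 2 |
| *w* | females one male can fertilize (mating index) | 2 | *w* ≥ 2 |

*z* ≥ 2 is required because *z* = 1 declines even without a driver; *w* ≥ 2
reflects promiscuous mating. With *w*·*M* ≥ *F* (females limiting, equality
inclusive) every female reproduces and the egg pool is *N* = *z*·*F*; once
females outnumber what the males can service (*w*·*M* < *F*), *N* = *z*·*w*·*M*
and the population declines with the male supply.

State per generation: males *M*, females *F*, genotype counts *A* (X'Y),
*B* (XY), *C* (X'X'), *D* (X'X), *E* (XX), and the X' frequencies *R* (in
males) and *K* (in females). Offspring counts are the egg-by-sperm genotype
products: the egg pool carries X' at frequency *K*; the sperm pool carries X'
at *t·R*, X at (1−*R*)/2 and Y at the rest. This yields, with egg number *N*,

    M' = (1/2 − t)·N·R + N/2        F' = (t − 1/2)·N·R + N/2

and the induced frequency recursion

    R' = K        K' = K/2 + t·R / ((2t − 1)·R + 1)

The compact form of *K*′ is implemented in production; its expanded
allele-counting form, [K/2 + tR + (t − 1/2)KR] / [(2t − 1)R + 1], and a full
egg×sperm enumeration both serve as *test oracles only*, and the suite checks
the three routes agree to 1e−12. For any *t* > 0.5 the recursion drives *R*,
*K* → 1 (fixation of X'), faster for stronger drive; at *t* = 0.5 the weighted
mean (2*K* + *R*)/3 is conserved and both frequencies converge to it.

Counts are real-valued expectations: the model is deterministic by
construction and carries no demographic stochasticity (no Wright–Fisher
variant, no overlapping generations, no driver fitness costs, no suppressor
dynamics — all out of scope).

## Extinction threshold and phase structure

At fixation (*R* = *K* = 1) the male-limited step gives
Total′ = *z*·*w*·(1 − *t*)·Total, so a steady state (rate 1) requires

    t_threshold = 1 − 1/(z·w)

The female-limited candidate would require *t* = 1/*z* ≤ 0.5, contradicting
drive, so the steady state exists only in the male-limited regime;
`analytic_threshold` exposes this rejected candidate explicitly. The minimum
over admissible parameters (*z* = *w* = 2) is 0.75: drivers weaker than 75%
expand forever (the sex ratio stabilizes at M/F = (1−*t*)/*t* in the
female-limited regime when *t* ≤ *w*/(1+*w*), or the male-limited analogue
above it), drivers stronger than 75% expand transiently, cross rate 1
downward, and go extinct — the stronger the sooner.

`numeric_threshold` recovers the boundary without the formula: bisection on
*t* ∈ (0.5, 1) using the sign of the long-run log change rate. The rate is
measured only after the frequency recursion has converged (*R* > 1 − 1e−9),
so transient pre-fixation growth cannot contaminate the sign, and the count
recursion is iterated on counts renormalized to unit total each generation —
the recursion is scale-free, and renormalization keeps arbitrarily long
growth phases inside floating-point range.

### Outcome classification

`simulate_trajectory` labels a run as:

* **extinction** — either sex drops below the extinction floor. The floor is
  a numerical choice (the model never reaches exact zero); default 1.0,
  i.e. fewer than one expected individual, configurable.
* **steady** — |rate − 1| < 1e−6 for 50 consecutive generations after the
  frequencies have settled. "Settled" means either X' fixation
  (*R* > 1 − 1e−6) or stationary frequencies (|ΔR|, |ΔK| < 1e−9); the second
  branch exists so the Mendelian null (*t* = 0.5, rate ≡ 1, frequencies
  frozen forever away from fixation) classifies as steady rather than
  running out the horizon.
* **expansion** — rate > 1 + 1e−6 sustained for the same window after
  settlement (this also stops the run before unbounded growth overflows).
* **undetermined** — horizon (default 500 generations) exhausted. This is a
  horizon artifact near the threshold, not an error: drivers barely above
  threshold decline at a rate arbitrarily close to 1 and need correspondingly
  long horizons.

A tie at exactly the threshold classifies as steady, since the limiting rate
there is exactly 1.

## The meiosis mechanism

The driver's toxic protein is present in every primary spermatocyte and is
scored as present/absent per cell (binary; protein-amount dilution is not
modeled). Four probabilities govern its fate:

| symbol | meaning | preset default |
|---|---|---|
| *p1* | meiosis I segregates the protein asymmetrically | 0.82 |
| *q* | protein cosegregates with the Y, given asymmetric MI | 0.73 |
| *p2* | meiosis II segregates the protein asymmetrically | 0.80 |
| *k* | killing penetrance of a protein-positive spermatid | 1.0 |

A symmetric division leaves *both* daughters protein-positive (there is no
protein-loss branch). *p2* is chromosome-independent — identical for X-X and
Y-Y meiosis-II divisions — and the two sister divisions are assumed
independent (independence is our assumption; correlation between them is
unobserved). A protein-carrying secondary spermatocyte contributes 2 − *p2*
expected protein-positive spermatids, giving

    E[(Y, Ste+)] = (2 − p2)·(p1·q + 1 − p1)
    E[(X, Ste+)] = (2 − p2)·(p1·(1 − q) + 1 − p1)

of the two spermatids per chromosome class. The fraction of protein-positive
spermatids that are Y-bearing, (1 − *p1* + *p1*·*q*)/(2 − *p1*), is invariant
to *p2* (the 2 − *p2* factor cancels) — so spermatid FISH scoring alone can
never constrain the meiosis-II asymmetry. Killing with penetrance *k* leaves
2 − *k*·E[Ste+] functional sperm per class and the realized drive strength

    t = survX / (survX + survY)

In the idealized limit *p1* = *q* = *p2* = *k* = 1 each meiosis delivers two
X-bearing and one Y-bearing sperm: *t* = 2/3. This is the model's central
point — the *second* asymmetric division spares half the Y-bearing spermatids
and caps the drive well below completeness, which with the threshold above
(≥ 0.75 for all admissible *z*, *w*) places the mechanism's drive in the
safe, non-extinction zone. *k* defaults to 1 (protein-positive spermatids
fail to compact their DNA); *k* < 1 is exposed for sensitivity analysis, and
*k* = 0 or *q* = 0.5 gives *t* = 0.5 exactly.

`simulate_meioses` is the Monte Carlo twin (one Bernoulli draw per branch
point, one killing draw per protein-positive spermatid, vectorized over
meioses, deterministic under seed). The tests compare its class frequencies
to the closed form at four standard errors using the *exact* per-meiosis
count variance π(4 − 3·p2) − π²(2 − p2)² (the class count is 0/1/2-valued;
a naive per-spermatid binomial SE would understate the spread because the
spermatids of one meiosis are correlated).

`estimate_cytology_params` is the binomial MLE (observed fractions) with
exact Clopper–Pearson 95% intervals (statsmodels, `method="beta"`); *q* is
estimated only among asymmetric meiosis-I cells and flagged undefined when
none were scored.

## Synthetic data

The generators emulate the *statistical* structure of the study's assays —
category counts and seeds, not images:

* telophase-I/II scoring tables: binomial asymmetry, and (MI only) binomial
  Y-cosegregation among asymmetric cells;
* spermatid FISH tables: each scored protein-positive spermatid is a
  nondisjunction product (XY or nullo) at a low rate (default 0.02, middle
  of the observed 0–4% band) and otherwise Y-bearing with the closed-form
  fraction above; the nondisjunction category is generated *and kept* so the
  downstream exclusion rule is exercised;
* progeny tables: 10 males per genotype, five mating periods each, Poisson
  offspring per period (mean 60 → ≈ 3000 pooled offspring per genotype,
  matching the scale at which the pooled sex ratio is informative), each
  offspring female with probability *t* plus an optional per-period ageing
  increment. Poisson is a stand-in: per-male count distributions are not
  published, and only the sex-labeling process matters for drive inference.

Sample-size defaults (200 MI cells, 150 MII cells, 300 FISH spermatids) are
realistic scoring scales chosen once. Every table records its seed and
generating parameters. Presets named after genotypes (e.g. `X^Ste200/Y`) are
convenience fixtures with probabilities drawn from the reported cytological
ranges; they are presets, not measurements. What passing tests show is that
the *estimators and tests recover what the generators put in* — they cannot
validate the binomial/Poisson form against real count data, nor pick up
overdispersion, male-to-male heterogeneity, or scoring error, none of which
are modeled.

## Statistics

Three tests, all two-sided, no multiple-testing correction (per-comparison
exact P values are reported):

* **Fisher exact (2×2)** for between-genotype count comparisons. Conditions
  on both margins; p sums hypergeometric probabilities of all tables at most
  as probable as the observed one.
* **Exact binomial** for the one-sample 50:50 null on spermatid chromosome
  identity. The source analyses label this comparison a Fisher exact test
  without printing its 2×2 construction; for a single sample against a fixed
  null the exact binomial test is the cleanly defined equivalent, so it is
  the primary implementation here and the 2×2 Fisher form is reserved for
  genuine two-sample comparisons.
* **Unpaired t** on per-male female:male progeny ratios, defaulting to the
  classic equal-variance Student form (common graphing-software default;
  which variant the source used is not stated); Welch available by flag.

Both exact tests use the "sum of outcome probabilities ≤ observed" two-sided
convention with a relative tie tolerance of 1e−12 — stated explicitly because
two-sided exact conventions differ between packages. Probability mass comes
from scipy's hypergeometric/binomial pmfs (cached per margin); the test suite
checks the p-values against exact integer enumeration (all 2×2 tables with
n ≤ 40, all (k, n) with n ≤ 30) and cross-checks scipy's own
`fisher_exact`/`binomtest`. Exact tests are conservative: simulated size at
α = 0.05 under the null stays below the nominal level.

Drive strength is estimated from pooled progeny — t̂ = females/(females +
males) over all assayed males, exact binomial CI — with per-male ratios kept
as the unit of analysis for the t test.

## Pipeline

`run_full_pipeline` chains: generate study (driver cross + Mendelian control
cross from one master seed via `SeedSequence.spawn`) → exclude nondisjunction
spermatids → binomial identity test, Fisher progeny test, per-male ratio
t test → estimate (p1, q, p2) and t̂ → analytic threshold for the configured
(z, w) → classify population dynamics at t̂. Because sampling noise in a
near-Mendelian cross can push the pooled female fraction slightly below 0.5,
t̂ is clamped into the model's domain [0.5, 1] before classification. The
killing penetrance *k* is not a scored quantity, so the cytology-implied
drive estimate plugs in the configured *k*. Reports serialize to JSON with
sorted keys and 12-significant-digit floats, making byte-identical
reproducibility under a seed a testable contract.

## Problem sizes and numerical choices

Default horizons (500 generations), the bisection tolerance (1e−6 on *t*;
the acceptance script uses 1e−5), 100,000-meiosis Monte Carlo runs and
1,000-replicate coverage checks are the package's chosen working sizes;
all complete in seconds on one core. Frequencies are clipped to [0, 1] only
within a 1e−12 round-off tolerance (anything larger raises); double
precision throughout. Degenerate inputs are absorbed or rejected explicitly:
an empty population advances to the all-zero state, an all-killed
spermatid pool (*k* = 1, *p1* = *p2* = 0) has no defined drive strength, a
zero-male progeny record has an infinite sex ratio, and *t* = 0.5 has no
fixation time.

## Known limitations

* The population model is deterministic; extinction of small populations is
  a threshold convention, not demographic stochasticity, and the "safe zone"
  below threshold ignores drift, fitness costs and suppressor evolution.
* The meiosis model has no protein-loss branch, no amount effects, assumes
  independent sister meiosis-II divisions, and does not model the
  high-expression meiotic-catastrophe (complete sterility) regime.
* Synthetic data are clean binomial/Poisson processes; real scoring data may
  be overdispersed or heterogeneous across males.
* Generation counts to extinction are validated by ordering properties
  (stronger drive dies no later), not by absolute values, which depend on
  the extinction-floor convention.
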