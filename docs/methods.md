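# Methods

## Model

`rdnasim` simulates the rDNA copy number (CN) carried by sperm produced
by *Drosophila* male germline lineages over a fixed window of stem-cell
activity.  The state of one lineage is a single nonnegative integer: the
CN of the tracked rDNA locus in the current germline stem cell (GSC).
Per-chromatid genotypes are not tracked; the unequal sister chromatid
exchange (USCE) event is summarised by its net copy transfer.

One GSC division proceeds as:

1. **Event.** With probability `usce_freq_gsc` a USCE occurs.
2. **Magnitude.** The copy-number change is drawn as
   `delta ~ Normal(sqrt(C), sqrt(C))`, where `C` is the CN at the time of
   the division, rounded to the nearest whole repeat unit and bounded by
   `|delta| <= C` (one exchange can at most double a chromatid, and
   neither chromatid can go below zero).
3. **Inheritance.** With probability `gsc_gain_bias` the self-renewing
   GSC receives `C + delta` and the gonialblast (GB) `C - delta`;
   otherwise the roles swap.  The two daughters always sum to `2C`.
4. **Cyst expansion.** The GB undergoes `sg_rounds = 4` symmetric
   doublings (15 cell divisions) producing 16 terminal cells, counted as
   sperm.  With probability `usce_freq_sg` one USCE is applied at a
   uniformly chosen cyst division; the affected daughters receive
   `C' + delta` and `C' - delta` in random (50/50) order — direction in
   the transit-amplifying compartment is always unbiased.

Sperm from every division of every GSC of every fly are pooled into one
distribution per scenario (cumulative pooling: differentiating cells that
inherited low CN early in the process contribute only their own cysts,
while later cysts are templated from the continually updated GSC).  A
configuration switch (`pool_last_k`) restricts pooling to the last *k*
divisions for sensitivity analysis.

Meiosis is not modelled: a "sperm" is one of the 16 cyst products.  GSC
loss, replacement and dedifferentiation are not modelled; lineages are
independent.  Extrachromosomal rDNA circles and the retrotransposon
biology that triggers the breaks are outside the model — only the
resulting USCE frequency enters as a parameter.

Under this model the expected per-division GSC drift is
`usce_freq_gsc * (2*gsc_gain_bias - 1) * E[delta]`, so unbiased
inheritance (bias 0.5) makes the lineage CN a martingale, bias above 0.5
magnifies, and bias below 0.5 erodes.  CN 0 is absorbing (the delta
distribution is degenerate at 0).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `initial_cn` | 100 (magnifying) / 200 (nonmagnifying) | copies | low-CN condition that triggers magnification vs. intact total |
| `n_divisions` | 28 | divisions | one GSC division every 12 h for two weeks |
| `n_gsc_per_fly` | 10 | cells | GSCs per testis niche |
| `n_flies` | 100 | animals | population size of the study |
| `usce_freq_gsc` | 0.04 or 0.5 | per division | observed DSB frequency in the nonmagnifying condition (4%, likely an overestimate) vs. observed frequency of asymmetric GSC anaphases under magnification (50%) |
| `usce_freq_sg` | 0 or 0.5 | per cyst | set equal to the GSC rate when active, a deliberate overestimate for the differentiating compartment |
| `gsc_gain_bias` | 0.8 / 0.5 / 0.2 | probability | observed nonrandom sister chromatid segregation is ~80%; 0.5 is the random control and 0.2 the mirrored control |
| `sperm_per_division` | 16 | cells | four symmetric SG doublings; must equal `2**sg_rounds` |
| `seed` | required | — | pins every stream; no hidden default |

## Design choices where the design was open

* **Sign of the drawn change.**  The per-event change is kept exactly as
  drawn from `Normal(sqrt(C), sqrt(C))`: a negative draw (probability
  `Phi(-1) ≈ 0.16`) means the nominally gaining chromatid actually loses
  copies.  This preserves the stated mean `sqrt(C)` of the change.  The
  alternative convention — truncating negative draws to zero so every
  event is a strict transfer — inflates the mean change to
  `~1.083*sqrt(C)` and with it the long-run magnification; it remains
  available as `delta_mode="censored"` and is covered by the tests.
* **Discreteness.**  CN is a count of repeat units, so draws are rounded
  to integers by default; `delta_discrete=False` provides a continuous
  mode.  The effect on pooled means is far below Monte-Carlo noise.
* **Placement of cyst USCE.**  The event probability is defined per
  cyst, with the event placed uniformly among the 15 cyst divisions.
  Pool-level means are invariant to this choice (every exchange
  conserves the cyst sum); tail shape is not, so an alternative
  per-division Bernoulli scheme (`sg_usce_mode="per_division"`, rate
  `usce_freq_sg/15` for a matched expected event count) is exposed.
* **Unit of comparison.**  The equivalence procedure compares pooled
  per-sperm values by default; a per-fly-mean mode (`by="fly-mean"`) is
  available as the conservative unit-of-analysis alternative.  Pooled
  means and means of per-fly means coincide here because the design is
  balanced; both are reported.

## Randomness

A scenario's seed feeds a `numpy.random.SeedSequence` spawn tree: one
child per fly, one grandchild per GSC, and per GSC two independent
streams (GSC divisions / cyst expansions).  Consequences used by the
tests: runs are bit-identical for a given seed; removing a fly leaves
every other fly's records unchanged; and two scenarios differing only in
cyst-level activity share identical GSC trajectories on a common seed
(common random numbers), which makes matched comparisons sharp — adding
cyst USCE then changes the pooled mean by exactly zero, since cyst
exchanges conserve cyst sums.

Stream discipline per GSC division: event uniform, then (if an event)
the Normal draw, then the direction uniform.  Per cyst: event uniform,
position draw, then per event the Normal draw and the order uniform.

## Statistics

The Brunner–Munzel test is implemented from midranks with per-group
placement variances, Welch–Satterthwaite degrees of freedom and a t
reference; `alternative="less"` means the first sample is stochastically
smaller.  Completely separated or doubly constant samples have zero
placement variance; they are returned with a `degenerate` flag and the
p-value assigned from the relative effect (0, ½ or 1) rather than by
dividing by zero.  When either group has fewer than 10 observations the
p-value comes from a permutation of the relative effect (exact
enumeration up to 20,000 assignments, otherwise Monte Carlo); the
asymptotic path is cross-checked in the tests against an independent
reference implementation and against the brute-force pairwise count.

Equivalence within `margin` copies: test `x - margin` vs `y` with
alternative "greater" and `x + margin` vs `y` with alternative "less".
Each p-value is large when the data are compatible with a difference no
larger than the margin; both above 0.95 declare equivalence (the
complement of TOST's "both one-sided p < 0.05").

## What the synthetic scenarios do and do not show

The fixture generator produces scenarios whose outcomes are known by
construction: zero-USCE scenarios (every sperm equals the initial CN
exactly), forced-event scenarios with a constant-delta override (GSC
trajectories are arithmetic progressions, with the absorbing floor at 0
exercised deliberately), and the six-scenario study matrix with expected
pooled means.  The override hook exists only for testing and is never
set in scientific presets.

Passing these checks shows the engine implements the stated stochastic
process — conservation, absorption, bias response, martingale behaviour
— at the study's sample sizes.  It does not validate the model against
real germlines: real GSC pools turn over and dedifferentiate, USCE rates
and inheritance bias are empirical point estimates, selection against
low-CN germ cells is not modelled, and meiotic recombination is ignored.

## Problem sizes and runtime

Full-scale scenarios (448,000 sperm) run in about a second each; the
complete test suite, which includes two full-scale scenarios, a
50-replicate full-scale martingale check and a 2,000-replicate null
calibration of the rank test, runs in about a minute on one CPU.  The
acceptance script simulates the two full-scale bias-80% scenarios and
their equivalence test in a few seconds.

## Known limitations

* A single scalar CN per lineage: no X/Y locus distinction, no
  per-chromatid bookkeeping, no distinction between exchange events of
  equal magnitude and opposite sign within one division.
* The normal magnitude model is a phenomenological fit; nothing enforces
  agreement with molecular step-size distributions.
* With CN near zero the integer rounding and the `|delta| <= C` cap make
  the walk's small-CN behaviour convention-dependent; conclusions about
  near-extinct arrays should not be read off this model.
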