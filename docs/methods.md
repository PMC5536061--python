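# Methods

This note documents the statistical models, defaults, numerical choices
and known limitations of `cocultrx`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Gene sets and overlap matrices

Gene symbols are canonicalized by whitespace-stripping and uppercasing
only; alias mapping (e.g. ADFP ↔ PLIN2, Hath1 ↔ ATOH1) is deliberately
out of scope and must be done upstream, because silent alias resolution
is a common source of irreproducible overlap counts. Analysis sets are
restricted to the supplied universe before any computation; genes falling
outside are counted and logged, never silently dropped.

Overlap frequencies are row-relative percentages (100·|A∩B|/|A|) rounded
half away from zero to one decimal, matching how published
overlap-frequency matrices are formatted. Raw counts are kept symmetric
and unrounded. One cell of the packaged reference matrix is flagged as a
printed discrepancy: a common count of 28 over a 6038-gene set computes
to 0.46% → 0.5% at one decimal, while the source table prints 0.4%. The
fixture records both; nothing is forced.

## Over-representation statistic

For a dataset of n genes inside an N-gene universe and a pathway with K
target genes in that universe, the overlap k is tested against the genome
frequency p = K/N with

    z = (k − n·p) / sqrt(n·p·(1−p) · c),

where c = 1 (binomial variance, the default — the usual genome-background
approximation when n ≪ N) or c = (N−n)/(N−1) (hypergeometric variance,
exact for sampling without replacement). Significance is one-sided
enrichment at a configurable confidence, default 90% (z ≥ 1.2816);
depletion is not tested, and no multiple-testing correction is applied —
the matrix reports its number of tests so users can correct externally.
Pathways covering none or all of the universe are excluded with a logged
warning (degenerate background).

The choice of variance matters at the dataset sizes this package models:
for a 6038-gene dataset in a 7000-gene universe the finite-population
factor is (7000−6038)/6999 ≈ 0.137, so the binomial variance overstates
the null spread almost threefold in standard deviations and the test
becomes severely conservative. The validation studies therefore run with
`variance="hypergeometric"`, which is the correct null for the synthetic
generator (datasets are drawn without replacement from the universe);
the binomial default is kept for the public API as the conventional
genome-background form for small datasets. Calibration measured by
`studies.null_screen_calibration` (49 pathways × datasets of 579/1371/6038
over a 7000-gene universe, 2000 Monte-Carlo replicates) sits within
0.10 ± 0.02 at 90% confidence.

The exact hypergeometric upper tail P(X ≥ k) (scipy's `hypergeom.sf`)
serves as an independent oracle. `decision_agreement` compares z-based
and exact-tail decisions over a deterministic grid of small counts
(N ∈ 20…200 step 10, K step 5, n ∈ 5…30 step 5, all feasible k,
restricted to n·p ≥ 5 and n < N); disagreements cluster at the decision
boundary and agreement exceeds 95%.

Crosstalk of a focal pathway with another pathway inside a dataset
reports the shared genes dataset ∩ focal ∩ other, their representativity
100·|shared|/|dataset ∩ other| (missing when the denominator is empty),
and a significance test of the focal-regulatable part of the dataset
against the other pathway's targets over the universe — the most literal
reading of "common regulatable genes". Alternative denominators would be
reasonable; this one is fixed and documented rather than configurable
per-cell.

## Mixture fold changes

The co-culture mixture expectation is prop·mean_A + (1−prop)·mean_B with
prop defaulting to the 0.9 seeding fraction. Signed folds are
observed/reference when observed ≥ reference and −reference/observed
otherwise, so |fold| ≥ 1 always, swapping arguments flips the sign, and
a fold of ±1 means "at expectation". Integer rounding (half away from
zero) is applied only in reports; raw folds stay in the data model.
"Not detected" propagates as not-evaluable — never as zero, which would
fabricate infinite repression.

Three genes of the packaged reference table print integers that cannot be
derived from their printed means under any standard rounding (computed
−13 vs printed −14; −8 vs −10; −4 vs −3); they were presumably computed
from unrounded raw means. The fixtures keep the printed values, the
acceptance test asserts the computed ones and the mismatch explicitly.

Treated-arm folds use the delta method for the spread of a ratio
(sd ≈ |fold|·sqrt((sd_t/m_t)² + (sd_c/m_c)²)) and a pooled two-sample
Student t-test at p < 0.05, the convention for triplicate qPCR. Direction
calls (up/down/unchanged) default to |fold| ≥ 2 with significance; the
threshold is configurable and recorded in the run manifest.

## RTCA analytics

Delta cell index is computed per well against the nearest sampled time at
or before the requested treatment time (impedance readers sample
discretely, typically every 15 min); δ(t_treat) is exactly zero by
construction and δ is invariant to uniform rescaling of the trace. A zero
cell index at treatment time is a per-well error.

The proliferation slope is an ordinary least-squares line on the
well-averaged CI versus time. The automatic window search returns the
longest window of ≥ 12 h reaching r² ≥ 0.98 (ties broken by better fit);
on a full lag/linear/plateau trace a long noise-free plateau can tie or
beat the linear phase by this criterion, so growth-curve analyses should
pass the proliferative window explicitly (the pipelines accept one). A
perfectly flat window is given r² = 1 by convention (zero residual).

Doubling time is reported only with its convention made explicit, because
a linear-phase slope alone does not determine it: the linear convention
ref_ci/slope depends on the reference CI at which the doubling is read
(default: mean CI over the fit window), and the exponential convention
ln2/slope requires a log-scale fit. Published slope→doubling-time pairs
are internally inconsistent under any single convention, so no doubling
time is asserted against external values anywhere in the package.

Dose-response summaries aggregate wells as mean ± SEM (n = wells) and
test each dose against the vehicle group with a two-sample t-test at
p < 0.05; single-well groups and a missing vehicle group are errors.
AdipoRed/Hoechst ratios are computed per well before aggregation, so a
common multiplicative well effect (exposure, cell number) cancels
exactly.

## Synthetic data: what it emulates, and what it does not

The gene-set generator draws 49 pathways of 133 genes each from a
7000-gene universe. The size 133 is chosen so the expected pathway-union
coverage of a random dataset, 1 − (1 − 133/7000)^49 ≈ 0.61, matches the
reported ~61% coverage of phenotype datasets by extracellular signaling
pathways; dataset coverage is then planted exactly by stratified sampling
(⌈0.61·n⌋ genes from the union, the rest outside). Because the coverage
target matches the union's share of the universe, this stratification
leaves the per-pathway null overlap distribution essentially
hypergeometric, so the same study serves coverage and calibration.
Enrichment is planted per (pathway, dataset) pair by fixing the overlap
count at round(multiplier·n·K/N) — exact, hence directly scorable —
before filling the rest of the dataset from outside the planted
pathways. Infeasible plantings (overlap above min(n, K)) error before
any sampling; note 3× planting is arithmetically impossible once
n > N/3, which is why the planted-recovery study uses three datasets of
size 579 (the smaller phenotype-dataset scale) rather than the largest
one.

The qPCR generator takes true monoculture means from the packaged
reference panel, sets the co-culture truth to the mixture expectation
divided by a per-gene emergence factor (1 = passive mixture), and
perturbs replicates multiplicatively with mean-preserving lognormal noise
(default CV 10%, since qPCR ratio SDs scale with the mean; a normal
alternative is available). Treated arms multiply (or divide, for negative
signed folds) the co-culture truth by the planted fold.

The RTCA generator produces lag → linear → plateau traces with i.i.d.
Gaussian well noise and, when treatment/evaluation times are set, a
planted per-dose linear drift that offsets delta CI at the evaluation
time by exactly the planted amount before noise.

What passing the recovery suites does **not** show about real data: the
generators have no probe-level artifacts, no correlated noise between
wells or replicates, no batch effects, no alias ambiguity in symbols, and
pathway sets are random rather than biologically structured (real
pathways overlap non-uniformly). The studies validate the estimators and
decision rules, not the biology.

## Validation studies and problem sizes

`cocultrx.studies` fixes the study designs: null calibration with 2000
screen replicates (49 × 3 cells each); planted-pathway recovery over 100
independent seeds; emergence recovery over 200 seeds with factors
{1, 6, 8} on the goblet-marker-like genes (SOX9, TFF3, MUC2) at CV 5%,
n = 3; slope error over 100 noisy traces at σ = 0.01. These sizes give
Monte-Carlo standard errors comfortably below the tolerances being
checked while keeping the full suite fast.

One honest caveat, stated here because the numbers imply it: recovering a
planted factor of 8 as the exact integer −8 requires the estimated fold
to land within ±6.25% (the ±0.5 rounding window at 8), while triplicate
means at CV 5% give the fold estimator a relative sd of ≈4%, so the
long-run exact-recovery probability for that gene is ≈0.88 — close to,
and for some seeds below, a 0.90 target. Exact-integer recovery of large
folds from triplicates at 5% noise is intrinsically borderline; the raw
(unrounded) fold, which the data model always keeps, recovers the planted
factor within 10% essentially always.

## Reproducibility

All generators are driven by a single integer seed through numpy's
`default_rng`; per-replicate seeds in the studies derive from the master
seed via `SeedSequence`. Identical seeds give identical tables and
byte-identical written files. Pipeline manifests record input hashes,
parameters and the package version, and contain no timestamps, so re-runs
are byte-identical.
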