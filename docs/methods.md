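# Methods

## Setting and data model

The package evaluates binary readers of chest radiographs against a
reference standard. A *case* is one radiograph with a contemporaneous CT;
the CT report supplies the ground-truth label for each finding, so truth is
never missing. Each reader (the reporting radiologist, an algorithm)
contributes a call per case and finding: positive, negative, or
*unavailable* when the reader produced no output. Data are long-format CSV
(`case_id,finding,truth,<reader>...`, cells 0/1/NA), one row per
(case, finding); the cohort is rectangular (every finding is labelled for
every case). The packaged reference tables are the 2×2 counts of a
published single-centre blunt-trauma cohort: 1404 radiologist-read cases,
1400 algorithm-read cases (four radiographs were technically inadequate for
the algorithm), seven findings.

Two policies govern unavailable calls and are recorded in every report:
`drop` (the study's own choice — denominators shrink to the processed
cases) and `count_negative` (a deployed triage system's failure is
operationally a miss). Default: `drop`.

## Accuracy statistics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and prevalence (TP+FN)/n
carry exact Clopper–Pearson intervals: the equal-tailed inversion of the
binomial tails, computed as beta quantiles (lower = 0 at k = 0, upper = 1
at k = n). These intervals are conservative — coverage is at least the
nominal level for every true proportion — which the suite checks by
simulation at n ∈ {20, 172}.

Cohen's κ = (p_o − p_e)/(1 − p_e) with p_o = (TP+TN)/n and
p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/n². When both margins are constant
(p_e = 1) κ is undefined; the package raises an explicit error rather than
substituting 0 or 1, because silent substitution corrupts bootstrap
distributions. Inside the bootstrap, degenerate replicates are dropped and
counted (`n_degenerate`); more than 10% degenerate replicates aborts with
an error.

κ intervals: default `analytic`, the large-sample Fleiss–Cohen–Everitt
variance (fast, deterministic; cross-checked against statsmodels in the
tests); `bootstrap` draws multinomial resamples of the n cases and takes
percentiles. On the packaged tables the analytic intervals match the
published ones closely, which suggests the original analysis also used a
large-sample interval, but the package makes no claim about matching an
unstated method.

Display convention: percentages on the 0–100 scale at 1 decimal place, κ at
2; all computation at full precision.

## Paired comparison of two readers

The difference Δκ = κ_B − κ_A is assessed by a paired case bootstrap
(default 10 000 iterations): cases are the resampling unit, drawn with
replacement, and both readers' calls travel with their case, so the
bootstrap distribution of Δκ respects the readers' within-case
correlation. Reported: bootstrap median, 2.5th/97.5th percentiles, and a
two-sided p-value by interval inversion,

    p = 2 · min(frac(Δκ ≤ 0), frac(Δκ ≥ 0)), clamped to [1/n_boot, 1],

so p ≤ α exactly when the (1−α) percentile interval excludes 0. The
clamping acknowledges that a bootstrap with n_boot draws cannot certify a
p-value below 1/n_boot.

Pairing policy: `intersection` (default) computes the difference only on
cases where both readers produced output, since pairing is undefined
elsewhere; `per_reader` resamples all cases and lets each reader's κ use
its own available denominator, matching marginal-table denominators (1404
vs 1400 in the packaged study). Resampling is unstratified — "paired" means
pairing of readers within case, not stratified sampling.

Multi-finding runs derive one seed per finding from the base seed and a
CRC-32 of the finding name, so per-finding results are reproducible and
independent of finding order. Exchanging the two readers negates the
median and bounds and preserves the p-value exactly (same replicate
draws), which the suite asserts.

Monte-Carlo calibration (also run as a test, at the study's size and
operating points — n = 1400, prevalence 0.123, se 0.4 / sp 0.99,
dependence 0.3/0.1, 500 null cohorts × 1000 bootstrap iterations): the
empirical type-I error at 0.05 sits within 3 binomial SEs of 5%, and with
a 0.22 sensitivity gap the median Δκ is positive in > 95% of 200 cohorts.

## Hybrid (OR-rule) reader

The combined call is positive iff at least one contributing reader call is
positive; with one reader unavailable the available reader decides; with
both unavailable the combined call is unavailable. By construction hybrid
sensitivity ≥ each component's and hybrid specificity ≤ each component's
(property-tested). Under conditional independence the hybrid sensitivity
has the closed form se_A + se_B − se_A·se_B and specificity sp_A·sp_B,
which the generator reproduces at n = 10⁵.

## Synthetic cohorts

`simulate_dataset` draws truth ~ Bernoulli(prevalence) and then both
readers' calls from a common-shock mixture conditional on truth: with
probability `dep` (separately `dep_pos` on truth-positives, `dep_neg` on
negatives) both readers threshold one shared uniform draw — the comonotone
coupling, i.e. the Fréchet upper bound on agreement compatible with the two
marginal operating points — and otherwise two independent uniforms. This
construction preserves each reader's se/sp exactly for every dep ∈ [0, 1],
reaches conditional independence at dep = 0, and has closed-form joint
cells

    P[both positive | truth+] = dep·min(se_A, se_B) + (1−dep)·se_A·se_B,

so the generator-implied κ of each reader is available analytically for
recovery tests (κ against truth depends only on prevalence and that
reader's se/sp). A Gaussian copula would have been the obvious
alternative; the mixture was chosen precisely for these closed forms.
Because the mixture of two valid joints is always valid, every in-range
parameter set is feasible; parameter validation therefore reduces to range
checks.

Defaults emulate the packaged study's pneumothorax row: n = 1404,
prevalence 0.123, reader A 0.331/0.994, reader B 0.392/0.998, algorithm
failure rate 4/1404. The dependence defaults (0.3 on positives — readers
jointly miss subtle findings more often than independence predicts — and
0.1 on negatives) are working values for tests: the source study publishes
no joint reader distribution, so they are not estimates of anything.

Confidence scores (`simulate_scores`) use a binormal model: latent
N(−d/2, 1) for truth-negatives and N(+d/2, 1) for positives with
d = `score_separation`, mapped to (0, 1) by the logistic function so 0.5
is the symmetric threshold. The model is used solely because its AUC has
the closed form Φ(d/√2) for oracle tests; no claim is made that real
algorithm scores are binormal. What the generator does *not* emulate:
inter-finding correlation within a case (findings are simulated
independently, whereas real trauma patients frequently have co-occurring
injuries), reader drift over a decade of reporting, and any image-level
structure. Passing recovery tests therefore demonstrate correctness of the
statistics under the stated sampling model, not robustness to those
real-data features.

`recovery_harness` repeatedly simulates, reruns the accuracy and
comparison stages, and reports bias/RMSE of se, sp and κ against the
generator-implied values plus rejection rates of the paired bootstrap. At
the packaged study's operating points and n = 1400, mean recovered κ is
within 0.03 of the closed-form value over 200 replicates (an acceptance
test).

## Reporting

`run_pipeline` accepts exactly one source — a per-case CSV, the packaged
confusion tables, or a simulation config — and emits prevalence, accuracy,
comparison and hybrid tables as CSV plus a markdown report. With the
packaged tables only marginal 2×2 counts exist, so the paired comparison
and hybrid stages (which need per-case pairing) are omitted. All seeds,
policies and the package version are recorded in the bundle metadata; run
timestamps go to the stderr log only, so identical inputs and seed yield
byte-identical report files. A binary reader contributes a single ROC
operating point; AUC is computed only for score-bearing readers
(Mann–Whitney, ties half, via scikit-learn), with a brute-force pairwise
oracle in the tests.

## Known limitations and non-reproducing cells

Five κ cells of the published agreement table do not reproduce from the
published 2×2 counts under the standard κ formula (verified independently
with statsmodels and scikit-learn): algorithm pneumothorax prints 0.53 vs
computed 0.5250, algorithm pneumomediastinum 0.19 vs 0.1969, algorithm
humerus 0.38 vs 0.3984, and scapula 0.38/0.23 vs 0.3872/0.2394. The
original values were plausibly bootstrap medians or used a different
denominator; the package reports what the printed counts imply. The
published paired Δκ medians and p-values require the per-case pairing,
which was not published, and are therefore out of reach by design; the
paired bootstrap is instead validated by Monte-Carlo calibration as above.

Problem sizes used in the test suite (500 null cohorts at n_boot = 1000
for type-I error, 200 for power and recovery, 2000 replicates for interval
coverage) were chosen to put Monte-Carlo error well inside the asserted
tolerances while keeping the default run in tens of seconds.
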