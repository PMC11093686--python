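# Methods

## Model and assumptions

Two-sample Mendelian randomization treats genetic variants as instruments
for a modifiable exposure. For instrument *j*, the observed
exposure association β̂<sub>Xj</sub> ~ N(β<sub>Xj</sub>, se<sub>Xj</sub>²)
comes from one GWAS and the outcome association
β̂<sub>Yj</sub> ~ N(β<sub>Yj</sub>, se<sub>Yj</sub>²) from another,
non-overlapping GWAS. A valid instrument is (1) robustly associated with the
exposure, (2) affects the outcome only through the exposure, and (3) is
independent of confounders; then β<sub>Yj</sub> = θ·β<sub>Xj</sub> and the
Wald ratio β̂<sub>Yj</sub>/β̂<sub>Xj</sub> estimates the causal effect θ.
With a binary outcome θ is a log-odds ratio per unit (here: per SD of plasma
homocysteine). All estimators here work on summary statistics only and
assume instruments are mutually independent (the packaged panel was
LD-pruned at r² < 0.05).

## Harmonization and instrument qualification

Exposure and outcome effects are aligned to the exposure's effect allele.
With only the effect allele recorded (as in the packaged table, where all
four studies share one coded allele), a differing non-complementary allele
is interpreted as the other allele and the outcome beta's sign is flipped; a
complementary allele is ambiguous — strand flip or allele swap — and the
variant is excluded by default (`assume_same_strand=True` treats it as an
allele swap instead). This is the conservative convention for palindromic
ambiguity. Variants absent from the outcome study are dropped and logged;
proxy substitution is deliberately not automated (a caller-supplied proxy
table can be applied upstream).

Selection filters candidates at genome-wide significance (p < 5×10⁻⁸),
removes variants with pleiotropy annotations, and greedily LD-prunes
against a caller-supplied pairwise r² table: within each correlated group
(r² ≥ 0.05) the variant with the smallest exposure p-value survives, ties
broken toward the lexicographically smaller rsID for determinism. The
package never queries reference panels; LD and annotations are plain-table
inputs, which keeps every analysis fully reproducible offline.

Instrument strength is summarized by F = (β<sub>X</sub>/se<sub>X</sub>)²,
the squared z-score; F < 10 is flagged as the conventional weak-instrument
zone. The packaged panel spans F ≈ 32–511.

## Estimators

**IVW.** First-order weights w<sub>j</sub> = β<sub>Xj</sub>²/se<sub>Yj</sub>²
(exposure-side noise ignored; with F ≥ 30 its contribution is below 3% of
the ratio variance, and a second-order delta-method SE is available on the
Wald ratio for checking). Fixed-effect SE is (Σw<sub>j</sub>)^(−1/2); the
multiplicative random-effects model inflates it by max(1, √(Q/(J−1))),
never deflating under homogeneity. The default `auto` policy uses
multiplicative random effects at J ≥ 4 and fixed otherwise, matching the
convention of the widely used reference implementations; on the packaged
data the multiplicative random-effects intervals are the ones that
correspond to the published per-study CIs, and the acceptance tests record
that correspondence explicitly.

**MR-Egger.** Weighted least squares of β<sub>Y</sub> on β<sub>X</sub> with
a free intercept, weights 1/se<sub>Y</sub>², after orienting every
(β<sub>X</sub>, β<sub>Y</sub>) pair so that β<sub>X</sub> ≥ 0 (the fit is
not invariant to per-variant allele coding; orientation to the
exposure-increasing allele is the standard choice). Coefficient covariance
is scaled by max(1, σ̂²) where σ̂² is the weighted residual mean square —
overdispersion widens the intervals, underdispersion never narrows them.
P-values and CIs use the normal reference by default; a t reference with
J−2 df is available. The normal default was chosen because, under the
no-pleiotropy generator below, the intercept test's type-I error at α = 0.05
sits inside the binomial band around the nominal level (the max(1,·)
truncation already makes it slightly conservative), whereas the t reference
is markedly conservative at J = 14.

**Weighted median.** Wald ratios are sorted, tied ratios merged with their
weights summed (this makes the estimate exactly invariant to input order,
including tie configurations), and the standardized cumulative weight
function s<sub>j</sub> = (cum<sub>j</sub> − w<sub>j</sub>/2)/Σw is linearly
interpolated at 0.5. The SE is the standard deviation of the weighted
median over a parametric bootstrap (default 10,000 resamples of β̂<sub>X</sub>
and β̂<sub>Y</sub> from their sampling distributions, default seed 12345);
the point estimate involves no resampling.

**Cochran's Q.** Q = Σw<sub>j</sub>(θ̂<sub>j</sub> − θ̂)² about the
fixed-effect IVW estimate, χ²<sub>J−1</sub> p-value, and
I² = max(0, (Q−df)/Q).

## Diagnostics

**MR-PRESSO.** The observed statistic is Σ<sub>j</sub>
w<sub>j</sub>(β̂<sub>Yj</sub> − θ̂<sub>−j</sub>β̂<sub>Xj</sub>)² with
w<sub>j</sub> = 1/se<sub>Yj</sub>² and θ̂<sub>−j</sub> the leave-one-out
fixed-effect IVW fit. The null is simulated (default 5,000 draws, default
seed 12345) by redrawing β<sub>Y</sub>* about the leave-one-out fitted
values at the reported SEs, and by default also β<sub>X</sub>* about the
observed exposure betas (`resample_exposure=False` gives the
outcome-only variant). Empirical p-values use (r+1)/(n+1), so the smallest
attainable p is 1/(n_sim+1). Per-variant outlier tests are
Bonferroni-flagged at α/J. Because a gross outlier sits inside the
leave-one-out fits of *other* variants, it inflates their residuals and can
drag a clean neighbour over the threshold; flagged candidates are therefore
re-tested in a confirmatory stage against the fit from non-candidate
variants only, and candidates that stop being extreme are released. In
calibration runs with one variant displaced by 10 outcome-SEs among 20
instruments, this two-stage rule flags exactly the planted variant in ≈98%
of seeds while leaving the null calibration of the global test intact. The
distortion test (shift of the IVW estimate when outliers are removed,
against a bootstrap null built from the clean variants) is computed only
when outliers exist.

**Steiger.** Exposure variance explained is summed per instrument as
F<sub>j</sub>/(F<sub>j</sub> + N<sub>exp</sub> − 2); outcome variance
analogously from the outcome z-scores with the effective case-control size
N<sub>eff</sub> = 4/(1/cases + 1/controls). Direction exposure→outcome is
supported when the instruments explain more variance in the exposure; the
p-value compares the two multiple correlations by Fisher z. Note the
monotonicity: r²<sub>outcome</sub> *decreases* in N<sub>eff</sub>, so a
correct direction at some cohort size remains correct for every larger
cohort (shrinking a cohort at fixed betas and SEs can flip it). Steiger
output is reported as a diagnostic, never used to filter instruments. The
published per-study Steiger p-values are not reproduced numerically — the
exact sample sizes and r² formula behind them are not stated — so only the
direction calls are checked.

**Leave-one-out.** J re-fits of IVW (same model policy as the main fit),
each omitting one variant, plus the full-set estimate.

## Meta-analysis

Per-study IVW log-odds estimates are pooled by fixed-effect inverse
variance; this choice is verifiable end-to-end: back-computing each study's
SE from its published CI and pooling reproduces the published combined OR
1.032 with CI (0.885, 1.203) to three decimals, which a random-effects
model would not. DerSimonian–Laird random effects is available as an
option. The partial sample overlap between the Tyrmi et al. cohort (which
contains FinnGen R6) and FinnGen R7 is reported as a warning in the run log
and deliberately not corrected for; no overlap-aware covariance model is
included.

## Synthetic-data generator

`simulate_instrument_set` draws true exposure effects uniformly on
±[0.044, 0.16] with random signs, fixed se<sub>X</sub> = 0.008 and
se<sub>Y</sub> = 0.035, J = 14 by default — calibrated so simulated F
statistics span roughly 30–400, the range of the packaged panel, with
outcome noise matching a mid-sized case-control GWAS. True outcome effects
are θ·b<sub>X</sub> + sign(b<sub>X</sub>)·α: direct effects α attach to the
exposure-increasing allele, so a directional mean biases causal estimates
coherently regardless of per-variant allele coding (with signed coding a
fixed-sign α would cancel under Egger's orientation and "directional"
pleiotropy would be indistinguishable from balanced). Modes: `none`,
`balanced` (zero-mean α), `directional` (the Egger intercept estimates the
directional mean), and `inside_violated` (α proportional to instrument
strength, breaking the InSIDE assumption). Gross outliers displace observed
outcome betas by a stated number of SEs. `replicate_study_trio` shares one
exposure draw across several outcome cohorts with per-study SE scales and
availability masks, mimicking the 14-vs-11 instrument asymmetry of the real
design.

What the generator does **not** emulate: LD between instruments, winner's
curse in instrument discovery, sample overlap between exposure and outcome
GWAS, allele-frequency-dependent SEs, and non-collapsibility of odds
ratios. Passing calibration tests therefore demonstrate correctness of the
estimators under the stated sampling model, not robustness to those
real-data complications.

## Numerical choices and degenerate inputs

95% intervals use z = 1.959964 throughout (t optional for Egger). P-values
are clamped into (0, 1]. A single-instrument IVW degenerates to the Wald
ratio; Egger requires J ≥ 3 and rejects designs with all |β<sub>X</sub>|
equal; PRESSO requires J ≥ 4 and n_sim ≥ 1,000. Zero exposure betas raise
rather than propagate infinities. Selection tie-breaks and the
weighted-median tie merge are described above; all simulation entry points
take explicit integer seeds and are bit-reproducible given (data, options,
seed).

Test problem sizes were chosen to keep Monte-Carlo error well below the
effects being tested while staying lightweight: 500 replicates for
recovery/coverage/type-I checks (binomial 95% bands), 200 replicates for
empirical-p calibration, 100 seeds × 5,000 simulations for planted-outlier
detection.

## Known limitations

* First-order IVW weights ignore exposure-side noise; at F < 30 the
  resulting weak-instrument attenuation becomes visible (≈1/(1+1/F̄)).
* The bootstrap SE for the weighted median assumes normal sampling of the
  betas; it is not a CI-transformation-invariant interval.
* MR-PRESSO's global test conditions on observed leave-one-out fits; it is
  approximate for very small J.
* Harmonization with only effect alleles recorded cannot rescue ambiguous
  palindromic variants; callers with strand information should resolve them
  upstream.
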