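# Methods

## The analysis model

Multiplex bead-array serology reports, per serum sample j and antigen-isotype
channel i, a median fluorescence intensity (MFI) proportional to the amount of
bound antibody. All analysis runs on the log2 scale after sample-wise median
centering: subtracting each sample's median log2 MFI across the marker panel
removes multiplicative sample effects (dilution, secondary-antibody labelling,
plate position) and any batch effect shared by a sample's measurements, while
leaving marker-specific signal intact as long as only a minority of markers
respond in any one sample. Median centering is idempotent and stateless — no
training-set statistic leaks between cohorts.

A low-reactivity pre-filter runs before centering, on absolute log2 MFI:
a marker is kept only if its nearest-rank 75% quantile across all samples
exceeds log2 MFI 10. The pipeline exposes it as an optional stage
(`--prefilter/--no-prefilter`) because it belongs to candidate discovery; a
targeted validation panel may already be curated.

### Quantile convention

All empirical quantiles are **nearest-rank**: the smallest observed value
whose cumulative fraction reaches the level. This makes every cutoff an
attained data value, which the escalation scan over observed values requires,
and makes the "at most 2% of controls positive" guarantee exact: with
strictly-greater-than positivity, at most `n − ceil(0.98 n)` of n calibration
controls can exceed their own 98% quantile.

## Control-anchored binarization

Per marker, the base cutoff is the nearest-rank 98% quantile of the healthy
control (HC) intensities; a sample is positive iff its value is strictly
greater. The cutoff then optionally *escalates*: scanning the distinct
observed values (HC and patients pooled) above the base cutoff, the largest
candidate is accepted that strictly reduces the HC positive count while
leaving the patient positive count unchanged — strictly better specificity at
identical sensitivity. Restricting candidates to observed values makes the
rule deterministic with no step-size parameter. Escalation can never lower
patient sensitivity or HC specificity (the acceptance condition forbids it),
and the test suite checks the implementation against an exhaustive scan
oracle.

Calibration uses HC only — never sicca controls (NSS) or disease controls,
which serve purely as evaluation groups. At least 10 controls are required
for the quantile to mean anything; fewer is a hard error advising pooled
controls.

## Screening statistics

* **Mann–Whitney U** (two-sided): exact enumeration when the pooled sample is
  ≤ 12 without ties, otherwise normal approximation with tie and continuity
  correction (scipy).
* **Fold change**: 2^(median(case) − median(control)) — a linear-scale ratio
  of group medians computed on the log2 scale; the screening criterion is
  two-sided (max(FC, 1/FC) ≥ 1.5).
* **SAM-type d**: (mean difference) / (pooled SE + s0). The fudge factor s0
  defaults to the median of per-marker pooled standard errors across the
  screened panel, the standard choice that damps near-zero-variance markers.
  Significance is by group-label permutation: full enumeration when there are
  at most 30,000 labelings, otherwise Monte Carlo with the observed labelling
  included in the reference set (so p ≥ 1/(B+1)).
* **Quantile span**: the "absolute span" criterion is implemented as the max
  over the 25/50/75% quantiles of |case − control| quantile differences in
  log2 units; the underlying phrase is under-specified in the source
  literature, so the criterion is kept config-switchable.
* **Fisher's exact test** (two-sided, hypergeometric tail summation) on the
  binarized 2×2 table; an empty margin is uninformative and returns p = 1
  with a warning.

Discovery and validation screens report raw p-values at α = 0.05; false
discovery rate control (Benjamini–Hochberg) is applied only in the clinical
association screen, where the marker dimension within each outcome forms the
adjustment family — each clinical question is its own screen.

## OR-rule panels and greedy forward selection

A panel predicts disease if **any** member marker's binarized call is
positive. Panels are built from IgG channels only (IgA reactivity tracks
disease activity and drifts over time). Selection is greedy: seed with the
most prevalent marker in the target subgroup (Ro/SSA-negative patients), then
repeatedly add the marker with the largest *incremental union coverage* among
those keeping panel HC specificity at or above the floor (default 0.95).
"High sensitivity with low co-prevalence to the previous markers" and
"maximal marginal union coverage" are the same objective under fixed marker
prevalence, and marginal coverage makes each greedy step a single
well-defined criterion; the co-prevalence matrix is still emitted for
inspection. Union coverage is submodular, so the greedy panel is within
(1 − 1/e) of the best same-size panel, and is exactly optimal when responder
sets are disjoint — both properties are asserted against a brute-force
subset-enumeration oracle. Ties break by higher single-marker HC specificity,
then lexicographic marker id, for determinism.

Panel metrics (sensitivity in the target subgroup, specificity vs HC and vs
NSS, with exact Clopper–Pearson 95% CIs) are reported on the selection cohort
by default, as screening studies do; **in-sample metrics are optimistically
biased**, and the evaluation function accepts any held-out call matrix for
honest estimates (the calibration tests use a held-out split).

## Clinical associations

Each binary clinical characteristic is regressed on each marker's centered
log2 level: maximum-likelihood logistic fit (Newton/IRLS, log-likelihood
tolerance 1e-8, ≤ 100 iterations), Wald p for the slope. The predictor is the
continuous centered level, not the binarized call (reported coefficient
magnitudes around 0.45–1 log-odds per log2 unit are consistent with a
continuous predictor); a binarized-predictor mode would be a one-line switch.
Analyses are complete-case per outcome: patients with a missing flag are
dropped, and outcomes with fewer than 10 complete cases or a single observed
class are skipped with a warning. Complete separation is flagged
non-estimable rather than returning a divergent coefficient. An association
passes the reporting filter when p ≤ 0.05 **and** |β| ≥ 0.45 — the magnitude
filter is two-sided because protective (negative) associations are as
meaningful as risk associations. Models are unadjusted; a covariate hook
exists but defaults off.

## Synthetic cohorts

The generator draws, per sample j and channel i,

    log2 MFI_ij = μ_i + δ_ij·e_i + c_j + b_batch(j) + ε_ij

with responder indicator δ_ij ~ Bernoulli(π_{i,group(j)}), noise
ε ~ N(0, σ_i), per-sample offset c_j ~ N(0, 0.3), and one batch per simulated
recruitment center (patients split across three centers ≈ 62/21/17%, controls
from one), b ~ N(0, 0.25). The emitted matrix is 2^(log2 value). Ro/SSA
status is the responder indicator of a designated channel (`RO60|IgG`), so
the seronegative subgroup arises from the same generative process the
analysis sees. Markers can be grouped into *disjoint responder sets* (each
sample responds to at most one group member) — the complementary structure an
OR-rule panel exploits. Clinical outcomes follow a logistic ledger,
Bernoulli(expit(β0 + β·x)) on the centered log2 level, with configurable
missingness.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| σ_i (noise, log2 units) | 0.5 | typical bead-array replicate scatter; ±1 log2 ≈ 2-fold at 2σ |
| e_i (responder shift) | 3.0 (= 6σ) | seropositive sera sit roughly an order of magnitude above background |
| background μ_i | U(10.5, 13) | above the log2-MFI-10 pre-filter floor; 10% of channels drawn low (U(7, 9.5)) to exercise the filter |
| patient prevalences | up to 0.19 | the observed ceiling for novel autoantibody seroprevalence |
| HC prevalence | 0.01 | consistent with the ≤ 2% control-positivity calibration budget |
| sample offset sd | 0.3 | moderate sample-to-sample scaling on the log2 scale |
| batch offset sd | 0.25 | center-level shifts smaller than sample-level ones |
| synthetic HC cohort (panel scenarios) | 140 | see below |

**Why 140 controls in panel scenarios.** The nearest-rank 98% cutoff leaves
exactly `n − ceil(0.98 n)` calibration controls positive per marker: 2 of
118, i.e. 1.69% — within the 2% budget. But a three-marker OR panel can then
cost up to 6/118 = 5.08% HC positivity, arithmetically past a 95% selection
floor even when every marker individually behaves. At n = 140 the same worst
case is 6/140 = 4.3%, so the per-marker 2% budget and the 95% panel floor are
jointly attainable. Calibration-guarantee checks that specifically emulate
the 118-control validation cohort keep n = 118.

**What passing tests do and do not show.** The generator is Gaussian on the
log2 scale (log-normal MFI) with location-shift responders. Real bead-array
data have heavier right tails, occasional bead failures, isotype cross-talk,
and responder populations with broadened variance — none of which are
emulated (heavier-tailed noise is a config hook, not the default). Recovery
results therefore demonstrate that the *procedures* are correct and
calibrated under their own assumptions, not that any particular published
marker list or panel would be reproduced; that would require the original
sera. One consequence worth knowing: with quantile-anchored cutoffs, a truly
null marker still shows ≈ 2% positivity in every group, so "null" markers in
recovery scenarios carry genuine noise coverage — the greedy selector must
beat that floor, and at planted prevalences of 8–12% in 200 target samples it
does so in ≥ 95% of seeds, with occasional honest failures when a planted
binomial draw comes in low.

## ELISA titers

Optical densities are mapped to arbitrary units through the five-point
standard ladder (2.5–40 U/ml) by piecewise-linear interpolation on the
(log2 concentration, response) plane — five points under-constrain a
four-parameter logistic, and log-linear interpolation is exact at the nodes
and monotone in between. Out-of-range ODs are censored (`<2.5` / `>40`) with
NaN titers and are meant to be excluded from cutoff calibration unless the
user explicitly maps them to the range bounds. Decreasing (competitive-format)
ladders are supported by flipping the response axis.

## Numerical and degenerate-input choices

* Positivity is strictly greater-than the cutoff, so the cutoff value itself
  is negative — required for the ≤ 2% control-positivity guarantee under the
  nearest-rank convention.
* Median centering of a row with fewer than 2 markers is a hard error;
  non-positive linear MFI is rejected at ingest naming the cell.
* PCA QC accepts rank-1 (collinear) data — component 1 then explains 100% of
  the variance — and rejects only matrices with no variation at all.
* Permutation p-values include the observed labelling in the reference set.
* All CSV writers use fixed float formatting; the pipeline is byte-identical
  under a fixed seed, and each stage's manifest (config, seed, SHA-256 input
  digests) supports exact replay.

## Known limitations

* In-sample panel metrics are optimistic; use the held-out evaluation path
  for unbiased operating points.
* The escalation rule conditions on the observed case set; with small case
  groups the escalated cutoff is noisy (the base cutoff is always recorded
  alongside it, so either can be reported).
* The closed-form panel operating point (`panel_operating_point`) assumes a
  common background μ across markers and approximates the median-centering
  residual as Gaussian; it is meant for calibration checks on synthetic
  truths, not for real data.
* No native instrument-file parsing (exports vary by vendor software); users
  pre-export CSV. No plate-effect normalization beyond sample-median
  centering, and no cross-assay bridging of ELISA and bead-array scales.
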