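# Methods

This note records the statistical procedures implemented in `pepscreen`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions used throughout.

## Antigen tiling

An antigen of length *L* is decomposed into peptides of length *l*
(default 20) whose starts advance by a fixed offset *o* (default 10), so
tile *i* starts at `1 + (i−1)·o` and the number of tiles is
`ceil((L−l)/o) + 1`. The final tile is truncated to end exactly at *L*
rather than back-shifted; this reproduces printed panel designs in which
the terminal peptide is shorter (the bundled MGMT panel ends in a 17-mer
at residue 206). Coordinates are 1-based inclusive. The inverse operation
(overlap assembly) requires each consecutive pair of tiles to overlap by at
least one residue with full agreement in the overlap, and is used to
validate panel coordinates: the bundled MGMT panel assembles into a
consistent 206-residue antigen once end coordinates are derived from the
peptide sequence lengths (two printed design spans are internally off by
one residue, treated as typographical).

## Spot signal and quality control

The pipeline starts from per-spot median chemiluminescence intensities as
produced by spot-quantification software; image processing is out of
scope. The background for a spot is the arithmetic mean intensity of the
blank spots in the same subarray block (blanks are printed within each
block, so the background is local by default; eight blanks per block is
the designed count and deviations are logged). SNR = (signal −
background)/background, which makes it invariant under global intensity
rescaling. Negative SNR values are retained unclipped so thresholding sees
the full distribution.

Arrays pass QC when every positive-control spot reaches SNR ≥ 2.0 and the
negative control stays at SNR ≤ 1.0 (both configurable; the assay design
specifies the controls but no acceptance rule, so these are conservative
conventions). Failing or control-less arrays are excluded from aggregation
with logged reasons. Each serum's profile is the per-peptide arithmetic
mean over its QC-passing replicate arrays (two per serum in the emulated
design; the combination rule is not dictated by the assay, and the mean is
chosen for symmetry). A serum with zero passing replicates is marked
missing and skipped downstream.

## Seropositivity cut-offs

The cut-off for each peptide maximizes the case-minus-control difference
in positive response rate. The candidate set is the observed pooled SNR
values, which makes the search exact and checkable by exhaustive
enumeration; a fixed-step grid (default step 0.1) is available for
sensitivity analysis since printed panel cut-offs tend to one-decimal
values. The objective is compared in integer arithmetic
(`#case≥c · n_ctrl − #ctrl≥c · n_case`) so that mathematically tied
candidates are true ties, broken toward the smallest candidate (maximal
sensitivity at equal discrimination). A serum is positive when SNR ≥
cut-off; the boundary is inclusive.

**Candidate floor.** For a peptide with no real group difference the
unconstrained objective is maximized by sampling noise and can land inside
the seronegative bulk, which would call large fractions of both groups
positive. The cohort-level search therefore floors the candidates at a
conventional minimal positive SNR of 2.0 (configurable, and disabled by
default in the single-peptide `optimize_cutoff` primitive). Published
panel cut-offs of this assay family never fall below 2 and frequently sit
exactly at 2, consistent with such a floor. With the floor, end-to-end
serostatus recovery on the default synthetic preset exceeds 95%; without
it, null peptides dominate the error.

## Group comparison, coverage, peptide selection

Per-peptide 2×2 tables (seropositive × group) are tested with the
two-sided Fisher exact test (minimum-likelihood two-sided convention, via
scipy) and Bonferroni-corrected with the panel size *m* (default: number
of peptides compared); raw and adjusted p are reported side by side
because screening reports conventionally quote raw p. Rates and
differences are rendered to whole percent with round-half-away-from-zero.
Coverage of a peptide in a serum set is the seropositive fraction,
computed per (peptide, time point) for longitudinal cohorts with cut-offs
frozen from the preoperative case–control comparison; per-patient SNR
trajectories and status transitions (e.g. `+/-/+` for seroconversion at
day 30 and rebound at recurrence) are emitted alongside. "Highly
responsive" peptides are those with Bonferroni-adjusted p below 0.05,
ranked by rate difference, top *k* = 5 by default — the selection rule is
a package convention for a selection whose published rule is unstated.

## Serology–IHC association

IHC staining percentages are dichotomized with boundary-exclusive
thresholds: MGMT expression positive when > 10% of nuclei stain, Ki-67
high when > 20% (values exactly at the threshold fall in the
negative/low class). Pooled serostatus for the association is "positive
for at least one of the selected peptides" (configurable to single-peptide
mode). Association uses the midrank Spearman coefficient, which on
binary–binary data equals the phi coefficient
`(ad − bc)/√((a+b)(c+d)(a+c)(b+d))`; p-values use the t-approximation by
default (appropriate at the ~21-subject scale this assay produces), with
an exact permutation p available as a cross-check. The permutation
distribution of binary data is atomic, so exact and approximate p can
differ numerically while agreeing on the significance decision; the test
suite asserts decision agreement rather than numeric closeness.

## Survival

RFS is days from surgery to observed recurrence (event) or last follow-up
(censored); zero-length intervals and recurrence before surgery are
rejected. Kaplan–Meier estimation and the two-group log-rank test are
delegated to lifelines behind the module surface. The Cox
proportional-hazards fit is implemented in-package: Newton iteration with
step-halving on the partial likelihood, convergence when the maximum
coefficient change falls below 1e-8 (cap 100 iterations), Breslow tie
handling by default with Efron available — Breslow is the default of the
legacy commercial package such analyses are usually run in, and lifelines
(Efron-only) serves as an independent cross-check in the tests. Wald 95%
CIs are `exp(β ± 1.96·SE)`. Monotone likelihood (perfect separation) is
detected by coefficient blow-up (|β| > 20) and reported as a
non-converged fit with a diagnostic warning rather than an exception.
Forward selection adds, at each step, the candidate with the smallest
likelihood-ratio p below 0.05 (no removal step; ties keep candidate
order), matching the forward-selection convention of multivariable
screening reports. Age is dichotomized at 65 and WHO grade as II versus
III–IV for the covariate set.

## Synthetic-data generator

The generator is the package's stand-in for study sera and defines the
conditions under which the pipeline is validated:

* per-peptide seropositivity prevalences default to the published positive
  response rates of the 20-peptide MGMT screen (glioma 1–45%, healthy
  0–7%); the default cohort is 100 cases vs 300 controls, and a
  `study_shape` preset reproduces the published study shape (67 vs 311,
  52 post-operative and 11 recurrence sera);
* latent SNR is a log-normal mixture — seronegative median 0.5 (σ = 0.6),
  seropositive median 6 (σ = 0.4) — because SNR is a positive-skewed
  ratio; the medians straddle the printed cut-off scale and give a
  separable but noisy mixture;
* spot intensities are `background · (1 + SNR) · (1 + ε)` with per-block
  Gaussian background (mean 100, CV 10%) and multiplicative spot noise
  (CV 8%); blanks carry `background · (1 + ε)`, positive controls a fixed
  SNR of 8, the negative control SNR 0;
* day-30 latent SNR is the preoperative level × 0.3 (antigen removed with
  the tumor); at recurrence, preoperatively seropositive patients rebound
  to 1.0 × the preoperative level while seronegative patients stay low;
* recurrence times are exponential with hazard
  `baseline · exp(logHR · serostatus)` (baseline 1/400 per day, default
  HR 2 for the designated peptide), censored by an independent uniform
  time whose horizon is solved numerically to hit the target 30%
  censoring rate; clinical covariates are drawn from marginals shaped
  like the published cohort, and IHC expression is correlated with pooled
  serostatus at the published 2×2 odds.

The generator does **not** emulate spatial artifacts, batch effects,
isotype structure, inter-array drift requiring normalization, or
non-exponential hazards. Passing tests therefore demonstrate correctness
of the analysis under a clean, well-separated generative model — not
robustness of the assay to real-world technical variation.

## Numerical conventions and problem sizes

All randomness flows from explicit integer seeds through numpy
Generators; pipeline reruns with identical config are byte-identical
(verified file-by-file in the tests). Exhaustive oracle checks run at
desk scale: the cut-off optimizer against brute-force search on 1,000
random instances, Fisher's exact test against full hypergeometric
enumeration for every 2×2 table with total count ≤ 40, and the Cox
Newton solution against a grid-search maximizer of the hand-written
partial likelihood on small (n ≤ 8) instances. Stochastic guarantees
(Cox CI coverage of a true HR 2 at n = 500 over 200 replicates, log-rank
type-I control over 200 seeds, ≥ 95% end-to-end serostatus recovery at
100/300) are asserted per seed-batch in the acceptance suite. These sizes
were chosen so the full validation runs comfortably on a single CPU.

## Known limitations

* The cut-off search is in-sample and optimistically biased by
  construction (no cross-validation; ROC/AUC-based thresholding is out of
  scope by design).
* The candidate-floor default (2.0) is an assay convention, not an
  estimated quantity; screens on a different SNR scale must adjust it.
* Published per-peptide p-values and survival hazard ratios from the real
  cohort are not reproducible without the underlying sera; the package
  validates machinery (oracle equivalence, parameter recovery), not those
  specific numbers.
* Cox model diagnostics are limited to convergence/separation reporting;
  proportional-hazards checking, time-dependent covariates and competing
  risks are out of scope.
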