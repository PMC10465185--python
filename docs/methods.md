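# Methods

## The assay and its statistical model

The package analyses an in vitro autologous killing assay. Per donor, sorted
CD4+ T-cell targets (conventional Tconv and regulatory Treg) are labelled
with a proliferation dye, stimulated, and measured in three culture arms:
co-culture with CD56-bright NK cells, co-culture with CD56-dim NK cells, and
alone (no NK cells — the spontaneous-death background). A viability dye
marks dead cells. Three modelling layers sit on top of the event-level data.

### Dye-dilution mixture

Dye fluorescence halves with each division, so on the log10 scale the
intensity of a cell in generation *g* is modelled as
Normal(`mu0 - g*log10(2)`, `sigma`). The population histogram is a finite
mixture over generations 0..`g_max` with free weights. Two constraints are
deliberate:

* **peak spacing is fixed at exactly log10(2)** — perfect halving is the
  physical premise of dye-dilution assays, and freeing the spacing makes
  sparse high generations unidentifiable;
* **one shared sigma across peaks** — stabilizes the fit when late
  generations hold few cells.

The free parameters (`mu0`, `sigma`, weights) are estimated by EM; every
M-step is closed-form under the spacing constraint, so the log-likelihood is
monotone (this is asserted by a test). Cells are assigned the generation
with maximal posterior responsibility; responsibilities within 1e-9 of the
maximum count as ties and resolve to the lower generation, so a cell exactly
between two peaks is attributed to the fewer-divisions interpretation.

**Initialization.** `mu0` starts at the mode of the upper-quartile
intensities (the brightest peak is the undivided one). When stimulation is
strong, few cells remain undivided and that mode can sit one or two peaks
low; the fitter therefore also tries the mode shifted by +1 and +2 peak
spacings, runs 30 EM iterations from each start, and continues the best
likelihood to convergence. Convergence is declared when successive total
log-likelihoods differ by less than 1e-8 (cap 500 iterations;
non-convergence sets a flag and warns, it does not raise). `sigma` is
floored at 1e-4 to keep degenerate single-peak inputs finite.

### Proliferation indices

With per-generation cell counts `n_g`, precursor (founder) counts are
`P_g = n_g / 2^g`. Percent divided is computed over acquired cells,
`sum_{g>=1} n_g / sum n_g` — this matches how cytometry results are usually
narrated; the division and proliferation indices use precursors per their
definitions: `DI = sum g P_g / sum P_g` (average divisions per founder
cell), `PI = sum_{g>=1} g P_g / sum_{g>=1} P_g` (the same average among
founders that divided). `DI <= PI` always; PI is undefined (a distinct
`UndefinedResultError`) when nothing divided. Matched populations are
compared with two-tailed paired t-tests; zero-variance differences are
rejected rather than returning an infinite statistic.

### Specific killing

Targets are gated as the dye-stained rows (NK cells are not dye-stained);
no viability-based or scatter-based pre-gating is applied, so dead cells are
counted. Specific killing is the plain difference
`dead fraction (co-culture) - dead fraction (alone)`, computed per donor x
effector x target, for all cells and within the high/low proliferative
strata. "High" means at or above a day-specific division threshold: >= 2
divisions at day 2.5, >= 3 at day 3.5 (the lower early threshold reflects
the slower proliferation at day 2.5). The background subtracted from a
stratum is always the *same* stratum of the *same* donor and target in the
alone arm. Negative differences are legitimate outcomes (background
exceeded co-culture death); they are preserved and flagged, not truncated —
truncation is deferred to the inference boundary so that the stages stay
composable.

### Beta regression

Observed proportions are modelled as `y_i ~ Beta(mu_i*phi, (1-mu_i)*phi)`
with `logit(mu_i) = alpha + beta_g(i) + gamma_p(i)`, where `g` indexes the
contrast of interest (proliferative stratum, cell type, or assay day) and
`p` the donor/sample pair. Choices that were genuinely open:

* **Priors**: Normal(0, 2.5) on logit-scale coefficients and
  Normal(3, 1.5) on `log(phi)` — standard weakly informative defaults for
  logit-linked regressions; the data (14-28 observations) dominate them.
* **Pair effects are fixed effects** with reference-level coding, mirroring
  a regression "with pair as predictor". A hierarchical pair term would
  shrink donors toward each other; with one observation per cell within
  pair there is little to gain and identifiability to lose.
* **Pair marginalization**: a group's mean is the equal-weight average of
  `logit^-1(alpha + beta_g + gamma_p)` over observed pair levels, per draw.
  Fold changes are per-draw ratios of these means, so the median fold
  change is not the ratio of medians.
* **Boundary transform**: raw responses are clamped into
  `[epsilon, 1 - epsilon]`, `epsilon = 0.005`; the clamp count is reported
  and logged. This is how out-of-model values (negative specific killing)
  enter the Beta likelihood.
* **Summaries**: equal-tailed 95% intervals from linear-interpolation
  sample quantiles (not HPD); the false sign rate is the fraction of draws
  whose sign opposes the median's sign (0.5 when the median is exactly 0).

**Sampling.** The sampler is a self-contained adaptive random-walk
Metropolis: chains start at the posterior mode (found by BFGS) with the
inverse finite-difference Hessian as initial proposal covariance; during
warmup the proposal tracks the chain's empirical covariance (scaled
2.38^2/d) and a global step size is tuned toward 23.4% acceptance; both are
then frozen. Defaults are 4 chains x (2500 warmup + 2500 kept), with 10
internal steps per kept draw to decorrelate the walk. Split-R-hat is
computed for every parameter (via arviz); values above 1.01 attach a
convergence warning. The sampler is validated against dense-grid quadrature
of the same log-posterior on small datasets (agreement within 0.02 on
posterior means) and against prior quantiles in prior-only mode.

## The synthetic cohort

The generator emulates the study design directly: 14 donors (10 at day 2.5,
4 at day 3.5), both T-cell targets, both NK co-culture arms plus the alone
arm, 20 000 cells per population (real assays plate 50 000; reduced for
desk-scale runs). Per cell: a generation drawn from a per-(subset, day)
probability vector, a dye intensity from the Gaussian peak model
(`mu0 = 4.5`, `sigma = 0.08` log10 units), and a Bernoulli death indicator.
Death probabilities are **additive on the proportion scale** — stratum
background plus, in co-culture, the stratum's specific-killing mean
(clamped to [0, 1]) — because the downstream statistic is an arithmetic
subtraction of percentages; an additive generative rate makes the
generator's parameters the estimand of the pipeline, which is what the
round-trip tests exploit.

Donor heterogeneity is a Normal(0, 0.15) offset on the logit scale, drawn
once per donor x target subset and shared across that subset's three
culture arms. Sharing across arms preserves the paired structure
(background subtraction removes most of the offset; what survives is the
logit nonlinearity), while independent offsets between Tconv and Treg leave
genuine donor-level scatter in the paired contrasts. The 0.15 scale is a
calibration choice, not a measured quantity.

Calibration defaults are set to the study's printed values: generation
distributions reproduce the division fractions (94%/71% of Tconv/Treg
divided by day 2.5, 97%/87% by day 3.5, with the printed extreme-generation
fractions); stratum backgrounds aggregate to day-level spontaneous death of
7.0%/16.2% (Tconv) and 8.6%/9.7% (Treg); stratified killing means are
25.6%/17.7% (CD56br on Tconv high/low), 22.0%/15.0% (CD56br on Treg), and
near-flat CD56dim values whose all-cells means sit at ~22.5%/20.7%.

What the generator does **not** emulate: scatter channels, spillover and
compensation, doublets, autofluorescence, instrument drift, dye transfer
between cells, death-in-culture distorting generation counts, NK-cell death
(NK rows are emitted dye-negative and alive, purely as gating decoys), or
any effector:target ratio effect. Passing tests therefore demonstrate that
the pipeline recovers the parameters of this idealized generative process —
they do not certify performance on real instrument exports, where peak CVs
vary by generation and backgrounds need not be additive.

## Problem sizes and numerical notes

* Full-cohort runs (tests and the acceptance script) use 20 000 cells per
  population and the default sampler; one cohort analysis takes ~1 minute
  on a single CPU, dominated by the 28 per-donor EM fits.
* Peak models are fitted per donor x subset with the three culture arms
  pooled (proliferation is condition-independent in this design; pooling
  triples the evidence per fit).
* At `sigma = 0.08` adjacent peaks overlap at ~1.9 sigma from each mean, so
  even the true-parameter classifier misassigns ~5% of cells;
  classification fidelity is judged against that Bayes-optimal benchmark
  rather than an absolute number.
* The interval-calibration study draws ~120 datasets from the model's own
  prior predictive (12 observations, 2 groups) and checks 95%-interval
  coverage of the group effect with a reduced sampler; prior-predictive
  responses are valid Beta draws and are fitted without the epsilon clamp,
  which exists for out-of-model values only.
* Degenerate inputs are errors by design: empty generation profiles,
  zero-variance paired differences, proportions outside [0, 1], missing
  background arms (reported with donor and target), and missing dye
  intensities in generation assignment (reported with row indices).

## Known limitations

* The EM fitter assumes a common sigma and exact halving; real dye data
  show generation-dependent peak widths and imperfect dilution.
* Pair effects as fixed effects scale poorly beyond a few dozen donors;
  a hierarchical formulation would then be preferable.
* The random-walk sampler is adequate for the ~3-20 parameter models here
  but is not a general replacement for gradient-based samplers at higher
  dimension.
* Fold-change estimates on small cohorts (4-7 donors in a group) carry
  substantial donor-sampling variance; credible intervals report posterior
  uncertainty given the realized cohort, not across-cohort variability.
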