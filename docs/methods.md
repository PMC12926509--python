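# Methods

## The measurement and its estimators

Stable-isotope labelling kinetics (SILK) infuses ¹³C₆-leucine intravenously
(3 mg/kg/h for 10 min, then 2 mg/kg/h for up to 9 h), so that proteins
synthesized during the infusion incorporate labelled leucine. Serial CSF
sampling then tracks the labelled fraction of each targeted peptide. The
package works throughout on the **mole fraction labelled**

    f = TTR / (1 + TTR),      TTR = labelled / unlabelled peak-area ratio,

which is bounded in [0, 1) and is the quantity plotted on kinetic curves;
TTR is retained for reporting. A TTR of 100% is identically 50% mol.

Three rates are estimated per peptide per subject:

* **FSR** (fractional synthesis rate, %/h) — ordinary least-squares slope of
  f against time over the upslope window (first timepoint through the peak
  of labelling, inclusive), divided by the plasma precursor plateau
  enrichment: `FSR = 100 · slope / plateau`. In vitro, where labelled and
  unlabelled leucine in the media are equimolar, the conventional
  normalization divides by 1 instead (`precursor_convention="unity"`); both
  normalizations are supported and the one used is flagged.
* **FCR** (fractional clearance rate, /h) — the negative OLS slope of
  ln f over the clearance window (peak onward in vivo; all declared chase
  timepoints in vitro). Nonpositive enrichments are excluded, never offset:
  an additive offset biases small-enrichment decay slopes.
* **Half-life** (h) — `t½ = ln 2 / k` with k from a nonlinear least-squares
  fit of `A·exp(−k·(t − t_peak))` over the same window, initialized at the
  log-linear solution (Levenberg–Marquardt, xtol 1e-8, ≤200 iterations).
  On exact exponential data k equals the FCR to numerical precision.

Fits are unweighted (the protocol specifies plain linear regression), need
at least 3 points each (2 points always give r² = 1), and are fully
deterministic. Undefined rates are NaN with an explanatory flag; a subject
is never aborted because one peptide fails.

The plasma **precursor plateau** is the arithmetic mean of plasma leucine
mole fractions inside a window, by default the second half of the infusion;
the mean is preferred over the last sample because single MRM measurements
carry multiplicative noise. A plateau with coefficient of variation above
0.15 (configurable) is flagged unsteady. Because infusion duration varied
with clinical circumstances, a cohort may opt into a **surrogate plateau**:
the steadiest profile (smallest CV, or a designated subject) normalizes the
other subjects' FSRs, recorded in each result's provenance. Both
"surrogate everywhere" and "surrogate only where missing" are supported.

**Species classification** of peptides (human-synthesized vs bovine
media-derived protein in organoid experiments) digests both reference
sequences in silico with the tryptic rule — cleave C-terminal to K/R except
before proline, zero missed cleavages by default — and calls a peptide
unique, shared or absent by exact membership among the digest products.

## Group statistics

Cohorts are small (4–10 per arm), so the primary machinery is exact:

* **Mann–Whitney U** — U is the number of (x, y) pairs with x < y plus half
  the ties, reported as the smaller of the two one-sided statistics (so
  complete separation prints U = 0). With no ties and n₁+n₂ ≤ 25 the null
  distribution of U is enumerated by the standard dynamic-programming
  recurrence N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1); the two-sided p is
  2·min(lower, upper tail), capped at 1. Under complete separation this
  gives 2/C(12,4) = 0.004 for 8 vs 4 and 2/C(13,5) = 0.002 for 8 vs 5.
  Ties (or larger samples) fall back to a seeded Monte-Carlo permutation
  test rather than the mid-rank normal approximation, which these sample
  sizes cannot support.
* **Spearman ρ** — Pearson correlation of mid-ranks; the two-sided p is
  exact by full enumeration of all n! rank permutations for n ≤ 8,
  otherwise the t approximation with df = n−2.
* **Welch t** — unequal-variance t with Welch–Satterthwaite (non-integer)
  degrees of freedom.
* **Shapiro–Wilk** is exposed as a screening hook (delegating to the
  standard implementation) and gates nothing by default; no
  multiple-testing correction is applied by default (a Holm option exists).

Undefined rates are excluded from comparisons with exclusion counts
reported per group, mirroring clinical practice where clearance could not
be captured in every participant.

## The simulator

The synthetic cohorts emulate the clinical experiment, not leucine
pharmacokinetics. Plasma precursor enrichment is phenomenological —
`p(t) = P_max(1 − e^{−t/τ_r})` during the infusion, exponential decay with
constant τ_d afterwards — because in practice plasma enrichment is measured
rather than modelled; only the curve's shape (rise, plateau, washout)
matters downstream. Defaults: P_max = 0.10, τ_r = 0.5 h, τ_d = 1.0 h,
9-h infusion.

Each protein pool carries labelled and unlabelled amounts:

    dA_L/dt = S·p(t−δ) − k_c·A_L          A_L(0) = 0
    dA_U/dt = S·(1−p(t−δ)) − k_c·A_U      A_U(0) = A0

integrated with fixed-step RK4 (0.01 h; fixed-step for bit-level
determinism across platforms), sampled as E = A_L/(A_L+A_U). Mass balance
gives d(A_L+A_U)/dt = S − k_c(A_L+A_U). **Pools default to the tracee
steady state A0 = S/k_c**, under which the total pool is constant and the
chase log-slope of E identifies k_c exactly; explicit non-steady A0 is
supported, but then the total pool drifts toward S/k_c during the
experiment and both slope estimators acquire bias (for S/A0 = 0.05/h
against k_c = 0.005/h the pool grows ~40% in 9 h and the regression FSR
under-recovers by about a third — quantified against an adaptive-ODE oracle
in the test suite). The transit delay δ implements ventricular→lumbar lag
as p ≡ 0 for t < δ.

The optional second compartment is a flow-through lumbar pool fed from the
ventricular one: dL/dt = r·V − (r + k_c)·L per channel. Lumbar enrichment
lags the ventricular curve and converges to it as r grows, which is the
behaviour needed to ask whether sampling site can confound a ten-fold
clearance contrast; it is a sensitivity stand-in, not a fitted model.

**Noise** is applied on the peak-area scale: each channel's expected area
(total area split by E) is multiplied by an independent unit-mean lognormal
factor with the configured CV, so the measured ratio is stochastic and the
full ingest path is exercised. Between-subject biology is lognormal
variation of S and k_c (CV 0.15 by default). Cohorts export
transition-report and plasma CSVs plus a ground-truth JSON manifest; all
outputs are bit-reproducible given the seed.

### Sampling designs

* Clinical CSF grid (default): hourly through the 9-h infusion, then a
  72-h chase (24, 32, …, 72 h). Plasma: hourly, 1–9 h.
* Extended grid for slow-clearing subjects: chase 12-hourly out to 120 h,
  emulating prolonged lumbar drainage; chase duration differing between
  cohorts is a feature of the emulated protocol. A pool with half-life of
  weeks barely decays within 72 h, so its clearance cannot be resolved
  there against 5% noise.
* FCR-recovery studies use a chase-only design — 8 samples starting 15 h
  after infusion end (precursor enrichment has decayed to ~10⁻⁷ of plateau)
  spanning ~2.2 half-lives — under which the log-linear estimator is
  unbiased to ~10⁻⁶ relative.
* FSR-recovery studies sample hourly from 1 to 9 h; the first draw is taken
  one hour into the infusion because the sub-hour bolus/rise transient
  violates the linear-upslope assumption.

## Numerical and design notes

* Sample times must lie on the integrator grid (multiples of the step);
  a step larger than the smallest sample spacing is a configuration error.
* Peak detection takes the global maximum, earliest on ties. On a nearly
  flat noisy curve the detected peak can land so late that fewer than three
  clearance points remain; such FCRs are undefined and excluded (with
  counts), exactly as the comparison layer treats them.
* Zero/negative unlabelled areas make the TTR undefined; the point is
  excluded with a logged reason, never imputed.
* CSV outputs use a fixed column order and 9 significant digits so that
  reruns are diff-able; manifests carry SHA-256 digests of every input and
  output (their timestamps are the only non-reproducible field).
* The exponential decay fit leaves the amplitude A free rather than
  anchoring it at the observed peak; anchoring would propagate a single
  noisy measurement into k.

## Known limitations and what the tests do and do not show

Measured recovery of the estimators (noiseless, steady-state pools):
FCR is recovered to ~10⁻⁶ relative on chase-only designs across
k_c ∈ [0.005, 0.2]/h, but on the clinical grid, where the clearance window
opens at an in-pulse peak sample, residual precursor inflow flattens the
first chase segment and biases FCR ≈ −8% at k_c = 0.02/h. The OLS upslope
FSR carries a curvature bias that grows with k_c·T (about −1% at
k_c = 0.002/h up to −9% at 0.02/h over a 9-h window, and ~−20% by
0.05/h): both are properties of the empirical-slope method itself, not of
the implementation, and both are reproduced and frozen in the test suite.

The simulator draws a single well-mixed pool per protein with lognormal
area noise; it does not emulate chromatographic interference,
retention-time drift, transition-level variation, leucine recycling,
pool-size drift from disease progression, or CSF hydraulics. Passing
recovery tests therefore show that the estimators invert the stated
generative model at desk scale — they do not certify accuracy on real
MRM data, where peak integration quality and precursor-pool assumptions
dominate. The two-compartment option is a plausibility probe for
sampling-site effects, not a validated physiological model.
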