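# Methods

## Quantal potency estimation

The assay endpoint is binary per animal (protected from the tonic–clonic
seizure or not), observed in dose groups of 8 mice. The dose–response model
is a probit curve in log dose: the protection probability at dose *d* (mg/kg)
is p(d) = Φ(a + b·log₁₀ d). `fit_log_probit` estimates (a, b) by
maximum-likelihood binomial regression with a probit link (iteratively
reweighted least squares, log-likelihood tolerance 1e−10, at most 100
iterations; statsmodels GLM provides the solver). The reported quantities
are:

* **ED50** = 10^(−a/b), the dose protecting half the animals;
* **slope** = b, in probits per log₁₀ dose unit;
* **SEM and 95% CL** by the delta method on the log₁₀ scale:
  SE(log₁₀ED50)² = gᵀ Σ g with g = (−1/b, −log₁₀ED50/b), then
  SEM = ED50·ln10·SE and CL = ED50·10^(±1.96·SE). The CL→SEM back-transform
  `sem_from_cl` = (upper − lower)/(2·1.96) ingests published intervals;
* **n** (`count_probit_window_n`) — the animals tested at doses whose
  *observed* protected fraction lies in [Φ(−1), Φ(1)] = [0.1587, 0.8413],
  inclusive with a 1e−9 tolerance. Membership uses observed rather than
  model-expected fractions: the convention is not fully determined by
  published tables, and the observed rule is self-contained and
  fit-independent. Equal doses are pooled before the fraction is assessed.

Fully unprotected and fully protected groups stay in the likelihood (they
inform the tails); no empirical-probit corrections are applied. Degenerate
inputs are handled explicitly: fewer than two distinct doses, or all-0%/
all-100% response, raise `NonEstimableError`; completely separated data (a
dose threshold exactly splitting 0% from 100% groups admits no finite ML
slope) return a `converged=False` estimate with `slope = inf`, the ED50
placed at the geometric midpoint of the separating gap, and NaN dispersion —
never a silent number.

On two-dose datasets with both fractions strictly inside (0, 1) the ML fit
is saturated and equals the line through the two empirical probits; the test
suite holds the fit to that closed form (1e−6 on log₁₀ED50) and to a
brute-force likelihood maximisation.

## Isobolographic transformation

Designs are fixed-dose rays: adjuncts at constant doses Dᵢ with solo ED50s
ED50ᵢ, one varied drug. Under Loewe dose equivalence the additive prediction
is

    ED50_add,varied = ED50_varied · (1 − Σᵢ Dᵢ/ED50ᵢ),
    ED50_add,total  = ED50_add,varied + Σᵢ Dᵢ,

with the delta-method variance
Var_add = (1 − Σfᵢ)²·Var(ED50_varied) + Σᵢ (ED50_varied·Dᵢ/ED50ᵢ²)²·Var(ED50ᵢ)
and n_add the sum of the probit-window counts of the solo curves entering
the calculation. Designs whose adjunct fractions sum to ≥ 1 are refused
(the fixed doses alone reach the additive ED50). Mixture ED50s are reported
as **total mixture dose** (varied + fixed), the convention of published
interaction tables; the varied-only component is kept alongside.

Fraction bookkeeping: at the experimental mixture ED50, the varied drug's
fraction is its in-mixture ED50 over its solo ED50 and each adjunct's is
Dᵢ/ED50ᵢ; each fraction is rounded to 2 decimals **half away from zero**
before summing, because published "sum of fractions" columns are sums of the
printed 2-decimal fractions. Unrounded fractions are retained and sum to
exactly 1 on the additivity line. Percent ED50 changes round to the nearest
integer from unrounded operands.

**Three-drug convention.** The bundled three-drug designs reproduce their
source tables only under a pooling convention: the two fixed adjuncts
(ISOP 25 + BOR 25 mg/kg) are treated as a single 50 mg/kg adjunct on ISOP's
dose–response curve for the additive prediction (making the three-drug
additive totals, SEMs and n identical to the two-drug ISOP-50 rows), while
BOR keeps a solo ED50 of 250 mg/kg — the value implied by its printed 0.10
fraction, never directly published — for the fraction bookkeeping. The two
conventions are mutually inconsistent (25/235.7 rounds to 0.11, not 0.10);
the package implements the general multi-adjunct formula as the default and
exposes the pooling as an explicit `additivity_adjuncts` override, so the
bundled fixture states exactly what the source did rather than resolving the
inconsistency. Several other bookkeeping values are likewise back-derived
conventions, not published numbers: the per-drug solo probit-window counts
(16/16/16/24 for CBZ/PHT/PB/VPA, 28 for ISOP, consistent with the published
pooled n_add of 44 and 52) and BOR's ED50 above. Solo SEMs of the four
classic drugs were never published, so summary-mode Welch tests consume the
published additive SEMs directly and the recomputed additive total is
reported alongside for cross-checking.

## Interaction testing

`welch_t` compares two summary estimates: t = |v₁ − v₂|/√(SEM₁² + SEM₂²),
Welch–Satterthwaite df = (SEM₁²+SEM₂²)²/(SEM₁⁴/(n₁−1) + SEM₂⁴/(n₂−1))
**rounded to the nearest integer** (published df of 65 and 41 arise from
64.85 and 41.49; flooring fails both), two-sided p from Student's t. The t
is reported as an absolute value. Classification at level α (default 0.05,
strict inequality): p < α with the experimental total below the additive
total → synergistic; above → antagonistic; otherwise additive.

`dunnett_compare` approximates the classical ANOVA + Dunnett post-hoc
comparison for settings where only (ED50, SEM) summaries exist: each
treatment yields zᵢ = |ED50_c − ED50ᵢ|/√(SEM_c² + SEMᵢ²), and the
family-wise adjusted p is the Monte-Carlo probability (default 100,000
seeded draws) that the maximum |z| across the family — correlated through
the shared control draw — exceeds the observed zᵢ. The omnibus ANOVA F is
not computed: no replicate-level data exist for an ED50. Simulation places
the family-wise null rejection rate at 0.049 for k = 3 at α = 0.05.

## Synthetic data generator

`simulate_quantal` draws n_protected ~ Binomial(n_per_group, Φ(b·(log₁₀ d −
log₁₀ ED50))) per dose with one `numpy` generator seeded per dataset;
identical (config, seed) reproduces the dataset byte-for-byte on CSV export.
Defaults mirror the assay: 8 animals/group, dose ranges like the study's
(e.g. 6–16 mg/kg for a carbamazepine-like drug with ED50 9.52 mg/kg; the
slope default of 6 probits/log₁₀ in the validation studies is chosen so that
a 6–16 mg/kg range spans roughly 10–90% protection, as a usable assay design
must). `simulate_mixture` converts the varied dose to its Loewe-equivalent
total d_eq = d + Σᵢ ED50_true·Dᵢ/ED50ᵢ and evaluates
p = Φ(b·(log₁₀(IF·d_eq) − log₁₀ ED50_true)). The interaction factor IF is a
potency multiplier on the equivalent dose — the simplest mechanism that
makes Loewe additivity *exactly* true at IF = 1, synergy at IF > 1,
antagonism at IF < 1.

What the generator does **not** emulate: between-animal heterogeneity beyond
binomial sampling, litter or day effects, dose-preparation error,
non-probit-shaped responses, and pharmacokinetic interaction mechanisms.
Passing tests therefore certify the estimator and decision machinery under
the assumed model, not the biology of any real assay.

A subtlety documented because it is intrinsic to fixed-dose designs: the
mixture response is probit-linear in log₁₀ *equivalent total* dose, not in
log₁₀ of the varied dose, so refitting the mixture on the varied-dose scale
(as the assay itself does) carries a small deterministic curvature
distortion (≈0.4% of the ED50 under the bundled conditions). The
additivity-by-construction check (`validation.additivity_check`) therefore
refits the mixture in equivalent-dose space and subtracts the adjunct
equivalents afterwards, with paired solo doses equal to the equivalent
totals; the paired difference is then exactly mean-zero and is asserted
within 3 Monte-Carlo SEs.

## Validation studies and problem sizes

`validation` packages the simulation studies the analysis scripts and
acceptance checks run; sizes are chosen to give stable Monte-Carlo estimates
at interactive runtimes:

* ED50 recovery: 500 replicates, 100 animals/group, 5 log-spaced doses —
  mean fitted ED50 within ±3% of truth, delta-method SEM within 25% of the
  empirical spread;
* classification operating characteristics: 1,000 replicates of the full
  simulate → fit → isobole → Welch pipeline at 8/group; exactly additive
  mixtures are called additive ≈96% of the time (type-I ≈4% at a nominal 5%
  — small-n probit SEMs are approximate), and a two-fold potentiation with
  adjunct fraction 0.2 is detected as synergy ≈99% of the time. Replicates
  with non-estimable curves (all-or-none response at small n) are excluded
  and counted;
* Dunnett calibration: 10,000 null replicates against a 200,000-draw
  critical value.

## Known limitations

* The Litchfield–Wilcoxon graphical log-probit procedure used historically
  (nomogram arithmetic, chi-square heterogeneity factor) is replaced by its
  ML equivalent; refit ED50s can differ slightly from nomogram values. All
  table reproductions here consume published ED50s, not refits.
* Summary-mode dispersion is only as good as the published SEMs; where a
  source's own rounding leaves residue (the valproate additive cells differ
  from recomputation by up to 0.06 mg/kg), the recomputed value is reported
  next to the published one rather than reconciled.
* Only fixed-adjunct-dose (ray) designs are supported; fixed-ratio
  isobolography and nonparallel-curve corrections are out of scope, as is
  figure rendering (coordinates are exported as CSV).
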