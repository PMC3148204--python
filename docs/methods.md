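# Methods

## Model and definitions

Decision curve analysis evaluates a prediction model by the clinical
consequences of using it as a treatment rule. Treat subject *i* iff the
predicted disease probability exceeds a threshold, p_i > p_t, where
p_t = L/(L+P) is the probability at which a decision maker is indifferent
between treating and not treating (L = loss of treating a disease-free
subject, P = profit of treating a diseased one; only the ratio matters).
At threshold p_t the sample splits into joint proportions a (true positive),
b (false positive), c (false negative), d (true negative), with prevalence
π = a + c.

The raw benefits are U_treated = aP − bL among the treated and
U_untreated = dL − cP among the untreated. Between two models evaluated on
the same sample at the same threshold, the two differences are equal
(both equal (a₁ − a₂)(P + L) when a + c is shared), so model *ranking* does
not depend on which side is examined — but normalised differences do.
Dividing by P and by L respectively gives the unitless forms

* u_treated = a − b·p_t/(1−p_t), maximum π;
* u_untreated = d − c·(1−p_t)/p_t, maximum 1−π;
* u_overall = u_treated + u_untreated, maximum 1, attained only when
  b = c = 0.

u_overall is invariant to recoding the outcome (swapping cases with
non-cases, treated with untreated, p_t with 1−p_t), which u_treated alone is
not; the summation is taken as the definition of the overall form, with no
further normalisation. At p_t = 0.5 it reduces to (a+d) − (b+c), the
percentage correctly classified minus the percentage misclassified.

Degenerate strategies give the reference lines: treat-none (u_treated ≡ 0,
u_untreated = (1−π) − π(1−p_t)/p_t), treat-all
(u_treated = π − (1−π)p_t/(1−p_t), u_untreated ≡ 0), and the perfect model
(π, 1−π, 1). A binary test with sensitivity *sens* and specificity *spec*
is the degenerate model p_i ∈ {0, 1}; its proportions
(sens·π, (1−spec)(1−π), (1−sens)·π, spec·(1−π)) are constant in p_t.

## ROC linkage

Written through sensitivity and specificity,
u_treated = sens·π − (1−spec)(1−π)·p_t/(1−p_t). For a continuous model,
maximising u_treated over the dichotomising cutoff corresponds, in real
arithmetic, to the ROC operating point whose slope equals
[(1−π)/π][p_t/(1−p_t)]. The empirical ROC is a step function with no
well-defined slopes, so the implementation maximises u_treated directly over
every candidate cutoff and reports the analytic slope as a diagnostic — the
optimum is identical and there are no differentiation artifacts. Candidate
cutoffs are midpoints between consecutive distinct sorted probabilities plus
one sentinel above the maximum and one below the minimum, which enumerates
every classification a cutoff can induce. At p_t = π the identity
u_treated = π·(sens + spec − 1) holds at every cutoff, so the
net-benefit-optimal and Youden-optimal cutoffs coincide exactly; the test
suite asserts this as an exact (1e-12) identity, not an approximation.
Dichotomising a model at a fixed cutoff freezes sens and spec, so its
decision curve varies with p_t only through the weights, producing the
characteristic arc that collapses below the treat-none/treat-all references
away from the cutoff.

## Case-control estimation

When cases are over-sampled, the sample prevalence π no longer estimates the
population prevalence π₀, and model probabilities are miscalibrated by the
sampling odds. Given an externally known π₀, each probability is corrected
by odds rescaling, odds(p̃) = odds(p)·[π₀/(1−π₀)]·[(1−π)/π] — equivalently a
logistic intercept shift — leaving 0 and 1 fixed and preserving ranks (so
the ROC curve is unchanged). Classifying the adjusted probabilities at p_t
yields proportions a′, b′, c′, d′ that are themselves inconsistent, but
whose sensitivity a′/(a′+c′) and specificity d′/(b′+d′) remain consistent;
plugging them with π₀ into the sensitivity/specificity form gives the
case-control net-benefit estimators for all three kinds. With π₀ = π the
whole pipeline reduces algebraically to the cohort analysis, and the code
reproduces that reduction to 1e-12. When π₀ is uncertain, curves can be
drawn per assumed π₀ or swept over a π₀ grid at fixed p_t.

## Numerical choices

* **Tie rule.** Subjects with p_i exactly equal to p_t (or to a
  dichotomisation cutoff) are *not* treated: treatment requires a strict
  inequality. The same rule applies to adjusted probabilities. No tie rule
  can be invariant under outcome recoding, so the recoding-invariance test
  uses tie-free data (dyadic thresholds for the bitwise-exact variant).
* **Grid.** Thresholds run over 0.01…0.99 in steps of 0.01 by default. The
  endpoints are excluded because the untreated weight (1−p_t)/p_t diverges
  at 0 and the treated weight at 1. Curves are evaluated pointwise with no
  smoothing; plots join grid points linearly, clip the y-axis to
  [−0.05, 1.05] and draw diverging references only where they exceed the
  clip.
* **Conservation in floating point.** u_overall is computed as
  u_treated + u_untreated rather than the expanded four-term form, making
  conservation and recoding invariance bitwise identities instead of
  1e-12-close ones. All pure-arithmetic identities are asserted at 1e-12.
* **Cutoff ties.** When several cutoffs attain the maximal criterion (within
  1e-12), the one with the highest specificity — fewest treated — is chosen,
  in both the Youden and the net-benefit selectors, keeping the p_t = π
  coincidence deterministic even under exact ties.
* **Degenerate inputs.** classify accepts single-class samples (a + c may be
  0 or 1), but reference curves, ROC construction and the case-control
  adjustment require both classes / prevalence strictly inside (0, 1).
  Case-control grid points with undefined sensitivity or specificity yield
  NaN with a warning rather than a substituted 0 (with both classes present
  this cannot occur, since class totals do not depend on the threshold).
* **Logistic fitting** is a convenience wrapper over statsmodels' IRLS
  (binomial GLM), tolerance 1e-8, at most 100 iterations; perfect separation
  produces a warning and capped-iteration estimates rather than an error.
  Fitted probabilities are the in-sample values; no optimism correction is
  attempted.

## Synthetic data

`generate_risk_cohort` emulates a Framingham-like prognostic setting: six
covariates (binary sex at frequency 0.5 plus five standardised continuous
measurements), linear predictor −1.39 + 0.6·sex + 0.9·x₁ + 0.25·x₂ + 0.5·x₃
+ 0.3·x₄ + 0.45·x₅, outcomes Bernoulli of the logistic transform. The
intercept was tuned once by Monte-Carlo integration so the marginal
prevalence is ≈ 0.30 (realised prevalence at n = 10,000 falls within
[0.27, 0.33]); the coefficients are chosen for a realistic spread of risk
(AUC ≈ 0.78), not to match any published fit. `generate_binary_test_data`
produces 0/1-probability data at specified sensitivity/specificity/
prevalence, either stochastically or with exact cell counts when n divides
compatibly. `sample_case_control` draws fixed numbers of cases and controls
without replacement and *refits* the logistic model on the subsample, so the
probability miscalibration the adjustment corrects genuinely occurs. All
generators take explicit seeds (numpy PCG64) and are deterministic given
them.

What the generator does not emulate: censoring and follow-up time (the
binary endpoint is taken at face value), covariate correlation, measurement
error, and model misspecification. Passing tests therefore demonstrate the
estimators' algebraic correctness and their sampling behaviour under a
well-specified logistic truth; they do not certify performance under
misspecified or time-to-event data.

## Simulation scale and checks

The case-control recovery check uses a population of n = 50,000 (realised
prevalence ≈ 0.30), a 500+500 case-control subsample with refit, and
compares the π₀-adjusted curve to the full-population cohort curve over the
default grid (maximum absolute deviation ≤ 0.03, about three Monte-Carlo
standard deviations). The bias check runs 200 replicates of a 250+250
design against a population of 20,000 at p_t = 0.3: the mean estimate sits
within twice the single-replicate sampling SD of the population value. The
replicate mean carries a small positive offset (≈ +0.003) from in-sample
refitting on 500 subjects — an optimism of order 1/n that no amount of
replication removes — which is why the bias is judged against the
estimator's sampling spread rather than the standard error of the mean.
Similarly, the calibration round-trip is checked on the (π₀, 1−π₀)-weighted
mixture of case and control mean probabilities: the unweighted sample mean
of correctly calibrated probabilities converges to
π₀ + var(p)(1−2π₀)/(2π₀(1−π₀)) in a balanced design, not to π₀, because the
sample over-represents high-risk subjects.

## Limitations

No confidence intervals or standard errors for net benefit; no utility
elicitation for P and L; no optimism correction or cross-validation of the
convenience logistic fit; no handling of censoring, matched designs or
sampling weights; π₀ must come from outside the data. AUC and ROC bands are
out of scope — the ROC machinery exists only to connect cutoff selection to
net benefit.
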