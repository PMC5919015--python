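# Methods

## The model

Growth bands in calcified structures (bivalve shells here, equally otoliths
or vertebrae) are only usable for age estimation once their deposition
period is validated. The marginal increment ratio

MIR = MI / PI × 100

(forming increment over last completed increment) cycles through the
deposition period, so a population sampled across months carries the
periodicity signal in its MIR-versus-month trajectory. The package models
the expected MIR at month *t* as a truncated Fourier series with an
**estimated** period γ:

- order 1 (H1): ψ(t) = β₀ + β₁ sin(2πt/γ) + β₂ cos(2πt/γ)
- order 2 (H2): H1 + β₃ sin(4πt/γ) + β₄ cos(4πt/γ)

H1 is symmetric (its extremes are exactly half a period apart); H2 can
describe asymmetric cycles — fast band formation followed by a plateau, or
the reverse. γ ≈ 12 on monthly data indicates annual deposition; γ is never
fixed in advance, so annual periodicity is a conclusion of the fit, not an
assumption. The second-order extra terms use the doubled angle (the second
Fourier harmonic). A literal squared-sinusoid basis (`squared_trig=True`)
is also available for cross-checking; note it is linearly reducible to a
constant plus a second harmonic and therefore confounds β₀, which is why
the Fourier reading is the default.

## Likelihood

MIR scatter grows with the level, so the error is multiplicative:
observations are lognormal around the curve. With the error variance
concentrated out, the objective is

−2 ln L(θ) = n [ ln(2π S/n) + 1 ],  S = Σ (ln ψ_obs − ln ψ_exp)²,

with the implicit variance estimate σ̂² = S/n. The additive constant
2 Σ ln ψ_obs of the full lognormal density is omitted; it cancels in every
likelihood difference used here (profiles and the LRT), and the objective
values match the convention in which published MIR analyses print −2 ln L.

**Two-period replication.** Before fitting, each record observed at month
t is paired with a copy at t + 12 (`replicate_two_periods`, on by default,
exposed as a flag). This is the standard device for fitting periodic
curves to within-cycle samples. The doubled count enters the objective as
written, so −2 ln L of a replicated dataset is exactly twice the
unreplicated value; model comparisons are unaffected (both fits use the
same convention) but reported objectives depend on it, and the fit report
records `n_used` for that reason.

## Optimization

Because −2 ln L is a strictly increasing function of S, maximum likelihood
is exactly nonlinear least squares in the log residuals. Fits therefore run
a trust-region Gauss–Newton method (a Newton-type algorithm) with an
analytic Jacobian, which is much better conditioned than Newton steps on
the raw concentrated objective. Inside the optimizer a prediction that
dips below 10⁻³ MIR % is mapped onto a smooth positive exponential tail so
log residuals stay finite with a usable gradient; at any reasonable
optimum predictions are far above the floor and the surrogate is inactive.

Periodic likelihoods are multimodal in phase and period, so the fit is
multi-start (default 16): linear harmonic regressions of raw MIR on the
basis at fixed γ ∈ {10, 11, 12, 13, 14}, phase rotations (90°, 180°, 270°)
of the start nearest the nominal period, then seeded jittered copies. γ is
bounded to (2, 24) months to exclude aliases of monthly sampling; betas
are unbounded. Co-optimal starts within 10⁻⁶ objective units resolve to
the candidate with γ nearest 12, with all co-optima logged. Convergence
tolerances: 10⁻¹² relative on objective and step, 10⁻¹⁰ on the gradient.

## Profile-likelihood intervals

For each parameter, the 95 % likelihood interval is the set of pinned
values whose re-optimized deviance rises at most 3.84 (χ², df = 1) above
the minimum. The search walks a grid of 41 points per side spanning ±6
Wald standard errors (from a central-difference Hessian of −2 ln L at the
MLE), warm-starting each re-optimization from its neighbour, and doubles
the span up to 3 times if the profile has not crossed the threshold.
Endpoints are then located by bisection to 10⁻⁴ objective units. If the
profile never crosses inside the expanded range the interval is reported
open, with the reached bound flagged censored. The threshold is
configurable for other confidence levels; 0 collapses the interval to the
point estimate.

## Model selection

H1 is nested in H2 (β₃ = β₄ = 0). The primary statistic follows the
printed convention of published MIR analyses,

LRT = 2 [(−2 ln L)_H1 − (−2 ln L)_H2],

i.e. twice the deviance drop (four times the log-likelihood gain), with
the conventional deviance difference Δ(−2 ln L) co-reported. The decision
rule compares the primary statistic to a fixed critical value, 3.84 by
default — the χ²(1) quantile customarily printed with such tables even
though H2 adds two parameters. `df_convention` records this without
resolving it; users calibrating sizes should refer Δ(−2 ln L) to χ²(2).
Under an order-1 truth the test is anticonservative by construction, which
is documented rather than corrected, for fidelity to the field's
convention.

## Increment-ratio-by-age check

MIR comparability across ages assumes bands keep a roughly constant
proportion through life. `increment_variability` computes
IR_i = GI_i/GI_{i−1} × 100 per individual, averages within age class
(per-individual regression is available via the raw IR table), and fits
OLS of mean IR on age with the slope F test on (1, k−2) df. Both plain and
adjusted r² are reported; the adjusted value can be negative for a
non-informative fit.

## Synthetic data

`synthetic_data.simulate` draws ψ_obs = ψ_curve(t)·exp(ε),
ε ~ N(0, σ_log²), at a configurable per-month sampling effort (uneven
monthly counts emulate commercial-capture sampling). This matches the
likelihood's error structure exactly, so recovery and coverage experiments
measure the estimator under correct specification. Defaults: 25 records
per month (n = 300), σ_log = 0.05 — a clean validation series. What the
generator does **not** emulate: individual sawtooth MIR trajectories and
their asynchrony, year effects, age-dependent noise, reader error, and the
much larger dispersion (log-sd ≈ 0.3–0.8) of real MIR series. Passing
recovery tests therefore demonstrate correctness of the estimator, not
robustness to real-data misspecification.

## Verified properties

The test suite checks, among others: the objective against a literal
term-by-term transcription (10⁻¹⁰ relative); the nesting inequality
(−2 ln L)_H2 ≤ (−2 ln L)_H1 over 50 simulated datasets; order-1 extreme
separation of exactly γ/2; median relative bias of every parameter below
2 % over 100 replicates at n = 300, σ_log = 0.05; and ≥ 90 % coverage of
the true γ by the 95 % profile interval over 200 replicates. These sizes
were chosen to make Monte-Carlo error small relative to the thresholds
while keeping the default suite fast.

`scripts/acceptance.py` additionally exercises the full pipeline at the
two published study conditions (annual-cycle truths at sample sizes 89 and
183 with log-noise derived from the published objectives), averaging the
refit objectives, LRT and γ estimates over 10 replicate datasets because a
single dataset's fitted objective inherits an ~10 % spread from the
realized noise variance.

## Known limitations

- The raw per-individual records of the two geoduck case studies are a
  supplementary spreadsheet of the source publication and are not
  redistributed; the reproduction tests that need them look for
  `data/s1_table_a.csv` / `data/s1_table_b.csv` and fail with instructions
  otherwise.
- Whether the published observation count in the objective refers to the
  replicated or original records is not documented there; both are
  supported (`FitConfig.replicate`), replicated is the default, and
  `n_used` is always reported.
- Records with MIR ≤ 0 are excluded at load time (log undefined); a
  dataset dominated by zero marginal increments needs a different error
  model.
- No random effects: individuals are treated as exchangeable within month.
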