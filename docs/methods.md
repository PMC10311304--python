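# Methods

## Model and assumptions

Measurements are percentages on a normalized inhibition scale: the dose-zero
base value is B (100 under the DREAM convention) and stronger drug effect
drives the expected response toward 0, so "Einf = 0" means a maximally
effective drug. Responses are conditionally independent given the dose, with
homoscedastic Gaussian noise (s.d. σ). Replicates are treated as distinct
points; no plate or edge effects are modelled.

Monotherapy follows the four-parameter Hill equation E(x) = E0 +
(E1−E0)/(1+(C/x)^H). The dose-zero value is defined as E0 by the limit
convention rather than computed arithmetic, so x = 0 never divides by zero.
Two-drug combinations follow the detailed-balance surface (the most general
response surface that still honours the mass-action equilibrium between
unaffected and affected cell populations). Its four asymptote levels E0, E1,
E2, E3 are the expected responses at dose (0,0), (∞,0), (0,∞) and (∞,∞); the
association parameter α scales the joint-dose term, so α > 1 means each drug
increases the apparent potency of the other. The surface reduces exactly to
each drug's Hill curve on the monotherapy slices, and α has no effect there —
both identities are enforced by property tests to machine precision.

## Priors

| parameter | prior | rationale |
|---|---|---|
| E0 | Normal(B, variance 0.03·B) | the normalization itself is noisy; at B=100 the s.d. is √3 ≈ 1.73 ("variance" is read literally) |
| Ei/E0 | Uniform(0,1) or Beta(0.46, 0.58) | uninformative, or an empirical option reflecting that maximal effects in single-agent screens pile up near 0 and 1 |
| log C | Uniform(log δ, log M) | uninformative over the plausible IC50 range; IC50s outside the tested dose window are admitted a priori |
| H, σ, α | lognormal(0, 1) | positive, moderately small; gives P(H<5) ≈ P(σ<5) ≈ 0.95 and prior median α = 1 (no potency interaction) |

The efficacy priors are placed on the ratios Ei/E0 hierarchically (draw E0,
then the ratio), so densities expressed in Ei carry a 1/E0 Jacobian.
`log_prior_*` return densities with respect to the coordinates
(E0, Ei, log C, H, σ, α), matching the factorization above.

Defaults for the IC50 bounds are δ = 1e-10, M = 1e6 when no dataset is in
scope; given a dataset, δ is half the smallest non-zero dose and M ten times
the largest dose, which keeps δ below every tested dose and M above all of
them. Bounds are stored on the raw dose scale; natural logs are used
throughout. Responses are modelled on the raw 0–100-ish scale rather than
rescaled to [0,1], since B is configuration and all reporting is in response
units.

## Posterior sampling

Sampling runs on an unconstrained reparameterization — identity for E0, logit
for each Ei/E0, log for C, H, σ and α — so every draw satisfies the parameter
constraints by construction. The backend is emcee's affine-invariant ensemble
sampler with a move mixture of 50% stretch, 30% differential evolution and
20% DE-snooker; the mixture was chosen because stretch moves alone mix slowly
through the posterior's flat directions (an IC50 the dose window cannot
resolve) while DE moves alone stall on the well-identified posteriors.

Each requested chain is an independent ensemble of 2·ndim+2 walkers (12 for
monotherapy, 22 for combinations) initialized from prior draws. The default
configuration is 4 chains × 1000 iterations with 500 warm-up iterations, i.e.
2000 retained draws; one walker state is stored per post-warmup step, cycling
through walkers, so the stored draw count is exactly chains × (iterations −
warmup). `thin` (default 2) runs that many internal ensemble steps per
retained iteration — backend tuning that buys effective sample size without
changing the bookkeeping. A default combination fit takes a few seconds on
one CPU.

Convergence is *reported, never enforced*: rank-normalized split R-hat and
ESS per parameter (arviz), with a `converged` flag at R-hat < 1.05 and
ESS ≥ 100 — conventional thresholds, not model content. Posteriors dominated
by the flat IC50 prior (doses far from C) legitimately mix slowly and may be
flagged; their intervals are wide, which is the honest answer, and the
simulation-based calibration below confirms the intervals remain trustworthy.
Single-chain runs report "insufficient chains" instead of a cross-chain
R-hat.

## Synergy summaries

ΔHSA = min(E1, E2) − E3 and log α are computed per posterior draw, so the min
is taken inside the joint posterior, never on marginal summaries. Reported
probabilities are exact empirical fractions of draws with ΔHSA > 0 and α > 1
(strict inequalities; ties count as non-synergistic; no kernel smoothing on
the numeric path). Parameter tables give the median and central 95% interval;
IC50s are summarized on the log scale and exponentiated (quantiles commute
with the monotone map).

## Prediction and calibration

The predictive density for an unseen response is the Monte-Carlo mixture over
all retained draws — a Gaussian mixture, never a single Gaussian at the
posterior-mean parameters. Point predictions are posterior-predictive means.
The summary "test log-likelihood" is the **mean** per-point log predictive
density; the per-point vector is retained so a sum convention can be
recovered. Calibration uses the full mixture CDF as the probability integral
transform (the predictive distribution is continuous, so no randomized PIT is
needed), tested for uniformity per combination with a one-sample
Kolmogorov–Smirnov test (scipy's p-value, exact at small n; the 5% level
flags miscalibration). Pooling PIT values across combinations is available
but is an extension beyond the per-combination protocol.

Split protocols: for 6×6 matrices, 7 of the 35 non-zero-dose points are held
out — exactly one from each 5-point monotherapy slice plus 5 of the 25 grid
points, so every monotherapy retains a test measurement; for 15-point grids,
3 points are held out with no slice constraint (the slices are too small).
The dose-zero base point is never eligible for testing. Splits are seeded
index draws without replacement and serialize as index lists. A fingerprint
of the training data travels with each posterior, and evaluation refuses a
split whose training set does not match (contamination guard).

## Synthetic data

The generator draws responses from the model itself: surface mean plus
Gaussian noise at every cell including the base cell. It emulates the two
screen layouts (6×6: 1 base + 2×5 monotherapy + 5×5 grid; ALMANAC: 1 base +
2×3 + 3×3) with 5- or 3-point log-spaced dose ladders. With an explicit
ground truth the ladder is centred on each drug's IC50 (±1.5 decades), making
identifiability controllable — an "unsaturating" fixture with all doses below
C/30 reproduces the wide-Einf regime by design. With truths drawn from the
prior, a fixed ladder spanning 10^-1.5–10^1.5 is combined with the
dose-derived bounds rule so the generating and fitting priors coincide, the
precondition for exact simulation-based calibration. Negative simulated
responses are kept (the noise model allows them); only the CSV loader applies
the real-data rule of rejecting negative measurements — a deliberate
asymmetry.

What the generator does **not** emulate: plate/edge effects, replicate
correlation, heteroscedastic noise, non-Hill response shapes, or
growth-stimulating (response-enhancing) scales. Passing calibration tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to real-screen artefacts.

## Test problem sizes and numerical choices

The simulation-based calibration suite uses 50 prior-drawn 6×6 matrices with
the default sampler settings, checking that 90% credible intervals for
log C1, log C2, log α and E3 cover the generating values within binomial 95%
noise of 90%, and that per-matrix PIT/K-S rejections at the 5% level stay
within binomial noise of 5%. The acceptance script runs a 20-matrix version
of the same loop plus single-fit round trips. Tolerances: algebraic
identities at 1e-10 relative error; density oracles at 1e-8; Monte-Carlo
checks at binomial/K-S noise levels with fixed seeds. Overflow in the surface
weights is prevented by normalizing the four exponents by their maximum
(log-sum-exp style), and Hill fractions use expit of H·log(x/C), exact at
x = 0.

## Known limitations

Only two-drug combinations are modelled. The Beta efficacy-prior shape
(0.46, 0.58) is taken as a fixed empirical constant, not refit. Ensemble MCMC
is less efficient than gradient-based samplers on these posteriors; strongly
prior-dominated fits can carry convergence flags even though their credible
intervals are calibrated. The K-S uniformity test has low power at 7 test
points per matrix — persistent miscalibration shows up across a screen, not
reliably in a single matrix.
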