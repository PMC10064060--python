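# Methods

This note documents the generative models, estimators and numerical choices
behind `resst`, and what the synthetic-data tests do and do not establish.

## Task model

A session is a sequence of trials, each belonging to one cue condition
(Go+, Neutral, Stop+) and one trial type (go or stop). Schedules use exact
counts, not i.i.d. draws: a 600-trial test block contains exactly 140 go
and 60 stop trials per condition in seeded random order. Exact counts make
the design (and every test built on it) deterministic given a seed while
preserving trial-order unpredictability; a configuration whose fractions do
not yield integer counts is rejected rather than rounded.

Stop trials in each condition carry their own one-up/one-down staircase:
SSD starts at 50 ms, moves up 50 ms after a correct stop and down 50 ms
after a failed stop, clamped to [50, 1000] ms. Rewards follow the
condition's schedule for correct trials (Go+: 30/5 points for go/stop;
Neutral: 17/17; Stop+: 5/30); all failures score 0. Time is integer-valued
milliseconds in the engine; the RT limit is 1.5 s (a slower go response is
recorded as a go omission), the cue→go delay is uniform on [900, 1200] ms,
and the inter-trial interval (500 ms) affects only simulated timestamps.
A response on a stop trial before the RT limit is a failed stop regardless
of which key was pressed. Test-phase staircases are re-initialized at
50 ms by default; `run_session(initial_staircases=...)` allows carrying
states over from a learning block, since the original procedure is silent
on this point.

## Race agent and cohort

The independent-race agent draws a go finish time T_go per trial from a
per-condition ex-Gaussian (mu, sigma, tau); on stop trials it responds iff
T_go < SSD + SSRT_c. The ex-Gaussian is the standard parametric surrogate
for RT distributions and can match any printed mean/SD pair; context
independence — the hallmark assumption of the horse race — holds by
construction because the T_go law never depends on the SSD. Attentional
lapses (p_go_omission, default 0.02), choice errors (p_choice_error,
default 0.01), stop trigger failures (default 0; the knob exists to
stress-test the SSRT estimator, which ignores them) and trial-to-trial
SSRT noise (default 0) are optional.

The shipped template sets mu = 484/517/551 ms, sigma = 110 ms, tau =
135 ms (so condition means mu + tau = 619/652/686 ms, within-subject trial
SD ≈ 174 ms) and SSRT = 230/253/230 ms for Go+/Neutral/Stop+. Between-
subject heterogeneity is Gaussian per parameter with resampling to respect
invariants: a shared speed offset on mu (SD 55 ms) plus small independent
per-condition jitter (SD 12 ms), sigma 15 ms, tau 20 ms, SSRT 20 ms. The
shared-offset structure keeps each subject's condition ordering intact —
the within-subject pattern the analysis chain is meant to detect — while
producing realistic subject scatter; the magnitudes are the package's own
choice (no subject-level dispersion is published for this design beyond
condition SD/SEM values, which mix subject and trial variance).

A 14-subject cohort simulated from these defaults lands within a few ms of
the target condition means (617/655/689 ms observed at seed 42), with all
subjects inside the p(respond) inclusion window.

## Staircase tracking and its finite-sample bias

The one-up/one-down rule converges on the SSD where p(respond | SSD) =
0.5. Over a whole cold-started session, however, the raw failed-stop
proportion is systematically below 0.5: the staircase must climb from
50 ms to its equilibrium (~350–420 ms here, i.e. ~6–8 net up-steps), and a
net up-step costs exactly half a failed stop, so with 60 stop trials per
condition the expected raw proportion is ≈ 0.45. This is a property of the
procedure, not a bug; it affects any cold-started tracking run of this
length. The package therefore exposes two quantities:

- `p_respond` (subject summaries): the raw proportion over all stop
  trials — the quantity a study tabulates and feeds into the inclusion
  window and the SSRT estimator;
- `long_run_stop_failure_rate`: the stationary tracking rate, estimated
  after discarding the first half of each staircase's stop trials
  (half-chain burn-in). Once both endpoints of the retained stretch are
  stationary, up- and down-steps balance exactly and the estimator is
  unbiased for the 0.5 tracking point; simulated sessions give
  49.6–50.1%.

## SSRT by the integration method

For one subject × condition: build the go RT list including choice-error
RTs (they are committed responses of the go process; the estimator's
consensus usage includes them), replace each go omission by the maximum
observed go RT (an omission is an arbitrarily slow go finish), sort, take
the order statistic at rank ⌈p(respond)·N⌉ (clamped to [1, N], no
interpolation — ties in printed RT resolution make interpolation spurious
precision), and subtract the mean SSD over all presented stop trials (no
burn-in trimming, matching how mean SSD is tabulated). The estimate is
undefined and flagged when p(respond) is 0 or 1.

Under the staircase the estimator is remarkably robust to the cold-start
transient: the downward bias of mean SSD and the downward shift of the
p(respond) quantile nearly cancel. Simulating 50 template subjects through
full sessions, the median estimated SSRT lands within a few ms of the
generating 230/253/230 ms (the recovery test allows ±15 ms).

## Subject screening

Three screens, any failure excluding the subject:

1. **SSD unimodality.** Hartigan's dip statistic — half the maximum
   deviation between the empirical CDF and the closest unimodal CDF — is
   computed exactly with the greatest-convex-minorant / least-concave-
   majorant algorithm (validated to 1e-7 against a linear-programming
   oracle that encodes the definition directly). Significance comes from a
   1,000-sample bootstrap against the uniform null, the conventional
   least-favorable reference; the p-value is the proportion of null dips
   at least as large as the observed one. Because staircase SSDs live on a
   50 ms grid, ties alone would push every sample's dip past the
   continuous null's critical value (≈ 0.13 observed from ties vs ≈ 0.065
   critical at n = 60); screening therefore dequantizes SSDs with seeded
   uniform jitter of ± half a step before the test — the standard
   continuity correction for discrete data. With it, clean staircase runs
   essentially never reject while sessions whose equilibrium shifts
   mid-run (bimodal trajectories) reject reliably. RT dip tests are
   reported but do not drive exclusion.
   Note the dip is invariant under affine increasing transforms but *not*
   under general monotone transforms — convexity is not order-determined
   ({1, 2, 4, 5} has dip 1/6, its log 1/8).

2. **Race-model independence.** The independent race implies failed-stop
   responses are the fast tail of the go distribution, so mean failed-stop
   RT must be strictly below mean go RT in every condition. Equality fails
   (conservative strictness); a condition without failed stops is "not
   evaluable" and does not fail the subject.

3. **p(respond) window.** Every condition's raw failed-stop proportion
   must lie in the closed interval [0.35, 0.65].

Null tables are shared across subjects with equal sample sizes, so
screening is order-independent and much faster than per-subject
bootstraps.

## Classical inference

The repeated-measures ANOVA is the textbook two-way decomposition
(SS_subjects + SS_conditions + SS_error), F = MS_cond/MS_error with
uncorrected df (k−1, (k−1)(n−1)); partial eta squared is
SS_cond/(SS_cond + SS_error) and Cohen's f = √(η²ₚ/(1−η²ₚ)). No sphericity
correction is applied by default (matching the uncorrected-df reporting
convention); Greenhouse–Geisser is available behind a flag. Tukey–Kramer
post-hocs use the studentized range with MS_error and df_error from the
within-subject decomposition. First-level (per-subject) tests between two
conditions are Welch two-sample t-tests on trial-level RTs: trial counts
differ between conditions within a subject, so the samples cannot be
literally paired; the construction is pluggable via `stats`.

## Bayesian population prevalence

With k of n subjects significant at first-level rate α, and first-level
sensitivity taken as 1 for effect-bearing subjects, a subject is
significant with probability θ = α + (1−α)γ where γ is the population
prevalence. Under a uniform prior the posterior density on γ ∈ [0, 1] is
∝ θᵏ(1−θ)ⁿ⁻ᵏ; the MAP has the closed form max(0, (k/n − α)/(1−α)).

HPDIs are computed by a water-level search: for a level c the super-level
set of this unimodal-or-monotone density is an interval; endpoints are
bracketed on a grid and polished by Brent root-finding, interval mass is
evaluated by adaptive quadrature, and the level is solved so the interval
holds exactly the requested mass. This machinery (rather than equal-tail
logic) matters because the density is monotone when k = n or k = 0; for
k = n the lower endpoint agrees with the closed-form tail solution
((1 − m(1 − α^{n+1}))^{1/(n+1)} − α)/(1 − α) to ~1e-9. MAP/HPDI are
reported at 2 dp in human-readable summaries and at full precision in
JSON.

## Diffusion model

The go decision is a Wiener process between absorbing boundaries 0 and a,
start z, drift v, within-trial noise s = 0.1 (Ratcliff scaling
convention), with across-trial variability: drift ~ N(v, η), start
uniform on z ± sz/2, non-decision time uniform on Ter ± st/2. RT =
first-passage time + non-decision time; upper boundary = correct
response.

**Simulation** (agents) uses vectorized Euler–Maruyama. Noise is always
generated at a fixed base resolution (0.05 ms) and aggregated to the
requested step, so halving the step refines the *same* Brownian paths —
the standard strong-convergence construction; a one-pass coupled
simulator steps both resolutions on shared increments, making the
discretization check (quantile shift < 1 ms between dt = 0.1 ms and
0.05 ms) nearly noise-free. Boundaries are shrunk by the Siegmund
continuity correction 0.5826·s·√dt to remove the leading discrete-
observation bias; the simulated absorption probability then matches the
closed form (1 − e^{−2vz/s²})/(1 − e^{−2va/s²}) within Monte-Carlo error.

**Fitting** (ddm) is quantile-based: correct RTs per condition are binned
at their 0.1/0.3/0.5/0.7/0.9 quantiles (6 bins); error RTs get their own
quantile bins when at least 5 errors exist, otherwise a single pooled
error bin (errors are sparse under realistic accuracy). Predicted bin
probabilities come from the classical large-time eigenfunction series of
the defective first-passage CDF (term count chosen adaptively so the
truncated tail is < ~1e-10 at the earliest bin edge), with η integrated by
11-node Gauss–Hermite and sz/st by 11-node Gauss–Legendre quadrature; the
defective masses over both boundaries sum to 1 within 1e-6 and are stable
to < 1e-4 under node-count refinement. The search objective is the
percentile χ² (Σ(O − Np)²/Np, predictions floored at 1e-10) by default or
the multinomial log-likelihood Σ O·ln p; **BIC is always computed from the
multinomial log-likelihood at the optimum**, with m = number of free
parameters and N = total trial count across conditions.

Three cue-bias variants share a, Ter and η across conditions: `both_free`
(z and v per condition, 9 free parameters), `v_only` (7) and `z_only`
(7); sz = st = 0 unless explicitly enabled (which of the variability
parameters the original fits freed is not documented; fixing the two
uniform ranges keeps the problem well-conditioned at a few hundred trials
per condition). Optimization is Nelder–Mead in a transformed space
(log a, log Ter, log η, logit z/a, raw v) from an EZ-style moment-based
initial point plus seeded perturbed restarts (5 by default, ~800
iterations each); the best restart is kept and a convergence flag
reported. At 500 trials/condition the cue-bias structure (the z ordering)
is recovered reliably, while a, η and v trade off along a ridge —
parameter-level agreement there should not be over-read.

Model comparison is per-subject argmin BIC plus cohort BIC sums;
`zscore_params` standardizes a per-condition parameter across subjects
(zeros under zero variance), and `friedman_on_params` runs the Friedman
test across conditions, returning None for a parameter the variant shares
across conditions.

## Reproducibility

Every stochastic function takes an explicit seed or Generator; there is no
hidden global RNG state. The pipeline spawns per-stage child seeds from a
single root via `SeedSequence`, so one integer reproduces a whole study,
and reruns are bit-identical.

## What the synthetic data do and do not establish

The generators reproduce the *structure* the analyses assume: an
independent race with context independence, condition-ordered go RT
distributions, tracking staircases, and (for the diffusion branch) a
starting-point cue bias. They are stationary within a session — no
learning, fatigue, sequential dependencies (e.g. post-stop slowing), or
reward-history effects — and use parametric RT families (ex-Gaussian,
diffusion first-passage) that real data only approximate. Passing the
recovery suites therefore shows the estimators and the pipeline are
correct and well-calibrated *under the model's own assumptions*; it does
not certify behavior on data that violate them (trigger failures and SSRT
noise knobs exist precisely to probe such violations). Real-cohort
quantities (specific F values, condition means, BIC sums) depend on 14
particular humans and are not reproduction targets; the analytic
quantities (prevalence summaries, effect-size conversion, design counts)
are reproduced exactly.

## Problem sizes in the shipped tests

Monte-Carlo checks use the largest sizes that keep the default suite
practical on one CPU: race-agent distributional checks at n = 2×10⁴–10⁵
draws, diffusion simulator gates at n = 3×10⁴ trials with 3-SE bounds
(standard errors scale accordingly), SSRT recovery over 50 simulated
subjects, staircase tracking over 20 sessions, dip-test calibration over
1,000 replicates of n = 200 against a 2,000-sample null table, z-ordering
recovery over 20 fits and model recovery over a 14-subject cohort
(3 variants each). The full suite runs in roughly a quarter hour.
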