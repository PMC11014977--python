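# Methods

This note documents the models, the numerical choices, and the synthetic
data conditions the package uses, including what the simulations can and
cannot establish.

## Task engine

`build_schedule(n_trials, init_len, comp_len, coop_len, start_mode)` lays
out an initialization run followed by strictly alternating competitive and
cooperative blocks, truncating the final block to hit `n_trials` exactly.
The default (163, 5, 13, 10, competitive-first) is the study-shaped design;
163 is not a multiple of a 13+10 cycle, so truncation is unavoidable and
the competitive-first ordering is a configurable choice.

The adaptive agent estimates the probability `p` that the participant picks
card 1 from running conditional frequencies keyed by the last two
(choice, outcome) pairs, with add-one smoothing, falling back to the
one-trial context and then to the marginal frequency when a context is
unseen; an empty history yields `p = 0.5`.  This estimator is a deliberate
minimal design: it uses exactly the two-trial information window the task
prescribes, it is label-symmetric (relabeling cards flips `p` to `1 − p`),
and it is exposed as an ordinary class so a different predictor can be
substituted.  The AA then plays card 1 with probability `p` in cooperative
mode, `1 − p` in competitive mode, and `0.5` during initialization.
Sessions use simultaneous-move semantics and one RNG stream keyed by
(subject id, seed), so every session is bit-reproducible.

## Experts and the controller

The influence expert updates its opponent-choice estimate as

```
p_opp ← clamp[0,1]( p_opp + η·(1[aa=1] − p_opp) + s·κ·(1[self=1] − q_self) )
q_self ← q_self + η_self·(1[self=1] − q_self)
```

with `s = +1` (cooperative) or `−1` (competitive) the only difference
between the experts, and `η_self` tied to `η` by default.  The second term
is the mentalizing component: `q_self` is the opponent's presumed estimate
of the participant's own policy, and `κ` scales how strongly one's own
(surprising) action is expected to attract (cooperative) or repel
(competitive) the opponent's next move.  Values are match-payoff based
(`V₁ = p_opp·R`, `R = 1`), so both options' values move every trial —
unlike plain RL, which touches only the chosen option.

Reliability is decisiveness, `|V₁ − V₀|`, not accuracy.  The controller
passes the reliability difference through `ω = σ(slope·(Δ − δ))`, mixes the
experts' values by `ω`, and emits choices through a shared softmax.  Trial
classification uses the sign of `Δ − δ` (ties competitive); a `Δ`-only
variant is available via `use_bias_in_classification=False` because the
two conventions appear in different analysis contexts and the
bias-adjusted form is the one tied to the individual-difference parameter.

The depth-1 theory-of-mind experts simulate the opponent as a level-0
Gaussian-approximate Bayesian observer of the participant's own choices
(log-odds tracker with volatility `vol`, Laplace updates with a
three-step Newton mode search, probit-moderated predictions), best-responding
softly under a hard-coded cooperative or competitive payoff tag.  Tests
verify the tracker against exact grid-integration Bayes to within 0.02 on
short sequences.  The generic mixture wrapper arbitrates over any expert
pair exposing `values()`/`update()`, which is how both the influence
mixture and the 1-ToM mixture are built from one controller implementation.

## Fitting and model evidence

Parameters live on unconstrained scales (logit for rates and probabilities,
log for positive magnitudes, identity for the bias) with independent
Normal(0, 3²) priors — wide enough to be effectively uninformative over the
behaviorally meaningful range.  MAP estimation uses multistart L-BFGS-B
(default 8 starts: the prior mean plus standard-normal draws), and the log
model evidence is the Laplace integral at the mode,
`F = log p(y, θ̂) + (d/2)·log 2π − ½·log|−H|`, with a central
finite-difference Hessian (step 1e−4) and eigenvalue clipping (flagged)
when a direction is flat.  This choice approximates a full variational
scheme at its Laplace limit and is accurate at desk scale: on the one-
parameter bias model, `F` sits within ~0.02 nats of adaptive quadrature,
and the evidence is exactly invariant under linear reparameterization.
Per-trial choice probabilities are floored at 1e−9, so every model returns
a finite likelihood for any input.

Group-level selection follows the standard variational random-effects
scheme: responsibilities are softmaxes of `F` plus digamma terms, Dirichlet
concentrations accumulate them (`α₀ = 1`), and iteration stops at
`Δα < 1e−6`.  Exceedance probabilities use the exact Beta form for two
models and seeded chunked Monte Carlo otherwise (default 10⁷ draws).  The
omnibus risk compares the variational free energy of the random-effects
model against the equal-frequency null, and `pEP = EP·(1−BOR) + BOR/K`.

## Panel regressions

The covariate builder defines, for trial `t`: stay/switch, lagged wins and
switches (`t−1..t−3`), and the lagged cooperativity signature of the AA —
1 when the AA stayed after the participant's win or switched after the
participant's loss (equivalently: the AA landed on the participant's
previous card).  Analysis rows start at trial 6, so the initialization
trials are excluded and every lag is defined.

The panel logit is a random-intercept model estimated by maximum likelihood
with Gauss–Hermite quadrature (12 nodes by default; 40 nodes reproduce an
adaptive-quadrature oracle to ~1e−5), with cluster-robust sandwich
covariance (per-cluster score outer products with a G/(G−1) correction).
With a single cluster the random-intercept SD is not identified and is
pinned near zero.  Marginal effects are average marginal effects — the mean
discrete change in the marginal predicted probability for binary
covariates, the mean derivative otherwise; a literal
`mean(logit⁻¹(w))` form is kept behind `literal=True` for comparability,
but it is not the default because it returns 0.5 for a null effect.
The linear panel regression uses OLS with the same cluster-robust
covariance (coefficients are their own marginal effects), and collinearity
is screened with variance inflation factors (warning above 5).  Perfect
separation and singular designs raise explicit errors naming the columns.

## Synthetic populations

Per-subject parameters are drawn from normal distributions on the
unconstrained scale.  The defaults define the study conditions and were
calibrated once, then frozen, to the task's documented operating point:
win rates clearly above chance in cooperative and below chance in
competitive blocks, roughly half of trials classified competitive, a
decisively recoverable mixture model at the group level, and replayed
single experts whose stay probabilities bracket one half.  For the
mixed-intentions model the means correspond to `η ≈ 0.27`, `κ ≈ 0.6`,
`β ≈ 3.5`, `slope ≈ 12`, `δ ≈ 0.1`.

These targets are in tension in one respect worth knowing about: in a
binary matching game, tracking the opponent's choice is informationally
equivalent to tracking one's own reward, so the mentalizing weight `κ` is
the only signal separating influence learners from plain RL.  Regimes with
small `κ` and soft choices produce the subtle lag-1 behavioral signatures
seen in humans but make the mixture unidentifiable; regimes that make the
mixture decisively recoverable strengthen the win-stay component enough
that the lag-1 cooperativity-signature effect on staying reverses sign,
and classification aligns so well with the true blocks that block-type
regressors inherit the prediction-error interaction.  The frozen defaults
sit at the identifiable end; the corresponding regression-direction checks
in the acceptance tests document the discrepancy rather than hide it.  The
raw form of the signature — staying after a negative prediction error is
far more likely on cooperative-classified than competitive-classified
trials — holds robustly in either regime.

Replay analyses follow the generative design: a study-shaped population is
simulated, the model of interest is fitted to it, new parameter sets are
drawn from the fitted population mean/SD, and each draw is replayed against
the stored AA choice sequences as a non-contingent opponent.  Stand-alone
replay banks are produced from lapsing win-stay/lose-switch agents played
against the live AA; both are synthetic stand-ins for deposited opponent
sequences and are documented as such so real sequences can be swapped in.

## Problem sizes and determinism

The recovery analyses default to the study-scale designs (20 subjects per
generator for model recovery; 50 replicates at 158 trials for parameter
recovery; 310 replayed datasets for the generative analyses) with 6
optimizer restarts in the batch analyses and 8 for single fits.  Every
stochastic step is seeded: sessions from (subject id, seed), populations,
banks, and Monte Carlo draws from dedicated child streams, so all outputs
are reproducible from a configuration plus one integer.

## Known limitations

- The adaptive agent's predictor and the expert update rules are minimal
  well-defined stand-ins for richer published variants; both are pluggable.
- The evidence approximation is MAP + Laplace, not a full variational
  posterior; strongly multimodal posteriors would be summarized by their
  best mode.
- Simulated populations are more internally consistent than human data
  (no lapses, fatigue, or reaction-time structure), so passing recovery
  tests bounds what the *method* can do under the design, not what any
  human dataset will show.
- The linear panel model is pooled OLS with cluster-robust errors rather
  than a random-intercept GLS; with the balanced panels used here the
  coefficient differences are negligible.
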