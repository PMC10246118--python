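# Methods

This note documents the model, the algorithmic choices and their
rationale, the synthetic systems used for verification, and the known
limitations. Notation: `z_t ∈ R^L` latent state, `y_t ∈ R^N`
observation, `λ` natural parameters, `μ = ∇A(λ)` mean parameters,
`A(λ)` the log-partition function.

## Model class and assumptions

The filter operates in a single *minimal, constant-base-measure*
exponential family per run. Minimality makes `λ ↔ μ` a bijection;
a constant base measure is what makes the variational prediction step
close in the family (the mixture `E_{q_{t-1}}[p_θ(z_t|z_{t-1})]` has a
log-density whose `z_t`-dependence is `λ·t(z_t)` up to normalisation
only when `h` does not depend on `z`). Shipped families:

* **Gaussian** (full covariance). Sufficient statistics
  `t(z) = (z, vech(zz^T))`. Storage: `[η₁, vech₂(Λ₂)]` with
  `η₁ = P⁻¹m`, `Λ₂ = −½P⁻¹`, where `vech₂` doubles the off-diagonal
  entries. This convention makes three things exact simultaneously:
  `λ·t(z)` equals the quadratic form, `μ = ∇A(λ)` holds coordinate-wise
  in the stored layout (verified by finite differences), and the
  conjugate Gaussian-likelihood increment `(C^T R⁻¹(y−b), −½C^T R⁻¹C)`
  is literally a vector addition.
* **Continuous Bernoulli**, factorised on `[0,1]^L`, `t(z) = z`. The
  normaliser `A(λ) = log((e^λ−1)/λ)` and its first three derivatives
  are evaluated by series for `|λ| < 10⁻⁴` (the closed forms are 0/0
  there) and by `log1p/expm1` forms elsewhere; sampling is inverse-CDF.
  The inverse mean map is a safeguarded Newton iteration (relative
  tolerance 10⁻¹², ≤100 iterations, bisection fallback in the saturated
  tails).
* **Gamma**, factorised on the positive orthant, `t(z) = (log z, z)`,
  naturals `(α−1, −β)`. The inverse mean map solves
  `log α − ψ(α) = log E[z] − E[log z]` by Newton from the standard
  closed-form starting point.
* **Bernoulli** (discrete), used for conjugacy and duality tests.

Positive-definiteness of Gaussian precisions is enforced with a
*relative* eigenvalue test (`λ_min > 10⁻¹⁰ λ_max`) plus an explicit
Cholesky attempt; violations raise, never silently project. The
relative test admits well-conditioned but tiny-scale matrices (e.g.
near-deterministic dynamics `Q → 0` limits used in tests).

## The per-step recursion

**Predict.** `λ̄ = E_{q_{t-1}}[λ_θ(z)]`, exact for linear-Gaussian
dynamics, otherwise a Monte-Carlo average over `n_mc_predict = 64`
draws (default; the second natural-parameter block is deterministic for
fixed-`Q` Gaussian dynamics, so the MC error concentrates in the mean
block). Averaged naturals are validated against the family's domain;
an excursion raises with diagnostics.

**Correction.** For Gaussian families the predicted covariance is
inflated by `M P M^T`, `M = ∂m_θ/∂z` at the previous mean — for linear
dynamics this reproduces the Kalman prediction exactly (tested to
10⁻¹² and relied on by the Kalman-equivalence tests). For CB/Gamma
families no exact recipe exists; the implemented extension matches the
predictive marginal variance to a law-of-total-variance Monte-Carlo
estimate (moment matching for Gamma; variance-only widening for CB,
whose single parameter cannot hold the mean fixed). The non-Gaussian
correction is off in the CB experiments below.

**Update.** Gaussian latent + Gaussian likelihood uses the conjugate
increment. Everything else uses CVI with default damping `β = 0.5`
and 10 iterations: `λ ← (1−β)λ + β(λ̄ + g)` where `g = ∇_μ E_q[log
p(y|z)]` expressed in the natural layout. Closed forms are implemented
for Gaussian/Gaussian (one exact step), Gaussian/Poisson
(`E[e^{c^T z}] = e^{c^T m + ½c^T P c}`), and CB/Gaussian (uses `A''`
and `A'''` of the CB normaliser to convert `∇_λ` to `∇_μ`). Steps that
leave the natural domain are backtracked (halve `β`, ≤20 times). The
Poisson expected rate caps its exponent at 30: beyond that the rate is
astronomically unphysical, the gradient carries no usable information,
and the uncapped value only overflows the update.

**Learn.** With `λ*` fixed (no gradient flows into it), `steps`
gradient updates are taken on one of two objectives, both evaluated on
fresh draws `z ~ q_{t-1}` (which does not depend on `θ`, so plain
backpropagation through `λ_θ` is the exact pathwise gradient):

* `loss = "natural"`: `½‖λ* − λ̄_θ‖²`. For a natural-parameter map
  flexible enough to reach `λ̄_θ = λ*` this shares its optimum with the
  KL objective below, and its gradient is cheapest.
* `loss = "mean"` (default): `KL(q(·;λ*) ‖ q̄(·;λ̄_θ))`, whose gradient
  in `λ̄_θ` is the mean-parameter residual `μ(λ̄_θ) − μ(λ*)`. For
  *restricted* model classes the two objectives differ materially: with
  a linear map and fixed `Q`, the first natural block of `λ*` is scaled
  by the posterior precision while `λ̄_θ`'s is scaled by `Q⁻¹`, and the
  squared loss then has a badly biased fixed point (we observed the
  recovered transition coefficient drifting far above its true value,
  even diverging). The KL objective's fixed point is the regression of
  posterior means, which is self-consistent; it is therefore the
  default.

Optimisers: Adam (MLP dynamics) and SGD (linear dynamics), each with an
optional Robbins–Monro `1/√t` step-size decay. The decay matters for
*static*-parameter estimation: with a constant step, parameter noise
feeds back through the filter and attenuates the estimate (in the
scalar recovery study, constant-rate estimates settle 5–10% below the
truth; with `0.05/√t` SGD the estimate lands within 0.05 of the true
0.9 on every tested seed). The optimiser state additionally tracks a
Polyak-style suffix average of the parameters (restarted at
power-of-two step counts, so it always spans roughly the latest half
of the run); for static linear parameters the averaged estimate
roughly halves the worst-case seed-to-seed error relative to the last
iterate and is what `apply_averaged_theta` reports. Defaults for MLP dynamics: Adam at
`10⁻²/√t`, one step per observation, batch 64.

`Q` (Gaussian state noise) is optionally trainable through a
lower-triangular Cholesky factor with softplus diagonal. Trainable `Q`
doubles as *adaptive process noise*: while the mean map is still wrong,
the mean-matching gradient grows `Q` to cover the unexplained
prediction error, which keeps the filter honest enough to track from
observations; as the mean map improves, `Q` shrinks back toward the
posterior-error floor. This bootstrap is what makes learning from a
randomly initialised network work in the Van der Pol study (with fixed
small `Q` the overconfident filter never tracks, the learning targets
stay poor, and the model never improves).

**Initial posterior** `q(z₀)`: standard normal (Gaussian), `λ = 0`
i.e. uniform (CB), shape 2 / rate 2 (Gamma); all configurable.

All randomness flows from a single seeded generator in `FilterState`;
identical `(seed, config)` give bit-identical runs, and the CLI
checkpoint (posterior, `θ`, optimiser state, RNG state) restores a run
mid-stream bit-for-bit.

## Diagnostics used as oracles

`free_energy` (MC, plus a closed linear-Gaussian form) lets tests
verify that the closed-form `λ̄` is the minimiser. `bound_gap`
estimates the Jensen gap `E[A(λ_θ(z))] − A(λ̄_θ)`; evaluating both
terms on one sample makes the estimate nonnegative for every draw (by
convexity of `A` on the empirical measure), and for linear-Gaussian
dynamics it equals `½ tr(A^T Q⁻¹ A P)` — derived by taking the Gaussian
expectation of `A(λ_θ(z))` and verified against Monte Carlo before
being frozen into tests. `two_step_bound`/`single_step_bound` expose
the two per-step evidence bounds whose difference is exactly that gap.

## Synthetic systems

* **lds** — linear-Gaussian SSM; random stable `A` (spectral radius
  0.9) unless given; `Q = 0.1 I`, `R = 0.1 I`. The exact-oracle system.
* **crnn** — `z' = z + (Δ/τ)(γ W tanh z − z) + noise`, `W_{ij} ~
  N(0, 1/L)`, defaults `γ = 2.5`, `τ = 25 ms`, `Δ = 1 ms`,
  `Q = 10⁻³ I`; linear-Gaussian readout (`C_{ij} ~ N(0, 1/L)`,
  `R = 0.01 I`). Standard random-coupling benchmark; chaotic for
  large `L`.
* **vdp** — Euler-discretised Van der Pol oscillator
  (`τ₁ = τ₂ = 0.1`, `γ = 1.5`, per-step noise `σ = 0.05`, `Δ = 0.01`)
  with Poisson counts `y ~ Poisson(Δ e^{Cz+b})`, `N = 50` neurons,
  `C ~ N(0, 0.25)`, and `b` calibrated per neuron so the mean count is
  ≈ 0.1 per bin — sparse-spiking regime. Calibration failure
  (overflowing rates) raises rather than clipping.
* **cb** — conditionally continuous-Bernoulli transitions on `[0,1]²`
  whose conditional-mean field is an Euler step of a Hopf-type limit
  cycle (rotation `ω = 0.6`, radial attraction `ρ = 2` toward radius
  0.75 in centred coordinates), with the target mean mapped to CB
  naturals and amplified by `κ = 3` so states saturate at the boundary
  (switching-like behaviour); linear-Gaussian readout, `r² = 0.01`.
  Parameters were chosen once to produce a saturating limit cycle and
  are fixed in the config.

What these emulate: low-dimensional smooth or switching latent
dynamics under Gaussian or sparse Poisson readouts with *known, fixed*
observation parameters `ψ`. What they do not: non-stationary readouts,
unsorted/overlapping spikes, model mismatch in the likelihood family,
high latent dimension. Passing the verification suite therefore
demonstrates correctness of the inference machinery and learnability in
these regimes, not performance on real recordings.

## Verification problem sizes

Chosen to give sharp checks at desk scale: Kalman equivalence on 20
random systems (`L ≤ 3`, `T = 100`, tolerance 10⁻⁸); prediction
optimality to 10⁻⁴ (Gaussian, exact free energy) and 3 MC standard
errors with 10⁵ samples (CB/Gamma); parameter recovery with `T = 2000`
over 5 seeds (|Â − 0.9| < 0.05 scalar; Frobenius < 0.15 for a 2-d
rotation); Van der Pol with 3500 training + 500 frozen-model evaluation
steps (last-500 RMSE below first-500, one-step dynamics KL ≥ 5× below
its value at initialisation); CB-versus-Gaussian generation on 3 seeds
(`T = 2000` training, 1000-step sampled rollouts, symmetrised log
Chamfer against the true latents).

## Known limitations

* The observation parameters `ψ = {C, b, R, Δ}` are fixed and assumed
  known; learning them online is out of scope.
* Filtering only — no backward smoothing pass.
* The non-Gaussian variance correction is heuristic (variance matching
  only) and off by default.
* CVI pairings are implemented where closed forms exist
  (Gaussian/Gaussian, Gaussian/Poisson, CB/Gaussian); other pairings
  raise `NotImplementedError` rather than falling back to a sampled
  gradient.
* Online learning of static parameters from filtered (not smoothed)
  estimates carries a small attenuation bias that the decaying step
  size controls but does not remove; expect recovered linear dynamics
  to sit within a few percent of, and typically slightly below, the
  truth.
* The per-step cost is dominated by `L×L` factorisations and the MLP
  batch pass; the implementation is plain NumPy and aimed at
  `L ≲ 20` at interactive rates.
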