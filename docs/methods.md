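# Methods

Definitions, conventions, validity conditions and numerical choices behind
`lgca_walks`. Everything here is implemented and unit-tested; equation
references are to the docstrings of the named functions.

## 1. Geometry and scales

A node carries `b ≥ 2` unit velocity channels `c_j = (cos 2πj/b, sin 2πj/b)`.
The effective dimension is `d = 1` for `b = 2` (walk confined to a line)
and `d = 2` otherwise. The channel sets satisfy the normalization identity

```
Σ_j (c_i · c_j)² = b/d        (exactly, any i)
```

which is what makes the linear kernel below reproduce a prescribed VACF;
`tests/test_channels.py` and the property suite verify it for `b` up to 16.

A walker moves a lattice spacing `ε` each step `τ`. Given a walk speed
`v = ε/τ` and a random-walk diffusion coefficient `D_rw = ε²/(2dτ)`,

```
ε = 2 d D_rw / v,    τ = 2 d D_rw / v².
```

The headline parameter set (`v = 16`, `D_rw = 1`, `b = 4`) gives
`ε = 0.25`, `τ = 0.015625`.

## 2. The four kernels (`kernels.py`)

* **classical** — uniform `1/b`; VACF is a Kronecker delta, MSD `= 2dD_rw t`.
* **persistent** — `P(i | prev) ∝ exp[β (c_prev · c_i)]`, `β ≥ 0`. The
  transition matrix is circulant and reflection-symmetric, so the VACF is
  `g(k) = λ₁ᵏ` with `λ₁` the cosine-mode eigenvalue; for `b = 4`,
  `λ₁ = tanh(β/2)`. Continuum form `g(t) = e^{αt}`,
  `α = v² ln λ₁ / (2dD_rw)`.
* **time_correlated** — non-homogeneous linear kernel conditioned on the
  *initial* channel, `P(i | i₀, k) = [1 + d (c_{i₀} · c_i) g(kτ)]/b`. Its
  first moment is `Σ_i P_i (c_{i₀}·c_i) = g(kτ)` exactly (by the
  normalization identity), so the walk realizes the target VACF for any
  prescribed `g` — but it is only a probability vector while
  `|g(kτ)| ≤ 1/d`.
* **generalized** — maximum-caliber kernel
  `P(i | i₀, k) ∝ exp[d g(kτ) (c_{i₀} · c_i)]`. Always valid; the realized
  VACF saturates: for `b = 4` the realized first moment is
  `tanh(d·g(kτ)/2) = tanh(g(kτ))` at `d = 2`, i.e.
  `g_real(t) = tanh(C0 (Δ/t)^φ)` for a power-law target. Its
  long-time behavior is an effective power law with exponent
  `2C0φ/sinh(2C0)` (`generalized_tail_exponent`).

### Validity of the linear kernel, and the ballistic extension

For a power-law target `g(t) = C0 (Δ/t)^φ` the kernel is valid from step 1
iff `|g(τ)| ≤ 1/d`, which for `C0 = 1/d` reduces to `Δ ≤ τ`. The headline
parameters have `Δ = 0.016` *marginally above* `τ = 0.015625`, so the
kernel is invalid at `k = 1` only. Constructing that model raises a
configuration error unless `ballistic_until_valid=True`, which keeps the
walker on its initial channel (realized `g = 1`) until the first valid
step and logs the deviation. All comparisons with simulation use the
*realized* per-step VACF (ballistic steps count as `g = 1`), never the
unattainable target.

The `piecewise_ballistic` family makes the ballistic phase explicit:
`g = 1` up to `t* = Δ C0^{1/φ}` and the power law beyond. Note that the
tail is continuous at `g(t*) = 1 > 1/d` for `d = 2`, so realizing it on a
planar lattice always needs the same extension until `g ≤ 1/d`.

## 3. Closed-form MSDs (`theory.py`)

Two Taylor–Green–Kubo structures appear:

* **stationary** (persistent walk; linearized generalized kernel):
  correlations depend on lag only, `⟨c_i · c_j⟩ = g(|j−i| τ)`, giving
  `MSD(t) = 2dD_rw t + 2v² ∫₀ᵗ (t−s) g(s) ds`.
* **initial-orientation** (time-correlated and generalized models):
  conditioned on `c₀`, the step means factorize,
  `⟨c_i · c_j⟩ = g(iτ) g(jτ)` for `i ≠ j`, giving
  `MSD(t) = 2dD_rw [t − 2∫ g²] + v² (∫ g)²` with integrals from the
  validity onset (`Δ` for the small-crossover power law; `t*` plus
  ballistic memory terms for the piecewise family).

Closed forms are provided for: the classical walk; the persistent walk
(discrete sum and continuum form); the power-law time-correlated walk
(generic exponent plus `φ = 1/2` and `φ = 1` logarithmic branches); the
piecewise-ballistic walk; the generalized walk (`tanh` VACF, by
quadrature of the two one-dimensional integrals); and the stationary
generalized walk (generic branch plus `φ = 1`, `φ = 2` logarithmic
branches). Within `10⁻⁶` of the removable singularities the special-case
branches are used directly — the generic expressions contain `1/(1−φ)`
factors that amplify round-off catastrophically there (continuity across
the switch is tested).

**Oracles.** `msd_numeric_oracle` evaluates the defining integrals by
adaptive quadrature; the initial-orientation double integral is evaluated
as a genuinely nested quadrature rather than via the identity
`∫∫_{u≥s} g g = (∫g)²/2`, so it is an independent check of the algebra
that uses that identity. All closed forms agree with their oracles to a
relative `10⁻⁶` (`test_criterion_3`).

**Discrete predictions.** `msd_persistent_discrete` and
`msd_independent_discrete` are the *exact* finite-`k` expectations of the
simulated process (e.g. `MSD = ε²(k + S² − Q)` with `S = Σ g_i`,
`Q = Σ g_i²` for the initial-orientation structure); simulation acceptance
tests compare against these, not the continuum limits.

## 4. Simulation engine (`engine.py`)

Pure function of `(config, n_particles, n_steps, seed)`. One PCG64 stream
(`numpy.random.default_rng(seed)`): first a block of `n_particles`
uniforms for the initial channels, then one `(n_particles, n_steps)` block
in particle-major order, each consumed by an inverse-CDF categorical draw
(a variate on a CDF boundary selects the higher index). Per step, the
kernel is materialized once as a `(b, b)` matrix indexed by the
conditioning channel, so runs of `10⁴ × 200` take well under a second.
Positions are reconstructed exactly from the channel history.

## 5. Estimators (`stats.py`)

* `empirical_vacf`: mean over particles of `c_{i₀} · c_{i_k}`, with SEM.
* `empirical_msd`: mean of `|x_k − x₀|²`, with SEM.
* `estimate_diffusion_coefficient`: OLS slope of MSD vs `t` divided by
  `2d`, with a nonlinearity flag when `R² < 0.98`.
* `classify_regime`: log-log OLS exponent; labelled `normal` when the 95%
  CI overlaps `[1 − tol, 1 + tol]` (default `tol = 0.05`). The band is
  needed because MSD errors are correlated across lags, which makes the
  bare OLS CI too sharp a test.
* `fit_vacf_power_law`: fits `g = A t^{−φ}` by nonlinear least squares in
  *linear* space. Three deliberate choices, each of which removes a bias
  that was measured in replicate studies: (i) no log transform —
  `E[log ĝ] < log E[ĝ]` biases φ upward-noise-downward at low-SNR lags;
  (ii) negative noisy values are kept — censoring them removes only
  downward noise; (iii) points are unweighted, with a pooled (median) SEM
  setting the CI scale — weighting by per-lag estimated SEMs biases the
  fit because sample mean and sample variance are correlated. With 4000
  particles × 50 lags the estimator is unbiased to < 0.01 in φ with
  nominal CI coverage (`test_criterion_6`). Only the lumped amplitude
  `A = C0 Δ^φ` is identifiable; `C0` and `Δ` cannot be separated from a
  single power law. A quadratic-in-`log t` residual test flags
  non-power-law inputs.

## 6. Markov trichotomy (`markov.py`)

For a homogeneous symmetric orientation chain (circulant transition
matrix with `p_j = p_{b−j}`), the VACF is carried by the cosine Fourier
mode: `g(k) = λ₁ᵏ` with real `λ₁ = Σ_j p_j cos(2πj/b)`. Hence exactly
three decay classes — delta (`λ₁ = 0`), alternating (`λ₁ < 0`),
exponential (`λ₁ > 0`) — and never a power law; long-range temporal
correlations require the non-homogeneous kernels. `chain_vacf` computes
`g(k)` by brute-force matrix powers (no spectral shortcut), and
`classify_decay` verifies `g(k) = g(1)ᵏ` to an absolute tolerance before
classifying (absolute, because matrix powers carry ~10⁻¹⁵ additive noise
that breaks ratio tests once `λ₁ᵏ` underflows it). Chains outside the
hypotheses are rejected, not classified.

## 7. Regime thresholds (`thresholds.py`)

Both correlated-MSD families decompose as
`MSD(t) = (const + linear in t) + (anomalous remainder ~ t^p)`, and each
regime boundary is where `p` crosses a critical value (0 = transient
disappears, 1 = superdiffusion onset). Fitting a log-log slope to the full
MSD is badly biased near the boundary (the linear part dominates), so the
remainder exponent is measured with a double-differencing scheme on a
log-spaced grid with ratio `σ`:

```
R  = MSD − 2dD_rw t
D1(t) = R(σt) − R(t)
E(t)  = D1(σt) − σ D1(t)
```

`E` annihilates constant and linear components *exactly*; for a pure
power `c t^p`, `E ∝ t^p`, so the log-log slope of `|E|` is `p` with no
contamination. Points where `|E|` falls below `64 · eps · MSD(t)` (the
float-cancellation floor of computing `R`) are excluded, and the slope is
fitted on the latest usable points. The thresholds are then located by
bisection in φ (tolerance `10⁻³`):

* `tc_transient_threshold` — the time-correlated family's remainder is
  `∝ [(t/Δ)^{1−φ} − 1]²` near the boundary; its growth only becomes
  visible once `|1−φ| ln(t_max/Δ) ≳ 1`, so the grid spans 14 decades
  (the closed form is analytic; this costs nothing). Residual bias ≈ 0.03.
* `gtc_remainder_threshold` / `gtc_superdiffusion_threshold` — remainder
  `∝ t^{2−φ}` on the stationary generalized family; window `[10², 10⁸]`;
  bias < 10⁻³.

Measured values: 1.028, 2.000, 1.000 against analytic 1, 2, 1.

## 8. Limitations

* The time-correlated walk can only realize `|g| ≤ 1/d`; stronger targets
  are necessarily distorted (ballistic extension) or must use the
  generalized kernel, whose realized VACF is the `tanh`-saturated target.
* The continuum closed forms for the power-law families assume the
  small-crossover limit `Δ ≪ t`; simulation comparisons therefore use the
  exact discrete sums instead.
* `classify_regime` measures an *effective* exponent over the observed
  window; inside a crossover (see the README example) it will report the
  transient exponent, which is the intended behavior.
* The stationary generalized closed form (`msd_gtc_stationary`,
  `method="closed"`) closes the *linearized* correlation integral
  (`tanh x ≈ x`); `method="quadrature"` evaluates the full `tanh` form.
  They agree to leading order for `C0 ≲ 0.5` but are distinct curves.
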