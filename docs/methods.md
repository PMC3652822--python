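# Methods

## Model

Two phenotypic states, normal (`n`) and persister (`p`), with
environment-dependent net per-capita rates and stochastic switching:

```
dn/dt = μ_n n − a n + b p
dp/dt = μ_p p + a n − b p
```

The model is deterministic (mean-field); demographic noise is out of
scope. Time is in **hours** throughout, not configurable. Each
environment carries one signed net rate per phenotype; death rates under
stress are exposed as read-only `κ ≡ −μ`. The canonical parameter sets
(`presets`) use *E. coli*-like magnitudes: `μ_n = 2/h`, `μ_p = 0.2/h` in
growth medium; `κ_n = 2/h`, `κ_p = 0.1/h` under drug; defaults
`a = 10⁻⁵/h`, `b = 10⁻³/h`.

Key derived quantities are controlled by the rate gaps
`Δμ = μ_n − μ_p > 0` (growth) and `Δκ = κ_n − κ_p > 0` (stress).

## Exact layer

The model is linear, `x′ = Mx` with the Metzler matrix
`M = [[μ_n−a, b], [a, μ_p−b]]`, whose spectrum is always real
(discriminant `(gap)² + 4ab ≥ 0`). `propagate_exact` evaluates
`exp(M dt)` through its spectral projectors,

```
exp(M dt) = e^{(m+q)dt} (qI + D)/(2q) + e^{(m−q)dt} (qI − D)/(2q)
```

(`M = mI + D`, `D` traceless with eigenvalues ±q). The diagonal entries
of `qI ± D` are evaluated via `q ∓ d = M₀₁M₁₀/(q ± d)` whenever direct
subtraction would cancel, so every projector entry is a nonnegative
closed form and the *small* eigencomponent keeps full relative precision
even after tens of e-folds of decay (a naive `cosh/sinh` form loses ~11
digits on a 30 h kill curve). For `q·dt < 10⁻⁶` (near-degenerate
eigenvalues) a 4th-order Taylor series in `q·dt` is used instead; the
crossover keeps both branches below ~10⁻²⁶ truncation error.

With a finite carrying capacity `K`, only phenotypes with *positive* net
rate have their growth term multiplied by `(1 − N/K)`; death and
switching terms are untouched. This variant is nonlinear and is
integrated with LSODA at `rtol 10⁻¹⁰ / atol 10⁻¹²` (it serves as an
oracle in tests, so the tolerances are oracle-grade).

`dominant_eigenpair` returns the Perron root and the `n/p` ratio of its
eigenvector, picking whichever matrix row gives the better-conditioned
quotient (the row whose diagonal is far from the eigenvalue) — the other
row loses ~7 digits in the stress orientation.

## Small-switching layer

The oriented ratio `r` = majority/minority (`n/p` in growth, `p/n` in
stress; general rates `g` = gap, `s_out`/`s_in` = switching out of/into
the majority) obeys the Riccati equation

```
dr/dt = −s_out r² + (g − s_out + s_in) r + s_in
```

**exactly** — this is an identity of the linear model, not an
approximation. Its fixed points are computed with the cancellation-safe
`q`-scheme (`r_stable = (B+√(B²+4 s_out s_in))/(2 s_out)`,
`r_unstable = −2 s_in/(B+√·)`), and the relaxation rate is the exact
linearization `√(B²+4 s_out s_in) ≈ g + s_out + s_in`.

For small switching rates the unstable root collapses to 0 and the
stable root to `r* = g/s_out`, reducing the dynamics to the logistic
equation `dr/dt = g r (1 − r/r*)`. Everything downstream uses the
logistic solution in its overflow-safe inverse form
`r(t) = r* r₀ / (r₀ + (r*−r₀)e^{−gt})`, plus the two closed-form
integrals `∫r dt` and `∫dt/r` for time-averaged per-capita rates. The
double-exponential total population uses first-order eigenstructure:

```
N(t) = (n₀+e) e^{(μ_n−a)t} + (p₀−e) e^{(μ_p−b)t},   e = (a n₀ + b p₀)/d,
d = (μ_n−a) − (μ_p−b)
```

which is exact at `t = 0` and accurate to `O((a,b)/gap)` throughout; a
degenerate spectrum (`d = 0`) is rejected rather than regularized.

A structured `SmallSwitchingWarning` (never an error) is emitted when
`max(a,b)` exceeds 10% of the relevant gap; the threshold is a module
constant, chosen because the layer's leading-order error is linear in
`switching/gap`.

## Shift-experiment observables

Transition times are defined by subpopulation equality (`n = p`) after a
shift. Because the oriented ratio obeys the Riccati equation exactly,
the package's default "full form" is the exact crossing time

```
T = ln[ (1−r_u)(r_s−x₀) / ((r_s−1)(x₀−r_u)) ] / λ,    x₀ = 1/r₀
```

(`r_u, r_s` the Riccati fixed points of the *post*-shift environment, λ
its relaxation rate), which agrees with root-finding on exact
trajectories to machine precision. The familiar limits `T_s ≈ ln(r₀)/Δκ`
and `T_g ≈ ln(r₀)/Δμ` sit behind `approx=True`. The equilibration times
`T′` are the inflection of the declining subpopulation's per-capita
rate, i.e. the ratio's passage through the midpoint of its fixed points:
`T′ = ln[(r_s−x₀)/(x₀−r_u)]/λ ≥ T`.

**Inversion prefactor.** Starting from the pre-shift steady state
(`r₀ = Δμ/a` before stress, `Δκ/b` before growth), the leading-order kink
times are

```
T_s = ln(ρ/a)/Δκ,   T_g = ln(ρ/b)/Δμ,   ρ = ΔμΔκ/(Δμ+Δκ).
```

The prefactor is ρ, not the bare gap, because the slow component of the
kill curve is seeded twice: by persisters formed during growth
(`p₀ ≈ a n₀/Δμ`) *and* by normal cells switching during the fast kill
phase (`∫a·n dt ≈ a n₀/Δκ`). Both contributions are first order in `a`,
so neither may be dropped: the bare-gap inversion misestimates `a` by the
factor `(1 + Δμ/Δκ) ≈ 2` for typical rates, while the ρ-form recovers it
to <1% on noiseless data. The bare-gap variants remain available via
`simple=True` for comparison with the older limit expressions. This was
the one genuinely open design decision in the package; the exact-crossing
oracle settled it.

**Fitting.** `fit_double_exponential` performs least squares on log₁₀
counts (homoscedastic there, matching multiplicative CFU noise) with a
deterministic initializer: straight-line fits to the first and last
thirds of the log curve give the two rates, their intercepts the
amplitudes. The model is evaluated with a log-sum-exp so 30-decade
curves don't overflow. Data whose early and late slopes agree within
10⁻⁶ relative (or whose fitted components merge) are flagged
`degenerate` and fitted as a single exponential with `amp_slow → 0`.
The transition estimate from data is the equality point of the two
*fitted* components; curvature-based estimators are out of scope.
`switching_rates_from_curves` warns when the fitted pre-shift ratio
differs more than 2× from the expected steady state, since the inversion
assumes equilibrated pre-shift structure.

## Periodic environments

The per-cycle propagator is `M = exp(M_s t_s) exp(M_g t_g)`; the
long-time growth rate is `λ̄ = ln ρ(M)/(t_g+t_s)`. This Floquet route is
the *authoritative* definition for any durations (the closed forms have
restricted validity; the propagator does not). It is evaluated on a
log-rescaled propagator because a single 200 h cycle spans ±400 e-folds
and `tr²` overflows doubles otherwise.

When both phases are long enough to equilibrate the structure,
bookkeeping of per-phase exponential growth plus the log-amplitude
penalty paid at each shift gives

```
λ̄ ≈ [ (μ_n−a) t_g − (κ_p+b) t_s + ln(b/Δμ) + ln(a/Δκ) ] / (t_g+t_s),
```

reported alongside the Floquet value (`lambda_bar_steady_state`), with a
warning when a phase is shorter than ~3 relaxation times. Maximizing it
gives `a_opt = 1/t_g`, `b_opt = 1/t_s` exactly; the correction terms,
evaluated at zero switching rates, vanish for this functional form, so
the explicit closed-form optimum is the pure leading order (an implicit
self-consistent solve of the same stationarity conditions is available
behind `implicit=True` and coincides to solver tolerance). No
short-duration closed forms are provided: in that regime the Floquet
route *is* the result, and the numeric optimizer (deterministic 40×40
log-grid over `[10⁻⁶, 1] /h` + one Nelder–Mead refinement, no stochastic
restarts) is the authoritative check. The optimizer reports
`interior_maximum=False` when the best grid point lies on the lower
boundary, the signature of the short-duration regime where growth only
decreases with switching.

## Synthetic data

The generator reproduces the two canonical experiment designs (shift and
periodic protocols) by sampling the exact piecewise solution and
corrupting counts with one of:

- `lognormal` (default, σ = 0.1 on log₁₀ counts): multiplicative plating
  scatter, the dominant noise in serial-dilution CFU counts;
- `poisson_cfu`: colony-count shot noise at a plated fraction;
- `none`: exact model output.

A seed is mandatory for stochastic noise and is recorded, with all
generating parameters, in a JSON sidecar next to the CSV; identical
seeds give byte-identical tables. What the generator does **not**
emulate: demographic stochasticity at low counts (relevant below ~100
cells, exactly where persister counts end up late in a kill curve),
detection limits/zero counts, inoculum variability between replicates,
and any adaptive (stress-induced) switching. Passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to every pathology of real plate counts.

## Problem sizes and numerical defaults

- Propagator validation: 108 parameter sets spanning `μ_n ≤ 2/h`,
  `μ_p ≤ 0.2/h`, switching `10⁻⁶–10⁻¹ /h`, 30 h spans, against DOP853 at
  `rtol 10⁻¹²`; observed worst error ~5·10⁻¹².
- Recovery pipeline: 15 h + 15 h protocols, 40 samples per phase,
  3×3 grid of `(a,b)` over `[10⁻⁶, 10⁻³] /h`.
- Stationary phase: `a = 10⁻³`, `b = 0.05 /h`, `K = 10⁸`, 400 h — the
  back-switching rate is enlarged so the `p/n → a/b` balance (relaxation
  ~`1/b`) completes in reasonable simulated time; the physics is
  unchanged.
- Periodic optimum: 40×40 grid; capacity cycles: 20 cycles of 15 h + 5 h
  with `b = 0.05 /h` for the same convergence reason.

## Limitations

- Two phenotypes only; no toxin–antitoxin circuit mechanics, no
  condition-dependent (SOS-induced) switching rates — the model can serve
  as the null model against which such adaptivity is detected.
- Inference returns point estimates with residuals; no bootstrap or
  Bayesian uncertainty in this version.
- The inversion assumes the pre-shift culture reached its steady-state
  structure; violations are warned about, not corrected.
- Stochastic environment durations are not modelled; the periodic cycle
  stands in for the typical period of a fluctuating environment.
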