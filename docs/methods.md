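# Methods

## Model and assumptions

The environment is an `Nx`-dimensional demand vector `D(t)` following an
Ornstein–Uhlenbeck process, integrated by explicit Euler–Maruyama:
`D ← D − M(D − D̄)dt + √(2Γdt)η`. This update *is* the model definition;
no higher-order scheme is used. The stationary law is Gaussian with mean
`D̄` and covariance `ΓM⁻¹`. `build_anisotropy_matrix(α, λ1, λ2)` returns
`R(α)·diag(λ2, λ1)·R(α)ᵀ`, so the low-stiffness eigenvector — the direction
of largest demand spread `√(Γ/λ2)` — points along `α`. Epochs share one
time grid; the demand state is continuous across epoch switches.

Because downstream circuits divide by `D`, demands are floored at
`ε_D = 10⁻²·|D̄|` component-wise and every clamp is counted. The guard is
inactive (`clamp_count = 0`) for `Γ ≲ 0.01` at unit stiffness; at
`Γ = 0.05` it triggers at about 5·10⁻⁶ per step, and at `Γ = 0.2` (demand
sd ≈ 0.45 around a mean of 1) at about 0.3% of steps — at that point the
truncation is part of the simulated environment and is reported with every
trajectory.

Circuits treat metabolite concentrations algebraically, `x = P/D`
(metabolite turnover is fast relative to regulation). SEPI is linear with
no degradation and no floors. The learning architecture floors activities
at `a_floor = 10⁻⁶` (multiplicative dynamics must stay revivable) and
floors production at `10⁻³` before division (inhibitors can transiently
exceed activators); both floors are counted, and production flooring is
logged.

The two Hill-kinetics circuits are one-dimensional homeostats. In the
allosteric pair, activating and degrading enzyme branches are
self-activating with occupancies `c₊ⁿ/(c₊ⁿ+xⁿ)` and `xᵐ/(c₋ᵐ+xᵐ)`; decay
rates default to the occupancy at the set point, so `x = 1` is the static
fixed point and simultaneous scaling of `(a₊, a₋)` is marginal — the
circuit's memory, mirroring the rectified-linear model. In the bifunctional
circuit a single enzyme pool `A` partitions by a Hill isotherm into
synthesizing/degrading fractions (`a₊ + a₋ = A` exactly), and `A` is
produced at rate `f(x) = β(x−1)² + f0`, a variance sensor minimized at the
set point.

## Numerical integration

The circuit kernels are numba-compiled and share the demand grid
(`dt = 10⁻²` in 1D; `5·10⁻³` in 2D, where the stability guard
`dt·λmax < 0.1` binds at `λ1 = 10`). One qualification: a well-adapted
learning circuit realizes a feedback gain of order `Σ_μ a_μ/(τa·min D)`,
which can exceed the explicit-Euler stability limit of the demand grid by
orders of magnitude. The regulator update therefore takes
stability-preserving sub-steps within each demand sample (demand held
constant), sized so each sub-step stays well inside the stability region;
below a gain of 50 the scheme is identical to plain single-stepping, and
the run remains deterministic. The biochemical circuits sub-step their
stiff metabolite equation (10 sub-steps by default) and switch to a
quasi-steady-state solve when `τx/τa < 10⁻²`.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `D̄` | 1 (per component) | demand | sets the scale; mean demand fixed at 1 |
| `dt` | 10⁻² (1D) / 5·10⁻³ (2D) | time | stability guard `dt·λmax < 0.1` |
| `(λ1, λ2)` | (10, 1) | 1/time | anisotropy 10, the correlated reference case |
| `Γ` | swept in [10⁻³, 1] | demand²/time | spans inactive → learned regimes |
| `τa` | 10 | time | separates regulation from demand fluctuation (~1/λ) |
| `κ` | 10⁻³ | — | degradation, ≪ set point; see below for protocol values |
| `d` | 0 | — | strong rectification; −10 is the linear control |
| `a_floor` | 10⁻⁶ | — | revivability of multiplicative activities |
| `a(0)` | 1/Na | — | uniform, un-adapted start |
| allosteric `c₋` | 2.5 | conc. | set point below the degrading branch's inflection (below) |
| bifunctional `β` | 5 | — | variance-sensor gain; `f0 = κ` puts static `A* = 1` |

A balance argument fixes the adapted state of the rectified circuit: an
active regulator is stationary when its time-averaged rectified drive
equals κ, which pins the relative tracking error at
`sd((D−P)/D) ≈ κ√(2π)` (verified directly in simulation). Three
consequences shaped the epoch protocols, whose exact parameters are the
package's own choices:

- **Equilibration.** Activities plateau only after the balance point is
  reached; with κ = 10⁻³ that lies beyond desk-scale epochs, so epoch
  protocols that assert flatness or re-learning use κ in 0.02–0.05, where
  epochs of 2000–4000 time units equilibrate. The variance-epoch
  demonstration uses κ = 0.02, Γ ∈ {0.008, 0.016, 0.032, 0.064} (all well
  above threshold, all clamp-free), 3000-unit epochs and a 3000-unit
  burn-in at epoch-1 conditions so the first reported epoch starts
  adapted.
- **Forgetting.** With `d = 0` the drive is non-negative, so surplus
  activities decay only at rate κ/τa. Sequentially rotated inputs
  therefore show hysteresis in the learned angle — a real property of the
  model. Angle recovery is assessed with independent adaptation per input
  angle (κ = 0.03, Γ = 0.1, 4000 time units), which recovers α to within a
  few degrees at anisotropy 10.
- **Degradation penalty.** The same balance implies a residual error floor
  `~2πκ²` and a small overshoot of ⟨x⟩; at the spec-scale κ = 10⁻³ the
  penalty is negligible, at κ = 0.05 it is visible as the learning circuit
  sitting slightly below SEPI at small Γ.

## Optimal-control ceiling

The ceiling is the stationary linear-quadratic tracking optimum for state
`(D − D̄, P − D̄)` with `Ṗ = u` and cost `E[‖P − D‖² + ρ‖u‖²]`, solved by
the algebraic Riccati equation; closed-loop performance and CIP come from a
Lyapunov equation. Sweeping the effort price ρ traces the
(CIP, performance) frontier; `ceiling_at_cip` interpolates it in log-CIP.
The CIP constraint is a time-average (Lagrangian) one, matching how
simulated circuits are scored (`(1/T)∫‖Ṗ‖²dt` by first differences,
transient discarded); no pointwise rate cap is modeled. Misspecified
ceilings re-score a policy optimized for `diag(M)` under the true
environment — the bound any correlation-blind strategy obeys. The Riccati
solution was cross-checked against a dense brute-force grid of linear
feedbacks (Lyapunov-scored) and against closed-loop simulation.

## Activation threshold

Learning engages when a surplus regulator's time-averaged rectified drive
`⟨max(d, σ·(1−x))⟩` exceeds κ. The detector initializes the circuit at the
non-negative-least-squares mean-matching state (surplus regulators at the
floor) — active regulators hover at drive = κ by stationarity, so
activation is judged on the surplus set — and bisects Γ with common random
numbers. An activity-based count is not usable at desk scale: surplus
activities decay at κ/τa and would need ≥10⁴ time units to traverse an
order of magnitude. Measured thresholds follow `Γ_min = c·κ²` essentially
exactly (c ≈ 6–8 for the geometries tested): at `d = 0` the surplus drive
is dominated by the half-Gaussian tail of its fluctuation, of size
∝ `sd(x) ∝ √Γ`, so the balance sets `√Γ_min ∝ κ`. A mean-drive-dominated
regime would instead give `Γ_min ∝ κ`; it is not realized at these
parameters. Aligned surplus regulators (along the dominant fluctuation
direction) activate at smaller Γ than misaligned ones, as expected.

## Synthetic environments and scope

All data are generated internally: Gaussian OU demands with epoch-wise
constant structure, by design. Real microbial demands are non-Gaussian,
non-stationary within epochs, and coupled to the organism's own actions;
none of that is modeled, so passing tests show that the *mechanism* works
under its stated assumptions, not that it quantitatively describes any
particular organism. The circuits are deterministic given `D(t)` — no
molecular noise or transcriptional delay.

## Design choices in open territory

- The allosteric defaults `c± = 1, n = m = 2` make the two branch
  occupancies exactly cancel in curvature at the set point, so the enzyme
  pair never upregulates; the package sets `c₋ = 2.5`, placing the set
  point below the degrading branch's inflection so both occupancies are
  convex there and fluctuations upregulate both enzymes. The non-learning
  analogue drops the degrading branch; its buffering is then fixed by the
  environment and cannot adapt.
- The bifunctional analogue freezes `A` at its static steady state
  `f0/κ`. Buffering scales with `A`, so the learning circuit's error grows
  ~√Γ while the frozen analogue's grows ~Γ — the operational meaning of
  "flat" used in the tests.
- Ablation gains are paired differences against SEPI on common demand
  realizations, averaged over five input angles
  {0, π/8, π/4, 3π/8, π/2}; the Na = 2 row uses regulators at {0°, 90°}
  (the SEPI-matched arrangement — the default equally-spaced {0°, 180°}
  cannot positively span the mean demand). With self-activation off but
  extra regulators present, a small positive gain remains (extra response
  directions help even linearly); the collapse-to-SEPI statements apply to
  the matched `Na = Nx` case.
- Transient discard is 30% of each epoch (adaptation takes a few τa and
  epochs are long by construction); the angle-recovery protocol averages
  activities over the final 30% of each run instead, since the learned
  angle is meaningful only after full adaptation.
- Monte-Carlo error bars use ≥3–5 independent seeds per comparison, with
  paired (common-random-number) designs wherever a difference is the
  quantity of interest.

## Known limitations

- Sequential angle epochs lag the input (hysteresis) whenever κ is small;
  only the independent-adaptation protocol recovers angles sharply.
- The Euler–Maruyama closed-loop simulator carries O(dt) bias (~1–2% at
  `dt = 10⁻²`), visible when cross-checking the analytic Lyapunov values.
- At `Γ ≳ 0.2` with unit stiffness the demand positivity guard truncates
  the environment's lower tail, and measured circuit statistics inherit
  that truncation.
- Problem sizes throughout (epoch lengths 2000–6000 time units, 5–7 point
  sweeps, 3–5 seeds) are desk-scale choices; all qualitative conclusions
  were stable under doubling them.
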