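# Methods

## Model

The simulator integrates a phenotype-structured PDE system for tumor
invasion under time-switched oxygen. Normoxic cells `n(x, t)`
proliferate logistically against the total occupancy `n + H + e` when
oxygen is above the hypoxic threshold `c_H`, convert to the hypoxic
phenotype at rate `μ_nh` below it, and die at rate `γ_n` below the
necrotic threshold `c_N`. Hypoxic cells `h(x, t, μ)` carry a structure
coordinate `μ ∈ [0, 1]`, their own back-transition rate: freshly
converted cells enter at the basal coordinate `μ₀ = 0.5`, and a drift
`v(μ, c) = −(α(1 − c) + μ − μ₀)/β` moves them toward lower `μ`
(stronger hypoxic memory) while oxygen is low and back toward `μ₀`
after re-oxygenation. Hypoxic cells diffuse through the space left free
by cells and ECM, migrate up ECM gradients (haptotaxis, coefficient
`ξ_h`), escape back to normoxia at rate `μ` when oxygen is high, and
degrade ECM at rate `δ`. ECM `e(x, t)` only decays; oxygen `c(t)` is
spatially homogeneous — a square wave between `c₁ = 1` and `c₂ = 0.4`
in cyclic runs, or a constant in the two verification regimes.

Key structural assumptions: go-or-grow (proliferation and migration are
mutually exclusive phenotypes); sharp Heaviside switching at the oxygen
thresholds with the convention `ℋ(0) = 0`, so the exact threshold
counts as the normoxic side everywhere (gating and the memory
timescale alike); all conversion happens through the single injection
coordinate `μ₀`; and oxygen is an external driver, not a consumed
field.

### Memory timescale switching

The drift timescale `β` is regime-dependent: induction `β_l` while
`c < c_H`, erasure `β_h` while `c ≥ c_H`. The defaults `β_l = 2`,
`β_h = 20` encode the observation that phenotypic memory is induced
within roughly half a cell division to two divisions but erased only
over many divisions (with proliferation rate `λ_n = 0.1`, one division
time is 10 time units; the experiment grid spans `β_l ∈ [2, 10]`,
`β_h ∈ [20, 50]`). The memory strength `α = 0.8` is chosen so that the
equilibrium phenotype under the hypoxic level `c₂ = 0.4`,
`μ* = μ₀ − α(1 − c₂) = 0.02`, is minimal but still positive; a
configuration driving `μ*` non-positive is rejected at validation.
`α = 0` is the memoryless control: the drift then vanishes identically
at `μ₀`, where all hypoxic mass sits.

## Parameters

| symbol | meaning | default |
|---|---|---|
| `D_h` | hypoxic-cell diffusivity | 0.01 |
| `ξ_h` | haptotaxis coefficient | 0.001 |
| `λ_n` | normoxic proliferation rate | 0.1 |
| `μ_nh` | normoxic→hypoxic transition rate | 0.5 |
| `μ₀` | basal hypoxic→normoxic rate / injection coordinate | 0.5 |
| `γ_n, γ_h` | necrosis rates | 0.001 |
| `δ` | ECM degradation rate | 15 |
| `c_H, c_N` | hypoxic / necrotic oxygen thresholds | 0.5 / 0.1 |
| `α` | memory-induction strength | 0.8 |
| `β_l, β_h` | memory induction / erasure timescales | 2 / 20 |

All quantities are dimensionless (lengths scaled by the invasion
length scale, times by the diffusive timescale, densities by carrying
capacity, oxygen by the normoxic level). Only the dimensionless system
is simulated.

The initial state is an all-normoxic step tumor `n = 0.5` on
`x ∈ [4, 6]` inside an otherwise uniform ECM `e = 0.5`, with `h ≡ 0`,
on the domain `[0, 10]`.

## Discretization

Node-centered uniform meshes: `N = 201` spatial nodes (`dx = 0.05`)
and `M = 101` phenotype nodes (`dμ = 0.01`) by default. The phenotype
mesh must contain `μ₀` as an exact node (validated at construction),
because conversion injects mass at that single coordinate.

* **Spatial transport** — conservative central fluxes with arithmetic
  face averages of the motility factor `1 − n − H − e`, of `h` (for
  haptotaxis), and one-sided ECM differences; the *combined*
  diffusive + haptotactic flux is zeroed at `x = 0, X`.
* **Trait drift** — conservative donor-cell upwinding with the face
  velocity evaluated exactly (the velocity is linear in `μ`), and zero
  convective flux at `μ = 0, 1`. This preserves the per-`x` phenotype
  mass to machine precision by telescoping, which is the property the
  verification suite leans on; a node-velocity variant of the stencil
  would not telescope exactly.
* **Injection** — `h` is a density over `μ`, so the conversion source
  adds `μ_nh n / dμ` at the injection node; its `μ`-integral then
  equals the normoxic loss `μ_nh n` exactly and total cell mass is
  conserved through transitions to machine precision. All
  `μ`-integrals use the rectangle rule (plain node sum × `dμ`), and
  spatial integrals likewise (sum × `dx`): uniform weights are what
  make the conservative fluxes telescope to exactly zero. A
  consequence worth knowing: the rectangle-rule mass of the step
  initial profile is `n0 (b − a) + n0 dx` (1.025 at the default grid),
  converging to the continuum value 1 as `dx → 0`; the analytic
  comparisons therefore take `N₀` from the discrete quadrature, not
  from the continuum formula.
* **ECM** — multiplicative decay `e ← e (1 − δ dt H)`.
* **Time stepping** — forward Euler with a fixed step set once per
  run: `dt = 0.9 · min(dx²/(2 D_h), dμ/f_max, 1/r_max)`, where `f_max`
  is the largest trait speed over `μ ∈ [0, 1]` and both oxygen levels
  (computed before the run; the velocity is linear in `μ`, so the
  endpoints suffice), and `r_max = max(δ, μ_nh, 1, γ)` bounds the
  pointwise decay rates. The third bound is needed for positivity:
  with `δ = 15`, forward Euler overshoots the ECM negative whenever
  `dt > 1/(δH)`, and the transport bounds alone do not prevent that on
  coarse grids or in the memoryless limit (where the advection bound
  is dropped — all hypoxic mass sits at the stationary coordinate, so
  the trait CFL is vacuous). With the default grid and a memory arm
  the advection bound (`dμ/0.49 ≈ 0.0204`) is the binding one.
* **Negativity policy** — entries in `(−10⁻¹², 0)` are clipped to zero
  and counted; anything below −10⁻¹² aborts the run as a stability or
  implementation failure rather than being silently repaired.

Oxygen phases are left-open/right-closed: the instant a phase ends
still belongs to it, `t = 0` starts normoxic, and the step uses the
oxygen level at the step's start time.

## Observables

The tumor right boundary is the largest `x` where `n + H` crosses
`10⁻⁶`, linearly interpolated between mesh nodes (making hitting times
grid-insensitive; the raw-node reading differs by at most `dx`). The
front is the band 0.5 units inward of the boundary. Tumor "volume" in
1D is `∫(n + H) dx`. Phenotype distributions are `h` integrated over a
region and normalized to unit weight; the strong-memory fraction sums
weights with `μ < 0.25`; the Jensen–Shannon divergence uses the
natural log (bounded by `ln 2`). Metrics over empty regions, and
hitting times never attained, return NaN — an explicit undefined
marker, never 0.

Two conventions were genuinely open and are fixed as follows: the mean
front hypoxic fraction averages over *all* recorded outputs (every 0.1
time units), not only cycle boundaries; and the "maximal memory
effect" period is the argmax of the mean of |percent change in final
volume| and |percent change in hitting time|, skipping a hitting-time
entry when the target is never reached.

## Verification strategy

Under constant oxygen the totals obey closed forms that the solver is
checked against: exponential conversion `n_tot = N₀ e^{−μ_nh t}` with
`n_tot + h_tot = N₀` under sustained hypoxia, and logistic growth
toward `1 − e_tot` under sustained normoxia (where no hypoxic cell
ever appears and the ECM is untouched). The logistic comparison is
made on the density scale — the lumped law describes the density
inside the initially occupied region, where the initial condition
carries no ECM; mass- and density-scale comparisons are proportional
for the step profile, so this is presentation, not substance. Both
closed forms are themselves validated against high-accuracy ODE
integration in the test suite, and the trait-advection operator
against the characteristic ODE `dμ/dt = v(μ)`.

At the default mesh the sup-error against the exponential oracle is
1.7 × 10⁻³ (dominated by the forward-Euler time error) and halves
under one grid refinement, consistent with the first-order scheme.

## Scale of the standard runs

All experiment families run on the default 201 × 101 mesh to
`t_final = 60` (cyclic step `dt ≈ 0.018`, about 3300 steps per memory
arm — a few seconds per run on one core). The grid-sensitivity checks
in the acceptance suite repeat a subset of each sweep with `dx` and
`dμ` halved and assert that every qualitative ordering (memory arm:
smaller volume, farther front, for every period; volume decreasing and
invasion increasing in hypoxic bias; front-to-bulk strong-memory ratio
≥ 1) is unchanged.

## Limitations

* Oxygen is spatially homogeneous and externally prescribed; no
  consumption, no gradients, hence no intratumoral hypoxic niches.
* 1D space only; invasion "volume" is a line integral.
* Sharp Heaviside switching means behaviour exactly at `c = c_H` is a
  convention, and the memory timescale switches discretely rather than
  interpolating near the threshold.
* First-order upwinding adds numerical diffusion in `μ`; the phenotype
  distribution near the drift equilibrium is spread over a few mesh
  cells rather than a true point mass (the equilibrium mean is
  recovered to ~10⁻² on the default mesh).
* With the reference parameterization the invasion front reaches
  `x ≈ 9.53–9.60` by `t = 60` for period-5 cycles (converged under
  refinement), so boundary-hitting targets beyond that are reported as
  not-reached rather than extrapolated.
* Forward Euler and the explicit scheme make the per-run cost scale as
  `N · M · t_final / dt`; the scheme is deliberately kept identical to
  the printed difference equations rather than upgraded to a
  higher-order or implicit integrator.
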