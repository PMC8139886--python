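# Methods

## Model

The super compact pairwise (SCPW) model approximates SIS dynamics on a
configuration-model-like contact network. Expected node counts [S], [I] and
connected-pair counts [SI], [SS], [II] evolve under transmission at rate τ
along S–I edges and recovery at rate γ; expected triples are closed by the
factor Q = α[S]/([SI]+[SS])² + β/([SI]+[SS]), which stands in for
(S₂ − S₁)/S₁², the pair/triple ratio of the susceptible-degree distribution.
The closure constants α and β are functions of the first three raw degree
moments only, which is the model's defining property: network structure
enters solely through ⟨k⟩, ⟨k²⟩, ⟨k³⟩.

Assumptions inherited from the closure: large network, negligible
clustering, degrees not all equal (α and β have denominator ⟨k²⟩ − ⟨k⟩², so
a regular network is a genuine singular limit — `derived_constants` refuses
it rather than guessing a limit; the threshold formula itself remains valid
there and is exposed separately). The model is deterministic (expected
values), so it cannot represent stochastic die-out above threshold.

Nondimensionalization: fractions v = [S]/N, w = [I]/N, x = [SI]/(⟨k⟩N),
y = [SS]/(⟨k⟩N), z = [II]/(⟨k⟩N) on the time scale T = γt, leaving the single
parameter δ = τ/γ. Two conservation laws, v + w = 1 and 2x + y + z = 1,
reduce the five equations to three; both reductions are implemented — (w, x, z)
vanishes at the disease-free equilibrium (DFE) and is used for its Jacobian,
(v, x, y) is most compact and underlies the steady-state polynomials. The
steady-state constants σ = ⟨k⟩δ_c, λ = αδ_c/⟨k⟩, μ = βδ_c satisfy λ + μ = 1
identically; this identity is asserted before any expansion is evaluated,
because it is what cancels the constant term of the near-threshold series.

A note on the steady-state polynomial P(x, y): deriving it from the reduced
(v, x, y) equations (add half the y-equation to the x-equation, substitute
v = 1 − σ(δ/δ_c)x, clear denominators) gives the term μx²(x + y), and the
near/far expansions are consistent with that form, so that is what the
package implements. The companion polynomial Q has the trivial factor x —
the DFE — divided out, so x = 0 does not generally solve Q.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| δ = τ/γ | transmission/recovery ratio (dimensionless) | — | the single epidemiological input |
| `tail_mass` | Poisson truncation upper-tail mass | 1e-12 | third-moment truncation error ~K³·tail ≈ 1e-8 absolute at mean 10; pmf renormalized after truncation |
| `variance_tol` | relative degeneracy guard on ⟨k²⟩ − ⟨k⟩² | 1e-10 | refuse α, β at the regular-network 0/0 |
| `denominator_guard` | minimum x + y (or [SI]+[SS]) | 1e-12 | the closure is singular with no susceptible-anchored pairs; error, never regularize |
| integrator | LSODA, rtol 1e-8 / atol 1e-10, t_end 200 | — | stiff-capable; convergence event stops early when the rate norm < 1e-10 |
| `init_w` | initial prevalence for epidemic runs | 1e-2 | proportionate-mixing pair seed x:y:z = vw:v²:w², renormalized to 2x+y+z = 1; steady states do not depend on it |
| Newton | max 100 iterations, residual < 1e-12 or step < 1e-14, step-halving damping | — | accepted roots must have residuals < 1e-10 and lie in x > 0, y ≥ 0, x+y < 1, 2x+y < 1 |
| `seed_switch` | δ/δ_c below which the near seed is used | 2 | either seed usually converges; continuation overrides inside diagrams |
| `max_eta`, `max_eps` | regime guards for the expansions | 0.5, 0.9 | no good intermediate-regime approximation exists; surface the limit instead of extrapolating (relaxed internally for diagram columns) |
| far-sensitivity δ | evaluation point for far-regime grids | 1.5 | all far partials share a 1/δ factor, so relative structure is δ-invariant; δ is recorded in grid metadata |

Near-threshold sensitivities are reported as their δ → δ_c limit values by
default (∂w*/∂⟨k³⟩ is exactly 0 there); the full δ-dependent derivative of
the near approximation is available via `sens_near(m, delta=...)` and reduces
to the limit values at δ = δ_c.

## Numerical choices

- Moments use exact compensated summation (`math.fsum`), stable to ~1e-12
  relative for sequences up to 1e7 entries.
- Conservation along trajectories is monitored, not enforced by projection;
  drift beyond 1e-6 raises. Positivity is checked, and violations are
  surfaced rather than clipped.
- DFE stability is decided by the closed-form block conditions
  (Det B = 2(1 − δk̄) > 0 and Tr B < 0), which the eigenvalue sweep in the
  tests confirms flips exactly at δ_c = 1/k̄.
- Endemic stability is assessed numerically — eigenvalues of the (v, x, y)
  Jacobian by central finite differences with step 1e-7 — because stability
  is only established analytically near the threshold.
- `solve_endemic` falls back to a 40-step geometric continuation from just
  above δ_c if both asymptotic seeds fail; inside `bifurcation_diagram` each
  grid point is seeded by its predecessor, and δ_c itself is always appended
  to the grid.
- The test-time root oracle eliminates y from (P, Q) via a sympy resultant
  and enumerates all real roots, which is exhaustive where Newton is not;
  the production path stays seeded Newton for robustness and speed.

## Synthetic networks

The fixture generator reproduces the two study networks: a deterministic
bimodal sequence (5000 nodes of degree 3 and 5000 of degree 5; moments
exactly (4, 17, 76), δ_c = 4/13) and a seeded Poisson mean-10 sample of
10,000 draws, resampled as a whole when the degree sum is odd so a graphical
realization exists. The analytic Poisson law (⟨k²⟩ = 110, ⟨k³⟩ = 1310,
δ_c = 0.1) and a sampled sequence are both supported; sampled third moments
scatter around 1310 with a standard error of ~4 at N = 10,000, so no attempt
is made to match any particular realization. What the generator does **not**
emulate: degree correlations, clustering, finite-size stochastic epidemic
dynamics, or any edge-level structure — the SCPW model never sees those, so
passing tests validate the moment-closure analysis, not agreement with
simulations on real contact networks.

## Problem sizes

The test suite and the acceptance script run at the study scales throughout
— 10,000-node fixtures, δ grids of 21–41 points, ODE horizons up to T = 2000
with convergence-based early stopping — since every computation here is
desk-scale (seconds).

## Known limitations

- No approximation bridges the intermediate regime between η ≤ 0.5 and
  ε ≤ 0.9; the exact Newton branch is the only option there.
- Approximation error of the expansions is checked empirically (second-order
  remainder ratios on the two example networks), not bounded analytically;
  other network families may behave worse.
- The threshold formula, like the compact pairwise model's, is positive for
  power-law-ish networks where the true large-N threshold vanishes; the
  model is not intended for heavy-tailed degree distributions at large N.
- The far-regime implied threshold (w* = 0 crossing at δ* = −Gδ_c, with
  G = (δ_c + μ − σ)/(λσ)) requires G < 0; the classification of δ* as an
  over- or underestimate of δ_c is reported together with the moment rule
  ⟨k²⟩ ≥ ⟨k⟩² + ⟨k⟩ that guarantees overestimation.
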