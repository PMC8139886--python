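# scpw — super compact pairwise SIS epidemics on heterogeneous networks

`scpw` analyzes SIS (susceptible–infectious–susceptible) epidemics on contact
networks through the **super compact pairwise (SCPW) model**: a four-equation
moment closure of the pairwise SIS equations whose only network input is the
first three raw moments of the degree distribution, ⟨k⟩, ⟨k²⟩, ⟨k³⟩. It is
aimed at infectious-disease modellers who want network-aware thresholds,
endemic prevalence, and moment-level control insights without simulating the
network itself.

## The model

The SCPW system tracks expected node counts [S], [I] and pair counts [SI],
[SS], [II] with transmission rate τ and recovery rate γ, closing the triples
with

    Q = α[S]/([SI]+[SS])² + β/([SI]+[SS]),
    α = (⟨k²⟩² − ⟨k⟩⟨k³⟩)/(⟨k²⟩ − ⟨k⟩²),
    β = (⟨k³⟩ − ⟨k⟩⟨k²⟩)/(⟨k²⟩ − ⟨k⟩²) − 1.

After nondimensionalizing (fractions v, w, x, y, z; time T = γt; single
parameter δ = τ/γ) the toolkit provides:

- **Epidemic threshold** δ_c = ⟨k⟩/(⟨k²⟩ − ⟨k⟩): the disease-free equilibrium
  is stable iff δ < δ_c (determinant of the reduced Jacobian block is
  2(1 − δk̄) with k̄ = (⟨k²⟩ − ⟨k⟩)/⟨k⟩), and a stable endemic branch emerges
  through a forward transcritical bifurcation at δ_c.
- **Exact endemic equilibrium**, from the steady-state polynomial system
  P(x, y) = Q(x, y) = 0 by seeded Newton iteration, with bifurcation diagrams
  over a δ grid (cross-checked against long-time ODE integration).
- **Asymptotic prevalence** in two regimes, with small parameters
  η = 1 − δ_c/δ (near threshold) and ε = δ_c/δ (far from threshold):

      w* ≈ σ/(λσ + μδ_c + μ − δ_c) · η,        w* ≈ 1 + (δ_c + μ − σ)/(λσ) · ε,

  where σ = ⟨k⟩δ_c, λ = αδ_c/⟨k⟩, μ = βδ_c.
- **Moment sensitivities** ∂w*/∂⟨kⁿ⟩ in closed form for both regimes, with
  feasibility masking (Jensen ⟨k²⟩ ≥ ⟨k⟩², Cauchy–Schwarz ⟨k²⟩² ≤ ⟨k³⟩⟨k⟩)
  and heat-map grids. Near the threshold, prevalence falls with ⟨k⟩ and rises
  with ⟨k²⟩; far from it the signs reverse — containment and mitigation call
  for different network interventions.

## Worked example

```python
import scpw

m = scpw.moments_from_sequence([3] * 5000 + [5] * 5000)   # bimodal network
c = scpw.derived_constants(m)
print(f"moments: <k>={m.k1}, <k^2>={m.k2}, <k^3>={m.k3}")
print(f"threshold delta_c = {c.delta_c:.4f}")

delta = 2 * c.delta_c
eq = scpw.solve_endemic(delta, c)
print(f"endemic prevalence at delta=2*delta_c: w* = {eq.w:.6f} (stable={eq.stable})")
traj = scpw.integrate("nondim", scpw.default_initial_state(0.01), delta, c, kmean=m.k1)
print(f"long-time ODE prevalence:              w  = {traj.terminal.w:.6f}")
t = scpw.sens_near(m)
print(f"near sensitivities: dw/d<k> = {t.d_k1:.4f}, dw/d<k^2> = {t.d_k2:.4f}, dw/d<k^3> = {t.d_k3}")
```

prints

```
moments: <k>=4.0, <k^2>=17.0, <k^3>=76.0
threshold delta_c = 0.3077
endemic prevalence at delta=2*delta_c: w* = 0.532514 (stable=True)
long-time ODE prevalence:              w  = 0.532514
near sensitivities: dw/d<k> = -0.3696, dw/d<k^2> = 0.0870, dw/d<k^3> = 0.0
```

The bimodal network (half degree 3, half degree 5) has threshold
δ_c = 4/13 ≈ 0.3077: below it any outbreak dies out; at δ = 2δ_c roughly 53 %
of the population is infectious at the endemic steady state, and the
root-solve agrees with brute-force ODE integration to better than 1e-6. The
negative ∂w*/∂⟨k⟩ and positive ∂w*/∂⟨k²⟩ say that near the threshold,
prevalence is reduced by raising the mean degree or lowering the second
moment (both raise δ_c).

The same analyses are available from the shell, e.g.

```
scpw threshold --family bimodal
scpw bifurcate --family poisson --mean 10 --delta-min 0 --delta-max 0.5 \
    --n-points 26 --out bif.csv
scpw sensitivity --regime far --k3 100 --out sens.csv --plot sens.png
```

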