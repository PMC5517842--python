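# melsim — melanoma combination therapy as a free-boundary PDE

`melsim` simulates the response of an avascular, radially symmetric melanoma
to combined **BRAF/MEK inhibition** and **PD-1 checkpoint blockade**.  It is
aimed at modellers studying tumour–immune dynamics and drug-combination
design: the model predicts not only how much each drug shrinks the tumour but
also where in dose space the two drugs become *antagonistic* — zones where
raising one dose makes the outcome worse.

## The model

Inside the tumour ball 0 ≤ r ≤ R(t), fourteen fields evolve by
reaction–diffusion–advection: dendritic cells *D*, effector T cells *T₁*
(Th1) and *T₈* (CD8⁺), Tregs *T_r*, MDSCs *M*, cancer cells *C*, the
cytokines IL-12, IL-2, TGF-β, IL-6 and IL-10, membrane PD-1 (*P*), and the
drugs anti-PD-1 (*A*) and BRAF/MEKi (*B*).  PD-L1 is algebraic,
L = ρ_L(T₁+T₈+ε_M M+ε_C C), and the PD-1–PD-L1 complex acts through the
product P·L: it damps effector T-cell activation by 1/(1+P·L/K′_TQ) and
promotes Treg activation by P·L/(K′_Q+P·L).

The total cell density is constant (θ = 0.6039 g/cm³), so net cell
production S drives a radial velocity u with θ∇·u = S, and the free boundary
moves with the cells:

    dR/dt = u(R, t),      u(r) = (θ r²)⁻¹ ∫₀ʳ s² S(s) ds.

Each drug enters with a piecewise source (level γ to day 30, ramp to zero by
day 33).  BRAF/MEKi damps cancer proliferation by 1/(1+B/K_CB) and boosts
dendritic-cell IL-12 production; anti-PD-1 depletes P.  The efficacy of a
dose pair is E(γ_B, γ_A) = (R₆₀(0,0) − R₆₀(γ_B,γ_A))/R₆₀(0,0).

The solver is a fully implicit moving-mesh finite-difference scheme (Picard
iteration, one tridiagonal solve per field per iteration); the mesh moves
with the converged velocity.  See `docs/methods.md` for the numerics and the
handful of places where stored constants and internally consistent choices
diverge from their commonly quoted values.

## Worked example

```python
from melsim import simulate, DoseSchedule, SolverOptions

control = simulate(t_end=60.0)                      # untreated
combo = simulate(schedule_A=DoseSchedule(0.3e-9),   # anti-PD-1, g/cm^3/day
                 schedule_B=DoseSchedule(0.5e-9))   # BRAF/MEKi, g/cm^3/day

print(f"control R(60)  = {control.R[-1]:.4f} cm")
print(f"combined R(60) = {combo.R[-1]:.4f} cm")
print(f"doubling time  = {control.exponential_doubling_time():.1f} days")
```

prints

```
control R(60)  = 0.0365 cm
combined R(60) = 0.0218 cm
doubling time  = 10.0 days
```

The untreated tumour grows from 0.01 cm to ≈ 0.037 cm in 60 days, its volume
doubling about every 10 days; the reference combination cuts the day-60
radius by roughly 40%.  `control.averages` holds the per-species spatial
averages over time (a pandas DataFrame), and `control.final_state` the full
radial profiles.

The same experiments are available from the shell:

```bash
melanoma-sim control --out results/control
melanoma-sim therapy --gamma-a 3e-10 --gamma-b 5e-10 --out results/combo
melanoma-sim map --nb 6 --na 5 --out results/map       # efficacy heat map data
melanoma-sim sensitivity --n 100 --seed 1 --out results/prcc
melanoma-sim derive-params                              # regenerate the parameter table
```

Each command writes CSV payloads plus a `meta.json` recording the full
effective configuration.  Parameter overrides and solver settings come from
a YAML file passed with `--config`.

Beyond single runs, `melsim.experiments` maps E(γ_B, γ_A) over dose grids
(maximum ≈ 0.97 at high doses), sweeps day-60 T-cell averages along one-drug
axes to locate antagonism (T̄₁, T̄₈ fall with γ_B when γ_A is high, rise when
it is low), and can inject IL-12 directly to neutralise the pathway behind
the antagonism.  `melsim.sensitivity` runs Latin-hypercube/PRCC global
sensitivity of R(60) over ten production and killing parameters.

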