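# Methods

## The model

`melsim` simulates an avascular, radially symmetric melanoma under combined
BRAF/MEK inhibition and PD-1 checkpoint blockade.  Inside the tumour ball
0 ≤ r ≤ R(t) it evolves fourteen fields (g/cm³): six cell species — dendritic
cells D, Th1 cells T₁, cytotoxic T cells T₈, Tregs T_r, MDSCs M, cancer cells
C — five cytokines (IL-12, IL-2, TGF-β, IL-6, IL-10), membrane PD-1 (P) and
the two drugs, anti-PD-1 (A) and BRAF/MEKi (B).

Two algebraic closures remove stiff sub-systems:

* PD-L1 is slaved to its carriers, L = ρ_L(T₁ + T₈ + ε_M M + ε_C C).
* The PD-1–PD-L1 complex equilibrates on sub-second time scales, so both of
  its effects are functions of the product P·L: effector T-cell activation
  and proliferation are damped by 1/(1 + P·L/K′_TQ), and Treg activation is
  promoted by P·L/(K′_Q + P·L), with K′_Q = 2 K′_TQ by construction (at the
  reference steady state the inhibition equals 1/3 and the promotion 1/2).

The kinetics follow mass-action/Michaelis–Menten balances: DC activation by
tumour-derived danger signals gated by C/(K_C + C); IL-12-driven T-cell
activation damped by IL-10, Tregs, and the checkpoint; IL-2-driven
proliferation; TGF-β- and complex-driven Treg differentiation; IL-6-gated
MDSC recruitment toward an influx level M₀; logistic cancer growth damped by
1/(1 + B/K_CB) and reduced by T-cell killing (η₁T₁ + η₈T₈)C.  BRAF/MEKi also
restores DC function, boosting IL-12 production by (1 + λ_I12B·B/(K_B + B)).
P evolves as the T-cell activation/death budget scaled by P per unit of
PD-1-bearing T-cell mass, minus blocking by the antibody (μ_PA·P·A).  Drugs
are dosed by a piecewise source: constant γ to day 30, linear ramp to zero at
day 33.  T_r and M are chemotactically recruited along IL-6 gradients
(coefficient χ); the same coefficient appears, scaled by ε_T, in the P
budget.

Because the total cell density is held constant at θ = 0.6039 g/cm³, net
cell production S (the sum of the six cell right-hand sides, including
chemotaxis) drives a radial velocity, θ∇·u = S, i.e.
u(r) = (θ r²)⁻¹ ∫₀ʳ s²S ds, and the free boundary moves with it:
dR/dt = u(R, t).  Boundary conditions: symmetry at r = 0; at r = R a Robin
influx for the effector T cells, ∂X/∂r + σ_T(I₁₂)(X − X̂) = 0 with
σ_T = σ₀ I₁₂/(I₁₂ + K_I12), and homogeneous Neumann for everything else.

## Parameters

All defaults live in `ParameterSet` (`baseline_parameters()`); units are
g/cm³, day⁻¹, cm²/day, cm³/(g·day).  Most "estimated" constants follow from
steady-state balances in which each species sits at its half-saturation
value; the `derive_*` functions implement those balances so the entire
default table can be regenerated and audited (`melanoma-sim derive-params`).
Where the original estimates chained rounded intermediates (Treg rates, drug
uptake constants), the derivations reproduce that arithmetic so regenerated
values agree with the stored defaults digit-for-digit.

Parameters that deserve comment:

* `d_M` = 0.03/day (an alternative 0.015 appears in the MDSC balance;
  overridable).
* `K_TI10` = 8.75e-11 g/cm³, the steady IL-10 level — the value the ½-factor
  in every T-cell balance actually requires; the alternative 2e-7 is
  available as an override.
* `Kp_TQ`/`Kp_Q` absorb the unknown complex association constant σ; only the
  product scale is identifiable, and the sensitivity sweep samples it as a
  multiplicative factor on `Kp_TQ`.
* `lam_I12B` defaults to 1 (the IL-12 boost saturating at high B).

## Initial conditions

Cells start uniform at D = 2e-4, T₁ = 4e-3, T₈ = 2e-3, T_r = 3e-3, M = 0.22,
and **C = 0.3747** — the value that makes the cells sum exactly to θ.  The
alternative C(0) = 0.3774 (available via
`SolverOptions(rescale_initial_c=False)`) violates the total-density
constraint by 0.45%; because the constraint equilibrium satisfies
d(total)/dt = ∇·u (θ − total), the violation is *amplified* by
e^{3|ln(R_f/R_0)|} whenever the tumour contracts, which destroys every
high-dose simulation long before day 60.  Cytokines start near their steady
values (I₁₂ = 4e-10, I₂ = 4.74e-11, T_β = 2.62e-13, I₆ = 3.06e-11,
I₁₀ = 9.66e-11); A = B = 0; R(0) = 0.01 cm.

Initial P defaults to the ratio-consistent value ρ_P(T₁ + T₈ + ε_T T_r)(0)
= 2.09e-9.  This matters: with no antibody the P equation materially
conserves the ratio P/(T₁ + T₈ + ε_T T_r) at whatever value it starts from.
Starting P at the reference steady level 8.3e-10 against the (elevated)
initial T-cell load locks that ratio at ~0.4 ρ_P forever, checkpoint
inhibition never reaches its intended strength, and the untreated tumour
stalls at R(60) ≈ 0.023 cm instead of ≈ 0.037 cm.  The alternative is kept
as `SolverOptions(printed_initial_p=True)`.

## Numerics

Fully implicit moving-mesh finite differences.  Each step solves, per field,
the non-uniform three-point discretisation of ∂X/∂t = δΔX − ∇·(uX) + F with
the spherical Laplacian X_rr + (2/r)X_r; cytokines and drugs omit advection.
At r = 0 the (2/r) terms take their symmetric limits (Laplacian → 3X_rr,
∇·u → 3u_r).  The outer boundary applies the flux condition through a ghost
node eliminated from the PDE row (second order; the PDE, including
reactions, holds at the boundary node).  Nonlinear coefficients are lagged
and Picard-iterated — one tridiagonal solve per field per iteration — until
the relative change drops below `picard_tol`; each field's own linear loss
terms sit on the implicit diagonal (TGF-β turns over at ~500/day, so a fully
lagged source would diverge at practical step sizes).  After convergence the
velocity from the converged state moves the mesh, rᵢ ← rᵢ + uᵢτ, advancing
the boundary.  Negative values produced by the (non-positivity-preserving)
scheme are clipped to zero and the clipped magnitude is logged; in baseline
runs it is exactly zero.

Quadratures: spatial averages use trapezoid ratios (∫r²X dr / ∫r² dr, exact
for constants); the velocity integral reconstructs S piecewise-linearly and
integrates it against s² exactly, so a constant source gives u = Sr/(3θ) to
machine precision.  Remeshing to a uniform grid (monotone cubic
interpolation) triggers if adjacent spacings differ by more than 5×; in
practice the near-uniform velocity keeps the Lagrangian mesh regular.

Resolution defaults, chosen for self-convergence (halving τ and doubling N
moves R(60) by < 0.1%):

| setting | nodes | τ (day) | use |
|---|---|---|---|
| default | 101 | 0.005 | single runs, control validation |
| coarse  | 61  | 0.01  | dose maps, antagonism sweeps |
| sweep   | 41  | 0.04  | 100-simulation sensitivity sweep |

`picard_tol` = 1e-8, `picard_max` = 50 (typical convergence: 3–4 iterations).

## Experiments and sensitivity

Efficacy of a dose pair is E = (R₆₀(0,0) − R₆₀(γ_B,γ_A))/R₆₀(0,0) ∈ [0,1],
mapped over γ_B ∈ [0, 5e-9] and γ_A ∈ [0, 1.4e-9] g/cm³/day.  The map is
deterministic and embarrassingly parallel; failed cells are flagged, not
fatal.  Antagonism is detected as a relative decrease > 1e-3 between
adjacent doses in day-60 T̄₁/T̄₈ (or E).  A direct IL-12 source γ_I12 can be
added to probe the cancer→DC→IL-12→T-cell pathway that causes the
antagonism.

Global sensitivity: Latin hypercube over ten production/killing parameters
(half-to-double ranges), one control simulation per sample at the sweep
resolution, PRCC of R(60) with average-rank ties and p-values from
t = PRCC·√(df/(1 − PRCC²)), df = n − 2 − (k − 1).  Defaults n = 100,
significance p < 0.01.  Magnitudes at this n and resolution are indicative;
the robust outputs are the signs and the η₈-versus-η₁ ordering.

The volume doubling time of the control run is reported as the exponential
fit over days 5–35.  The first half-day is an insertion transient — the
implanted MDSC load (0.22) exceeds its influx level (0.21), so the tumour
briefly shrinks (< 0.2% in R) before settling into clean exponential growth;
a first-crossing doubling measure is also provided
(`volume_doubling_time()`), which that transient inflates to ~13 days.

## What the simulations do and do not show

All inputs are model constants; there is no external data and no fitting.
Agreement with the published anchors (control radius, doubling time,
efficacy maximum, treatment ordering, antagonism reversal, PRCC signs)
validates the implementation of the model, not the model's fidelity to
melanoma biology.  Known limitations inherited from the model: avascular
tumour, radial symmetry, constant naive-cell reservoirs, quasi-steady
necrosis/danger-signal pathway (DC activation depends directly on C), no
pharmacokinetics linking γ_A/γ_B to administered doses, and a continuum
description that becomes physically questionable when high-dose therapy
shrinks the tumour to a few tens of microns.
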