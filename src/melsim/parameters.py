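"""Parameter set and steady-state parameter derivations.

The simulator's rate constants, half-saturations and structural constants are
taken from published estimates for melanoma–immune interactions.  Most of the
"Estimated" entries follow from simple steady-state balances: each production
rate is chosen so that, at a reference steady state in which every species sits
at its half-saturation value, production exactly cancels loss.  Those balances
are implemented here as executable functions so that the full default table can
be regenerated (and audited) from the handful of primary inputs — molecular
weights, half-lives, receptor counts and reference cell densities.

Where the original arithmetic chained *rounded* intermediate values (e.g. the
Treg activation rates and the drug-uptake constants), the derivations here do
the same, so the regenerated numbers agree digit-for-digit with the stored
defaults; see :func:`round_sig`.

Units: densities/concentrations g/cm^3, rates day^-1, diffusion cm^2/day,
killing and blocking rates cm^3/(g day), lengths cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as _dc_fields, replace
from typing import Iterator

__all__ = [
    "ParameterSet",
    "baseline_parameters",
    "round_sig",
    "derive_diffusion_coefficient",
    "derive_t_cell_activation_rates",
    "derive_treg_rates",
    "derive_tumor_growth_params",
    "derive_cytokine_production_rates",
    "derive_checkpoint_params",
    "derive_drug_params",
    "regenerate_estimated_table",
]

# Reference molecule: VEGF, used as the anchor of the cube-root scaling law for
# protein diffusivities.
_MW_VEGF_KDA = 24.0
_DELTA_VEGF = 8.64e-2  # cm^2/day

# Molecular weights (kDa) used for the diffusion-coefficient estimates.
MOLECULAR_WEIGHTS_KDA = {
    "I12": 70.0,
    "I2": 17.6,
    "Tb": 25.0,
    "I6": 21.0,
    "I10": 20.5,
    "A": 32.0,
    "B": 0.48993,  # small-molecule BRAF/MEK inhibitor, 489.93 Da
}


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 maps to 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class ParameterSet:
    """Complete constant set for the tumour–immune–drug model.

    Attribute groups mirror the roles the constants play: diffusion, boundary
    flux/chemotaxis, activation/production, killing/uptake, checkpoint
    expression, death/degradation, reservoirs, half-saturations and the
    structural total-cell-density constant ``theta``.
    """

    # --- diffusion (cm^2/day) ---
    delta_D: float
    delta_T: float
    delta_M: float
    delta_C: float
    delta_I12: float
    delta_I2: float
    delta_Tb: float
    delta_I6: float
    delta_I10: float
    delta_A: float
    delta_B: float
    # --- boundary flux & chemotaxis ---
    sigma_0: float  # 1/cm
    chi: float      # cm^5/(g day)
    # --- activation / production ---
    lam_DC: float
    lam_T1I12: float
    lam_T1I2: float
    lam_T8I12: float
    lam_T8I2: float
    lam_TrTb: float
    lam_TrQ: float
    lam_M: float
    lam_C: float
    lam_0: float
    lam_I12D: float
    lam_I12B: float  # dimensionless boost of IL-12 production by BRAF/MEKi
    lam_I2T1: float
    lam_TbC: float
    lam_TbTr: float
    lam_TbM: float
    lam_I6C: float
    lam_I10C: float
    lam_I10M: float
    # --- killing / uptake ---
    eta_1: float   # cm^3/(g day)
    eta_8: float   # cm^3/(g day)
    mu_PA: float   # cm^3/(g day)
    mu_BC: float   # day^-1
    # --- checkpoint expression ---
    rho_P: float
    rho_L: float
    eps_T: float
    eps_M: float
    eps_C: float
    Kp_TQ: float   # g^2/cm^6, inhibition scale for T-cell function (K'_TQ)
    Kp_Q: float    # g^2/cm^6, half-saturation of Treg promotion (K'_Q)
    # --- deaths / degradations (day^-1) ---
    d_D: float
    d_T1: float
    d_T8: float
    d_Tr: float
    d_M: float
    d_C: float
    d_I12: float
    d_I2: float
    d_Tb: float
    d_I6: float
    d_I10: float
    d_A: float
    d_B: float
    # --- reservoirs / capacities (g/cm^3) ---
    D_0: float
    T_10: float
    T_80: float
    M_0: float
    C_M: float
    That_1: float
    That_8: float
    # --- half-saturations (g/cm^3) ---
    K_T1: float
    K_T8: float
    K_Tr: float    # also the Treg half-saturation in the T-cell inhibition factor
    K_C: float
    K_I12: float
    K_I2: float
    K_Tb: float
    K_I6: float
    K_I10: float
    K_B: float
    K_CB: float
    K_TI10: float
    # --- structural ---
    theta: float   # total cell density (g/cm^3)
    Pbar: float    # reference steady-state PD-1 concentration
    Lbar: float    # reference steady-state PD-L1 concentration

    def __post_init__(self) -> None:
        for f in _dc_fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")
        for name in ("eps_T", "eps_M", "eps_C"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    # -- conveniences -------------------------------------------------------
    def names(self) -> Iterator[str]:
        return (f.name for f in _dc_fields(self))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        """Return a copy with named values replaced; unknown names are rejected."""
        known = {f.name for f in _dc_fields(self)}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {', '.join(unknown)}")
        return replace(self, **overrides)


def baseline_parameters() -> ParameterSet:
    """The default parameter set (the published summary tables verbatim).

    Notes on three entries:

    * ``d_M`` is 0.03/day (the tabulated value; an alternative 0.015/day
      appears in the MDSC steady-state estimate) — overridable.
    * ``K_TI10`` defaults to the steady-state IL-10 concentration 8.75e-11,
      which is the value actually used by the half-factor in every T-cell
      rate derivation; an alternative 2e-7 is sometimes quoted — overridable.
    * ``Kp_TQ``/``Kp_Q`` absorb the unknown complex association constant:
      every occurrence of the PD-1–PD-L1 complex is rewritten in terms of the
      product P*L, with Kp_Q = 2*Kp_TQ exactly.
    """
    return ParameterSet(
        delta_D=8.64e-7, delta_T=8.64e-7, delta_M=8.64e-7, delta_C=8.64e-7,
        delta_I12=6.05e-2, delta_I2=9.58e-2, delta_Tb=8.52e-2,
        delta_I6=9.03e-2, delta_I10=9.11e-2, delta_A=7.85e-2, delta_B=3.16e-1,
        sigma_0=1.0, chi=10.0,
        lam_DC=4.0, lam_T1I12=18.64, lam_T1I2=0.25, lam_T8I12=16.6,
        lam_T8I2=0.25, lam_TrTb=0.415, lam_TrQ=0.083, lam_M=1.05,
        lam_C=0.616, lam_0=0.069, lam_I12D=2.76e-6, lam_I12B=1.0,
        lam_I2T1=2.82e-8, lam_TbC=2.18e-10, lam_TbTr=5.57e-9, lam_TbM=2.18e-10,
        lam_I6C=3.54e-10, lam_I10C=9.10e-10, lam_I10M=1.82e-9,
        eta_1=11.5, eta_8=46.0, mu_PA=6.04e6, mu_BC=6.17e-10,
        rho_P=2.49e-7, rho_L=5.22e-7, eps_T=0.8, eps_M=0.005, eps_C=0.01,
        Kp_TQ=1.77e-18, Kp_Q=3.54e-18,
        d_D=0.1, d_T1=0.197, d_T8=0.18, d_Tr=0.2, d_M=0.03, d_C=0.17,
        d_I12=1.38, d_I2=2.376, d_Tb=499.066, d_I6=4.16, d_I10=8.32,
        d_A=0.046, d_B=1.66,
        D_0=2e-5, T_10=4e-4, T_80=2e-4, M_0=0.21, C_M=0.8,
        That_1=4e-3, That_8=2e-3,
        K_T1=2e-3, K_T8=1e-3, K_Tr=5e-4, K_C=0.4,
        K_I12=8e-10, K_I2=2.37e-11, K_Tb=2.68e-13, K_I6=3.4e-11,
        K_I10=8.75e-11, K_B=6.69e-10, K_CB=3.06e-9, K_TI10=8.75e-11,
        theta=0.6039, Pbar=8.46e-10, Lbar=4.176e-9,
    )


# ---------------------------------------------------------------------------
# Derivations
# ---------------------------------------------------------------------------

def derive_diffusion_coefficient(molecular_weight_kda: float) -> float:
    """Protein diffusivity from the cube-root molecular-weight scaling law.

    delta_p = (M_V / M_p)^(1/3) * delta_V anchored on VEGF
    (M_V = 24 kDa, delta_V = 8.64e-2 cm^2/day).  Strictly decreasing in the
    molecular weight.
    """
    if molecular_weight_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return (_MW_VEGF_KDA / molecular_weight_kda) ** (1.0 / 3.0) * _DELTA_VEGF


def derive_t_cell_activation_rates(params: ParameterSet | None = None) -> tuple[float, float]:
    """IL-12 activation rates of CD4+ (Th1) and CD8+ T cells.

    At the reference steady state every Hill factor equals 1/2 and the
    checkpoint inhibition equals 1/3 (complex at twice its inhibition scale),
    so the balance for each effector T cell reads::

        (lam * T_reservoir * 1/2 * 1/2 * 1/2 + lam_I2 * T * 1/2) * 1/3 = d_T * T

    solved for ``lam``, with steady densities T1 = K_T1 and T8 = K_T8.
    """
    p = params or baseline_parameters()
    if p.T_10 <= 0 or p.T_80 <= 0:
        raise ValueError("degenerate naive T-cell reservoir density")
    lam_t1 = (3.0 * p.d_T1 * p.K_T1 - 0.5 * p.lam_T1I2 * p.K_T1) * 8.0 / p.T_10
    lam_t8 = (3.0 * p.d_T8 * p.K_T8 - 0.5 * p.lam_T8I2 * p.K_T8) * 8.0 / p.T_80
    return lam_t1, lam_t8


def derive_treg_rates(params: ParameterSet | None = None) -> tuple[float, float]:
    """Treg activation rates by TGF-beta and by the checkpoint complex.

    Assumes TGF-beta activates Tregs five times more strongly than the
    PD-1–PD-L1 complex (lam_TrTb = 5 * lam_TrQ) and balances, at steady state
    with both saturation factors at 1/2::

        3 * lam_TrQ * T_10 = d_Tr * Tr ,   Tr = K_Tr.

    The complex rate is reported at its two-significant-figure printed
    precision and the TGF-beta rate as five times that value, mirroring the
    original two-step arithmetic.
    """
    p = params or baseline_parameters()
    lam_q = round_sig(p.d_Tr * p.K_Tr / (3.0 * p.T_10), 2)
    return 5.0 * lam_q, lam_q


def derive_tumor_growth_params(params: ParameterSet | None = None) -> tuple[float, float, float, float]:
    """Cancer growth rate, T-cell killing rates, and BRAF/MEKi inhibition scale.

    The net per-capita growth in the untreated tumour is lam_0 (volume doubles
    in ln2/lam_0 ~ 10 days); without immune pressure it would be 2*lam_0, and
    under full therapy it drops to lam_0/5.  With the steady cancer density at
    half its carrying capacity these three statements give::

        lam_C = 2*(2*lam_0 + d_C)
        eta_1*T1 + eta_8*T8 = lam_0,  eta_8 = 4*eta_1
        K_CB  = K_B * (5*d_C + 6*lam_0) / (4*lam_0)

    ``K_CB`` is +inf when ``lam_0`` is 0 (no inhibition scale is defined).
    """
    p = params or baseline_parameters()
    lam_c = 2.0 * (2.0 * p.lam_0 + p.d_C)
    eta_1 = p.lam_0 / (p.K_T1 + 4.0 * p.K_T8)
    eta_8 = 4.0 * eta_1
    if p.lam_0 > 0:
        k_cb = p.K_B * (5.0 * p.d_C + 6.0 * p.lam_0) / (4.0 * p.lam_0)
    else:  # pragma: no cover - ParameterSet enforces lam_0 > 0
        k_cb = math.inf
    return lam_c, eta_1, eta_8, k_cb


def derive_cytokine_production_rates(params: ParameterSet | None = None) -> dict[str, float]:
    """Cytokine production and degradation rates from steady-state balances.

    Degradations follow d = ln2 / t_half with half-lives of 2 min (TGF-beta),
    4 h (IL-6) and 2 h (IL-10).  Each production rate then cancels the loss at
    the reference steady state (cytokines at their half-saturation values,
    producers at D = 4e-4, T1 = K_T1, Tr = K_Tr, M = 0.2, C = 0.4 g/cm^3),
    with melanoma cells producing twice the TGF-beta of MDSCs and equal IL-10
    from cancer cells and MDSCs.
    """
    p = params or baseline_parameters()
    d_ref = 4e-4   # steady-state DC density
    m_ref, c_ref = 0.2, 0.4
    if c_ref <= 0 or d_ref <= 0:
        raise ValueError("zero producer density")
    d_tb = math.log(2.0) / (2.0 / 1440.0)
    d_i6 = math.log(2.0) / (4.0 / 24.0)
    d_i10 = math.log(2.0) / (2.0 / 24.0)
    lam_i12d = p.d_I12 * p.K_I12 / d_ref
    lam_i2t1 = p.d_I2 * p.K_I2 / p.K_T1
    lam_tbm = (d_tb * p.K_Tb - p.lam_TbTr * p.K_Tr) / (3.0 * m_ref)
    lam_tbc = 2.0 * lam_tbm * m_ref / c_ref
    lam_i6c = d_i6 * p.K_I6 / c_ref
    lam_i10c = d_i10 * p.K_I10 / (2.0 * c_ref)
    lam_i10m = lam_i10c * c_ref / m_ref
    return {
        "lam_I12D": lam_i12d, "lam_I2T1": lam_i2t1,
        "lam_TbC": lam_tbc, "lam_TbM": lam_tbm,
        "lam_I6C": lam_i6c, "lam_I10C": lam_i10c, "lam_I10M": lam_i10m,
        "d_Tb": d_tb, "d_I6": d_i6, "d_I10": d_i10,
    }


# masses used in the checkpoint expression estimates (g)
_M_PD1 = 8.3e-20
_M_PDL1 = 5.8e-20
_M_TCELL = 1e-9
_PD1_PER_TCELL = 3000
_PDL1_PER_TCELL = 9000


def derive_checkpoint_params(params: ParameterSet | None = None) -> dict[str, float]:
    """PD-1/PD-L1 expression ratios and the complex inhibition scales.

    rho_P and rho_L are mass ratios (3000 PD-1 and 9000 PD-L1 proteins per
    T cell, protein masses 8.3e-20 g and 5.8e-20 g, T-cell mass 1e-9 g).  The
    reference steady concentrations are

        Pbar = rho_P*(T1 + T8 + eps_T*Tr),
        Lbar = rho_L*(T1 + T8 + eps_M*M + eps_C*C),

    and the complex factors are parameterised by Kp_TQ = Pbar*Lbar/2 (T-cell
    inhibition, so that P*L/Kp_TQ = 2 at reference) and Kp_Q = Pbar*Lbar
    (Treg promotion at half-maximum at reference).
    """
    p = params or baseline_parameters()
    rho_p = _PD1_PER_TCELL * _M_PD1 / _M_TCELL
    rho_l = _PDL1_PER_TCELL * _M_PDL1 / _M_TCELL
    t1, t8, tr = p.K_T1, p.K_T8, p.K_Tr
    m_ref, c_ref = 0.2, 0.4
    pbar = rho_p * (t1 + t8 + p.eps_T * tr)
    lbar = rho_l * (t1 + t8 + p.eps_M * m_ref + p.eps_C * c_ref)
    return {
        "rho_P": rho_p, "rho_L": rho_l, "Pbar": pbar, "Lbar": lbar,
        "Kp_TQ": 0.5 * pbar * lbar, "Kp_Q": pbar * lbar,
    }


def derive_drug_params(params: ParameterSet | None = None) -> dict[str, float]:
    """Drug degradation, blocking and uptake constants.

    Anti-PD-1 half-life 15 days; 10% of the antibody is consumed blocking
    PD-1 while 90% degrades, so mu_PA = d_A / (9*Pbar).  BRAF/MEKi half-life
    10 h; its quasi-steady level under a reference source gamma_B = 1e-9
    g/cm^3/day is K_B ~ (10/9)*gamma_B/d_B, and 10% uptake by cancer cells
    (at C = 0.4) gives mu_BC = 2*d_B*K_B/(9*C).  Rates are chained at their
    printed table precision, as in the original estimates.
    """
    p = params or baseline_parameters()
    gamma_b_ref = 1e-9
    c_ref = 0.4
    d_a = math.log(2.0) / 15.0
    d_b = math.log(2.0) / (10.0 / 24.0)
    d_a_p = round_sig(d_a, 2)
    d_b_p = round_sig(d_b, 3)
    mu_pa = d_a_p / (9.0 * p.Pbar)
    k_b = (10.0 / 9.0) * gamma_b_ref / d_b_p
    mu_bc = 2.0 * d_b_p * k_b / (9.0 * c_ref)
    return {"d_A": d_a, "mu_PA": mu_pa, "d_B": d_b, "K_B": k_b, "mu_BC": mu_bc}


def regenerate_estimated_table(params: ParameterSet | None = None) -> dict[str, tuple[float, float]]:
    """Re-derive every 'estimated' default and pair it with the stored value.

    Returns ``{name: (derived, stored)}`` for all entries that the derivation
    functions can regenerate.  Used by the ``derive-params`` CLI command and
    the parameter round-trip tests.
    """
    p = params or baseline_parameters()
    out: dict[str, tuple[float, float]] = {}
    for key, mw in MOLECULAR_WEIGHTS_KDA.items():
        out[f"delta_{key}"] = (derive_diffusion_coefficient(mw), getattr(p, f"delta_{key}"))
    lam_t1, lam_t8 = derive_t_cell_activation_rates(p)
    out["lam_T1I12"] = (lam_t1, p.lam_T1I12)
    out["lam_T8I12"] = (lam_t8, p.lam_T8I12)
    lam_trtb, lam_trq = derive_treg_rates(p)
    out["lam_TrTb"] = (lam_trtb, p.lam_TrTb)
    out["lam_TrQ"] = (lam_trq, p.lam_TrQ)
    lam_c, eta_1, eta_8, k_cb = derive_tumor_growth_params(p)
    out["lam_C"] = (lam_c, p.lam_C)
    out["eta_1"] = (eta_1, p.eta_1)
    out["eta_8"] = (eta_8, p.eta_8)
    out["K_CB"] = (k_cb, p.K_CB)
    for name, val in derive_cytokine_production_rates(p).items():
        out[name] = (val, getattr(p, name))
    ck = derive_checkpoint_params(p)
    for name in ("rho_P", "rho_L", "Kp_TQ", "Kp_Q", "Pbar", "Lbar"):
        out[name] = (ck[name], getattr(p, name))
    for name, val in derive_drug_params(p).items():
        out[name] = (val, getattr(p, name))
    return out
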