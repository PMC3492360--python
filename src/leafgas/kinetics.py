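"""Pointwise rate laws: FvCB carboxylation, CO2/HCO3- interconversion,
fluorescence-to-J conversion and unit/rate conversions.

The gross carboxylation rate is the minimum of three limiting rates

.. math::

    w_c = \\frac{V_{cmax}(C_c-\\Gamma^*)}{C_c+K_{mC}(1+O/K_{mO})},\\qquad
    w_j = \\frac{J(C_c-\\Gamma^*)}{4C_c+8\\Gamma^*},\\qquad
    w_p = \\frac{3T_p(C_c-\\Gamma^*)}{C_c-(1+3\\alpha)\\Gamma^*},

with :math:`C_c` the chloroplast CO2 partial pressure (µbar; numerically
interchangeable with µmol mol-1 near 1 bar), O the O2 partial pressure
(mbar) and :math:`\\Gamma^*` the CO2 compensation point in the absence of
day respiration.  Net assimilation is :math:`A = A_G - R_d`.

Leaf-area rates (µmol m-2 s-1) convert to tissue-volume rates through the
leaf thickness and the areal fractions of the phase in which they act
(chloroplast for photosynthesis, cytosol for respiration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .params import CarbonateParams, Environment, FvCBParams

__all__ = [
    "FvCBRates",
    "fvcb_rates",
    "electron_transport_from_fluorescence",
    "volumetric_rates",
    "net_hydration",
    "gamma_star_from_specificity",
    "concentration_units",
]



@dataclass(frozen=True)
class FvCBRates:
    """The three limiting rates, the gross rate and the active limb."""

    wc: float
    wj: float
    wp: float
    ag: float
    limb: str
    below_compensation: bool = False


def fvcb_rates(
    cc: float, env: Environment, params: FvCBParams, j: float
) -> FvCBRates:
    """Evaluate the FvCB limiting rates at chloroplast CO2 ``cc`` (µbar).

    For ``cc`` above the compensation point the gross rate is the minimum of
    the three limbs; below it the (negative) Rubisco-limited value is
    returned and flagged, since the electron-transport and TPU expressions
    are not meaningful there.

    Raises ``ValueError`` for non-positive ``cc``.
    """
    if cc <= 0:
        raise ValueError("chloroplast CO2 must be positive")
    if j < 0:
        raise ValueError("electron transport rate must be non-negative")
    g = params.gamma_star_at(env.o2_mbar)
    wc = params.vcmax * (cc - g) / (
        cc + params.kmc * (1.0 + env.o2_mbar / params.kmo)
    )
    wj = j * (cc - g) / (4.0 * cc + 8.0 * g)
    denom_p = cc - (1.0 + 3.0 * params.alpha) * g
    wp = 3.0 * params.tp * (cc - g) / denom_p if denom_p > 0 else np.inf
    if cc < g:
        return FvCBRates(wc, wj, wp, wc, "rubisco", below_compensation=True)
    limbs = {"rubisco": wc, "electron_transport": wj, "tpu": wp}
    limb = min(limbs, key=limbs.get)
    return FvCBRates(wc, wj, wp, limbs[limb], limb)


def electron_transport_from_fluorescence(
    phi2: float, iinc: float, s: float
) -> float:
    """Potential electron transport J = s·I_inc·Φ2 (µmol e- m-2 s-1).

    ``phi2`` is the photosystem-II efficiency from fluorescence
    (1 − Fs/Fm′); ``s`` the empirical calibration slope.
    """
    if not 0.0 <= phi2 <= 1.0:
        raise ValueError("PSII efficiency must lie in [0, 1]")
    if s <= 0 or iinc < 0:
        raise ValueError("s must be positive and I_inc non-negative")
    return s * iinc * phi2


def volumetric_rates(
    ag: float, rd: float, d_um: float, fc: float, fm: float
) -> tuple[float, float]:
    """Convert leaf-area rates to volumetric rates (µmol m-3 s-1).

    ``A_{G,v} = A_G/(d·f_c)`` applies in the chloroplast layer only and
    ``R_v = R_d/(d·f_m)`` in the respiring cytosol, with ``d_um`` the leaf
    thickness in µm and ``fc``/``fm`` the chloroplast and cytosol areal
    fractions of the cross-section.
    """
    if d_um <= 0 or fc <= 0 or fm <= 0:
        raise ValueError("thickness and phase fractions must be positive")
    d = d_um * 1e-6
    return ag / (d * fc), rd / (d * fm)


def net_hydration(
    c_co2_aq: float | np.ndarray,
    c_hco3: float | np.ndarray,
    carb: CarbonateParams,
) -> float | np.ndarray:
    """Net CO2 -> HCO3- hydration rate B (mol m-3 s-1), uncatalysed.

    ``B = k1·[CO2] − k2·([H+]/(K_a+[H+]))·[HCO3-]``; B = 0 defines the
    equilibrium ratio [HCO3-]/[CO2] = k1/k2_eff.
    """
    if np.any(np.asarray(c_co2_aq) < 0) or np.any(np.asarray(c_hco3) < 0):
        raise ValueError("concentrations must be non-negative")
    return carb.k1 * c_co2_aq - carb.k2_effective * c_hco3


def gamma_star_from_specificity(sco: float, o_mbar: float) -> float:
    """CO2 compensation point Γ* = 0.5·O/S_c/o (µbar)."""
    if sco <= 0 or o_mbar <= 0:
        raise ValueError("specificity and O2 must be positive")
    return 0.5 * o_mbar / sco


def concentration_units(
    x_umol_mol: float | np.ndarray,
    env: Environment,
    phase: Literal["gas", "aqueous"],
    henry: float = 0.83,
) -> float | np.ndarray:
    """Mole fraction (µmol mol-1) to concentration (µmol m-3).

    Gas phase: multiply by P/(R·T); aqueous phase: additionally by Henry's
    constant ``henry`` (mol m-3 liquid per mol m-3 gas, 0.83 for CO2 at
    25 °C).  The mapping is linear and therefore trivially invertible.
    """
    if np.any(np.asarray(x_umol_mol) < 0):
        raise ValueError("mole fraction must be non-negative")
    c_gas = x_umol_mol * env.gas_molar_density
    if phase == "gas":
        return c_gas
    if phase == "aqueous":
        return c_gas * henry
    raise ValueError(f"unknown phase {phase!r}")
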