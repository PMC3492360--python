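"""Synthetic gas-exchange / chlorophyll-fluorescence datasets.

Measured CO2-response and light-response curves of wheat flag leaves (the
kind of data the calibration routines ingest) are not redistributable, so
this module generates datasets with the same structure: step-wise C_a
series at fixed irradiance, irradiance series at fixed C_a, each at 21 %
and 2 % O2, with mutually consistent (Â_N, Ĉ_i, Φ2, ĝ_s) per record.

Two generator modes:

* ``lumped`` — a classical two-resistance model: FvCB demand intersected
  with the supply chain C_i = C_a − A/g_s, C_c = C_i − A/g_m.  Fast and
  exactly invertible by the variable-J estimators at electron-transport-
  limited points, which makes it the reference for estimator
  self-consistency tests.
* ``microscale`` — the full 2-D tissue model via
  :func:`leafgas.transport.run_condition` (used to build self-consistent
  calibration fixtures).

The empirical submodels are documented saturating forms: stomatal
conductance g_s(I) = g_min + (g_max − g_min)·I/(I + K_I), and PSII
efficiency Φ2(I) = Φ2_max/(1 + I/I_half); Φ2 is back-computed from the J
actually used, so Eq J = s·I·Φ2 always holds exactly in the records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .calibration import GasExchangeRecord
from .kinetics import fvcb_rates
from .params import Environment, FvCBParams

__all__ = [
    "SyntheticProtocol",
    "stomatal_conductance",
    "psii_efficiency",
    "default_j_response",
    "solve_lumped_operating_point",
    "generate_gas_exchange_dataset",
]

CA_SERIES = (50.0, 100.0, 150.0, 200.0, 250.0, 350.0, 500.0, 650.0, 1000.0, 1500.0)
IINC_SERIES = (0.0, 20.0, 50.0, 100.0, 150.0, 200.0, 500.0, 1000.0, 1500.0, 2000.0)


@dataclass(frozen=True)
class SyntheticProtocol:
    """Measurement protocol emulated by the dataset generator.

    CO2 curves run the ``ca_series`` at ``iinc_for_co2``; light curves run
    the ``iinc_series`` at 350 µmol mol-1 (21 % O2) or 1000 µmol mol-1
    (2 % O2, suppressing photorespiration).  ``noise_sigma`` applies
    multiplicative Gaussian noise to Â_N and Ĉ_i (0 = noise-free).
    """

    ca_series: tuple[float, ...] = CA_SERIES
    iinc_series: tuple[float, ...] = IINC_SERIES
    o2_levels_pct: tuple[float, ...] = (21.0, 2.0)
    iinc_for_co2: float = 1000.0
    ca_for_light_pr: float = 350.0
    ca_for_light_npr: float = 1000.0
    noise_sigma: float = 0.0
    gs_min: float = 0.05
    gs_max: float = 0.45
    k_i: float = 300.0
    phi2_max: float = 0.78
    i_half: float = 1300.0
    gm_true: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ca_series or not self.iinc_series:
            raise ValueError("protocol series must be non-empty")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def stomatal_conductance(
    iinc: float, gs_min: float = 0.05, gs_max: float = 0.45, k_i: float = 300.0
) -> float:
    """Saturating stomatal light response g_s(I) (mol m-2 s-1)."""
    return gs_min + (gs_max - gs_min) * iinc / (iinc + k_i)


def psii_efficiency(
    iinc: float, phi2_max: float = 0.78, i_half: float = 1300.0
) -> float:
    """Declining PSII efficiency with light, Φ2 = Φ2max/(1 + I/I_half)."""
    return phi2_max / (1.0 + iinc / i_half)


def default_j_response(iinc: float, s: float) -> float:
    """Electron transport J = s·I·Φ2(I) with the default PSII response."""
    return s * iinc * psii_efficiency(iinc)


def solve_lumped_operating_point(
    fvcb: FvCBParams,
    env: Environment,
    gs: float,
    gm: float,
    j: float,
) -> tuple[float, float, float, str]:
    """Intersect FvCB demand with the two-resistance supply chain.

    Solves A = A_G(C_c) − R_d with C_i = C_a − A/g_s and C_c = C_i − A/g_m.
    Returns (A_net, C_i, C_c, active limb).
    """
    rd = fvcb.rd(env.o2_mbar)

    def mismatch(a: float) -> float:
        cc = env.ca - a / gs - a / gm
        if cc <= 0:
            return -1e9  # supply exhausted: demand must come down
        return fvcb_rates(cc, env, fvcb, j).ag - rd - a

    a_hi = min(fvcb.vcmax, j / 4.0 + 1.0, 3.0 * fvcb.tp) + 1.0
    a_lo = -rd - 1.0
    # mismatch is decreasing in a; bracket then root-find
    if mismatch(a_lo) < 0:
        raise ValueError("no feasible operating point (supply exhausted)")
    a = brentq(mismatch, a_lo, a_hi, xtol=1e-10)
    ci = env.ca - a / gs
    cc = ci - a / gm
    limb = fvcb_rates(cc, env, fvcb, j).limb
    return a, ci, cc, limb


def generate_gas_exchange_dataset(
    fvcb: FvCBParams,
    protocol: SyntheticProtocol = SyntheticProtocol(),
    mode: str = "lumped",
    curve: str = "co2",
    geometry=None,
    props=None,
    depi_of_iinc: Optional[Callable[[float], float]] = None,
    h_um: float = 0.5,
) -> list[GasExchangeRecord]:
    """Generate a synthetic measurement campaign as GasExchangeRecord list.

    ``curve`` selects the CO2-response (C_a series at fixed I) or the
    light-response protocol.  In ``microscale`` mode a geometry and
    transport properties are required and every record is a full PDE solve;
    ``depi_of_iinc`` then sets the per-irradiance epidermal diffusivity
    (stomata opening with light).  Records are deterministic for a fixed
    protocol seed; infeasible operating points are flagged rather than
    dropped.
    """
    rng = np.random.default_rng(protocol.seed)
    records: list[GasExchangeRecord] = []
    if mode not in ("lumped", "microscale"):
        raise ValueError(f"unknown generator mode {mode!r}")
    if mode == "microscale" and (geometry is None or props is None):
        raise ValueError("microscale mode needs a geometry and TransportProps")

    points: list[tuple[float, float, float]] = []  # (ca, iinc, o2_pct)
    if curve == "co2":
        for o2 in protocol.o2_levels_pct:
            for ca in protocol.ca_series:
                points.append((ca, protocol.iinc_for_co2, o2))
    elif curve == "light":
        for o2 in protocol.o2_levels_pct:
            ca = protocol.ca_for_light_pr if o2 > 5 else protocol.ca_for_light_npr
            for iinc in protocol.iinc_series:
                points.append((ca, iinc, o2))
    else:
        raise ValueError(f"unknown curve kind {curve!r}")

    warm = None
    for ca, iinc, o2 in points:
        env = Environment(ca=ca, o2_mbar=o2 * 10.0, iinc=iinc)
        j = default_j_response(iinc, fvcb.s)
        gs = stomatal_conductance(iinc, protocol.gs_min, protocol.gs_max, protocol.k_i)
        flag = ""
        limb = ""
        if mode == "lumped":
            try:
                an, ci, _cc, limb = solve_lumped_operating_point(
                    fvcb, env, gs, protocol.gm_true, j
                )
            except ValueError:
                an, ci, flag = np.nan, np.nan, "infeasible"
        else:
            from .transport import run_condition

            p = props
            if depi_of_iinc is not None:
                p = props.replace(d_epidermis=depi_of_iinc(iinc))
            fld, s = run_condition(
                geometry, p, fvcb, env.replace(j=j), h_um=h_um, initial=warm
            )
            warm = fld
            an, ci = s.an, s.ci_bar
        if protocol.noise_sigma > 0 and not flag:
            an *= 1.0 + protocol.noise_sigma * rng.standard_normal()
            ci *= 1.0 + protocol.noise_sigma * rng.standard_normal()
        phi2 = j / (fvcb.s * iinc) if iinc > 0 else protocol.phi2_max
        records.append(
            GasExchangeRecord(
                ca=ca,
                o2_pct=o2,
                iinc=iinc,
                an_hat=an,
                ci_hat=ci,
                phi2=phi2,
                j_hat=j,
                gs_hat=gs,
                tags={"mode": mode, "curve": curve, "limb": limb, "flag": flag},
            )
        )
    return records
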