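"""Whole-leaf quantities from microscale fields, and the measurement-side
estimators used for comparison with gas-exchange / fluorescence data.

Microscale fields are reduced to the macroscale variables a gas-exchange
instrument reports: net assimilation Ā_N (flux through the epidermis per
projected leaf area), the pore-average intercellular CO2 C̄_i, the
mesophyll-cell average C̄_m (aqueous phases excluding the wall, converted
to gas-equivalent mole fraction), and the model mesophyll conductance

.. math::  \\bar g_m = \\bar A_N / (\\bar C_i - \\bar C_m).

The measurement-side (variable-J / Harley) estimators invert the
electron-transport-limited FvCB rate:

.. math::  \\hat C_c = \\Gamma^* \\frac{J + 8(\\hat A_N + R_d)}
                                   {J - 4(\\hat A_N + R_d)},\\qquad
           \\hat g_m = \\hat A_N / (\\hat C_i - \\hat C_c).

The serial resistance analysis follows the ambient → epidermis →
intercellular space → cell wall → plasmalemma → cytosol → chloroplast
envelope → stroma path: each compartment's resistance is the drop between
successive boundary-layer average concentrations (gas-equivalent mole
fraction) divided by the net flux per exposed leaf area, so the seven drops
telescope exactly to the ambient-to-stroma difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import ComputationalMesh, PhaseLabel
from .params import Environment, FvCBParams, SolverSettings, TransportProps

__all__ = [
    "SimulationSummary",
    "ResistanceBreakdown",
    "volume_average",
    "whole_leaf_assimilation",
    "model_mesophyll_conductance",
    "harley_cc",
    "harley_gm",
    "resistance_breakdown",
    "summarize",
    "co2_response_curve",
    "light_response_curve",
    "EstimatorUndefinedError",
]

P = PhaseLabel

COMPARTMENTS = (
    "epidermis",
    "intercellular space",
    "cell wall",
    "plasma membrane",
    "cytosol",
    "chloroplast envelope",
    "stroma",
)


class EstimatorUndefinedError(ValueError):
    """An estimator's denominator vanished (e.g. J <= 4(A+Rd), zero flux)."""


@dataclass(frozen=True)
class ResistanceBreakdown:
    """Serial resistances (m2 s mol-1) and their percentage shares."""

    resistances: dict[str, float]
    total: float

    @property
    def percents(self) -> dict[str, float]:
        return {k: 100.0 * v / self.total for k, v in self.resistances.items()}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compartment": list(self.resistances),
                "resistance_m2_s_mol": list(self.resistances.values()),
                "percent": list(self.percents.values()),
            }
        )


@dataclass(frozen=True)
class SimulationSummary:
    """Whole-leaf summary of one converged steady-state simulation."""

    an: float  # µmol m-2 s-1
    ci_bar: float  # µmol mol-1
    cm_bar: float  # µmol mol-1
    gm_bar: float  # mol m-2 s-1 (nan when undefined)
    resistances: Optional[ResistanceBreakdown]
    env: Environment
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "A_net": self.an,
            "Ci_bar": self.ci_bar,
            "Cm_bar": self.cm_bar,
            "gm_bar": self.gm_bar,
            "Ca": self.env.ca,
            "O2_mbar": self.env.o2_mbar,
            "Iinc": self.env.iinc,
            "flags": ";".join(self.flags),
        }


def _mesophyll_mask(mesh: ComputationalMesh) -> np.ndarray:
    if mesh.geometry is not None and mesh.geometry.cells:
        ids = [c.cell_id for c in mesh.geometry.cells if c.kind == "mesophyll"]
        return np.isin(mesh.cell_ids, ids)
    return np.ones(mesh.shape, dtype=bool)


def volume_average(field, region) -> float:
    """Area-weighted mean gas-equivalent mole fraction (µmol mol-1) over a
    region given as a phase, an iterable of phases, or a boolean mask."""
    x = field.mole_fraction()
    mask = _region_mask(field.mesh, region)
    if not mask.any():
        raise ValueError("volume average over an empty region")
    return float(x[mask].mean())


def _region_mask(mesh: ComputationalMesh, region) -> np.ndarray:
    if isinstance(region, np.ndarray):
        return region.astype(bool)
    if isinstance(region, PhaseLabel):
        region = [region]
    codes = [int(r) for r in region]
    return np.isin(mesh.labels, codes)


def whole_leaf_assimilation(field) -> float:
    """Net CO2 uptake Ā_N (µmol m-2 s-1 of projected leaf area): the flux
    through the outer epidermis boundaries, positive into the leaf."""
    if not field.converged:
        raise ValueError("assimilation requires a converged field")
    return field.boundary_influx_mol_m2s * 1e6


def model_mesophyll_conductance(an: float, ci_bar: float, cm_bar: float) -> float:
    """Model-side mesophyll conductance ḡ_m = Ā_N/(C̄_i − C̄_m), mol m-2 s-1.

    Returns NaN (undefined-at-compensation) when Ā_N is ~0; raises on the
    inconsistent case Ā_N > 0 with C̄_i <= C̄_m.
    """
    if abs(an) < 1e-12:
        return np.nan
    if ci_bar <= cm_bar and an > 0:
        raise EstimatorUndefinedError(
            "Ci <= Cm with positive assimilation — inconsistent field"
        )
    return an / (ci_bar - cm_bar)


def harley_cc(an_hat: float, rd: float, j: float, gamma_star: float) -> float:
    """Variable-J estimate of chloroplast CO2 (µmol mol-1)."""
    denom = j - 4.0 * (an_hat + rd)
    if denom <= 0:
        raise EstimatorUndefinedError(
            "J <= 4(A+Rd): variable-J estimator undefined (low-CO2 region)"
        )
    return gamma_star * (j + 8.0 * (an_hat + rd)) / denom


def harley_gm(an_hat: float, ci_hat: float, cc_hat: float) -> float:
    """Measurement-side mesophyll conductance ĝ_m = Â_N/(Ĉ_i − Ĉ_c)."""
    if ci_hat <= cc_hat:
        raise EstimatorUndefinedError("Ci <= Cc: mesophyll conductance undefined")
    return an_hat / (ci_hat - cc_hat)


# -- resistance analysis ---------------------------------------------------


def _adjacent(labels: np.ndarray, a_mask: np.ndarray, b_mask: np.ndarray) -> np.ndarray:
    """Pixels of ``a_mask`` 4-adjacent to any pixel of ``b_mask``."""
    nb = np.zeros_like(b_mask)
    nb[1:, :] |= b_mask[:-1, :]
    nb[:-1, :] |= b_mask[1:, :]
    nb[:, 1:] |= b_mask[:, :-1]
    nb[:, :-1] |= b_mask[:, 1:]
    return a_mask & nb


def resistance_breakdown(field) -> ResistanceBreakdown:
    """Serial resistance decomposition of the CO2 path to the stroma.

    Potentials are boundary-layer averages (elements adjacent to the
    relevant interface) of the gas-equivalent mole fraction; membrane
    resistances come from the concentration jump across the interface.
    Because each compartment's drop is the difference of successive
    potentials, the drops telescope exactly to C_a − C̄_stroma and the
    percentages sum to 100.
    """
    an = whole_leaf_assimilation(field)
    if an <= 1e-9:
        raise EstimatorUndefinedError(
            "zero or inward-negative net flux: the ambient-to-stroma serial "
            "decomposition is undefined without net uptake"
        )
    mesh = field.mesh
    lab = mesh.labels
    x = field.mole_fraction()
    meso = _mesophyll_mask(mesh)

    pore = lab == int(P.PORE)
    epi = lab == int(P.EPIDERMIS)
    wall = (lab == int(P.CELL_WALL)) & meso
    cyt_out = (lab == int(P.CYTOSOL)) & meso & ~mesh.inner_cyto
    chl = (lab == int(P.CHLOROPLAST)) & meso

    def mean_over(mask, name):
        if not mask.any():
            raise EstimatorUndefinedError(
                f"no elements for the {name} boundary layer"
            )
        return float(x[mask].mean())

    p0 = field.env.ca
    p1 = mean_over(_adjacent(lab, pore, epi), "pore|epidermis")
    p2 = mean_over(_adjacent(lab, pore, wall), "pore|wall")
    p3 = mean_over(_adjacent(lab, wall, cyt_out), "wall|cytosol")
    p4 = mean_over(_adjacent(lab, cyt_out, wall), "cytosol|wall")
    p5 = mean_over(_adjacent(lab, cyt_out, chl), "cytosol|envelope")
    p6 = mean_over(_adjacent(lab, chl, cyt_out), "envelope|stroma")
    p7 = mean_over(chl, "stroma")

    potentials = np.array([p0, p1, p2, p3, p4, p5, p6, p7])
    drops = dict(zip(COMPARTMENTS, -np.diff(potentials)))
    res = {k: v / an for k, v in drops.items()}
    total = (p0 - p7) / an
    return ResistanceBreakdown(res, total)


def summarize(field) -> SimulationSummary:
    """Build the :class:`SimulationSummary` of a converged field."""
    mesh = field.mesh
    lab = mesh.labels
    meso = _mesophyll_mask(mesh)
    an = whole_leaf_assimilation(field)
    ci = volume_average(field, P.PORE)
    cm_mask = np.isin(lab, [int(P.CYTOSOL), int(P.CHLOROPLAST), int(P.VACUOLE)]) & meso
    cm = volume_average(field, cm_mask)
    flags = []
    if field.env.ca < 100:
        flags.append("low_ca_gm_unreliable")
    if field.limb_consistency < 0.99:
        flags.append("limb_inconsistency")
    try:
        gm = model_mesophyll_conductance(an, ci, cm)
    except EstimatorUndefinedError:
        gm = np.nan
        flags.append("gm_undefined")
    if np.isnan(gm) and abs(an) < 1e-12:
        flags.append("gm_at_compensation")
    try:
        rb = resistance_breakdown(field)
    except EstimatorUndefinedError:
        rb = None
    return SimulationSummary(
        an=an, ci_bar=ci, cm_bar=cm, gm_bar=gm, resistances=rb,
        env=field.env, flags=tuple(flags),
    )


# -- response curves -------------------------------------------------------


def co2_response_curve(
    geometry,
    props: TransportProps,
    fvcb: FvCBParams,
    env_template: Environment,
    ca_list: Sequence[float],
    h_um: float = 0.5,
    settings: SolverSettings = SolverSettings(),
    **run_kw,
) -> pd.DataFrame:
    """Sweep ambient CO2 at fixed irradiance; one steady solve per step.

    Returns a table of Ā_N, C̄_i, C̄_m and ḡ_m per C_a.  Consecutive steps
    warm-start from the previous field.
    """
    from .geometry import mesh as make_mesh
    from .transport import run_condition

    m = geometry if isinstance(geometry, ComputationalMesh) else make_mesh(geometry, h_um)
    rows = []
    fld = None
    for ca in ca_list:
        env = env_template.replace(ca=float(ca))
        fld, s = run_condition(
            m, props, fvcb, env, settings=settings, initial=fld, **run_kw
        )
        rows.append(_curve_row(s))
    return pd.DataFrame(rows)


def light_response_curve(
    geometry,
    props: TransportProps,
    fvcb: FvCBParams,
    env_template: Environment,
    iinc_list: Sequence[float],
    depi_map: dict[float, float],
    j_map: Optional[dict[float, float]] = None,
    h_um: float = 0.5,
    settings: SolverSettings = SolverSettings(),
    **run_kw,
) -> pd.DataFrame:
    """Sweep irradiance with a per-irradiance epidermal diffusivity.

    ``depi_map`` supplies the (fitted) effective epidermal diffusivity for
    every requested irradiance — the epidermis lumps the stomata, whose
    aperture responds to light — and ``j_map`` the electron transport rate
    (defaults to the environment template's J scaled by the default PSII
    light response of :mod:`leafgas.synthetic`).
    """
    from .geometry import mesh as make_mesh
    from .transport import run_condition

    m = geometry if isinstance(geometry, ComputationalMesh) else make_mesh(geometry, h_um)
    rows = []
    fld = None
    for iinc in iinc_list:
        if iinc not in depi_map:
            raise KeyError(f"no epidermal diffusivity supplied for I_inc = {iinc}")
        if j_map is not None and iinc in j_map:
            j = j_map[iinc]
        else:
            from .synthetic import default_j_response

            j = default_j_response(iinc, fvcb.s)
        env = env_template.replace(iinc=float(iinc), j=j)
        fld, s = run_condition(
            m,
            props.replace(d_epidermis=depi_map[iinc]),
            fvcb,
            env,
            settings=settings,
            initial=fld,
            **run_kw,
        )
        rows.append(_curve_row(s))
    return pd.DataFrame(rows)


def _curve_row(s: SimulationSummary) -> dict:
    return {
        "Ca_umol_mol": s.env.ca,
        "O2_pct": s.env.o2_mbar / 10.0,
        "Iinc": s.env.iinc,
        "A_net": s.an,
        "Ci_bar": s.ci_bar,
        "Cm_bar": s.cm_bar,
        "gm_bar": s.gm_bar,
        "flags": ";".join(s.flags),
    }
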