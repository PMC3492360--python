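"""Steady-state coupled CO2 / HCO3- reaction–diffusion on a labelled mesh.

The solver works on the gas-equivalent potential ``u``: the CO2
concentration in mol m-3 of gas in the gas phases (pore, epidermis) and
``C_liq/H`` in the aqueous phases.  Henry equilibrium at gas–liquid
interfaces then means ``u`` is continuous there, and the diffusion operator
keeps divergence form with effective conductivity ``D`` (gas) or ``H·D``
(aqueous).  Membranes are face conductances ``P_m·H`` (the chloroplast
envelope counts as two membranes at half permeability; faces that would
physically cross several membranes get the series permeability).

Reactions:

* gross FvCB carboxylation as a volumetric sink in the chloroplast layer,
  linearised limb-by-limb inside a damped Picard iteration;
* day respiration as a constant volumetric source in the respiring phases
  (cytosol by default; optionally distributed over epidermis, cytosol and
  phloem in proportion to area);
* net CO2 hydration ``B = k1·C_CO2 - k2_eff·C_HCO3`` coupling CO2 to a
  HCO3- field that diffuses within each aqueous compartment and crosses
  neither membranes nor gas interfaces.  The coupling is linear and
  assembled implicitly.

Ambient CO2 is imposed as a Dirichlet condition on the outer epidermis
edges of both leaf surfaces (wheat is amphistomatous); lateral boundaries
are impermeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import AQUEOUS_PHASES, ComputationalMesh, PhaseLabel
from .kinetics import volumetric_rates
from .params import (
    CarbonateParams,
    Environment,
    FvCBParams,
    SolverSettings,
    TransportProps,
)

__all__ = [
    "TransportOperator",
    "save_field_image",
    "ConcentrationField",
    "SolverError",
    "AssemblyError",
    "solve_steady_state",
    "run_condition",
    "lumped_intracellular_mesh",
]

P = PhaseLabel

#: number of single membranes crossed by a face between two phases
#: (the chloroplast envelope counts double).  Pairs not listed and
#: same-phase faces are membrane-free.
_MEMBRANES: dict[frozenset, float] = {
    frozenset({P.CELL_WALL, P.CYTOSOL}): 1,
    frozenset({P.CELL_WALL, P.PHLOEM}): 1,
    frozenset({P.CELL_WALL, P.XYLEM}): 1,
    frozenset({P.CYTOSOL, P.CHLOROPLAST}): 2,
    frozenset({P.CYTOSOL, P.VACUOLE}): 1,
    frozenset({P.CELL_WALL, P.CHLOROPLAST}): 3,
    frozenset({P.CELL_WALL, P.VACUOLE}): 2,
    frozenset({P.CHLOROPLAST, P.VACUOLE}): 3,
    frozenset({P.CYTOSOL, P.PHLOEM}): 2,
    frozenset({P.CYTOSOL, P.XYLEM}): 2,
    frozenset({P.PHLOEM, P.XYLEM}): 2,
    # gas directly against a protoplast phase only occurs if the wall is
    # unresolved locally; the missing membranes are still imposed
    frozenset({P.PORE, P.CYTOSOL}): 1,
    frozenset({P.EPIDERMIS, P.CYTOSOL}): 1,
    frozenset({P.PORE, P.CHLOROPLAST}): 3,
    frozenset({P.EPIDERMIS, P.CHLOROPLAST}): 3,
    frozenset({P.PORE, P.VACUOLE}): 2,
    frozenset({P.EPIDERMIS, P.VACUOLE}): 2,
    frozenset({P.PORE, P.PHLOEM}): 1,
    frozenset({P.EPIDERMIS, P.PHLOEM}): 1,
    frozenset({P.PORE, P.XYLEM}): 1,
    frozenset({P.EPIDERMIS, P.XYLEM}): 1,
}


class SolverError(RuntimeError):
    def __init__(self, msg: str, residuals: Optional[list[float]] = None):
        super().__init__(msg)
        self.residuals = residuals or []


class AssemblyError(ValueError):
    pass


@dataclass
class ConcentrationField:
    """Converged steady-state concentration fields on a mesh.

    ``co2`` is phase-native (µmol m-3: gas basis in pore/epidermis, liquid
    basis in aqueous phases); ``hco3`` is µmol m-3 in aqueous phases and
    NaN elsewhere.  ``u`` is the solver's gas-equivalent potential in
    mol m-3.  ``limbs`` records the active FvCB limb per chloroplast
    element (-1 elsewhere).
    """

    mesh: ComputationalMesh
    u: np.ndarray
    hco3_molm3: np.ndarray
    env: Environment
    props: TransportProps
    iterations: int = 0
    residual: float = np.nan
    converged: bool = False
    limbs: Optional[np.ndarray] = None
    limb_consistency: float = 1.0
    boundary_influx_mol_m2s: float = 0.0
    reaction_totals: dict = field(default_factory=dict)

    @property
    def co2(self) -> np.ndarray:
        aqueous = np.isin(self.mesh.labels, [int(q) for q in AQUEOUS_PHASES])
        native = np.where(aqueous, self.u * self.props.henry, self.u)
        return native * 1e6

    @property
    def hco3(self) -> np.ndarray:
        aqueous = np.isin(self.mesh.labels, [int(q) for q in AQUEOUS_PHASES])
        out = np.where(aqueous, self.hco3_molm3 * 1e6, np.nan)
        return out

    def mole_fraction(self) -> np.ndarray:
        """Gas-equivalent CO2 mole fraction (µmol mol-1) per element."""
        return self.u / self.env.gas_molar_density * 1e6


class TransportOperator:
    """Discrete steady-state operator on a labelled raster mesh.

    Parameters
    ----------
    fvcb, j_umol :
        FvCB parameters and the electron transport rate actually delivered;
        ``None`` disables photosynthesis and respiration (linear problem).
    carb :
        CO2/HCO3- interconversion parameters; ``None`` drops the HCO3-
        field entirely.
    linear_sinks :
        optional ``[(phase or boolean mask, k)]`` first-order sinks
        ``k·C_native`` (s-1) for verification against closed-form
        reaction–diffusion solutions.
    sink_mask, resp_mask :
        override the photosynthesis / respiration regions (used by the
        lumped-intracellular variant); defaults are the chloroplast layer
        and the mesophyll cytosol.
    """

    def __init__(
        self,
        mesh: ComputationalMesh,
        props: TransportProps,
        env: Environment,
        fvcb: Optional[FvCBParams] = None,
        j_umol: Optional[float] = None,
        carb: Optional[CarbonateParams] = None,
        respiration: str = "cytosol",
        single_surface: bool = False,
        linear_sinks: Optional[Sequence] = None,
        sink_mask: Optional[np.ndarray] = None,
        resp_mask: Optional[np.ndarray] = None,
    ):
        self.mesh = mesh
        self.props = props
        self.env = env
        self.fvcb = fvcb
        self.carb = carb
        self.single_surface = single_surface
        if fvcb is not None and j_umol is None:
            j_umol = env.j
        if fvcb is not None and j_umol is None:
            raise AssemblyError(
                "an electron transport rate J is required when FvCB kinetics "
                "are active (set Environment.j or pass j_umol)"
            )
        self.j_umol = j_umol

        labels = mesh.labels
        ny, nx = labels.shape
        self.n = labels.size
        lab = labels.ravel()
        self.aqueous = np.isin(lab, [int(q) for q in AQUEOUS_PHASES])
        self.gas = ~self.aqueous

        # per-element effective conductivity for the gas-equivalent potential
        H = props.henry
        kappa = np.empty(self.n)
        d_aq = {
            int(P.CELL_WALL): props.d_wall,
            int(P.CYTOSOL): props.d_cytosol,
            int(P.CHLOROPLAST): props.d_cytosol,
            int(P.VACUOLE): props.d_cytosol,
            int(P.PHLOEM): props.d_cytosol,
            int(P.XYLEM): props.d_cytosol,
        }
        # helox raises the diffusivity of every gas-filled path: the pores
        # and the epidermal effective medium (which lumps the stomata)
        kappa[lab == int(P.PORE)] = props.d_pore * props.helox
        kappa[lab == int(P.EPIDERMIS)] = props.d_epidermis * props.helox
        for code, dv in d_aq.items():
            kappa[lab == code] = dv * H
        self.kappa = kappa

        # face lists (4-connectivity)
        idx = np.arange(self.n).reshape(ny, nx)
        ia = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
        ib = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
        self.face_a, self.face_b = ia, ib
        la, lb = lab[ia], lab[ib]
        hm = mesh.h_um * 1e-6

        res = 1.0 / (2.0 * kappa[ia]) + 1.0 / (2.0 * kappa[ib])
        n_mem = np.zeros(ia.size)
        pair_codes = np.minimum(la, lb) * 16 + np.maximum(la, lb)
        mem_lookup = np.zeros(16 * 16)
        for pair, count in _MEMBRANES.items():
            a, b = sorted(int(x) for x in pair)
            mem_lookup[a * 16 + b] = count
        n_mem = mem_lookup[pair_codes]
        with np.errstate(divide="ignore"):
            res = res + n_mem / (props.p_membrane * H * hm)
        self.face_G = 1.0 / res
        self.face_membranes = n_mem

        # Dirichlet boundary faces: outer edges of the top (adaxial) row and,
        # unless single-sided, the bottom (abaxial) row
        top = idx[0, :]
        bot = idx[-1, :]
        self.bc_idx = top if single_surface else np.concatenate([top, bot])
        self.bc_G = 2.0 * kappa[self.bc_idx]
        self.u_b = env.ca * 1e-6 * env.gas_molar_density

        V = mesh.element_volume_m3
        self.V = V

        # region masks for the reaction terms
        if sink_mask is None:
            sink_mask = lab == int(P.CHLOROPLAST)
        else:
            sink_mask = sink_mask.ravel().astype(bool)
        if resp_mask is None:
            resp_mask = self._default_resp_mask(lab, respiration)
        else:
            resp_mask = resp_mask.ravel().astype(bool)
        self.sink_mask, self.resp_mask = sink_mask, resp_mask
        domain_area = self.n  # in elements
        self.f_sink = sink_mask.sum() / domain_area
        self.f_resp = resp_mask.sum() / domain_area if resp_mask.any() else 1.0

        # HCO3- unknowns
        if carb is not None:
            self.v_of = np.full(self.n, -1, dtype=np.int64)
            aq_idx = np.flatnonzero(self.aqueous)
            self.v_of[aq_idx] = self.n + np.arange(aq_idx.size)
            self.n_v = aq_idx.size
            self.aq_idx = aq_idx
        else:
            self.n_v = 0
        self.n_total = self.n + self.n_v

        self.linear_sinks = list(linear_sinks or [])
        self._base = None

    @staticmethod
    def _default_resp_mask(lab: np.ndarray, mode: str) -> np.ndarray:
        if mode == "cytosol":
            return lab == int(P.CYTOSOL)
        if mode == "distributed":
            return np.isin(lab, [int(P.CYTOSOL), int(P.EPIDERMIS), int(P.PHLOEM)])
        raise AssemblyError(f"unknown respiration mode {mode!r}")

    # -- assembly ----------------------------------------------------------

    def _base_system(self):
        """Constant part of (A, b): diffusion, Dirichlet, hydration
        coupling, respiration source and any injected linear sinks."""
        if self._base is not None:
            return self._base
        n, nt = self.n, self.n_total
        rows, cols, vals = [], [], []
        ia, ib, G = self.face_a, self.face_b, self.face_G
        rows += [ia, ib, ia, ib]
        cols += [ib, ia, ia, ib]
        vals += [-G, -G, G, G]
        rows.append(self.bc_idx)
        cols.append(self.bc_idx)
        vals.append(self.bc_G)
        b = np.zeros(nt)
        np.add.at(b, self.bc_idx, self.bc_G * self.u_b)

        V, H = self.V, self.props.henry
        if self.fvcb is not None:
            rd = self.fvcb.rd(self.env.o2_mbar)
            _, r_v = volumetric_rates(
                1.0, rd, self.mesh.thickness_um, max(self.f_sink, 1e-12), self.f_resp
            )
            b[np.flatnonzero(self.resp_mask)] += r_v * 1e-6 * V

        for phase_or_mask, k in self.linear_sinks:
            if isinstance(phase_or_mask, PhaseLabel):
                mask = self.mesh.labels.ravel() == int(phase_or_mask)
            else:
                mask = np.asarray(phase_or_mask).ravel().astype(bool)
            native_factor = np.where(self.aqueous[mask], H, 1.0)
            i = np.flatnonzero(mask)
            rows.append(i)
            cols.append(i)
            vals.append(k * native_factor * V)

        if self.carb is not None:
            k1, k2e = self.carb.k1, self.carb.k2_effective
            aq = self.aq_idx
            vi = self.v_of[aq]
            # CO2 row: +k1·H·u - k2e·v  (sink -B)
            rows += [aq, aq]
            cols += [aq, vi]
            vals += [np.full(aq.size, k1 * H * V), np.full(aq.size, -k2e * V)]
            # HCO3 row: -k1·H·u + k2e·v + diffusion within compartments
            rows += [vi, vi]
            cols += [aq, vi]
            vals += [np.full(aq.size, -k1 * H * V), np.full(aq.size, k2e * V)]
            # HCO3 diffusion only across membrane-free aqueous faces
            fa, fb = self.face_a, self.face_b
            open_face = (
                self.aqueous[fa] & self.aqueous[fb] & (self.face_membranes == 0)
            )
            va, vb = self.v_of[fa[open_face]], self.v_of[fb[open_face]]
            Gv = np.full(va.size, self.props.d_hco3)
            rows += [va, vb, va, vb]
            cols += [vb, va, va, vb]
            vals += [-Gv, -Gv, Gv, Gv]

        rows = np.concatenate([np.asarray(r, dtype=np.int64) for r in rows])
        cols = np.concatenate([np.asarray(c, dtype=np.int64) for c in cols])
        vals = np.concatenate([np.asarray(v, dtype=float) for v in vals])
        A = sp.csr_matrix((vals, (rows, cols)), shape=(nt, nt))
        self._base = (A, b)
        return self._base

    # -- FvCB linearisation ------------------------------------------------

    def _fvcb_linearise(self, u: np.ndarray):
        """Per-sink-element linear sink ``s1·u - s0`` (mol m-3 s-1 basis,
        already multiplied by the element volume) for the active limb at the
        current iterate, plus the active limb codes."""
        fv, env = self.fvcb, self.env
        i = np.flatnonzero(self.sink_mask)
        conv = 1e6 / env.gas_molar_density  # µbar per (mol m-3 gas-equiv)
        cc = np.maximum(u[i] * conv, 1e-3)
        g = fv.gamma_star_at(env.o2_mbar)
        kp = fv.kmc * (1.0 + env.o2_mbar / fv.kmo)
        vc_v, _ = volumetric_rates(
            fv.vcmax, 1.0, self.mesh.thickness_um, self.f_sink, 1.0
        )
        scale = 1e-6  # µmol -> mol
        wc_slope = vc_v * scale / (cc + kp)  # per µbar
        j_v = (self.j_umol or 0.0) / (fv.vcmax) * vc_v
        wj_slope = j_v * scale / (4.0 * cc + 8.0 * g)
        tp_v = fv.tp / fv.vcmax * vc_v
        denom_p = cc - (1.0 + 3.0 * fv.alpha) * g
        wp_rate = np.where(denom_p > 0, 3.0 * tp_v * scale * (cc - g) / denom_p, np.inf)

        wc = wc_slope * (cc - g)
        wj = wj_slope * (cc - g)
        rates = np.stack([wc, wj, wp_rate])
        limb = np.argmin(rates, axis=0)
        limb[cc < g] = 0  # below compensation: Rubisco-limited value, flagged
        V = self.V
        s1 = np.zeros(i.size)
        s0 = np.zeros(i.size)
        for code, slope in ((0, wc_slope), (1, wj_slope)):
            m = limb == code
            s1[m] = slope[m] * conv * V  # sink = slope·(cc-g) = s1·u - s0
            s0[m] = slope[m] * g * V
        m = limb == 2
        s0[m] = -wp_rate[m] * V
        return i, s1, s0, limb

    def fvcb_rates_at(self, u: np.ndarray):
        """Exact (non-linearised) limb rates at ``u`` for consistency checks;
        returns (indices, rates stacked [wc, wj, wp], argmin limb)."""
        fv, env = self.fvcb, self.env
        i = np.flatnonzero(self.sink_mask)
        conv = 1e6 / env.gas_molar_density
        cc = np.maximum(u[i] * conv, 1e-3)
        g = fv.gamma_star_at(env.o2_mbar)
        kp = fv.kmc * (1.0 + env.o2_mbar / fv.kmo)
        wc = fv.vcmax * (cc - g) / (cc + kp)
        wj = (self.j_umol or 0.0) * (cc - g) / (4.0 * cc + 8.0 * g)
        denom = cc - (1.0 + 3.0 * fv.alpha) * g
        wp = np.where(denom > 0, 3.0 * fv.tp * (cc - g) / denom, np.inf)
        rates = np.stack([wc, wj, wp])
        limb = np.argmin(rates, axis=0)
        limb[cc < g] = 0
        return i, rates, limb


def _initial_state(op: TransportOperator) -> np.ndarray:
    x = np.full(op.n_total, op.u_b)
    if op.carb is not None:
        x[op.n :] = op.carb.equilibrium_ratio * op.props.henry * op.u_b
    return x


def solve_steady_state(
    op: TransportOperator,
    settings: SolverSettings = SolverSettings(),
    initial: Optional[np.ndarray | ConcentrationField] = None,
) -> ConcentrationField:
    """Solve the operator to steady state with a damped Picard iteration.

    The linear subproblem is factorised once (sparse LU); later Picard
    iterations reuse that factorisation as a preconditioner for GMRES since
    only the chloroplast-sink diagonal changes, refactorising on demand.
    Raises :class:`SolverError` on non-convergence (with the residual
    history) or if the converged field has negative concentrations.
    """
    A0, b0 = op._base_system()
    if initial is None:
        x = _initial_state(op)
    elif isinstance(initial, ConcentrationField):
        x = np.concatenate(
            [initial.u.ravel(), initial.hco3_molm3.ravel()[op.aq_idx]]
            if op.carb is not None
            else [initial.u.ravel()]
        )
    else:
        x = np.asarray(initial, dtype=float).copy()

    linear = op.fvcb is None
    lu = None
    lu_key = None
    residuals: list[float] = []
    limb_prev = None
    max_outer = 1 if linear else settings.max_outer

    for it in range(max_outer):
        if linear:
            A, b = A0, b0
        else:
            i, s1, s0, limb = op._fvcb_linearise(x[: op.n])
            diag = np.zeros(op.n_total)
            diag[i] = s1
            A = A0 + sp.diags(diag)
            b = b0.copy()
            b[i] += s0
        if lu is None:
            lu = spla.splu(A.tocsc())
            lu_key = it
            x_new = lu.solve(b)
        else:
            M = spla.LinearOperator((op.n_total, op.n_total), lu.solve)
            x_new, info = spla.gmres(
                A, b, x0=x, M=M, rtol=1e-12, atol=0.0, maxiter=100
            )
            if info != 0:
                lu = spla.splu(A.tocsc())
                lu_key = it
                x_new = lu.solve(b)
        if linear:
            x = x_new
            residuals.append(0.0)
            break
        if it == 0:
            omega = 1.0
        elif residuals and len(residuals) > 1 and residuals[-1] > residuals[-2]:
            omega = max(settings.damping * 0.3, omega * 0.5)
        else:
            omega = min(1.0, omega * 1.4)
        x_next = x + omega * (x_new - x)
        denom = max(np.abs(x_next[: op.n]).max(), 1e-300)
        res = np.abs(x_next[: op.n] - x[: op.n]).max() / denom
        residuals.append(res)
        x = x_next
        limb_stable = limb_prev is not None and np.array_equal(limb, limb_prev)
        limb_prev = limb
        if res < settings.rtol and limb_stable:
            break
    else:
        raise SolverError(
            f"Picard iteration did not converge in {max_outer} steps "
            f"(last residual {residuals[-1]:.2e})",
            residuals,
        )

    u = x[: op.n]
    if u.min() < -1e-9 * max(abs(op.u_b), u.max(), 1e-30):
        raise SolverError("negative CO2 concentrations in converged field", residuals)
    u = np.maximum(u, 0.0)

    hco3 = np.zeros(op.n)
    if op.carb is not None:
        hco3[op.aq_idx] = x[op.n :]

    limbs = np.full(op.n, -1, dtype=np.int8)
    consistency = 1.0
    if op.fvcb is not None:
        i, rates, limb_now = op.fvcb_rates_at(u)
        limbs[i] = limb_now
        if limb_prev is not None and i.size:
            consistency = float(np.mean(limb_now == limb_prev))

    mesh = op.mesh
    influx = float(np.sum(op.bc_G * (op.u_b - u[op.bc_idx])))
    width_m = mesh.width_um * 1e-6
    field = ConcentrationField(
        mesh=mesh,
        u=u.reshape(mesh.shape),
        hco3_molm3=hco3.reshape(mesh.shape),
        env=op.env,
        props=op.props,
        iterations=len(residuals),
        residual=residuals[-1] if residuals else 0.0,
        converged=True,
        limbs=limbs.reshape(mesh.shape),
        limb_consistency=consistency,
        boundary_influx_mol_m2s=influx / width_m,
    )
    _record_reaction_totals(op, field, u, hco3)
    return field


def _record_reaction_totals(op, field, u, hco3) -> None:
    """Store the volume integrals of the reaction terms (mol m-2 s-1 per
    projected leaf area) for mass-balance accounting."""
    width_m = op.mesh.width_um * 1e-6
    V = op.V
    totals = {"assimilation": 0.0, "respiration": 0.0, "hydration": 0.0}
    if op.fvcb is not None:
        i, rates, limb = op.fvcb_rates_at(u)
        conv = 1e6 / op.env.gas_molar_density
        ag_leaf = rates[limb, np.arange(i.size)]  # µmol m-2 s-1 leaf basis
        ag_v, _ = volumetric_rates(
            1.0, 1.0, op.mesh.thickness_um, op.f_sink, 1.0
        )
        totals["assimilation"] = float(
            np.sum(ag_leaf * ag_v * 1e-6 * V) / width_m
        )
        rd = op.fvcb.rd(op.env.o2_mbar)
        _, r_v = volumetric_rates(1.0, rd, op.mesh.thickness_um, 1.0, op.f_resp)
        totals["respiration"] = float(r_v * 1e-6 * V * op.resp_mask.sum() / width_m)
    if op.carb is not None:
        H = op.props.henry
        B = op.carb.k1 * H * u[op.aq_idx] - op.carb.k2_effective * hco3[op.aq_idx]
        totals["hydration"] = float(np.sum(B * V) / width_m)
    for phase_or_mask, k in op.linear_sinks:
        if isinstance(phase_or_mask, PhaseLabel):
            mask = op.mesh.labels.ravel() == int(phase_or_mask)
        else:
            mask = np.asarray(phase_or_mask).ravel().astype(bool)
        native = np.where(op.aqueous[mask], op.props.henry, 1.0)
        totals.setdefault("linear_sinks", 0.0)
        totals["linear_sinks"] += float(np.sum(k * native * u[mask] * V) / width_m)
    field.reaction_totals = totals


def field_to_dataframe(field: ConcentrationField):
    """Per-element table (id, centroid µm, phase, CO2, HCO3) for export."""
    import pandas as pd

    m = field.mesh
    ny, nx = m.shape
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    return pd.DataFrame(
        {
            "element": np.arange(m.n_elements),
            "x_um": (ii.ravel() + 0.5) * m.h_um,
            "y_um": (jj.ravel() + 0.5) * m.h_um,
            "phase": [PhaseLabel(v).name for v in m.labels.ravel()],
            "C_CO2_umol_m3": field.co2.ravel(),
            "C_HCO3_umol_m3": field.hco3.ravel(),
        }
    )


def save_field_image(field: ConcentrationField, path, dpi: int = 200):
    """Render the CO2 concentration map (gas-equivalent mole fraction,
    µmol mol-1) with phase boundaries visible through the concentration
    contrast; adaxial surface at the top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = field.mesh
    fig, ax = plt.subplots(figsize=(5, 5 * m.thickness_um / m.width_um))
    im = ax.imshow(
        field.mole_fraction(),
        origin="upper",
        extent=(0, m.width_um, m.thickness_um, 0),
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="CO2 (µmol mol$^{-1}$, gas-equivalent)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("depth y (µm, adaxial at 0)")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def lumped_intracellular_mesh(mesh: ComputationalMesh) -> ComputationalMesh:
    """Merge chloroplast and vacuole into a single cytosolic compartment
    (the classical lumped intracellular model: organelles not resolved)."""
    labels = mesh.labels.copy()
    labels[np.isin(labels, [int(P.CHLOROPLAST), int(P.VACUOLE)])] = int(P.CYTOSOL)
    return ComputationalMesh(
        labels,
        mesh.cell_ids.copy(),
        np.zeros_like(mesh.inner_cyto),
        mesh.h_um,
        mesh.width_um,
        mesh.thickness_um,
        mesh.geometry,
    )


def run_condition(
    geometry_or_mesh,
    props: TransportProps,
    fvcb: FvCBParams,
    env: Environment,
    carb: Optional[CarbonateParams] = None,
    settings: SolverSettings = SolverSettings(),
    h_um: float = 0.5,
    respiration: str = "cytosol",
    lumped_intracellular: bool = False,
    single_surface: bool = False,
    initial=None,
):
    """One full simulation: mesh, assemble, solve, summarise.

    Returns ``(ConcentrationField, SimulationSummary)``.  ``carb`` defaults
    to the standard uncatalysed carbonate kinetics; pass an explicit
    :class:`CarbonateParams` to change pH, or ``carb=False`` to drop the
    HCO3- field.
    """
    from . import macroscale
    from .geometry import LeafGeometry, mesh as make_mesh

    if isinstance(geometry_or_mesh, ComputationalMesh):
        m = geometry_or_mesh
    else:
        m = make_mesh(geometry_or_mesh, h_um)
    if carb is None:
        carb = CarbonateParams()
    elif carb is False:
        carb = None

    sink_mask = None
    resp_mask = None
    if lumped_intracellular:
        m = lumped_intracellular_mesh(m)
        meso = _mesophyll_mask(m)
        sink_mask = (m.labels == int(P.CYTOSOL)) & meso
    op = TransportOperator(
        m,
        props,
        env,
        fvcb=fvcb,
        carb=carb,
        respiration=respiration,
        single_surface=single_surface,
        sink_mask=sink_mask,
        resp_mask=resp_mask,
    )
    fld = solve_steady_state(op, settings, initial=initial)
    summary = macroscale.summarize(fld)
    return fld, summary


def _mesophyll_mask(m: ComputationalMesh) -> np.ndarray:
    """Pixels belonging to mesophyll cells (all cells if kinds unknown)."""
    if m.geometry is not None and m.geometry.cells:
        meso_ids = {c.cell_id for c in m.geometry.cells if c.kind == "mesophyll"}
        return np.isin(m.cell_ids, list(meso_ids))
    return m.cell_ids >= 0
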