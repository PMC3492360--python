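"""Steady-state solver against closed-form 1-D oracles, conservation and
qualitative whole-leaf behaviour."""

import numpy as np
import pytest

from leafgas import (
    CarbonateParams,
    Environment,
    PhaseLabel,
    SolverSettings,
    TransportProps,
    mesh_from_labels,
    run_condition,
    solve_steady_state,
)
from leafgas.transport import SolverError, TransportOperator

P = PhaseLabel
PROPS = TransportProps()
ENV = Environment(ca=350.0)
U_B = 350e-6 * ENV.gas_molar_density


def transfer_matrix_profile(layers, u_top, y_eval):
    """Closed-form 1-D steady profile for stacked layers.

    ``layers``: list of (thickness_m, kappa, k_vol, r_mem_above) where
    ``kappa`` is the conductivity of the solved potential, ``k_vol`` a
    linear volumetric sink coefficient on that potential (1/s·basis), and
    ``r_mem_above`` a membrane resistance at the layer's upper interface.
    Dirichlet ``u_top`` at the top, zero flux at the bottom.  Marches a
    (u, flux) state from the bottom and rescales — the problem is linear
    and homogeneous.  Layer order: top to bottom; y measured downward from
    the top.  Returns u at depths ``y_eval``.
    """
    # march upward from the bottom with unit amplitude
    u, phi = 1.0, 0.0  # phi = -kappa du/dy, positive downward
    states = []  # per layer: (u_bottom, phi_bottom) at the layer's lower edge
    for thickness, kappa, k_vol, r_mem in reversed(layers):
        states.append((u, phi))
        if k_vol > 0:
            lam = np.sqrt(kappa / k_vol)
            c, s = np.cosh(thickness / lam), np.sinh(thickness / lam)
            u_new = u * c + phi * s * lam / kappa
            phi_new = u * kappa * s / lam + phi * c
        else:
            u_new = u + phi * thickness / kappa
            phi_new = phi
        u, phi = u_new, phi_new
        u = u + phi * r_mem  # jump across the membrane above this layer
    scale = u_top / u
    states = [(su * scale, sp * scale) for su, sp in states]

    # evaluate at requested depths
    out = np.empty_like(np.asarray(y_eval, dtype=float))
    tops = np.cumsum([0.0] + [L[0] for L in layers])
    for i, y in enumerate(np.asarray(y_eval, dtype=float)):
        li = min(np.searchsorted(tops, y, side="right") - 1, len(layers) - 1)
        thickness, kappa, k_vol, _ = layers[li]
        ub, pb = states[len(layers) - 1 - li]
        dy = tops[li + 1] - y  # distance above the layer's lower edge
        if k_vol > 0:
            lam = np.sqrt(kappa / k_vol)
            out[i] = ub * np.cosh(dy / lam) + pb * np.sinh(dy / lam) * lam / kappa
        else:
            out[i] = ub + pb * dy / kappa
    return out


class TestLinearOracles:
    def test_uniform_equilibrium_all_reactions_off(self):
        m = mesh_from_labels(np.zeros((40, 6), dtype=np.int8), 1.0)
        f = solve_steady_state(TransportOperator(m, PROPS, ENV))
        assert np.allclose(f.u, U_B, rtol=1e-12)
        assert np.allclose(f.mole_fraction(), 350.0, rtol=1e-9)

    def test_zero_boundary_gives_zero_field(self):
        m = mesh_from_labels(np.zeros((20, 4), dtype=np.int8), 1.0)
        f = solve_steady_state(TransportOperator(m, PROPS, Environment(ca=0.0)))
        assert np.allclose(f.u, 0.0, atol=1e-20)

    def test_uniform_equilibrium_with_henry_phases(self):
        lab = np.zeros((30, 4), dtype=np.int8)
        lab[10:] = int(P.CELL_WALL)
        m = mesh_from_labels(lab, 0.5)
        f = solve_steady_state(TransportOperator(m, PROPS, ENV))
        # gas-equivalent potential uniform; native liquid = H x native gas
        assert np.allclose(f.u, U_B, rtol=1e-12)
        co2 = f.co2
        assert co2[20, 0] / co2[5, 0] == pytest.approx(PROPS.henry, rel=1e-9)

    def test_first_order_sink_matches_cosh_profile(self):
        k = 50.0  # s-1 on the native aqueous concentration
        lam_um = np.sqrt(PROPS.d_cytosol / k) * 1e6
        h = lam_um / 20.0
        ny = int(round(6 * lam_um / h))
        lab = np.full((ny, 4), int(P.CYTOSOL), dtype=np.int8)
        m = mesh_from_labels(lab, h)
        op = TransportOperator(
            m, PROPS, ENV, linear_sinks=[(P.CYTOSOL, k)], single_surface=True
        )
        f = solve_steady_state(op)
        y = (np.arange(ny) + 0.5) * h
        L = ny * h
        ana = U_B * np.cosh((L - y) / lam_um) / np.cosh(L / lam_um)
        err = np.abs(f.u[:, 0] - ana) / ana.max()
        assert err.max() < 0.01

    def test_multilayer_slab_matches_transfer_matrix(self):
        """Pore / wall / cytosol stack with membrane and Henry interfaces
        and a linearised sink in the cytosol, vs the closed form."""
        h = 0.25e-6
        n_pore, n_wall, n_cyt = 40, 8, 120
        lab = np.concatenate(
            [
                np.full(n_pore, int(P.PORE)),
                np.full(n_wall, int(P.CELL_WALL)),
                np.full(n_cyt, int(P.CYTOSOL)),
            ]
        )
        m = mesh_from_labels(np.tile(lab[:, None], (1, 4)).astype(np.int8), h * 1e6)
        k = 20.0
        op = TransportOperator(
            m, PROPS, ENV, linear_sinks=[(P.CYTOSOL, k)], single_surface=True
        )
        f = solve_steady_state(op)
        H = PROPS.henry
        layers = [
            (n_pore * h, PROPS.d_pore, 0.0, 0.0),
            (n_wall * h, H * PROPS.d_wall, 0.0, 0.0),
            # plasmalemma above the cytosol layer
            (n_cyt * h, H * PROPS.d_cytosol, k * H, 1.0 / (PROPS.p_membrane * H)),
        ]
        y = (np.arange(lab.size) + 0.5) * h
        # Dirichlet is half a cell outside the first element
        ana = transfer_matrix_profile(layers, U_B, y)
        err = np.abs(f.u[:, 0] - ana) / U_B
        assert err.max() < 0.01

    def test_flux_continuity_across_henry_interface(self):
        lab = np.zeros((60, 4), dtype=np.int8)
        lab[30:] = int(P.CELL_WALL)
        m = mesh_from_labels(lab, 0.5)
        op = TransportOperator(
            m, PROPS, ENV, linear_sinks=[(P.CELL_WALL, 10.0)], single_surface=True
        )
        f = solve_steady_state(op)
        # influx through the boundary equals the sink integral (steady state)
        sink = f.reaction_totals["linear_sinks"]
        assert f.boundary_influx_mol_m2s == pytest.approx(sink, rel=1e-10)
        # native concentration ratio at the interface approaches Henry's H
        co2 = f.co2[:, 0]
        assert co2[30] / co2[29] == pytest.approx(PROPS.henry, rel=0.02)


class TestSolverBehaviour:
    def test_mass_balance_at_steady_state(self, baseline_run):
        f, s = baseline_run
        rt = f.reaction_totals
        net = rt["assimilation"] - rt["respiration"]
        assert f.boundary_influx_mol_m2s == pytest.approx(net, rel=1e-3)
        # closed HCO3- compartments: net hydration integrates to ~zero
        assert abs(rt["hydration"]) < 1e-12

    def test_field_physically_ordered(self, baseline_run):
        f, s = baseline_run
        assert s.an > 0
        assert s.cm_bar < s.ci_bar < f.env.ca
        assert f.u.min() >= 0
        assert f.limb_consistency >= 0.99

    def test_hco3_tracked_only_in_aqueous_phases(self, baseline_run):
        f, _ = baseline_run
        gas = np.isin(f.mesh.labels, [int(P.PORE), int(P.EPIDERMIS)])
        assert np.all(np.isnan(f.hco3[gas]))
        assert np.all(np.isfinite(f.hco3[~gas]))

    def test_nonconvergence_error_carries_residuals(self, small_mesh, fvcb, baseline_env):
        op = TransportOperator(
            small_mesh, PROPS, baseline_env, fvcb=fvcb, carb=CarbonateParams()
        )
        with pytest.raises(SolverError) as exc:
            solve_steady_state(op, SolverSettings(rtol=1e-14, max_outer=2))
        assert len(exc.value.residuals) > 0

    def test_missing_electron_transport_rate_raises(self, small_mesh, fvcb):
        from leafgas.transport import AssemblyError

        with pytest.raises(AssemblyError, match="electron transport"):
            TransportOperator(small_mesh, PROPS, Environment(ca=350.0, j=None), fvcb=fvcb)


class TestRunCondition:
    def test_helox_increases_assimilation(self, small_mesh, fvcb, baseline_env, baseline_run):
        f0, s0 = baseline_run
        _, s_helox = run_condition(
            small_mesh, PROPS.replace(helox=2.33), fvcb, baseline_env, initial=f0
        )
        assert s_helox.an > s0.an

    def test_larger_membrane_permeability_raises_gm(
        self, small_mesh, fvcb, baseline_env, baseline_run
    ):
        f0, s0 = baseline_run
        _, s = run_condition(
            small_mesh, PROPS.replace(p_membrane=PROPS.p_membrane * 10), fvcb,
            baseline_env, initial=f0,
        )
        assert s.gm_bar > s0.gm_bar

    def test_low_o2_uses_nonphotorespiratory_respiration(self, small_mesh, fvcb):
        # in darkness the leaf releases exactly R_d, so the O2 level picks
        # the respiration constant actually used
        env_dark_21 = Environment(ca=350.0, o2_mbar=210.0, iinc=0.0, j=0.0)
        env_dark_2 = Environment(ca=350.0, o2_mbar=20.0, iinc=0.0, j=0.0)
        _, s21 = run_condition(small_mesh, PROPS, fvcb, env_dark_21)
        _, s2 = run_condition(small_mesh, PROPS, fvcb, env_dark_2)
        assert s21.an == pytest.approx(-fvcb.rd_pr, rel=1e-3)
        assert s2.an == pytest.approx(-fvcb.rd_npr, rel=1e-3)

    def test_mesh_refinement_changes_an_below_one_percent(
        self, small_geometry, fvcb, baseline_env, baseline_run
    ):
        _, s_coarse = baseline_run
        _, s_fine = run_condition(
            small_geometry, PROPS, fvcb, baseline_env, h_um=0.25
        )
        assert abs(s_fine.an / s_coarse.an - 1.0) < 0.01
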