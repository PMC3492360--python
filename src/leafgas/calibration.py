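"""Two-stage estimation of the effective diffusivities from gas exchange.

The epidermis is modelled as a homogeneous medium whose effective
diffusivity ``D_epi`` lumps the stomata, and the cell-wall diffusivity
``D_w`` is interchangeable with the modelled wall thickness — neither can
be measured directly, so both are estimated from gas-exchange and
fluorescence data:

1. at the reference condition (350 µmol mol-1 CO2, 21 % O2, I_inc
   1000 µmol m-2 s-1, 25 °C) ``(D_epi, D_w)`` are fitted simultaneously by
   least squares on the model's intercellular CO2 C̄_i against the measured
   Ĉ_i and the model's mesophyll CO2 C̄_m against the variable-J estimate
   Ĉ_c;
2. because stomata open with light, a separate ``D_epi`` is then fitted
   per irradiance (matching C̄_i to Ĉ_i) while ``D_w`` stays fixed.

Each objective evaluation is a full steady-state PDE solve; the optimiser
is derivative-free (Nelder–Mead over log-parameters, positivity by
construction) and consecutive solves warm-start from the previous field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from .kinetics import electron_transport_from_fluorescence
from .macroscale import harley_cc
from .params import Environment, FvCBParams, SolverSettings, TransportProps

__all__ = [
    "GasExchangeRecord",
    "CalibrationResult",
    "fit_depi_dw",
    "fit_depi_per_irradiance",
    "depi_to_conductance",
    "records_to_csv",
    "records_from_csv",
]

#: CSV schema shared with the synthetic-data generator
CSV_COLUMNS = [
    "Ca_umol_mol",
    "O2_pct",
    "Iinc_umol_m2_s",
    "A_net_umol_m2_s",
    "Ci_umol_mol",
    "Phi2",
    "J_umol_m2_s",
    "gs_mol_m2_s",
]


@dataclass(frozen=True)
class GasExchangeRecord:
    """One gas-exchange / fluorescence measurement point."""

    ca: float
    o2_pct: float
    iinc: float
    an_hat: float
    ci_hat: float
    phi2: Optional[float] = None
    j_hat: Optional[float] = None
    gs_hat: Optional[float] = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            np.isfinite(self.an_hat)
            and self.an_hat > 0
            and np.isfinite(self.ci_hat)
            and self.ci_hat > self.ca
        ):
            raise ValueError("Ci must not exceed Ca when assimilation is positive")

    def j(self, s: float) -> float:
        """Electron transport: measured directly or via J = s·I·Φ2."""
        if self.j_hat is not None:
            return self.j_hat
        if self.phi2 is None:
            raise ValueError("record carries neither J nor Φ2")
        return electron_transport_from_fluorescence(self.phi2, self.iinc, s)

    @property
    def o2_mbar(self) -> float:
        return self.o2_pct * 10.0


@dataclass
class CalibrationResult:
    """Point estimates with residual diagnostics."""

    d_epi: float
    d_w: float
    residuals: np.ndarray
    n_evaluations: int
    success: bool
    message: str = ""
    per_iinc: Optional[pd.DataFrame] = None
    ill_conditioned: bool = False

    def to_dict(self) -> dict:
        return {
            "D_epi_m2_s": self.d_epi,
            "D_w_m2_s": self.d_w,
            "residuals": list(map(float, np.atleast_1d(self.residuals))),
            "n_evaluations": self.n_evaluations,
            "success": self.success,
            "message": self.message,
            "ill_conditioned": self.ill_conditioned,
        }


def records_to_csv(records: Sequence[GasExchangeRecord], path: str | Path) -> Path:
    rows = [
        {
            "Ca_umol_mol": r.ca,
            "O2_pct": r.o2_pct,
            "Iinc_umol_m2_s": r.iinc,
            "A_net_umol_m2_s": r.an_hat,
            "Ci_umol_mol": r.ci_hat,
            "Phi2": r.phi2,
            "J_umol_m2_s": r.j_hat,
            "gs_mol_m2_s": r.gs_hat,
        }
        for r in records
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    return path


def records_from_csv(path: str | Path) -> list[GasExchangeRecord]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV lacks required columns: {sorted(missing)}")

    def opt(row, col):
        return None if col not in row or pd.isna(row[col]) else float(row[col])

    return [
        GasExchangeRecord(
            ca=float(r["Ca_umol_mol"]),
            o2_pct=float(r["O2_pct"]),
            iinc=float(r["Iinc_umol_m2_s"]),
            an_hat=float(r["A_net_umol_m2_s"]),
            ci_hat=float(r["Ci_umol_mol"]),
            phi2=opt(r, "Phi2"),
            j_hat=opt(r, "J_umol_m2_s"),
            gs_hat=opt(r, "gs_mol_m2_s"),
        )
        for _, r in df.iterrows()
    ]


class _SimCache:
    """Warm-started steady solves keyed by nothing: each call reuses the
    previous converged field as the Picard initial guess."""

    def __init__(self, mesh, fvcb, env, settings):
        self.mesh = mesh
        self.fvcb = fvcb
        self.env = env
        self.settings = settings
        self.field = None
        self.n = 0

    def summary(self, props: TransportProps):
        from .transport import run_condition

        fld, s = run_condition(
            self.mesh,
            props,
            self.fvcb,
            self.env,
            settings=self.settings,
            initial=self.field,
        )
        self.field = fld
        self.n += 1
        return s


def fit_depi_dw(
    geometry,
    fvcb: FvCBParams,
    record: GasExchangeRecord,
    props: TransportProps = TransportProps(),
    h_um: float = 0.5,
    settings: SolverSettings = SolverSettings(),
    xatol: float = 5e-3,
    max_evaluations: int = 120,
    cc_hat: Optional[float] = None,
) -> CalibrationResult:
    """Simultaneous least-squares fit of (D_epi, D_w) at one reference point.

    Minimises ``(C̄_i − Ĉ_i)² + (C̄_m − Ĉ_c)²`` over log10(D_epi, D_w).
    By default Ĉ_c comes from the variable-J estimator applied to the
    record; pass ``cc_hat`` explicitly to target a known mesophyll
    concentration instead (the variable-J estimate carries a bias whenever
    part of the chloroplast field is not electron-transport limited).
    Initial guess: the ``props`` values.  Warns (flag, not failure) when
    the objective surface is locally flat (non-identifiable).
    """
    from .geometry import ComputationalMesh, mesh as make_mesh

    m = geometry if isinstance(geometry, ComputationalMesh) else make_mesh(geometry, h_um)
    j = record.j(fvcb.s)
    rd = fvcb.rd(record.o2_mbar)
    if cc_hat is None:
        cc_hat = harley_cc(record.an_hat, rd, j, fvcb.gamma_star)
    env = Environment(
        ca=record.ca, o2_mbar=record.o2_mbar, iinc=record.iinc, j=j
    )
    cache = _SimCache(m, fvcb, env, settings)

    def objective(logp: np.ndarray) -> float:
        p = props.replace(d_epidermis=10.0 ** logp[0], d_wall=10.0 ** logp[1])
        s = cache.summary(p)
        return (s.ci_bar - record.ci_hat) ** 2 + (s.cm_bar - cc_hat) ** 2

    x0 = np.log10([props.d_epidermis, props.d_wall])
    f0 = objective(x0)
    if f0 < 1e-10:
        return CalibrationResult(
            d_epi=props.d_epidermis, d_w=props.d_wall,
            residuals=np.zeros(2), n_evaluations=cache.n,
            success=True, message="already optimal at initial guess",
        )
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": xatol,
            "fatol": max(f0 * 1e-8, 1e-12),
            "maxfev": max_evaluations,
        },
    )
    d_epi, d_w = 10.0 ** res.x
    final = cache.summary(props.replace(d_epidermis=d_epi, d_wall=d_w))
    residuals = np.array([final.ci_bar - record.ci_hat, final.cm_bar - cc_hat])
    # flatness probe along each log-axis
    probe = [
        abs(objective(res.x + dx) - res.fun)
        for dx in (np.array([0.05, 0.0]), np.array([0.0, 0.05]))
    ]
    ill = any(p < max(res.fun, 1e-12) * 1e-3 + 1e-12 for p in probe)
    return CalibrationResult(
        d_epi=d_epi,
        d_w=d_w,
        residuals=residuals,
        n_evaluations=cache.n,
        success=bool(res.success or res.fun <= f0),
        message=res.message,
        ill_conditioned=ill,
    )


def fit_depi_per_irradiance(
    geometry,
    fvcb: FvCBParams,
    records: Sequence[GasExchangeRecord],
    d_w: float,
    props: TransportProps = TransportProps(),
    h_um: float = 0.5,
    settings: SolverSettings = SolverSettings(),
    rtol: float = 5e-3,
    span: float = 30.0,
) -> pd.DataFrame:
    """Fit one D_epi per irradiance, keeping D_w fixed.

    For each record, solves ``C̄_i(D_epi) = Ĉ_i`` by bracketed root-finding
    on log10(D_epi) (C̄_i is monotone increasing in the epidermal
    diffusivity).  Points with |Â_N| < 0.5 µmol m-2 s-1 are flagged
    ill-conditioned (C̄_i ≈ C_a is then insensitive to D_epi).
    """
    from .geometry import ComputationalMesh, mesh as make_mesh

    m = geometry if isinstance(geometry, ComputationalMesh) else make_mesh(geometry, h_um)
    base = props.replace(d_wall=d_w)
    rows = []
    for rec in records:
        j = rec.j(fvcb.s)
        env = Environment(ca=rec.ca, o2_mbar=rec.o2_mbar, iinc=rec.iinc, j=j)
        cache = _SimCache(m, fvcb, env, settings)
        flag = ""
        if abs(rec.an_hat) < 0.5:
            rows.append(
                {"Iinc": rec.iinc, "D_epi_m2_s": np.nan, "flag": "ill_conditioned"}
            )
            continue

        def mismatch(logd: float) -> float:
            s = cache.summary(base.replace(d_epidermis=10.0**logd))
            return s.ci_bar - rec.ci_hat

        log0 = math.log10(props.d_epidermis)
        lo, hi = log0 - math.log10(span), log0 + math.log10(span)
        flo, fhi = mismatch(lo), mismatch(hi)
        if flo * fhi > 0:
            rows.append(
                {
                    "Iinc": rec.iinc,
                    "D_epi_m2_s": np.nan,
                    "flag": f"no_root_in_bracket (f({lo:.1f})={flo:.1f}, "
                    f"f({hi:.1f})={fhi:.1f})",
                }
            )
            continue
        logd = brentq(mismatch, lo, hi, rtol=1e-12, xtol=rtol / math.log(10))
        rows.append({"Iinc": rec.iinc, "D_epi_m2_s": 10.0**logd, "flag": flag})
    return pd.DataFrame(rows)


def depi_to_conductance(
    d_epi: float, t_epi_um: float, env: Environment = Environment()
) -> float:
    """Equivalent epidermal conductance g = (D_epi/t)·P/(RT) per surface
    (mol m-2 s-1); two epidermes in series are the caller's arithmetic."""
    if t_epi_um <= 0:
        raise ValueError("epidermis thickness must be positive")
    return d_epi / (t_epi_um * 1e-6) * env.gas_molar_density
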