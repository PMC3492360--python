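"""Parameter containers for the microscale leaf gas-exchange model.

Three groups of parameters drive a simulation:

* :class:`FvCBParams` — biochemical constants of the Farquhar–von
  Caemmerer–Berry (FvCB) model of C3 photosynthesis, as estimated for wheat
  flag leaves from combined gas-exchange / chlorophyll-fluorescence data.
* :class:`CarbonateParams` — uncatalysed CO2 <-> HCO3- interconversion
  kinetics in the aqueous phases (no carbonic anhydrase).
* :class:`TransportProps` — phase diffusivities, membrane permeability and
  the Henry partition coefficient of the physical transport model.

:class:`Environment` bundles the boundary conditions of a single steady-state
run (ambient CO2, O2, irradiance, temperature, pressure).

All classes are plain frozen dataclasses; named default sets mirror the
published wheat parameterisation and are available through
:func:`load_fvcb_params`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

R_GAS = 8.314  # J mol-1 K-1


@dataclass(frozen=True)
class FvCBParams:
    """FvCB photosynthesis parameters (leaf-area basis).

    Units: rates in µmol m-2 s-1, Michaelis constants in µbar (CO2) and
    mbar (O2), specificity ``sco`` in mbar µbar-1, ``gamma_star`` in µbar.
    ``rd_pr`` / ``rd_npr`` are day respiration under photorespiratory
    (21 % O2) and non-photorespiratory (2 % O2) conditions; ``s`` is the
    fluorescence-to-J calibration slope and ``alpha`` the fraction of
    glycolate carbon not returned to the chloroplast under TPU limitation.
    """

    vcmax: float = 65.8
    kmc: float = 168.0
    kmo: float = 473.0
    sco: float = 3.13
    gamma_star: float = 34.0
    rd_pr: float = 1.317
    rd_npr: float = 1.573
    tp: float = 12.9
    s: float = 0.380
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("vcmax", "kmc", "kmo", "sco", "gamma_star", "tp", "s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FvCB parameter {name!r} must be positive")
        if not 0.0 <= self.alpha <= 0.5:
            raise ValueError("alpha must lie in [0, 0.5]")

    def rd(self, o2_mbar: float) -> float:
        """Day respiration for the given O2 level.

        Non-photorespiratory estimates apply below 100 mbar O2 (the 2 %
        treatment); photorespiratory values otherwise (21 %).
        """
        return self.rd_npr if o2_mbar < 100.0 else self.rd_pr

    def gamma_star_at(self, o2_mbar: float) -> float:
        """CO2 compensation point at the given O2 level.

        Γ* = 0.5·O/S_c/o is proportional to O; the stored value anchors the
        published estimate at 21 % O2 (210 mbar).
        """
        return self.gamma_star * o2_mbar / 210.0


@dataclass(frozen=True)
class CarbonateParams:
    """Uncatalysed CO2 hydration / HCO3- dehydration kinetics.

    ``k1`` (s-1) hydrates CO2; ``k2`` (s-1) dehydrates carbonic acid, of
    which only the fraction [H+]/(K_a+[H+]) of the HCO3- pool is available;
    ``ka`` (mol L-1) is the acid dissociation constant of H2CO3.  Default pH
    is 7.0 in every aqueous phase; dissociation to carbonate is neglected
    (insignificant below pH 8).
    """

    k1: float = 0.039
    k2: float = 23.0
    ka: float = 2.5e-4
    ph: float = 7.0

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.ka) <= 0:
            raise ValueError("rate constants must be positive")
        if not 6.0 <= self.ph <= 8.0:
            raise ValueError("pH must lie in [6, 8]")

    @property
    def proton(self) -> float:
        """[H+] in mol L-1."""
        return 10.0 ** (-self.ph)

    @property
    def k2_effective(self) -> float:
        """Effective first-order dehydration constant k2·[H+]/(K_a+[H+])."""
        h = self.proton
        return self.k2 * h / (self.ka + h)

    @property
    def equilibrium_ratio(self) -> float:
        """HCO3-:CO2 concentration ratio at which net hydration vanishes."""
        return self.k1 / self.k2_effective


@dataclass(frozen=True)
class TransportProps:
    """Physical transport properties (SI units, m2 s-1 / m s-1).

    ``d_wall`` and ``d_epidermis`` are effective (calibrated) diffusivities:
    the epidermis is a homogeneous medium whose diffusivity lumps stomatal
    conductance, and the cell-wall value is interchangeable with the modelled
    wall thickness.  The chloroplast envelope is a double membrane and gets
    half the single-membrane permeability.  ``helox`` multiplies the
    gas-phase diffusivities (2.33 for a helium–oxygen atmosphere).
    """

    d_pore: float = 1.60e-5
    d_cytosol: float = 1.67e-9
    d_wall: float = 3.437e-7
    d_epidermis: float = 1.672e-7
    d_hco3: float = 1.17e-9
    p_membrane: float = 3.5e-3
    henry: float = 0.83
    helox: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"transport property {f.name!r} must be positive")

    @property
    def p_envelope(self) -> float:
        """Chloroplast-envelope permeability (double membrane, P_m/2)."""
        return self.p_membrane / 2.0

    def replace(self, **kw) -> "TransportProps":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Environment:
    """Ambient conditions of one steady-state run.

    ``ca`` ambient CO2 mole fraction (µmol mol-1); ``o2_mbar`` chloroplast
    O2 partial pressure (21 % -> 210, 2 % -> 20); ``iinc`` incident photon
    flux (µmol m-2 s-1); ``j`` the potential linear electron transport rate
    (µmol e- m-2 s-1) actually delivered at ``iinc`` — supply it directly or
    derive it from fluorescence via
    :func:`leafgas.kinetics.electron_transport_from_fluorescence`.
    """

    ca: float = 350.0
    o2_mbar: float = 210.0
    iinc: float = 1000.0
    tleaf_k: float = 298.15
    pressure_pa: float = 101325.0
    j: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ca < 0 or self.o2_mbar <= 0 or self.iinc < 0:
            raise ValueError("environment values must be non-negative (O2 positive)")
        if self.tleaf_k <= 0 or self.pressure_pa <= 0:
            raise ValueError("temperature and pressure must be positive")

    @property
    def gas_molar_density(self) -> float:
        """P/(R·T), mol m-3 of gas."""
        return self.pressure_pa / (R_GAS * self.tleaf_k)

    def replace(self, **kw) -> "Environment":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SolverSettings:
    """Steady-state solver controls (Picard outer iteration)."""

    rtol: float = 1e-6
    max_outer: int = 60
    damping: float = 0.5
    scheme: str = "picard-limb"

    def __post_init__(self) -> None:
        if self.rtol <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must lie in (0, 1]")


#: Named FvCB parameter sets for wheat flag leaves (high / low nitrogen at
#: the flowering stage).  Values are the published point estimates.
PARAMETER_SETS: dict[str, FvCBParams] = {
    "highN_flowering": FvCBParams(
        vcmax=65.8, kmc=168.0, kmo=473.0, sco=3.13, gamma_star=34.0,
        rd_pr=1.317, rd_npr=1.573, tp=12.9, s=0.380,
    ),
    "lowN_flowering": FvCBParams(
        vcmax=58.5, kmc=168.0, kmo=473.0, sco=3.13, gamma_star=34.0,
        rd_pr=0.939, rd_npr=1.375, tp=11.1, s=0.403,
    ),
}


def load_fvcb_params(source: str | Path) -> FvCBParams:
    """Load FvCB parameters from a named set or a JSON/TOML file.

    ``source`` may be one of the keys of :data:`PARAMETER_SETS` or a path to
    a JSON (``.json``) or TOML (``.toml``) file whose keys match the
    :class:`FvCBParams` field names.
    """
    if isinstance(source, str) and source in PARAMETER_SETS:
        return PARAMETER_SETS[source]
    path = Path(source)
    if not path.exists():
        raise KeyError(
            f"unknown parameter set {source!r}; available: "
            f"{sorted(PARAMETER_SETS)} or a JSON/TOML file path"
        )
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return FvCBParams(**data)
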