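"""Reproducible runs from a single configuration (TOML or dataclass).

A :class:`RunConfig` pins everything one steady-state simulation needs —
geometry source (generator parameters or a geometry file), the FvCB
parameter set, the environment, solver settings and output flags — and
:func:`run_from_config` executes it into an artifact directory containing
the config echo (with a content hash), the geometry, the concentration
field, the whole-leaf summary and the resistance table.  Re-running the
same config reproduces the summaries bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__version__ = "0.1.0"

log = logging.getLogger("leafgas")


@dataclass
class RunConfig:
    """One reproducible simulation run."""

    out_dir: str = "run"
    geometry_file: Optional[str] = None  # geom.json or labelled raster
    parameter_set: str = "highN_flowering"
    ca: float = 350.0
    o2_pct: float = 21.0
    iinc: float = 1000.0
    j: Optional[float] = None  # derived from the default PSII response if None
    h_um: float = 0.5
    seed: int = 0
    helox: bool = False
    lumped_intracellular: bool = False
    single_surface: bool = False
    respiration: str = "cytosol"
    generator: dict = field(default_factory=dict)  # GeometryGenParams overrides

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        return cls(**data)

    def content_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run_from_config(config: RunConfig | str | Path) -> Path:
    """Execute a configured run into its artifact directory.

    Writes ``config.json``, ``geometry.json`` (generator runs),
    ``field.csv``, ``summary.csv`` and ``resistances.csv``.  Partial
    outputs are removed if the run fails.
    """
    from .geometry import (
        GeometryGenParams,
        generate_leaf_microstructure,
        import_labeled_raster,
        load_geometry_json,
        save_geometry_json,
    )
    from .params import Environment, TransportProps, load_fvcb_params
    from .synthetic import default_j_response
    from .transport import field_to_dataframe, run_condition

    if not isinstance(config, RunConfig):
        config = RunConfig.from_toml(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        fvcb = load_fvcb_params(config.parameter_set)
        if config.geometry_file:
            src = Path(config.geometry_file)
            if not src.exists():
                raise FileNotFoundError(src)
            if src.suffix == ".json":
                geom = load_geometry_json(src)
            else:
                geom = import_labeled_raster(src)
        else:
            geom = generate_leaf_microstructure(
                GeometryGenParams(seed=config.seed, **config.generator)
            )
        props = TransportProps(helox=2.33 if config.helox else 1.0)
        j = config.j
        if j is None:
            j = default_j_response(config.iinc, fvcb.s)
        env = Environment(
            ca=config.ca, o2_mbar=config.o2_pct * 10.0, iinc=config.iinc, j=j
        )
        log.info("run %s: Ca=%g O2=%g%% I=%g J=%.1f", config.content_hash(),
                 config.ca, config.o2_pct, config.iinc, j)
        fld, summary = run_condition(
            geom,
            props,
            fvcb,
            env,
            h_um=config.h_um,
            respiration=config.respiration,
            lumped_intracellular=config.lumped_intracellular,
            single_surface=config.single_surface,
        )
        log.info("converged in %d iterations (residual %.2e)",
                 fld.iterations, fld.residual)

        provenance = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        }
        doc = {"config": dataclasses.asdict(config), "provenance": provenance}
        p = out / "config.json"
        p.write_text(json.dumps(doc, indent=1))
        written.append(p)
        if not geom.is_raster_backed:
            p = out / "geometry.json"
            save_geometry_json(geom, p)
            written.append(p)
        p = out / "field.csv"
        field_to_dataframe(fld).to_csv(p, index=False)
        written.append(p)
        import pandas as pd

        p = out / "summary.csv"
        pd.DataFrame([summary.to_dict() | provenance]).to_csv(p, index=False)
        written.append(p)
        if summary.resistances is not None:
            p = out / "resistances.csv"
            summary.resistances.to_dataframe().to_csv(p, index=False)
            written.append(p)
        return out
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
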