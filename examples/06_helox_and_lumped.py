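"""Two in-silico experiments on the same microstructure.

1. Helox (helium-oxygen) raises the gas-phase CO2 diffusivity 2.33x and
   probes how much the gas-filled path (stomata + intercellular space)
   limits photosynthesis.
2. The lumped-intracellular variant merges chloroplasts and vacuole into
   one cytosolic compartment; resolving the chloroplast layer near the
   plasma membrane yields a higher mesophyll conductance."""

from leafgas import (
    Environment, GeometryGenParams, TransportProps,
    generate_leaf_microstructure, load_fvcb_params, run_condition,
)
from leafgas.synthetic import default_j_response

geom = generate_leaf_microstructure(GeometryGenParams(seed=0))
fvcb = load_fvcb_params("highN_flowering")
env = Environment(ca=350.0, o2_mbar=210.0, iinc=1000.0,
                  j=default_j_response(1000.0, fvcb.s))

field, s_air = run_condition(geom, TransportProps(), fvcb, env, h_um=0.5)
_, s_helox = run_condition(geom, TransportProps(helox=2.33), fvcb, env,
                           h_um=0.5, initial=field)
print(f"A_N in air:   {s_air.an:.2f} µmol m-2 s-1")
print(f"A_N in helox: {s_helox.an:.2f} µmol m-2 s-1 "
      f"(+{100 * (s_helox.an / s_air.an - 1):.1f} %)")

_, s_lumped = run_condition(geom, TransportProps(), fvcb, env, h_um=0.5,
                            lumped_intracellular=True)
print(f"\ng_m layered chloroplasts: {s_air.gm_bar:.3f} mol m-2 s-1")
print(f"g_m lumped intracellular: {s_lumped.gm_bar:.3f} mol m-2 s-1 "
      f"(layered is +{100 * (s_air.gm_bar / s_lumped.gm_bar - 1):.1f} % higher)")
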