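"""One steady-state simulation at the reference condition and the serial
resistance analysis of the CO2 path from ambient air to the stroma.

Prints the whole-leaf quantities a gas-exchange instrument would report:
net assimilation A_N (µmol m-2 s-1), intercellular and mesophyll CO2
(µmol mol-1) and the mesophyll conductance g_m = A_N/(Ci - Cm).
"""

from leafgas import (
    Environment,
    GeometryGenParams,
    TransportProps,
    generate_leaf_microstructure,
    load_fvcb_params,
    run_condition,
)
from leafgas.synthetic import default_j_response

geom = generate_leaf_microstructure(GeometryGenParams(seed=0))
fvcb = load_fvcb_params("highN_flowering")
env = Environment(ca=350.0, o2_mbar=210.0, iinc=1000.0,
                  j=default_j_response(1000.0, fvcb.s))

field, summary = run_condition(geom, TransportProps(), fvcb, env, h_um=0.5)
print(f"converged in {field.iterations} outer iterations")
print(f"A_N  = {summary.an:6.2f} µmol m-2 s-1   (net CO2 uptake)")
print(f"Ci   = {summary.ci_bar:6.1f} µmol mol-1    (pore average)")
print(f"Cm   = {summary.cm_bar:6.1f} µmol mol-1    (mesophyll-cell average)")
print(f"g_m  = {summary.gm_bar:6.3f} mol m-2 s-1   (mesophyll conductance)")

print("\nserial resistance decomposition (ambient -> stroma):")
print(summary.resistances.to_dataframe().to_string(index=False,
                                                   float_format="%.3f"))
print("the percentages sum to 100; the chloroplast envelope (a double "
      "membrane) costs about twice the plasma membrane")
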