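"""Light-response curve with a per-irradiance epidermal diffusivity.

The epidermis lumps the stomata, which open with light, so its effective
diffusivity D_epi rises with irradiance; here it is scaled with a
saturating stomatal light response.  Electron transport J follows the
default PSII efficiency decline."""

from leafgas import (
    Environment, GeometryGenParams, TransportProps,
    generate_leaf_microstructure, light_response_curve, load_fvcb_params,
)
from leafgas.synthetic import stomatal_conductance

geom = generate_leaf_microstructure(GeometryGenParams(seed=0, width_um=60.0))
fvcb = load_fvcb_params("highN_flowering")
props = TransportProps()

iincs = (100.0, 200.0, 500.0, 1000.0, 2000.0)
depi = {i: props.d_epidermis * stomatal_conductance(i) / stomatal_conductance(1000.0)
        for i in iincs}
df = light_response_curve(geom, props, fvcb, Environment(ca=350.0),
                          iincs, depi)
print(df[["Iinc", "A_net", "Ci_bar", "gm_bar"]]
      .to_string(index=False, float_format="%.3f"))
print("\nA saturates with light; g_m increases with irradiance as the "
      "stomata (and the fitted D_epi) open")
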