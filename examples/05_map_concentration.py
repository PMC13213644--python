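"""Pixel-wise concentration mapping: train a calibration, apply it per pixel.

Builds a hypercube whose three regions hold the three root classes, trains an
SNV + LSSVM calibration on simulated reference spectra, predicts every
foreground pixel and renders the red (high) to black (low) map.
"""

import numpy as np

from hsichem import (
    SimulationConfig,
    calibrate_reflectance,
    chain_from_name,
    lssvm_train,
    predict_pixel_map,
    render_map,
    simulate_hypercube,
    simulate_spectrum_set,
    threshold_mask,
)

config = SimulationConfig(seed=5)
sset = simulate_spectrum_set(config)
chain = chain_from_name("SNV")
model = lssvm_train(chain(sset.spectra),
                    sset.concentrations["norisoboldine"].to_numpy())
model.chain = chain
model.wavelengths = sset.wavelengths

layout = np.full((12, 18), "", dtype=object)
layout[2:10, 1:6] = "tuberous"
layout[2:10, 7:12] = "taproot"
layout[2:10, 13:17] = "old"
raw, refs, truth = simulate_hypercube(config, layout)
cube = calibrate_reflectance(raw, refs)

mask = threshold_mask(cube, 800.0)
cmap = predict_pixel_map(cube, model, mask, analyte="norisoboldine")
path = render_map(cmap, "norisoboldine_map.png")

for label in ("tuberous", "taproot", "old"):
    sel = truth["labels"] == label
    print(f"  mean predicted norisoboldine, {label:>8}: "
          f"{np.nanmean(cmap.values[sel]):.3f} mg/g "
          f"(true {np.nanmean(truth['concentrations'][sel][:, 0]):.3f})")
print(f"map written to {path} (+ colorbar); tuberous regions light up red — "
      "the marker compound concentrates in the medicinal tissue.")
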