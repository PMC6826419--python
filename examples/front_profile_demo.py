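"""Invasive-front profiling demo.

Simulates a noisy fluorescence image of a migrating cell sheet (pixel
0.5 um), segments it via minimum-error thresholding of the actin channel,
extracts the free-edge front line, and profiles both p120 isoform channels
versus distance from the front, ending in 30-um binned isoform ratios
compared against confluent control images.
"""

import numpy as np

from cateno_iso import (
    FrontSimConfig,
    binned_ratio,
    distance_profile,
    extract_front,
    front_bins_vs_control,
    segment_sheet,
    simulate_front_image,
)

profiles = []
for seed in range(5):
    sim = simulate_front_image(FrontSimConfig(), seed=seed)
    mask = segment_sheet(sim.image, n_steps=5)
    front = extract_front(mask)
    profiles.append(distance_profile(sim.image, mask, front))

controls = [simulate_front_image(FrontSimConfig(confluent=True),
                                 seed=100 + k).image for k in range(5)]
binned = binned_ratio(profiles, control_images=controls)
test = front_bins_vs_control(binned)

print(f"front pixels in last image: {len(front)}")
print(f"confluent reference ratio:  {binned.confluent_reference:.3f}")
print("\n30-um bin   mean p120-3/p120-1 ratio   Dunn p (vs confluent)")
for col in binned.ratios.columns:
    if col not in test["vs_control"]:
        continue  # bins beyond the sheet depth carry no pixels
    row = test["vs_control"][col]
    print(f"{col:>10}   {binned.ratios[col].mean():24.3f}   "
          f"{row['p_adj']:.4f}")
print()
print("The ratio is several-fold elevated in the first bins and decays to")
print("the confluent value: p120-3 is enriched at the invasive front.")
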