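"""Concentric-ring neuron-density profile around a synthetic implant site.

Renders a NeuN image whose neuron density ramps from 59% of background at
the implant hole up to 100% at 600 um, detects somata with the built-in
blob detector, bins them into 50 um annuli by distance from the hole edge,
and normalizes densities to the 600-650 um background annulus.
"""

from imequant import histo
from imequant.synth.ihc import default_ihc_config, gen_ihc_image

cfg = default_ihc_config("DEXSPPIN", seed=1)
image, truth = gen_ihc_image(cfg)
labels = histo.ring_labels(image.hole_mask, image.microns_per_pixel)
centroids = histo.detect_centroids(image, soma_diameter_um=cfg.soma_diameter_um)
prof = histo.density_profile(centroids, labels, image.microns_per_pixel)

print(f"detected {len(centroids)} somata ({len(truth.centroids)} rendered)\n")
print(f"{'bin (um)':>12} {'count':>6} {'density/mm2':>12} {'normalized':>11} {'truth':>6}")
for i in range(histo.N_BINS):
    lo, hi = prof.bin_edges[i], prof.bin_edges[i + 1]
    print(f"{lo:5.0f}-{hi:<5.0f} {prof.counts[i]:>6d} {prof.density[i]:>12.0f} "
          f"{prof.normalized[i]:>11.2f} {truth.profile[i]:>6.2f}")

print("\nNormalized density near the hole tracks the configured retention")
print("(~0.59 in the 0-50 um bin for this arm) and rises to 1 at background.")
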