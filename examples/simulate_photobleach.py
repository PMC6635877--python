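"""Simulate a single-molecule photobleach stack with full ground truth.

Builds a rod-shaped cyanobacterial cell with three 37-copy YFP-labelled
organelles, renders a 300-frame bleach acquisition (80 nm/px, 5 ms
exposure, Poisson noise) and writes it as 16-bit TIFF + JSON sidecar.
"""

import numpy as np

from organelle_stoich import (
    CellGeometry, OpticalModel, OrganelleSpec, simulate_photobleach_stack, write_stack,
)

geometry = CellGeometry(length=3.0, radius=0.5, thylakoid_thickness=0.15,
                        thylakoid_photon_density=2e3, cytosol_photon_density=5e2)
optics = OpticalModel(pixel_size=80.0, exposure=5.0, baseline=100.0)
organelles = [
    OrganelleSpec(position=(x, 0.0, 0.0), diameter=200.0, copy_number=37,
                  photons_per_fluorophore=1000.0, bleach_rate=0.02)
    for x in (-0.9, 0.0, 0.9)
]

stack, truth = simulate_photobleach_stack(geometry, organelles, optics,
                                          n_frames=300, rng_seed=1)
path = write_stack(stack, "scratch/photobleach.tif", ground_truth=truth)

surv = truth.surviving
print(f"wrote {path}: {stack.shape[0]} frames of {stack.shape[1]}x{stack.shape[2]} px")
print(f"surviving fluorophores per organelle, frame 0:   {surv[0].astype(int)}")
print(f"surviving fluorophores per organelle, frame 150: {surv[150].astype(int)}")
print(f"surviving fluorophores per organelle, frame 299: {surv[-1].astype(int)}")
print("Each organelle starts with its full complement of 37 fluorescent tags;")
print("by late frames nearly all have bleached, which is what lets the analysis")
print("read off the brightness of a single fluorophore from the trace tails.")
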