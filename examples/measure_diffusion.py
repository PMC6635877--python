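"""Measure organelle mobility from a simulated confocal time-lapse.

Renders 40 frames (60 s interval) of three 200 nm organelles diffusing at
D = 1.3e-5 µm²/s inside the cell, then runs the full analysis: drift
registration, detection and tracking, time-averaged MSD, a first-6-lag fit
for the apparent diffusion coefficient, and the anomalous exponent.
"""

import numpy as np

from organelle_stoich import (
    anomalous_exponent, fit_apparent_D, msd, register_drift,
    simulate_diffusion_stack, tracks_from_stack,
)
from organelle_stoich.validation import diffusion_validation_scene

TRUE_D = 1.3e-5  # µm²/s

geometry, organelles, optics = diffusion_validation_scene(TRUE_D)
stack, truth = simulate_diffusion_stack(geometry, organelles, optics,
                                        n_frames=40, frame_interval=60.0, rng_seed=1)

frames, shifts, _ = register_drift(stack.frames)
tracks = tracks_from_stack(frames, pixel_size_um=optics.pixel_size_um,
                           frame_interval=60.0, expected_D=TRUE_D)
print(f"{len(tracks)} tracks recovered (3 organelles simulated); "
      f"max residual drift {np.abs(shifts).max():.2f} px")

for tr in tracks:
    profile = msd(tr)
    d = fit_apparent_D(profile)
    alpha = anomalous_exponent(profile)
    print(f"track {tr.track_id}: D = {d*1e5:.2f}e-5 µm²/s, alpha = {alpha:.2f}, "
          f"{len(tr)} frames")

print(f"\ntruth: D = {TRUE_D*1e5:.2f}e-5 µm²/s, alpha = 1 (Brownian).")
print("Single 40-frame tracks scatter around the truth; averaging ~100 replicate")
print("simulations pins the ensemble mean to within a few percent — that ensemble")
print("check is what scripts/acceptance.py recomputes.")
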