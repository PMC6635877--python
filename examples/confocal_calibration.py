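"""Calibrate confocal focus intensities to absolute molecule counts.

Single-molecule imaging gives absolute copies but low throughput; confocal
imaging gives thousands of organelles but only arbitrary intensity units.
Anchoring the confocal intensity peak on the single-molecule copy-number
peak for the same strain under the reference condition yields a conversion
factor applicable to every other growth condition.
"""

import numpy as np

from organelle_stoich import (
    calibrate, compare_conditions, grouped_sampling_error, kde_estimate,
)

rng = np.random.default_rng(2)
GAIN = 13.7  # unknown-to-the-analysis intensity units per molecule

# reference condition: true copies ~37, measured by both modalities
copies_ref = rng.normal(37, 6, 2500)
confocal_ref = copies_ref * GAIN + rng.normal(0, 25, copies_ref.size)
slimfield_peak = kde_estimate(copies_ref[:300], kernel_width="standard").peak
confocal_peak = kde_estimate(confocal_ref, kernel_width="standard").peak

cal = calibrate(confocal_peak=confocal_peak, slimfield_peak=slimfield_peak,
                strain_confocal="ccmL", strain_slimfield="ccmL")
print(f"conversion factor: {cal.factor:.4f} molecules per intensity unit")

# a second growth condition with ~1.8x the copies, confocal only
copies_b = rng.normal(66, 9, 2500)
confocal_b = copies_b * GAIN + rng.normal(0, 25, copies_b.size)
peak_b = kde_estimate(confocal_b, kernel_width="standard").peak
print(f"condition B calibrated peak: {cal.apply(peak_b):.1f} molecules "
      f"(truth ~66; reference was {slimfield_peak:.1f})")

comp = compare_conditions(copies_b, copies_ref, oligomer_size=5)
print(f"Mann-Whitney U: p = {comp.p_value:.2e} ({comp.stars}); "
      f"fold change {comp.fold_change:.2f} in pentamer units")

err = grouped_sampling_error(confocal_ref, group_size=85, n_resamples=10, rng_seed=0)
print(f"sampling error of the confocal peak (randomized groups of 85): "
      f"{100*err.relative_error:.1f}% — kept below 5% for a trustworthy peak")
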