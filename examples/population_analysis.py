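"""Population structure of copy-number distributions.

Decomposes a trimodal copy-number sample into three Gaussian populations,
subtracts an autofluorescence background distribution, and asks whether the
high-copy population could simply be two organelles overlapping within one
diffraction-limited focus (nearest-neighbor model).
"""

import numpy as np

from organelle_stoich import (
    CellGeometry, fit_triple_gaussian, kde_estimate, overlap_fraction,
    subtract_background_distribution,
)

rng = np.random.default_rng(1)

# three populations: partially capped (~35), fully capped (60), and overlaps (~95)
values = np.concatenate([
    rng.normal(35, 6, 1500), rng.normal(60, 5, 300), rng.normal(95, 9, 200),
])
dist = kde_estimate(values, kernel_width=2.0)
fit = fit_triple_gaussian(dist, initial_means=[35, 60, 95])
for mu, sd, frac in zip(fit.means, fit.sds, fit.fractions):
    print(f"population: mean {mu:5.1f} molecules, sd {sd:4.1f}, {100*frac:4.1f}% of organelles")

# is the third population explained by random focus overlap?
cell = CellGeometry(length=3.0, radius=0.5)
singles = kde_estimate(values[values < 75], kernel_width=2.0)
model = overlap_fraction(10, cell, resolution_radius=250.0, mode="analytic",
                         singles=singles)
grid2, dens2 = model.pair_distribution
print(f"\nwith 10 foci/cell and 250 nm resolution, {100*model.overlap_fraction:.0f}% of "
      "foci have an unresolvable neighbor;")
print(f"the predicted merged-pair distribution peaks at {grid2[np.argmax(dens2)]:.0f} "
      "molecules — where the third population sits.")

# chlorophyll-style background subtraction: a dim autofluorescence population
# overlapping the signal drags the apparent peak down until it is removed
bg = rng.normal(22, 8, 4000)
signal = rng.normal(37, 8, 1200)
mix = np.concatenate([signal, rng.choice(bg, 800)])
contaminated = kde_estimate(mix, kernel_width=2.0)
corrected = subtract_background_distribution(
    contaminated, kde_estimate(bg, kernel_width=2.0), background_rate=0.4,
)
clean_peak = kde_estimate(signal, kernel_width=2.0).peak
print(f"\nbackground-contaminated peak: {contaminated.peak:.1f}; after subtraction: "
      f"{corrected.peak:.1f}; uncontaminated signal alone: {clean_peak:.1f}")
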