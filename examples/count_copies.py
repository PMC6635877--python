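"""Count fluorophore copies per organelle by photobleach step analysis.

Simulates bleach traces for a population of 37-copy organelles, estimates
the characteristic single-fluorophore intensity two independent ways
(end-of-bleach distribution and intensity-axis periodicity), divides each
trace's back-extrapolated initial intensity by it, and summarizes the
population as a kernel-density peak ± HWHM.
"""

import numpy as np

from organelle_stoich import (
    chung_kennedy_filter, copies_per_focus, kde_estimate, simulate_bleach_traces,
    unit_intensity_endpoint, unit_intensity_fourier,
)

COUNTS_PER_FLUOROPHORE = 200.0  # ground truth the estimators must recover

traces, _, _ = simulate_bleach_traces(
    np.full(200, 37), COUNTS_PER_FLUOROPHORE, bleach_rate=0.01, n_frames=1100,
    background_noise_sd=30.0, rng_seed=1,
)

unit = unit_intensity_endpoint(list(traces), tail_fraction=0.3)
print(f"I_unit (endpoint method): {unit.value:.1f} ± {unit.uncertainty:.1f} counts "
      f"(truth {COUNTS_PER_FLUOROPHORE:.0f})")

late = np.concatenate([t[200:400] for t in traces])
try:
    unit_f = unit_intensity_fourier(late[late > 100])
    print(f"I_unit (Fourier method):  {unit_f.value:.1f} counts — the two estimators "
          "should agree within ~15%")
except Exception as exc:
    print(f"Fourier estimator declined: {exc}")

copies = np.array([copies_per_focus(t, unit).copies for t in traces])
dist = kde_estimate(copies, kernel_width="standard")
print(f"copy-number distribution: peak {dist.peak:.1f} ± {dist.hwhm:.1f} (HWHM), "
      f"n = {dist.n}")
print("The peak is the modal stoichiometry of the population — here it should sit")
print("within a few percent of the true 37 copies per organelle.")

filt = chung_kennedy_filter(traces[0], window=10, exponent=4.0)
print(f"example trace: raw start {traces[0][:3].round(0)}, "
      f"filtered start {filt[:3].round(0)} (step-preserving filter)")
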