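# organelle-stoich

Absolute protein stoichiometry and mobility of single organelles from
fluorescence microscopy, built around the β-carboxysome — the CO₂-fixing
bacterial microcompartment of rod-shaped cyanobacteria — with each shell or
cargo protein tagged by YFP.

The package is for microscopists and quantitative biologists who need to
turn raw image stacks into numbers: *how many copies of a protein does one
organelle carry, how does that distribution shift between growth
conditions, and how mobile is the organelle in the cell?* It provides:

* **a ground-truth simulator** — 3D Gaussian PSF over a spherocylindrical
  cell model (cytosol + thylakoid background), per-fluorophore exponential
  photobleaching, Brownian organelle motion, Poisson camera noise — so every
  estimator can be validated against known truth;
* **photobleach step counting** — focus detection, iterative-Gaussian-mask
  sub-pixel localization, 5 px-radius ROI photometry with 17×17 px
  background correction, SNR > 0.4 gating, greedy tracking with
  overtracked tails, Chung–Kennedy edge-preserving filtering, and copy
  numbers `S = I(0) / I_unit`, where the single-fluorophore intensity
  `I_unit` comes from the end-of-bleach distribution cross-checked by the
  periodicity (Fourier) of the intensity distribution;
* **population analytics** — kernel-density peak ± HWHM, chlorophyll
  background-distribution subtraction, triple-Gaussian decomposition,
  a nearest-neighbor model for random focus overlap, subunit→functional-unit
  conversion (e.g. pentamers, L₈S₈ Rubisco), confocal-to-absolute
  calibration, Mann-Whitney condition comparison and randomized-grouping
  sampling errors;
* **diffusion analysis** — drift registration, tracking, time-averaged
  MSD(τ), apparent diffusion coefficient `D = slope/4` from the first six
  lags, and the anomalous exponent α.

See `docs/methods.md` for the model, estimators and their assumptions.

## Worked example

Counting copies in a simulated population of 37-copy organelles
(`examples/count_copies.py`):

```text
I_unit (endpoint method): 202.8 ± 39.7 counts (truth 200)
I_unit (Fourier method):  200.9 counts — the two estimators should agree within ~15%
copy-number distribution: peak 37.3 ± 0.7 (HWHM), n = 200
```

The endpoint estimator reads the brightness of one fluorophore from the
tail of the bleaching process; dividing each organelle's back-extrapolated
initial intensity by it recovers the true stoichiometry of 37 within a few
percent, and the peak ± HWHM line is the summary statistic used for whole
populations. Measuring mobility (`examples/measure_diffusion.py`):

```text
3 tracks recovered (3 organelles simulated); max residual drift 0.45 px
track 0: D = 0.81e-5 µm²/s, alpha = 0.89, 40 frames
track 1: D = 2.42e-5 µm²/s, alpha = 1.28, 40 frames
track 2: D = 1.15e-5 µm²/s, alpha = 0.99, 40 frames
```

against a simulated truth of D = 1.30×10⁻⁵ µm²/s — single 40-frame tracks
scatter widely; the ensemble mean over 100 replicate simulations recovers
the truth to within a few percent. The other examples cover
stack simulation, population decomposition with the overlap model, and
confocal calibration.

A thin command-line interface wraps the same library functions:

```sh
organelle-stoich simulate slimfield --config config.yaml --seed 1 --out run/
organelle-stoich slimfield --config config.yaml --stack run/slimfield.tif --out run/
organelle-stoich report --config config.yaml --per-focus run/per_focus.csv --out run/
```

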