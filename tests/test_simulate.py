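"""Simulator physics: photon bookkeeping, bleaching statistics, Brownian motion."""

import numpy as np
import pytest

from organelle_stoich import (
    CellGeometry,
    ConfigurationError,
    OpticalModel,
    OrganelleSpec,
    render_frame,
    simulate_bleach_traces,
    simulate_diffusion_stack,
    simulate_photobleach_stack,
)
from organelle_stoich.detection import measure_intensity
from organelle_stoich.simulate import default_shape

from conftest import make_organelles


class TestRenderFrame:
    def test_empty_scene_is_baseline(self, dark_cell, slimfield_optics):
        img = render_frame(dark_cell, [], slimfield_optics, noise=False)
        assert np.allclose(img, slimfield_optics.baseline)

    def test_photon_conservation(self, dark_cell):
        """With noise off, total counts above baseline equal gain x emitted photons."""
        opt = OpticalModel(counts_per_photon=2.0, baseline=50.0)
        org = [OrganelleSpec(copy_number=1, photons_per_fluorophore=1000.0)]
        img = render_frame(dark_cell, org, opt, noise=False)
        assert (img - opt.baseline).sum() / opt.counts_per_photon == pytest.approx(1000.0, rel=1e-3)

    def test_roi_counts_match_numeric_psf_integration(self, dark_cell, slimfield_optics):
        """Summed 5-px-ROI counts of a noiseless emitter equal the numerically
        integrated PSF mass inside the ROI (independent sub-grid oracle)."""
        photons = 1000.0
        org = [OrganelleSpec(copy_number=1, photons_per_fluorophore=photons)]
        shape = (31, 61)  # odd: emitter sits exactly on a pixel center
        img = render_frame(dark_cell, org, slimfield_optics, noise=False, shape=shape)
        cx, cy = (shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0
        m = measure_intensity(img - slimfield_optics.baseline, (cx, cy))

        # oracle: integrate the continuous 2D Gaussian over every pixel square of
        # the 17x17 window by sub-grid quadrature, then apply the same
        # inner-sum-minus-annulus-mean correction the photometry performs
        sigma_px = slimfield_optics.psf_sigma_lateral / slimfield_optics.pixel_size
        sub = (np.arange(30) + 0.5) / 30 - 0.5
        inner_mass, annulus_masses = 0.0, []
        for r in range(int(cy) - 8, int(cy) + 9):
            for c in range(int(cx) - 8, int(cx) + 9):
                xs = c + sub
                ys = r + sub
                gx = np.exp(-0.5 * ((xs - cx) / sigma_px) ** 2) / (sigma_px * np.sqrt(2 * np.pi))
                gy = np.exp(-0.5 * ((ys - cy) / sigma_px) ** 2) / (sigma_px * np.sqrt(2 * np.pi))
                mass = np.outer(gy, gx).sum() / 30**2
                if (r - cy) ** 2 + (c - cx) ** 2 <= 5.0**2:
                    inner_mass += mass
                else:
                    annulus_masses.append(mass)
        expected = (
            slimfield_optics.counts_per_photon
            * photons
            * (inner_mass - m.n_inner * np.mean(annulus_masses))
        )
        assert m.summed_intensity == pytest.approx(expected, rel=5e-3)

    def test_cell_scene_has_visible_foci(self, cell, slimfield_optics):
        """Three 200 nm organelles over cytosol+thylakoid background stand out."""
        orgs = make_organelles(copy_number=37, photons=1000.0, bleach_rate=0.0)
        img = render_frame(cell, orgs, slimfield_optics, rng=np.random.default_rng(0))
        shape = img.shape
        centers = [(int((x / 0.08) + (shape[1] - 1) / 2), (shape[0] - 1) // 2) for x in (-0.9, 0.0, 0.9)]
        bg_level = np.median(img)
        for cx, cy in centers:
            assert img[cy, cx] > bg_level + 10 * np.sqrt(bg_level)

    def test_invalid_optics_rejected(self):
        with pytest.raises(ConfigurationError):
            OpticalModel(pixel_size=-1.0)
        with pytest.raises(ConfigurationError):
            OpticalModel(counts_per_photon=0.0)

    def test_surviving_cannot_exceed_copy_number(self, dark_cell, slimfield_optics):
        org = [OrganelleSpec(copy_number=2, photons_per_fluorophore=10.0)]
        with pytest.raises(ConfigurationError):
            render_frame(dark_cell, org, slimfield_optics, surviving=[5], noise=False)


class TestPhotobleaching:
    def test_zero_rate_means_constant_survival(self, dark_cell, slimfield_optics):
        orgs = [OrganelleSpec(copy_number=20, photons_per_fluorophore=100.0, bleach_rate=0.0)]
        _, gt = simulate_photobleach_stack(dark_cell, orgs, slimfield_optics, 30, rng_seed=0)
        assert np.all(gt.surviving == 20)

    def test_exponential_survival_law(self):
        """Mean surviving fraction follows exp(-rate * t) within 3 binomial sd."""
        rate = 0.02
        n = 1000
        traces, surv, _ = simulate_bleach_traces([n], 1.0, rate, 200, rng_seed=3, shot_noise=False)
        for t in (25, 50, 100, 150):
            p = np.exp(-rate * t)
            sd = np.sqrt(n * p * (1 - p))
            assert abs(surv[0, t] - n * p) < 3 * sd

    def test_survival_monotone_nonincreasing(self, dark_cell, slimfield_optics):
        orgs = make_organelles(copy_number=50, bleach_rate=0.05, n=2)
        _, gt = simulate_photobleach_stack(dark_cell, orgs, slimfield_optics, 100, rng_seed=1)
        assert np.all(np.diff(gt.surviving, axis=0) <= 0)

    def test_fully_bleached_endpoint_indistinguishable_from_background(
        self, dark_cell, slimfield_optics
    ):
        """After >99% bleaching the final-frame ROI holds only noise."""
        orgs = [OrganelleSpec(copy_number=37, photons_per_fluorophore=1000.0, bleach_rate=0.05)]
        stack, gt = simulate_photobleach_stack(dark_cell, orgs, slimfield_optics, 300, rng_seed=2)
        assert gt.surviving[-1, 0] == 0
        shape = stack.frames[0].shape
        center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
        m = measure_intensity(stack.frames[-1], center)
        # summed noise sd over ~81 px of Poisson(baseline=100): ~9 * 10 counts
        assert abs(m.summed_intensity) < 3 * 9 * np.sqrt(slimfield_optics.baseline)

    def test_identical_seed_reproduces_stack(self, cell, slimfield_optics):
        orgs = make_organelles(copy_number=10, bleach_rate=0.02)
        s1, _ = simulate_photobleach_stack(cell, orgs, slimfield_optics, 20, rng_seed=42)
        s2, _ = simulate_photobleach_stack(cell, orgs, slimfield_optics, 20, rng_seed=42)
        assert np.array_equal(s1.frames, s2.frames)

    def test_zero_frames_rejected(self, dark_cell, slimfield_optics):
        with pytest.raises(ConfigurationError):
            simulate_photobleach_stack(dark_cell, [], slimfield_optics, 0)


class TestDiffusion:
    def test_frozen_organelle_has_constant_centroids(self, dark_cell, slimfield_optics):
        orgs = make_organelles(diffusion=0.0, bleach_rate=0.0, n=1)
        _, gt = simulate_diffusion_stack(dark_cell, orgs, slimfield_optics, 15, 60.0, rng_seed=0)
        assert np.allclose(gt.centroids, gt.centroids[0])

    def test_brownian_step_variance(self):
        """Unbounded per-frame squared steps average 6*D*dt in 3D within 3 MC sd."""
        D, dt = 1.3e-5, 60.0
        geo = CellGeometry(length=3.0, radius=0.5)
        opt = OpticalModel(pixel_size=41.5)
        orgs = [OrganelleSpec(copy_number=0, diffusion_coefficient=D)] * 10
        _, gt = simulate_diffusion_stack(
            geo, orgs, opt, n_frames=1001, frame_interval=dt, rng_seed=7,
            noise=False, bounded=False, shape=(4, 4),
        )
        steps = np.diff(gt.centroids, axis=0)            # (1000, 10, 3)
        sq_xy = (steps[..., :2] ** 2).sum(-1).ravel()    # 2D projected steps
        expected = 4 * D * dt
        se = sq_xy.std(ddof=1) / np.sqrt(sq_xy.size)
        assert abs(sq_xy.mean() - expected) < 3 * se

    def test_validation_scene_yields_three_full_tracks(self, cell):
        """3 organelles of 200 nm over 40 frames: stack plus 3 tracks of length 40."""
        opt = OpticalModel(pixel_size=41.5)
        orgs = make_organelles(copy_number=1, photons=5000.0, bleach_rate=0.0,
                               diffusion=1.3e-5)
        stack, gt = simulate_diffusion_stack(cell, orgs, opt, 40, 60.0, rng_seed=11)
        assert stack.frames.shape[0] == 40
        assert gt.centroids.shape == (40, 3, 3)
        assert np.all(cell.contains(gt.centroids.reshape(-1, 3)))

    def test_initial_position_outside_cell_rejected(self, dark_cell, slimfield_optics):
        orgs = [OrganelleSpec(position=(5.0, 0.0, 0.0), diffusion_coefficient=1e-5)]
        with pytest.raises(ConfigurationError):
            simulate_diffusion_stack(dark_cell, orgs, slimfield_optics, 5, 60.0, rng_seed=0)

    def test_reflection_keeps_organelles_inside(self, dark_cell, slimfield_optics):
        orgs = [OrganelleSpec(position=(1.0, 0.3, 0.0), diffusion_coefficient=5e-4)]
        _, gt = simulate_diffusion_stack(dark_cell, orgs, slimfield_optics, 200, 60.0,
                                         rng_seed=3, noise=False, shape=(4, 4))
        assert np.all(dark_cell.contains(gt.centroids.reshape(-1, 3)))
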