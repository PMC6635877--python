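import numpy as np
import pytest

from organelle_stoich import (
    CellGeometry,
    OpticalModel,
    OrganelleSpec,
    analyze_stack,
    simulate_photobleach_stack,
)


@pytest.fixture(scope="session")
def slimfield_optics():
    return OpticalModel(pixel_size=80.0, counts_per_photon=1.0, baseline=100.0, exposure=5.0)


@pytest.fixture(scope="session")
def cell():
    return CellGeometry(
        length=3.0, radius=0.5, thylakoid_thickness=0.15,
        thylakoid_photon_density=2e3, cytosol_photon_density=5e2,
    )


@pytest.fixture(scope="session")
def dark_cell():
    """Cell geometry without any background emission."""
    return CellGeometry(length=3.0, radius=0.5, thylakoid_thickness=0.15)


def make_organelles(copy_number=37, photons=1000.0, bleach_rate=0.01, n=3, diffusion=0.0):
    xs = np.linspace(-0.9, 0.9, n) if n > 1 else [0.0]
    return [
        OrganelleSpec(position=(float(x), 0.0, 0.0), diameter=200.0, copy_number=copy_number,
                      photons_per_fluorophore=photons, bleach_rate=bleach_rate,
                      diffusion_coefficient=diffusion)
        for x in xs
    ]


@pytest.fixture(scope="session")
def bleach_stack(cell, slimfield_optics):
    """A photobleach stack of three 37-copy organelles, fully bleaching."""
    organelles = make_organelles()
    stack, gt = simulate_photobleach_stack(cell, organelles, slimfield_optics,
                                           n_frames=700, rng_seed=5)
    return stack, gt, organelles


@pytest.fixture(scope="session")
def bleach_tracks(bleach_stack):
    stack, gt, organelles = bleach_stack
    tracks = analyze_stack(stack.frames, n_tail=100, max_displacement=2.0)
    return [t for t in tracks if len(t) > 50]
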