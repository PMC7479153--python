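import numpy as np
import pytest

from fluctra import ParticleSpecies, PSFModel, ScanProtocol, SimulationBox


@pytest.fixture(scope="session")
def psf() -> PSFModel:
    """Calibration-grade confocal volume: 0.25 um radial waist, S = 0.2."""
    return PSFModel(omega_r=0.25, structural_factor=0.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scan() -> ScanProtocol:
    """64 x 64 pixel, 40-frame scan for fast unit-level renders."""
    return ScanProtocol(shape=(64, 64), n_frames=40)


def make_box(psf: PSFModel, duration: float, timestep: float, seed: int = 0,
             lateral: float | None = None) -> SimulationBox:
    lat = lateral if lateral is not None else 12.0 * psf.omega_r
    return SimulationBox(
        box_dimensions=(lat, lat, 10.0 * psf.omega_z),
        timestep=timestep,
        duration=duration,
        rng_seed=seed,
    )


def monomer(d: float, eps: float = 0.5, density: float = 1.0) -> ParticleSpecies:
    return ParticleSpecies(
        diffusion_coefficient=d,
        brightness_per_subunit=eps,
        subunit_count=1,
        number_density=density,
    )
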