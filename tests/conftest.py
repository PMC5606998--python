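import numpy as np
import pytest

from ototrap import optics, synthetic


@pytest.fixture(scope="session")
def beam():
    return optics.TrapBeam(power_mw=500.0)


@pytest.fixture(scope="session")
def sphere():
    return optics.SphereParticle()


@pytest.fixture(scope="session")
def default_scan():
    """One synthetic deflection scan with its ground truth (fixed seed)."""
    cfg = synthetic.ScanGeneratorConfig(seed=7)
    scan, truth = synthetic.generate_scan(cfg)
    return cfg, scan, truth


@pytest.fixture(scope="session")
def clean_radial_scan():
    """Noise-free single-amplitude scan: an exactly radial field."""
    cfg = synthetic.ScanGeneratorConfig(
        seed=0,
        noise_sd_pn=0.0,
        sector_edges_deg=(0.0,),
        sector_amplitudes_pn=(4.0,),
        grid_step_um=2.0,
    )
    scan, truth = synthetic.generate_scan(cfg)
    return cfg, scan, truth


def grid_positions(half_um: float, step_um: float) -> np.ndarray:
    coords = np.arange(-half_um, half_um + 1e-9, step_um)
    xx, yy = np.meshgrid(coords, coords)
    return np.column_stack([xx.ravel(), yy.ravel()])
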