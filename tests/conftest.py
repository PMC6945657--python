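import numpy as np
import pytest

from linactune import (
    BeamConfig,
    PhantomSpec,
    ScanCurve,
    generate_dose_grid,
    generate_reference_scans,
)


@pytest.fixture(scope="session")
def phantom():
    return PhantomSpec()


@pytest.fixture(scope="session")
def beam_6mv():
    return BeamConfig(energy=6.26)


@pytest.fixture(scope="session")
def noiseless_grid(beam_6mv, phantom):
    """Zero-noise grid: sampled dose equals the analytic model exactly."""
    from linactune.simulate import ModelConstants

    return generate_dose_grid(
        beam_6mv, phantom, n_histories=1_000_000, seed=0,
        constants=ModelConstants(kappa=0.0),
    )


@pytest.fixture(scope="session")
def golden_6mv(phantom):
    """Golden reference scans at a 6 MV-like truth configuration."""
    truth = BeamConfig(6.26, energy_fwhm=0.15, focal_spot_fwhm=0.10, divergence=0.0)
    return generate_reference_scans(truth, phantom, nominal_label="6MV-like")


def make_curve(values, kind="pdd", spacing=0.2, start=0.1, depth=None):
    """Small helper: a ScanCurve from raw values on a uniform grid."""
    values = np.asarray(values, dtype=float)
    positions = start + spacing * np.arange(values.size)
    if kind == "pdd":
        return ScanCurve.pdd(positions, values, spacing)
    return ScanCurve.lateral(positions, values, depth=depth or 10.0, spacing=spacing)
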