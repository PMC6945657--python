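"""Synthetic linac dose simulator.

Generates Monte-Carlo-like 3D dose grids and noiseless "golden" reference
scans from a small analytic beam model.  The model is a deliberately simple
stand-in for a full radiation-transport calculation: what matters for the
tuning procedure is that

* the depth-dose shape responds monotonically to the initial electron
  energy (and weakly to the energy spread),
* the lateral profile's penumbra widens with the focal-spot FWHM and its
  in-field flatness (horns) responds to divergence and energy spread, and
* per-voxel statistical noise shrinks as 1/sqrt(histories).

Depth dose follows a build-up/attenuation form ``A (1 - exp(-beta z))
exp(-mu z)``; lateral profiles are a flat-top convolved with a Gaussian
penumbra (error-function shoulders) carrying a quadratic horn term.
All model constants live in :class:`ModelConstants` and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import erf

from .beam import BeamConfig, PhantomSpec
from .curves import ScanCurve

__all__ = [
    "ModelConstants",
    "DoseGrid",
    "ReferenceScans",
    "pdd_model",
    "profile_model",
    "generate_dose_grid",
    "generate_dose_grid_ladder",
    "average_uncertainty",
    "generate_reference_scans",
]


@dataclass(frozen=True)
class ModelConstants:
    """Constants of the analytic dose model and of the noise law.

    Attenuation: mu(E) = mu0 / E * (1 + mu_efwhm * energy_fwhm / E)  [1/cm]
    Build-up:    beta(E) = beta0 / E                                  [1/cm]
    Penumbra:    sigma = sigma0 + sigma_focal * focal_spot_fwhm * M(z)
                         + sigma_depth * z                            [cm]
    Horns:       h = horn0 + horn_div * divergence
                     - horn_efwhm * energy_fwhm                       [rel.]
    Noise:       u_v = kappa / sqrt((N/1e6) * max(D/Dmax, unc_floor)) [%]

    where M(z) = (ssd + z)/ssd is the divergent magnification.  The horn
    sensitivities are deliberately exaggerated relative to a clinical linac
    so that one candidate-grid step changes the profile by more than the
    stage-level statistical noise; see the methods note.
    """

    mu0: float = 0.28
    mu_efwhm: float = 0.05
    beta0: float = 13.6
    amplitude: float = 1.0
    sigma0: float = 0.15
    sigma_focal: float = 1.0
    sigma_depth: float = 0.02
    horn0: float = 0.01
    horn_div: float = 0.08
    horn_efwhm: float = 2.0
    kappa: float = 8.0
    unc_floor: float = 0.01
    unc_threshold: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class DoseGrid:
    """Binned 3D dose with per-voxel relative 1-sigma uncertainty.

    ``dose`` is indexed (ix, iy, iz) in arbitrary units; ``rel_uncertainty``
    is the relative 1-sigma statistical uncertainty in percent of the local
    dose.  Both arrays share the phantom's bin layout.
    """

    dose: np.ndarray
    rel_uncertainty: np.ndarray
    phantom: PhantomSpec
    n_histories: int
    seed: int
    expected_dose: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dose.shape != self.rel_uncertainty.shape:
            raise ValueError("dose and rel_uncertainty shapes differ")
        if self.expected_dose is not None and self.expected_dose.shape != self.dose.shape:
            raise ValueError("expected_dose shape differs from dose")
        if self.dose.shape != self.phantom.shape:
            raise ValueError(
                f"grid shape {self.dose.shape} inconsistent with phantom "
                f"{self.phantom.shape}"
            )
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")
        if np.any(self.rel_uncertainty < 0):
            raise ValueError("rel_uncertainty must be non-negative")


@dataclass(frozen=True)
class ReferenceScans:
    """A golden set of noiseless reference scans.

    One PDD plus one lateral profile per scan depth, with the hidden
    generating beam parameters retained for recovery experiments.
    """

    pdd: ScanCurve
    profiles: tuple  # of (depth_cm, ScanCurve)
    nominal_label: str
    true_config: BeamConfig

    def __post_init__(self) -> None:
        depths = [d for d, _ in self.profiles]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("profile depths must be strictly increasing")

    @property
    def depths(self) -> list:
        return [d for d, _ in self.profiles]

    def profile_at(self, depth: float) -> ScanCurve:
        for d, curve in self.profiles:
            if d == depth:
                return curve
        raise KeyError(f"no reference profile at depth {depth} cm")


def _mu(config: BeamConfig, c: ModelConstants) -> float:
    return c.mu0 / config.energy * (1.0 + c.mu_efwhm * config.energy_fwhm / config.energy)


def _beta(config: BeamConfig, c: ModelConstants) -> float:
    return c.beta0 / config.energy


def pdd_model(depth, config: BeamConfig, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Relative central-axis dose at ``depth`` cm (unnormalized).

    Build-up times exponential attenuation; the depth of maximum dose is
    ln(1 + beta/mu)/beta and increases with beam energy.
    """
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be >= 0")
    mu = _mu(config, constants)
    beta = _beta(config, constants)
    out = constants.amplitude * (1.0 - np.exp(-beta * z)) * np.exp(-mu * z)
    return out if out.ndim else float(out)


def depth_of_maximum(config: BeamConfig, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Closed-form depth of the PDD maximum, ln(1 + beta/mu)/beta in cm."""
    mu = _mu(config, constants)
    beta = _beta(config, constants)
    return math.log(1.0 + beta / mu) / beta


def _sigma(depth, config: BeamConfig, phantom: PhantomSpec, c: ModelConstants):
    mag = (phantom.ssd + depth) / phantom.ssd
    return c.sigma0 + c.sigma_focal * config.focal_spot_fwhm * mag + c.sigma_depth * depth


def _horn(config: BeamConfig, c: ModelConstants) -> float:
    return c.horn0 + c.horn_div * config.divergence - c.horn_efwhm * config.energy_fwhm


def profile_model(
    x,
    depth,
    config: BeamConfig,
    phantom: PhantomSpec,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    field_width: float | None = None,
):
    """Relative lateral dose at off-axis position ``x`` cm and ``depth`` cm.

    A flat top with error-function penumbrae at the divergently projected
    field edges, modulated in-field by a quadratic horn/dip term.  Pass
    ``field_width`` to use the y-axis collimator setting instead of x.
    """
    xv = np.asarray(x, dtype=float)
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be >= 0")
    w0 = phantom.field_x if field_width is None else field_width
    w = w0 * (phantom.ssd + z) / phantom.ssd
    sigma = _sigma(z, config, phantom, constants)
    half = w / 2.0
    ax = np.abs(xv)
    envelope = 0.5 * (
        erf((half - ax) / (math.sqrt(2.0) * sigma))
        + erf((half + ax) / (math.sqrt(2.0) * sigma))
    )
    h = _horn(config, constants)
    horn = np.where(ax < half, h * (2.0 * xv / w) ** 2, 0.0)
    out = envelope * (1.0 + horn)
    return out if out.ndim else float(out)


def _noiseless_grid(config: BeamConfig, phantom: PhantomSpec, c: ModelConstants) -> np.ndarray:
    """Separable noiseless dose: pdd(z) * profile_x(x, z) * profile_y(y, z)."""
    xs = phantom.centers("x")
    ys = phantom.centers("y")
    zs = phantom.centers("z")
    pdd = pdd_model(zs, config, c)  # (nz,)
    px = profile_model(xs[:, None], zs[None, :], config, phantom, c)  # (nx, nz)
    py = profile_model(
        ys[:, None], zs[None, :], config, phantom, c, field_width=phantom.field_y
    )  # (ny, nz)
    return pdd[None, None, :] * px[:, None, :] * py[None, :, :]


def generate_dose_grid(
    config: BeamConfig,
    phantom: PhantomSpec = PhantomSpec(),
    n_histories: int = 25_000_000,
    seed: int = 0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> DoseGrid:
    """Simulate a noisy dose grid at ``n_histories`` primary histories.

    Each voxel receives independent Gaussian noise with relative 1-sigma
    ``u_v = kappa / sqrt((N/1e6) * max(D_v/D_max, floor))`` percent, the
    canonical 1/sqrt(N) Monte-Carlo scaling with a low-dose floor.  Sampled
    doses are clipped at zero (a scored dose cannot be negative).
    Deterministic for a fixed seed.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    noiseless = _noiseless_grid(config, phantom, constants)
    dmax = noiseless.max()
    if dmax <= 0:
        raise ValueError("degenerate configuration: zero dose everywhere")
    rel = np.maximum(noiseless / dmax, constants.unc_floor)
    u = constants.kappa / np.sqrt((n_histories / 1e6) * rel)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(noiseless.shape)
    sampled = np.clip(noiseless * (1.0 + (u / 100.0) * eps), 0.0, None)
    return DoseGrid(
        dose=sampled,
        rel_uncertainty=u,
        phantom=phantom,
        n_histories=int(n_histories),
        seed=int(seed),
        expected_dose=noiseless,
    )


def generate_dose_grid_ladder(
    config: BeamConfig,
    phantom: PhantomSpec,
    history_ladder,
    seed: int,
    constants: ModelConstants = DEFAULT_CONSTANTS,
):
    """Yield grids along an increasing history ladder from ONE accumulating run.

    Emulates resuming a Monte-Carlo simulation: the noise fields of
    successive rungs are nested sums of independent increments, so the
    rung-N1 and rung-N2 noises correlate as sqrt(N1/N2) while each rung's
    marginal distribution matches :func:`generate_dose_grid` exactly
    (standard-normal per-voxel deviate scaled by the 1/sqrt(N) law).
    """
    ladder = [int(n) for n in history_ladder]
    if not ladder or ladder[0] < 1:
        raise ValueError("history ladder must start at >= 1 history")
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("history ladder must be strictly increasing")
    noiseless = _noiseless_grid(config, phantom, constants)
    dmax = noiseless.max()
    if dmax <= 0:
        raise ValueError("degenerate configuration: zero dose everywhere")
    rel = np.maximum(noiseless / dmax, constants.unc_floor)
    rng = np.random.default_rng(seed)
    total = np.zeros_like(noiseless)
    n_prev = 0
    for n in ladder:
        total = total + math.sqrt(n - n_prev) * rng.standard_normal(noiseless.shape)
        n_prev = n
        eps = total / math.sqrt(n)
        u = constants.kappa / np.sqrt((n / 1e6) * rel)
        sampled = np.clip(noiseless * (1.0 + (u / 100.0) * eps), 0.0, None)
        yield DoseGrid(
            dose=sampled,
            rel_uncertainty=u,
            phantom=phantom,
            n_histories=n,
            seed=int(seed),
            expected_dose=noiseless,
        )


def average_uncertainty(grid: DoseGrid, threshold: float | None = None) -> float:
    """Mean relative 1-sigma uncertainty (%) over high-dose voxels.

    Averages ``rel_uncertainty`` over voxels whose dose exceeds
    ``threshold`` (default: the model constant, 50%) of the grid maximum —
    a common convention for reporting the statistical quality of an MC dose
    calculation.  When the grid carries its expected (noiseless) dose the
    voxel selection uses it, so the reported average is a deterministic
    function of the noise law rather than of one noise realization; a grid
    without it falls back to the sampled dose.
    """
    if threshold is None:
        threshold = DEFAULT_CONSTANTS.unc_threshold
    base = grid.expected_dose if grid.expected_dose is not None else grid.dose
    dmax = base.max()
    mask = base > threshold * dmax
    if dmax <= 0 or not mask.any():
        raise ValueError("degenerate grid: no voxel above the dose threshold")
    return float(grid.rel_uncertainty[mask].mean())


def generate_reference_scans(
    true_config: BeamConfig,
    phantom: PhantomSpec = PhantomSpec(),
    scan_depths=(1.6, 5.0, 10.0, 20.0, 30.0),
    constants: ModelConstants = DEFAULT_CONSTANTS,
    nominal_label: str = "",
) -> ReferenceScans:
    """Noiseless golden scans sampled on the phantom's bin centers.

    The PDD is the central-axis dose (including the negligible off-axis
    envelope factors, so that a zero-noise simulated grid reproduces it
    exactly); profiles are generated at the bin center nearest each
    requested scan depth, keeping the requested depth as the label.
    Curves are normalized per the scan conventions (PDD max = 100, lateral
    central axis = 100).
    """
    depths = list(scan_depths)
    if not depths:
        raise ValueError("scan_depths must be nonempty")
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("scan_depths must be strictly increasing")
    if depths[-1] > phantom.size_z:
        raise ValueError("scan depth outside phantom")

    from .curves import nearest_bin_center

    zs = phantom.centers("z")
    xs = phantom.centers("x")
    x0 = 0.0
    cax = (
        pdd_model(zs, true_config, constants)
        * profile_model(x0, zs, true_config, phantom, constants)
        * profile_model(x0, zs, true_config, phantom, constants, field_width=phantom.field_y)
    )
    pdd = ScanCurve.pdd(zs, cax, spacing=phantom.bin).normalized()

    profiles = []
    for d in depths:
        zc = nearest_bin_center(d, phantom.bin, phantom.size_z)
        vals = profile_model(xs, zc, true_config, phantom, constants)
        curve = ScanCurve.lateral(xs, vals, depth=d, spacing=phantom.bin).normalized()
        profiles.append((d, curve))

    return ReferenceScans(
        pdd=pdd,
        profiles=tuple(profiles),
        nominal_label=nominal_label,
        true_config=true_config,
    )
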