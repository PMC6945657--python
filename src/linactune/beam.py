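"""Beam and phantom descriptions.

The initial electron beam striking the linac target is summarized by four
tunable parameters: its mean kinetic energy, the FWHM of the primary energy
distribution, the FWHM of the focal spot, and the angular divergence.  Dose
is scored in a rectangular water phantom of uniform cubic bins at a fixed
source-to-surface distance (SSD).
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class BeamConfig:
    """The four tunable parameters of the initial electron beam.

    Parameters
    ----------
    energy : float
        Mean initial electron energy E0 in MeV.  Must be positive.
    energy_fwhm : float
        FWHM of the primary energy distribution in MeV (>= 0).
    focal_spot_fwhm : float
        FWHM of the focal spot in cm (>= 0).
    divergence : float
        Beam divergence in degrees, in [0, 90).
    """

    energy: float
    energy_fwhm: float = 0.0
    focal_spot_fwhm: float = 0.0
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not self.energy > 0:
            raise ValueError(f"energy must be positive, got {self.energy}")
        if self.energy_fwhm < 0:
            raise ValueError(f"energy_fwhm must be >= 0, got {self.energy_fwhm}")
        if self.focal_spot_fwhm < 0:
            raise ValueError(
                f"focal_spot_fwhm must be >= 0, got {self.focal_spot_fwhm}"
            )
        if not 0 <= self.divergence < 90:
            raise ValueError(
                f"divergence must be in [0, 90) degrees, got {self.divergence}"
            )

    def with_(self, **kwargs) -> "BeamConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PhantomSpec:
    """Binned water phantom and field geometry.

    Defaults reproduce the commissioning setup: a 16.2 x 16.2 x 31.0 cm^3
    water phantom with 0.2 cm cubic bins at SSD 100 cm and a single
    10 x 10 cm^2 field.  Lateral coordinates (x, y) are centered on the beam
    axis; z is depth below the phantom surface.  All lengths are in cm.
    """

    size_x: float = 16.2
    size_y: float = 16.2
    size_z: float = 31.0
    bin: float = 0.2
    ssd: float = 100.0
    field_x: float = 10.0
    field_y: float = 10.0

    def __post_init__(self) -> None:
        for name in ("size_x", "size_y", "size_z", "bin", "ssd", "field_x", "field_y"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("size_x", "size_y", "size_z"):
            size = getattr(self, name)
            n = size / self.bin
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{name}={size} is not an integer multiple of bin={self.bin}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Number of bins (nx, ny, nz)."""
        return (
            int(round(self.size_x / self.bin)),
            int(round(self.size_y / self.bin)),
            int(round(self.size_z / self.bin)),
        )

    def centers(self, axis: str):
        """Bin-center coordinates along ``axis`` ('x', 'y' or 'z').

        Lateral axes are centered on the beam axis; depth runs from the
        surface downward, with centers at (i + 1/2) * bin.
        """
        import numpy as np

        nx, ny, nz = self.shape
        if axis == "z":
            return (np.arange(nz) + 0.5) * self.bin
        n = nx if axis == "x" else ny
        size = self.size_x if axis == "x" else self.size_y
        return (np.arange(n) + 0.5) * self.bin - size / 2.0
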