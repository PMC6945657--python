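"""1D scan curves: extraction from dose grids, normalization, resampling.

A :class:`ScanCurve` is what a water-tank scanning system produces: dose
versus position on a uniform grid, either a percent-depth-dose (PDD) along
the beam axis or a lateral profile at a fixed depth.  PDDs are normalized
to 100 at their maximum, lateral profiles to 100 on the central axis; the
same convention is applied to both members of any gamma comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ScanCurve",
    "nearest_bin_center",
    "extract_pdd",
    "extract_profile",
    "resample_curve",
]

PDD_MAX_100 = "pdd_max_100"
CAX_100 = "cax_100"


def nearest_bin_center(depth: float, bin_size: float, size_z: float) -> float:
    """Depth of the bin center nearest ``depth``; ties resolve toward the surface.

    Bin centers sit at (i + 1/2) * bin.  E.g. with 0.2 cm bins a requested
    depth of 1.6 cm (a bin edge) maps to the center at 1.5 cm.
    """
    if not 0 <= depth <= size_z:
        raise ValueError(f"depth {depth} outside phantom [0, {size_z}]")
    d = depth / bin_size - 0.5
    i = int(np.floor(d)) if (d - np.floor(d)) <= 0.5 else int(np.ceil(d))
    nz = int(round(size_z / bin_size))
    i = min(max(i, 0), nz - 1)
    return (i + 0.5) * bin_size


@dataclass(frozen=True)
class ScanCurve:
    """A 1D dose curve on a uniform position grid.

    ``kind`` is 'pdd' or 'lateral'; ``depth`` (cm) applies to lateral
    profiles only.  ``values`` are percent dose once normalized.
    """

    kind: str
    positions: np.ndarray
    values: np.ndarray
    spacing: float
    normalization: str
    depth: Optional[float] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)
        if self.kind not in ("pdd", "lateral"):
            raise ValueError(f"kind must be 'pdd' or 'lateral', got {self.kind!r}")
        if pos.ndim != 1 or pos.shape != val.shape or pos.size < 2:
            raise ValueError("positions and values must be equal-length 1D, size >= 2")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(np.abs(steps - self.spacing) > 1e-9):
            raise ValueError("positions must have constant spacing")
        if np.any(val < 0):
            raise ValueError("dose values must be non-negative")
        if np.any(~np.isfinite(val)):
            raise ValueError("dose values must be finite")

    # -- construction -----------------------------------------------------

    @classmethod
    def pdd(cls, positions, values, spacing: float) -> "ScanCurve":
        return cls("pdd", np.asarray(positions, float), np.asarray(values, float),
                   spacing, PDD_MAX_100)

    @classmethod
    def lateral(cls, positions, values, depth: float, spacing: float) -> "ScanCurve":
        return cls("lateral", np.asarray(positions, float), np.asarray(values, float),
                   spacing, CAX_100, depth=depth)

    # -- normalization ----------------------------------------------------

    def _reference_value(self) -> float:
        if self.kind == "pdd":
            ref = float(self.values.max())
        else:
            ref = float(self._cax_value())
        if ref <= 0:
            raise ValueError("degenerate curve: normalization value is zero")
        return ref

    def _cax_value(self) -> float:
        """Value at position 0 (central axis): nearest sample, averaging an
        exact tie between the two straddling samples."""
        idx = np.argsort(np.abs(self.positions))
        i0 = idx[0]
        if len(idx) > 1 and abs(abs(self.positions[idx[1]]) - abs(self.positions[i0])) < 1e-12:
            return 0.5 * (self.values[i0] + self.values[idx[1]])
        return self.values[i0]

    def normalized(self) -> "ScanCurve":
        """Scale so the PDD maximum (or lateral CAX value) equals 100."""
        return replace(self, values=self.values * (100.0 / self._reference_value()))

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return abs(self._reference_value() - 100.0) <= tol

    def max(self) -> float:
        return float(self.values.max())


def _central_indices(n: int) -> tuple[int, ...]:
    """Central bin index (odd n) or the two central indices (even n)."""
    return (n // 2,) if n % 2 else (n // 2 - 1, n // 2)


def extract_pdd(grid) -> ScanCurve:
    """Central-axis depth-dose curve from a dose grid, normalized to 100.

    An even lateral bin count averages the two central columns.
    """
    nx, ny, nz = grid.dose.shape
    ix = _central_indices(nx)
    iy = _central_indices(ny)
    axis = grid.dose[np.ix_(ix, iy, range(nz))].mean(axis=(0, 1))
    if axis.max() <= 0:
        raise ValueError("degenerate grid: all-zero central axis")
    zs = grid.phantom.centers("z")
    return ScanCurve.pdd(zs, axis, spacing=grid.phantom.bin).normalized()


def extract_profile(grid, depth: float) -> ScanCurve:
    """Lateral x-profile at ``depth`` cm, normalized to 100 on the central axis.

    The nearest z bin center is used (ties toward the surface); the profile
    is taken at the central y column(s).
    """
    p = grid.phantom
    zc = nearest_bin_center(depth, p.bin, p.size_z)
    iz = int(round(zc / p.bin - 0.5))
    nx, ny, _ = grid.dose.shape
    iy = _central_indices(ny)
    prof = grid.dose[:, iy, iz].mean(axis=1) if len(iy) > 1 else grid.dose[:, iy[0], iz]
    xs = p.centers("x")
    return ScanCurve.lateral(xs, prof, depth=depth, spacing=p.bin).normalized()


def resample_curve(curve: ScanCurve, factor: int = 5) -> ScanCurve:
    """Linearly interpolate onto a grid ``factor`` times finer.

    Endpoints are preserved; ``factor=1`` returns the curve unchanged.
    This is the curve-wise specialization of the one-fifth-bin grid
    refinement used by the gamma engine (the 3D engine interpolates
    tri-linearly).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    factor = int(factor)
    if factor == 1:
        return curve
    n = curve.positions.size
    new_pos = curve.positions[0] + np.arange((n - 1) * factor + 1) * (curve.spacing / factor)
    new_pos[-1] = curve.positions[-1]
    new_val = np.interp(new_pos, curve.positions, curve.values)
    return replace(curve, positions=new_pos, values=new_val, spacing=curve.spacing / factor)
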