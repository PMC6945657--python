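"""Gamma-index comparison of dose distributions.

For each reference ("measured") point p with dose d_e(p), the gamma index
against an evaluated ("simulated") distribution is

    Gamma(p) = min_i sqrt( (dd_i / dD)^2 + (ds_i / dS)^2 )

where dd_i is the dose difference and ds_i the distance between p and the
i-th evaluated candidate point, and (dD, dS) are the dose-difference and
distance-to-agreement acceptance criteria.  A point passes when
Gamma <= 1 (exactly; a 1e-9 guard absorbs floating-point rounding on
boundary cases, not criterion slack).  Candidates are the evaluated
samples within min(5 dS, 1.5 cm) of p after refining the evaluated
distribution to one-fifth of its native bin by (tri-)linear interpolation.  dD is taken as a percentage of the
global maximum of the reference distribution (a configurable local mode
normalizes to the local reference dose instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curves import ScanCurve, resample_curve

# absorbs floating-point rounding on exact-boundary gamma values
_PASS_EPS = 1e-9

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "CRITERIA_3_3",
    "CRITERIA_2_2",
    "CRITERIA_1_1",
    "gamma_point",
    "gamma_curve",
    "gamma_grid",
    "multi_criteria_report",
    "MultiCriteriaReport",
]


@dataclass(frozen=True)
class GammaCriteria:
    """A (dose %, DTA mm) acceptance pair plus search conventions."""

    dose_pct: float
    dta_mm: float
    search_cap_cm: float = 1.5
    resample_factor: int = 5
    local: bool = False

    def __post_init__(self) -> None:
        if self.dose_pct <= 0 or self.dta_mm <= 0 or self.search_cap_cm <= 0:
            raise ValueError("dose_pct, dta_mm and search_cap_cm must be positive")
        if self.resample_factor < 1:
            raise ValueError("resample_factor must be >= 1")

    @property
    def window_cm(self) -> float:
        """Half-width of the candidate search window: min(5 dS, cap)."""
        return min(5.0 * self.dta_mm / 10.0, self.search_cap_cm)

    def label(self) -> str:
        return f"{self.dose_pct:g}%/{self.dta_mm:g}mm"


CRITERIA_3_3 = GammaCriteria(3.0, 3.0)
CRITERIA_2_2 = GammaCriteria(2.0, 2.0)
CRITERIA_1_1 = GammaCriteria(1.0, 1.0)


@dataclass(frozen=True)
class GammaResult:
    """Per-point gamma values and the derived passing rate.

    Reference points whose search window contains no evaluated sample are
    excluded from the denominator and tallied in ``n_uncovered``.
    """

    gamma_values: np.ndarray
    criteria: GammaCriteria
    n_points: int
    n_pass: int
    n_uncovered: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_pass <= self.n_points:
            raise ValueError("n_pass out of range")

    @property
    def passing_rate(self) -> float:
        """Percentage of covered reference points with Gamma <= 1."""
        return 100.0 * self.n_pass / self.n_points

    def to_dict(self, include_gamma: bool = False) -> dict:
        out = {
            "criteria": {
                "dose_pct": self.criteria.dose_pct,
                "dta_mm": self.criteria.dta_mm,
                "search_cap_cm": self.criteria.search_cap_cm,
                "resample_factor": self.criteria.resample_factor,
                "local": self.criteria.local,
            },
            "n_points": self.n_points,
            "n_pass": self.n_pass,
            "n_uncovered": self.n_uncovered,
            "passing_rate": self.passing_rate,
        }
        if include_gamma:
            out["gamma_values"] = [float(g) for g in self.gamma_values]
        return out


def gamma_point(
    ref_position: float,
    ref_dose: float,
    evaluated: ScanCurve,
    criteria: GammaCriteria,
    ref_max: float = 100.0,
) -> float | None:
    """Gamma index of a single reference point against a resampled curve.

    ``evaluated`` must already be resampled to the criteria's refinement.
    Returns None when no evaluated sample falls inside the search window
    (the caller excludes such points from the passing-rate denominator).
    """
    pos = evaluated.positions
    lo = np.searchsorted(pos, ref_position - criteria.window_cm, side="left")
    hi = np.searchsorted(pos, ref_position + criteria.window_cm, side="right")
    if hi <= lo:
        return None
    dose_tol = criteria.dose_pct / 100.0 * (ref_dose if criteria.local else ref_max)
    if dose_tol <= 0:
        return None
    dd = (evaluated.values[lo:hi] - ref_dose) / dose_tol
    ds = (pos[lo:hi] - ref_position) * 10.0 / criteria.dta_mm  # cm -> mm
    return float(np.sqrt(np.min(dd * dd + ds * ds)))


def _check_comparable(reference: ScanCurve, evaluated: ScanCurve) -> None:
    if reference.kind != evaluated.kind:
        raise ValueError(
            f"curve kinds differ: {reference.kind!r} vs {evaluated.kind!r}"
        )
    if reference.normalization != evaluated.normalization:
        raise ValueError(
            "normalization mismatch: "
            f"{reference.normalization!r} vs {evaluated.normalization!r}"
        )
    lo = max(reference.positions[0], evaluated.positions[0])
    hi = min(reference.positions[-1], evaluated.positions[-1])
    span = reference.positions[-1] - reference.positions[0]
    if hi - lo < 0.5 * span:
        raise ValueError("overlapping support below 50% of the reference extent")


def gamma_curve(
    reference: ScanCurve,
    evaluated: ScanCurve,
    criteria: GammaCriteria,
) -> GammaResult:
    """Gamma comparison of two scan curves of the same kind.

    The evaluated curve is refined by the criteria's resample factor
    (linear interpolation); every reference sample is a fixed evaluation
    site.  The reference is never interpolated.
    """
    _check_comparable(reference, evaluated)
    fine = resample_curve(evaluated, criteria.resample_factor)
    ref_max = reference.max()
    gammas = []
    n_uncovered = 0
    for p, d in zip(reference.positions, reference.values):
        g = gamma_point(float(p), float(d), fine, criteria, ref_max=ref_max)
        if g is None:
            n_uncovered += 1
        else:
            gammas.append(g)
    gam = np.asarray(gammas)
    if gam.size == 0:
        raise ValueError("no reference point is covered by the evaluated curve")
    return GammaResult(
        gamma_values=gam,
        criteria=criteria,
        n_points=int(gam.size),
        n_pass=int(np.count_nonzero(gam <= 1.0 + _PASS_EPS)),
        n_uncovered=n_uncovered,
    )


@dataclass(frozen=True)
class MultiCriteriaReport:
    """Passing rates at (3%,3mm), (2%,2mm) and (1%,1mm)."""

    rate_3_3: float
    rate_2_2: float
    rate_1_1: float
    results: tuple = field(default=(), repr=False)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rate_3_3, self.rate_2_2, self.rate_1_1)


def multi_criteria_report(reference: ScanCurve, evaluated: ScanCurve) -> MultiCriteriaReport:
    """Passing rates under the three standard acceptance criteria."""
    results = tuple(
        gamma_curve(reference, evaluated, c)
        for c in (CRITERIA_3_3, CRITERIA_2_2, CRITERIA_1_1)
    )
    return MultiCriteriaReport(
        rate_3_3=results[0].passing_rate,
        rate_2_2=results[1].passing_rate,
        rate_1_1=results[2].passing_rate,
        results=results,
    )


def gamma_grid(reference_points, evaluated, criteria: GammaCriteria) -> GammaResult:
    """3D gamma of scattered reference points against a dose grid.

    ``reference_points`` is a sequence of ((x, y, z), dose_percent); the
    evaluated grid is normalized to 100 at its maximum and virtually
    refined to one-fifth bin in each direction by tri-linear interpolation.
    The candidate set is the refined lattice within Euclidean distance
    min(5 dS, 1.5 cm) of each reference point.
    """
    from scipy.interpolate import RegularGridInterpolator

    pts = [(np.asarray(p, float), float(d)) for p, d in reference_points]
    if not pts:
        raise ValueError("reference_points must be nonempty")
    p = evaluated.phantom
    axes = (p.centers("x"), p.centers("y"), p.centers("z"))
    dose = evaluated.dose * (100.0 / evaluated.dose.max())
    interp = RegularGridInterpolator(axes, dose, method="linear", bounds_error=False)

    step = p.bin / criteria.resample_factor
    r = criteria.window_cm
    k = int(math.floor(r / step))
    offs = np.arange(-k, k + 1) * step
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    ball = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    dist = np.linalg.norm(ball, axis=1)
    keep = dist <= r + 1e-12
    ball, dist = ball[keep], dist[keep]

    ref_max = max(d for _, d in pts)
    gammas = []
    n_uncovered = 0
    for ppos, pdose in pts:
        cand = ppos[None, :] + ball
        vals = interp(cand)
        ok = np.isfinite(vals)
        if not ok.any():
            n_uncovered += 1
            continue
        dose_tol = criteria.dose_pct / 100.0 * (pdose if criteria.local else ref_max)
        dd = (vals[ok] - pdose) / dose_tol
        ds = dist[ok] * 10.0 / criteria.dta_mm
        gammas.append(float(np.sqrt(np.min(dd * dd + ds * ds))))
    gam = np.asarray(gammas)
    if gam.size == 0:
        raise ValueError("no reference point is covered by the evaluated grid")
    return GammaResult(
        gamma_values=gam,
        criteria=criteria,
        n_points=int(gam.size),
        n_pass=int(np.count_nonzero(gam <= 1.0 + _PASS_EPS)),
        n_uncovered=n_uncovered,
    )
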