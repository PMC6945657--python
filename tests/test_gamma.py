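"""Gamma engine: boundary cases, invariants, and a brute-force oracle.

The oracle re-derives the gamma index by exhaustive minimization over a
50x-refined evaluated curve, independently of the engine's search code.
"""

import numpy as np
import pytest

from linactune import (
    CRITERIA_1_1,
    GammaCriteria,
    gamma_curve,
    gamma_grid,
    gamma_point,
    multi_criteria_report,
    resample_curve,
)
from conftest import make_curve


def brute_force_gamma(reference, evaluated, criteria, refine=50):
    """Independent oracle: exhaustive search on a ``refine``-x grid."""
    n = evaluated.positions.size
    fine_pos = evaluated.positions[0] + np.arange((n - 1) * refine + 1) * (
        evaluated.spacing / refine
    )
    fine_val = np.interp(fine_pos, evaluated.positions, evaluated.values)
    window = min(5.0 * criteria.dta_mm / 10.0, criteria.search_cap_cm)
    ref_max = reference.values.max()
    gammas = []
    for p, d in zip(reference.positions, reference.values):
        sel = np.abs(fine_pos - p) <= window
        if not sel.any():
            continue
        dd = (fine_val[sel] - d) / (criteria.dose_pct / 100.0 * ref_max)
        ds = (fine_pos[sel] - p) * 10.0 / criteria.dta_mm
        gammas.append(np.sqrt(np.min(dd**2 + ds**2)))
    gammas = np.asarray(gammas)
    return 100.0 * np.count_nonzero(gammas <= 1.0 + 1e-9) / gammas.size


class TestGammaPoint:
    def test_identical_distributions_give_zero(self):
        curve = make_curve(np.linspace(20, 100, 30)).normalized()
        fine = resample_curve(curve, 5)
        for p, d in zip(curve.positions, curve.values):
            g = gamma_point(p, d, fine, CRITERIA_1_1, ref_max=100.0)
            assert g == pytest.approx(0.0, abs=1e-9)

    def test_exact_dose_offset_on_boundary(self):
        """A uniform offset of exactly dD gives Gamma = 1 (boundary pass)."""
        ref = make_curve(np.full(30, 100.0))
        ev = make_curve(np.full(30, 102.0))
        res = gamma_curve(ref, ev, GammaCriteria(2.0, 2.0))
        assert res.gamma_values == pytest.approx(1.0)
        assert res.passing_rate == 100.0

    def test_one_mm_shift_of_steep_ramp_is_near_unity(self):
        """Shifting a steep monotone ramp by +1 mm gives Gamma ~ 1 at 1%/1mm.

        The ramp is steep enough (60 %/cm vs a 1.25 % dose tolerance) that
        the minimum is forced out to the 1 mm distance-to-agreement, so the
        gamma value is dominated by the spatial term.  Cross-checked against
        the exhaustive fine-grid oracle.
        """
        slope = 60.0
        x = np.arange(11) * 0.2
        vals = 10 + slope * x
        ref = make_curve(vals, start=0.1)
        ev = make_curve(vals, start=0.2)  # same samples, +1 mm in position
        res = gamma_curve(ref, ev, CRITERIA_1_1)
        interior = res.gamma_values[2:-2]
        assert np.all(np.abs(interior - 1.0) < 0.05)
        # agreement with the brute-force minimizer at 50x refinement
        assert gamma_curve(ref, ev, CRITERIA_1_1).passing_rate == pytest.approx(
            brute_force_gamma(ref, ev, CRITERIA_1_1), abs=1.0)

    def test_empty_window_returns_none(self):
        curve = resample_curve(make_curve(np.full(10, 50.0)), 5)
        far = curve.positions[-1] + 10.0
        assert gamma_point(far, 50.0, curve, CRITERIA_1_1) is None

    @pytest.mark.parametrize("dta,expected", [(1.0, 0.5), (3.0, 1.5), (2.0, 1.0)])
    def test_search_window_min_of_5dta_and_cap(self, dta, expected):
        assert GammaCriteria(1.0, dta).window_cm == pytest.approx(expected)


class TestGammaCurve:
    def test_identical_curves_pass_everywhere(self):
        curve = make_curve(np.linspace(5, 100, 50)).normalized()
        report = multi_criteria_report(curve, curve)
        assert report.as_tuple() == (100.0, 100.0, 100.0)

    def test_single_displaced_point_of_fifty(self):
        """49/50 matching points and one far outlier -> 98.0%."""
        vals = np.linspace(10, 100, 50)
        ref = make_curve(vals)
        bad = vals.copy()
        bad[25] += 50.0
        res = gamma_curve(ref, make_curve(bad), GammaCriteria(1.0, 1.0))
        assert res.passing_rate == pytest.approx(98.0)

    def test_normalization_mismatch_rejected(self):
        pdd = make_curve(np.linspace(10, 100, 30), kind="pdd")
        lat = make_curve(np.linspace(10, 100, 30), kind="lateral")
        with pytest.raises(ValueError):
            gamma_curve(pdd, lat, CRITERIA_1_1)

    def test_insufficient_overlap_rejected(self):
        ref = make_curve(np.full(100, 50.0), start=0.1)
        ev = make_curve(np.full(10, 50.0), start=18.0)
        with pytest.raises(ValueError):
            gamma_curve(ref, ev, CRITERIA_1_1)

    def test_orientation_invariance(self):
        """Mirroring both curves leaves all gamma values unchanged."""
        rng = np.random.default_rng(3)
        vals = 60 + 30 * np.sin(np.arange(40) / 5.0)
        ev_vals = vals * (1 + 0.02 * rng.standard_normal(40))
        ref, ev = make_curve(vals), make_curve(ev_vals)
        flipped_ref = make_curve(vals[::-1])
        flipped_ev = make_curve(ev_vals[::-1])
        a = gamma_curve(ref, ev, CRITERIA_1_1)
        b = gamma_curve(flipped_ref, flipped_ev, CRITERIA_1_1)
        np.testing.assert_allclose(np.sort(a.gamma_values), np.sort(b.gamma_values),
                                   atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_criteria_nesting_pointwise(self, seed):
        """Passing the tight criteria implies passing the looser ones."""
        rng = np.random.default_rng(seed)
        vals = 60 + 30 * np.sin(np.arange(80) / 7.0)
        ev = vals * (1 + 0.03 * rng.standard_normal(80))
        ref_c, ev_c = make_curve(vals), make_curve(np.clip(ev, 0, None))
        report = multi_criteria_report(ref_c, ev_c)
        g33, g22, g11 = (r.gamma_values for r in report.results)
        assert np.all((g11 <= 1.0) <= (g22 <= 1.0))
        assert np.all((g22 <= 1.0) <= (g33 <= 1.0))
        assert report.rate_3_3 >= report.rate_2_2 >= report.rate_1_1

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_on_random_perturbations(self, seed):
        """Passing rate within 1 point of the 50x brute-force minimizer."""
        rng = np.random.default_rng(100 + seed)
        n = 100  # instance size keeps one point worth 1.0 rate points
        x = np.arange(n) * 0.2
        vals = 100 * np.exp(-0.5 * ((x - 10.0) / 5.0) ** 2) + 5
        ev = vals * (1 + 0.015 * rng.standard_normal(n)) + 0.3 * rng.standard_normal(n)
        ref_c = make_curve(vals)
        ev_c = make_curve(np.clip(ev, 0, None))
        for crit in (GammaCriteria(1.0, 1.0), GammaCriteria(2.0, 2.0)):
            engine = gamma_curve(ref_c, ev_c, crit).passing_rate
            oracle = brute_force_gamma(ref_c, ev_c, crit)
            assert engine == pytest.approx(oracle, abs=1.0)

    def test_replacing_evaluated_by_reference_never_increases_gamma(self):
        rng = np.random.default_rng(9)
        vals = np.linspace(20, 100, 50)
        ev = vals + 3 * rng.standard_normal(50)
        patched = ev.copy()
        patched[20:30] = vals[20:30]  # restore reference on a subinterval
        ref_c = make_curve(vals)
        g_orig = gamma_curve(ref_c, make_curve(np.clip(ev, 0, None)), CRITERIA_1_1)
        g_patch = gamma_curve(ref_c, make_curve(np.clip(patched, 0, None)), CRITERIA_1_1)
        assert np.all(g_patch.gamma_values[22:28] <= g_orig.gamma_values[22:28] + 1e-12)


class TestGammaGrid:
    def test_reference_sampled_from_grid_gives_zero(self, noiseless_grid, phantom):
        dose = noiseless_grid.dose * (100.0 / noiseless_grid.dose.max())
        xs, ys, zs = (phantom.centers(a) for a in "xyz")
        pts = [((xs[40], ys[40], zs[k]), dose[40, 40, k]) for k in range(10, 100, 10)]
        res = gamma_grid(pts, noiseless_grid, GammaCriteria(3.0, 3.0))
        assert res.gamma_values == pytest.approx(0.0, abs=1e-9)
        assert res.passing_rate == 100.0

    def test_uniform_offset_exactly_dose_criterion(self, phantom):
        import numpy as np
        from linactune.simulate import DoseGrid

        shape = phantom.shape
        grid = DoseGrid(np.full(shape, 1.0), np.zeros(shape), phantom, 1, 0)
        # evaluated is flat 100 after normalization; one reference point sits
        # exactly dD below it, a second anchors the global reference maximum
        res = gamma_grid(
            [((0.0, 0.0, 15.0), 98.0), ((2.0, 2.0, 15.0), 100.0)],
            grid, GammaCriteria(2.0, 2.0))
        assert res.gamma_values[0] == pytest.approx(1.0, abs=1e-9)
        assert res.gamma_values[1] == pytest.approx(0.0, abs=1e-9)

    def test_toy_case_matches_brute_force(self, beam_6mv, phantom):
        """10-point 3D case vs exhaustive 1D-along-axis refinement oracle."""
        from linactune import generate_dose_grid
        from linactune.simulate import ModelConstants

        grid = generate_dose_grid(beam_6mv, phantom, 1_000_000, seed=11,
                                  constants=ModelConstants(kappa=2.0))
        norm = grid.dose * (100.0 / grid.dose.max())
        zs = phantom.centers("z")
        # reference: noiseless model on the central axis, normalized likewise
        noiseless = generate_dose_grid(beam_6mv, phantom, 10, seed=0,
                                       constants=ModelConstants(kappa=0.0))
        ref_axis = noiseless.dose[40, 40, :] * (100.0 / noiseless.dose.max())
        pts = [((0.0, 0.0, zs[k]), ref_axis[k]) for k in range(20, 120, 10)]
        crit = GammaCriteria(2.0, 1.0)  # 0.5 cm search ball keeps the oracle tractable
        res = gamma_grid(pts, grid, crit)

        # oracle: dense tri-linear interpolation on a finer lattice
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (phantom.centers("x"), phantom.centers("y"), zs), norm,
            method="linear", bounds_error=False)
        window = crit.window_cm
        step = phantom.bin / 25
        k = int(window / step)
        offs = np.arange(-k, k + 1) * step
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        ball = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], 1)
        dist = np.linalg.norm(ball, axis=1)
        keep = dist <= window
        ball, dist = ball[keep], dist[keep]
        ref_max = max(d for _, d in pts)
        for gamma_engine, (p, d) in zip(res.gamma_values, pts):
            vals = interp(np.asarray(p) + ball)
            ok = np.isfinite(vals)
            dd = (vals[ok] - d) / (crit.dose_pct / 100 * ref_max)
            ds = dist[ok] * 10 / crit.dta_mm
            oracle = np.sqrt(np.min(dd**2 + ds**2))
            assert gamma_engine == pytest.approx(oracle, abs=0.05)
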