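"""Ligand-depletion isotherm, fluorescence observable, and intensity corrections."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capbind.binding_model import (
    BindingParameters,
    TitrationCurve,
    TitrationPoint,
    ValidationError,
    complex_concentration,
    correct_curve,
    correct_intensities,
    model_fluorescence,
    read_titration_csv,
    write_titration_csv,
)


def bisection_complex(kas, p0, l0, tol=1e-14):
    """Independent root of K·(p0−x)(l0−x) − x = 0 on [0, min(p0, l0)]."""
    lo, hi = 0.0, min(p0, l0)
    if hi == 0:
        return 0.0
    f = lambda x: kas * (p0 - x) * (l0 - x) - x
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


class TestComplexConcentration:
    def test_symmetric_unit_case(self):
        # root of (1-x)^2 = x -> (3 - sqrt(5))/2
        expected = (3 - math.sqrt(5)) / 2
        assert complex_concentration(1.0, 1.0, 1.0) == pytest.approx(expected, abs=1e-12)
        assert bisection_complex(1.0, 1.0, 1.0) == pytest.approx(expected, abs=1e-9)

    def test_zero_ligand_gives_zero_complex(self):
        assert complex_concentration(5.0, 0.1, 0.0) == 0.0

    def test_stoichiometric_limit_for_tight_binder(self):
        assert complex_concentration(1e9, 0.1, 5.0) == pytest.approx(0.1, abs=1e-6)

    def test_matches_bisection_on_coarse_grid(self):
        for kas in (1e-3, 1.0, 1e3, 1e6):
            for p0 in (0.01, 0.1, 1.0):
                for l0 in (0.0, 0.05, 1.0, 100.0):
                    got = complex_concentration(kas, p0, l0)
                    want = bisection_complex(kas, p0, l0)
                    assert got == pytest.approx(want, abs=1e-10 * max(p0, 1e-12))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            complex_concentration(-1.0, 0.1, 1.0)
        with pytest.raises(ValidationError):
            complex_concentration(1.0, -0.1, 1.0)
        with pytest.raises(ValidationError):
            complex_concentration(1.0, 0.1, -1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        kas=st.floats(1e-3, 1e6),
        p0=st.floats(0.01, 10.0),
        l0=st.floats(0.0, 1e4),
        bump=st.floats(1e-6, 2.0),
    )
    def test_monotone_in_each_argument(self, kas, p0, l0, bump):
        base = complex_concentration(kas, p0, l0)
        assert complex_concentration(kas * (1 + bump), p0, l0) >= base - 1e-12
        assert complex_concentration(kas, p0 + bump, l0) >= base - 1e-12
        assert complex_concentration(kas, p0, l0 + bump) >= base - 1e-12


class TestModelFluorescence:
    def test_inert_ligand_is_flat(self):
        p = BindingParameters(kas=1.0, p0_act=0.1, f0=100.0, delta_f=0.0, f_lig=0.0)
        for l0 in (0.0, 1.0, 100.0):
            assert model_fluorescence(p, l0) == pytest.approx(100.0)

    def test_quench_plus_free_ligand_example(self):
        # [PL] solves 10(0.1-x)(0.05-x)=x -> x = (2.5 - sqrt(4.25))/20
        p = BindingParameters(kas=10.0, p0_act=0.1, f0=100.0, delta_f=500.0, f_lig=2.0)
        pl = (2.5 - math.sqrt(4.25)) / 20.0
        expected = 100.0 - 500.0 * pl + 2.0 * (0.05 - pl)
        assert model_fluorescence(p, 0.05) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(89.0950, abs=1e-4)

    def test_free_ligand_emission_dominates_at_saturation(self):
        p = BindingParameters(kas=10.0, p0_act=0.1, f0=100.0, delta_f=500.0, f_lig=2.0)
        l0 = 1e3
        asymptote = 100.0 - 500.0 * 0.1 + 2.0 * (l0 - 0.1)
        assert model_fluorescence(p, l0) == pytest.approx(asymptote, rel=1e-3)
        # slope approaches f_lig
        slope = model_fluorescence(p, 2e3) - model_fluorescence(p, 2e3 - 1.0)
        assert slope == pytest.approx(2.0, rel=1e-3)

    def test_pure_quench_monotone_non_increasing(self):
        p = BindingParameters(kas=5.0, p0_act=0.1, f0=100.0, delta_f=300.0, f_lig=0.0)
        l0 = np.linspace(0, 50, 200)
        f = model_fluorescence(p, l0)
        assert np.all(np.diff(f) <= 1e-12)

    def test_zero_ligand_returns_baseline(self):
        p = BindingParameters(kas=5.0, p0_act=0.1, f0=123.4, delta_f=300.0, f_lig=1.0)
        assert model_fluorescence(p, 0.0) == pytest.approx(123.4)


class TestCorrections:
    def test_identity_without_optional_fields(self):
        assert correct_intensities(TitrationPoint(1.0, 100.0)) == pytest.approx(100.0)

    def test_inner_filter_half_path(self):
        pt = TitrationPoint(1.0, 100.0, a_ex=0.1, a_em=0.05)
        assert correct_intensities(pt) == pytest.approx(100.0 * 10 ** 0.075, abs=1e-9)
        assert 100.0 * 10 ** 0.075 == pytest.approx(118.850, abs=1e-3)

    def test_dilution_scaling(self):
        pt = TitrationPoint(1.0, 100.0, volume=1540.0)
        assert correct_intensities(pt, reference_volume=1400.0) == pytest.approx(110.0)

    def test_volume_below_reference_rejected(self):
        pt = TitrationPoint(1.0, 100.0, volume=1300.0)
        with pytest.raises(ValidationError):
            correct_intensities(pt, reference_volume=1400.0)

    def test_correct_curve_uses_first_volume_as_reference(self):
        pts = [TitrationPoint(float(i), 100.0, volume=1400.0 + 10 * i) for i in range(6)]
        pts[0] = TitrationPoint(0.0, 100.0, volume=1400.0)
        curve = TitrationCurve("p", "m7GTP", pts)
        corrected = correct_curve(curve)
        assert corrected.points[0].fluorescence_raw == pytest.approx(100.0)
        assert corrected.points[5].fluorescence_raw == pytest.approx(100.0 * 1450 / 1400)


class TestCurveValidation:
    def _points(self, ligs):
        return [TitrationPoint(l, 10.0) for l in ligs]

    def test_requires_six_points(self):
        with pytest.raises(ValidationError):
            TitrationCurve("p", "m7GTP", self._points([0, 1, 2, 3, 4]))

    def test_requires_zero_first_point(self):
        with pytest.raises(ValidationError):
            TitrationCurve("p", "m7GTP", self._points([1, 2, 3, 4, 5, 6]))

    def test_requires_sorted_ligand(self):
        with pytest.raises(ValidationError):
            TitrationCurve("p", "m7GTP", self._points([0, 2, 1, 3, 4, 5]))

    def test_negative_fluorescence_rejected(self):
        with pytest.raises(ValidationError):
            TitrationPoint(0.0, -1.0)


def test_titration_csv_round_trip(tmp_path):
    pts = [
        TitrationPoint(0.0, 100.0, volume=1400.0),
        TitrationPoint(0.5, 95.0, volume=1410.0, a_ex=0.01, a_em=0.0),
    ] + [TitrationPoint(float(i), 90.0 - i, volume=1410.0 + i) for i in range(1, 5)]
    curve = TitrationCurve("heIF4E1a", "m7GTP", pts, buffer_tag="glycerol10")
    path = tmp_path / "curve.csv"
    write_titration_csv(curve, path)
    back = read_titration_csv(path)
    assert back.protein_id == "heIF4E1a"
    assert back.ligand == "m7GTP"
    assert back.buffer_tag == "glycerol10"
    assert len(back.points) == len(curve.points)
    for a, b in zip(curve.points, back.points):
        assert b.ligand_total == pytest.approx(a.ligand_total)
        assert b.fluorescence_raw == pytest.approx(a.fluorescence_raw)
        assert (b.volume is None) == (a.volume is None)
        if a.a_ex is not None:
            assert b.a_ex == pytest.approx(a.a_ex)
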