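"""Core probability model and calibration algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vaxcov as vc
from vaxcov.errors import CalibrationError, ValidationError

from conftest import enumerate_coverage


def prof(p):
    ids = tuple(f"b{i}" for i in range(len(p)))
    return vc.PopulationProfile(ids, p)


def pres(v, d=1):
    ids = tuple(f"b{i}" for i in range(len(v)))
    return vc.VaccinePresentation(ids, v, d)


class TestUncalibratedCoverage:
    @pytest.mark.parametrize(
        "p, v, d, expected",
        [
            # three-barrier worked example: 80% * 50% * 50%
            ((0.20, 0.50, 0.50), (0.0, 0.0, 0.0), 1, 0.20),
            # same population, technology lifts pass rates to 100%, 80%, 50%
            ((0.20, 0.50, 0.50), (1.0, 0.6, 0.0), 1, 0.40),
            # perfect presentation removes every barrier
            ((0.9, 0.3, 0.7), (1.0, 1.0, 1.0), 3, 1.0),
            # two-dose case: (0.85 * 0.95)^2
            ((0.3, 0.1), (0.5, 0.5), 2, 0.65205625),
        ],
    )
    def test_examples(self, p, v, d, expected):
        assert vc.uncalibrated_coverage(prof(p), pres(v, d)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_mismatched_barrier_ids_rejected(self):
        profile = vc.PopulationProfile(("a", "b"), [0.1, 0.2])
        presentation = vc.VaccinePresentation(("a", "c"), [0.1, 0.2], 1)
        with pytest.raises(ValidationError, match="barrier ids"):
            vc.uncalibrated_coverage(profile, presentation)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(p=(0.2, 1.3)), "p"),
            (dict(p=(0.2, -0.1)), "p"),
            (dict(v=(0.5, 1.5)), "v"),
            (dict(d=0), "doses"),
            (dict(d=1.5), "doses"),
        ],
    )
    def test_out_of_range_inputs_name_the_field(self, kwargs, field):
        p = kwargs.get("p", (0.2, 0.5))
        v = kwargs.get("v", (0.5, 0.5))
        d = kwargs.get("d", 1)
        with pytest.raises(ValidationError, match=field):
            vc.uncalibrated_coverage(prof(p), pres(v, d))

    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=6),
        v_seed=st.data(),
        d=st.integers(1, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_range_and_monotonicity(self, p, v_seed, d):
        n = len(p)
        v = v_seed.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        u = vc.uncalibrated_coverage(prof(p), pres(v, d))
        assert 0.0 <= u <= 1.0
        # raising any technology score cannot lower coverage
        i = v_seed.draw(st.integers(0, n - 1))
        v_up = list(v)
        v_up[i] = min(1.0, v[i] + v_seed.draw(st.floats(0, 1)))
        assert vc.uncalibrated_coverage(prof(p), pres(v_up, d)) >= u - 1e-15
        # raising any prevalence cannot raise coverage
        p_up = list(p)
        p_up[i] = min(1.0, p[i] + v_seed.draw(st.floats(0, 1)))
        assert vc.uncalibrated_coverage(prof(p_up), pres(v, d)) <= u + 1e-15
        # an extra dose cannot raise coverage
        assert vc.uncalibrated_coverage(prof(p), pres(v, d + 1)) <= u + 1e-15

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_exhaustive_enumeration_small(self, d):
        p = (0.25, 0.5)
        v = (0.75, 0.25)
        assert vc.uncalibrated_coverage(prof(p), pres(v, d)) == pytest.approx(
            enumerate_coverage(p, v, d), abs=1e-12
        )


class TestLeastDesirable:
    @pytest.mark.parametrize(
        "p, d_worst, expected",
        [
            ((0.2, 0.5), 4, 0.0256),  # (0.8 * 0.5)^4
            ((0.0, 0.0, 0.0), 7, 1.0),
            ((1.0, 0.5), 1, 0.0),
        ],
    )
    def test_examples(self, p, d_worst, expected):
        assert vc.least_desirable_coverage(prof(p), d_worst) == pytest.approx(
            expected, abs=1e-12
        )

    def test_equals_zero_vector_presentation(self):
        p = prof((0.3, 0.6, 0.1))
        zero = pres((0.0, 0.0, 0.0), 4)
        assert vc.least_desirable_coverage(p, 4) == vc.uncalibrated_coverage(p, zero)


class TestCalibration:
    def test_fit_hand_example(self):
        ctx = vc.fit_calibration(M=0.9, C_c=0.8, U_c=0.6, U_l=0.1)
        assert ctx.S == pytest.approx(0.25, abs=1e-12)
        assert ctx.beta == pytest.approx(0.65, abs=1e-12)
        # the stored intercept identity holds exactly
        assert ctx.beta == ctx.C_c - ctx.S * ctx.U_c

    def test_no_headroom_means_zero_slope(self):
        ctx = vc.fit_calibration(M=0.85, C_c=0.85, U_c=0.5, U_l=0.2)
        assert ctx.S == 0.0

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(CalibrationError, match="U_c"):
            vc.fit_calibration(M=0.9, C_c=0.8, U_c=1.0, U_l=0.1)
        with pytest.raises(CalibrationError, match="C_c"):
            vc.fit_calibration(M=0.8, C_c=0.9, U_c=0.5, U_l=0.1)
        with pytest.raises(CalibrationError, match="U_l"):
            vc.fit_calibration(M=0.9, C_c=0.8, U_c=0.3, U_l=0.5)

    def test_calibrate_examples(self):
        ctx = vc.fit_calibration(M=0.9, C_c=0.8, U_c=0.6, U_l=0.0256)
        assert vc.calibrate(0.6, ctx) == pytest.approx(0.8, abs=1e-12)  # anchor at U_c
        assert vc.calibrate(1.0, ctx) == pytest.approx(0.9, abs=1e-12)  # anchor at U=1
        assert vc.calibrate(0.0256, ctx) == pytest.approx(0.6564, abs=1e-12)

    @given(
        C_c=st.floats(0.1, 0.95),
        m_gap=st.floats(0.0, 0.05),
        U_c=st.floats(0.0, 0.99),
        u_gap=st.floats(0.0, 1.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_anchor_identities(self, C_c, m_gap, U_c, u_gap):
        M = min(C_c + m_gap, 1.0)
        U_l = U_c * u_gap
        ctx = vc.fit_calibration(M, C_c, U_c, U_l)
        assert vc.calibrate(U_c, ctx) == pytest.approx(C_c, abs=1e-12)
        assert vc.calibrate(1.0, ctx) == pytest.approx(M, abs=1e-12)


class TestResidualRisk:
    @pytest.mark.parametrize(
        "U_t, U_l, expected",
        [
            (0.3, 0.3, 1.0),  # no improvement over the worst case
            (1.0, 0.3, 0.0),  # every addressable barrier removed
            (0.5, 0.0256, 1.0 - 0.4744 / 0.9744),
        ],
    )
    def test_examples(self, U_t, U_l, expected):
        assert vc.residual_risk(U_t, U_l) == pytest.approx(expected, abs=1e-12)

    def test_ordering_and_degenerate_errors(self):
        with pytest.raises(ValidationError, match="U_t"):
            vc.residual_risk(0.1, 0.2)
        with pytest.raises(ValidationError, match="U_l"):
            vc.residual_risk(1.0, 1.0)


class TestEstimateCoverage:
    def test_worked_example_all_intermediates(self, calibration_example):
        ex = calibration_example
        est = vc.estimate_coverage(
            ex["profile"], ex["test"], ex["calib"], ex["M"], ex["C_c"], ex["d_worst"]
        )
        audit = est.audit()
        for name, frac in ex["exact"].items():
            assert audit[name] == pytest.approx(float(frac), abs=1e-12), name
        assert est.valid

    def test_test_equal_to_calibration_returns_observed_coverage(self, calibration_example):
        ex = calibration_example
        est = vc.estimate_coverage(
            ex["profile"], ex["calib"], ex["calib"], ex["M"], ex["C_c"], ex["d_worst"]
        )
        assert est.C_t == pytest.approx(ex["C_c"], abs=1e-12)

    def test_perfect_presentation_reaches_maximum(self, calibration_example):
        ex = calibration_example
        perfect = vc.VaccinePresentation(("b1", "b2"), [1.0, 1.0], 1)
        est = vc.estimate_coverage(
            ex["profile"], perfect, ex["calib"], ex["M"], ex["C_c"], ex["d_worst"]
        )
        assert est.x_t == 0.0
        assert est.C_t == pytest.approx(ex["M"], abs=1e-12)

    def test_overreported_maximum_flags_estimate_invalid(self):
        # an M above 100% (administrative over-reporting) can push the
        # estimate past 1; it must be flagged, not clamped
        profile = prof((0.5, 0.5))
        calib = pres((0.0, 0.0), 1)
        perfect = pres((1.0, 1.0), 1)
        est = vc.estimate_coverage(profile, perfect, calib, M=1.2, C_c=0.2, d_worst=4)
        assert est.C_t > 1.0
        assert not est.valid

    @given(
        data=st.data(),
        n=st.integers(1, 5),
        d_calib=st.integers(1, 4),
    )
    @settings(max_examples=300, deadline=None)
    def test_self_consistency_random_contexts(self, data, n, d_calib):
        # estimating the calibration presentation itself must return C_c
        p = data.draw(st.lists(st.floats(0.01, 0.99), min_size=n, max_size=n))
        # calibration scores bounded away from 1 so U_c < 1 is guaranteed
        v = data.draw(st.lists(st.floats(0, 0.99), min_size=n, max_size=n))
        C_c = data.draw(st.floats(0.2, 0.9))
        M = min(1.0, C_c + data.draw(st.floats(0.0, 0.1)))
        profile, calib = prof(p), pres(v, d_calib)
        est = vc.estimate_coverage(profile, calib, calib, M, C_c, d_worst=4)
        assert est.C_t == pytest.approx(C_c, abs=1e-9)

    def test_boundary_collapse(self, calibration_example):
        ex = calibration_example
        # test presentation == least desirable -> C_t == C_l
        worst = vc.VaccinePresentation(("b1", "b2"), [0.0, 0.0], ex["d_worst"])
        est = vc.estimate_coverage(
            ex["profile"], worst, ex["calib"], ex["M"], ex["C_c"], ex["d_worst"]
        )
        assert est.x_t == pytest.approx(1.0, abs=1e-12)
        assert est.C_t == pytest.approx(est.C_l, abs=1e-12)

    @given(data=st.data())
    @settings(max_examples=200, deadline=None)
    def test_estimate_monotone_in_test_scores_and_doses(self, data):
        n = data.draw(st.integers(1, 4))
        p = data.draw(st.lists(st.floats(0.05, 0.95), min_size=n, max_size=n))
        v_c = data.draw(st.lists(st.floats(0, 0.99), min_size=n, max_size=n))
        v_t = data.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        d_t = data.draw(st.integers(1, 3))
        C_c = data.draw(st.floats(0.3, 0.85))
        M = min(1.0, C_c + data.draw(st.floats(0.0, 0.1)))
        profile, calib = prof(p), pres(v_c, 1)
        est = vc.estimate_coverage(profile, pres(v_t, d_t), calib, M, C_c, d_worst=4)
        i = data.draw(st.integers(0, n - 1))
        v_up = list(v_t)
        v_up[i] = min(1.0, v_t[i] + data.draw(st.floats(0, 1)))
        est_up = vc.estimate_coverage(profile, pres(v_up, d_t), calib, M, C_c, d_worst=4)
        assert est_up.C_t >= est.C_t - 1e-12
        est_more_doses = vc.estimate_coverage(
            profile, pres(v_t, d_t + 1), calib, M, C_c, d_worst=4
        )
        assert est_more_doses.C_t <= est.C_t + 1e-12
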