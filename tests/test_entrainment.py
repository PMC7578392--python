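"""Distance-to-line geometry, responsibilities, contributions, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from prosentrain import (
    DyadFeatures,
    ReferenceLine,
    ValidationError,
    adjusted_contribution,
    classify_entrainment,
    compute_entrainment,
    count_converging,
    delta_entrainment,
    point_to_line_distance,
    select_reference_line,
    signed_contribution,
    speaker_responsibility,
)


def brute_force_distance(point, slope):
    """Independent oracle: coarse scan along the line, then 1-D refinement."""
    x, y = point
    ts = np.linspace(-2000.0, 2000.0, 20001)
    d2 = (ts - x) ** 2 + (slope * ts - y) ** 2
    t0 = ts[np.argmin(d2)]
    res = minimize_scalar(
        lambda t: np.hypot(t - x, slope * t - y),
        bounds=(t0 - 1.0, t0 + 1.0), method="bounded",
        options={"xatol": 1e-12},
    )
    return res.fun


def dyad(start, end, dyad_id="d", k=1):
    return DyadFeatures(
        dyad_id=dyad_id,
        start={k: start}, end={k: end}, usable={k: True},
    )


LINE_1 = ReferenceLine(1.0)
LINE_HALF = ReferenceLine(0.5, halved_axis="partner")


class TestPointToLineDistance:
    def test_point_on_matching_line(self):
        assert point_to_line_distance((150.0, 150.0), LINE_1) == 0.0

    def test_exact_octave_on_half_matching_line(self):
        assert point_to_line_distance((200.0, 100.0), LINE_HALF) == 0.0

    def test_known_offset(self):
        assert point_to_line_distance((120.0, 100.0), LINE_1) == pytest.approx(
            20.0 / np.sqrt(2.0), abs=1e-4
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        points = rng.uniform(20.0, 500.0, size=(1000, 2))
        slopes = rng.choice([0.5, 1.0, 2.0], size=1000)
        for (x, y), m in zip(points, slopes):
            line = ReferenceLine(1.0) if m == 1.0 else ReferenceLine(
                0.5, halved_axis="partner" if m == 0.5 else "participant"
            )
            closed = point_to_line_distance((x, y), line)
            assert abs(closed - brute_force_distance((x, y), m)) < 1e-6

    def test_nonfinite_point_rejected(self):
        with pytest.raises(ValidationError):
            point_to_line_distance((np.nan, 100.0), LINE_1)


class TestSelectReferenceLine:
    @pytest.mark.parametrize(
        "classes,slope",
        [(("child", "adult_female"), 1.0),
         (("teen_boy", "adult_female"), 2.0),  # effective: boy axis halved
         (("adult_female", "teen_boy"), 0.5),
         (("teen_girl", "adult_female"), 1.0),
         (("child", "adult_male"), 1.0)],
    )
    def test_pairings(self, classes, slope):
        line = select_reference_line(*classes)
        assert line.effective_slope == pytest.approx(slope)

    def test_override_wins(self):
        line = select_reference_line("teen_boy", "adult_female", override=1.0)
        assert line.effective_slope == 1.0

    def test_axis_swap_reciprocal_slope(self):
        # d((a, b), slope 1/2) == d((b, a), slope 2)
        a, b = 210.0, 95.0
        assert point_to_line_distance((a, b), LINE_HALF) == pytest.approx(
            point_to_line_distance((b, a), ReferenceLine(0.5, halved_axis="participant"))
        )


class TestDeltaEntrainment:
    def test_convergence_by_ten_along_x(self):
        feat = dyad((120.0, 100.0), (110.0, 100.0))
        assert delta_entrainment(feat, LINE_1, 1) == pytest.approx(10.0 / np.sqrt(2), abs=1e-4)

    def test_no_change_is_zero(self):
        feat = dyad((120.0, 100.0), (120.0, 100.0))
        assert delta_entrainment(feat, LINE_1, 1) == 0.0

    def test_time_reversal_antisymmetry(self):
        fwd = delta_entrainment(dyad((120.0, 100.0), (110.0, 100.0)), LINE_1, 1)
        rev = delta_entrainment(dyad((110.0, 100.0), (120.0, 100.0)), LINE_1, 1)
        assert fwd == pytest.approx(-rev)

    def test_unusable_feature_rejected(self):
        feat = DyadFeatures("d", {1: (0, 0)}, {1: (0, 0)}, {1: False})
        with pytest.raises(ValidationError, match="not usable"):
            delta_entrainment(feat, LINE_1, 1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        s=st.tuples(st.floats(50, 400), st.floats(50, 400)),
        e=st.tuples(st.floats(50, 400), st.floats(50, 400)),
        t=st.floats(-50, 50),
        m=st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_translation_along_line_invariance(self, s, e, t, m):
        line = ReferenceLine(1.0) if m == 1.0 else ReferenceLine(
            0.5, halved_axis="partner" if m == 0.5 else "participant"
        )
        shift = (t, m * t)
        base = delta_entrainment(dyad(s, e), line, 1)
        moved = delta_entrainment(
            dyad((s[0] + shift[0], s[1] + shift[1]), (e[0] + shift[0], e[1] + shift[1])),
            line, 1,
        )
        assert moved == pytest.approx(base, abs=1e-8)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        s=st.tuples(st.floats(50, 400), st.floats(50, 400)),
        e=st.tuples(st.floats(50, 400), st.floats(50, 400)),
    )
    def test_axis_exchange_with_reciprocal_slope_preserves_delta(self, s, e):
        d_fwd = delta_entrainment(dyad(s, e), LINE_HALF, 1)
        swapped = dyad((s[1], s[0]), (e[1], e[0]))
        d_swap = delta_entrainment(
            swapped, ReferenceLine(0.5, halved_axis="participant"), 1
        )
        assert d_fwd == pytest.approx(d_swap, abs=1e-9)


class TestResponsibilityAndContributions:
    def test_worked_four_six_split(self):
        feat = dyad((120.0, 100.0), (116.0, 106.0))  # d3 = 4, d4 = 6
        r1, r2, degenerate = speaker_responsibility(feat, 1)
        assert (r1, r2) == pytest.approx((0.4, 0.6))
        assert not degenerate

    def test_single_mover(self):
        feat = dyad((120.0, 100.0), (115.0, 100.0))
        r1, r2, _ = speaker_responsibility(feat, 1)
        assert (r1, r2) == (1.0, 0.0)

    def test_no_motion_falls_back_to_even_split(self):
        feat = dyad((120.0, 100.0), (120.0, 100.0))
        r1, r2, degenerate = speaker_responsibility(feat, 1)
        assert (r1, r2) == (0.5, 0.5)
        assert degenerate

    @pytest.mark.parametrize(
        "delta,resp,expected",
        [(-10.0, 0.4, -0.4), (10.0, 0.4, 0.4), (0.0, 0.7, 0.0)],
    )
    def test_signed_contribution(self, delta, resp, expected):
        assert signed_contribution(delta, resp) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "delta,resp,expected", [(10.0, 0.4, 4.0), (-10.0, 0.4, -4.0)]
    )
    def test_adjusted_contribution(self, delta, resp, expected):
        assert adjusted_contribution(delta, resp) == pytest.approx(expected)

    def test_out_of_range_responsibility_rejected(self):
        with pytest.raises(ValidationError):
            signed_contribution(1.0, 1.2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        s=st.tuples(st.floats(50, 400), st.floats(50, 400)),
        e=st.tuples(st.floats(50, 400), st.floats(50, 400)),
    )
    def test_sums_resp_one_and_adjusted_delta(self, s, e):
        res = compute_entrainment(dyad(s, e), LINE_1, 1)
        assert res.resp1 + res.resp2 == pytest.approx(1.0)
        assert res.adjusted1 + res.adjusted2 == pytest.approx(res.delta_ent, abs=1e-9)
        assert abs(res.contribution1) <= 1.0 and abs(res.contribution2) <= 1.0
        assert res.d1 >= 0 and res.d2 >= 0 and res.d3 >= 0 and res.d4 >= 0


class TestClassification:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.5, "maintenance"), (-6.0, "divergence"), (1.0, "maintenance"),
         (-1.0, "maintenance"), (1.0001, "convergence"), (3.0, "convergence")],
    )
    def test_band(self, delta, expected):
        assert classify_entrainment(delta) == expected

    def test_custom_band(self):
        assert classify_entrainment(1.5, maintenance_band=2.0) == "maintenance"


class TestCountConverging:
    def test_strictly_greater_than_two(self):
        count, prop = count_converging([3.0, -6.0, 2.0, 2.1])
        assert count == 2
        assert prop == pytest.approx(0.5)

    def test_all_zero(self):
        assert count_converging([0.0, 0.0, 0.0])[0] == 0

    def test_quarter_proportion(self):
        deltas = [3.0, 2.5, 4.0] + [0.0] * 9
        count, prop = count_converging(deltas)
        assert count == 3
        assert prop == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            count_converging([])


class TestMinOverLines:
    def test_takes_the_closer_line(self):
        # point near the half-matching line but scored with l1 selected
        feat = dyad((200.0, 101.0), (200.0, 100.0))
        res = compute_entrainment(feat, LINE_1, 1, min_over_lines=True)
        assert res.d1 == pytest.approx(
            point_to_line_distance((200.0, 101.0), LINE_HALF)
        )
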