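"""Contour correspondence, averaging, control points and Δ statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachmap.averaging import (
    ContourAverager,
    ControlPoint,
    bbox_metrics,
    control_points,
    correspond_loops,
    delta_interval,
    mean_contour,
    mean_delta,
    round_half_away,
)
from reachmap.errors import ConfigError, DataQualityError
from reachmap.extraction import Loop, ResampledLoop, canonicalize, resample_loop


def _shift(loop, dx, dy):
    out = ResampledLoop(loop.vertices + np.array([dx, dy]))
    out.area = loop.area
    return out


@settings(max_examples=200, derandomize=True)
@given(
    dx=st.floats(min_value=0, max_value=1e6, allow_nan=False),
    dy=st.floats(min_value=0, max_value=1e6, allow_nan=False),
)
def test_delta_closed_form(dx, dy):
    """Δ equals twice the Euclidean norm of the half-width pair."""
    assert delta_interval(dx, dy) == pytest.approx(2.0 * np.hypot(dx, dy))


def test_delta_examples_and_errors():
    assert round_half_away(delta_interval(194, 60)) == 406
    assert delta_interval(0, 0) == 0
    assert delta_interval(3, 4) == 10
    with pytest.raises(ConfigError):
        delta_interval(-1, 2)


def test_identity_pairing_for_identical_loops(circle_factory):
    loops = [circle_factory(200.0) for _ in range(3)]
    ref, matched = correspond_loops(loops)
    for j in range(3):
        np.testing.assert_allclose(matched[j], loops[ref].vertices)


def test_concentric_circles_match_radially(circle_factory):
    inner, outer = circle_factory(100.0), circle_factory(300.0)
    _, matched = correspond_loops([inner, outer])
    ang = [np.arctan2(m[:, 1], m[:, 0]) for m in matched]
    dtheta = np.abs(np.angle(np.exp(1j * (ang[0] - ang[1]))))
    assert dtheta.max() < 2 * np.pi / 100 + 1e-9  # within one resampling step


def test_mixed_areas_rejected(circle_factory):
    a, b = circle_factory(100.0), circle_factory(120.0)
    a.area, b.area = "AoC", "AoA"
    with pytest.raises(DataQualityError, match="mixed areas"):
        correspond_loops([a, b])


def test_mean_of_identical_loops_is_identity(circle_factory):
    loops = [circle_factory(150.0) for _ in range(30)]
    mc = mean_contour(loops)
    np.testing.assert_allclose(mc.mean_points, loops[0].vertices, atol=1e-9)
    assert mc.dx.max() == pytest.approx(0.0, abs=1e-9)
    assert mc.n == 30


def test_concentric_circles_average_to_middle_circle(circle_factory):
    mc = mean_contour([circle_factory(100.0), circle_factory(300.0)])
    r = np.hypot(*mc.mean_points.T)
    assert r == pytest.approx(200.0, abs=2.0)


def test_offset_loops_average_to_midpoint(circle_factory):
    """For offsets below the vertex spacing, nearest-vertex matching is the
    identity pairing and the mean contour sits exactly at the midpoint."""
    d = 1.0  # vertex spacing of the 100-gon is 2*pi*100/100 ~ 6.3
    left = _shift(circle_factory(100.0), -d, 0)
    right = _shift(circle_factory(100.0), +d, 0)
    mc = mean_contour([left, right])
    assert mc.mean_points[:, 0].mean() == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(
        mc.mean_points, circle_factory(100.0).vertices, atol=1e-9
    )


def test_translation_equivariance(circle_factory):
    rng = np.random.default_rng(5)
    loops = [
        _shift(circle_factory(100.0 + 10 * k), *rng.normal(0, 5, 2)) for k in range(5)
    ]
    mc = mean_contour(loops)
    v = np.array([37.0, -11.0])
    shifted = mean_contour([_shift(lp, *v) for lp in loops])
    np.testing.assert_allclose(shifted.mean_points, mc.mean_points + v, atol=1e-9)
    np.testing.assert_allclose(shifted.dx, mc.dx, atol=1e-9)
    np.testing.assert_allclose(shifted.dy, mc.dy, atol=1e-9)


def test_permutation_invariance(circle_factory):
    loops = [circle_factory(100.0 + 7 * k) for k in range(6)]
    mc = mean_contour(loops)
    mc_perm = mean_contour(loops[::-1])
    np.testing.assert_allclose(mc_perm.mean_points, mc.mean_points)


def test_single_loop_rejected(circle_factory):
    with pytest.raises(DataQualityError):
        mean_contour([circle_factory(100.0)])


def test_control_points_of_rectangle():
    """Extremes of an axis-aligned rectangle are its side coordinates."""
    rect = Loop(
        np.array([[-260.0, 40.0], [92.0, 40.0], [92.0, 689.0], [-260.0, 689.0]])
    )
    loops = [resample_loop(canonicalize(rect), 100) for _ in range(3)]
    mc = mean_contour(loops)
    cps = control_points(mc)
    assert cps[0].x == pytest.approx(92.0)
    assert cps[1].x == pytest.approx(-260.0)
    assert cps[2].y == pytest.approx(689.0)
    assert cps[3].y == pytest.approx(40.0)
    length, height = bbox_metrics(cps)
    assert (length, height) == (pytest.approx(352.0), pytest.approx(649.0))


def test_control_points_of_circle(circle_factory):
    mc = mean_contour([circle_factory(200.0) for _ in range(2)])
    cps = control_points(mc)
    step = 2 * np.pi * 200 / 100
    assert cps[0].x == pytest.approx(200.0, abs=step)
    assert cps[1].x == pytest.approx(-200.0, abs=step)
    assert cps[2].y == pytest.approx(200.0, abs=step)
    assert cps[3].y == pytest.approx(-200.0, abs=step)


def _cp(delta):
    return ControlPoint("A", 0, 0, 0, 0, float(delta), 30, 0.05)


def test_mean_delta_rounding():
    assert mean_delta([_cp(225), _cp(406), _cp(288), _cp(111)]) == 258
    assert mean_delta([_cp(108), _cp(97), _cp(109), _cp(76)]) == 98
    assert mean_delta([_cp(0)] * 4) == 0


def test_bbox_degenerate():
    cps = [ControlPoint("A", 5, 5, 0, 0, 0, 30, 0.05)] * 4
    assert bbox_metrics(cps) == (0.0, 0.0)


def test_averager_estimator(circle_factory):
    loops = [circle_factory(100.0), circle_factory(300.0)]
    avg = ContourAverager(p=0.05).fit(loops)
    assert avg.mean_contour_.n == 2
    assert len(avg.control_points_) == 4
    length, height = avg.bbox()
    assert length == pytest.approx(400.0, rel=0.02)
    assert avg.get_params() == {"p": 0.05}
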