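"""Wheelchair geometry model, polygon subtraction and map composition."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from reachmap.averaging import ContourAverager
from reachmap.composition import (
    ReachMapComposer,
    WheelchairGeometry,
    ZonePolygon,
    anthropometric_checks,
    compose_map,
    export_map_points,
    geometry_from_config,
    subtract_regions,
)
from reachmap.errors import ConfigError, DataQualityError
from reachmap.extraction import extract_resampled
from reachmap.simulate import (
    AreaKind,
    KinematicChain,
    analytic_forward_extent,
    make_cohort,
)


@pytest.fixture(scope="module")
def noiseless_contours():
    """Mean contours of a zero-noise cohort sharing one 50th-pct chain."""
    cohort = make_cohort(4, 2, master_seed=11, n_samples=300, noise_sd=0.0, length_cv=0.0)
    contours = {}
    for area, clouds in cohort.items():
        loops = [extract_resampled(c) for c in clouds]
        contours[area] = ContourAverager().fit(loops).mean_contour_
    return contours


def test_default_geometry_reproduces_reference_features():
    g = geometry_from_config({})
    assert (g.fdl, g.ful, g.arl) == (-30.0, 170.0, 420.0)
    assert (g.sl, g.sh, g.sh_halfwidth) == (190.0, 730.0, 30.0)
    assert (g.sbv_x, g.wheel_radius) == (80.0, 300.0)


def test_geometry_overrides_and_ordering():
    g = geometry_from_config({"SL": 240})
    assert g.sl == 240.0 and g.arl == 420.0
    with pytest.raises(ConfigError):
        geometry_from_config({"ful": -40})  # FUL <= FDL
    with pytest.raises(ConfigError):
        geometry_from_config({"bogus": 1})


def test_wheel_disc_discretization():
    g = WheelchairGeometry()
    disc = g.wheel_disc()
    assert len(disc.exterior.coords) == 361
    assert disc.area == pytest.approx(np.pi * 300**2, rel=1e-3)


def test_subtract_disjoint_is_identity(unit_square):
    sq = ZonePolygon("z", unit_square.vertices)
    far = Point(100, 100).buffer(1)
    out = subtract_regions(sq, [far])
    assert out.area == pytest.approx(1.0)


def test_subtract_concentric_discs_gives_annulus_area():
    big = Point(0, 0).buffer(2.0, quad_segs=256)
    small = Point(0, 0).buffer(1.0, quad_segs=256)
    out = subtract_regions(big, [small])
    assert out.area == pytest.approx(3 * np.pi, rel=1e-3)
    assert len(out.holes) == 1


def test_subtract_self_is_empty(unit_square):
    sq = ZonePolygon("z", unit_square.vertices)
    out = subtract_regions(sq, [sq])
    assert out.area == 0.0


def test_compose_requires_all_areas(noiseless_contours):
    partial = {AreaKind.AoC: noiseless_contours[AreaKind.AoC]}
    with pytest.raises(DataQualityError, match="missing areas"):
        compose_map(partial)


def test_composed_zones_disjoint_and_wheel_free(noiseless_contours):
    m = compose_map(noiseless_contours)
    labels = [z.label for z in m.zones]
    assert labels == ["AoC", "AoA", "AoR"]
    wb = m.geometry.wheel_disc()
    for i, zi in enumerate(m.zones):
        assert zi.polygon.intersection(wb).area < 1.0
        for zj in m.zones[i + 1 :]:
            assert zi.polygon.intersection(zj.polygon).area < 1.0
    # all zone mass sits above the lower frame level
    for z in m.zones:
        assert z.ring[:, 1].min() >= m.geometry.fdl - 1e-6


def test_bands_adjacent_from_nested_workspaces(noiseless_contours):
    """AoA band touches the AoC band it was carved around (Fig-9 structure)."""
    m = compose_map(noiseless_contours)
    aoc, aoa, aor = (m.zone(k) for k in ("AoC", "AoA", "AoR"))
    assert aoc.area > 0 and aoa.area > 0 and aor.area > 0
    assert aoc.polygon.buffer(1.0).intersects(aoa.polygon)
    assert aoa.polygon.buffer(1.0).intersects(aor.polygon)


def test_geometry_shift_equivariance(noiseless_contours):
    """Rigidly shifting chair and contours translates the composed map."""
    shift = np.array([60.0, -25.0])
    base = compose_map(noiseless_contours)
    moved_contours = {}
    for area, mc in noiseless_contours.items():
        import dataclasses

        moved_contours[area] = dataclasses.replace(
            mc, mean_points=mc.mean_points + shift
        )
    moved = compose_map(moved_contours, base.geometry.translate(*shift))
    for z0, z1 in zip(base.zones, moved.zones):
        p0 = Polygon(z0.ring + shift)
        assert p0.symmetric_difference(Polygon(z1.ring)).area < 1.0


def test_export_round_trip_area(noiseless_contours):
    m = compose_map(noiseless_contours)
    df = export_map_points(m, n_points=40)
    assert set(df["zone"]) == {"AoC", "AoA", "AoR"}
    for z in m.zones:
        ring = df[df["zone"] == z.label][["x_mm", "y_mm"]].to_numpy()
        assert abs(Polygon(ring).area - z.area) <= 0.02 * z.area + 1.0


def test_export_square_corners():
    sq = ZonePolygon("AoC", np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]))
    m = ReachMapComposer()
    from reachmap.composition import ReachMap

    reach = ReachMap(zones=[sq], geometry=WheelchairGeometry())
    df = export_map_points(reach, n_points=4)
    assert len(df) == 4


def test_anthropometric_checks_synthetic(noiseless_contours):
    chain = KinematicChain()
    checks = anthropometric_checks(noiseless_contours, WheelchairGeometry())
    expected_arm = abs(analytic_forward_extent(chain, AreaKind.AoA))
    assert checks["arm_forearm_reach_mm"] == pytest.approx(expected_arm, rel=0.02)
    expected_fore = abs(analytic_forward_extent(chain, AreaKind.AoC)) + 80.0
    assert checks["forearm_reach_mm"] == pytest.approx(expected_fore, rel=0.02)


def test_anthropometric_checks_landmarks():
    out = anthropometric_checks(
        geometry=WheelchairGeometry(),
        landmarks={"arm_forearm_x": -753.0, "forearm_x": -361.0},
    )
    assert out["arm_forearm_reach_mm"] == 753.0
    assert out["forearm_reach_mm"] == 441.0


def test_composer_estimator(noiseless_contours):
    comp = ReachMapComposer(geometry_config={"sl": 200}).fit(noiseless_contours)
    assert comp.geometry_.sl == 200.0
    assert len(comp.map_.zones) == 3
    assert comp.get_params() == {"geometry_config": {"sl": 200}}
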