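"""Per-tree features: closed forms, oracles, invariances."""

import math

import numpy as np
import pytest

import dendrofire as df
from dendrofire.morphology import BASAL, Morphology, SwcPoint
from dendrofire.morphometrics import ElectrotonicConstants


def _straight_cell(seg_specs):
    """soma + chain/fork cells from (length, radius, parent_section) specs."""
    pts = [SwcPoint(1, 1, 0.0, 0.0, 0.0, 8.0, -1)]
    tails = []
    nid = 2
    dirs = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1)]
    for i, (length, radius, parent) in enumerate(seg_specs):
        par = pts[0] if parent == -1 else tails[parent]
        d = np.array(dirs[i % len(dirs)], float)
        d = d / np.linalg.norm(d)
        pos = par.xyz + d * length
        p = SwcPoint(nid, 3, *map(float, pos), radius, par.id)
        pts.append(p)
        tails.append(p)
        nid += 1
    return Morphology.from_points(pts)


def test_total_length_sums_sections():
    # two separate stems of 100 and 50 um
    m = _straight_cell([(100.0, 1.0, -1), (50.0, 1.0, -1)])
    assert df.total_length(m, structure=BASAL) == pytest.approx(150.0)


def test_total_length_empty_tree_warns():
    m = Morphology.from_points([SwcPoint(1, 1, 0, 0, 0, 8.0, -1)])
    with pytest.warns(UserWarning, match="empty"):
        assert df.total_length(m, structure=BASAL) == 0.0


def test_total_length_matches_pointwise_oracle(random_trees):
    for m in random_trees:
        brute = sum(
            math.dist(p.xyz, m.point(p.parent_id).xyz)
            for p in m.points
            if p.parent_id != -1 and p.structure == BASAL
        )
        assert df.total_length(m, structure=BASAL) == pytest.approx(
            brute, rel=1e-12
        )


def test_volume_closed_forms():
    one = _straight_cell([(100.0, 1.0, -1)])
    assert df.volume(one, structure=BASAL) == pytest.approx(
        100 * math.pi, rel=1e-12
    )
    two = _straight_cell([(100.0, 1.0, -1), (50.0, 0.5, -1)])
    expected = math.pi * (100 * 1.0**2 + 50 * 0.5**2)
    assert df.volume(two, structure=BASAL) == pytest.approx(
        expected, rel=1e-12
    )
    assert expected == pytest.approx(353.429, abs=5e-4)


def test_median_diameter_conventions():
    # separate stems -> one diameter value per section
    m3 = _straight_cell([(10, 0.5, -1), (10, 1.0, -1), (10, 4.0, -1)])
    assert df.median_diameter(m3, structure=BASAL) == pytest.approx(2.0)
    m4 = _straight_cell(
        [(10, 0.5, -1), (10, 1.0, -1), (10, 1.5, -1), (10, 2.0, -1)]
    )
    assert df.median_diameter(m4, structure=BASAL) == pytest.approx(2.5)


def test_median_diameter_matches_sort_and_pick(random_trees):
    for m in random_trees:
        secs = m.sections_of(BASAL)
        diams = sorted(s.diameter for s in secs)
        n = len(diams)
        expected = (
            diams[n // 2] if n % 2 else (diams[n // 2 - 1] + diams[n // 2]) / 2
        )
        assert df.median_diameter(m, structure=BASAL) == pytest.approx(
            expected, rel=1e-12
        )


def test_median_diameter_empty_tree_errors():
    m = Morphology.from_points([SwcPoint(1, 1, 0, 0, 0, 8.0, -1)])
    with pytest.raises(ValueError, match="empty"):
        df.median_diameter(m, structure=BASAL)


def test_branch_number_small_cases(fixtures):
    stem = _straight_cell([(100.0, 1.0, -1)])
    assert df.branch_number(stem, structure=BASAL) == 1
    fork = _straight_cell([(50, 1.0, -1), (30, 0.8, 0), (30, 0.8, 0)])
    assert df.branch_number(fork, structure=BASAL) == 3
    assert df.branch_number(fixtures["y_tree"], structure=BASAL) == 3


def test_branch_number_is_2t_minus_1_per_stem(random_trees):
    # strictly binary generator: branches = 2*tips - 1 for each stem
    for m in random_trees:
        secs = m.sections_of(BASAL)
        tails = {s.points[-1].id for s in secs}
        heads = {s.points[0].id for s in secs}
        tips = len(tails - heads)
        stems = len(m.stems(BASAL))
        assert df.branch_number(m, structure=BASAL) == 2 * tips - stems


def test_mep_unit_lambda_stick(fixtures, consts):
    lam = consts.length_constant_um(1.0)
    assert lam == pytest.approx(845.2, abs=0.1)
    assert df.mep(fixtures["unit_lambda_stick"], structure=BASAL) == (
        pytest.approx(1.0, abs=1e-9)
    )


def test_mep_symmetric_y_tree(fixtures):
    # stem 0.2 lambda + two identical 0.3 lambda children -> MEP 0.5
    assert df.mep(fixtures["y_tree"], structure=BASAL) == pytest.approx(
        0.5, rel=1e-9
    )


def test_mep_matches_bruteforce_tip_paths(random_trees, consts):
    for m in random_trees:
        secs = m.sections_of(BASAL)
        by_tail = {s.points[-1].id: i for i, s in enumerate(secs)}
        heads = {s.points[0].id for s in secs}
        lam = [consts.length_constant_um(s.radius) for s in secs]
        tips = [
            i for i, s in enumerate(secs) if s.points[-1].id not in heads
        ]
        paths = []
        for i in tips:
            total = 0.0
            j = i
            while j is not None:
                total += secs[j].length / lam[j]
                j = by_tail.get(secs[j].points[0].id)
            paths.append(total)
        brute = float(np.mean(paths))
        assert df.mep(m, structure=BASAL) == pytest.approx(brute, abs=1e-12)


def test_scaling_radii_volume_and_mep(random_trees):
    m = random_trees[0]
    doubled = Morphology.from_points(
        [
            p if p.parent_id == -1 else
            type(p)(p.id, p.structure, p.x, p.y, p.z, 2 * p.radius,
                    p.parent_id)
            for p in m.points
        ]
    )
    assert df.volume(doubled, structure=BASAL) == pytest.approx(
        4 * df.volume(m, structure=BASAL), rel=1e-12
    )
    assert df.mep(doubled, structure=BASAL) == pytest.approx(
        df.mep(m, structure=BASAL) / math.sqrt(2), rel=1e-9
    )


def test_features_invariant_under_rigid_motion(random_trees):
    theta = 0.7
    rot = np.array(
        [
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    shift = np.array([12.0, -3.0, 40.0])
    m = random_trees[1]
    moved = Morphology.from_points(
        [
            type(p)(p.id, p.structure, *map(float, rot @ p.xyz + shift),
                    p.radius, p.parent_id)
            for p in m.points
        ]
    )
    fa = df.feature_vector(m, structure=BASAL).as_dict()
    fb = df.feature_vector(moved, structure=BASAL).as_dict()
    for key, val in fa.items():
        assert fb[key] == pytest.approx(val, rel=1e-9)


def test_electrotonic_constants_validate():
    with pytest.raises(ValueError):
        ElectrotonicConstants(r_m=-1.0)
    with pytest.raises(ValueError):
        ElectrotonicConstants().length_constant_um(0.0)
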