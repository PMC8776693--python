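"""Texture matrices vs independent brute-force enumeration oracles."""

import numpy as np
import pytest

from ofrad.image import DiscretizedVolume
from ofrad.texture import (
    DIRECTIONS_13,
    build_glcm,
    build_glcm_per_direction,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_correlation,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

# ---------------------------------------------------------------------------
# brute-force oracles (pure python loops)
# ---------------------------------------------------------------------------


def oracle_glcm_direction(labels, ng, off):
    m = np.zeros((ng, ng))
    nx, ny, nz = labels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = labels[x, y, z]
                if a == 0:
                    continue
                for sgn in (1, -1):
                    u, v, w = x + sgn * off[0], y + sgn * off[1], z + sgn * off[2]
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz:
                        b = labels[u, v, w]
                        if b > 0:
                            m[a - 1, b - 1] += 1
    return m


def oracle_glcm_merged(labels, ng):
    return sum(oracle_glcm_direction(labels, ng, off) for off in DIRECTIONS_13)


def oracle_runs(labels, off):
    """All maximal runs along one direction as (level, length) pairs."""
    nx, ny, nz = labels.shape

    def inside(p):
        return 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz

    runs = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lv = labels[x, y, z]
                if lv == 0:
                    continue
                prev = (x - off[0], y - off[1], z - off[2])
                if inside(prev) and labels[prev] == lv:
                    continue  # not the start of its run
                length = 1
                cur = (x + off[0], y + off[1], z + off[2])
                while inside(cur) and labels[cur] == lv:
                    length += 1
                    cur = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                runs.append((lv, length))
    return runs


def oracle_glrlm(labels, ng):
    runs = []
    for off in DIRECTIONS_13:
        runs.extend(oracle_runs(labels, off))
    rmax = max((r for _, r in runs), default=1)
    m = np.zeros((ng, rmax))
    for lv, r in runs:
        m[lv - 1, r - 1] += 1
    return m


def oracle_zones(labels):
    """Flood-fill 26-connected zones -> list of (level, size)."""
    nx, ny, nz = labels.shape
    seen = np.zeros(labels.shape, dtype=bool)
    zones = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if labels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                lv = labels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                if dx == dy == dz == 0:
                                    continue
                                u, v, w = cx + dx, cy + dy, cz + dz
                                if (
                                    0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                                    and not seen[u, v, w] and labels[u, v, w] == lv
                                ):
                                    seen[u, v, w] = True
                                    stack.append((u, v, w))
                zones.append((lv, size))
    return zones


def oracle_glszm(labels, ng):
    zones = oracle_zones(labels)
    smax = max((s for _, s in zones), default=1)
    m = np.zeros((ng, smax))
    for lv, s in zones:
        m[lv - 1, s - 1] += 1
    return m


def oracle_ngtdm(labels, ng):
    nx, ny, nz = labels.shape
    s = np.zeros(ng)
    counts = np.zeros(ng)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lv = labels[x, y, z]
                if lv == 0:
                    continue
                counts[lv - 1] += 1
                nb = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if dx == dy == dz == 0:
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and labels[u, v, w] > 0:
                                nb.append(labels[u, v, w])
                if nb:
                    s[lv - 1] += abs(lv - sum(nb) / len(nb))
    p = counts / counts.sum()
    return s, p


def _dvol(labels, ng):
    return DiscretizedVolume(np.asarray(labels, dtype=np.int32), ng)


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


class TestWorkedExamples:
    def test_constant_roi_correlation_zero_by_convention(self):
        d = _dvol(np.ones((3, 3, 3)), 4)
        feats = glcm_features(d)
        assert feats["GCorrelation1"] == 0.0
        assert feats["GCorrelation"] == 0.0

    def test_striped_volume_has_unit_correlation_along_stripe_axis(self):
        labels = np.zeros((6, 4, 4), dtype=np.int32)
        labels[0::2] = 1
        labels[1::2] = 2
        d = _dvol(labels, 2)
        per_dir = build_glcm_per_direction(d)
        # direction (0,1,0): constant along stripes -> same-level pairs only
        idx_along = DIRECTIONS_13.index((0, 1, 0))
        assert glcm_correlation(per_dir[idx_along]) == pytest.approx(1.0)
        oracle = oracle_glcm_direction(labels, 2, (0, 1, 0))
        assert np.array_equal(per_dir[idx_along] * oracle.sum(), oracle)

    def test_glrlm_single_row_example(self):
        # one 1x1x3 row [1,1,2]: along (0,0,1) runs are (1,2) and (2,1)
        labels = np.array([[[1, 1, 2]]], dtype=np.int32)
        runs = oracle_runs(labels, (0, 0, 1))
        assert sorted(runs) == [(1, 2), (2, 1)]
        m = np.zeros((2, 2))
        for lv, r in runs:
            m[lv - 1, r - 1] += 1
        assert glrlm_features(m)["RLV"] == pytest.approx(0.25)

    def test_all_distinct_labels_rlv_zero(self):
        labels = np.arange(1, 9, dtype=np.int32).reshape(2, 2, 2)
        assert glrlm_features(build_glrlm(_dvol(labels, 8)))["RLV"] == 0.0

    def test_glszm_single_zone_sums(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[0, 0, :2] = 1
        labels[0, 1, :2] = 1  # one 26-connected zone of 4 voxels at level 1
        m = build_glszm(_dvol(labels, 2))
        f = glszm_features(m)
        assert f["LZE"] == pytest.approx(16.0)
        assert f["LGZE"] == pytest.approx(1.0)
        assert f["SZLGE"] == pytest.approx(1.0 / 16.0)
        assert f["LZHGE"] == pytest.approx(16.0)
        assert f["ZLV"] == 0.0 and f["GLV"] == 0.0

    def test_all_singleton_zones(self):
        # isolated voxels of alternating levels, no 26-adjacency
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[0, 0, 3] = 2
        labels[3, 3, 0] = 1
        f = glszm_features(build_glszm(_dvol(labels, 2)))
        assert f["LZE"] == pytest.approx(1.0)
        assert f["ZLV"] == 0.0

    def test_ngtdm_constant_roi_busyness_zero(self):
        s, p = build_ngtdm(_dvol(np.ones((3, 3, 3)), 2))
        assert ngtdm_features(s, p)["Busyness"] == 0.0

    def test_ngtdm_checkerboard_matches_oracle(self):
        x, y, z = np.indices((3, 3, 3))
        labels = ((x + y + z) % 2 + 1).astype(np.int32)
        s, p = build_ngtdm(_dvol(labels, 2))
        so, po = oracle_ngtdm(labels, 2)
        assert np.allclose(s, so)
        assert np.allclose(p, po)
        assert ngtdm_features(s, p)["Busyness"] == pytest.approx(
            float((po * so).sum())
            / sum(abs((i + 1) * po[i] - (j + 1) * po[j]) for i in range(2) for j in range(2))
        )


# ---------------------------------------------------------------------------
# randomized oracle equivalence (>= 100 instances)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("trial", range(10))
def test_oracle_equivalence_random_volumes(trial):
    """GLCM / GLRLM / GLSZM / NGTDM match brute-force enumeration exactly on
    random small volumes with random ROI holes (10 trials x 12 volumes)."""
    rng = np.random.default_rng(1000 + trial)
    for _ in range(12):
        ng = int(rng.integers(2, 5))
        shape = tuple(rng.integers(2, 7, 3))
        labels = rng.integers(1, ng + 1, shape).astype(np.int32)
        labels[rng.random(shape) < 0.25] = 0  # voxels outside the ROI
        if not (labels > 0).any():
            labels.flat[0] = 1
        d = _dvol(labels, ng)

        merged = build_glcm(d)
        om = oracle_glcm_merged(labels, ng)
        if om.sum() > 0:
            assert np.allclose(merged, om / om.sum())
        for off, got in zip(DIRECTIONS_13, build_glcm_per_direction(d)):
            o = oracle_glcm_direction(labels, ng, off)
            assert np.allclose(got * max(o.sum(), 1), o)

        grl = build_glrlm(d)
        org = oracle_glrlm(labels, ng)
        assert grl.shape == org.shape
        assert np.array_equal(grl, org)

        gsz = build_glszm(d)
        osz = oracle_glszm(labels, ng)
        assert gsz.shape == osz.shape
        assert np.array_equal(gsz, osz)

        s, p = build_ngtdm(d)
        so, po = oracle_ngtdm(labels, ng)
        assert np.allclose(s, so, atol=1e-10)
        assert np.allclose(p, po, atol=1e-12)


@pytest.mark.parametrize("axes", [(0, 1), (0, 2), (1, 2)])
def test_direction_pooled_features_rotation_invariant(axes):
    """Rotating the volume 90 degrees leaves direction-pooled statistics
    unchanged (the 13-direction set is closed under axis rotations)."""
    rng = np.random.default_rng(42)
    labels = rng.integers(0, 4, (6, 6, 6)).astype(np.int32)
    d1 = _dvol(labels, 3)
    d2 = _dvol(np.rot90(labels, k=1, axes=axes).copy(), 3)
    assert glcm_features(d1)["GCorrelation1"] == pytest.approx(glcm_features(d2)["GCorrelation1"])
    assert glrlm_features(build_glrlm(d1))["RLV"] == pytest.approx(
        glrlm_features(build_glrlm(d2))["RLV"]
    )
    f1 = glszm_features(build_glszm(d1))
    f2 = glszm_features(build_glszm(d2))
    assert f1 == pytest.approx(f2)
    s1, p1 = build_ngtdm(d1)
    s2, p2 = build_ngtdm(d2)
    assert ngtdm_features(s1, p1)["Busyness"] == pytest.approx(ngtdm_features(s2, p2)["Busyness"])
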