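"""Geometric metrics against explicit-loop brute-force oracles."""

import numpy as np
import pytest

from avmseg import metrics as mt
from avmseg.io_formats import BinaryMask3D
from avmseg.metrics import ConfusionCounts


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def loop_confusion(a, b):
    tp = fp = fn = tn = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                av, bv = bool(a[i, j, k]), bool(b[i, j, k])
                tp += av and bv
                fp += av and not bv
                fn += bv and not av
                tn += not av and not bv
    return tp, fp, fn, tn


def loop_surface(mask):
    pts = []
    s = mask.shape
    for i in range(s[0]):
        for j in range(s[1]):
            for k in range(s[2]):
                if not mask[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (not (0 <= ni < s[0] and 0 <= nj < s[1]
                             and 0 <= nk < s[2])) or not mask[ni, nj, nk]:
                        pts.append((i, j, k))
                        break
    return np.array(pts, dtype=float)


def loop_directed_hd(pa, pb):
    best = 0.0
    for a in pa:
        dmin = min(float(np.sqrt(((a - b) ** 2).sum())) for b in pb)
        best = max(best, dmin)
    return best


def random_mask(rng, shape=(8, 8, 8), p=0.3):
    while True:
        m = (rng.random(shape) < p).astype(np.uint8)
        if m.any():
            return m


# ---------------------------------------------------------------------------
# Confusion-count metrics
# ---------------------------------------------------------------------------

def test_confusion_counts_match_triple_loop(rng):
    for _ in range(20):
        a, b = random_mask(rng), random_mask(rng)
        c = mt.confusion_counts(a, b)
        assert (c.tp, c.fp, c.fn, c.tn) == loop_confusion(a, b)


def test_confusion_counts_trivial_cases():
    b = np.zeros((4, 4, 4), np.uint8)
    b[:2, 0, 0] = 1  # 2 voxels... make 7
    b = np.zeros((4, 4, 4), np.uint8)
    b.flat[:7] = 1
    c = mt.confusion_counts(np.zeros_like(b), b)
    assert (c.tp, c.fn) == (0, 7)
    c2 = mt.confusion_counts(b, b)
    assert c2.fp == 0 and c2.fn == 0
    with pytest.raises(ValueError):
        mt.confusion_counts(b, np.zeros((5, 4, 4)))


@pytest.mark.parametrize("counts, exp_dsc, exp_sens, exp_f2", [
    (ConfusionCounts(8, 2, 4, 100), 16 / 22, 8 / 12, 40 / 52),
    (ConfusionCounts(5, 0, 0, 10), 1.0, 1.0, 1.0),
])
def test_overlap_metric_closed_forms(counts, exp_dsc, exp_sens, exp_f2):
    assert mt.dsc(counts) == pytest.approx(exp_dsc, abs=1e-15)
    assert mt.sensitivity(counts) == pytest.approx(exp_sens, abs=1e-15)
    assert mt.f2(counts) == pytest.approx(exp_f2, abs=1e-15)


def test_f2_equals_dsc_for_symmetric_errors():
    # with fp == fn the recall weighting cancels: F2 = DSC analytically
    for tp, e in [(10, 3), (50, 7), (1, 1)]:
        c = ConfusionCounts(tp, e, e, 0)
        assert mt.f2(c) == pytest.approx(mt.dsc(c), abs=1e-12)


def test_dsc_monotone_in_overlap():
    # growing |A∩B| at fixed |A|,|B| must increase DSC
    vals = [mt.dsc(ConfusionCounts(tp, 10 - tp, 10 - tp, 0))
            for tp in range(1, 11)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_empty_mask_conventions():
    empty = ConfusionCounts(0, 0, 0, 64)
    assert mt.dsc(empty) == 1.0  # both empty: vacuous agreement
    pred_only = ConfusionCounts(0, 5, 0, 59)
    assert mt.dsc(pred_only) == 0.0
    assert mt.sensitivity(pred_only) == 0.0


# ---------------------------------------------------------------------------
# Surfaces and distances
# ---------------------------------------------------------------------------

def test_surface_points_enumerations():
    single = np.zeros((5, 5, 5), np.uint8)
    single[2, 2, 2] = 1
    assert len(mt.surface_points(single).points) == 1

    cube = np.zeros((5, 5, 5), np.uint8)
    cube[1:4, 1:4, 1:4] = 1
    assert len(mt.surface_points(cube).points) == 26  # all but the center

    rod = np.zeros((3, 3, 7), np.uint8)
    rod[1, 1, 1:6] = 1
    assert len(mt.surface_points(rod).points) == 5  # every rod voxel

    with pytest.raises(ValueError):
        mt.surface_points(np.zeros((3, 3, 3), np.uint8))


def test_surface_matches_loop_oracle(rng):
    for _ in range(10):
        m = random_mask(rng)
        got = mt.surface_points(m).points
        exp = loop_surface(m)
        assert sorted(map(tuple, got)) == sorted(map(tuple, exp))


def test_directed_hausdorff_single_pair():
    a = mt.SurfaceSet(np.array([[0.0, 0.0, 0.0]]))
    b = mt.SurfaceSet(np.array([[3.0, 0.0, 0.0]]))
    assert mt.directed_hausdorff(a, b) == pytest.approx(3.0, abs=1e-15)
    assert mt.hausdorff(a, a) == 0.0


def test_distance_metrics_match_loop_oracle(rng):
    for _ in range(10):
        pa = rng.random((rng.integers(2, 20), 3)) * 10
        pb = rng.random((rng.integers(2, 20), 3)) * 10
        a, b = mt.SurfaceSet(pa), mt.SurfaceSet(pb)
        hab, hba = loop_directed_hd(pa, pb), loop_directed_hd(pb, pa)
        assert mt.directed_hausdorff(a, b) == pytest.approx(hab, abs=1e-12)
        assert mt.hausdorff(a, b) == pytest.approx(max(hab, hba), abs=1e-12)
        assert mt.hausdorff(a, b) == mt.hausdorff(b, a)
        # the reported surface metric is the mean of the two directed maxima
        assert mt.mean_surface_distance(a, b) == pytest.approx(
            0.5 * (hab + hba), abs=1e-12)
        assert mt.mean_surface_distance(a, b) <= mt.hausdorff(a, b) + 1e-12


def test_msd_literal_differs_from_average_surface_distance():
    pa = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    pb = np.array([[0.0, 0, 0], [1.0, 0, 0], [7.0, 0, 0]])
    a, b = mt.SurfaceSet(pa), mt.SurfaceSet(pb)
    msd = mt.mean_surface_distance(a, b)     # (h(A,B)=1 + h(B,A)=5) / 2
    asd = mt.average_surface_distance(a, b)  # (0+0+1 + 0+0+5) / 6
    assert msd == pytest.approx(3.0)
    assert asd == pytest.approx(1.0)
    assert msd != pytest.approx(asd)


def test_anisotropic_spacing_scales_distances():
    m1 = np.zeros((6, 6, 6), np.uint8)
    m2 = np.zeros((6, 6, 6), np.uint8)
    m1[1, 1, 1] = 1
    m2[3, 1, 1] = 1
    iso = mt.hausdorff(mt.surface_points(m1, (1, 1, 1)),
                       mt.surface_points(m2, (1, 1, 1)))
    aniso = mt.hausdorff(mt.surface_points(m1, (2, 1, 1)),
                         mt.surface_points(m2, (2, 1, 1)))
    assert aniso == pytest.approx(2 * iso, abs=1e-12)


# ---------------------------------------------------------------------------
# WMT
# ---------------------------------------------------------------------------

def test_wmt_identity_and_empty_tract(rng):
    a = random_mask(rng)
    wm = random_mask(rng)
    assert mt.wmt(a, a, wm) == 0.0
    assert mt.wmt(a, a, np.zeros_like(a)) == 0.0


def test_wmt_fraction_example():
    # |A|=100 with 20 tract voxels inside; |B|=200 with 10 inside
    a = np.zeros((10, 10, 10), np.uint8)
    b = np.zeros((10, 10, 10), np.uint8)
    wm = np.zeros((10, 10, 10), np.uint8)
    a.flat[:100] = 1
    b.flat[:200] = 1
    wm.flat[:20] = 1            # 20 in A; also within B's first 200
    wm.flat[200:210] = 0        # keep B's count at 20 first, fix below
    # make B contain exactly 10 tract voxels: move 10 of them outside B
    wm.flat[:20] = 0
    wm.flat[:10] = 1            # 10 tract voxels inside both A and B
    wm.flat[990:1000] = 1       # 10 outside both
    a_frac, b_frac = 10 / 100, 10 / 200
    assert mt.wmt(a, b, wm) == pytest.approx(abs(a_frac - b_frac), abs=1e-15)


def test_wmt_target_vs_tract_normalizer():
    a = np.zeros((6, 6, 6), np.uint8)
    b = np.zeros((6, 6, 6), np.uint8)
    wm = np.zeros((6, 6, 6), np.uint8)
    a.flat[:40] = 1
    b.flat[20:80] = 1
    wm.flat[10:30] = 1
    in_a, in_b, nw = 20, 10, 20
    assert mt.wmt(a, b, wm, "target") == pytest.approx(
        abs(in_a / 40 - in_b / 60), abs=1e-15)
    assert mt.wmt(a, b, wm, "tract") == pytest.approx(
        abs(in_a / nw - in_b / nw), abs=1e-15)
    with pytest.raises(ValueError):
        mt.wmt(np.zeros_like(a), b, wm)


# ---------------------------------------------------------------------------
# Case / dataset evaluation
# ---------------------------------------------------------------------------

def test_evaluate_case_perfect_prediction(default_case):
    m = mt.evaluate_case(default_case.nidus_mask, default_case.nidus_mask,
                         default_case.tract_mask)
    assert (m.dsc, m.sensitivity, m.f2) == (1.0, 1.0, 1.0)
    assert m.hd_mm == 0.0 and m.msd_mm == 0.0 and m.wmt == 0.0


def test_evaluate_case_composition(rng):
    a, b, wm = random_mask(rng, (10, 10, 10)), random_mask(rng, (10, 10, 10)), \
        random_mask(rng, (10, 10, 10))
    rec = mt.evaluate_case(a, b, wm, spacing_mm=(1, 1, 1))
    c = mt.confusion_counts(a, b)
    sa, sb = mt.surface_points(a), mt.surface_points(b)
    assert rec.dsc == mt.dsc(c)
    assert rec.hd_mm == mt.hausdorff(sa, sb)
    assert rec.msd_mm == mt.mean_surface_distance(sa, sb)
    assert rec.wmt == mt.wmt(a, b, wm)


def test_evaluate_case_empty_prediction_flagged():
    truth = np.zeros((6, 6, 6), np.uint8)
    truth[2:4, 2:4, 2:4] = 1
    rec = mt.evaluate_case(np.zeros_like(truth), truth, None)
    assert rec.empty_prediction
    assert rec.dsc == 0.0 and np.isnan(rec.hd_mm)
    # nonempty prediction against empty truth: zero overlap, no distances
    swapped = mt.evaluate_case(truth, np.zeros_like(truth), None)
    assert swapped.dsc == 0.0 and np.isnan(swapped.hd_mm)
    # both empty: vacuous agreement, flagged
    both = mt.evaluate_case(np.zeros_like(truth), np.zeros_like(truth), None)
    assert both.dsc == 1.0 and both.empty_prediction


def test_summarize_mean_sd_hand_computed(rng):
    recs = [mt.CaseMetrics(0.8, 0.9, 0.85, 3.0, 1.0, 0.1),
            mt.CaseMetrics(0.6, 0.7, 0.65, 5.0, 2.0, 0.2),
            mt.CaseMetrics(0.7, 0.8, 0.75, 4.0, 1.5, 0.3)]
    df = mt.summarize(recs)
    assert len(df) == 4  # 3 cases + summary row
    assert df.iloc[-1]["dsc"] == pytest.approx(0.7)
    assert df.attrs["sd"]["dsc"] == pytest.approx(np.std([.8, .6, .7], ddof=1))
    assert df.iloc[-1]["hd_mm"] == pytest.approx(4.0)
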