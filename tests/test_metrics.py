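import numpy as np
import pytest

from fetseg import (
    DEFAULT_SCHEMA,
    EvalReport,
    aggregate_mean,
    asd,
    dsc,
    evaluate,
    hausdorff,
    report_table,
)
from fetseg.metrics import boundary_points, parse_report_table


def border_oracle(region):
    """Exhaustive pixel scan: a region pixel is border iff some 4-neighbour
    is outside the region or the pixel touches the image edge."""
    h, w = region.shape
    pts = []
    for y in range(h):
        for x in range(w):
            if not region[y, x]:
                continue
            if y in (0, h - 1) or x in (0, w - 1):
                pts.append((y, x))
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if not region[y + dy, x + dx]:
                    pts.append((y, x))
                    break
    return sorted(pts)


def brute_metrics(pred, truth, c):
    """All-pairs max-min / mean-min distances between border point sets."""
    pa = border_oracle(pred == c)
    pb = border_oracle(truth == c)
    diag = float(np.hypot(*pred.shape))
    na, nb = (pred == c).sum(), (truth == c).sum()
    d = 2.0 * ((pred == c) & (truth == c)).sum() / (na + nb) if na + nb else 1.0
    if not pa and not pb:
        return d, 0.0, 0.0
    if not pa or not pb:
        return d, diag, diag
    dist = lambda p, q: float(np.hypot(p[0] - q[0], p[1] - q[1]))
    mins_ab = [min(dist(a, b) for b in pb) for a in pa]
    mins_ba = [min(dist(b, a) for a in pa) for b in pb]
    return d, max(max(mins_ab), max(mins_ba)), float(np.mean(mins_ab))


def test_identical_masks_are_perfect(rng):
    m = rng.integers(0, 4, (10, 10))
    for c in range(4):
        assert dsc(m, m, c) == 1.0
        assert hausdorff(m, m, c) == 0.0
        assert asd(m, m, c) == 0.0


def test_dsc_examples():
    a = np.zeros((4, 4), int)
    b = np.zeros((4, 4), int)
    a[0, :2] = 1
    b[3, :2] = 1
    assert dsc(a, b, 1) == 0.0  # disjoint equal-size sets
    a2 = np.zeros((4, 4), int)
    b2 = np.zeros((4, 4), int)
    a2[0, :4] = 1  # |A| = 4
    b2[0, 2:] = 1
    b2[1, :2] = 1  # |B| = 4, overlap 2
    assert dsc(a2, b2, 1) == 0.5


def test_hausdorff_three_four_five():
    a = np.zeros((6, 6), int)
    b = np.zeros((6, 6), int)
    a[0, 0] = 1
    b[3, 4] = 1
    assert hausdorff(a, b, 1) == 5.0


def test_asd_directed_mean_example():
    a = np.zeros((3, 3), int)
    b = np.zeros((3, 3), int)
    a[0, 0] = a[0, 1] = 1  # pred border {(0,0), (0,1)}
    b[0, 0] = 1  # truth border {(0,0)}
    assert asd(a, b, 1) == pytest.approx(0.5)
    assert asd(b, a, 1) == pytest.approx(0.0)  # directed: not symmetric


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        dsc(np.zeros((2, 2), int), np.zeros((3, 2), int), 0)


def test_boundary_extraction_matches_pixel_scan(rng):
    for _ in range(50):
        region = rng.random(tuple(rng.integers(1, 10, 2))) < 0.4
        got = sorted(map(tuple, boundary_points(region)))
        assert got == border_oracle(region)


def test_metrics_match_brute_force_oracle(rng):
    """>=200 random <=12x12 label-map pairs, all three metrics, all classes."""
    checked = 0
    for _ in range(70):
        h, w = rng.integers(2, 13, size=2)
        pred = rng.integers(0, 3, (h, w))
        truth = rng.integers(0, 3, (h, w))
        for c in range(3):
            d_o, hd_o, asd_o = brute_metrics(pred, truth, c)
            assert dsc(pred, truth, c) == pytest.approx(d_o, abs=1e-12)
            assert hausdorff(pred, truth, c) == pytest.approx(hd_o, abs=1e-9)
            assert asd(pred, truth, c) == pytest.approx(asd_o, abs=1e-9)
            checked += 1
    assert checked >= 200


def test_symmetry_properties(rng):
    a = rng.integers(0, 3, (9, 9))
    b = rng.integers(0, 3, (9, 9))
    for c in range(3):
        assert dsc(a, b, c) == dsc(b, a, c)
        assert hausdorff(a, b, c) == hausdorff(b, a, c)
    assert asd(a, b, 1, symmetric=True) == pytest.approx(asd(b, a, 1, symmetric=True))


def test_hausdorff_triangle_inequality(rng):
    for _ in range(20):
        maps = [rng.integers(0, 2, (8, 8)) for _ in range(3)]
        if any(m.sum() == 0 for m in maps):
            continue
        ab = hausdorff(maps[0], maps[1], 1)
        bc = hausdorff(maps[1], maps[2], 1)
        ac = hausdorff(maps[0], maps[2], 1)
        assert ac <= ab + bc + 1e-9


def test_empty_set_conventions():
    empty = np.zeros((5, 5), int)
    some = np.zeros((5, 5), int)
    some[2, 2] = 1
    diag = float(np.hypot(5, 5))
    assert dsc(empty, empty, 1) == 1.0
    assert hausdorff(empty, empty, 1) == 0.0
    assert asd(empty, empty, 1) == 0.0
    assert dsc(some, empty, 1) == 0.0
    assert hausdorff(some, empty, 1) == diag
    assert asd(empty, some, 1) == diag


def test_mean_is_unweighted_over_all_classes_including_background():
    rep = EvalReport(
        {
            "background": (0.99506, 2.67867, 0.67628),
            "brain": (0.98508, 3.07074, 0.67105),
            "CSP": (0.8037, 1.05123, 0.33891),
            "LV": (0.82084, 0.65873, 0.17955),
        }
    )
    assert rep.mean[0] == pytest.approx(0.90117, abs=5.1e-6)
    assert rep.mean[1] == pytest.approx(1.86484, abs=5.1e-6)
    assert rep.mean[2] == pytest.approx(0.46645, abs=5.1e-6)


def test_evaluate_perfect_prediction(small_phantoms):
    s = small_phantoms[0]
    rep = evaluate(s.label_map, s.label_map, DEFAULT_SCHEMA)
    for triple in rep.per_class.values():
        assert triple == (1.0, 0.0, 0.0)
    assert rep.mean == (1.0, 0.0, 0.0)


def test_report_table_layout_and_round_trip():
    rep = EvalReport(
        {
            "background": (0.123456789, 1.5, 0.25),
            "brain": (0.9, 2.0, 0.5),
            "CSP": (0.8, 3.0, 0.75),
            "LV": (0.7, 4.0, 1.0),
        }
    )
    table = report_table({"model_a": rep})
    lines = table.strip().splitlines()
    assert len(lines) == 2
    cells = lines[1].split(",")
    assert len(cells) == 1 + 15  # model + (4 classes + mean) x 3 metrics
    assert cells[1] == "0.12346"  # rounded to 5 decimals
    parsed = parse_report_table(table)
    assert parsed["model_a"]["background"][0] == 0.12346
    assert parsed["model_a"]["LV"] == (0.7, 4.0, 1.0)


def test_report_table_rejects_inconsistent_schemas():
    a = EvalReport({"background": (1, 0, 0), "brain": (1, 0, 0)})
    b = EvalReport({"background": (1, 0, 0), "head": (1, 0, 0)})
    with pytest.raises(ValueError):
        report_table({"a": a, "b": b})
    with pytest.raises(ValueError):
        report_table({})


def test_aggregate_mean_rejects_empty():
    with pytest.raises(ValueError):
        aggregate_mean([])
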