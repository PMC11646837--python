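"""IoU geometry, frame matching, metric arithmetic, kappa, and box I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score

from vishsi.detection_eval import (
    CLASSES,
    BinaryDetectionCounts,
    BoundingBox,
    ConfusionMatrix3,
    FrameRecord,
    binary_metrics,
    cohen_kappa,
    evaluate_dataset,
    iou,
    match_frame,
    multiclass_metrics,
    read_boxes_coco,
    read_boxes_csv,
    records_from_box_maps,
    round_half_up,
    write_boxes_coco,
    write_boxes_csv,
)
from vishsi.reference_data import REFERENCE_EVALUATIONS


def box(label, x0, y0, x1, y1, conf=None):
    return BoundingBox(label, x0, y0, x1, y1, confidence=conf)


# -- IoU -------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        (box("scc", 0, 0, 2, 2), box("scc", 0, 0, 2, 2), 1.0),
        (box("scc", 0, 0, 1, 1), box("scc", 5, 5, 6, 6), 0.0),
        (box("scc", 0, 0, 2, 2), box("scc", 1, 1, 3, 3), 1 / 7),
        (box("scc", 0, 0, 10, 10), box("scc", 0, 2.5, 10, 12.5), 0.6),
    ],
)
def test_iou_known_values(a, b, expected):
    assert iou(a, b) == pytest.approx(expected, abs=1e-12)
    assert iou(b, a) == pytest.approx(expected, abs=1e-12)


def _raster_iou(a, b, scale=4):
    """Brute-force pixel-rasterisation oracle (exact for coords on a 1/scale
    grid)."""
    x1 = int(min(a.x_min, b.x_min) * scale)
    x2 = int(max(a.x_max, b.x_max) * scale)
    y1 = int(min(a.y_min, b.y_min) * scale)
    y2 = int(max(a.y_max, b.y_max) * scale)
    xx, yy = np.meshgrid(np.arange(x1, x2), np.arange(y1, y2))

    def inside(bx):
        return (
            (xx >= bx.x_min * scale)
            & (xx < bx.x_max * scale)
            & (yy >= bx.y_min * scale)
            & (yy < bx.y_max * scale)
        )

    ma, mb = inside(a), inside(b)
    union = (ma | mb).sum()
    return (ma & mb).sum() / union if union else 0.0


def test_iou_matches_rasterisation_oracle():
    """1000 random box pairs on a quarter-pixel grid, exact agreement."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        coords = np.round(rng.uniform(0, 20, 8) * 4) / 4
        x = np.sort(coords[:2]) + [0, 0.25]
        y = np.sort(coords[2:4]) + [0, 0.25]
        u = np.sort(coords[4:6]) + [0, 0.25]
        v = np.sort(coords[6:8]) + [0, 0.25]
        a = box("scc", x[0], y[0], x[1], y[1])
        b = box("scc", u[0], v[0], u[1], v[1])
        assert iou(a, b) == pytest.approx(_raster_iou(a, b), abs=1e-9)


def test_degenerate_box_rejected():
    with pytest.raises(ValueError):
        BoundingBox("scc", 0, 0, 0, 1)


# -- frame matching --------------------------------------------------------

def test_match_simple_detection():
    rec = FrameRecord(
        "f1",
        truths=(box("scc", 0, 0, 10, 10),),
        predictions=(box("scc", 0, 2.5, 10, 12.5, 0.9),),  # IoU 0.6
    )
    out = match_frame(rec)
    assert (out.true_label, out.predicted_label) == ("scc", "scc")


def test_match_missed_when_no_predictions():
    rec = FrameRecord("f1", truths=(box("dysplasia", 0, 0, 5, 5),))
    out = match_frame(rec)
    assert (out.true_label, out.predicted_label) == ("dysplasia", "normal")


@pytest.mark.parametrize(
    "pred,thr,expected_pred",
    [
        # IoU = 1/7 ≈ 0.143: below 0.5, above 0.1
        (box("scc", 1, 1, 3, 3, 0.8), 0.5, "normal"),
        (box("scc", 1, 1, 3, 3, 0.8), 0.1, "scc"),
        # IoU = 0.4 exactly: pred (0,0,2,0.8) inside truth, 1.6/4
        (box("scc", 0, 0, 2, 0.8, 0.8), 0.5, "normal"),
        (box("scc", 0, 0, 2, 0.8, 0.8), 0.3, "scc"),
    ],
)
def test_match_flips_across_threshold(pred, thr, expected_pred):
    truth = box("scc", 0, 0, 2, 2)
    out = match_frame(FrameRecord("f", (truth,), (pred,)), iou_threshold=thr)
    assert out.predicted_label == expected_pred


def test_unmatched_prediction_on_normal_frame_is_false_positive():
    rec = FrameRecord("f", truths=(), predictions=(box("dysplasia", 0, 0, 5, 5, 0.7),))
    out = match_frame(rec)
    assert (out.true_label, out.predicted_label) == ("normal", "dysplasia")


def test_severity_max_labeling():
    rec = FrameRecord(
        "f",
        truths=(box("dysplasia", 0, 0, 10, 10), box("scc", 20, 20, 30, 30)),
        predictions=(
            box("dysplasia", 0, 0, 10, 10, 0.9),
            box("dysplasia", 20, 20, 30, 30, 0.8),
        ),
    )
    out = match_frame(rec)
    assert out.true_label == "scc"  # most severe truth
    assert out.predicted_label == "dysplasia"  # most severe matched prediction


def test_greedy_matching_prefers_higher_confidence():
    truth = box("scc", 0, 0, 10, 10)
    rec = FrameRecord(
        "f",
        truths=(truth,),
        predictions=(
            box("dysplasia", 0, 0, 10, 10, 0.6),
            box("scc", 0, 0, 10, 10, 0.9),
        ),
    )
    out = match_frame(rec)
    # high-confidence scc claims the truth; dysplasia is left unmatched
    assert out.predicted_label == "scc"


# -- binary metrics --------------------------------------------------------

@pytest.mark.parametrize(
    "counts,acc",
    [
        (BinaryDetectionCounts(217, 77, 293, 28), 83),  # RGB-WLI
        (BinaryDetectionCounts(252, 42, 292, 16), 90),  # HSI-WLI
    ],
)
def test_binary_accuracy_matches_reference(counts, acc):
    m = binary_metrics(counts)
    assert round_half_up(100 * m["accuracy"]) == acc


def test_binary_undefined_denominators():
    m = binary_metrics(BinaryDetectionCounts(0, 0, 10, 0))
    assert m["sensitivity"] is None
    assert m["specificity"] == 1.0


# -- multiclass metrics ----------------------------------------------------

def test_reference_dysplasia_metrics():
    cm = REFERENCE_EVALUATIONS["rgb_wli"]["confusion_matrix"]
    m = multiclass_metrics(cm)
    dys = m["per_class"]["dysplasia"]
    assert round_half_up(100 * dys["sensitivity"]) == 70
    # (293 + 141) / (321 + 186) = 434/507
    assert dys["specificity_paper"] == pytest.approx(434 / 507)
    assert round_half_up(100 * dys["specificity_paper"]) == 86


def test_diagonal_matrix_is_perfect():
    cm = ConfusionMatrix3(np.diag([10, 20, 30]))
    m = multiclass_metrics(cm)
    for cls in CLASSES:
        assert m["per_class"][cls]["sensitivity"] == 1.0
        assert m["per_class"][cls]["precision"] == 1.0
    assert m["accuracy"] == 1.0
    assert m["kappa"] == pytest.approx(1.0)


def test_empty_column_flags_undefined():
    cm = ConfusionMatrix3(np.array([[10, 0, 0], [5, 0, 0], [0, 0, 5]]))
    m = multiclass_metrics(cm)
    assert m["per_class"]["dysplasia"]["precision"] is None


# -- kappa -----------------------------------------------------------------

@pytest.mark.parametrize(
    "name,expected",
    [("rgb_wli", 0.71), ("rgb_nbi", 0.72), ("hsi_wli", 0.84), ("hsi_nbi", 0.83)],
)
def test_kappa_reference_values(name, expected):
    cm = REFERENCE_EVALUATIONS[name]["confusion_matrix"]
    assert round_half_up(cohen_kappa(cm), 2) == expected


def test_kappa_matches_sklearn_oracle(rng):
    for _ in range(20):
        cm = ConfusionMatrix3(rng.integers(1, 60, size=(3, 3)))
        y_true = np.repeat(np.arange(3), cm.counts.sum(axis=1))
        y_pred = np.concatenate(
            [np.repeat(np.arange(3), cm.counts[i]) for i in range(3)]
        )
        assert cohen_kappa(cm) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12
        )


@given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
def test_kappa_permutation_invariance(cells):
    counts = np.array(cells).reshape(3, 3)
    if counts.sum() == 0:
        counts[0, 0] = 1
    cm = ConfusionMatrix3(counts)
    n = counts.sum()
    pe = float((counts.sum(1) * counts.sum(0)).sum()) / n**2
    if pe >= 1:
        return
    k = cohen_kappa(cm)
    assert -1 - 1e-9 <= k <= 1 + 1e-9
    perm = [2, 0, 1]
    cm_p = ConfusionMatrix3(counts[perm][:, perm])
    assert cohen_kappa(cm_p) == pytest.approx(k, abs=1e-12)
    # kappa = 1 iff diagonal with positive trace
    if np.trace(counts) == n:
        assert k == pytest.approx(1.0)
    else:
        assert k < 1


# -- dataset evaluation ----------------------------------------------------

def _perfect_records(n=12):
    recs = []
    for i in range(n):
        label = CLASSES[i % 3]
        if label == "normal":
            recs.append(FrameRecord(f"f{i}", (), ()))
        else:
            t = box(label, 0, 0, 10, 10)
            recs.append(
                FrameRecord(f"f{i}", (t,), (box(label, 0, 0, 10, 10, 0.9),))
            )
    return recs


def test_all_correct_dataset():
    res = evaluate_dataset(_perfect_records())
    assert res["multiclass"]["accuracy"] == 1.0
    assert res["multiclass"]["kappa"] == pytest.approx(1.0)
    assert res["binary"]["accuracy"] == 1.0


def test_dataset_order_invariance():
    recs = _perfect_records(9)
    recs[3] = FrameRecord("f3", (box("scc", 0, 0, 5, 5),), ())  # one miss
    res1 = evaluate_dataset(recs)
    res2 = evaluate_dataset(list(reversed(recs)))
    assert np.array_equal(
        res1["confusion_matrix"].counts, res2["confusion_matrix"].counts
    )


def test_duplicate_frame_ids_rejected():
    recs = [_perfect_records(2)[0]] * 2
    with pytest.raises(ValueError):
        evaluate_dataset(recs)


def test_two_path_consistency_and_binary_collapse():
    """Metrics from evaluate_dataset equal metrics from its own confusion
    matrix; binary accuracy dominates 3-class accuracy."""
    from vishsi.synthetic_data import frames_from_confusion_matrix

    cm = REFERENCE_EVALUATIONS["hsi_wli"]["confusion_matrix"]
    res = evaluate_dataset(frames_from_confusion_matrix(cm, seed=3))
    direct = multiclass_metrics(res["confusion_matrix"])
    assert res["multiclass"]["kappa"] == pytest.approx(direct["kappa"])
    assert res["multiclass"]["accuracy"] == pytest.approx(direct["accuracy"])
    assert res["binary"]["accuracy"] >= res["multiclass"]["accuracy"]


# -- rounding --------------------------------------------------------------

@pytest.mark.parametrize(
    "value,decimals,expected",
    [(82.5, 0, 83.0), (81.49, 0, 81.0), (0.835, 2, 0.84), (0.8349, 2, 0.83)],
)
def test_round_half_up(value, decimals, expected):
    assert round_half_up(value, decimals) == expected


# -- box I/O ---------------------------------------------------------------

def _mixed_records():
    return [
        FrameRecord(
            "a.png",
            truths=(box("scc", 1, 2, 11, 22),),
            predictions=(box("scc", 1.5, 2, 11, 21, 0.87),),
        ),
        FrameRecord("b.png", truths=(), predictions=()),
        FrameRecord(
            "c.png",
            truths=(box("dysplasia", 3, 3, 9, 9),),
            predictions=(box("dysplasia", 3, 3, 9, 9, 0.5),),
        ),
    ]


@pytest.mark.parametrize("fmt", ["coco", "csv"])
def test_box_io_round_trip(tmp_path, fmt):
    recs = _mixed_records()
    if fmt == "coco":
        tp, pp = tmp_path / "t.json", tmp_path / "p.json"
        write_boxes_coco(recs, tp, which="truths")
        write_boxes_coco(recs, pp, which="predictions")
        truths, preds = read_boxes_coco(tp), read_boxes_coco(pp)
    else:
        tp, pp = tmp_path / "t.csv", tmp_path / "p.csv"
        write_boxes_csv(recs, tp, which="truths")
        write_boxes_csv(recs, pp, which="predictions")
        truths, preds = read_boxes_csv(tp), read_boxes_csv(pp)
    back = records_from_box_maps(truths, preds)
    assert len(back) == 3
    r1 = evaluate_dataset(recs)["report"]
    r2 = evaluate_dataset(back)["report"]
    assert r1 == r2
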