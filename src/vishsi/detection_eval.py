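"""Frame-level detection and 3-class classification evaluation.

Predicted boxes are matched to ground truth greedily in descending
confidence at an IoU threshold (default 0.5).  Each frame is then reduced
to a (true class, predicted class) pair:

* the frame's true class is the most severe class among its ground-truth
  boxes (SCC > dysplasia > normal; normal when there are none);
* the predicted class is the most severe class among IoU-matched
  predictions; a frame with truths but no match is predicted normal
  (a miss), and unmatched predictions on a normal frame make it a false
  positive of the predicted class.

Frame pairs aggregate into a binary neoplasm-vs-normal count table and a
3×3 confusion matrix, from which sensitivity, specificity (two variants),
precision, F1, accuracy and Cohen's kappa are derived.  The non-standard
"paper-variant" specificity for class c — the fraction of true non-c frames
that land in their own correct class — is reported alongside the usual
TN/(TN+FP) definition.  Percentages round half-up to integers and kappa to
two decimals at report time only; internals keep full precision.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "CLASSES",
    "SEVERITY",
    "BoundingBox",
    "FrameRecord",
    "BinaryDetectionCounts",
    "ConfusionMatrix3",
    "iou",
    "match_frame",
    "binary_metrics",
    "multiclass_metrics",
    "cohen_kappa",
    "evaluate_dataset",
    "round_half_up",
    "read_boxes_coco",
    "write_boxes_coco",
    "read_boxes_csv",
    "write_boxes_csv",
]

CLASSES = ("normal", "dysplasia", "scc")
SEVERITY = {"normal": 0, "dysplasia": 1, "scc": 2}


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: 0-based pixel coordinates, half-open intervals."""

    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate box")
        if self.confidence is not None and not 0 <= self.confidence <= 1:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class FrameRecord:
    """One evaluated frame: ground-truth boxes plus predicted boxes."""

    frame_id: str
    truths: tuple[BoundingBox, ...] = ()
    predictions: tuple[BoundingBox, ...] = ()
    modality: str = "WLI"


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _most_severe(labels) -> str:
    return max(labels, key=SEVERITY.__getitem__, default="normal")


@dataclass(frozen=True)
class FrameOutcome:
    frame_id: str
    true_label: str
    predicted_label: str
    n_matched: int


def match_frame(record: FrameRecord, iou_threshold: float = 0.5) -> FrameOutcome:
    """Reduce one frame's boxes to a (true, predicted) class pair.

    Predictions are matched greedily in descending confidence (ties: larger
    IoU, then lower box index) to unmatched truths at IoU ≥ threshold.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("IoU threshold must lie in (0, 1]")
    true_label = _most_severe(b.label for b in record.truths)
    order = sorted(
        range(len(record.predictions)),
        key=lambda i: (-(record.predictions[i].confidence or 0.0), i),
    )
    unmatched_truths = list(range(len(record.truths)))
    matched_labels: list[str] = []
    for i in order:
        pred = record.predictions[i]
        best_j, best_iou = None, iou_threshold
        for j in unmatched_truths:
            v = iou(pred, record.truths[j])
            if v > best_iou or (v == best_iou and v >= iou_threshold and best_j is None):
                best_j, best_iou = j, v
        if best_j is not None:
            unmatched_truths.remove(best_j)
            matched_labels.append(pred.label)
    if record.truths:
        predicted = _most_severe(matched_labels)
    else:
        # any prediction on a normal frame is a false positive of its class
        predicted = _most_severe(p.label for p in record.predictions)
    return FrameOutcome(record.frame_id, true_label, predicted, len(matched_labels))


@dataclass(frozen=True)
class BinaryDetectionCounts:
    """Neoplasm-vs-normal frame counts."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3×3 frame-count matrix, rows = true class, columns = predicted class,
    in the order (normal, dysplasia, scc)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("confusion matrix must be 3×3 non-negative integers")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def collapse_binary(self) -> BinaryDetectionCounts:
        """Collapse to neoplasm (dysplasia+scc) vs normal detection counts."""
        c = self.counts
        return BinaryDetectionCounts(
            TP=int(c[1:, 1:].sum()),
            FN=int(c[1:, 0].sum()),
            TN=int(c[0, 0]),
            FP=int(c[0, 1:].sum()),
        )


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used in the report tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def binary_metrics(counts: BinaryDetectionCounts) -> dict:
    """Sensitivity, specificity, precision, F1 and accuracy as unit fractions.

    Undefined ratios (zero denominators) are reported as ``None``, never 0.
    """
    if counts.total == 0:
        raise ValueError("empty count table")
    sens = _ratio(counts.TP, counts.TP + counts.FN)
    spec = _ratio(counts.TN, counts.TN + counts.FP)
    prec = _ratio(counts.TP, counts.TP + counts.FP)
    f1 = _ratio(2 * counts.TP, 2 * counts.TP + counts.FN + counts.FP)
    acc = (counts.TP + counts.TN) / counts.total
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "accuracy": acc,
    }


def multiclass_metrics(cm: ConfusionMatrix3) -> dict:
    """Per-class and overall 3-class metrics as unit fractions.

    For class c: sensitivity = diagonal / row total; precision = diagonal /
    column total; F1 from those; paper-variant specificity = (sum of the
    other classes' diagonal entries) / (sum of the other classes' row
    totals); standard specificity = TN/(TN+FP) one-vs-rest.  Overall
    accuracy = trace / total; kappa via :func:`cohen_kappa`.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows, cols, diag = c.sum(axis=1), c.sum(axis=0), np.diag(c)
    per_class = {}
    for i, name in enumerate(CLASSES):
        sens = _ratio(diag[i], rows[i])
        prec = _ratio(diag[i], cols[i])
        f1 = (
            None
            if sens is None or prec is None or (sens + prec) == 0
            else 2 * sens * prec / (sens + prec)
        )
        others = [j for j in range(3) if j != i]
        spec_paper = _ratio(diag[others].sum(), rows[others].sum())
        fp = cols[i] - diag[i]
        tn = total - rows[i] - fp
        spec_std = _ratio(tn, tn + fp)
        per_class[name] = {
            "sensitivity": sens,
            "specificity_paper": spec_paper,
            "specificity_standard": spec_std,
            "precision": prec,
            "f1": f1,
        }
    try:
        kappa = cohen_kappa(cm)
    except ZeroDivisionError:
        kappa = None  # single-class marginals: chance agreement is 1
    return {
        "per_class": per_class,
        "accuracy": float(np.trace(c) / total),
        "kappa": kappa,
    }


def cohen_kappa(cm: ConfusionMatrix3) -> float:
    """Chance-corrected agreement: (p_o − p_e)/(1 − p_e), p_e from marginals."""
    c = cm.counts.astype(float)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if p_e >= 1:
        raise ZeroDivisionError("kappa undefined: chance agreement is 1")
    return float((p_o - p_e) / (1 - p_e))


def format_report(
    binary: dict, multi: dict, counts: BinaryDetectionCounts, cm: ConfusionMatrix3
) -> dict:
    """Serializable report with table-style rounding applied."""

    def pct(x):
        return None if x is None else round_half_up(100 * x)

    return {
        "binary_counts": {k: getattr(counts, k) for k in ("TP", "FN", "TN", "FP")},
        "confusion_matrix": cm.counts.tolist(),
        "detection": {k: pct(v) for k, v in binary.items()},
        "classification": {
            "per_class": {
                name: {k: pct(v) for k, v in d.items()}
                for name, d in multi["per_class"].items()
            },
            "accuracy": pct(multi["accuracy"]),
            "kappa": None if multi["kappa"] is None else round_half_up(multi["kappa"], 2),
        },
    }


def evaluate_dataset(records, iou_threshold: float = 0.5) -> dict:
    """Aggregate frame outcomes into counts, a confusion matrix and metrics."""
    records = list(records)
    if not records:
        raise ValueError("no frames to evaluate")
    ids = Counter(r.frame_id for r in records)
    dup = [k for k, v in ids.items() if v > 1]
    if dup:
        raise ValueError(f"duplicate frame ids: {dup[:5]}")
    cm = np.zeros((3, 3), dtype=int)
    for rec in records:
        out = match_frame(rec, iou_threshold)
        cm[CLASSES.index(out.true_label), CLASSES.index(out.predicted_label)] += 1
    cm3 = ConfusionMatrix3(cm)
    counts = cm3.collapse_binary()
    binary = binary_metrics(counts)
    multi = multiclass_metrics(cm3)
    return {
        "counts": counts,
        "confusion_matrix": cm3,
        "binary": binary,
        "multiclass": multi,
        "report": format_report(binary, multi, counts, cm3),
    }


# -- box I/O ---------------------------------------------------------------

_CAT_IDS = {name: i + 1 for i, name in enumerate(CLASSES)}


def write_boxes_coco(records, path, which: str = "truths") -> None:
    """Write frame boxes as COCO-style JSON (bbox = [x, y, w, h])."""
    images, annotations = [], []
    ann_id = 1
    for idx, rec in enumerate(records, start=1):
        images.append({"id": idx, "file_name": rec.frame_id})
        for box in getattr(rec, which):
            ann = {
                "id": ann_id,
                "image_id": idx,
                "category_id": _CAT_IDS[box.label],
                "bbox": [box.x_min, box.y_min, box.x_max - box.x_min, box.y_max - box.y_min],
                "area": box.area,
                "iscrowd": 0,
            }
            if box.confidence is not None:
                ann["score"] = box.confidence
            annotations.append(ann)
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": n} for n, i in _CAT_IDS.items()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_boxes_coco(path) -> dict[str, list[BoundingBox]]:
    """Read COCO-style JSON into frame-id → box list (all frames present)."""
    with open(path) as fh:
        payload = json.load(fh)
    cats = {c["id"]: c["name"].lower() for c in payload.get("categories", [])}
    frames = {img["id"]: img["file_name"] for img in payload["images"]}
    out: dict[str, list[BoundingBox]] = {name: [] for name in frames.values()}
    for ann in payload.get("annotations", []):
        x, y, w, h = ann["bbox"]
        out[frames[ann["image_id"]]].append(
            BoundingBox(
                label=cats.get(ann["category_id"], "normal"),
                x_min=x,
                y_min=y,
                x_max=x + w,
                y_max=y + h,
                confidence=ann.get("score"),
            )
        )
    return out


def write_boxes_csv(records, path, which: str = "truths") -> None:
    """Flat CSV dialect: frame_id,class,x_min,y_min,x_max,y_max,confidence."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_id", "class", "x_min", "y_min", "x_max", "y_max", "confidence"])
        for rec in records:
            boxes = getattr(rec, which)
            if not boxes:
                w.writerow([rec.frame_id, "", "", "", "", "", ""])
            for box in boxes:
                w.writerow(
                    [
                        rec.frame_id,
                        box.label,
                        box.x_min,
                        box.y_min,
                        box.x_max,
                        box.y_max,
                        "" if box.confidence is None else box.confidence,
                    ]
                )


def read_boxes_csv(path) -> dict[str, list[BoundingBox]]:
    out: dict[str, list[BoundingBox]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            fid = row["frame_id"]
            out.setdefault(fid, [])
            if not row["class"]:
                continue  # frame with no boxes
            conf = row.get("confidence") or None
            out[fid].append(
                BoundingBox(
                    label=row["class"].lower(),
                    x_min=float(row["x_min"]),
                    y_min=float(row["y_min"]),
                    x_max=float(row["x_max"]),
                    y_max=float(row["y_max"]),
                    confidence=None if conf is None else float(conf),
                )
            )
    return out


def records_from_box_maps(
    truths: dict[str, list[BoundingBox]],
    predictions: dict[str, list[BoundingBox]],
    modality: str = "WLI",
) -> list[FrameRecord]:
    """Join truth and prediction box maps on frame id (union of frames)."""
    ids = sorted(set(truths) | set(predictions))
    return [
        FrameRecord(
            frame_id=fid,
            truths=tuple(truths.get(fid, [])),
            predictions=tuple(predictions.get(fid, [])),
            modality=modality,
        )
        for fid in ids
    ]
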