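"""Published frame-level evaluation counts for the four detector
configurations (RGB/HSI × WLI/NBI) of the esophageal-neoplasm study this
package's evaluation arithmetic is validated against.

Each entry carries the binary detection frame counts, the 3-class confusion
matrix (rows = true normal/dysplasia/SCC, columns = predicted), and the
metric values printed in the study's report tables.  A handful of printed
cells are internally inconsistent with the count tables they accompany;
:func:`find_inconsistencies` recomputes every printed cell from the counts
and returns the cells that disagree, so they can be flagged rather than
silently matched.
"""

from __future__ import annotations

import numpy as np

from .detection_eval import (
    BinaryDetectionCounts,
    ConfusionMatrix3,
    binary_metrics,
    cohen_kappa,
    multiclass_metrics,
    round_half_up,
)

__all__ = ["REFERENCE_EVALUATIONS", "find_inconsistencies"]

REFERENCE_EVALUATIONS: dict[str, dict] = {
    "rgb_wli": {
        "binary_counts": BinaryDetectionCounts(TP=217, FN=77, TN=293, FP=28),
        "confusion_matrix": ConfusionMatrix3(
            np.array([[293, 18, 10], [32, 76, 0], [45, 0, 141]])
        ),
        # printed detection row: sensitivity, specificity, precision, F1, accuracy (%)
        "printed_detection": {
            "sensitivity": 74,
            "specificity": 91,
            "precision": 89,
            "f1": 81,
            "accuracy": 83,
        },
        "printed_classification": {
            "accuracy": 83,
            "kappa": 0.71,
            "dysplasia": {
                "sensitivity": 70,
                "specificity_paper": 86,
                "precision": 81,
                "f1": 75,
            },
            "scc": {
                "sensitivity": 76,
                "specificity_paper": 86,
                "precision": 93,
                "f1": 84,
            },
        },
    },
    "rgb_nbi": {
        "binary_counts": BinaryDetectionCounts(TP=335, FN=82, TN=250, FP=49),
        "confusion_matrix": ConfusionMatrix3(
            np.array([[250, 38, 11], [45, 174, 0], [37, 0, 161]])
        ),
        "printed_detection": {
            "sensitivity": 80,
            "specificity": 84,
            "precision": 87,
            "f1": 84,
            "accuracy": 82,
        },
        "printed_classification": {
            "accuracy": 84,  # inconsistent: the matrix gives 82
            "kappa": 0.72,
            "dysplasia": {
                "sensitivity": 79,
                "specificity_paper": 83,
                "precision": 82,
                "f1": 81,
            },
            "scc": {
                "sensitivity": 81,
                "specificity_paper": 82,
                "precision": 94,
                "f1": 87,
            },
        },
    },
    "hsi_wli": {
        "binary_counts": BinaryDetectionCounts(TP=252, FN=42, TN=292, FP=16),
        "confusion_matrix": ConfusionMatrix3(
            np.array([[292, 7, 9], [17, 91, 0], [25, 0, 161]])
        ),
        "printed_detection": {
            "sensitivity": 86,
            "specificity": 94,  # inconsistent: the counts give 95
            "precision": 94,
            "f1": 90,
            "accuracy": 90,
        },
        "printed_classification": {
            "accuracy": 90,
            "kappa": 0.84,  # one table prints 0.92; the matrix gives 0.84
            "dysplasia": {
                "sensitivity": 84,
                "specificity_paper": 92,
                "precision": 93,
                "f1": 88,
            },
            "scc": {
                "sensitivity": 87,
                "specificity_paper": 92,
                "precision": 95,
                "f1": 90,
            },
        },
    },
    "hsi_nbi": {
        "binary_counts": BinaryDetectionCounts(TP=359, FN=58, TN=252, FP=17),
        "confusion_matrix": ConfusionMatrix3(
            np.array([[252, 9, 8], [32, 185, 2], [26, 0, 172]])
        ),
        "printed_detection": {
            "sensitivity": 86,
            "specificity": 99,  # inconsistent: the counts give 94
            "precision": 95,
            "f1": 91,
            "accuracy": 89,
        },
        "printed_classification": {
            "accuracy": 91,  # inconsistent: the matrix gives 89
            "kappa": 0.83,
            "dysplasia": {
                "sensitivity": 84,
                "specificity_paper": 91,
                "precision": 95,
                "f1": 90,
            },
            "scc": {
                "sensitivity": 87,
                "specificity_paper": 90,
                "precision": 95,
                "f1": 91,
            },
        },
    },
}

#: Printed kappa for HSI-WLI in the per-class performance table, which
#: disagrees with both the confusion matrix and the matrix's own kappa cell.
ALTERNATE_PRINTED_KAPPA_HSI_WLI = 0.92


def _pct(x: float | None) -> float | None:
    return None if x is None else round_half_up(100 * x)


def find_inconsistencies() -> list[dict]:
    """Recompute every printed metric cell from the count tables.

    Returns one record per printed cell that disagrees with the value the
    counts imply under the documented rounding (integer percent half-up,
    kappa to two decimals).
    """
    issues: list[dict] = []
    for name, entry in REFERENCE_EVALUATIONS.items():
        computed_bin = binary_metrics(entry["binary_counts"])
        for key, printed in entry["printed_detection"].items():
            got = _pct(computed_bin[key])
            if got != printed:
                issues.append(
                    {"model": name, "table": "detection", "metric": key,
                     "printed": printed, "computed": got}
                )
        cm = entry["confusion_matrix"]
        multi = multiclass_metrics(cm)
        printed_cls = entry["printed_classification"]
        got_acc = _pct(multi["accuracy"])
        if got_acc != printed_cls["accuracy"]:
            issues.append(
                {"model": name, "table": "classification", "metric": "accuracy",
                 "printed": printed_cls["accuracy"], "computed": got_acc}
            )
        got_kappa = round_half_up(cohen_kappa(cm), 2)
        if got_kappa != printed_cls["kappa"]:
            issues.append(
                {"model": name, "table": "classification", "metric": "kappa",
                 "printed": printed_cls["kappa"], "computed": got_kappa}
            )
        for cls in ("dysplasia", "scc"):
            for key, printed in printed_cls[cls].items():
                got = _pct(multi["per_class"][cls][key])
                if got != printed:
                    issues.append(
                        {"model": name, "table": "classification",
                         "metric": f"{cls}.{key}", "printed": printed,
                         "computed": got}
                    )
    if ALTERNATE_PRINTED_KAPPA_HSI_WLI != round_half_up(
        cohen_kappa(REFERENCE_EVALUATIONS["hsi_wli"]["confusion_matrix"]), 2
    ):
        issues.append(
            {"model": "hsi_wli", "table": "classification",
             "metric": "kappa(alternate cell)",
             "printed": ALTERNATE_PRINTED_KAPPA_HSI_WLI,
             "computed": round_half_up(
                 cohen_kappa(REFERENCE_EVALUATIONS["hsi_wli"]["confusion_matrix"]), 2
             )}
        )
    return issues
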