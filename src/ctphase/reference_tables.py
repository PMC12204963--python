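"""Reference diagnostic-accuracy counts for regression-testing the metrics.

These are the published per-class confusion counts from the clinical
evaluation of the two-step contrast-phase method: an internal test set of
288 phases (96 exams, both strategies) and an external multi-centre test
set of 645 phases (215 exams, two-step only).  Each cell stores
``(TP, FN, TN, FP)`` in a one-vs-rest analysis; the expected printed
metric values (percent to 1 decimal, AUC to 3 decimals) are kept
alongside so the metric formulas can be checked cell by cell.
"""

from __future__ import annotations

# (TP, FN, TN, FP) per class, internal test set (n = 288 phases)
INTERNAL_ONE_STEP = {
    "EAP": (80, 9, 195, 4),
    "LAP": (3, 4, 272, 9),
    "PVP": (88, 8, 189, 3),
    "DP": (93, 3, 184, 8),
}

INTERNAL_TWO_STEP = {
    "EAP": (86, 3, 199, 0),
    "LAP": (7, 0, 278, 3),
    "PVP": (95, 1, 191, 1),
    "DP": (95, 1, 191, 1),
}

# external multi-centre test set (n = 645 phases), two-step model
EXTERNAL_TWO_STEP = {
    "EAP": (58, 3, 583, 1),
    "LAP": (153, 1, 488, 3),
    "PVP": (214, 1, 429, 1),
    "DP": (214, 1, 429, 1),
}

# printed metric values: (sensitivity, specificity, accuracy, PPV, NPV, AUC)
PRINTED_INTERNAL_ONE_STEP = {
    "EAP": (89.9, 98.0, 95.5, 95.2, 95.6, 0.939),
    "LAP": (42.9, 96.8, 95.5, 25.0, 98.6, 0.698),
    "PVP": (91.7, 98.4, 96.2, 96.7, 95.9, 0.951),
    "DP": (96.9, 95.8, 96.2, 92.1, 98.4, 0.964),
}

PRINTED_INTERNAL_TWO_STEP = {
    "EAP": (96.6, 100.0, 99.0, 100.0, 98.5, 0.983),
    "LAP": (100.0, 98.9, 99.0, 70.0, 100.0, 0.995),
    "PVP": (99.0, 99.5, 99.3, 99.0, 99.5, 0.992),
    "DP": (99.0, 99.5, 99.3, 99.0, 99.5, 0.992),
}

PRINTED_EXTERNAL_TWO_STEP = {
    "EAP": (95.1, 99.8, 99.4, 98.3, 99.5, 0.975),
    "LAP": (99.4, 99.4, 99.4, 98.1, 99.8, 0.994),
    "PVP": (99.5, 99.8, 99.7, 99.5, 99.8, 0.997),
    "DP": (99.5, 99.8, 99.7, 99.5, 99.8, 0.997),
}

# overall phase-wise accuracies: (correct, total, printed percent)
OVERALL = {
    "internal_two_step": (283, 288, 98.3),
    "internal_one_step": (264, 288, 91.7),
    "external_two_step": (639, 645, 99.1),
}

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "ppv", "npv", "auc")
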