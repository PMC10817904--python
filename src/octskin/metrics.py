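"""Evaluation: boundary position error/accuracy, epidermal thickness, and
patch-classification reports.

A predicted boundary column is *correct* when it lies within a tolerance
(default 2 px, about 6.5 um axially) of the manual/reference row; position
accuracy is the fraction of correct columns over the full trace width.
Epidermal thickness (ET) is the per-column row distance DEJ - SC, converted
to micrometres via the axial pixel pitch; an image's ET is *correct* when
the predicted mean ET lies within the reference trace's own per-image
standard deviation of the manual mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "position_accuracy",
    "position_error",
    "epidermal_thickness",
    "et_accuracy",
    "classification_report",
    "EvalReport",
]

#: default axial pixel pitch used for metric reporting (um / px)
METRIC_AXIAL_PX_UM = 3.25


def _as_rows(trace) -> np.ndarray:
    return np.asarray(trace, dtype=np.float64).ravel()


def _check_pair(pred, manual) -> tuple[np.ndarray, np.ndarray]:
    p, m = _as_rows(pred), _as_rows(manual)
    if p.shape != m.shape:
        raise ValueError(f"trace length mismatch: {p.shape[0]} vs {m.shape[0]}")
    if p.size == 0:
        raise ValueError("empty traces")
    return p, m


def position_accuracy(pred, manual, tolerance: float = 2.0) -> float:
    """Fraction of columns with ``|pred - manual| <= tolerance`` pixels."""
    p, m = _check_pair(pred, manual)
    return float((np.abs(p - m) <= tolerance).mean())


def position_error(pred, manual) -> tuple[float, float]:
    """Mean and standard deviation of the per-column absolute difference."""
    p, m = _check_pair(pred, manual)
    diff = np.abs(p - m)
    return float(diff.mean()), float(diff.std())


def epidermal_thickness(
    sc,
    dej,
    axial_px_um: float = METRIC_AXIAL_PX_UM,
) -> dict:
    """Per-column and mean epidermal thickness in pixels and micrometres.

    Columns where the DEJ sits above the SC are anatomically impossible;
    they are flagged and excluded from the means with a warning.
    """
    s, d = _check_pair(sc, dej)
    t_px = d - s
    valid = t_px >= 0
    if not valid.any():
        raise ValueError("all columns have DEJ above SC; traces are inconsistent")
    if not valid.all():
        logger.warning("%d column(s) with DEJ above SC excluded from ET mean", int((~valid).sum()))
    mean_px = float(t_px[valid].mean())
    return {
        "per_column_px": t_px,
        "per_column_um": t_px * axial_px_um,
        "valid": valid,
        "mean_px": mean_px,
        "mean_um": mean_px * axial_px_um,
        "sd_px": float(t_px[valid].std()),
    }


def et_accuracy(pred_ets, manual_ets, manual_sds) -> float:
    """Fraction of images whose predicted mean ET lies within the manual SD."""
    p = np.asarray(pred_ets, dtype=np.float64).ravel()
    m = np.asarray(manual_ets, dtype=np.float64).ravel()
    s = np.asarray(manual_sds, dtype=np.float64).ravel()
    if not (p.shape == m.shape == s.shape):
        raise ValueError("per-image lists must be aligned")
    if p.size == 0:
        raise ValueError("no images")
    if (s < 0).any():
        raise ValueError("standard deviations must be >= 0")
    return float((np.abs(p - m) <= s).mean())


def classification_report(labels, probabilities, class_names=("non-boundary", "SC", "DEJ")) -> dict:
    """Per-class PPV, sensitivity, F1 (argmax decisions) and one-vs-rest AUC.

    Classes absent from ``labels`` are reported as NaN and flagged
    ``undefined``.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probabilities must be (n, n_classes) aligned with labels")
    pred = probs[:, :3].argmax(axis=1)
    ppv, sens, f1, _ = precision_recall_fscore_support(
        labels, pred, labels=[0, 1, 2], zero_division=0.0
    )
    report: dict = {}
    for c in range(3):
        present = bool((labels == c).any())
        if present:
            auc = float(roc_auc_score((labels == c).astype(int), probs[:, c]))
        else:
            auc = float("nan")
        report[class_names[c]] = {
            "ppv": float(ppv[c]) if present else float("nan"),
            "sensitivity": float(sens[c]) if present else float("nan"),
            "f1": float(f1[c]) if present else float("nan"),
            "auc": auc,
            "undefined": not present,
        }
    report["accuracy"] = float((pred == labels).mean())
    return report


@dataclass
class EvalReport:
    """Aggregated segmentation evaluation over a set of images."""

    per_boundary: dict = field(default_factory=dict)  # name -> {mean_diff, sd, position_accuracy}
    overall: dict = field(default_factory=dict)
    et_per_image_px: list = field(default_factory=list)
    et_per_image_um: list = field(default_factory=list)
    et_accuracy: float | None = None
    classification: dict | None = None

    @classmethod
    def from_traces(
        cls,
        pred_pairs,
        manual_pairs,
        tolerance: float = 2.0,
        axial_px_um: float = METRIC_AXIAL_PX_UM,
    ) -> "EvalReport":
        """Score per-image (SC, DEJ) predicted pairs against manual pairs."""
        if len(pred_pairs) != len(manual_pairs):
            raise ValueError("prediction / reference image counts differ")
        diffs = {"SC": [], "DEJ": []}
        pred_ets, man_ets, man_sds = [], [], []
        et_um = []
        for (psc, pdej), (msc, mdej) in zip(pred_pairs, manual_pairs):
            for name, p, m in (("SC", psc, msc), ("DEJ", pdej, mdej)):
                pr, mr = _check_pair(p, m)
                diffs[name].append(np.abs(pr - mr))
            try:
                pred_et = epidermal_thickness(psc, pdej, axial_px_um)
                man_et = epidermal_thickness(msc, mdej, axial_px_um)
            except ValueError:  # fully inverted traces: ET undefined for this image
                logger.warning("image with undefined ET excluded from ET accuracy")
                et_um.append(float("nan"))
                continue
            pred_ets.append(pred_et["mean_px"])
            man_ets.append(man_et["mean_px"])
            man_sds.append(man_et["sd_px"])
            et_um.append(pred_et["mean_um"])
        report = cls()
        all_diffs = []
        for name, d in diffs.items():
            d = np.concatenate(d)
            all_diffs.append(d)
            report.per_boundary[name] = {
                "mean_diff": float(d.mean()),
                "sd": float(d.std()),
                "position_accuracy": float((d <= tolerance).mean()),
            }
        alld = np.concatenate(all_diffs)
        report.overall = {
            "mean_diff": float(alld.mean()),
            "sd": float(alld.std()),
            "position_accuracy": float((alld <= tolerance).mean()),
        }
        report.et_per_image_px = pred_ets
        report.et_per_image_um = et_um
        report.et_accuracy = et_accuracy(pred_ets, man_ets, man_sds) if pred_ets else None
        return report

    def to_dict(self) -> dict:
        return {
            "per_boundary": self.per_boundary,
            "overall": self.overall,
            "et_per_image_px": self.et_per_image_px,
            "et_per_image_um": self.et_per_image_um,
            "et_accuracy": self.et_accuracy,
            "classification": self.classification,
        }
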