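"""Evaluation metrics: confusion summaries, ROC/AUC, fluctuation, raters.

The headline figure of merit throughout is SS-Avg — the average of
sensitivity and specificity (balanced accuracy) — because the cohort is
class-imbalanced (21 IP vs 32 CRSwNP at clinical scale) and raw
accuracy would reward the majority class.  ROC curves are built over
patient (or frame) statistics with the decision rule "statistic >= t",
AUC by the trapezoidal rule; the fluctuation summary quantifies the
run-to-run spread of repeated trainings that ensembling suppresses.

The clinician comparison reports each rater's raw correct-diagnosis
rate (the clinical study's metric) alongside a sensitivity/specificity
pair for overlay on the ROC plane, with raters banded by years of
practice (<5 entry, 5-10 intermediate, >10 veteran).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import CohortSchemaError
from .synthetic import LABEL_NEG, LABEL_POS

__all__ = [
    "ConfusionSummary",
    "RocCurve",
    "RaterRecord",
    "FluctuationSummary",
    "confusion",
    "roc",
    "median_case_roc",
    "fluctuation",
    "read_rater_table",
    "experience_band",
    "rater_summary",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Patient- or frame-level confusion counts with derived rates.

    Rates with an empty denominator (a class absent from the evaluated
    set) are NaN, deliberately distinct from zero.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def ss_avg(self) -> float:
        """Average of sensitivity and specificity (balanced accuracy)."""
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def fnr(self) -> float:
        return 1.0 - self.sensitivity

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / n if n else math.nan

    @property
    def undefined(self) -> bool:
        return (self.tp + self.fn == 0) or (self.tn + self.fp == 0)


def confusion(decisions: Mapping[str, str], labels: Mapping[str, str]
              ) -> ConfusionSummary:
    """Tally decisions against true labels (IP = positive class)."""
    if set(decisions) != set(labels):
        raise ValueError("decisions and labels must cover the same patients")
    tp = fn = tn = fp = 0
    for pid, truth in labels.items():
        called_pos = decisions[pid] == LABEL_POS
        if truth == LABEL_POS:
            tp, fn = tp + called_pos, fn + (not called_pos)
        elif truth == LABEL_NEG:
            tn, fp = tn + (not called_pos), fp + called_pos
        else:
            raise ValueError(f"unknown label {truth!r} for patient {pid}")
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class RocCurve:
    """Sorted (fpr, tpr) operating points spanning (0,0)..(1,1)."""

    points: np.ndarray  # shape (n, 2), columns fpr, tpr
    auc: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if np.any(np.diff(pts[:, 0]) < 0) or np.any(np.diff(pts[:, 1]) < 0):
            raise ValueError("ROC points must be monotone non-decreasing")
        object.__setattr__(self, "points", pts)


def roc(statistics, labels) -> RocCurve:
    """ROC curve over a statistic with decision rule ``statistic >= t``.

    Accepts parallel arrays or ``patient -> value`` mappings.  Tied
    statistic values collapse into a single operating point; the curve
    always includes (0,0) and (1,1); AUC is the trapezoidal area.
    """
    if isinstance(statistics, Mapping):
        pids = sorted(statistics)
        if set(pids) != set(labels):
            raise ValueError("statistics and labels must cover the same patients")
        stats = np.array([statistics[p] for p in pids], dtype=float)
        y = np.array([labels[p] == LABEL_POS for p in pids], dtype=int)
    else:
        stats = np.asarray(statistics, dtype=float)
        y = np.array([lab == LABEL_POS if isinstance(lab, str) else bool(lab)
                      for lab in labels], dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = _sk_roc_curve(y, stats, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], [0.0, 0.0]):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.allclose(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocCurve(points=pts, auc=auc)


def median_case_roc(curves: Sequence[RocCurve]) -> RocCurve:
    """The curve whose AUC is the median of the given curves.

    With an even count the lower median is returned, so the result is
    always one of the actual curves, never an interpolation.
    """
    if not curves:
        raise ValueError("need at least one curve")
    order = sorted(range(len(curves)), key=lambda i: curves[i].auc)
    return curves[order[(len(curves) - 1) // 2]]


@dataclass(frozen=True)
class FluctuationSummary:
    """Spread of a metric across repeated trainings (sample sd, n-1)."""

    mean: float
    sd: float
    min: float
    max: float
    n: int


def fluctuation(values: Sequence[float]) -> FluctuationSummary:
    """Descriptive spread of a per-model metric over >= 2 models."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    return FluctuationSummary(mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
                              min=float(arr.min()), max=float(arr.max()),
                              n=int(arr.size))


# ---------------------------------------------------------------------------
# clinician comparison
# ---------------------------------------------------------------------------

RATER_COLUMNS = ["rater_id", "years_experience", "patient_id", "call"]

#: experience bands; the boundary case is resolved as <5 / 5-10 / >10 years
BANDS = ("entry", "intermediate", "veteran")


def experience_band(years: float) -> str:
    if years < 0:
        raise ValueError("years_experience must be non-negative")
    if years < 5:
        return "entry"
    if years <= 10:
        return "intermediate"
    return "veteran"


@dataclass(frozen=True)
class RaterRecord:
    """One clinician's calls over the evaluated patients."""

    rater_id: str
    years_experience: float
    calls: Mapping[str, str] = field(default_factory=dict)

    @property
    def band(self) -> str:
        return experience_band(self.years_experience)


def read_rater_table(path: str | Path) -> list[RaterRecord]:
    """Read rater calls from CSV ``rater_id,years_experience,patient_id,call``."""
    df = pd.read_csv(path, dtype={"rater_id": str, "patient_id": str, "call": str})
    missing = [c for c in RATER_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"rater table {path} missing columns {missing}")
    if not len(df):
        raise CohortSchemaError(f"rater table {path} is empty")
    out: list[RaterRecord] = []
    for rid, grp in df.groupby("rater_id", sort=True):
        years = grp["years_experience"].astype(float).unique()
        if len(years) != 1:
            raise CohortSchemaError(f"rater {rid} has inconsistent years_experience")
        calls = dict(zip(grp["patient_id"], grp["call"]))
        if len(calls) != len(grp):
            raise CohortSchemaError(f"rater {rid} rated a patient twice")
        out.append(RaterRecord(rater_id=str(rid), years_experience=float(years[0]),
                               calls=calls))
    return out


def rater_summary(raters: Sequence[RaterRecord], labels: Mapping[str, str]) -> dict:
    """Per-rater and per-band diagnostic performance.

    For each rater: raw correct-diagnosis rate over the labeled
    patients, plus sensitivity/specificity for an ROC-plane overlay.
    Band summaries average the per-rater correct rates within the three
    experience bands.
    """
    per_rater = []
    for r in raters:
        missing = set(labels) - set(r.calls)
        if missing == set(labels):
            raise ValueError(f"rater {r.rater_id} covers no labeled patients")
        if missing:
            raise ValueError(
                f"rater {r.rater_id} missing calls for {sorted(missing)}")
        cm = confusion({p: r.calls[p] for p in labels}, labels)
        per_rater.append({
            "rater_id": r.rater_id,
            "years_experience": r.years_experience,
            "band": r.band,
            "correct_rate": cm.accuracy,
            "sensitivity": cm.sensitivity,
            "specificity": cm.specificity,
        })
    bands = {}
    for band in BANDS:
        rates = [d["correct_rate"] for d in per_rater if d["band"] == band]
        bands[band] = {
            "n_raters": len(rates),
            "mean_correct_rate": float(np.mean(rates)) if rates else math.nan,
        }
    overall = float(np.mean([d["correct_rate"] for d in per_rater]))
    roc_points = [(1.0 - d["specificity"], d["sensitivity"]) for d in per_rater]
    return {"per_rater": per_rater, "bands": bands,
            "mean_correct_rate": overall, "roc_points": roc_points}
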