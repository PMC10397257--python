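"""Cohort manifests and the patient-grouped cross-validation partition.

Grouped cross-validation is the backbone of the study design: every
frame of a patient lives in exactly one group, so no model is ever
evaluated on a patient whose frames it trained on.  The reference
cohort is 21 IP patients and 32 CRSwNP patients split into 8 groups
"as uniform as possible" in both patients and images; the greedy
longest-first packing below reproduces that structure (per-class group
sizes differ by at most one) with a deterministic, seeded tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import LABEL_NEG, LABEL_POS

__all__ = [
    "PatientRecord",
    "GroupAssignment",
    "JobSpec",
    "CohortSchemaError",
    "read_manifest",
    "write_manifest",
    "balanced_partition",
    "validate_no_leakage",
]

MANIFEST_COLUMNS = ["patient_id", "label", "fps", "n_frames", "source"]
VALID_LABELS = (LABEL_POS, LABEL_NEG)


class CohortSchemaError(ValueError):
    """A manifest or assignment file violates its schema."""


@dataclass(frozen=True)
class PatientRecord:
    """One labeled patient: frame source plus video metadata."""

    patient_id: str
    label: str
    fps: float
    n_frames: int
    source: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise CohortSchemaError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if self.fps <= 0:
            raise CohortSchemaError(f"fps must be positive, got {self.fps}")
        if self.n_frames < 1:
            raise CohortSchemaError(f"n_frames must be >= 1, got {self.n_frames}")

    @property
    def is_positive(self) -> bool:
        return self.label == LABEL_POS


@dataclass(frozen=True)
class GroupAssignment:
    """Patient -> group map for k-group grouped cross-validation."""

    k: int
    mapping: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {p: g for p, g in self.mapping.items() if not 0 <= g < self.k}
        if bad:
            raise ValueError(f"group indices outside 0..{self.k - 1}: {bad}")

    def group_members(self, group: int) -> list[str]:
        return sorted(p for p, g in self.mapping.items() if g == group)

    def group_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for g in self.mapping.values():
            sizes[g] += 1
        return sizes

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame(sorted(self.mapping.items()), columns=["patient_id", "group"])
        df.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "GroupAssignment":
        df = pd.read_csv(path)
        if list(df.columns) != ["patient_id", "group"]:
            raise CohortSchemaError(f"bad assignment header in {path}")
        mapping = dict(zip(df["patient_id"].astype(str), df["group"].astype(int)))
        if len(mapping) != len(df):
            raise CohortSchemaError("duplicate patient_id in assignment")
        return cls(k=int(df["group"].max()) + 1, mapping=mapping)


@dataclass(frozen=True)
class JobSpec:
    """One training job: which patients a model trains on and evaluates."""

    repeat_id: int
    fold_id: int
    train_patients: frozenset[str]
    eval_patients: frozenset[str]


def read_manifest(path: str | Path) -> list[PatientRecord]:
    """Read a cohort manifest CSV, validating schema row by row.

    Columns: ``patient_id,label,fps,n_frames,source``.  Duplicate ids,
    unknown labels and non-positive fps/n_frames raise
    :class:`CohortSchemaError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "label": str, "source": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"manifest {path} missing columns {missing}")
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.patient_id)
        if pid in seen:
            raise CohortSchemaError(
                f"duplicate patient_id {pid!r} at line {row_no} of {path}")
        seen.add(pid)
        try:
            records.append(PatientRecord(
                patient_id=pid, label=str(row.label), fps=float(row.fps),
                n_frames=int(row.n_frames), source=str(row.source)))
        except (CohortSchemaError, ValueError) as exc:
            raise CohortSchemaError(f"line {row_no} of {path}: {exc}") from exc
    return records


def write_manifest(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [(r.patient_id, r.label, r.fps, r.n_frames, r.source) for r in records]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def balanced_partition(records: Sequence[PatientRecord], k: int,
                       seed: int = 0) -> GroupAssignment:
    """Class-stratified greedy partition of patients into ``k`` groups.

    Within each class, patients are taken in decreasing ``n_frames``
    order (ties broken by a seeded shuffle) and each is assigned to the
    group currently holding the fewest patients of that class; ties go
    to the group with the smallest running image total, then to seeded
    group order.  Per-class group sizes therefore differ by at most one,
    and image totals are balanced greedily (longest-first bin packing).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    group_order = rng.permutation(k)  # seeded tie-break of group indices
    class_counts = {g: {lab: 0 for lab in VALID_LABELS} for g in range(k)}
    image_totals = {g: 0 for g in range(k)}
    mapping: dict[str, int] = {}

    for label in VALID_LABELS:
        members = [r for r in records if r.label == label]
        if 0 < len(members) < k:
            warnings.warn(
                f"class {label} has {len(members)} patients for {k} groups; "
                "some evaluation folds will lack this class", stacklevel=2)
        shuffled = list(rng.permutation(len(members)))
        members = [members[i] for i in shuffled]
        members.sort(key=lambda r: -r.n_frames)  # stable: seeded order breaks ties
        for rec in members:
            best = min(
                range(k),
                key=lambda g: (class_counts[g][label], image_totals[g],
                               int(np.where(group_order == g)[0][0])))
            mapping[rec.patient_id] = best
            class_counts[best][label] += 1
            image_totals[best] += rec.n_frames

    if len(mapping) != len(records):
        raise ValueError("duplicate patient_id in records")
    return GroupAssignment(k=k, mapping=mapping)


def validate_no_leakage(assignment: GroupAssignment,
                        training_jobs: Iterable[JobSpec]) -> list[str]:
    """Check that no patient appears on both sides of any training job.

    Returns a list of human-readable violations (empty means the plan is
    leakage-free).  Also flags evaluation patients that are not in the
    fold the job claims to evaluate.
    """
    violations: list[str] = []
    for job in training_jobs:
        leaked = job.train_patients & job.eval_patients
        for pid in sorted(leaked):
            violations.append(
                f"repeat {job.repeat_id} fold {job.fold_id}: patient {pid} "
                "appears in both training and evaluation sets")
        fold_members = set(assignment.group_members(job.fold_id))
        for pid in sorted(job.eval_patients - fold_members):
            violations.append(
                f"repeat {job.repeat_id} fold {job.fold_id}: patient {pid} "
                f"evaluated but not assigned to group {job.fold_id}")
        for pid in sorted(job.train_patients & fold_members):
            violations.append(
                f"repeat {job.repeat_id} fold {job.fold_id}: patient {pid} "
                f"of held-out group {job.fold_id} used for training")
    return violations
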