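"""Patient-level aggregation of frame scores.

Two original patient-unit decision rules sit at the heart of the
diagnostic system, both exploiting the fact that lesion evidence in a
video is temporally contiguous:

* **continuity analysis** — the patient statistic is the length of the
  longest run of consecutive frames whose score clears a frame
  threshold tau; the patient is called positive when the run reaches a
  length cutoff L.
* **five-second scoring** — the statistic is the maximum, over all
  contiguous windows spanning ``window_seconds`` of video, of the
  window's summed score.  We report the window *mean* (sum / W): it
  orders patients identically at fixed W, is invariant to frame rate,
  and keeps the cutoff theta interpretable on [0, 1].  At the reference
  119.88 frames/s a 5-s window is W = 599 frames.

Leave-one-repeat-out ensembles (24-of-25 at clinical scale) average
the committee's score streams frame by frame before aggregation, which
suppresses run-to-run training fluctuation.

Boundary convention, used uniformly: a score equal to tau counts as a
positive frame, and a statistic equal to its cutoff counts as a
positive patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort import GroupAssignment
from .synthetic import LABEL_NEG, LABEL_POS, ScoreStream

__all__ = [
    "AggregationConfig",
    "ensemble_stream",
    "ensemble_all",
    "frame_decision",
    "max_run_length",
    "max_window_mean",
    "window_frames",
    "patient_decision",
    "select_threshold",
    "select_fold_thresholds",
]


@dataclass(frozen=True)
class AggregationConfig:
    """Thresholds and window length of the two aggregation rules.

    ``run_length_threshold`` (L) and ``window_stat_threshold`` (theta)
    default to None, meaning "select on training folds per run" — no
    fixed clinical values exist for them.
    """

    frame_threshold: float = 0.5
    window_seconds: float = 5.0
    run_length_threshold: int | None = None
    window_stat_threshold: float | None = None
    ensemble_rule: str = "mean"  # or "vote"

    def __post_init__(self) -> None:
        if not 0.0 <= self.frame_threshold <= 1.0:
            raise ValueError("frame_threshold must lie in [0, 1]")
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.run_length_threshold is not None and self.run_length_threshold < 1:
            raise ValueError("run_length_threshold must be >= 1")
        if self.window_stat_threshold is not None and not 0.0 <= self.window_stat_threshold <= 1.0:
            raise ValueError("window_stat_threshold must lie in [0, 1]")
        if self.ensemble_rule not in ("mean", "vote"):
            raise ValueError("ensemble_rule must be 'mean' or 'vote'")


def _check_same_patient(streams: Sequence[ScoreStream]) -> None:
    if len(streams) < 2:
        raise ValueError("need at least 2 streams to form an ensemble")
    pids = {s.patient_id for s in streams}
    if len(pids) != 1:
        raise ValueError(f"streams mix patients: {sorted(pids)}")
    lengths = {len(s) for s in streams}
    if len(lengths) != 1:
        raise ValueError(f"streams have mismatched lengths: {sorted(lengths)}")


def ensemble_all(streams: Sequence[ScoreStream], rule: str = "mean",
                 frame_threshold: float = 0.5) -> ScoreStream:
    """Combine all given repeats of one patient frame by frame."""
    _check_same_patient(streams)
    mat = np.stack([s.scores for s in streams])
    if rule == "mean":
        combined = mat.mean(axis=0)
    elif rule == "vote":
        combined = ((mat >= frame_threshold).mean(axis=0) >= 0.5).astype(float)
    else:
        raise ValueError(f"unknown ensemble rule {rule!r}")
    return ScoreStream(patient_id=streams[0].patient_id, fps=streams[0].fps,
                       scores=combined, repeat_id="ens-all")


def ensemble_stream(streams: Sequence[ScoreStream], exclude_repeat: str,
                    rule: str = "mean", frame_threshold: float = 0.5) -> ScoreStream:
    """Leave-one-repeat-out ensemble for one patient.

    Averages (or majority-votes) the R-1 streams whose ``repeat_id``
    differs from ``exclude_repeat``; with R=25 this is the 24-of-25
    ensemble of the clinical protocol.
    """
    _check_same_patient(streams)
    present = [s.repeat_id for s in streams]
    if exclude_repeat not in present:
        raise ValueError(f"repeat {exclude_repeat!r} not among {present}")
    kept = [s for s in streams if s.repeat_id != exclude_repeat]
    if len(kept) < 1:
        raise ValueError("excluding that repeat leaves no streams")
    if len(kept) == 1:
        out = kept[0].scores.copy()
        if rule == "vote":
            out = (out >= frame_threshold).astype(float)
        return ScoreStream(patient_id=streams[0].patient_id, fps=streams[0].fps,
                           scores=out, repeat_id=f"ens-ex{exclude_repeat}")
    ens = ensemble_all(kept, rule=rule, frame_threshold=frame_threshold)
    return ScoreStream(patient_id=ens.patient_id, fps=ens.fps,
                       scores=ens.scores, repeat_id=f"ens-ex{exclude_repeat}")


def frame_decision(score: float, frame_threshold: float = 0.5) -> str:
    """Single-image-unit call: IP iff score >= tau (boundary positive)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return LABEL_POS if score >= frame_threshold else LABEL_NEG


def max_run_length(stream: ScoreStream | np.ndarray,
                   frame_threshold: float = 0.5) -> int:
    """Continuity statistic: longest run of consecutive positive frames.

    A frame is positive when its score >= tau; returns 0 when no frame
    clears the threshold.
    """
    scores = stream.scores if isinstance(stream, ScoreStream) else np.asarray(stream, float)
    if scores.size == 0:
        raise ValueError("empty stream")
    pos = scores >= frame_threshold
    if not pos.any():
        return 0
    # run lengths via boundaries of the boolean sequence
    padded = np.concatenate([[0], pos.astype(np.int8), [0]])
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def window_frames(window_seconds: float, fps: float, n_frames: int) -> int:
    """Window length in frames: round(seconds * fps), clipped to [1, n]."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    w = int(round(window_seconds * fps))
    return max(1, min(w, n_frames))


def max_window_mean(stream: ScoreStream | np.ndarray,
                    window_seconds: float = 5.0,
                    fps: float | None = None) -> float:
    """Five-second-scoring statistic: best sliding-window mean score.

    W = round(window_seconds * fps) frames (clipped to the stream
    length); returns the maximum over all contiguous length-W windows of
    the mean score, computed by a single sliding-sum pass.  Equal to the
    maximum window *sum* divided by W, so it ranks patients identically.
    """
    if isinstance(stream, ScoreStream):
        scores, f = stream.scores, stream.fps
    else:
        scores, f = np.asarray(stream, float), fps
    if f is None:
        raise ValueError("fps required when passing a bare score array")
    if scores.size == 0:
        raise ValueError("empty stream")
    w = window_frames(window_seconds, f, scores.size)
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    window_sums = csum[w:] - csum[:-w]
    return float(window_sums.max() / w)


def patient_decision(statistic: float, threshold: float) -> str:
    """Patient-unit call: IP iff the statistic reaches its cutoff."""
    return LABEL_POS if statistic >= threshold else LABEL_NEG


def select_threshold(statistics: Mapping[str, float],
                     labels: Mapping[str, str]) -> float:
    """Cutoff maximizing SS-Avg (mean of sensitivity and specificity).

    Candidates are the observed statistic values plus one value above
    the maximum (the all-negative rule); the decision rule is
    ``statistic >= t``.  Among maximizers the smallest cutoff is
    returned (favoring sensitivity).  Intended to be applied to
    training-fold patients only.
    """
    pids = sorted(statistics)
    if set(pids) != set(labels):
        raise ValueError("statistics and labels must cover the same patients")
    stats = np.array([statistics[p] for p in pids], dtype=float)
    y = np.array([labels[p] == LABEL_POS for p in pids])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    candidates = np.unique(stats)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    best_t, best_ss = None, -1.0
    for t in candidates:
        pred = stats >= t
        sens = (pred & y).sum() / n_pos if n_pos else np.nan
        spec = (~pred & ~y).sum() / n_neg if n_neg else np.nan
        ss = np.nanmean([sens, spec])
        if ss > best_ss + 1e-12:
            best_ss, best_t = ss, float(t)
    return best_t


def select_fold_thresholds(statistics: Mapping[str, float],
                           labels: Mapping[str, str],
                           assignment: GroupAssignment) -> dict[int, float]:
    """Per-fold cutoffs chosen on out-of-fold patients only.

    For evaluating fold f, the cutoff is selected by maximizing SS-Avg
    over the patients of every *other* fold, so the evaluation fold
    never influences its own operating point.
    """
    out: dict[int, float] = {}
    for f in range(assignment.k):
        train = {p: statistics[p] for p in statistics
                 if assignment.mapping[p] != f}
        if not train:
            raise ValueError(f"no out-of-fold patients available for fold {f}")
        out[f] = select_threshold(train, {p: labels[p] for p in train})
    return out
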