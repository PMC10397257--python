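"""The (K folds x R repeats) training committee.

Each job ``(repeat r, fold f)`` trains one frame classifier on the
augmented frames of every group except ``f`` and then scores, in video
order, every frame of every patient of group ``f``.  With K=8 and R=25
this is the clinical protocol's 200 models; the desk-scale defaults
(K=4, R=5) keep the same structure at laptop cost.  Repeats share the
partition but use different per-job seeds for pool construction and
epoch sampling, so they differ exactly the way repeated trainings of a
stochastic learner differ.

The coupling to any learning machinery is confined to
:class:`FrameClassifier`: ``fit`` takes frame samples with binary
labels and a seed, ``score`` returns values in [0, 1] (higher = more
IP-like).  The default backend is a deliberately small, deterministic
texture-feature + logistic-regression model — the quantity under study
here is the committee/aggregation protocol, not classifier capacity —
and an oracle backend that emits the synthetic generator's latent
scores supports classifier-free end-to-end checks.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, laplace
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import GroupAssignment, JobSpec, PatientRecord, validate_no_leakage
from .frame_prep import (FrameLoader, FramePrepConfig, build_pool, materialize,
                         sample_epoch)
from .synthetic import ScoreStream

__all__ = [
    "TrainingPlan",
    "FrameSample",
    "FrameClassifier",
    "TextureLogisticClassifier",
    "OracleClassifier",
    "make_backend",
    "enumerate_jobs",
    "job_seed",
    "run_committee",
    "ScoreStreamStore",
    "write_score_streams",
    "read_score_streams",
    "iter_score_rows",
    "store_from_streams",
]

log = logging.getLogger("endodx.committee")

STREAM_COLUMNS = ["patient_id", "repeat_id", "frame_index", "score"]


@dataclass(frozen=True)
class FrameSample:
    """One materialized frame: its identity plus pixel data."""

    ref: tuple[str, int]                 # (patient_id, frame_index)
    pixels: np.ndarray | None = None     # HxWx3 uint8; None for ref-only use
    #: set when the pixels are a pure (untransformed) render of ref, so
    #: derived features may be cached across models
    cacheable: bool = False


class FrameClassifier:
    """Contract every committee backend honors.

    ``fit(samples, labels, seed)`` trains in place; ``score(samples)``
    returns one value in [0, 1] per sample, higher meaning more
    IP-like.  Given the same samples and seed, both are deterministic.
    """

    def fit(self, samples: Sequence[FrameSample], labels: np.ndarray,
            seed: int) -> "FrameClassifier":
        raise NotImplementedError

    def score(self, samples: Sequence[FrameSample]) -> np.ndarray:
        raise NotImplementedError


def _texture_features(pixels: np.ndarray) -> np.ndarray:
    """Hand-crafted texture summary of one RGB frame (12 features).

    Channel statistics plus high-pass, gradient and Laplacian energies:
    cheap, rotation/flip-insensitive, and sensitive to the fine-scale
    papillary texture that distinguishes lesion frames.
    """
    x = pixels.astype(np.float64) / 255.0
    gray = x.mean(axis=2)
    hp1 = gray - gaussian_filter(gray, 1.0)
    hp2 = gray - gaussian_filter(gray, 2.0)
    gy, gx = np.gradient(gray)
    gmag = np.hypot(gx, gy)
    lap = laplace(gray)
    return np.array([
        x[..., 0].mean(), x[..., 1].mean(), x[..., 2].mean(),
        x[..., 0].std(), x[..., 1].std(), x[..., 2].std(),
        hp1.std(), np.abs(hp1).mean(), hp2.std(),
        gmag.mean(), gmag.std(), lap.std(),
    ])


class TextureLogisticClassifier(FrameClassifier):
    """Default backend: standardized texture features + logistic regression.

    Small, fast and fully deterministic given its training sample; the
    stochasticity across committee repeats comes from augmentation-pool
    and epoch sampling, mirroring run-to-run variability of heavier
    learners without their cost.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 500,
                 feature_cache: dict | None = None):
        self.C = C
        self.max_iter = max_iter
        #: optional ref -> feature-vector memo, shared across committee
        #: models; only consulted for samples marked cacheable
        self.feature_cache = feature_cache
        self._model = None

    def _features(self, samples: Sequence[FrameSample]) -> np.ndarray:
        cache = self.feature_cache
        rows = []
        for s in samples:
            if cache is not None and s.cacheable:
                feat = cache.get(s.ref)
                if feat is None:
                    feat = _texture_features(s.pixels)
                    cache[s.ref] = feat
            else:
                feat = _texture_features(s.pixels)
            rows.append(feat)
        return np.stack(rows)

    def fit(self, samples, labels, seed):
        X = self._features(samples)
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training sample must contain both classes")
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=self.C, max_iter=self.max_iter,
                               random_state=int(seed) % (2**31)))
        self._model.fit(X, y)
        return self

    def score(self, samples):
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        return self._model.predict_proba(self._features(samples))[:, 1]


class OracleClassifier(FrameClassifier):
    """Backend that looks up the synthetic generator's latent true score.

    Ignores pixels entirely; used to verify that the committee machinery
    is a faithful identity map around whatever backend it is given.
    """

    def __init__(self, truth: Mapping[tuple[str, int], float]):
        self.truth = truth

    def fit(self, samples, labels, seed):
        return self

    def score(self, samples):
        return np.array([self.truth[s.ref] for s in samples])


_BACKENDS: dict[str, type] = {
    "texture-logistic": TextureLogisticClassifier,
    "oracle": OracleClassifier,
}


def make_backend(name: str, **params) -> FrameClassifier:
    """Instantiate a registered backend by name."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; known: {sorted(_BACKENDS)}")
    return cls(**params)


@dataclass(frozen=True)
class TrainingPlan:
    """Full committee specification: folds x repeats x preparation."""

    k_folds: int = 4
    r_repeats: int = 5
    prep: FramePrepConfig = field(default_factory=FramePrepConfig)
    backend: str = "texture-logistic"
    backend_params: Mapping = field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.r_repeats < 1:
            raise ValueError("r_repeats must be >= 1")
        if self.master_seed < 0:
            raise ValueError("master_seed must be non-negative")


def enumerate_jobs(plan: TrainingPlan) -> list[tuple[int, int]]:
    """All (repeat, fold) jobs in lexicographic order; length K x R."""
    return [(r, f) for r in range(plan.r_repeats) for f in range(plan.k_folds)]


def job_seed(master_seed: int, repeat: int, fold: int) -> int:
    """Stable per-job seed derived from (master_seed, repeat, fold)."""
    h = hashlib.sha256(f"{master_seed}:{repeat}:{fold}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


#: in-memory store: (patient_id, repeat_id) -> ScoreStream
ScoreStreamStore = dict


def _load_patient_samples(rec: PatientRecord, loader: FrameLoader,
                          target_size: int) -> list[FrameSample]:
    from .frame_prep import AugmentDescriptor
    out = []
    for t in range(rec.n_frames):
        desc = AugmentDescriptor(frame_ref=(rec.patient_id, t))
        out.append(FrameSample(ref=(rec.patient_id, t),
                               pixels=materialize(desc, target_size, loader),
                               cacheable=True))
    return out


def run_committee(plan: TrainingPlan, records: Sequence[PatientRecord],
                  assignment: GroupAssignment, frames_root: str | Path,
                  backend_factory: Callable[[], FrameClassifier] | None = None,
                  ) -> ScoreStreamStore:
    """Run every (repeat, fold) job and collect held-out score streams.

    Returns a store with exactly one :class:`ScoreStream` per
    ``(patient, repeat)``; the model producing a patient's stream never
    saw that patient (the leakage check runs on every job and a
    violation raises).  Deterministic per plan + cohort + seed.
    """
    by_id = {r.patient_id: r for r in records}
    missing = set(by_id) - set(assignment.mapping)
    if missing:
        raise ValueError(f"patients not covered by assignment: {sorted(missing)}")
    if assignment.k != plan.k_folds:
        raise ValueError(
            f"assignment has {assignment.k} groups but plan expects {plan.k_folds}")

    loader = FrameLoader(frames_root, records)
    if backend_factory is None:
        shared_cache: dict = {}
        params = dict(plan.backend_params)
        if plan.backend == "texture-logistic":
            params.setdefault("feature_cache", shared_cache)
        backend_factory = lambda: make_backend(plan.backend, **params)

    label_of = {r.patient_id: int(r.is_positive) for r in records}
    store: ScoreStreamStore = {}
    eval_cache: dict[str, list[FrameSample]] = {}

    for repeat, fold in enumerate_jobs(plan):
        t0 = time.perf_counter()
        seed = job_seed(plan.master_seed, repeat, fold)
        train_recs = [r for r in records if assignment.mapping[r.patient_id] != fold]
        eval_recs = sorted((r for r in records
                            if assignment.mapping[r.patient_id] == fold),
                           key=lambda r: r.patient_id)
        job = JobSpec(repeat_id=repeat, fold_id=fold,
                      train_patients=frozenset(r.patient_id for r in train_recs),
                      eval_patients=frozenset(r.patient_id for r in eval_recs))
        violations = validate_no_leakage(assignment, [job])
        if violations:
            raise RuntimeError("patient leakage detected: " + "; ".join(violations))
        if not eval_recs:
            log.warning("repeat=%d fold=%d has no evaluation patients", repeat, fold)
            continue

        prep = replace(plan.prep, seed=seed)
        pool = build_pool(train_recs, prep)
        train_samples: list[FrameSample] = []
        train_labels: list[int] = []
        for e in range(prep.n_epochs):
            epoch = sample_epoch(pool, prep.epoch_size, e, seed,
                                 prep.sample_with_replacement)
            for desc in epoch:
                train_samples.append(FrameSample(
                    ref=desc.frame_ref,
                    pixels=materialize(desc, prep.target_size, loader)))
                train_labels.append(label_of[desc.frame_ref[0]])

        clf = backend_factory().fit(train_samples, np.array(train_labels), seed)

        for rec in eval_recs:
            if rec.patient_id not in eval_cache:
                eval_cache[rec.patient_id] = _load_patient_samples(
                    rec, loader, prep.target_size)
            scores = np.clip(clf.score(eval_cache[rec.patient_id]), 0.0, 1.0)
            store[(rec.patient_id, str(repeat))] = ScoreStream(
                patient_id=rec.patient_id, fps=rec.fps, scores=scores,
                repeat_id=str(repeat))
        log.info("job repeat=%d fold=%d seed=%d done in %.1fs",
                 repeat, fold, seed, time.perf_counter() - t0)
    return store


def store_from_streams(streams: Iterable[ScoreStream]) -> ScoreStreamStore:
    """Pack externally produced streams (classifier-free mode) into a store."""
    store: ScoreStreamStore = {}
    for s in streams:
        key = (s.patient_id, s.repeat_id or "0")
        if key in store:
            raise ValueError(f"duplicate stream for {key}")
        store[key] = s
    return store


# ---------------------------------------------------------------------------
# score-stream CSV I/O
# ---------------------------------------------------------------------------

def write_score_streams(store: ScoreStreamStore | Iterable[ScoreStream],
                        path: str | Path) -> None:
    """Write streams to CSV ``patient_id,repeat_id,frame_index,score``.

    Frames are written 0-based in video order, one stream after another.
    """
    streams = store.values() if isinstance(store, dict) else store
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(STREAM_COLUMNS) + "\n")
        for s in streams:
            rid = s.repeat_id or "0"
            for t, v in enumerate(s.scores):
                fh.write(f"{s.patient_id},{rid},{t},{v:.10g}\n")


def iter_score_rows(path: str | Path, chunksize: int = 65536
                    ) -> Iterator[tuple[str, str, int, float]]:
    """Stream validated rows from a score CSV with a bounded working set.

    Yields ``(patient_id, repeat_id, frame_index, score)``; malformed or
    out-of-range rows raise ``ValueError`` naming the line number.
    """
    line_no = 1  # header
    for chunk in pd.read_csv(path, chunksize=chunksize,
                             dtype={"patient_id": str, "repeat_id": str}):
        if list(chunk.columns) != STREAM_COLUMNS:
            raise ValueError(f"bad header in {path}: {list(chunk.columns)}")
        scores = chunk["score"].to_numpy(dtype=float)
        bad = ~(np.isfinite(scores) & (scores >= 0.0) & (scores <= 1.0))
        if bad.any():
            first = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"line {line_no + first + 1} of {path}: score "
                f"{scores[first]!r} outside [0, 1]")
        for pid, rid, fidx, sc in zip(chunk["patient_id"], chunk["repeat_id"],
                                      chunk["frame_index"], scores):
            yield str(pid), str(rid), int(fidx), float(sc)
        line_no += len(chunk)


def read_score_streams(path: str | Path, fps: float | None = None,
                       fps_by_patient: Mapping[str, float] | None = None
                       ) -> ScoreStreamStore:
    """Read a score CSV back into a store (inverse of write).

    Rows of one stream must be contiguous with frame_index counting up
    from 0; ``fps`` (scalar or per-patient map) attaches video timing,
    defaulting to 119.88 frames/s when unspecified.
    """
    store: ScoreStreamStore = {}
    cur_key: tuple[str, str] | None = None
    cur_scores: list[float] = []

    def flush():
        if cur_key is None:
            return
        pid, rid = cur_key
        f = (fps_by_patient or {}).get(pid, fps if fps is not None else 119.88)
        if cur_key in store:
            raise ValueError(f"non-contiguous rows for stream {cur_key} in {path}")
        store[cur_key] = ScoreStream(patient_id=pid, fps=f,
                                     scores=np.array(cur_scores), repeat_id=rid)

    for pid, rid, fidx, sc in iter_score_rows(path):
        key = (pid, rid)
        if key != cur_key:
            flush()
            cur_key, cur_scores = key, []
        if fidx != len(cur_scores):
            raise ValueError(
                f"stream {key} in {path}: expected frame_index "
                f"{len(cur_scores)}, got {fidx}")
        cur_scores.append(sc)
    flush()
    return store
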