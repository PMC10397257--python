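"""Seeded synthetic endoscopy cohorts.

Clinical endoscopic video of sinonasal inverted papilloma (IP) versus
chronic rhinosinusitis with nasal polyps (CRSwNP) is not publicly
deposited, so this module generates surrogate cohorts with the one
statistical property the patient-level aggregation methods rely on:
in a positive patient the diagnostic evidence is *temporally
contiguous* — the lesion drifts in and out of view in runs of frames,
not in independent single frames.

Two output forms are supported, driven by the same latent process:

* **score streams** — per-frame positive-class probabilities, standing
  in for the held-out output of a trained frame classifier;
* **frame images** — small procedural RGB frames in which
  lesion-visible frames of positive patients carry a high-frequency
  papillary ("raspberry-like") texture, so that a real classifier can
  be trained end to end.

Latent model, per positive patient: lesion visibility follows a
two-state Markov chain with mean visible dwell ``lesion_dwell`` frames
and stationary visible fraction ``lesion_fraction``.  The frame logit is
``+separation/2`` on visible frames and ``0`` elsewhere; negative
patients sit at ``-separation/2`` on every frame.  Additive AR(1) noise
(coefficient ``ar1_rho``, innovation sd ``noise_sd``) is applied on the
logit scale and the result squashed through the logistic function, so
scores stay in [0, 1] without clipping.

Everything is deterministic per ``(master_seed, patient index)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter
from scipy.special import expit

__all__ = [
    "SyntheticCohortConfig",
    "ScoreStream",
    "generate_score_streams",
    "generate_frame_images",
    "frame_filename",
]

LABEL_POS = "IP"
LABEL_NEG = "CRSwNP"

#: zero-padded, 1-based frame file pattern (video order)
FRAME_NAME = "frame_{:06d}.png"


def frame_filename(frame_index: int) -> str:
    """File name for 0-based ``frame_index`` (files are 1-based on disk)."""
    return FRAME_NAME.format(frame_index + 1)


@dataclass(frozen=True)
class ScoreStream:
    """Ordered per-frame positive-class scores for one patient.

    ``scores`` follow the original video order; each value is the
    probability-like output of one model (or ensemble) in [0, 1].
    """

    patient_id: str
    fps: float
    scores: np.ndarray
    repeat_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("scores must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("scores must be finite and within [0, 1]")
        object.__setattr__(self, "scores", arr)

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Knobs of the synthetic cohort generator.

    Defaults are the stock desk-scale benchmark used throughout the test
    suite: 20 + 20 patients, 200 frames each, class separation 3 on the
    logit scale, AR(1) noise with rho 0.8 and innovation sd 1, and the
    lesion in view for ~25% of a positive patient's frames in episodes
    of mean length 30 frames.
    """

    n_pos: int = 20
    n_neg: int = 20
    frames_per_patient: int | tuple[int, int] = 200
    fps: float = 119.88
    separation: float = 3.0
    ar1_rho: float = 0.8
    noise_sd: float = 1.0
    lesion_dwell: float = 30.0
    lesion_fraction: float = 0.25
    #: stationary fraction of distractor (polyp-like) segments in
    #: negative patients' images; 0 disables them
    distractor_fraction: float = 0.0
    image_size: int = 64
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("patient counts must be non-negative")
        lo, hi = self.frame_range()
        if lo < 1 or hi < lo:
            raise ValueError("frames_per_patient must be a positive int or (lo, hi) range")
        for name in ("fps", "separation", "ar1_rho", "noise_sd", "lesion_dwell",
                     "lesion_fraction", "distractor_fraction"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValueError("separation and noise_sd must be non-negative")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if not 0.0 <= self.distractor_fraction < 1.0:
            raise ValueError("distractor_fraction must lie in [0, 1)")
        if self.lesion_dwell < 1.0:
            raise ValueError("lesion_dwell must be >= 1 frame")
        if self.master_seed < 0:
            raise ValueError("master_seed must be non-negative")

    def frame_range(self) -> tuple[int, int]:
        if isinstance(self.frames_per_patient, tuple):
            return self.frames_per_patient
        return (self.frames_per_patient, self.frames_per_patient)

    @property
    def n_patients(self) -> int:
        return self.n_pos + self.n_neg


def _patient_id(index: int) -> str:
    return f"P{index + 1:03d}"


def _visibility_chain(rng: np.random.Generator, n: int, dwell: float,
                      fraction: float) -> np.ndarray:
    """Two-state Markov chain of lesion visibility (bool per frame).

    Mean visible dwell is ``dwell`` frames (geometric), stationary
    visible fraction is ``fraction``.
    """
    if fraction <= 0.0:
        return np.zeros(n, dtype=bool)
    if fraction >= 1.0:
        return np.ones(n, dtype=bool)
    p_exit = 1.0 / dwell
    p_enter = fraction * p_exit / (1.0 - fraction)
    if p_enter > 1.0:
        raise ValueError(
            "incompatible lesion_dwell / lesion_fraction: implied entry "
            f"probability {p_enter:.3f} exceeds 1")
    u = rng.random(n)
    vis = np.empty(n, dtype=bool)
    vis[0] = u[0] < fraction
    for t in range(1, n):
        if vis[t - 1]:
            vis[t] = u[t] >= p_exit
        else:
            vis[t] = u[t] < p_enter
    return vis


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise e_t = rho * e_{t-1} + N(0, sd)."""
    if sd == 0.0:
        return np.zeros(n)
    innov = rng.standard_normal(n) * sd
    # start at the stationary marginal so the series has no burn-in
    innov[0] = rng.standard_normal() * sd / math.sqrt(1.0 - rho * rho)
    if rho == 0.0:
        return innov
    return lfilter([1.0], [1.0, -rho], innov)


def _patient_latents(config: SyntheticCohortConfig, index: int) -> dict:
    """Latent state of patient ``index``: visibility, logits, scores."""
    rng = np.random.default_rng([config.master_seed, index])
    lo, hi = config.frame_range()
    n = int(rng.integers(lo, hi + 1))
    positive = index < config.n_pos
    if positive:
        vis = _visibility_chain(rng, n, config.lesion_dwell, config.lesion_fraction)
        mu = np.where(vis, config.separation / 2.0, 0.0)
    else:
        vis = np.zeros(n, dtype=bool)
        mu = np.full(n, -config.separation / 2.0)
    noise = _ar1_noise(rng, n, config.ar1_rho, config.noise_sd)
    logit = mu + noise
    return {
        "patient_id": _patient_id(index),
        "label": LABEL_POS if positive else LABEL_NEG,
        "n_frames": n,
        "visible": vis,
        "mu": mu,
        "logit": logit,
        "scores": expit(logit),
    }


def generate_score_streams(
    config: SyntheticCohortConfig,
) -> tuple[list[ScoreStream], dict[str, str]]:
    """Simulate held-out frame-classifier score streams for a cohort.

    Returns one :class:`ScoreStream` per patient (``repeat_id`` set to
    ``"truth"``) and a ``patient_id -> label`` map.  Identical config
    and seed reproduce the streams bit for bit.
    """
    streams: list[ScoreStream] = []
    labels: dict[str, str] = {}
    for i in range(config.n_patients):
        lat = _patient_latents(config, i)
        streams.append(ScoreStream(patient_id=lat["patient_id"], fps=config.fps,
                                   scores=lat["scores"], repeat_id="truth"))
        labels[lat["patient_id"]] = lat["label"]
    return streams, labels


# ---------------------------------------------------------------------------
# procedural frame rendering
# ---------------------------------------------------------------------------

# visual constants of the renderer (fractions of dynamic range)
_BG_FIELD_AMP = 0.06          # low-frequency mucosa shading
_LESION_AMP_PER_SEP = 0.04    # papillary texture amplitude per unit separation
_PIXEL_NOISE_PER_SD = 0.02    # per-pixel sensor noise per unit noise_sd
_BASE_COLOR = np.array([0.72, 0.45, 0.42])      # mucosa pink
_LESION_TINT = np.array([1.0, 0.55, 0.6])       # reddish papillary bumps
_DISTRACTOR_TINT = np.array([0.75, 0.85, 0.9])  # pale polyp-like bumps


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((size, size)), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _bump_texture(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    w = rng.standard_normal((size, size))
    t = w - gaussian_filter(w, sigma)
    sd = t.std()
    return t / sd if sd > 0 else t


def _render_patient_frames(config: SyntheticCohortConfig, index: int,
                           visible: np.ndarray,
                           distractor: np.ndarray) -> np.ndarray:
    """Render all frames of one patient as a (n, H, W, 3) uint8 array."""
    rng = np.random.default_rng([config.master_seed, index, 101])
    size = config.image_size
    n = visible.size
    rho = config.ar1_rho
    base = _BASE_COLOR + rng.normal(0.0, 0.02, 3)
    amp = _LESION_AMP_PER_SEP * config.separation
    noise_amp = _PIXEL_NOISE_PER_SD * config.noise_sd
    field = _smooth_field(rng, size, size / 8)
    frames = np.empty((n, size, size, 3), dtype=np.uint8)
    for t in range(n):
        if t > 0:
            innov = _smooth_field(rng, size, size / 8)
            field = rho * field + math.sqrt(1.0 - rho * rho) * innov
        img = base[None, None, :] + _BG_FIELD_AMP * field[:, :, None]
        if visible[t] and amp > 0:
            tex = _bump_texture(rng, size, 1.2)
            img = img + amp * tex[:, :, None] * _LESION_TINT[None, None, :]
        if distractor[t] and amp > 0:
            tex = _bump_texture(rng, size, 2.5)
            img = img + amp * tex[:, :, None] * _DISTRACTOR_TINT[None, None, :]
        if noise_amp > 0:
            img = img + rng.normal(0.0, noise_amp, (size, size, 3))
        frames[t] = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
    return frames


def generate_frame_images(config: SyntheticCohortConfig, out_dir: str | Path):
    """Write a full synthetic cohort to disk: frames, manifest, truth streams.

    Creates ``<out_dir>/<patient_id>/frame_000001.png ...`` (1-based,
    zero-padded, video order), a cohort manifest ``manifest.csv`` and the
    generator's latent truth streams ``truth_streams.csv`` (one stream
    per patient, ``repeat_id = "truth"``), which an oracle backend or a
    classifier-free run can consume directly.

    Returns ``(records, manifest_path)`` where ``records`` are
    :class:`endodx.cohort.PatientRecord` rows matching the manifest.
    Deterministic per config + seed, byte for byte.
    """
    from .cohort import PatientRecord, write_manifest
    from .committee import write_score_streams

    if config.image_size < 32:
        raise ValueError("image_size must be >= 32")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: list[PatientRecord] = []
    streams: list[ScoreStream] = []
    for i in range(config.n_patients):
        lat = _patient_latents(config, i)
        pid = lat["patient_id"]
        n = lat["n_frames"]
        if lat["label"] == LABEL_NEG and config.distractor_fraction > 0:
            drng = np.random.default_rng([config.master_seed, i, 7])
            distractor = _visibility_chain(drng, n, config.lesion_dwell,
                                           config.distractor_fraction)
        else:
            distractor = np.zeros(n, dtype=bool)
        frames = _render_patient_frames(config, i, lat["visible"], distractor)
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        for t in range(n):
            Image.fromarray(frames[t], mode="RGB").save(pdir / frame_filename(t))
        records.append(PatientRecord(patient_id=pid, label=lat["label"],
                                     fps=config.fps, n_frames=n, source=pid))
        streams.append(ScoreStream(patient_id=pid, fps=config.fps,
                                   scores=lat["scores"], repeat_id="truth"))

    manifest_path = out_dir / "manifest.csv"
    write_manifest(records, manifest_path)
    write_score_streams(streams, out_dir / "truth_streams.csv")
    return records, manifest_path


def truth_scores(config: SyntheticCohortConfig) -> dict[tuple[str, int], float]:
    """Latent true score per (patient_id, frame_index), for oracle backends."""
    out: dict[tuple[str, int], float] = {}
    for i in range(config.n_patients):
        lat = _patient_latents(config, i)
        for t, s in enumerate(lat["scores"]):
            out[(lat["patient_id"], t)] = float(s)
    return out
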