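"""Frame preparation: augmentation pools, epoch sampling, materialization.

The training protocol augments the raw frames into a large pool (6
million descriptors at clinical scale) and draws a fresh random subset
each epoch (120,000 at clinical scale, 50 epochs).  Storing 6 million
images is pointless; the pool is therefore a *lazy* sequence of
:class:`AugmentDescriptor` — source frame plus fully instantiated
transform parameters — and images are materialized on demand.  Every
descriptor is a pure function of ``(seed, pool index)``, so a pool of
any size costs nothing until read and is reproducible forever.

Source frames for the pool are drawn uniformly over *all frames of all
training patients*, deliberately ignoring per-patient balance: a
patient with a long video contributes proportionally more augmented
samples, exactly as in the original protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image, ImageEnhance

from .cohort import PatientRecord
from .synthetic import frame_filename

__all__ = [
    "TransformConfig",
    "TransformParams",
    "FramePrepConfig",
    "AugmentDescriptor",
    "AugmentationPool",
    "EpochSample",
    "FrameLoader",
    "build_pool",
    "sample_epoch",
    "materialize",
]

# domain separators for per-purpose RNG streams derived from one seed
_DOMAIN_POOL = 0xA0
_DOMAIN_EPOCH = 0xE0


@dataclass(frozen=True)
class TransformConfig:
    """Enabled transform families and their parameter ranges.

    All transforms are endoscopy-safe: flips and small rotations change
    viewpoint, crops change zoom, brightness/saturation jitter mimics
    illumination differences between scopes.  Set a range to zero (or a
    flag to False) to disable a family.
    """

    hflip: bool = True
    vflip: bool = True
    rotation_deg: float = 20.0
    crop_min: float = 0.8        # minimum crop side as fraction of image
    brightness_jitter: float = 0.2
    saturation_jitter: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_min <= 1.0:
            raise ValueError("crop_min must lie in (0, 1]")
        if self.rotation_deg < 0 or self.brightness_jitter < 0 or self.saturation_jitter < 0:
            raise ValueError("jitter ranges must be non-negative")


@dataclass(frozen=True)
class TransformParams:
    """Fully instantiated transform: applying it is deterministic."""

    hflip: bool = False
    vflip: bool = False
    angle: float = 0.0
    #: crop box as (left, top, right, bottom) fractions of the image
    crop: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)
    brightness: float = 1.0
    saturation: float = 1.0

    def is_identity(self) -> bool:
        return (not self.hflip and not self.vflip and self.angle == 0.0
                and self.crop == (0.0, 0.0, 1.0, 1.0)
                and self.brightness == 1.0 and self.saturation == 1.0)


IDENTITY = TransformParams()


@dataclass(frozen=True)
class AugmentDescriptor:
    """One augmented sample: source frame reference + transform."""

    frame_ref: tuple[str, int]  # (patient_id, 0-based frame index)
    params: TransformParams = IDENTITY


@dataclass(frozen=True)
class FramePrepConfig:
    """Sizes of the augmentation protocol.

    Clinical scale is ``target_size=224, pool_size=6_000_000,
    epoch_size=120_000, n_epochs=50``; the defaults are a desk scale
    with the same structure.
    """

    target_size: int = 64
    pool_size: int = 60_000
    epoch_size: int = 5_000
    n_epochs: int = 5
    transforms: TransformConfig = field(default_factory=TransformConfig)
    sample_with_replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")
        if self.pool_size < 0 or self.epoch_size < 0 or self.n_epochs < 0:
            raise ValueError("pool/epoch sizes must be non-negative")
        if self.epoch_size > self.pool_size:
            raise ValueError("epoch_size must not exceed pool_size")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def paper_scale_prep(seed: int = 0) -> FramePrepConfig:
    """The clinical-scale protocol sizes (224 px, 6M pool, 120k x 50 epochs)."""
    return FramePrepConfig(target_size=224, pool_size=6_000_000,
                           epoch_size=120_000, n_epochs=50, seed=seed)


def _draw_params(rng: np.random.Generator, t: TransformConfig) -> TransformParams:
    hflip = t.hflip and bool(rng.random() < 0.5)
    vflip = t.vflip and bool(rng.random() < 0.5)
    angle = float(rng.uniform(-t.rotation_deg, t.rotation_deg)) if t.rotation_deg > 0 else 0.0
    if t.crop_min < 1.0:
        side = float(rng.uniform(t.crop_min, 1.0))
        left = float(rng.uniform(0.0, 1.0 - side))
        top = float(rng.uniform(0.0, 1.0 - side))
        crop = (left, top, left + side, top + side)
    else:
        crop = (0.0, 0.0, 1.0, 1.0)
    bright = float(rng.uniform(1 - t.brightness_jitter, 1 + t.brightness_jitter))
    sat = float(rng.uniform(1 - t.saturation_jitter, 1 + t.saturation_jitter))
    return TransformParams(hflip=hflip, vflip=vflip, angle=angle, crop=crop,
                           brightness=bright, saturation=sat)


class AugmentationPool(Sequence):
    """Lazy pool of :class:`AugmentDescriptor`.

    ``pool[i]`` is computed on demand from ``(seed, i)``; the pool holds
    only the per-patient frame counts, so clinical-scale pools (millions
    of descriptors) are free to construct.
    """

    def __init__(self, records: Sequence[PatientRecord], config: FramePrepConfig):
        if not records:
            raise ValueError("records must be non-empty")
        self._records = list(records)
        self._config = config
        counts = np.array([r.n_frames for r in self._records], dtype=np.int64)
        self._cum = np.concatenate([[0], np.cumsum(counts)])
        self.total_frames = int(self._cum[-1])

    def __len__(self) -> int:
        return self._config.pool_size

    def _frame_ref(self, flat: int) -> tuple[str, int]:
        pi = int(np.searchsorted(self._cum, flat, side="right")) - 1
        return (self._records[pi].patient_id, int(flat - self._cum[pi]))

    def __getitem__(self, i: int) -> AugmentDescriptor:
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        if i < 0:
            i += len(self)
        if not 0 <= i < len(self):
            raise IndexError(i)
        rng = np.random.default_rng([self._config.seed, _DOMAIN_POOL, i])
        flat = int(rng.integers(self.total_frames))
        return AugmentDescriptor(frame_ref=self._frame_ref(flat),
                                 params=_draw_params(rng, self._config.transforms))

    @property
    def patient_ids(self) -> frozenset[str]:
        return frozenset(r.patient_id for r in self._records)


class EpochSample(Sequence):
    """Lazy view of one epoch's descriptors (indices into a pool)."""

    def __init__(self, pool: AugmentationPool, indices: np.ndarray):
        self._pool = pool
        self._indices = indices

    @property
    def indices(self) -> np.ndarray:
        """Pool indices of this epoch's draws (read-only view)."""
        v = self._indices.view()
        v.flags.writeable = False
        return v

    def __len__(self) -> int:
        return int(self._indices.size)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return self._pool[int(self._indices[i])]


def build_pool(records: Sequence[PatientRecord], config: FramePrepConfig) -> AugmentationPool:
    """Build the lazy augmentation pool over all frames of ``records``.

    Source frames are drawn uniformly over the union of all frames (not
    per-patient balanced); transform parameters are drawn independently
    per descriptor.  Deterministic per ``config.seed``.
    """
    return AugmentationPool(records, config)


def sample_epoch(pool: AugmentationPool, epoch_size: int, epoch_index: int,
                 seed: int, with_replacement: bool = False) -> EpochSample:
    """Draw one epoch's sample from the pool.

    Uniform without replacement within an epoch (with replacement behind
    the flag); epochs with different ``epoch_index`` are independent
    draws.  Deterministic per ``(seed, epoch_index)``.
    """
    if epoch_size > len(pool) and not with_replacement:
        raise ValueError(f"epoch_size {epoch_size} exceeds pool size {len(pool)}")
    rng = np.random.default_rng([seed, _DOMAIN_EPOCH, epoch_index])
    idx = rng.choice(len(pool), size=epoch_size, replace=with_replacement)
    return EpochSample(pool, idx)


class FrameLoader:
    """Reads raw frames from ``<root>/<source>/frame_%06d.png`` (1-based)."""

    def __init__(self, root: str | Path, records: Sequence[PatientRecord] = ()):
        self.root = Path(root)
        self._source = {r.patient_id: r.source for r in records}

    def __call__(self, patient_id: str, frame_index: int) -> Image.Image:
        src = self._source.get(patient_id, patient_id)
        path = self.root / src / frame_filename(frame_index)
        with Image.open(path) as img:
            return img.convert("RGB")


def materialize(descriptor: AugmentDescriptor, target_size: int,
                loader: Callable[[str, int], Image.Image]) -> np.ndarray:
    """Apply a descriptor's transform and resize; returns HxWx3 uint8.

    Order: flips, rotation (bilinear, edge-mean fill), crop, photometric
    jitter, resize.  An identity transform on an already-square image of
    the target size is returned bit-identical (no resampling pass).
    """
    pid, fidx = descriptor.frame_ref
    img = loader(pid, fidx)
    p = descriptor.params
    if p.is_identity() and img.size == (target_size, target_size):
        return np.asarray(img, dtype=np.uint8)
    if p.hflip:
        img = img.transpose(Image.Transpose.FLIP_LEFT_RIGHT)
    if p.vflip:
        img = img.transpose(Image.Transpose.FLIP_TOP_BOTTOM)
    if p.angle != 0.0:
        fill = tuple(int(c) for c in np.asarray(img).reshape(-1, 3).mean(axis=0))
        img = img.rotate(p.angle, resample=Image.Resampling.BILINEAR, fillcolor=fill)
    if p.crop != (0.0, 0.0, 1.0, 1.0):
        w, h = img.size
        box = (round(p.crop[0] * w), round(p.crop[1] * h),
               round(p.crop[2] * w), round(p.crop[3] * h))
        if box[2] - box[0] < 1 or box[3] - box[1] < 1:
            raise ValueError(f"degenerate crop box {box}")
        img = img.crop(box)
    if p.brightness != 1.0:
        img = ImageEnhance.Brightness(img).enhance(p.brightness)
    if p.saturation != 1.0:
        img = ImageEnhance.Color(img).enhance(p.saturation)
    if img.size != (target_size, target_size):
        img = img.resize((target_size, target_size), Image.Resampling.BILINEAR)
    return np.asarray(img, dtype=np.uint8)
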