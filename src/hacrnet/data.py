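"""Synthetic MRI phantoms, volume I/O, paired dataset assembly, and splits.

The phantom generator emulates the gross statistics of a brain MRI slice at
desk scale: piecewise-smooth "tissue" regions (overlapping soft-edged
ellipses with distinct mean intensities), band-limited texture, a smooth
multiplicative bias field (coil inhomogeneity), and Gaussian pixel noise.
It is a pure function of its configuration, seed included.

Real volumes are read from NIfTI files (or directories of 2-D images),
sliced along the last stored axis, and min-max normalized per volume.
Splitting is volume-level so adjacent slices of one subject never straddle
the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .degradation import DegradationConfig, degrade, normalize_intensity

__all__ = [
    "PhantomConfig",
    "SlicePair",
    "VolumeRecord",
    "generate_phantom",
    "generate_phantoms",
    "build_pairs",
    "split_dataset",
    "read_volume",
    "save_image",
    "load_image",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the synthetic slice generator.

    Amplitudes are in normalized intensity units; ``texture_amp`` scales a
    band-limited random field, ``bias_amp`` the deviation of the smooth
    multiplicative bias from 1, ``noise_sd`` the additive Gaussian noise.
    """

    size: int = 256
    n_ellipses: int = 6
    texture_amp: float = 0.10
    texture_scale: float = 1.2  # correlation length of the texture, pixels
    bias_amp: float = 0.08
    noise_sd: float = 0.003
    background: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.size < 32:
            raise ValueError(f"size must be >= 32, got {self.size}")
        if min(self.texture_amp, self.bias_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes must be nonnegative")


@dataclass
class SlicePair:
    """One (LR, HR) sample with provenance."""

    hr: np.ndarray  # 1 x H x W in [0, 1]
    lr: np.ndarray  # 1 x H/r x W/r in [0, 1]
    volume_id: str
    slice_index: int
    scale: int

    def __post_init__(self):
        self.hr = np.asarray(self.hr, dtype=np.float32)
        self.lr = np.asarray(self.lr, dtype=np.float32)
        if self.hr.ndim != 3 or self.lr.ndim != 3:
            raise ValueError("hr/lr must be C x H x W")
        eh = (self.hr.shape[1] // self.scale, self.hr.shape[2] // self.scale)
        if self.lr.shape[1:] != eh:
            raise ValueError(
                f"lr dims {self.lr.shape[1:]} != hr dims / scale {eh}"
            )
        for name, arr in (("hr", self.hr), ("lr", self.lr)):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} intensities outside [0, 1]")


@dataclass
class VolumeRecord:
    path: str
    shape: tuple[int, int, int]
    modality: str = "other"


def _soft_ellipse(size: int, cy, cx, ry, rx, angle) -> np.ndarray:
    """Soft-edged ellipse mask in [0, 1] (~2-pixel sigmoid edge)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    yr = (yy - cy) * np.cos(angle) + (xx - cx) * np.sin(angle)
    xr = -(yy - cy) * np.sin(angle) + (xx - cx) * np.cos(angle)
    q = np.sqrt((yr / ry) ** 2 + (xr / rx) ** 2)
    edge = 2.0 / min(ry, rx)
    return 1.0 / (1.0 + np.exp((q - 1.0) / edge))


def generate_phantom(cfg: PhantomConfig | None = None) -> np.ndarray:
    """Deterministic tissue-like test slice, shape (size, size), in [0, 1]."""
    cfg = cfg or PhantomConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.size
    img = np.full((n, n), cfg.background, dtype=np.float64)

    # piecewise-smooth regions: paint ellipses back to front with soft alpha
    for k in range(cfg.n_ellipses):
        cy, cx = rng.uniform(0.25 * n, 0.75 * n, size=2)
        ry, rx = rng.uniform(0.08 * n, 0.30 * n, size=2)
        angle = rng.uniform(0, np.pi)
        # means spread over [0.25, 0.85] so regions are separable in histogram
        level = 0.25 + 0.6 * ((k + rng.uniform(0, 0.5)) / max(cfg.n_ellipses, 1))
        alpha = _soft_ellipse(n, cy, cx, ry, rx, angle)
        img = img * (1 - alpha) + level * alpha

    foreground = img > cfg.background + 0.05
    if cfg.texture_amp > 0:
        # band-limited texture: white noise smoothed to the configured
        # correlation length (fine-grained, as in MRI parenchyma)
        tex = ndimage.gaussian_filter(rng.standard_normal((n, n)), cfg.texture_scale)
        tex /= max(tex.std(), 1e-12)
        img = img + cfg.texture_amp * tex * foreground
    if cfg.bias_amp > 0:
        # smooth multiplicative field from heavily blurred coarse noise
        bias = ndimage.gaussian_filter(rng.standard_normal((n, n)), n / 4)
        bias /= max(np.abs(bias).max(), 1e-12)
        img = img * (1.0 + cfg.bias_amp * bias)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=(n, n))
    return np.clip(img, 0.0, 1.0)


def generate_phantoms(count: int, cfg: PhantomConfig | None = None) -> list[np.ndarray]:
    """A reproducible family of phantoms: member k uses seed ``cfg.seed + k``."""
    cfg = cfg or PhantomConfig()
    return [
        generate_phantom(PhantomConfig(**{**cfg.__dict__, "seed": cfg.seed + k}))
        for k in range(count)
    ]


def build_pairs(
    hr_images,
    scale: int = 2,
    deg_cfg: DegradationConfig | None = None,
    volume_ids=None,
) -> list[SlicePair]:
    """Degrade each HR image to LR and wrap both with provenance.

    HR images may be (H, W) or (1, H, W); all dims must divide by the scale.
    """
    deg_cfg = deg_cfg or DegradationConfig(scale=scale)
    if deg_cfg.scale != scale:
        raise ValueError("scale argument disagrees with deg_cfg.scale")
    hr_images = [np.asarray(im) for im in hr_images]
    offenders = [
        i
        for i, im in enumerate(hr_images)
        if im.shape[-2] % scale or im.shape[-1] % scale
    ]
    if offenders:
        raise ValueError(
            f"HR dims not divisible by scale {scale} for images {offenders}"
        )
    volume_ids = volume_ids or [f"phantom-{i:04d}" for i in range(len(hr_images))]
    pairs = []
    for vid, im in zip(volume_ids, hr_images):
        hr = im if im.ndim == 3 else im[None]
        lr = degrade(hr, deg_cfg)
        pairs.append(SlicePair(hr=hr, lr=lr, volume_id=vid, slice_index=0, scale=scale))
    return pairs


def split_dataset(items, fractions=(0.7, 0.1, 0.2), seed: int = 0):
    """Seeded volume-level split into (train, val, test).

    ``items`` may be SlicePairs (grouped by ``volume_id``) or arbitrary
    hashable volume keys.  The partition is disjoint and exhaustive; all
    slices of a volume land in the same subset.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    items = list(items)
    by_vol: dict = {}
    for it in items:
        key = it.volume_id if isinstance(it, SlicePair) else it
        by_vol.setdefault(key, []).append(it)
    vols = sorted(by_vol)
    n_nonzero = sum(1 for f in fractions if f > 0)
    if len(vols) < n_nonzero:
        raise ValueError(
            f"{len(vols)} volume(s) cannot fill {n_nonzero} nonzero splits"
        )
    order = np.random.default_rng(seed).permutation(len(vols))
    n_train = int(round(fractions[0] * len(vols)))
    n_val = int(round(fractions[1] * len(vols)))
    n_train = min(n_train, len(vols) - (fractions[1] > 0) - (fractions[2] > 0))
    n_val = max(n_val, 1) if fractions[1] > 0 else 0
    groups = (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )
    out = []
    for g in groups:
        chunk = []
        for j in sorted(g):
            chunk.extend(by_vol[vols[j]])
        out.append(chunk)
    return tuple(out)


def read_volume(path, modality: str = "other"):
    """Read a NIfTI volume (or a directory of 2-D images) as normalized data.

    Returns (VolumeRecord, data) with data shaped (H, W, depth) in [0, 1];
    slices iterate along the last axis.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise IOError(f"no 2-D images found in directory {path}")
        slices = [load_image(p) for p in files]
        data = np.stack(slices, axis=-1).astype(np.float64)
    else:
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # corrupt / unreadable
            raise IOError(f"cannot read NIfTI volume at {path}: {exc}") from exc
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume at {path}, got {data.ndim} axes"
            )
    data = normalize_intensity(data)
    record = VolumeRecord(path=str(path), shape=tuple(data.shape), modality=modality)
    return record, data


def save_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] 2-D image as 16-bit grayscale PNG."""
    from PIL import Image

    img = np.asarray(np.squeeze(img), dtype=np.float64)
    arr = np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(arr, mode="I;16").save(str(path))


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF back to a [0, 1] float image."""
    from PIL import Image

    with Image.open(str(path)) as im:
        arr = np.asarray(im, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    denom = 65535.0 if arr.max() > 255 else (255.0 if arr.max() > 1 else 1.0)
    return arr / denom
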