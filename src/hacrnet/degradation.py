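"""HR -> LR observation model: normalization, Gaussian blur, bicubic decimation.

Low-resolution inputs are synthesized from high-resolution slices by a 3x3
Gaussian blur (sigma = 1) followed by bicubic downsampling at x2 or x4, the
standard spatial-domain MRI degradation protocol.  Intensities are min-max
normalized to [0, 1] per volume beforehand.

The bicubic step uses the cubic convolution kernel

    W(t) = (a+2)|t|^3 - (a+3)|t|^2 + 1        for |t| <= 1
         = a(|t|^3 - 5|t|^2 + 8|t| - 4)       for 1 < |t| < 2

with sharpness parameter ``a`` (default -0.5, the Catmull-Rom dialect).  No
extra anti-aliasing is applied on top of the blur: the blur *is* the
anti-alias stage of the protocol.  Borders reflect for both blur and
resampling to avoid dark rims at tissue boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DegradationConfig",
    "gaussian_kernel",
    "cubic_kernel",
    "bicubic_resize",
    "blur",
    "degrade",
    "normalize_intensity",
]


@dataclass(frozen=True)
class DegradationConfig:
    kernel_size: int = 3
    sigma: float = 1.0
    scale: int = 2
    bicubic_a: float = -0.5
    border_mode: str = "reflect"

    def validate(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.scale not in (2, 4):
            raise ValueError(f"scale must be 2 or 4, got {self.scale}")
        if self.border_mode != "reflect":
            raise ValueError("only reflect border handling is supported")


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Normalized isotropic Gaussian on the integer offset grid.

    Entries are proportional to exp(-(dx^2+dy^2) / (2 sigma^2)) and sum to 1.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def cubic_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """The cubic convolution interpolation kernel W_a(t)."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    near = t <= 1.0
    out[near] = (a + 2.0) * t[near] ** 3 - (a + 3.0) * t[near] ** 2 + 1.0
    far = (t > 1.0) & (t < 2.0)
    out[far] = a * (t[far] ** 3 - 5.0 * t[far] ** 2 + 8.0 * t[far] - 4.0)
    return out


def _resample_weights(n_in: int, n_out: int, a: float):
    """4-tap indices/weights per output coordinate (pixel-area mapping,
    reflected edges, weights renormalized against float drift)."""
    ratio = n_in / n_out
    x = (np.arange(n_out) + 0.5) * ratio - 0.5
    base = np.floor(x).astype(int)
    t = x - base
    idx = base[:, None] + np.arange(-1, 3)[None, :]
    # reflect out-of-range indices (symmetric, half-sample convention)
    idx = np.abs(idx)
    idx = np.where(idx >= n_in, 2 * n_in - 1 - idx, idx)
    idx = np.clip(idx, 0, n_in - 1)
    w = cubic_kernel(t[:, None] - np.arange(-1, 3)[None, :], a)
    w /= w.sum(axis=1, keepdims=True)
    return idx, w


def bicubic_resize(img: np.ndarray, out_h: int, out_w: int, a: float = -0.5) -> np.ndarray:
    """Separable cubic-convolution resampling of a 2-D image (up or down).

    Plain point sampling of the cubic kernel — the kernel support is not
    widened when downscaling, matching a blur-then-decimate protocol where
    anti-aliasing is the blur stage's job.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    idx, w = _resample_weights(img.shape[0], out_h, a)
    img = np.einsum("okw,ok->ow", img[idx, :], w)
    idx, w = _resample_weights(img.shape[1], out_w, a)
    img = np.einsum("hok,ok->ho", img[:, idx], w)
    return img


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Affine map of a volume onto [0, 1]: (x - min) / (max - min)."""
    volume = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(volume).all():
        raise ValueError("volume contains non-finite values")
    lo, hi = volume.min(), volume.max()
    if hi <= lo:
        raise ValueError("constant volume: min-max normalization is undefined")
    return (volume - lo) / (hi - lo)


def blur(img: np.ndarray, cfg: DegradationConfig | None = None) -> np.ndarray:
    """The blur stage alone: Gaussian filtering with reflect borders."""
    cfg = cfg or DegradationConfig()
    cfg.validate()
    kernel = gaussian_kernel(cfg.kernel_size, cfg.sigma)
    return ndimage.convolve(np.asarray(img, dtype=np.float64), kernel, mode="reflect")


def degrade(hr: np.ndarray, cfg: DegradationConfig | None = None) -> np.ndarray:
    """Blur then bicubic-decimate an HR image (or batch) to LR.

    Accepts a 2-D image or any array whose last two axes are spatial; all
    leading axes are processed slice by slice.  H and W must be divisible by
    the scale; output is clamped to [0, 1].
    """
    cfg = cfg or DegradationConfig()
    cfg.validate()
    hr = np.asarray(hr, dtype=np.float64)
    h, w = hr.shape[-2:]
    if h % cfg.scale or w % cfg.scale:
        raise ValueError(
            f"spatial dims ({h}, {w}) not divisible by scale {cfg.scale}; "
            "crop or pad the input explicitly"
        )
    kernel = gaussian_kernel(cfg.kernel_size, cfg.sigma)
    flat = hr.reshape(-1, h, w)
    out = np.empty((flat.shape[0], h // cfg.scale, w // cfg.scale))
    for i, sl in enumerate(flat):
        blurred = ndimage.convolve(sl, kernel, mode="reflect")
        out[i] = bicubic_resize(blurred, h // cfg.scale, w // cfg.scale, cfg.bicubic_a)
    np.clip(out, 0.0, 1.0, out=out)
    return out.reshape(hr.shape[:-2] + out.shape[-2:])
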