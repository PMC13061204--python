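"""Image-quality metrics for super-resolution evaluation.

PSNR and SSIM are computed on [0, 1] images with peak L = 1 (equivalent to
the 8-bit (2^n - 1) form after rescaling), SSIM with the canonical 11x11
Gaussian window (sigma = 1.5) and constants C1 = (0.01 L)^2, C2 = (0.03 L)^2.
LPIPS is exposed as a plugin interface: the caller supplies a feature
backend with pretrained deep features and learned channel weights; no
weights ship with this package.

Identical image pairs yield an infinite PSNR; the sentinel is kept per pair
but excluded from aggregates, with the exclusion count reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PairMetrics",
    "MetricReport",
    "LPIPSBackend",
    "LPIPSUnavailableError",
    "psnr",
    "ssim",
    "lpips",
    "error_map",
    "aggregate",
    "evaluate_pairs",
]


def _check_same_shape(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def psnr(x: np.ndarray, y: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE), in dB.

    Returns ``math.inf`` for identical images.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_same_shape(x, y)
    if peak <= 0:
        raise ValueError(f"peak must be > 0, got {peak}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    peak: float = 1.0,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Mean local structural similarity over a Gaussian-weighted window.

    S = (2 ux uy + C1)(2 cov + C2) / ((ux^2 + uy^2 + C1)(vx + vy + C2)),
    averaged over all fully valid window positions (no border padding).
    """
    x = np.asarray(np.squeeze(x), dtype=np.float64)
    y = np.asarray(np.squeeze(y), dtype=np.float64)
    _check_same_shape(x, y)
    if x.ndim != 2:
        raise ValueError(f"ssim expects single-channel 2-D images, got {x.shape}")
    if min(x.shape) < win_size:
        raise ValueError(
            f"image {x.shape} smaller than the {win_size}x{win_size} window; "
            "use larger inputs or a smaller window"
        )
    w = _gaussian_window(win_size, sigma)

    def wmean(img: np.ndarray) -> np.ndarray:
        return np.einsum("hwij,ij->hw", sliding_window_view(img, w.shape), w)

    ux, uy = wmean(x), wmean(y)
    uxx, uyy, uxy = wmean(x * x), wmean(y * y), wmean(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    s = ((2 * ux * uy + c1) * (2 * cov + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    return float(s.mean())


class LPIPSBackend(Protocol):
    """Supplier of pretrained deep features for perceptual distance.

    ``extract`` maps a 1xCxHxW image in [0, 1] to a list of feature maps
    (C_l, H_l, W_l); ``weights`` holds one nonnegative (C_l,) weight vector
    per layer.
    """

    def extract(self, image: np.ndarray) -> list[np.ndarray]: ...

    @property
    def weights(self) -> list[np.ndarray]: ...


class LPIPSUnavailableError(RuntimeError):
    """Raised when LPIPS is requested without a feature backend."""


def lpips(x: np.ndarray, y: np.ndarray, backend: LPIPSBackend | None) -> float:
    """Learned perceptual distance: per layer, unit-normalize feature vectors
    along channels, weight channel-wise, and average the squared difference
    over spatial positions; sum over layers.  Lower is better; 0 iff the
    feature stacks agree."""
    if backend is None:
        raise LPIPSUnavailableError(
            "LPIPS requires a pretrained feature backend plugin; none is "
            "installed. The metric is reported as absent."
        )
    _check_same_shape(np.asarray(x), np.asarray(y))

    def unit(f: np.ndarray) -> np.ndarray:
        norm = np.sqrt((f**2).sum(axis=0, keepdims=True)) + 1e-10
        return f / norm

    total = 0.0
    for fx, fy, w in zip(backend.extract(x), backend.extract(y), backend.weights):
        d = w[:, None, None] * (unit(fx) - unit(fy))
        hl, wl = d.shape[-2:]
        total += float((d**2).sum() / (hl * wl))
    return total


def error_map(sr: np.ndarray, hr: np.ndarray, rescale: bool = False) -> np.ndarray:
    """Per-pixel absolute residual |sr - hr|; optionally min-max scaled."""
    sr = np.asarray(sr, dtype=np.float64)
    hr = np.asarray(hr, dtype=np.float64)
    _check_same_shape(sr, hr)
    m = np.abs(sr - hr)
    if rescale and m.max() > 0:
        m = m / m.max()
    return m


@dataclass
class PairMetrics:
    pair_id: str
    psnr: float
    ssim: float
    lpips: float | None = None


@dataclass
class MetricReport:
    """Per-pair metric rows plus mean/SD aggregates.

    ``excluded_inf`` counts pairs whose PSNR was the infinite sentinel and
    was therefore left out of the PSNR mean/SD.
    """

    per_pair: list[PairMetrics]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    n: int = 0
    excluded_inf: int = 0


def aggregate(per_pair: Sequence[PairMetrics]) -> MetricReport:
    """Mean and sample SD of each metric across pairs (slices)."""
    rows = list(per_pair)
    if not rows:
        raise ValueError("cannot aggregate an empty metric table")
    report = MetricReport(per_pair=rows, n=len(rows))
    if len(rows) == 1:
        warnings.warn("single-pair report: SD is degenerate (reported as 0)")

    def agg(name: str, values: list[float]) -> None:
        if not values:
            return
        arr = np.asarray(values, dtype=np.float64)
        report.mean[name] = float(arr.mean())
        report.sd[name] = float(arr.std(ddof=1)) if len(values) > 1 else 0.0

    finite_psnr = [r.psnr for r in rows if math.isfinite(r.psnr)]
    report.excluded_inf = sum(1 for r in rows if math.isinf(r.psnr))
    if report.excluded_inf:
        warnings.warn(
            f"{report.excluded_inf} pair(s) with infinite PSNR excluded "
            "from aggregates"
        )
    agg("psnr", finite_psnr)
    agg("ssim", [r.ssim for r in rows])
    agg("lpips", [r.lpips for r in rows if r.lpips is not None])
    return report


def evaluate_pairs(
    predictions: Sequence[np.ndarray],
    references: Sequence[np.ndarray],
    ids: Sequence[str] | None = None,
    lpips_backend: LPIPSBackend | None = None,
) -> MetricReport:
    """PSNR/SSIM (and LPIPS when a backend is supplied) per pair, aggregated."""
    if len(predictions) != len(references):
        raise ValueError("predictions and references differ in length")
    ids = ids or [str(i) for i in range(len(predictions))]
    rows = []
    for pid, sr, hr in zip(ids, predictions, references):
        row = PairMetrics(pair_id=pid, psnr=psnr(sr, hr), ssim=ssim(sr, hr))
        if lpips_backend is not None:
            row.lpips = lpips(sr, hr, lpips_backend)
        rows.append(row)
    return aggregate(rows)
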