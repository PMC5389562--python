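"""Diffraction-limited spot detection and trace extraction.

Spots are found as local maxima on a low-bleach detection image (mean
of the first few frames of a channel's acquisition block), then each
candidate is fit with a symmetric 2D Gaussian plus constant offset in
a small window. A candidate is accepted only if the fit converges, the
fitted width falls inside the expected diffraction-limited range and
the normalized residuals pass a goodness threshold — i.e. acceptance
is based on the intensity profile actually being Gaussian. Intensity
traces are then read out per frame as a background-subtracted sum over
a circular ROI around the (sub-pixel) spot center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = ["Spot", "DetectionParams", "detect_spots", "extract_trace",
           "detection_image", "robust_image_noise_sd"]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds controlling spot detection and acceptance.

    ``threshold_sd`` is the peak height above the image median in
    units of the robust noise SD; ``fit_radius`` sets the square fit
    window; ``sigma_bounds`` bracket acceptable Gaussian widths for a
    diffraction-limited spot; ``max_reduced_residual`` bounds the fit's
    residual variance relative to the image noise variance.
    """

    threshold_sd: float = 5.0
    fit_radius: int = 4
    sigma_bounds: tuple[float, float] = (0.7, 2.5)
    max_reduced_residual: float = 3.0
    crop_origin: int = 0
    crop_size: int | None = None  # None: whole image


@dataclass(frozen=True)
class Spot:
    """One accepted spot: sub-pixel centroid and Gaussian fit summary.

    Coordinates are 0-based, pixel-center convention.
    """

    x: float
    y: float
    amplitude: float
    sigma: float
    background: float
    fit_rss: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def robust_image_noise_sd(image: np.ndarray) -> float:
    """Noise SD from the median absolute deviation of the image."""
    med = np.median(image)
    return float(np.median(np.abs(image - med)) * 1.4826)


def detection_image(stack: np.ndarray, n_frames: int = 5) -> np.ndarray:
    """Mean of the first ``n_frames`` frames: maximal signal before bleaching."""
    return np.asarray(stack[:n_frames], dtype=float).mean(axis=0)


def _gauss2d(params, xx, yy):
    a, x0, y0, sigma, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)) + b


def _fit_gaussian(window: np.ndarray, x_off: int, y_off: int):
    """Fit symmetric Gaussian + offset; returns params in image coords or None."""
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]
    b0 = float(np.median(window))
    a0 = float(window.max() - b0)
    cy, cx = np.unravel_index(np.argmax(window), window.shape)
    p0 = [max(a0, 1e-3), float(cx), float(cy), 1.2, b0]
    try:
        res = optimize.least_squares(
            lambda p: (_gauss2d(p, xx, yy) - window).ravel(),
            p0,
            bounds=([0, -1, -1, 0.2, -np.inf], [np.inf, w, h, 6.0, np.inf]),
            max_nfev=200,
        )
    except Exception:
        return None
    if not res.success:
        return None
    a, x0, y0, sigma, b = res.x
    rss = float(np.sum(res.fun**2))
    return a, x0 + x_off, y0 + y_off, sigma, b, rss


def detect_spots(
    image: np.ndarray,
    params: DetectionParams | None = None,
    channel: str = "",
) -> list[Spot]:
    """Detect and accept spots on a single image.

    Local maxima above ``threshold_sd`` robust noise SDs (over the
    image median) are fit with a symmetric 2D Gaussian + constant
    background in a window of radius ``fit_radius``. A spot is
    accepted iff the fit converges, sigma lies within
    ``sigma_bounds`` and the reduced residual (RSS / (n_pixels *
    noise_sd^2)) is below ``max_reduced_residual``. Detections closer
    than one fit-window radius are merged, keeping the brighter fit. Only
    spots inside the configured analysis crop are returned.
    """
    params = params or DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 7:
        raise ValueError("image must be 2-D and at least 7x7")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")

    noise_sd = robust_image_noise_sd(img)
    med = float(np.median(img))
    threshold = med + params.threshold_sd * max(noise_sd, 1e-12)

    r = params.fit_radius
    footprint = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    local_max = (img == ndimage.maximum_filter(img, footprint=footprint))
    candidates = np.argwhere(local_max & (img > threshold))

    h, w = img.shape
    accepted: list[Spot] = []
    for cy, cx in candidates:
        x0, x1 = cx - r, cx + r + 1
        y0, y1 = cy - r, cy + r + 1
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            continue
        fit = _fit_gaussian(img[y0:y1, x0:x1], x0, y0)
        if fit is None:
            continue
        a, x, y, sigma, b, rss = fit
        lo, hi = params.sigma_bounds
        if not lo <= sigma <= hi:
            continue
        n_pix = (2 * r + 1) ** 2
        if noise_sd > 0 and rss / (n_pix * noise_sd**2) > params.max_reduced_residual:
            continue
        accepted.append(
            Spot(x=float(x), y=float(y), amplitude=float(a), sigma=float(sigma),
                 background=float(b), fit_rss=rss, channel=channel)
        )

    # merge detections within one fit window, keeping the brighter fit
    accepted.sort(key=lambda s: -s.amplitude)
    kept: list[Spot] = []
    for s in accepted:
        if all((s.x - t.x) ** 2 + (s.y - t.y) ** 2 > r**2 for t in kept):
            kept.append(s)

    if params.crop_size is not None:
        o, c = params.crop_origin, params.crop_size
        kept = [s for s in kept if o <= s.x < o + c and o <= s.y < o + c]
    kept.sort(key=lambda s: (s.y, s.x))
    return kept


def extract_trace(
    stack: np.ndarray,
    x: float,
    y: float,
    roi_radius: float = 3.0,
    annulus: tuple[float, float] = (5.0, 8.0),
) -> tuple[np.ndarray, bool]:
    """Background-subtracted intensity trace at (x, y).

    Per frame: sum of pixels within ``roi_radius`` of the spot center
    minus the local background (median of an annulus) times the ROI
    pixel count. Returns the trace and an ``edge_clipped`` flag set
    when the annulus does not fit inside the image (such traces are
    excluded downstream).
    """
    if roi_radius < 1:
        raise ValueError("roi_radius must be >= 1")
    stack = np.asarray(stack)
    n_frames, h, w = stack.shape
    r_out = annulus[1]
    edge_clipped = not (r_out <= x <= w - 1 - r_out and r_out <= y <= h - 1 - r_out)

    half = int(np.ceil(r_out))
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dist2 = (xs - x) ** 2 + (ys - y) ** 2
    roi_mask = dist2 <= roi_radius**2
    ann_mask = (dist2 >= annulus[0] ** 2) & (dist2 <= annulus[1] ** 2)
    sub = stack[:, y0:y1, x0:x1].reshape(n_frames, -1).astype(float)
    roi_flat = roi_mask.ravel()
    ann_flat = ann_mask.ravel()
    roi_sum = sub[:, roi_flat].sum(axis=1)
    if ann_flat.any():
        bg = np.median(sub[:, ann_flat], axis=1)
    else:
        bg = np.zeros(n_frames)
    trace = roi_sum - bg * roi_flat.sum()
    return trace, edge_clipped
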