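"""Image-correction pipeline: HDR exposure fusion, flatfield division,
outlier-pixel repair, registration, stitching, Nyquist downsampling,
spectral unmixing and pre-stain subtraction.

All operations act on floating-point *rate* images (counts per ms after
offset removal) and are deterministic given their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import block_reduce
from skimage.registration import phase_cross_correlation

from .calibration import CrosstalkMatrix, NoiseModel
from .errors import CalibrationError, DegenerateRegistrationError, InputError
from .synthetic import ExposureStack

__all__ = [
    "HDRImage",
    "fuse_hdr",
    "correct_flatfield",
    "repair_outlier_pixels",
    "register_to_reference",
    "stitch_tiles",
    "downsample_nyquist",
    "unmix",
    "subtract_prestain",
    "apply_radial_distortion",
]


@dataclass
class HDRImage:
    """Per-pixel intensity-rate estimate fused from an exposure series.

    ``variance`` is the propagated read-noise variance of the rate estimate;
    pixels saturated in every frame carry an infinite-variance sentinel and
    are flagged in ``saturated_replaced``.
    """

    rate: np.ndarray
    variance: np.ndarray
    saturated_replaced: np.ndarray


def fuse_hdr(stack: ExposureStack, noise: NoiseModel,
             saturation_margin: float = 0.98) -> HDRImage:
    """Fuse an exposure series into a single rate image.

    Each unsaturated frame contributes the estimate
    ``(counts - offset) / exposure`` with read-noise variance
    ``read_sigma**2 / exposure**2`` (rate units).  Frames at or above
    ``saturation_margin * saturation_level`` are excluded per pixel; the
    remaining estimates are combined by inverse-variance weighting, the
    minimum-variance unbiased combination under the Gaussian read-noise
    model.  Longer exposures therefore dominate wherever they are not
    clipped, which is what boosts signal-to-noise in the dim parts of the
    image.  Pixels saturated in *all* frames are assigned the
    shortest-exposure estimate and flagged.
    """
    frames = stack.frames
    if frames.shape[0] == 0:
        raise InputError("empty exposure stack")
    exps = np.asarray(stack.exposure_ms, dtype=float)[:, None, None]
    sat_thresh = saturation_margin * noise.saturation_level
    valid = frames < sat_thresh
    rates = (frames - noise.read_offset) / exps
    # inverse-variance weights: 1/var_i = exposure_i**2 / sigma**2
    inv_var = np.where(valid, exps**2 / noise.read_sigma**2, 0.0)
    wsum = inv_var.sum(axis=0)
    all_saturated = wsum == 0.0
    safe_wsum = np.where(all_saturated, 1.0, wsum)
    rate = (inv_var * rates).sum(axis=0) / safe_wsum
    variance = np.where(all_saturated, np.inf, 1.0 / safe_wsum)
    rate = np.where(all_saturated, rates[0], rate)
    return HDRImage(rate=rate, variance=variance, saturated_replaced=all_saturated)


def correct_flatfield(image: np.ndarray, flatfield: np.ndarray) -> np.ndarray:
    """Divide out the multiplicative pixel-sensitivity/illumination profile."""
    image = np.asarray(image, dtype=float)
    flatfield = np.asarray(flatfield, dtype=float)
    if image.shape != flatfield.shape:
        raise InputError("image and flatfield shapes differ")
    if np.any(flatfield <= 0):
        raise CalibrationError("flatfield contains nonpositive pixels")
    return image / flatfield


def repair_outlier_pixels(image: np.ndarray, window: int = 3,
                          k_sigma: float = 5.0,
                          sigma_ref: float = 1.0) -> np.ndarray:
    """Replace hot/cold outlier pixels by the local window median.

    A pixel is repaired iff it deviates from the median over its
    ``window x window`` neighborhood by more than ``k_sigma * sigma_ref``;
    all other pixels pass through untouched.
    """
    if window < 3 or window % 2 == 0:
        raise InputError("window must be odd and >= 3")
    image = np.asarray(image, dtype=float)
    med = ndimage.median_filter(image, size=window, mode="reflect")
    outlier = np.abs(image - med) > k_sigma * sigma_ref
    return np.where(outlier, med, image)


def register_to_reference(moving: np.ndarray, reference: np.ndarray,
                          upsample: int = 10) -> tuple[tuple[float, float], np.ndarray]:
    """Estimate the subpixel shift mapping ``moving`` onto ``reference``.

    Cross-correlation maximisation with subpixel refinement; the moving
    image is resampled by linear interpolation.  The registration channel
    is typically the nuclear stain, whose shift is then applied to all
    channels of the cycle.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise InputError("moving and reference shapes differ")
    if np.ptp(reference) == 0:
        raise DegenerateRegistrationError("reference image is flat")
    shift, _, _ = phase_cross_correlation(reference, moving,
                                          upsample_factor=upsample,
                                          normalization=None)
    resampled = ndimage.shift(moving, shift, order=1, mode="constant", cval=0.0)
    return (float(shift[0]), float(shift[1])), resampled


def _feather_weight(shape: tuple[int, int]) -> np.ndarray:
    """Separable distance-to-edge ramp used for linear overlap blending."""
    h, w = shape
    wy = np.minimum(np.arange(h) + 1, h - np.arange(h)).astype(float)
    wx = np.minimum(np.arange(w) + 1, w - np.arange(w)).astype(float)
    return np.outer(wy, wx)


def stitch_tiles(tiles: list[np.ndarray],
                 nominal_offsets: list[tuple[int, int]],
                 overlap_refine: bool = False,
                 upsample: int = 10) -> np.ndarray:
    """Place overlapping tiles on a common canvas with feathered blending.

    ``nominal_offsets`` are (y, x) positions of each tile's upper-left
    corner.  With ``overlap_refine`` the offset of each tile after the
    first is adjusted by cross-correlating its overlap with the canvas
    accumulated so far (integer-pixel refinement).
    """
    if not tiles:
        raise InputError("no tiles")
    shape0 = tiles[0].shape
    if any(t.shape != shape0 for t in tiles):
        raise InputError("inconsistent tile shapes")
    offsets = [(int(round(dy)), int(round(dx))) for dy, dx in nominal_offsets]
    if len(offsets) != len(tiles):
        raise InputError("offsets do not match tiles")

    th, tw = shape0
    if overlap_refine and len(tiles) > 1:
        refined = [offsets[0]]
        for tile, (oy, ox) in zip(tiles[1:], offsets[1:]):
            prev_tile, (py, px) = tiles[0], refined[0]
            # overlap with the first already-placed tile, if any
            y0, y1 = max(oy, py), min(oy + th, py + th)
            x0, x1 = max(ox, px), min(ox + tw, px + tw)
            if y1 - y0 > 8 and x1 - x0 > 8:
                a = prev_tile[y0 - py:y1 - py, x0 - px:x1 - px]
                b = tile[y0 - oy:y1 - oy, x0 - ox:x1 - ox]
                if np.ptp(a) > 0 and np.ptp(b) > 0:
                    shift, _, _ = phase_cross_correlation(a, b,
                                                          upsample_factor=upsample,
                                                          normalization=None)
                    oy += int(round(shift[0]))
                    ox += int(round(shift[1]))
            refined.append((oy, ox))
        offsets = refined

    ys = [oy for oy, _ in offsets]
    xs = [ox for _, ox in offsets]
    y_min, x_min = min(ys), min(xs)
    canvas_h = max(ys) - y_min + th
    canvas_w = max(xs) - x_min + tw
    acc = np.zeros((canvas_h, canvas_w))
    wacc = np.zeros((canvas_h, canvas_w))
    feather = _feather_weight(shape0)
    for tile, (oy, ox) in zip(tiles, offsets):
        sl = (slice(oy - y_min, oy - y_min + th), slice(ox - x_min, ox - x_min + tw))
        acc[sl] += feather * tile
        wacc[sl] += feather
    with np.errstate(invalid="ignore"):
        mosaic = acc / wacc
    return np.where(wacc > 0, mosaic, 0.0)


def downsample_nyquist(image: np.ndarray, factor: float = 2) -> np.ndarray:
    """Anti-aliased decimation to the Nyquist-matched sampling.

    Integer factors use a block mean (exact mean preservation); non-integer
    factors apply a Gaussian low-pass at the new Nyquist frequency followed
    by linear resampling.
    """
    if factor < 1:
        raise InputError("downsampling factor must be >= 1")
    image = np.asarray(image, dtype=float)
    if factor == 1:
        return image.copy()
    if float(factor).is_integer():
        f = int(factor)
        h, w = image.shape
        crop = image[: (h // f) * f, : (w // f) * f]
        return block_reduce(crop, (f, f), np.mean)
    sigma = 0.5 * np.sqrt(factor**2 - 1.0)
    smooth = ndimage.gaussian_filter(image, sigma, mode="reflect")
    return ndimage.zoom(smooth, 1.0 / factor, order=1, mode="reflect",
                        grid_mode=True)


def unmix(channel_images: dict[str, np.ndarray] | np.ndarray,
          crosstalk: CrosstalkMatrix) -> dict[str, np.ndarray] | np.ndarray:
    """Invert the spectral crosstalk per pixel.

    Accepts either a (channels, H, W) array ordered like the matrix's
    channel list or a dict of per-channel images; returns the same
    container type.  Negative unmixed values are preserved — clipping would
    bias dim-signal statistics downstream.
    """
    crosstalk.check_invertible()
    as_dict = isinstance(channel_images, dict)
    if as_dict:
        missing = [ch for ch in crosstalk.channels if ch not in channel_images]
        if missing:
            raise InputError(f"missing channel images: {missing}")
        stacked = np.stack([np.asarray(channel_images[ch], dtype=float)
                            for ch in crosstalk.channels])
    else:
        stacked = np.asarray(channel_images, dtype=float)
        if stacked.shape[0] != len(crosstalk.channels):
            raise InputError("image count does not match crosstalk dimension")
    inv = np.linalg.inv(crosstalk.matrix)
    out = np.einsum("ij,j...->i...", inv, stacked)
    if as_dict:
        return {ch: out[i] for i, ch in enumerate(crosstalk.channels)}
    return out


def subtract_prestain(stained: np.ndarray, prestain: np.ndarray) -> np.ndarray:
    """Remove residual autofluorescence / incomplete-erasure signal.

    Both images must already be registered to the common reference.
    Negatives are preserved so that arcsinh scaling stays unbiased.
    """
    stained = np.asarray(stained, dtype=float)
    prestain = np.asarray(prestain, dtype=float)
    if stained.shape != prestain.shape:
        raise InputError("stained and pre-stain shapes differ")
    return stained - prestain


def apply_radial_distortion(image: np.ndarray,
                            coefficients: tuple[float, ...] = ()) -> np.ndarray:
    """Optional radial polynomial distortion correction (identity default).

    The correction resamples ``image`` at radii
    ``r' = r * (1 + k1*r^2 + k2*r^4 + ...)`` about the image center, with
    ``coefficients = (k1, k2, ...)`` in units of the half-diagonal.
    """
    if not coefficients or all(c == 0 for c in coefficients):
        return np.asarray(image, dtype=float).copy()
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx) / np.hypot(cy, cx)
    scale = np.ones_like(r)
    for i, k in enumerate(coefficients, start=1):
        scale += k * r ** (2 * i)
    coords = np.stack([cy + dy * scale, cx + dx * scale])
    return ndimage.map_coordinates(image, coords, order=1, mode="reflect")
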