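"""Multi-cycle image registration on the shared Mito reference channel.

Two modes mirror the two acquisition pipelines:

* ``register_translation`` — translation-only alignment with a narrow
  search window (default 50 px), as performed on-instrument between
  staining cycles.
* ``register_similarity`` — template matching over translation + scale
  (+/-5%) + rotation (+/-5 degrees), the off-instrument stitcher used when
  wider misalignment is possible.

Both score candidate transforms with the normalized cross-correlation
coefficient (NCC) computed over the overlap region of the two images
(mean-subtracted, unit-variance), and classify the result against the QC
thresholds: NCC below 0.8 requires manual verification, below 0.5 the
registration is excluded.

Coordinate convention: (row, col) 0-based; the reported shift is the
cycle-2 -> cycle-1 displacement, i.e. cycle2 pixel (r - dy, c - dx)
corresponds to cycle1 pixel (r, c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve
from skimage.transform import SimilarityTransform, warp, rescale

logger = logging.getLogger(__name__)

QC_ACCEPTED = "accepted"
QC_FLAG_MANUAL = "flag_manual"
QC_EXCLUDED = "excluded"

NCC_MANUAL_THRESHOLD = 0.8
NCC_EXCLUDE_THRESHOLD = 0.5


@dataclass(frozen=True)
class RegistrationResult:
    """Estimated cycle-2 -> cycle-1 transform and its quality score."""

    shift: tuple[float, float]  # (dy, dx) pixels
    scale: float = 1.0
    rotation_deg: float = 0.0
    ncc: float = float("nan")
    qc_status: str = QC_EXCLUDED

    def as_record(self) -> dict:
        return dict(shift_dy=self.shift[0], shift_dx=self.shift[1],
                    scale=self.scale, rotation_deg=self.rotation_deg,
                    ncc=self.ncc, qc_status=self.qc_status)


def qc_classify(ncc: float,
                manual: float = NCC_MANUAL_THRESHOLD,
                exclude: float = NCC_EXCLUDE_THRESHOLD) -> str:
    """Step-function QC: thresholds are 'below x', i.e. exclusive.

    ncc >= manual -> accepted; exclude <= ncc < manual -> flag_manual;
    ncc < exclude -> excluded.
    """
    if not -1.0 - 1e-9 <= ncc <= 1.0 + 1e-9:
        raise ValueError(f"ncc {ncc} outside [-1, 1]")
    if ncc >= manual:
        return QC_ACCEPTED
    if ncc >= exclude:
        return QC_FLAG_MANUAL
    return QC_EXCLUDED


def _check_images(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("registration expects 2-D images")
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty image: NCC undefined")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant image: NCC undefined")
    return a, b


def ncc_shift_map(img1: np.ndarray, img2: np.ndarray, max_shift: int) -> tuple[np.ndarray, np.ndarray]:
    """NCC over the overlap for every integer shift in a +/-max_shift window.

    Returns (shifts, ncc) where shifts run over dy, dx in
    [-max_shift, max_shift] and ncc has shape (2*max_shift+1, 2*max_shift+1);
    ncc[i, j] scores shift (i - max_shift, j - max_shift).

    All five overlap sums (sum a, sum b, sum ab, sum a^2, sum b^2 and the
    overlap size) are obtained with FFT correlations, so the map is exact
    up to floating-point error yet fast for plate-scale images.
    """
    img1, img2 = _check_images(img1, img2)
    n_rows, n_cols = img1.shape
    if max_shift >= min(n_rows, n_cols) / 2:
        raise ValueError("max_shift must be < half the smallest image dimension")

    ones = np.ones_like(img1)
    flip = lambda im: im[::-1, ::-1]
    # full correlation index (n-1+dy, n-1+dx) corresponds to shift (dy, dx)
    s12 = fftconvolve(img1, flip(img2), mode="full")
    s1 = fftconvolve(img1, flip(ones), mode="full")
    s2 = fftconvolve(ones, flip(img2), mode="full")
    s11 = fftconvolve(img1 * img1, flip(ones), mode="full")
    s22 = fftconvolve(ones, flip(img2 * img2), mode="full")
    n = fftconvolve(ones, flip(ones), mode="full")

    r0, c0 = n_rows - 1, n_cols - 1
    sl = np.s_[r0 - max_shift:r0 + max_shift + 1, c0 - max_shift:c0 + max_shift + 1]
    s12, s1, s2, s11, s22, n = (a[sl] for a in (s12, s1, s2, s11, s22, n))
    n = np.round(n)

    cov = s12 - s1 * s2 / n
    var1 = s11 - s1 * s1 / n
    var2 = s22 - s2 * s2 / n
    denom = np.sqrt(np.clip(var1, 0, None) * np.clip(var2, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), -np.inf)
    ncc = np.clip(ncc, -1.0, 1.0)
    shifts = np.arange(-max_shift, max_shift + 1)
    return shifts, ncc


def _quadratic_peak(ncc: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Quadratic interpolation of the NCC peak to subpixel precision."""
    def offset(vm, v0, vp):
        denom = vm - 2 * v0 + vp
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < ncc.shape[0] - 1:
        dy = offset(ncc[iy - 1, ix], ncc[iy, ix], ncc[iy + 1, ix])
    if 0 < ix < ncc.shape[1] - 1:
        dx = offset(ncc[iy, ix - 1], ncc[iy, ix], ncc[iy, ix + 1])
    return dy, dx


def register_translation(
    ref_cycle1: np.ndarray,
    ref_cycle2: np.ndarray,
    max_shift: int = 50,
    subpixel: bool = False,
    manual: float = NCC_MANUAL_THRESHOLD,
    exclude: float = NCC_EXCLUDE_THRESHOLD,
) -> RegistrationResult:
    """Translation-only registration: the integer shift maximizing NCC."""
    shifts, ncc = ncc_shift_map(ref_cycle1, ref_cycle2, max_shift)
    iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
    best = float(ncc[iy, ix])
    dy, dx = float(shifts[iy]), float(shifts[ix])
    if subpixel:
        oy, ox = _quadratic_peak(ncc, int(iy), int(ix))
        dy, dx = dy + oy, dx + ox
    return RegistrationResult(shift=(dy, dx), scale=1.0, rotation_deg=0.0,
                              ncc=best, qc_status=qc_classify(best, manual, exclude))


def _center_transform(shape: tuple[int, int], scale: float, rotation_deg: float) -> SimilarityTransform:
    """Similarity transform (scale, rotation) about the image center."""
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    # skimage transforms act on (x, y)
    shift_to = SimilarityTransform(translation=(-cx, -cy))
    core = SimilarityTransform(scale=scale, rotation=np.deg2rad(rotation_deg))
    shift_back = SimilarityTransform(translation=(cx, cy))
    return shift_to + core + shift_back


def _warp_similarity(img: np.ndarray, scale: float, rotation_deg: float,
                     dy: float = 0.0, dx: float = 0.0, order: int = 1) -> np.ndarray:
    tf = _center_transform(img.shape, scale, rotation_deg)
    tf = tf + SimilarityTransform(translation=(dx, dy))
    return warp(img, tf.inverse, order=order, mode="constant", cval=0.0,
                preserve_range=True)


def register_similarity(
    ref_cycle1: np.ndarray,
    ref_cycle2: np.ndarray,
    max_shift_frac: float = 0.5,
    scale_bound: float = 0.05,
    rotation_bound_deg: float = 5.0,
    coarse_step_scale: float = 0.01,
    coarse_step_deg: float = 1.0,
    fine_step_scale: float = 0.0025,
    fine_step_deg: float = 0.25,
    downsample: int = 2,
    manual: float = NCC_MANUAL_THRESHOLD,
    exclude: float = NCC_EXCLUDE_THRESHOLD,
) -> RegistrationResult:
    """Coarse-to-fine similarity registration.

    A (scale, rotation) grid is scanned; at each grid point cycle 2 is
    warped and the best translation is found by NCC.  The coarse pass runs
    on ``downsample``-fold reduced images, the refinement pass at full
    resolution in a narrow window around the coarse optimum.
    """
    img1, img2 = _check_images(ref_cycle1, ref_cycle2)
    max_shift = int(max_shift_frac * min(img1.shape) / 2) * 2 // 2
    max_shift = min(max_shift, min(img1.shape) // 2 - 1)

    def grid_search(a, b, scales, rots, window):
        best = (-np.inf, 1.0, 0.0, 0.0, 0.0)
        for s in scales:
            for r in rots:
                warped = _warp_similarity(b, s, r)
                res = register_translation(a, warped, max_shift=window,
                                           manual=manual, exclude=exclude)
                if res.ncc > best[0]:
                    best = (res.ncc, s, r, res.shift[0], res.shift[1])
        return best

    if downsample > 1:
        small1 = rescale(img1, 1.0 / downsample, anti_aliasing=True, preserve_range=True)
        small2 = rescale(img2, 1.0 / downsample, anti_aliasing=True, preserve_range=True)
    else:
        small1, small2 = img1, img2
    window_small = max(min(small1.shape) // 2 - 1, 1)
    window_small = min(window_small, int(np.ceil(max_shift / downsample)) + 2)

    scales = np.arange(1.0 - scale_bound, 1.0 + scale_bound + 1e-12, coarse_step_scale)
    rots = np.arange(-rotation_bound_deg, rotation_bound_deg + 1e-12, coarse_step_deg)
    _, s0, r0, _, _ = grid_search(small1, small2, scales, rots, window_small)

    fine_scales = np.clip(
        np.arange(s0 - coarse_step_scale, s0 + coarse_step_scale + 1e-12, fine_step_scale),
        1.0 - scale_bound, 1.0 + scale_bound)
    fine_rots = np.clip(
        np.arange(r0 - coarse_step_deg, r0 + coarse_step_deg + 1e-12, fine_step_deg),
        -rotation_bound_deg, rotation_bound_deg)
    ncc, s, r, dy, dx = grid_search(img1, img2, np.unique(fine_scales),
                                    np.unique(fine_rots), max_shift)
    return RegistrationResult(shift=(dy, dx), scale=float(s), rotation_deg=float(r),
                              ncc=float(ncc), qc_status=qc_classify(ncc, manual, exclude))


def _shift_integer(img: np.ndarray, dy: int, dx: int, fill=0) -> np.ndarray:
    """Shift with zero fill (exact, no interpolation)."""
    out = np.full_like(img, fill)
    src_r = slice(max(0, -dy), img.shape[0] - max(0, dy))
    src_c = slice(max(0, -dx), img.shape[1] - max(0, dx))
    dst_r = slice(max(0, dy), img.shape[0] + min(0, dy))
    dst_c = slice(max(0, dx), img.shape[1] + min(0, dx))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def apply_transform(
    stack: dict[str, np.ndarray],
    mask: np.ndarray,
    result: RegistrationResult,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Apply a registration result to all cycle-2 channels and the valid mask.

    Uncovered pixels are filled with zeros; the mask is transformed with the
    same parameters (nearest-neighbour).  Output dimensions are unchanged.
    """
    if result.qc_status == QC_EXCLUDED:
        raise ValueError("cannot apply an excluded registration")
    dy, dx = result.shift
    pure_translation = (result.scale == 1.0 and result.rotation_deg == 0.0
                        and float(dy).is_integer() and float(dx).is_integer())
    out: dict[str, np.ndarray] = {}
    if pure_translation:
        dyi, dxi = int(dy), int(dx)
        for name, img in stack.items():
            out[name] = _shift_integer(img, dyi, dxi)
        new_mask = _shift_integer(mask.astype(bool), dyi, dxi, fill=False)
    else:
        for name, img in stack.items():
            out[name] = _warp_similarity(np.asarray(img, dtype=float),
                                         result.scale, result.rotation_deg, dy, dx)
        m = _warp_similarity(mask.astype(float), result.scale,
                             result.rotation_deg, dy, dx, order=0)
        new_mask = m > 0.5
    return out, new_mask


def trim_to_overlap(
    cycle1_stack: dict[str, np.ndarray],
    cycle2_stack: dict[str, np.ndarray],
    mask1: np.ndarray,
    mask2: np.ndarray,
) -> tuple[dict[tuple[int, str], np.ndarray], np.ndarray, tuple[slice, slice]]:
    """Crop both cycles to the bounding box of the mask intersection.

    Returns (combined stack keyed by (cycle, channel), cropped joint mask,
    crop slices).  Raises on an empty intersection.
    """
    joint = np.asarray(mask1, bool) & np.asarray(mask2, bool)
    if not joint.any():
        raise ValueError("empty overlap between cycles: nothing to trim to")
    rows = np.flatnonzero(joint.any(axis=1))
    cols = np.flatnonzero(joint.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    combined: dict[tuple[int, str], np.ndarray] = {}
    for name, img in cycle1_stack.items():
        combined[(1, name)] = img[sl]
    for name, img in cycle2_stack.items():
        combined[(2, name)] = img[sl]
    return combined, joint[sl], sl


# fixed pseudo-color palette (RGB, one per channel in stack order)
_PALETTE = np.array([
    [0.00, 0.45, 1.00],   # blue
    [0.00, 0.85, 0.20],   # green
    [1.00, 0.25, 0.10],   # red
    [1.00, 0.80, 0.00],   # yellow
    [0.85, 0.20, 0.85],   # magenta
    [0.00, 0.85, 0.85],   # cyan
    [1.00, 0.55, 0.00],   # orange
    [0.60, 0.60, 0.60],   # grey
])


def merge_pseudocolor(stack: dict) -> np.ndarray:
    """Overlay all channels in pseudo-color (deterministic palette).

    Each channel is min-max scaled, tinted with a fixed palette color and
    summed; the result is clipped to [0, 1].
    """
    if not stack:
        raise ValueError("empty stack")
    keys = list(stack.keys())
    first = np.asarray(stack[keys[0]], dtype=float)
    rgb = np.zeros(first.shape + (3,), dtype=float)
    for i, key in enumerate(keys):
        img = np.asarray(stack[key], dtype=float)
        lo, hi = img.min(), img.max()
        scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        rgb += scaled[..., None] * _PALETTE[i % len(_PALETTE)]
    return np.clip(rgb, 0.0, 1.0)


def brute_force_translation(img1: np.ndarray, img2: np.ndarray, max_shift: int) -> tuple[tuple[int, int], float]:
    """Exhaustive-search NCC argmax (reference oracle, O(shifts * pixels))."""
    img1, img2 = _check_images(img1, img2)
    best_ncc, best_shift = -np.inf, (0, 0)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            a = img1[max(0, dy):img1.shape[0] + min(0, dy),
                     max(0, dx):img1.shape[1] + min(0, dx)]
            b = img2[max(0, -dy):img2.shape[0] - max(0, dy),
                     max(0, -dx):img2.shape[1] - max(0, dx)]
            if a.size < 2:
                continue
            am, bm = a - a.mean(), b - b.mean()
            denom = np.sqrt((am * am).sum() * (bm * bm).sum())
            if denom == 0:
                continue
            val = float((am * bm).sum() / denom)
            if val > best_ncc:
                best_ncc, best_shift = val, (dy, dx)
    return best_shift, best_ncc
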