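"""Nucleus/cell segmentation and derived cell regions.

Nuclei are segmented from the DNA channel (Otsu threshold + distance-
transform watershed); cell outlines grow from nucleus seeds on a merged
channel by marker-controlled watershed.  From those two masks the
additional cell regions are derived: cytoplasm (cell minus nucleus), a
ring band just outside the nucleus, a membrane band just inside the cell
boundary, and nucleolus spots detected in the RNA channel inside the
nucleus.  Border cells touching the image edge are flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, gaussian
from skimage.measure import label as cc_label
from skimage.morphology import disk
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)


@dataclass
class SegmentedCell:
    """Masks for one cell, all in field coordinates (boolean, full-frame)."""

    label: int
    nucleus: np.ndarray
    cell: np.ndarray
    cytoplasm: np.ndarray | None = None
    ring: np.ndarray | None = None
    membrane: np.ndarray | None = None
    nucleoli: np.ndarray | None = None
    nucleoli_count: int = 0
    border_flag: bool = False
    centroid: tuple[float, float] = (0.0, 0.0)

    def region_mask(self, region: str) -> np.ndarray:
        m = getattr(self, region, None)
        if m is None:
            raise ValueError(f"region {region!r} not derived for cell {self.label}")
        return m


def flatfield_correct(image: np.ndarray, smoothing_scale: float) -> np.ndarray:
    """Divide out a smooth illumination estimate, preserving the global mean.

    The illumination field is estimated as a quadratic polynomial surface
    fitted to a lightly denoised copy of the image; ``smoothing_scale``
    (which should exceed the cell diameter) sets the denoising scale cap.
    A low-order surface captures lamp gradients and vignetting without the
    edge bias of a large Gaussian, and individual cells cannot imprint on
    it.
    """
    img = np.asarray(image, dtype=float)
    if (img < 0).any():
        raise ValueError("negative pixels: not a raw intensity image")
    # light denoise only: the polynomial fit provides the heavy smoothing,
    # and a large Gaussian would flatten real gradients near the borders
    smooth = gaussian(img, sigma=min(3.0, smoothing_scale / 10.0),
                      preserve_range=True)
    rr, cc = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    r = (rr / max(img.shape[0] - 1, 1)).ravel()
    c = (cc / max(img.shape[1] - 1, 1)).ravel()
    design = np.column_stack([np.ones_like(r), r, c, r * c, r ** 2, c ** 2])
    coef, *_ = np.linalg.lstsq(design, smooth.ravel(), rcond=None)
    illum = (design @ coef).reshape(img.shape)
    if (illum <= 0).any():
        raise ValueError("illumination estimate is zero somewhere; cannot divide")
    corrected = img / illum
    mean = corrected.mean()
    if mean > 0:
        corrected *= img.mean() / mean
    return corrected


def segment_nuclei(dna_channel: np.ndarray, min_area: int = 50,
                   min_peak_distance: int = 7) -> np.ndarray:
    """Label map of nuclei from the DNA channel.

    Otsu threshold, hole filling, then a distance-transform watershed to
    split touching nuclei with distinct intensity peaks; objects below
    ``min_area`` pixels are discarded.
    """
    img = np.asarray(dna_channel, dtype=float)
    if img.ndim != 2 or (img < 0).any():
        raise ValueError("expected a 2-D non-negative image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    smooth = gaussian(img, sigma=1.0, preserve_range=True)
    thresh = threshold_otsu(smooth)
    fg = smooth > thresh
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_peak_distance, labels=fg,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(fg)
    else:
        labels = watershed(-dist, markers, mask=fg)
    labels = _drop_small(labels, min_area)
    return relabel_sequential(labels)


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    out = labels.copy()
    out[np.isin(labels, small)] = 0
    return out


def relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def segment_cells(merged_channel: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Cell label map by seeded watershed growth from nuclei.

    Each cell keeps the label of its seed nucleus; nuclei falling outside
    the merged-channel foreground are dropped with a warning.
    """
    img = np.asarray(merged_channel, dtype=float)
    if nuclei.max() == 0:
        return np.zeros(img.shape, dtype=np.int32)
    smooth = gaussian(img, sigma=1.5, preserve_range=True)
    thresh = threshold_otsu(smooth) if np.ptp(smooth) > 0 else np.inf
    fg = smooth > thresh
    fg |= nuclei > 0
    fg = ndi.binary_fill_holes(fg)
    dropped = []
    markers = np.zeros_like(nuclei)
    for lab in np.unique(nuclei[nuclei > 0]):
        nucleus = nuclei == lab
        if not (nucleus & fg).any():
            dropped.append(int(lab))
            continue
        markers[nucleus & fg] = lab
    if dropped:
        logger.warning("dropped %d nuclei outside foreground: %s", len(dropped), dropped)
    cells = watershed(-smooth, markers, mask=fg)
    return cells.astype(np.int32)


def merge_channels(*images: np.ndarray) -> np.ndarray:
    """Pixelwise max of per-channel min-max scaled images (cell-outline channel)."""
    scaled = []
    for img in images:
        img = np.asarray(img, dtype=float)
        lo, hi = img.min(), img.max()
        scaled.append((img - lo) / (hi - lo) if hi > lo else np.zeros_like(img))
    return np.max(scaled, axis=0)


def derive_regions(nucleus: np.ndarray, cell: np.ndarray,
                   ring_width: int = 3, membrane_width: int = 2) -> dict[str, np.ndarray]:
    """Derive cytoplasm, ring and membrane masks from nucleus and cell masks.

    cytoplasm = cell minus nucleus; ring = band of ring_width just outside
    the nucleus boundary clipped to the cell; membrane = band of
    membrane_width just inside the cell boundary.
    """
    if ring_width <= 0 or membrane_width <= 0:
        raise ValueError("region widths must be positive")
    nucleus = np.asarray(nucleus, bool)
    cell = np.asarray(cell, bool)
    if (nucleus & ~cell).any():
        raise ValueError("nucleus extends outside the cell mask")
    cytoplasm = cell & ~nucleus
    ring = ndi.binary_dilation(nucleus, structure=disk(ring_width)) & ~nucleus & cell
    membrane = cell & ~ndi.binary_erosion(cell, structure=disk(membrane_width))
    return {"cytoplasm": cytoplasm, "ring": ring, "membrane": membrane}


def detect_nucleoli(rna_channel: np.ndarray, nucleus: np.ndarray,
                    sigma_small: float = 1.0, sigma_large: float = 4.0,
                    relative_threshold: float = 0.2,
                    min_peak_distance: int = 2) -> tuple[int, np.ndarray]:
    """Detect nucleolus spots inside a nucleus (speckle detection).

    Spots are local maxima of the band-pass (difference-of-Gaussians)
    filtered signal inside the (slightly eroded) nucleus that rise at
    least ``relative_threshold`` of the in-nucleus dynamic range above the
    local background (the in-nucleus median).  Returns (count, spot label
    map) where spot masks are the watershed basins of the maxima over the
    thresholded area.
    """
    nucleus = np.asarray(nucleus, bool)
    if not nucleus.any():
        raise ValueError("empty nucleus mask")
    img = np.asarray(rna_channel, dtype=float)
    # fill the surroundings with the in-nucleus median so the nucleus edge
    # itself produces no band-pass response
    work = np.where(nucleus, img, np.median(img[nucleus]))
    dog = (gaussian(work, sigma_small, preserve_range=True)
           - gaussian(work, sigma_large, preserve_range=True))
    core = ndi.binary_erosion(nucleus, iterations=1)
    if not core.any():
        core = nucleus
    inside = dog[core]
    bg, peak = float(np.median(inside)), float(inside.max())
    if peak <= bg:
        return 0, np.zeros(img.shape, dtype=np.int32)
    threshold = bg + relative_threshold * (peak - bg)
    masked = np.where(core, dog, -np.inf)
    peaks = peak_local_max(masked, min_distance=min_peak_distance,
                           threshold_abs=threshold, exclude_border=False)
    if len(peaks) == 0:
        return 0, np.zeros(img.shape, dtype=np.int32)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    support = (dog > threshold) & core
    support |= markers > 0
    labels = watershed(-dog, markers, mask=support)
    return int(len(peaks)), labels.astype(np.int32)


@dataclass
class SegmentationConfig:
    min_nucleus_area: int = 50
    ring_width: int = 3
    membrane_width: int = 2
    spot_relative_threshold: float = 0.2


def segment_field(
    dna: np.ndarray,
    merged: np.ndarray,
    rna: np.ndarray | None = None,
    config: SegmentationConfig | None = None,
) -> list[SegmentedCell]:
    """Full per-field segmentation: nuclei, cells, regions, nucleoli, border flags."""
    config = config or SegmentationConfig()
    nuclei = segment_nuclei(dna, min_area=config.min_nucleus_area)
    cells = segment_cells(merged, nuclei)
    out: list[SegmentedCell] = []
    h, w = np.asarray(dna).shape
    for lab in np.unique(cells[cells > 0]):
        cell_mask = cells == lab
        nuc_mask = (nuclei == lab) & cell_mask
        if not nuc_mask.any():
            continue
        regions = derive_regions(nuc_mask, cell_mask,
                                 config.ring_width, config.membrane_width)
        border = bool(cell_mask[0, :].any() or cell_mask[-1, :].any()
                      or cell_mask[:, 0].any() or cell_mask[:, -1].any())
        count, spot_labels = (0, None)
        if rna is not None:
            count, spot_labels = detect_nucleoli(
                rna, nuc_mask, relative_threshold=config.spot_relative_threshold)
            spot_labels = spot_labels > 0
        rr, cc = np.nonzero(cell_mask)
        out.append(SegmentedCell(
            label=int(lab), nucleus=nuc_mask, cell=cell_mask,
            cytoplasm=regions["cytoplasm"], ring=regions["ring"],
            membrane=regions["membrane"], nucleoli=spot_labels,
            nucleoli_count=count, border_flag=border,
            centroid=(float(rr.mean()), float(cc.mean())),
        ))
    return out
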