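"""Per-cell feature extraction from registered multi-channel stacks.

Features are named ``<channel>_<region>_<family>_<stat>`` and cover four
families per channel x region combination:

* intensity — mean, median, sum, sd, q05, q95
* shape — area, perimeter, roundness (4*pi*A/P^2), axis ratio (region mask
  geometry; computed once per region, attributed to the channel that
  defines the region)
* texture — grey-level co-occurrence contrast / correlation / entropy
  (distance 1, 4-direction average, 32 grey levels) and gradient energy
* position — centroid and nucleus-cell centroid displacement

The catalog is deliberately compact (~60 columns with the default config)
and versioned through the config; the column set depends only on the
config, never on the data.  Border-flagged cells are excluded.  The Mito
channel of a registered stack is by convention the cycle-2 Mito image.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import perimeter as sk_perimeter

from .segment import SegmentedCell

INTENSITY_STATS = ("mean", "median", "sum", "sd", "q05", "q95")
SHAPE_STATS = ("area", "perimeter", "roundness", "axisratio")
TEXTURE_STATS = ("contrast", "correlation", "entropy", "gradenergy")
POSITION_STATS = ("centroidy", "centroidx", "nucdisplacement")


@dataclass
class FeatureConfig:
    """Which channel x region x family combinations to extract.

    ``channel_regions`` maps channel name -> tuple of region names
    (nucleus, cell, cytoplasm, ring, membrane, nucleoli).
    """

    channel_regions: dict[str, tuple[str, ...]] = dc_field(default_factory=lambda: {
        "DNA": ("nucleus", "cell"),
        "RNA": ("nucleus", "cytoplasm", "nucleoli"),
        "Mito": ("cytoplasm", "ring"),
        "ER": ("cytoplasm", "ring"),
        "Golgi": ("cytoplasm", "ring"),
        "Actin": ("cell", "membrane"),
        "Lyso": ("cytoplasm",),
    })
    texture_channels: tuple[str, ...] = ("DNA", "RNA", "Mito", "ER", "Actin", "Lyso")
    texture_region: str = "cytoplasm"
    shape_channel: str = "DNA"  # shape/position attributed to the DNA channel
    glcm_levels: int = 32
    version: str = "1"

    def columns(self) -> list[str]:
        cols: list[str] = []
        for ch, regions in self.channel_regions.items():
            for region in regions:
                for stat in INTENSITY_STATS:
                    cols.append(f"{ch}_{region}_intensity_{stat}")
        for region in ("nucleus", "cell"):
            for stat in SHAPE_STATS:
                cols.append(f"{self.shape_channel}_{region}_shape_{stat}")
        for ch in self.texture_channels:
            region = "nucleus" if ch == "DNA" else self.texture_region
            for stat in TEXTURE_STATS:
                cols.append(f"{ch}_{region}_texture_{stat}")
        for stat in POSITION_STATS:
            cols.append(f"{self.shape_channel}_cell_position_{stat}")
        cols.append("RNA_nucleoli_count_n")
        return cols


def _intensity_stats(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {s: np.nan for s in INTENSITY_STATS}
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sum": float(values.sum()),
        "sd": float(values.std(ddof=0)),
        "q05": float(np.quantile(values, 0.05)),
        "q95": float(np.quantile(values, 0.95)),
    }


def _shape_stats(mask: np.ndarray) -> dict[str, float]:
    area = float(mask.sum())
    if area == 0:
        return {s: np.nan for s in SHAPE_STATS}
    perim = float(sk_perimeter(mask))
    roundness = 4.0 * np.pi * area / perim ** 2 if perim > 0 else np.nan
    rr, cc = np.nonzero(mask)
    dr, dc = rr - rr.mean(), cc - cc.mean()
    cov = np.cov(np.vstack([dr, dc])) if rr.size > 1 else np.zeros((2, 2))
    evals = np.sort(np.linalg.eigvalsh(cov))
    axisratio = float(np.sqrt(evals[0] / evals[1])) if evals[1] > 0 else 1.0
    return {"area": area, "perimeter": perim,
            "roundness": float(min(roundness, 1.5)), "axisratio": axisratio}


def haralick_stats(patch: np.ndarray, mask: np.ndarray, levels: int = 32) -> dict[str, float]:
    """GLCM contrast/correlation/entropy at distance 1, 4-direction average.

    The patch is quantized to ``levels`` grey levels over the in-mask
    intensity range; out-of-mask pixels are excluded by assigning them a
    sentinel level that is trimmed from the co-occurrence matrix.
    """
    vals = patch[mask]
    if vals.size < 4 or np.ptp(vals) == 0:
        return {"contrast": 0.0, "correlation": 0.0, "entropy": 0.0}
    lo, hi = vals.min(), vals.max()
    quant = np.zeros(patch.shape, dtype=np.uint8)
    quant[mask] = np.clip(((patch[mask] - lo) / (hi - lo) * (levels - 1)), 0,
                          levels - 1).astype(np.uint8) + 1
    glcm = graycomatrix(quant, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=levels + 1, symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(float)  # drop the out-of-mask sentinel row/col
    totals = glcm.sum(axis=(0, 1), keepdims=True)
    totals[totals == 0] = 1.0
    glcm /= totals
    contrast = float(graycoprops(glcm, "contrast").mean())
    correlation = float(graycoprops(glcm, "correlation").mean())
    p = glcm.mean(axis=3)[:, :, 0]
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {"contrast": contrast, "correlation": correlation, "entropy": entropy}


def _gradient_energy(patch: np.ndarray, mask: np.ndarray) -> float:
    gy, gx = np.gradient(patch.astype(float))
    g2 = gy ** 2 + gx ** 2
    return float(g2[mask].mean()) if mask.any() else 0.0


def _bbox(mask: np.ndarray, pad: int = 2) -> tuple[slice, slice]:
    rr, cc = np.nonzero(mask)
    return (slice(max(rr.min() - pad, 0), rr.max() + pad + 1),
            slice(max(cc.min() - pad, 0), cc.max() + pad + 1))


def extract_features(
    stack: dict[str, np.ndarray],
    cells: list[SegmentedCell],
    config: FeatureConfig | None = None,
    pixel_area_um2: float = 1.0,
) -> pd.DataFrame:
    """Extract the configured feature table from one field.

    ``stack`` maps channel name -> registered/trimmed 2-D image; for a
    multi-cycle stack the caller supplies the cycle-2 Mito image under the
    key ``Mito``.  Border-flagged cells are excluded from the output.
    Raises if a configured channel is missing from the stack.
    """
    config = config or FeatureConfig()
    needed = set(config.channel_regions) | set(config.texture_channels) | {config.shape_channel}
    missing = sorted(needed - set(stack))
    if missing:
        raise ValueError(f"stack is missing configured channels: {missing}")
    columns = config.columns()
    rows: list[dict] = []
    for cell in cells:
        if cell.border_flag:
            continue
        rec: dict[str, float] = {"cell_label": cell.label}
        for ch, regions in config.channel_regions.items():
            img = np.asarray(stack[ch], dtype=float)
            for region in regions:
                try:
                    mask = cell.region_mask(region)
                except ValueError:
                    mask = np.zeros_like(cell.cell)
                stats = _intensity_stats(img[mask.astype(bool)])
                for stat, v in stats.items():
                    rec[f"{ch}_{region}_intensity_{stat}"] = v
        for region in ("nucleus", "cell"):
            for stat, v in _shape_stats(cell.region_mask(region)).items():
                rec[f"{config.shape_channel}_{region}_shape_{stat}"] = v
        for ch in config.texture_channels:
            region = "nucleus" if ch == "DNA" else config.texture_region
            mask = cell.region_mask(region).astype(bool)
            img = np.asarray(stack[ch], dtype=float)
            if mask.any():
                sl = _bbox(mask)
                h = haralick_stats(img[sl], mask[sl], levels=config.glcm_levels)
                ge = _gradient_energy(img[sl], mask[sl])
            else:
                h, ge = {"contrast": np.nan, "correlation": np.nan, "entropy": np.nan}, np.nan
            for stat, v in h.items():
                rec[f"{ch}_{region}_texture_{stat}"] = v
            rec[f"{ch}_{region}_texture_gradenergy"] = ge
        cy, cx = cell.centroid
        nrr, ncc = np.nonzero(cell.nucleus)
        ny, nx = (float(nrr.mean()), float(ncc.mean())) if nrr.size else (cy, cx)
        rec[f"{config.shape_channel}_cell_position_centroidy"] = cy
        rec[f"{config.shape_channel}_cell_position_centroidx"] = cx
        rec[f"{config.shape_channel}_cell_position_nucdisplacement"] = float(
            np.hypot(cy - ny, cx - nx))
        rec["RNA_nucleoli_count_n"] = float(cell.nucleoli_count)
        # area features scale with the physical pixel area
        for region in ("nucleus", "cell"):
            key = f"{config.shape_channel}_{region}_shape_area"
            rec[key] = rec[key] * pixel_area_um2
        rows.append(rec)
    df = pd.DataFrame(rows, columns=["cell_label"] + columns)
    return df
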