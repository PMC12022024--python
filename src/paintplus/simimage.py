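"""Synthetic multi-cycle fluorescence field images with known ground truth.

Each field contains non-overlapping elliptical cells (Poisson-disc placed
centers), each with a nucleus, 1-6 bright nucleolus spots in the RNA
channel, and granular organelle texture in the Mito channel.  Cycle-2
channels show the same scene under a known similarity transform (the
ground-truth cycle-2 -> cycle-1 transform) with independent noise; the
Mito reference channel is rendered in both cycles.  Ground-truth label
maps and nucleolus counts are recorded for segmentation benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import warp

from .registration import _center_transform, SimilarityTransform
from .simulate import FieldTransform

DEFAULT_CYCLE_CHANNELS = {1: ("DNA", "RNA", "Mito"),
                          2: ("Mito", "ER", "Golgi", "Actin", "Lyso")}
REFERENCE_CHANNEL = "Mito"

MAX_SHIFT_FRAC = 0.5
MAX_SCALE_DEV = 0.05
MAX_ROT_DEG = 5.0


@dataclass
class FieldSpec:
    """Rendering parameters for one synthetic field."""

    shape: tuple[int, int] = (512, 512)
    cycle_channels: dict = dc_field(default_factory=lambda: {
        k: tuple(v) for k, v in DEFAULT_CYCLE_CHANNELS.items()})
    n_cells: int = 25
    cell_radius: float = 22.0       # mean semi-major axis, px
    nucleus_frac: float = 0.45      # nucleus axes relative to cell axes
    margin: int = 8                 # keep cell centers away from the border
    foreground: float = 2000.0      # peak foreground intensity (16-bit scale)
    background: float = 100.0
    snr: float = 10.0               # foreground amplitude / noise sigma
    pixel_size_um: float = 0.65


@dataclass
class MultiCycleImageSet:
    """Per-field images: cycle -> channel -> 2-D grid, plus valid masks."""

    field_id: str
    cycles: dict[int, dict[str, np.ndarray]]
    masks: dict[int, np.ndarray]
    pixel_size_um: float = 0.65
    truth_transform: FieldTransform | None = None
    truth_nuclei: np.ndarray | None = None       # label map, cycle-1 frame
    truth_cells: np.ndarray | None = None        # label map, cycle-1 frame
    truth_nucleoli_counts: dict[int, int] | None = None

    def __post_init__(self) -> None:
        for cyc, chans in self.cycles.items():
            shapes = {img.shape for img in chans.values()}
            if len(shapes) > 1:
                raise ValueError(f"cycle {cyc}: channels have differing shapes")
        for cyc in self.cycles:
            if REFERENCE_CHANNEL not in self.cycles[cyc]:
                raise ValueError(f"cycle {cyc} lacks the {REFERENCE_CHANNEL} reference channel")


def poisson_disc_centers(shape: tuple[int, int], n: int, min_dist: float,
                         margin: int, rng: np.random.Generator,
                         max_attempts: int = 20000) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling: centers at least min_dist apart."""
    accepted: list[tuple[float, float]] = []
    attempts = 0
    while len(accepted) < n and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_dist ** 2 for ar, ac in accepted):
            accepted.append((r, c))
    return np.asarray(accepted)


def _ellipse_mask(shape, center, axes, theta) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _granular_texture(shape, sigma, rng) -> np.ndarray:
    """Smoothed positive noise in [0, 1] emulating organelle granularity."""
    noise = rng.standard_normal(shape)
    tex = ndi.gaussian_filter(noise, sigma)
    tex -= tex.min()
    ptp = tex.max() - tex.min() if tex.max() > tex.min() else 1.0
    return tex / ptp


def render_scene(spec: FieldSpec, seed: int) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, dict[int, int]]:
    """Render noiseless channel scenes plus ground-truth label maps.

    Returns (scenes by channel, nucleus labels, cell labels,
    nucleolus count per cell label).
    """
    rng = np.random.default_rng(seed)
    shape = spec.shape
    channels = sorted({ch for chans in spec.cycle_channels.values() for ch in chans})
    scenes = {ch: np.zeros(shape, dtype=float) for ch in channels}
    nuc_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleoli_counts: dict[int, int] = {}

    min_dist = 2.3 * spec.cell_radius
    margin = int(spec.margin + 1.3 * spec.cell_radius)
    centers = poisson_disc_centers(shape, spec.n_cells, min_dist, margin, rng)
    fg = spec.foreground

    # one shared granularity field per organelle channel (field-wide, cheap)
    textures = {ch: _granular_texture(shape, sigma=1.5, rng=rng)
                for ch in ("Mito", "ER", "Golgi", "Actin", "Lyso") if ch in scenes}

    for label, (cy, cx) in enumerate(centers, start=1):
        a = spec.cell_radius * rng.uniform(0.85, 1.15)
        b = a * rng.uniform(0.65, 0.95)
        theta = rng.uniform(0, np.pi)
        cell = _ellipse_mask(shape, (cy, cx), (a, b), theta)
        na, nb = a * spec.nucleus_frac, b * spec.nucleus_frac
        off = rng.uniform(-0.15, 0.15, size=2) * min(a, b)
        nucleus = _ellipse_mask(shape, (cy + off[0], cx + off[1]), (na, nb), theta)
        nucleus &= cell
        cell_labels[cell] = label
        nuc_labels[nucleus] = label

        cyto = cell & ~nucleus
        if "DNA" in scenes:
            scenes["DNA"][nucleus] += fg * rng.uniform(0.8, 1.0)
        if "RNA" in scenes:
            scenes["RNA"][nucleus] += 0.35 * fg
            scenes["RNA"][cyto] += 0.20 * fg
        for ch, tex in textures.items():
            scenes[ch][cyto] += fg * (0.25 + 0.6 * tex[cyto])
            scenes[ch][nucleus] += 0.10 * fg

        # nucleolus spots: bright Gaussian blobs in the RNA channel
        n_spots = int(rng.integers(1, 7))
        placed = []
        for _ in range(n_spots):
            for _attempt in range(30):
                sr = cy + off[0] + rng.uniform(-0.6, 0.6) * na
                sc = cx + off[1] + rng.uniform(-0.6, 0.6) * nb
                if not nucleus[int(round(sr)) % shape[0], int(round(sc)) % shape[1]]:
                    continue
                if all((sr - pr) ** 2 + (sc - pc) ** 2 >= 5.0 ** 2 for pr, pc in placed):
                    placed.append((sr, sc))
                    break
        if "RNA" in scenes:
            for sr, sc in placed:
                r0, r1 = max(0, int(sr) - 8), min(shape[0], int(sr) + 9)
                c0, c1 = max(0, int(sc) - 8), min(shape[1], int(sc) + 9)
                rr, cc = np.mgrid[r0:r1, c0:c1]
                blob = np.exp(-(((rr - sr) ** 2 + (cc - sc) ** 2) / (2 * 1.8 ** 2)))
                scenes["RNA"][r0:r1, c0:c1] += 1.2 * fg * blob * nucleus[r0:r1, c0:c1]
        nucleoli_counts[label] = len(placed)

    return scenes, nuc_labels, cell_labels, nucleoli_counts


def misalign(scene: np.ndarray, transform: FieldTransform) -> np.ndarray:
    """Render a scene as it would appear in cycle 2.

    ``transform`` is the ground-truth cycle-2 -> cycle-1 mapping, so the
    cycle-2 image samples the scene at the transformed coordinates; pixels
    mapping outside the scene are zero.
    """
    tf = _center_transform(scene.shape, transform.scale, transform.rotation_deg)
    tf = tf + SimilarityTransform(translation=(transform.dx, transform.dy))
    return warp(scene, tf, order=1, mode="constant", cval=0.0, preserve_range=True)


def _check_transform_bounds(t: FieldTransform, shape: tuple[int, int]) -> None:
    max_shift = MAX_SHIFT_FRAC * min(shape)
    if abs(t.dy) > max_shift or abs(t.dx) > max_shift:
        raise ValueError(f"transform shift ({t.dy}, {t.dx}) exceeds {max_shift:.0f} px bound")
    if abs(t.scale - 1.0) > MAX_SCALE_DEV + 1e-12:
        raise ValueError(f"transform scale {t.scale} outside +/-5% bound")
    if abs(t.rotation_deg) > MAX_ROT_DEG + 1e-12:
        raise ValueError(f"transform rotation {t.rotation_deg} outside +/-5 degree bound")


def generate_field(
    spec: FieldSpec,
    transform: FieldTransform | None = None,
    seed: int = 0,
    field_id: str = "F001",
) -> MultiCycleImageSet:
    """Generate one field: cycle-1 channels + misaligned noisy cycle-2 channels."""
    if transform is None:
        transform = FieldTransform()
    _check_transform_bounds(transform, spec.shape)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    scenes, nuc, cells, counts = render_scene(spec, seed)
    sigma = spec.foreground / spec.snr if spec.snr > 0 else 0.0

    cycles: dict[int, dict[str, np.ndarray]] = {}
    identity = (transform.dy == 0 and transform.dx == 0
                and transform.scale == 1.0 and transform.rotation_deg == 0)
    for cyc, chans in spec.cycle_channels.items():
        imgs = {}
        for ch in chans:
            base = scenes[ch]
            if cyc == 2 and not identity:
                base = misalign(base, transform)
            img = base + spec.background
            if sigma > 0:
                img = img + sigma * rng.standard_normal(spec.shape)
            imgs[ch] = np.clip(img, 0.0, 65535.0)
        cycles[cyc] = imgs

    masks = {cyc: np.ones(spec.shape, dtype=bool) for cyc in cycles}
    return MultiCycleImageSet(
        field_id=field_id, cycles=cycles, masks=masks,
        pixel_size_um=spec.pixel_size_um, truth_transform=transform,
        truth_nuclei=nuc, truth_cells=cells, truth_nucleoli_counts=counts,
    )


def generate_field_images(
    n_fields: int,
    spec: FieldSpec | None = None,
    transform_bounds: tuple[float, float, float] = (40.0, 0.0, 0.0),
    seed: int = 0,
) -> list[MultiCycleImageSet]:
    """Generate several fields with random within-bounds cycle-2 transforms.

    ``transform_bounds`` = (max |shift| px, max |scale - 1|, max |rotation| deg);
    shifts are drawn as integers so translation-only recovery can be exact.
    """
    if spec is None:
        spec = FieldSpec()
    rng = np.random.default_rng(seed)
    shift_b, scale_b, rot_b = transform_bounds
    fields = []
    for i in range(n_fields):
        t = FieldTransform(
            dy=float(rng.integers(-int(shift_b), int(shift_b) + 1)),
            dx=float(rng.integers(-int(shift_b), int(shift_b) + 1)),
            scale=1.0 + (rng.uniform(-scale_b, scale_b) if scale_b else 0.0),
            rotation_deg=rng.uniform(-rot_b, rot_b) if rot_b else 0.0,
        )
        fields.append(generate_field(spec, t, seed=int(rng.integers(2 ** 31)),
                                     field_id=f"F{i + 1:03d}"))
    return fields
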