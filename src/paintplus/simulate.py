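"""Synthetic ground truth and per-cell feature tables.

The generator emulates the statistical structure of a high-content screen:
log-normal baseline feature distributions per cell, sigmoidal (hill-type)
concentration-dependent effects planted for selected compound/feature pairs,
additive Gaussian measurement noise with a controllable MAD, and dose-
dependent cell loss governed by a per-compound cytotoxicity EC50.  Every
downstream stage (standardization, cytotoxicity gating, BMC modeling,
reporting) can therefore be tested against known truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plate import PlateLayout, ROLE_CONTROL

# Gaussian quantile constant: MAD of N(0, s) equals 0.6745*s
GAUSS_MAD = 0.674489750196082


@dataclass(frozen=True)
class EffectCurve:
    """Concentration-response effect added to a feature, in raw feature units.

    Families mirror the curve shapes later fitted during BMC modeling.
    """

    family: str = "hill"  # one of: cnst, hill, poly1, poly2, pow
    top: float = 0.0
    ac50_uM: float = 1.0
    slope: float = 2.0
    coefs: tuple[float, ...] = ()

    def __call__(self, conc_uM: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(conc_uM, dtype=float)
        if self.family == "cnst":
            out = np.zeros_like(x)
        elif self.family == "hill":
            with np.errstate(divide="ignore"):
                out = np.where(x > 0, self.top / (1.0 + (self.ac50_uM / np.maximum(x, 1e-300)) ** self.slope), 0.0)
        elif self.family == "poly1":
            out = self.coefs[0] * x
        elif self.family == "poly2":
            out = self.coefs[0] * x + self.coefs[1] * x ** 2
        elif self.family == "pow":
            out = self.coefs[0] * np.power(x, self.slope)
        else:
            raise ValueError(f"unknown effect family {self.family!r}")
        return out if out.shape else float(out)


@dataclass(frozen=True)
class FeatureSpec:
    """Baseline distribution of one feature: configured median and MAD."""

    name: str
    median: float = 100.0
    mad: float = 10.0


@dataclass
class FieldTransform:
    """True cycle-2 -> cycle-1 similarity transform for one imaged field."""

    dy: float = 0.0
    dx: float = 0.0
    scale: float = 1.0
    rotation_deg: float = 0.0


@dataclass
class GroundTruth:
    """Planted truth for a synthetic screen."""

    effects: dict[tuple[str, str], EffectCurve] = field(default_factory=dict)
    cytotox_ec50_uM: dict[str, float] = field(default_factory=dict)
    cytotox_slope: float = 2.0
    transforms: dict[str, FieldTransform] = field(default_factory=dict)
    nucleoli_counts: dict[tuple[str, int], int] = field(default_factory=dict)

    def effect(self, compound_id: str, feature: str) -> EffectCurve | None:
        return self.effects.get((compound_id, feature))

    def survival(self, compound_id: str, conc_uM: float) -> float:
        """Fraction of cells surviving at a concentration (sigmoidal loss)."""
        ec50 = self.cytotox_ec50_uM.get(compound_id, math.inf)
        if not math.isfinite(ec50):
            return 1.0
        return 1.0 / (1.0 + (conc_uM / ec50) ** self.cytotox_slope)


# Default feature roster covering the CPP channel set — DNA, RNA, Mito
# (cycle 2), plus cycle-2-only ER, Golgi, Actin, Lyso — built as the cross
# product of each channel's regions with a common stat battery (a desk-scale
# stand-in for the hundreds of features a commercial analysis produces).
_CHANNEL_REGIONS = {
    "DNA": ("nucleus", "cell"),
    "RNA": ("nucleus", "cytoplasm", "nucleoli"),
    "Mito": ("cytoplasm", "ring"),
    "ER": ("cytoplasm", "ring"),
    "Golgi": ("cytoplasm", "ring"),
    "Actin": ("cell", "membrane"),
    "Lyso": ("cytoplasm", "ring"),
}
_STAT_BATTERY = (  # (family, stat, baseline median scale, MAD/median)
    ("intensity", "mean", 1.00, 0.14),
    ("intensity", "median", 0.95, 0.14),
    ("intensity", "sd", 0.28, 0.15),
    ("intensity", "q05", 0.55, 0.15),
    ("intensity", "q95", 1.50, 0.13),
    ("texture", "contrast", 0.05, 0.16),
    ("texture", "entropy", 0.02, 0.12),
)
_CHANNEL_BASE_MEDIAN = {"DNA": 500.0, "RNA": 220.0, "Mito": 350.0, "ER": 240.0,
                        "Golgi": 150.0, "Actin": 280.0, "Lyso": 200.0}


def _build_default_features() -> tuple[FeatureSpec, ...]:
    feats = []
    for channel, regions in _CHANNEL_REGIONS.items():
        base = _CHANNEL_BASE_MEDIAN[channel]
        for i, region in enumerate(regions):
            region_scale = 1.0 - 0.15 * i
            for family, stat, med_scale, rel_mad in _STAT_BATTERY:
                med = base * region_scale * med_scale
                feats.append(FeatureSpec(f"{channel}_{region}_{family}_{stat}",
                                         median=med, mad=rel_mad * med))
    # a few shape features on the segmentation masks
    feats += [
        FeatureSpec("DNA_nucleus_shape_area", 300.0, 40.0),
        FeatureSpec("DNA_nucleus_shape_roundness", 0.88, 0.05),
        FeatureSpec("DNA_cell_shape_area", 900.0, 110.0),
    ]
    return tuple(feats)


DEFAULT_FEATURES: tuple[FeatureSpec, ...] = _build_default_features()


def features_for_channel(features: Sequence[FeatureSpec], channel: str) -> list[str]:
    return [f.name for f in features if f.name.split("_")[0] == channel]


# Channel signatures emulating a reference compound plate: diverse organelle-
# targeted modes of action with several compounds per Lyso / Mito / Actin
# group (as lysosomotropic drugs, mitochondrial inhibitors and actin
# disruptors appear in multiples on such plates), two broad-acting compounds
# and two inactive negative controls.  Values are effect tops in units of
# the baseline MAD; the first three compounds are the single-channel
# "planted actives" used for detection benchmarking.
DEFAULT_SIGNATURES: dict[str, dict[str, float]] = {
    # Lyso group (lysosomotropic; weak secondary ER stress shared by the group)
    "C01": {"Lyso": 8.0, "ER": 2.0},
    "C04": {"Lyso": 6.0, "ER": 2.0},
    # Actin group (cytoskeleton disruptors; secondary Golgi fragmentation)
    "C02": {"Actin": 8.0, "Golgi": 2.0},
    "C06": {"Actin": 6.0, "Golgi": 2.0},
    # Mito group (mitochondrial inhibitors; secondary nuclear condensation)
    "C03": {"Mito": 8.0, "DNA": 2.0},
    "C05": {"Mito": 6.0, "DNA": 2.0},
    # secretory-pathway group
    "C07": {"ER": 6.0, "Golgi": 4.0},
    "C10": {"ER": 6.0, "Golgi": 3.0},
    "C11": {"Golgi": 6.0, "ER": 3.0},
    # nucleic-acid group
    "C08": {"DNA": 6.0, "RNA": 4.0},
    "C09": {"RNA": 6.0, "DNA": 3.0},
    "C12": {"DNA": 6.0, "RNA": 3.0},
    "C13": {"DNA": 4.0, "RNA": 4.0},
    # negative controls
    "C14": {},
    "C15": {},
}

# a couple of compounds lose cells at high concentration
DEFAULT_CYTOTOX_EC50_UM = {"C05": 30.0, "C13": 10.0}


def default_ground_truth(
    layout: PlateLayout,
    features: Sequence[FeatureSpec] = DEFAULT_FEATURES,
    actives: Mapping[str, str] | Mapping[str, Mapping[str, float]] | None = None,
    effect_top_mads: float = 8.0,
    ac50_uM: float | None = None,
    hill_slope: float = 2.0,
    cytotox: Mapping[str, float] | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Plant channel-targeted actives on a layout.

    ``actives`` maps compound_id -> targeted channel (all features of that
    channel get a hill effect with top = ``effect_top_mads`` MADs) or
    compound_id -> {channel: top in MADs}.  By default the reference-plate
    signatures (``DEFAULT_SIGNATURES``) are planted for the compounds
    present in the layout.  Per compound, the half-maximal concentration is
    drawn log-uniformly from 0.3-3 uM unless ``ac50_uM`` pins it; the
    effect sign per feature is a seeded coin flip.
    """
    compounds = layout.compounds
    if actives is None:
        actives = {c: DEFAULT_SIGNATURES.get(c, {}) for c in compounds}
        if cytotox is None:
            cytotox = {c: DEFAULT_CYTOTOX_EC50_UM.get(c, math.inf) for c in compounds}
    if cytotox is None:
        cytotox = {}
    rng = np.random.default_rng(seed)
    spec_by_name = {f.name: f for f in features}
    effects: dict[tuple[str, str], EffectCurve] = {}
    for cmpd in compounds:
        sig = actives.get(cmpd)
        if sig is None:
            continue
        if isinstance(sig, str):
            sig = {sig: effect_top_mads}
        ac50 = ac50_uM if ac50_uM is not None else float(10 ** rng.uniform(np.log10(0.3), np.log10(3.0)))
        for channel, top_mads in sig.items():
            for fname in features_for_channel(features, channel):
                spec = spec_by_name[fname]
                # effect direction is a property of the feature, shared by
                # every compound hitting that channel: compounds with the
                # same mode of action move a feature the same way
                sign = 1.0 if (zlib.crc32(fname.encode()) & 1) else -1.0
                effects[(cmpd, fname)] = EffectCurve(
                    family="hill",
                    top=sign * top_mads * spec.mad,
                    ac50_uM=ac50,
                    slope=hill_slope,
                )
    ec50s = {c: cytotox.get(c, math.inf) for c in compounds}
    return GroundTruth(effects=effects, cytotox_ec50_uM=ec50s)


def _noise_sigmas(spec: FeatureSpec) -> tuple[float, float]:
    """Split the configured MAD between a log-normal baseline and additive
    Gaussian noise.

    The Gaussian component carries the MAD (sigma = mad / 0.6745); the
    log-normal shape parameter is kept small enough that the combined sample
    MAD stays within a few percent of the configured value.
    """
    sigma_g = spec.mad / GAUSS_MAD
    sigma_ln = 0.2 * sigma_g / max(abs(spec.median), 1e-12)
    return sigma_ln, sigma_g


def generate_feature_table(
    layout: PlateLayout,
    truth: GroundTruth,
    features: Sequence[FeatureSpec] = DEFAULT_FEATURES,
    n_cells_per_well: int = 100,
    n_biol_reps: int = 4,
    seed: int = 0,
    poisson_cells: bool = True,
) -> pd.DataFrame:
    """Simulate a per-cell feature table for ``n_biol_reps`` plates.

    Each biological replicate is one plate sharing the layout.  Per cell:
    value = lognormal baseline + planted effect at the well concentration
    + Gaussian noise.  Expected cell count per well is
    ``n_cells_per_well * survival(compound, conc)`` (Poisson-distributed
    unless ``poisson_cells`` is False).
    """
    if n_biol_reps < 1:
        raise ValueError("n_biol_reps must be >= 1")
    if n_cells_per_well < 1:
        raise ValueError("n_cells_per_well must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    blocks: dict[str, np.ndarray] = {}
    meta_records: list[dict] = []
    feat_names = [f.name for f in features]
    sigmas = {f.name: _noise_sigmas(f) for f in features}

    for brep in range(1, n_biol_reps + 1):
        plate_id = f"{layout.plate_id}_B{brep}"
        for w in layout.wells:
            if w.role == ROLE_CONTROL:
                mean_cells = float(n_cells_per_well)
            else:
                mean_cells = n_cells_per_well * truth.survival(w.compound_id, w.concentration_uM)
            n_cells = int(rng.poisson(mean_cells)) if poisson_cells else int(round(mean_cells))
            n_cells = max(n_cells, 1)
            block = np.empty((n_cells, len(feat_names)))
            for j, spec in enumerate(features):
                sigma_ln, sigma_g = sigmas[spec.name]
                base = spec.median * np.exp(sigma_ln * rng.standard_normal(n_cells))
                eff = 0.0
                if w.role != ROLE_CONTROL:
                    curve = truth.effect(w.compound_id, spec.name)
                    if curve is not None:
                        eff = curve(w.concentration_uM)
                block[:, j] = base + eff + sigma_g * rng.standard_normal(n_cells)
            key = f"{plate_id}:{w.name}"
            blocks[key] = block
            meta_records.append(
                dict(plate_id=plate_id, biol_rep=brep, well=w.name, row=w.row,
                     col=w.col, role=w.role, compound_id=w.compound_id or "",
                     concentration_uM=w.concentration_uM, tech_block=w.tech_block,
                     n_cells=n_cells, key=key)
            )

    metas = []
    datas = []
    for rec in meta_records:
        block = blocks[rec.pop("key")]
        n = block.shape[0]
        meta = pd.DataFrame({k: np.repeat(v, n) for k, v in rec.items() if k != "n_cells"})
        meta["cell_id"] = np.arange(n)
        metas.append(meta)
        datas.append(block)
    meta_df = pd.concat(metas, ignore_index=True)
    data_df = pd.DataFrame(np.vstack(datas), columns=feat_names)
    return pd.concat([meta_df, data_df], axis=1)


METADATA_COLUMNS = ("plate_id", "biol_rep", "well", "row", "col", "role",
                    "compound_id", "concentration_uM", "tech_block", "cell_id",
                    "field", "cell_label")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a cell/well table that are features, not metadata."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]
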