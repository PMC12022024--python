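"""Robust z-score standardization, cytotoxicity gating and replicate variability.

Single-cell features are standardized per plate against the pooled DMSO
solvent-control cell population:

    robust z = (x - median_ctrl) / (1.4826 * MAD_ctrl)

where MAD is the raw median absolute deviation (the 1.4826 Gaussian-
consistency factor appears exactly once, in the denominator).  Cell-level
z-scores are aggregated to wells by the median without further rescaling.
Population (per-well) features — the absolute cell number and the three
nucleolus-count fractions — are standardized only at the well level, the
cell number with the same robust z form against control wells, the
discrete nucleolus fractions with a plain z-score.

Cytotoxic concentrations are those whose PercentCells (well cell count as
a percentage of the solvent-control count, per biological replicate)
falls strictly below 53%.

Replicate variability follows the Diff / MedianDiff / SumDiff / SumResp /
RelSumDiff chain: per-well deviations from the all-replicate median per
condition, aggregated per technical (TRep), biological (BRep) or all
(AllRep) replicate grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .simulate import feature_columns

logger = logging.getLogger(__name__)

ROBUST_Z_CONSTANT = 1.4826
CYTOTOX_THRESHOLD_PERCENT = 53.0

WELL_KEYS = ["plate_id", "biol_rep", "well", "role", "compound_id",
             "concentration_uM", "tech_block"]

POPULATION_FEATURES = (
    "AbsoluteCellNumber",
    "RelativeCellNumber_1_2_Nucleoli",
    "RelativeCellNumber_3_4_Nucleoli",
    "RelativeCellNumber_5plus_Nucleoli",
)


def mad(values: np.ndarray) -> float:
    """Median absolute deviation from the median (no consistency factor)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan
    med = np.median(v)
    return float(np.median(np.abs(v - med)))


def robust_z(values: np.ndarray, ctrl_median: float, ctrl_mad: float) -> np.ndarray:
    return (np.asarray(values, dtype=float) - ctrl_median) / (ROBUST_Z_CONSTANT * ctrl_mad)


def robust_z_cells(cells: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Standardize cell-level features per plate against pooled control cells.

    Features whose control MAD is zero on any plate are removed from the
    output (logged).  Raises if a plate has no solvent-control cells.
    """
    if features is None:
        features = feature_columns(cells)
    out_parts = []
    dropped: set[str] = set()
    for plate_id, grp in cells.groupby("plate_id", sort=False):
        ctrl = grp[grp["role"] == "solvent_control"]
        if ctrl.empty:
            raise ValueError(f"plate {plate_id!r} has no solvent-control cells")
        z = grp.copy()
        for f in features:
            m = float(ctrl[f].median())
            s = mad(ctrl[f].to_numpy())
            if not np.isfinite(s) or s == 0:
                dropped.add(f)
                continue
            z[f] = robust_z(grp[f].to_numpy(), m, s)
        out_parts.append(z)
    if dropped:
        logger.info("features with a DMSO MAD of zero were removed: %s", sorted(dropped))
    out = pd.concat(out_parts, ignore_index=True)
    return out.drop(columns=sorted(dropped))


def aggregate_to_wells(cell_z: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Per-well median of cell-level robust z-scores (no further rescaling)."""
    if features is None:
        features = feature_columns(cell_z)
    keys = [k for k in WELL_KEYS if k in cell_z.columns]
    agg = cell_z.groupby(keys, sort=False, dropna=False)[features].median().reset_index()
    counts = cell_z.groupby(keys, sort=False, dropna=False).size().rename("n_cells").reset_index()
    return agg.merge(counts, on=keys)


def nucleoli_fractions(counts: np.ndarray) -> tuple[float, float, float]:
    """Fractions of cells with 1-2, 3-4 and 5+ nucleoli."""
    c = np.asarray(counts)
    c = c[c > 0]
    if c.size == 0:
        return (np.nan, np.nan, np.nan)
    return (float(((c >= 1) & (c <= 2)).mean()),
            float(((c >= 3) & (c <= 4)).mean()),
            float((c >= 5).mean()))


def population_feature_table(cells: pd.DataFrame,
                             nucleoli_column: str = "RNA_nucleoli_count_n") -> pd.DataFrame:
    """Raw per-well population features: cell count and nucleolus fractions."""
    keys = [k for k in WELL_KEYS if k in cells.columns]
    recs = []
    for key_vals, grp in cells.groupby(keys, sort=False, dropna=False):
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec["AbsoluteCellNumber"] = float(len(grp))
        if nucleoli_column in grp.columns:
            f12, f34, f5 = nucleoli_fractions(grp[nucleoli_column].to_numpy())
            rec["RelativeCellNumber_1_2_Nucleoli"] = f12
            rec["RelativeCellNumber_3_4_Nucleoli"] = f34
            rec["RelativeCellNumber_5plus_Nucleoli"] = f5
        recs.append(rec)
    return pd.DataFrame(recs)


def standardize_population_features(well_table: pd.DataFrame) -> pd.DataFrame:
    """Standardize population features at the well level only, per plate.

    AbsoluteCellNumber uses the robust z form against control wells; the
    discrete nucleolus fractions use a plain z-score (mean/SD of control
    wells).  Plain-z features with zero control SD are dropped with a
    warning.
    """
    out_parts = []
    dropped: set[str] = set()
    present = [f for f in POPULATION_FEATURES if f in well_table.columns]
    for plate_id, grp in well_table.groupby("plate_id", sort=False):
        ctrl = grp[grp["role"] == "solvent_control"]
        if len(ctrl) < 2:
            raise ValueError(f"plate {plate_id!r} has fewer than 2 control wells")
        z = grp.copy()
        for f in present:
            if f == "AbsoluteCellNumber":
                m, s = float(ctrl[f].median()), mad(ctrl[f].to_numpy())
                if s == 0 or not np.isfinite(s):
                    dropped.add(f)
                    continue
                z[f] = robust_z(grp[f].to_numpy(), m, s)
            else:
                mu, sd = float(ctrl[f].mean()), float(ctrl[f].std(ddof=1))
                if not np.isfinite(sd) or sd == 0:
                    dropped.add(f)
                    continue
                z[f] = (grp[f].to_numpy() - mu) / sd
        out_parts.append(z)
    if dropped:
        logger.warning("population features dropped (zero control spread): %s",
                       sorted(dropped))
    return pd.concat(out_parts, ignore_index=True).drop(columns=sorted(dropped))


def flag_cytotoxic(well_table: pd.DataFrame,
                   threshold_percent: float = CYTOTOX_THRESHOLD_PERCENT,
                   count_column: str = "n_cells") -> pd.DataFrame:
    """Compute PercentCells and cytotoxicity flags.

    PercentCells = 100 * well cell count / median control-well cell count,
    per biological replicate (plate).  A compound x concentration is
    flagged cytotoxic iff the median PercentCells over its wells (within
    biological replicate, then across replicates) is strictly below the
    threshold; the flag propagates to every well of that condition.
    """
    df = well_table.copy()
    parts = []
    for plate_id, grp in df.groupby("plate_id", sort=False):
        ctrl = grp[grp["role"] == "solvent_control"]
        if ctrl.empty:
            raise ValueError(f"plate {plate_id!r} has no control wells")
        ref = float(ctrl[count_column].median())
        if ref <= 0:
            raise ValueError(f"plate {plate_id!r}: zero control cell count")
        g = grp.copy()
        g["PercentCells"] = 100.0 * g[count_column] / ref
        parts.append(g)
    df = pd.concat(parts, ignore_index=True)

    cmpd = df[df["role"] != "solvent_control"]
    per_rep = (cmpd.groupby(["compound_id", "concentration_uM", "biol_rep"], sort=False)
               ["PercentCells"].median())
    per_cond = per_rep.groupby(["compound_id", "concentration_uM"]).median()
    flags = (per_cond < threshold_percent).rename("cytotoxic").reset_index()
    df = df.merge(flags, on=["compound_id", "concentration_uM"], how="left")
    df["cytotoxic"] = df["cytotoxic"].eq(True)  # missing (control wells) -> False
    return df


def aggregate_replicates(well_table: pd.DataFrame, level: str,
                         features: list[str] | None = None) -> pd.DataFrame:
    """Median profiles per replicate grouping.

    TRep: median over biological replicates for each technical block;
    BRep: median over technical blocks for each biological replicate;
    AllRep: median over all wells of a compound x concentration.
    """
    if features is None:
        features = [c for c in feature_columns(well_table)
                    if c not in ("n_cells", "PercentCells", "cytotoxic")]
    base = ["compound_id", "concentration_uM"]
    extra = {"TRep": ["tech_block"], "BRep": ["biol_rep"], "AllRep": []}
    if level not in extra:
        raise ValueError(f"unknown replicate level {level!r}")
    keys = base + extra[level]
    return well_table.groupby(keys, sort=False, dropna=False)[features].median().reset_index()


@dataclass
class VariabilityReport:
    """Replicate-variability summary."""

    diffs: pd.DataFrame                 # per well x feature Diff values
    median_diff: dict[str, pd.DataFrame]  # per grouping level
    summary: pd.DataFrame               # SumDiff, SumResp, RelSumDiff per replicate
    correlations: dict[str, pd.DataFrame] = dc_field(default_factory=dict)


def well_diffs(well_table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Diff per well = well z minus the all-replicate median of its condition."""
    cmpd = well_table[well_table["role"] != "solvent_control"].copy()
    med = (cmpd.groupby(["compound_id", "concentration_uM"], sort=False)[features]
           .transform("median"))
    diffs = cmpd.copy()
    diffs[features] = cmpd[features] - med
    return diffs


def variability_report(well_table: pd.DataFrame,
                       features: list[str] | None = None) -> VariabilityReport:
    """Compute the Diff / MedianDiff / SumDiff / SumResp / RelSumDiff chain."""
    if features is None:
        features = [c for c in feature_columns(well_table)
                    if c not in ("n_cells", "PercentCells", "cytotoxic")]
    diffs = well_diffs(well_table, features)
    cmpd = well_table[well_table["role"] != "solvent_control"]

    groupers = {"TRep": ["tech_block"], "BRep": ["biol_rep"], "AllRep": []}
    median_diff: dict[str, pd.DataFrame] = {}
    rows = []
    for level, keys in groupers.items():
        if keys:
            md = diffs.groupby(keys, sort=False)[features].median().reset_index()
            grouped_d = diffs.groupby(keys, sort=False)
            grouped_x = cmpd.groupby(keys, sort=False)
            for key_vals in md[keys].itertuples(index=False):
                kv = tuple(key_vals)
                d = grouped_d.get_group(kv)
                x = grouped_x.get_group(kv)
                sum_diff = float(np.abs(d[features].to_numpy()).sum())
                sum_resp = float(np.abs(x[features].to_numpy()).sum())
                rows.append(dict(level=level, **dict(zip(keys, kv)),
                                 SumDiff=sum_diff, SumResp=sum_resp,
                                 RelSumDiff=sum_diff / sum_resp if sum_resp > 0 else np.nan))
        else:
            md = diffs[features].median().to_frame().T
            sum_diff = float(np.abs(diffs[features].to_numpy()).sum())
            sum_resp = float(np.abs(cmpd[features].to_numpy()).sum())
            rows.append(dict(level=level, SumDiff=sum_diff, SumResp=sum_resp,
                             RelSumDiff=sum_diff / sum_resp if sum_resp > 0 else np.nan))
        median_diff[level] = md
    summary = pd.DataFrame(rows)
    return VariabilityReport(diffs=diffs, median_diff=median_diff, summary=summary)


def replicate_correlation(well_table: pd.DataFrame, level: str,
                          features: list[str] | None = None,
                          drop_cytotoxic: bool = True) -> pd.DataFrame:
    """Pearson correlation matrix between replicate profiles.

    Each replicate (technical block for TRep, biological replicate for
    BRep) is represented by its concatenated feature x condition median
    profile; cytotoxic concentrations are removed first.  Pairs involving
    a constant profile are reported as NaN.
    """
    if features is None:
        features = [c for c in feature_columns(well_table)
                    if c not in ("n_cells", "PercentCells", "cytotoxic")]
    df = well_table[well_table["role"] != "solvent_control"]
    if drop_cytotoxic and "cytotoxic" in df.columns:
        df = df[~df["cytotoxic"]]
    rep_col = {"TRep": "tech_block", "BRep": "biol_rep"}.get(level)
    if rep_col is None:
        raise ValueError(f"replicate correlation undefined for level {level!r}")
    profiles = (df.groupby([rep_col, "compound_id", "concentration_uM"], sort=False)
                [features].median())
    wide = profiles.unstack(level=0)  # rows: condition x feature later stacked
    reps = sorted(df[rep_col].unique())
    mat = pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            va = wide.xs(a, axis=1, level=1).to_numpy().ravel()
            vb = wide.xs(b, axis=1, level=1).to_numpy().ravel()
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 2 or np.std(va[ok]) == 0 or np.std(vb[ok]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(va[ok], vb[ok])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
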