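"""Category-level mode-of-action reporting statistics.

Features named ``<channel>_<region>_<family>_<stat>`` are grouped into
categories — one per (channel, region, analysis-module/family) combination
— and summarized as:

* Proportion BMC profiles: per compound x category, the fraction of member
  features whose log10 BMC is significantly low (p < 0.05, one-sided
  one-sample t against the across-compound mean/SD for that feature).
* Accumulation data: categories with at least 30% responding member
  features (BMC class OK or LOW), ranked by the median member BMC.
* Magnitude data: per feature, the BMC together with the normalized
  magnitude — the maximum |aggregated robust z| over the non-cytotoxic
  concentration range.
* Profile similarity: Spearman correlation of compound profiles at each
  compound's highest non-cytotoxic concentration (optionally excluding
  Lyso features), with average-linkage hierarchical clustering on 1 - rho.
* CV vs cell number: bootstrap resampling of cells per well to trace how
  feature reproducibility across plates depends on the number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .doseresponse import BMCRecord, CLASS_OK, CLASS_LOW
from .simulate import feature_columns


@dataclass
class CategoryMap:
    """feature -> (channel, region, module) category assignment."""

    assignments: dict[str, tuple[str, str, str]]

    @property
    def categories(self) -> list[tuple[str, str, str]]:
        return sorted(set(self.assignments.values()))

    def members(self, category: tuple[str, str, str]) -> list[str]:
        return sorted(f for f, c in self.assignments.items() if c == category)

    def category_name(self, category: tuple[str, str, str]) -> str:
        return " ".join(category)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(feature=f, channel=c[0], region=c[1], module=c[2])
             for f, c in sorted(self.assignments.items())]
        )


def assign_categories(feature_names: list[str]) -> CategoryMap:
    """Parse feature names into (channel, region, module) categories.

    Malformed names are collected and reported in one error rather than
    silently dropped.
    """
    assignments: dict[str, tuple[str, str, str]] = {}
    bad: list[str] = []
    for name in feature_names:
        parts = name.split("_")
        if len(parts) < 4:
            bad.append(name)
            continue
        channel, region, module = parts[0], parts[1], parts[2]
        if not (channel and region and module):
            bad.append(name)
            continue
        assignments[name] = (channel, region, module)
    if bad:
        raise ValueError(f"malformed feature names (expect channel_region_family_stat): {bad}")
    return CategoryMap(assignments)


def proportion_bmc(log_bmc: pd.DataFrame, categories: CategoryMap,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per compound x category proportion of significantly low feature BMCs.

    For each feature, each compound's log10 BMC is tested one-sided
    (lower tail) against the across-compound mean/SD:
    t = (x_c - mean) / sd with n - 1 degrees of freedom, p = P(T <= t).
    NA-class records must already be substituted (proportion_profiles
    context) so every compound contributes a value.
    """
    wide = log_bmc.pivot(index="feature", columns="compound_id", values="log10_BMC")
    n = wide.shape[1]
    if n < 3:
        raise ValueError(f"proportion BMC needs >= 3 compounds, got {n}")
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = wide.sub(mean, axis=0).div(sd, axis=0)
    pvals = pd.DataFrame(stats.t.cdf(tstat.to_numpy(), df=n - 1),
                         index=wide.index, columns=wide.columns)
    sig = (pvals < alpha) & (sd.to_numpy()[:, None] > 0)
    sig = pd.DataFrame(sig, index=wide.index, columns=wide.columns)

    rows = []
    for cat in categories.categories:
        members = [m for m in categories.members(cat) if m in sig.index]
        if not members:
            continue
        frac = sig.loc[members].mean(axis=0)
        for cmpd, v in frac.items():
            rows.append(dict(category=categories.category_name(cat),
                             channel=cat[0], region=cat[1], module=cat[2],
                             compound_id=cmpd, proportion=float(v),
                             n_features=len(members)))
    return pd.DataFrame(rows)


def accumulation_data(records: list[BMCRecord], categories: CategoryMap,
                      min_responding_frac: float = 0.30) -> pd.DataFrame:
    """Ranked (category, median BMC) lists per compound.

    A category enters the plot for a compound when at least
    ``min_responding_frac`` of its member features respond (class OK or
    LOW); its BMC is the median over the responding members' BMC values.
    """
    by_compound: dict[str, list[BMCRecord]] = {}
    for r in records:
        by_compound.setdefault(r.compound_id, []).append(r)
    rows = []
    for cmpd, recs in sorted(by_compound.items()):
        by_feature = {r.feature: r for r in recs}
        for cat in categories.categories:
            members = [m for m in categories.members(cat) if m in by_feature]
            if not members:
                continue
            responding = [by_feature[m] for m in members
                          if by_feature[m].bmc_class in (CLASS_OK, CLASS_LOW)]
            frac = len(responding) / len(members)
            if frac + 1e-12 < min_responding_frac:
                continue
            med = float(np.median([r.bmc_uM for r in responding]))
            rows.append(dict(compound_id=cmpd,
                             category=categories.category_name(cat),
                             median_BMC_uM=med, responding_frac=frac,
                             n_features=len(members)))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(["compound_id", "median_BMC_uM"], kind="mergesort")
    df["rank"] = df.groupby("compound_id").cumcount() + 1
    return df.reset_index(drop=True)


def magnitude_data(records: list[BMCRecord], profiles: pd.DataFrame,
                   features: list[str] | None = None) -> pd.DataFrame:
    """Per feature x compound: BMC and normalized magnitude.

    ``profiles`` is a replicate-aggregated well table (AllRep medians, one
    row per compound x concentration, with a ``cytotoxic`` column); the
    magnitude is the maximum |z| over non-cytotoxic concentrations.
    """
    if features is None:
        features = [c for c in feature_columns(profiles)
                    if c not in ("cytotoxic", "n_cells", "PercentCells")]
    df = profiles
    if "cytotoxic" in df.columns:
        df = df[~df["cytotoxic"].astype(bool)]
    rows = []
    mags = df.groupby("compound_id")[features].agg(lambda s: np.nanmax(np.abs(s)))
    for r in records:
        if r.feature not in mags.columns or r.compound_id not in mags.index:
            continue
        rows.append(dict(feature=r.feature, compound_id=r.compound_id,
                         bmc_class=r.bmc_class,
                         BMC_uM=r.bmc_uM if r.bmc_uM is not None else np.nan,
                         magnitude=float(mags.loc[r.compound_id, r.feature])))
    return pd.DataFrame(rows)


def highest_nontoxic_profiles(well_table: pd.DataFrame,
                              features: list[str] | None = None) -> pd.DataFrame:
    """One profile per compound: AllRep median z at its highest non-cytotoxic
    concentration."""
    if features is None:
        features = [c for c in feature_columns(well_table)
                    if c not in ("cytotoxic", "n_cells", "PercentCells")]
    df = well_table[well_table["role"] != "solvent_control"]
    if "cytotoxic" in df.columns:
        df = df[~df["cytotoxic"].astype(bool)]
    agg = df.groupby(["compound_id", "concentration_uM"], sort=True)[features].median()
    rows = {}
    for cmpd in agg.index.get_level_values(0).unique():
        sub = agg.loc[cmpd]
        rows[cmpd] = sub.loc[sub.index.max()]
    return pd.DataFrame(rows).T.rename_axis("compound_id")


def similarity_cluster(profiles: pd.DataFrame, include_lyso: bool = True,
                       k: int = 6) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlation between compound profiles + hierarchical clusters.

    ``profiles``: rows = compounds, columns = features.  Lyso-channel
    features are excluded when ``include_lyso`` is False.  Clustering uses
    average linkage on distance 1 - rho, cut into ``k`` flat clusters.
    Correlations involving a constant profile are NaN (such compounds are
    placed in their own cluster).
    """
    cols = list(profiles.columns)
    if not include_lyso:
        cols = [c for c in cols if not c.startswith("Lyso_")]
    mat = profiles[cols]
    rho, _ = stats.spearmanr(mat.to_numpy(), axis=1)
    if np.ndim(rho) == 0:  # spearmanr collapses the two-profile case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=mat.index, columns=mat.index)
    const = mat.std(axis=1) == 0
    corr.loc[const, :] = np.nan
    corr.loc[:, const] = np.nan
    np.fill_diagonal(corr.values, 1.0)

    dist = 1.0 - corr.fillna(0.0).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="average")
    k_eff = min(k, len(mat.index))
    labels = pd.Series(fcluster(Z, t=k_eff, criterion="maxclust"),
                       index=mat.index, name="cluster")
    return corr, labels


def cv_vs_ncells(cells: pd.DataFrame, n_cells_grid: list[int],
                 features: list[str] | None = None, n_draws: int = 8,
                 seed: int = 0) -> pd.DataFrame:
    """Median feature CV across plates as a function of cells sampled per well.

    For each n: per well and plate, n cells are drawn with replacement and
    each feature's median computed; the CV (sd/|mean|) of those medians is
    taken per well across plates; the median CV over wells and features is
    recorded.  The whole resample is repeated ``n_draws`` times and the
    median over repetitions reported, which stabilizes the Monte-Carlo
    estimate without biasing the n-dependence.
    """
    if features is None:
        features = feature_columns(cells)
    rng = np.random.default_rng(seed)
    groups = {key: grp[features].to_numpy()
              for key, grp in cells.groupby(["well", "plate_id"], sort=False)}
    wells = sorted({w for w, _ in groups})
    rows = []
    for n in n_cells_grid:
        draw_cvs = []
        for _ in range(n_draws):
            medians: dict[str, dict[str, np.ndarray]] = {}
            for (well, plate), arr in groups.items():
                idx = rng.integers(0, arr.shape[0], size=n)
                medians.setdefault(well, {})[plate] = np.median(arr[idx], axis=0)
            cvs = []
            for well in wells:
                plates = medians.get(well, {})
                if len(plates) < 2:
                    continue
                m = np.vstack(list(plates.values()))
                mean = m.mean(axis=0)
                sd = m.std(axis=0, ddof=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    cv = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.nan)
                cvs.append(cv)
            draw_cvs.append(float(np.nanmedian(np.vstack(cvs))))
        rows.append(dict(n_cells=n, median_cv=float(np.median(draw_cvs))))
    return pd.DataFrame(rows)
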