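"""End-to-end pipeline: synth -> (register -> extract) -> profile -> bmc -> report.

Each stage writes versioned outputs plus a machine-readable JSON log into
its own subdirectory of the run directory; a stage is skipped on rerun
when its log records the same config hash and its outputs still exist
(delete a stage directory to force recomputation of it and everything
downstream).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .plate import generate_plate_layout, PlateLayout
from .simulate import (default_ground_truth, generate_feature_table,
                       feature_columns, DEFAULT_FEATURES)
from .profiling import (robust_z_cells, aggregate_to_wells, flag_cytotoxic,
                        aggregate_replicates, variability_report)
from .doseresponse import bmc_table, bmc_for_downstream, BMCRecord
from .reporting import (assign_categories, proportion_bmc, accumulation_data,
                        magnitude_data, highest_nontoxic_profiles,
                        similarity_cluster)
from .io import write_table, read_table

logger = logging.getLogger(__name__)

STAGES = ("synth", "profile", "bmc", "report")


def _stage_dir(out_dir: Path, stage: str) -> Path:
    d = out_dir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _stage_done(out_dir: Path, stage: str, cfg_hash: str, outputs: list[str]) -> bool:
    log = out_dir / stage / "stage.json"
    if not log.exists():
        return False
    try:
        meta = json.loads(log.read_text())
    except json.JSONDecodeError:
        return False
    if meta.get("config_hash") != cfg_hash:
        return False
    return all((out_dir / stage / f).exists() for f in outputs)


def _write_stage_log(out_dir: Path, stage: str, cfg_hash: str, **info) -> None:
    log = dict(stage=stage, config_hash=cfg_hash, package_version=__version__, **info)
    (out_dir / stage / "stage.json").write_text(json.dumps(log, indent=2, default=str))


def run_pipeline(config: RunConfig, out_dir,
                 cell_table: pd.DataFrame | None = None,
                 layout: PlateLayout | None = None) -> dict:
    """Run the data-analysis pipeline and return the collected artifacts.

    Entry points: a precomputed per-cell feature table (+ layout), or
    nothing — in which case the synthesis stage generates a synthetic
    screen under the configured study conditions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.content_hash()
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "run.json").write_text(json.dumps(
        dict(config_hash=cfg_hash, seed=config.seed, package_version=__version__),
        indent=2))

    # --- synth ----------------------------------------------------------
    synth_dir = _stage_dir(out_dir, "synth")
    if cell_table is None:
        if _stage_done(out_dir, "synth", cfg_hash, ["layout.csv", "cells.parquet"]):
            layout = PlateLayout.from_csv(synth_dir / "layout.csv")
            cell_table = read_table(synth_dir / "cells.parquet")
            logger.info("synth: reusing cached outputs")
        else:
            layout = generate_plate_layout(
                config.n_compounds, config.n_conc, config.n_blocks,
                config.n_controls, config.top_conc_uM, seed=config.seed)
            truth = default_ground_truth(layout, seed=config.seed)
            cell_table = generate_feature_table(
                layout, truth, n_cells_per_well=config.n_cells_per_well,
                n_biol_reps=config.n_biol_reps, seed=config.seed)
            layout.to_csv(synth_dir / "layout.csv")
            write_table(cell_table, synth_dir / "cells.parquet")
            _write_stage_log(out_dir, "synth", cfg_hash,
                             n_wells=len(layout.wells), n_cells=len(cell_table))
    else:
        if layout is None:
            raise ValueError("a cell table entry point requires a layout")
        layout.to_csv(synth_dir / "layout.csv")
        write_table(cell_table, synth_dir / "cells.parquet")
        _write_stage_log(out_dir, "synth", cfg_hash, entry_point="cell_table",
                         n_cells=len(cell_table))

    features = feature_columns(cell_table)

    # --- profile --------------------------------------------------------
    profile_dir = _stage_dir(out_dir, "profile")
    if _stage_done(out_dir, "profile", cfg_hash, ["wells.parquet"]):
        wells = read_table(profile_dir / "wells.parquet")
        logger.info("profile: reusing cached outputs")
    else:
        cell_z = robust_z_cells(cell_table, features)
        wells = aggregate_to_wells(cell_z)
        wells = flag_cytotoxic(wells, config.cytotox_threshold_percent)
        write_table(wells, profile_dir / "wells.parquet")
        write_table(wells, profile_dir / "wells.csv")
        var = variability_report(wells)
        write_table(var.summary, profile_dir / "variability.csv")
        kept = feature_columns(wells)
        _write_stage_log(out_dir, "profile", cfg_hash, n_wells=len(wells),
                         n_features_in=len(features),
                         n_features_kept=len([f for f in features if f in kept]),
                         dropped_features=[f for f in features if f not in wells.columns])
    kept_features = [f for f in features if f in wells.columns]

    # --- bmc ------------------------------------------------------------
    bmc_dir = _stage_dir(out_dir, "bmc")
    bmc_df, records = bmc_table(wells, kept_features, seed=config.seed,
                                min_conc=config.min_conc_count,
                                min_reps=config.min_biol_reps)
    write_table(bmc_df, bmc_dir / "bmc.csv")
    _write_stage_log(out_dir, "bmc", cfg_hash, n_records=len(records),
                     class_counts=bmc_df["bmc_class"].value_counts().to_dict())

    # --- report ---------------------------------------------------------
    report_dir = _stage_dir(out_dir, "report")
    categories = assign_categories(kept_features)
    log_bmc = bmc_for_downstream(records, "proportion_profiles",
                                 max_tested_uM=config.top_conc_uM)
    prop = proportion_bmc(log_bmc, categories)
    accum = accumulation_data(records, categories, config.min_responding_frac)
    allrep = aggregate_replicates(wells, "AllRep", kept_features)
    flags = (wells.groupby(["compound_id", "concentration_uM"])  # conserve flags
             ["cytotoxic"].max().reset_index())
    allrep = allrep.merge(flags, on=["compound_id", "concentration_uM"], how="left")
    mag = magnitude_data(records, allrep, kept_features)
    profiles = highest_nontoxic_profiles(wells, kept_features)
    corr, clusters = similarity_cluster(profiles, include_lyso=config.include_lyso,
                                        k=config.n_clusters)
    write_table(prop, report_dir / "proportion_bmc.csv")
    write_table(accum, report_dir / "accumulation.csv")
    write_table(mag, report_dir / "magnitude.csv")
    corr.to_csv(report_dir / "similarity.csv")
    clusters.to_frame().to_csv(report_dir / "clusters.csv")
    _write_stage_log(out_dir, "report", cfg_hash, n_categories=len(categories.categories))

    return dict(layout=layout, cells=cell_table, wells=wells, bmc=bmc_df,
                records=records, proportion=prop, accumulation=accum,
                magnitude=mag, similarity=corr, clusters=clusters)
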