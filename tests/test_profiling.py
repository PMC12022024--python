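"""Robust z standardization, cytotoxicity gate, replicate variability equations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import paintplus as pp
from paintplus.profiling import (mad, robust_z, robust_z_cells, aggregate_to_wells,
                                 nucleoli_fractions, population_feature_table,
                                 standardize_population_features, flag_cytotoxic,
                                 aggregate_replicates, variability_report,
                                 replicate_correlation, ROBUST_Z_CONSTANT)


def _cells(values_by_well, feature="Mito_cytoplasm_intensity_mean"):
    """Tiny cell table: {(plate, well, role, compound, conc, block, brep): values}."""
    rows = []
    for (plate, well, role, cmpd, conc, block, brep), vals in values_by_well.items():
        for i, v in enumerate(vals):
            rows.append(dict(plate_id=plate, biol_rep=brep, well=well, row=0, col=0,
                             role=role, compound_id=cmpd, concentration_uM=conc,
                             tech_block=block, cell_id=i, **{feature: v}))
    return pd.DataFrame(rows)


# --- Eq. 1 robust z ---------------------------------------------------------

def test_robust_z_direct_example():
    """Controls {1..5}: median 3, MAD 1, so x = 3 + 1.4826 gives z = 1."""
    table = _cells({
        ("P1", "A01", "solvent_control", "", 0.0, 1, 1): [1, 2, 3, 4, 5],
        ("P1", "B01", "compound", "C01", 1.0, 1, 1): [4.4826, 3.0],
    })
    z = robust_z_cells(table)
    f = "Mito_cytoplasm_intensity_mean"
    treated = z[z.role == "compound"][f].to_numpy()
    assert treated[0] == pytest.approx(1.0, abs=1e-12)
    assert treated[1] == pytest.approx(0.0, abs=1e-12)


def test_robust_z_matches_brute_force_on_random_tables():
    rng = np.random.default_rng(0)
    vals_ctrl = rng.normal(50, 5, 40)
    vals_trt = rng.normal(60, 5, 25)
    table = _cells({
        ("P1", "A01", "solvent_control", "", 0.0, 1, 1): vals_ctrl,
        ("P1", "B01", "compound", "C01", 1.0, 1, 1): vals_trt,
    })
    z = robust_z_cells(table)
    f = "Mito_cytoplasm_intensity_mean"
    med = np.median(vals_ctrl)
    sigma = np.median(np.abs(vals_ctrl - med))
    expected = (vals_trt - med) / (1.4826 * sigma)
    got = z[z.role == "compound"][f].to_numpy()
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_zero_mad_features_removed():
    table = _cells({
        ("P1", "A01", "solvent_control", "", 0.0, 1, 1): [5, 5, 5, 5],
        ("P1", "B01", "compound", "C01", 1.0, 1, 1): [7, 8],
    })
    z = robust_z_cells(table)
    assert "Mito_cytoplasm_intensity_mean" not in z.columns


def test_plate_without_controls_errors():
    table = _cells({("P1", "B01", "compound", "C01", 1.0, 1, 1): [1, 2]})
    with pytest.raises(ValueError, match="control"):
        robust_z_cells(table)


def test_single_scaling_no_double_constant():
    """Guard against applying 1.4826 twice: z of ctrl q75-ish value stays put."""
    ctrl = np.array([0., 1., 2., 3., 4.])  # median 2, MAD 1
    z = robust_z(np.array([2 + 1.4826]), 2.0, 1.0)
    assert z[0] == pytest.approx(1.0)


@given(st.floats(min_value=0.1, max_value=100.0),
       st.floats(min_value=-50.0, max_value=50.0))
@settings(max_examples=50, deadline=None)
def test_scale_shift_equivariance(scale, shift):
    """Scaling raw values by c > 0 (and shifting both) leaves z unchanged."""
    rng = np.random.default_rng(42)
    ctrl = rng.normal(10, 2, 50)
    x = rng.normal(12, 2, 20)
    z0 = robust_z(x, np.median(ctrl), mad(ctrl))
    ctrl2, x2 = ctrl * scale + shift, x * scale + shift
    z1 = robust_z(x2, np.median(ctrl2), mad(ctrl2))
    np.testing.assert_allclose(z0, z1, atol=1e-8)


def test_control_self_consistency(small_screen):
    """Pooled control cells' own z-scores have 1.4826*MAD within 5% of 1."""
    z = robust_z_cells(small_screen)
    ctrl = z[z.role == "solvent_control"]
    f = "Mito_cytoplasm_intensity_mean"
    assert len(ctrl) >= 500
    plate = ctrl[ctrl.plate_id == ctrl.plate_id.iloc[0]]
    assert abs(np.median(plate[f])) < 0.05
    assert abs(ROBUST_Z_CONSTANT * mad(plate[f].to_numpy()) - 1.0) < 0.05


def test_control_well_medians_near_zero(small_wells):
    ctrl = small_wells[small_wells.role == "solvent_control"]
    assert len(ctrl) >= 16
    med = ctrl["Mito_cytoplasm_intensity_mean"].median()
    assert abs(med) < 0.2


# --- well aggregation -------------------------------------------------------

def test_aggregate_matches_brute_force():
    rng = np.random.default_rng(1)
    table = _cells({
        ("P1", "A01", "solvent_control", "", 0.0, 1, 1): rng.normal(size=11),
        ("P1", "B01", "compound", "C01", 1.0, 1, 1): rng.normal(size=7),
        ("P1", "B02", "compound", "C01", 3.0, 2, 1): rng.normal(size=8),
    })
    wells = aggregate_to_wells(table)
    f = "Mito_cytoplasm_intensity_mean"
    for well in ("A01", "B01", "B02"):
        expected = np.median(table[table.well == well][f])
        assert wells[wells.well == well][f].iloc[0] == pytest.approx(expected)
    assert wells[wells.well == "B01"]["n_cells"].iloc[0] == 7


# --- population features ----------------------------------------------------

def test_nucleoli_binning():
    assert nucleoli_fractions(np.array([1, 2, 3, 5, 6])) == (0.4, 0.2, 0.4)


def test_population_standardization_forms():
    rows = []
    for i, (well, role, count) in enumerate([
            ("A01", "solvent_control", 100), ("A02", "solvent_control", 110),
            ("A03", "solvent_control", 90), ("B01", "compound", 50)]):
        rows.append(dict(plate_id="P1", biol_rep=1, well=well, role=role,
                         compound_id="" if role != "compound" else "C01",
                         concentration_uM=0.0, tech_block=1,
                         AbsoluteCellNumber=float(count),
                         RelativeCellNumber_1_2_Nucleoli=[0.5, 0.6, 0.4, 0.3][i]))
    table = pd.DataFrame(rows)
    z = standardize_population_features(table)
    ctrl_counts = np.array([100.0, 110, 90])
    med, s = np.median(ctrl_counts), mad(ctrl_counts)
    expected = (50 - med) / (1.4826 * s)
    assert z[z.role == "compound"]["AbsoluteCellNumber"].iloc[0] == pytest.approx(expected)
    frac = np.array([0.5, 0.6, 0.4])
    expected_plain = (0.3 - frac.mean()) / frac.std(ddof=1)
    assert z[z.role == "compound"]["RelativeCellNumber_1_2_Nucleoli"].iloc[0] == pytest.approx(expected_plain)


def test_population_robust_z_unit_step():
    """AbsoluteCellNumber at ctrl median + 1.4826*MAD standardizes to 1."""
    ctrl = np.array([100.0, 110, 90, 95, 105])
    med, s = np.median(ctrl), mad(ctrl)
    rows = [dict(plate_id="P1", biol_rep=1, well=f"A{i:02d}", role="solvent_control",
                 compound_id="", concentration_uM=0.0, tech_block=1,
                 AbsoluteCellNumber=c) for i, c in enumerate(ctrl, 1)]
    rows.append(dict(plate_id="P1", biol_rep=1, well="B01", role="compound",
                     compound_id="C01", concentration_uM=1.0, tech_block=1,
                     AbsoluteCellNumber=med + 1.4826 * s))
    z = standardize_population_features(pd.DataFrame(rows))
    assert z[z.role == "compound"]["AbsoluteCellNumber"].iloc[0] == pytest.approx(1.0)


# --- cytotoxicity -----------------------------------------------------------

def _well_counts(percent_cases):
    rows = []
    for i in range(8):
        rows.append(dict(plate_id="P1", biol_rep=1, well=f"A{i:02d}",
                         role="solvent_control", compound_id="",
                         concentration_uM=0.0, tech_block=1, n_cells=1000))
    for j, pct in enumerate(percent_cases):
        rows.append(dict(plate_id="P1", biol_rep=1, well=f"B{j:02d}",
                         role="compound", compound_id=f"C{j:02d}",
                         concentration_uM=10.0, tech_block=1, n_cells=int(round(pct * 10))))
    return pd.DataFrame(rows)


@pytest.mark.parametrize("pct,expected", [
    (52.9, True),   # below 53 -> cytotoxic
    (53.0, False),  # boundary: strictly "below"
    (100.0, False),
])
def test_cytotoxicity_boundary_strictly_below_53(pct, expected):
    flagged = flag_cytotoxic(_well_counts([pct]))
    row = flagged[flagged.role == "compound"].iloc[0]
    assert row["PercentCells"] == pytest.approx(pct)
    assert bool(row["cytotoxic"]) is expected


def test_cytotoxicity_grid_probe():
    grid = np.arange(45.0, 61.0, 1.0)
    flagged = flag_cytotoxic(_well_counts(list(grid)))
    got = flagged[flagged.role == "compound"].sort_values("compound_id")
    for pct, flag in zip(grid, got["cytotoxic"]):
        assert bool(flag) is bool(pct < 53.0)


def test_zero_control_count_errors():
    df = _well_counts([80.0])
    df.loc[df.role == "solvent_control", "n_cells"] = 0
    with pytest.raises(ValueError, match="control"):
        flag_cytotoxic(df)


# --- replicate aggregation and variability ----------------------------------

def _two_well_table(z_values=(1.0, 3.0)):
    rows = []
    for i, z in enumerate(z_values):
        rows.append(dict(plate_id=f"P{i+1}", biol_rep=i + 1, well="B01",
                         role="compound", compound_id="C01", concentration_uM=1.0,
                         tech_block=1, f1=z))
    return pd.DataFrame(rows)


def test_variability_worked_example():
    """Two wells with z = {1, 3}: Diffs +/-1, SumDiff 2, SumResp 4, RelSumDiff 0.5."""
    rep = variability_report(_two_well_table(), features=["f1"])
    diffs = sorted(rep.diffs["f1"].tolist())
    assert diffs == [-1.0, 1.0]
    row = rep.summary[rep.summary.level == "AllRep"].iloc[0]
    assert row.SumDiff == pytest.approx(2.0)
    assert row.SumResp == pytest.approx(4.0)
    assert row.RelSumDiff == pytest.approx(0.5)


def test_identical_replicates_zero_sumdiff():
    rep = variability_report(_two_well_table((2.0, 2.0)), features=["f1"])
    row = rep.summary[rep.summary.level == "AllRep"].iloc[0]
    assert row.SumDiff == 0.0
    assert row.RelSumDiff == 0.0


def test_relsumdiff_scale_invariant():
    base = variability_report(_two_well_table((1.0, 3.0)), features=["f1"])
    scaled = variability_report(_two_well_table((5.0, 15.0)), features=["f1"])
    a = base.summary[base.summary.level == "AllRep"].iloc[0]
    b = scaled.summary[scaled.summary.level == "AllRep"].iloc[0]
    assert b.SumDiff == pytest.approx(5 * a.SumDiff)
    assert b.RelSumDiff == pytest.approx(a.RelSumDiff)


def test_variability_matches_brute_force_on_random_table(small_wells):
    feats = ["Mito_cytoplasm_intensity_mean", "Lyso_cytoplasm_intensity_mean"]
    rep = variability_report(small_wells, features=feats)
    cmpd = small_wells[small_wells.role != "solvent_control"]
    med = cmpd.groupby(["compound_id", "concentration_uM"])[feats].transform("median")
    diffs = cmpd[feats] - med
    assert rep.summary.loc[rep.summary.level == "AllRep", "SumDiff"].iloc[0] == \
        pytest.approx(np.abs(diffs.to_numpy()).sum())
    assert rep.summary.loc[rep.summary.level == "AllRep", "SumResp"].iloc[0] == \
        pytest.approx(np.abs(cmpd[feats].to_numpy()).sum())
    # per-technical-block brute force
    for block in (1, 2, 3):
        sub = diffs[cmpd.tech_block == block]
        got = rep.summary[(rep.summary.level == "TRep")
                          & (rep.summary.tech_block == block)].iloc[0]
        assert got.SumDiff == pytest.approx(np.abs(sub.to_numpy()).sum())


def test_aggregate_replicates_levels(small_wells):
    feats = ["Mito_cytoplasm_intensity_mean"]
    allrep = aggregate_replicates(small_wells, "AllRep", feats)
    brute = (small_wells[small_wells.role != "solvent_control"]
             .groupby(["compound_id", "concentration_uM"])[feats].median().reset_index())
    merged = allrep.merge(brute, on=["compound_id", "concentration_uM"],
                          suffixes=("_got", "_want"))
    np.testing.assert_allclose(merged[feats[0] + "_got"], merged[feats[0] + "_want"])
    trep = aggregate_replicates(small_wells, "TRep", feats)
    assert set(trep.tech_block.unique()) == {1, 2, 3}
    with pytest.raises(ValueError):
        aggregate_replicates(small_wells, "XRep", feats)


def test_aggregate_replicates_median_example():
    rows = [dict(plate_id="P1", biol_rep=r, well=f"B0{r}", role="compound",
                 compound_id="C01", concentration_uM=1.0, tech_block=1, f1=v)
            for r, v in enumerate([1.0, 2.0, 9.0], start=1)]
    out = aggregate_replicates(pd.DataFrame(rows), "AllRep", ["f1"])
    assert out["f1"].iloc[0] == 2.0


# --- replicate correlation --------------------------------------------------

def test_replicate_correlation_identical_and_flipped(small_wells):
    feats = [c for c in ("Mito_cytoplasm_intensity_mean",
                         "Lyso_cytoplasm_intensity_mean")]
    mat = replicate_correlation(small_wells, "BRep", feats)
    assert np.allclose(np.diag(mat), 1.0)
    assert ((mat.to_numpy() >= -1 - 1e-9) & (mat.to_numpy() <= 1 + 1e-9)).all()
    # duplicated replicate gives r = 1; sign-flipped gives r = -1
    dup = small_wells.copy()
    clone = dup[dup.biol_rep == 1].copy()
    clone["biol_rep"] = 4
    flipped = dup[dup.biol_rep == 1].copy()
    flipped["biol_rep"] = 5
    flipped[feats] = -flipped[feats]
    aug = pd.concat([dup, clone, flipped], ignore_index=True)
    mat2 = replicate_correlation(aug, "BRep", feats)
    assert mat2.loc[1, 4] == pytest.approx(1.0)
    assert mat2.loc[1, 5] == pytest.approx(-1.0)


def test_replicate_correlation_matches_numpy(small_wells):
    feats = ["Mito_cytoplasm_intensity_mean"]
    df = small_wells[(small_wells.role != "solvent_control") & (~small_wells.cytotoxic)]
    prof = df.groupby(["biol_rep", "compound_id", "concentration_uM"])[feats].median()
    mat = replicate_correlation(small_wells, "BRep", feats)
    a = prof.xs(1).to_numpy().ravel()
    b = prof.xs(2).to_numpy().ravel()
    assert mat.loc[1, 2] == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)
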