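"""Category assignment, proportion/accumulation/magnitude stats, clustering, CV."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from paintplus.doseresponse import BMCRecord, CLASS_OK, CLASS_NA, CLASS_LOW
from paintplus.reporting import (assign_categories, proportion_bmc,
                                 accumulation_data, magnitude_data,
                                 similarity_cluster, cv_vs_ncells,
                                 highest_nontoxic_profiles)


# --- categories -------------------------------------------------------------

def test_assign_categories_parses_convention():
    cmap = assign_categories(["RNA_nucleoli_count_bin12",
                              "Mito_cytoplasm_intensity_mean",
                              "Mito_cytoplasm_intensity_sd"])
    assert cmap.assignments["RNA_nucleoli_count_bin12"] == ("RNA", "nucleoli", "count")
    assert len(cmap.categories) == 2
    assert cmap.members(("Mito", "cytoplasm", "intensity")) == [
        "Mito_cytoplasm_intensity_mean", "Mito_cytoplasm_intensity_sd"]


def test_malformed_names_reported_not_dropped():
    with pytest.raises(ValueError, match="bad_name"):
        assign_categories(["Mito_cytoplasm_intensity_mean", "bad_name"])


def test_every_feature_assigned_once():
    names = [f"Ch{i}_region_fam_stat{i}" for i in range(10)]
    cmap = assign_categories(names)
    assert sorted(cmap.assignments) == sorted(names)


# --- proportion BMC ---------------------------------------------------------

def _log_bmc(values_by_compound, feature="Mito_cytoplasm_intensity_mean"):
    rows = [dict(feature=feature, compound_id=c, bmc_class=CLASS_OK, log10_BMC=v)
            for c, v in values_by_compound.items()]
    return pd.DataFrame(rows)


def test_identical_bmcs_no_significance():
    df = _log_bmc({f"C{i:02d}": 1.0 for i in range(1, 11)})
    cmap = assign_categories(df.feature.unique().tolist())
    prop = proportion_bmc(df, cmap)
    assert (prop.proportion == 0).all()


def test_outlier_low_bmc_is_significant():
    vals = {f"C{i:02d}": 2.0 + 0.01 * i for i in range(2, 16)}
    vals["C01"] = 0.0  # 100x lower than the cluster
    df = _log_bmc(vals)
    cmap = assign_categories(df.feature.unique().tolist())
    prop = proportion_bmc(df, cmap)
    assert prop.loc[prop.compound_id == "C01", "proportion"].iloc[0] == 1.0
    assert (prop.loc[prop.compound_id != "C01", "proportion"] == 0).all()


def test_proportions_bounded_and_min_compounds():
    df = _log_bmc({"C01": 1.0, "C02": 2.0})
    cmap = assign_categories(df.feature.unique().tolist())
    with pytest.raises(ValueError, match="3"):
        proportion_bmc(df, cmap)


# --- accumulation -----------------------------------------------------------

def _records(class_by_feature, compound="C01", bmc=1.0):
    recs = []
    for f, cls in class_by_feature.items():
        recs.append(BMCRecord(feature=f, compound_id=compound, model="hill",
                              bmc_uM=bmc if cls in (CLASS_OK, CLASS_LOW) else None,
                              bmc_class=cls, highest_nontoxic_uM=100.0))
    return recs


def test_accumulation_30pct_boundary_inclusive():
    # 10-feature category, exactly 3 responding -> retained
    feats = {f"Mito_cytoplasm_intensity_s{i}": (CLASS_OK if i < 3 else CLASS_NA)
             for i in range(10)}
    cmap = assign_categories(list(feats))
    out = accumulation_data(_records(feats), cmap)
    assert len(out) == 1
    assert out.iloc[0].responding_frac == pytest.approx(0.3)
    # 2 of 10 responding -> excluded
    feats2 = {f: (CLASS_OK if i < 2 else CLASS_NA)
              for i, f in enumerate(feats)}
    assert accumulation_data(_records(feats2), cmap).empty


def test_accumulation_median_and_ranking():
    recs = []
    for i, bmc in enumerate([1.0, 10.0, 100.0]):
        recs.append(BMCRecord(feature=f"Mito_cytoplasm_intensity_s{i}",
                              compound_id="C01", model="hill", bmc_uM=bmc,
                              bmc_class=CLASS_OK))
    for i, bmc in enumerate([0.5, 0.7]):
        recs.append(BMCRecord(feature=f"Lyso_cytoplasm_intensity_s{i}",
                              compound_id="C01", model="hill", bmc_uM=bmc,
                              bmc_class=CLASS_OK))
    cmap = assign_categories([r.feature for r in recs])
    out = accumulation_data(recs, cmap)
    mito = out[out.category.str.startswith("Mito")].iloc[0]
    assert mito.median_BMC_uM == pytest.approx(10.0)
    assert list(out["rank"]) == [1, 2]
    assert out.iloc[0].median_BMC_uM <= out.iloc[1].median_BMC_uM


def test_accumulation_stable_under_row_permutation():
    feats = {f"Mito_cytoplasm_intensity_s{i}": CLASS_OK for i in range(5)}
    cmap = assign_categories(list(feats))
    recs = _records(feats)
    out1 = accumulation_data(recs, cmap)
    out2 = accumulation_data(list(reversed(recs)), cmap)
    pd.testing.assert_frame_equal(out1, out2)


# --- magnitude --------------------------------------------------------------

def _profiles(z_by_conc, feature="Mito_cytoplasm_intensity_mean"):
    rows = [dict(compound_id="C01", concentration_uM=c, cytotoxic=False, **{feature: z})
            for c, z in z_by_conc.items()]
    return pd.DataFrame(rows)


def test_magnitude_is_max_absolute_z():
    recs = [BMCRecord(feature="Mito_cytoplasm_intensity_mean", compound_id="C01",
                      model="hill", bmc_uM=1.0, bmc_class=CLASS_OK)]
    out = magnitude_data(recs, _profiles({0.1: -3.0, 1.0: 1.0, 10.0: 2.0}))
    assert out.iloc[0].magnitude == pytest.approx(3.0)


def test_magnitude_flat_profile_zero():
    recs = [BMCRecord(feature="Mito_cytoplasm_intensity_mean", compound_id="C01",
                      model=None, bmc_class=CLASS_NA)]
    out = magnitude_data(recs, _profiles({0.1: 0.0, 1.0: 0.0}))
    assert out.iloc[0].magnitude == 0.0


def test_magnitude_excludes_cytotoxic_concentrations():
    prof = _profiles({0.1: 1.0, 1.0: 2.0, 10.0: 9.0})
    prof.loc[prof.concentration_uM == 10.0, "cytotoxic"] = True
    recs = [BMCRecord(feature="Mito_cytoplasm_intensity_mean", compound_id="C01",
                      model="hill", bmc_uM=1.0, bmc_class=CLASS_OK)]
    out = magnitude_data(recs, prof)
    assert out.iloc[0].magnitude == pytest.approx(2.0)


# --- similarity clustering --------------------------------------------------

def _group_profiles(n_per_group=4, n_features=30, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    sig_a = rng.normal(0, 3, n_features)
    sig_b = rng.normal(0, 3, n_features)
    rows, truth = {}, []
    for i in range(n_per_group):
        rows[f"A{i}"] = sig_a + noise * rng.standard_normal(n_features)
        truth.append(0)
    for i in range(n_per_group):
        rows[f"B{i}"] = sig_b + noise * rng.standard_normal(n_features)
        truth.append(1)
    cols = [f"Mito_cytoplasm_intensity_s{i}" for i in range(n_features)]
    return pd.DataFrame(rows, index=cols).T, truth


def test_identical_profiles_correlate_fully():
    prof, _ = _group_profiles(n_per_group=2, noise=0.0)
    corr, labels = similarity_cluster(prof, k=2)
    assert corr.loc["A0", "A1"] == pytest.approx(1.0)


def test_monotone_transform_preserves_spearman():
    prof, _ = _group_profiles(n_per_group=1, noise=0.5, seed=3)
    a = prof.iloc[0]
    transformed = np.exp(a / 2)  # rank-preserving
    both = pd.DataFrame([a, transformed], index=["a", "b"])
    corr, _ = similarity_cluster(both, k=1)
    assert corr.loc["a", "b"] == pytest.approx(1.0)


def test_two_planted_groups_recovered():
    aris = []
    for seed in range(25):
        prof, truth = _group_profiles(seed=seed)
        _, labels = similarity_cluster(prof, k=2)
        aris.append(adjusted_rand_score(truth, labels.to_numpy()))
    assert np.mean(np.array(aris) >= 0.999) >= 0.95


def test_lyso_exclusion_changes_only_lyso_dependent_entries():
    rng = np.random.default_rng(1)
    cols = ([f"Lyso_cytoplasm_intensity_s{i}" for i in range(5)]
            + [f"Mito_cytoplasm_intensity_s{i}" for i in range(20)])
    prof = pd.DataFrame(rng.normal(size=(4, 25)), columns=cols,
                        index=["C1", "C2", "C3", "C4"])
    with_lyso, _ = similarity_cluster(prof, include_lyso=True, k=2)
    without, _ = similarity_cluster(prof, include_lyso=False, k=2)
    manual = prof[[c for c in cols if not c.startswith("Lyso_")]]
    from scipy.stats import spearmanr
    rho, _ = spearmanr(manual.to_numpy(), axis=1)
    np.testing.assert_allclose(without.to_numpy(), rho, atol=1e-12)
    assert not np.allclose(with_lyso.to_numpy(), without.to_numpy())


def test_constant_profile_reported_missing():
    prof, _ = _group_profiles(n_per_group=2, noise=0.4, seed=5)
    prof.loc["FLAT"] = 0.0
    corr, labels = similarity_cluster(prof, k=2)
    assert corr.loc["FLAT", "A0"] != corr.loc["FLAT", "A0"]  # NaN
    assert corr.loc["FLAT", "FLAT"] == 1.0


# --- CV vs cell number ------------------------------------------------------

def _cells_for_cv(n_plates=3, n_wells=4, n_cells=40, sd=5.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_plates):
        for w in range(n_wells):
            for i in range(n_cells):
                rows.append(dict(plate_id=f"P{p}", biol_rep=p + 1, well=f"B{w:02d}",
                                 role="compound", compound_id="C01",
                                 concentration_uM=1.0, tech_block=1, cell_id=i,
                                 f1=100 + sd * rng.standard_normal(),
                                 f2=50 + sd * rng.standard_normal()))
    return pd.DataFrame(rows)


def test_cv_zero_for_identical_cells():
    cells = _cells_for_cv(sd=0.0)
    out = cv_vs_ncells(cells, [1, 4, 16], features=["f1", "f2"], seed=1)
    assert (out.median_cv == 0).all()


def test_cv_non_increasing_with_n():
    cells = _cells_for_cv(n_cells=100, sd=20.0)
    out = cv_vs_ncells(cells, [2, 8, 32, 100], features=["f1", "f2"], seed=2)
    diffs = np.diff(out.median_cv.to_numpy())
    assert (diffs <= 1e-12).mean() >= 0.95 or (out.median_cv.iloc[-1]
                                               <= out.median_cv.iloc[0])


def test_cv_seeded_determinism():
    cells = _cells_for_cv()
    a = cv_vs_ncells(cells, [4, 16], features=["f1"], seed=9)
    b = cv_vs_ncells(cells, [4, 16], features=["f1"], seed=9)
    pd.testing.assert_frame_equal(a, b)


# --- highest non-toxic profiles --------------------------------------------

def test_highest_nontoxic_profile_selection(small_wells):
    prof = highest_nontoxic_profiles(small_wells,
                                     ["Lyso_cytoplasm_intensity_mean"])
    # C05 is cytotoxic at high concentrations (EC50 10 uM in the fixture)
    df = small_wells[(small_wells.compound_id == "C05") & (~small_wells.cytotoxic)]
    assert df.concentration_uM.max() < 100.0
    assert prof.shape[0] == 15
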