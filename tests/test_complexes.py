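"""OXPHOS annotation validation and complex/module/category summaries."""

import numpy as np
import pandas as pd
import pytest

from mitopulse.complexes import (
    CATEGORY_MT_OXPHOS,
    CATEGORY_NUC_MITO,
    CATEGORY_NUC_NONMITO,
    CATEGORY_NUC_OXPHOS,
    EXPECTED_COMPLEX_TOTALS,
    assign_categories,
    category_correlation,
    load_annotation,
    summarize_by_category,
    summarize_by_module,
)
from mitopulse.quant import quantify_psilac
from mitopulse.simulate import default_psilac_scenario


@pytest.fixture(scope="module")
def annotation():
    return load_annotation()


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

def test_packaged_annotation_totals(annotation):
    assert (annotation.encoding == "mitochondrial").sum() == 13
    totals = annotation[annotation["complex"] != "none"].groupby("complex").size()
    assert totals.to_dict() == EXPECTED_COMPLEX_TOTALS


def test_packaged_ci_has_seven_modules(annotation):
    ci_modules = set(annotation.loc[annotation["complex"] == "CI", "module"]) - {""}
    assert len(ci_modules) == 7


def test_mitochondrial_entries_use_accessions(annotation):
    mito = annotation[annotation.encoding == "mitochondrial"]
    assert mito.protein_id.str.fullmatch(r"P\d{5}").all()
    assert "P03901" in set(mito.protein_id)  # MT-ND4L


# ---------------------------------------------------------------------------
# validation of user-supplied tables
# ---------------------------------------------------------------------------

def _write(tmp_path, frame):
    path = tmp_path / "ann.tsv"
    frame.to_csv(path, sep="\t", index=False)
    return str(path)


def _valid_frame():
    return pd.DataFrame(
        {
            "protein_id": ["A", "B"],
            "gene": ["A", "B"],
            "encoding": ["nuclear", "mitochondrial"],
            "complex": ["CI", "CI"],
            "module": ["N module", "ND1 module"],
        }
    )


def test_duplicate_protein_rejected(tmp_path):
    frame = _valid_frame()
    frame.loc[1, "protein_id"] = "A"
    with pytest.raises(ValueError, match="'A'"):
        load_annotation(_write(tmp_path, frame))


def test_unknown_complex_rejected_with_row(tmp_path):
    frame = _valid_frame()
    frame.loc[1, "complex"] = "CVI"
    with pytest.raises(ValueError, match="CVI"):
        load_annotation(_write(tmp_path, frame))


def test_module_in_two_complexes_rejected(tmp_path):
    frame = _valid_frame()
    frame.loc[1, "complex"] = "CIII"
    frame.loc[1, "module"] = "N module"  # same label as the CI row
    with pytest.raises(ValueError, match="multiple complexes"):
        load_annotation(_write(tmp_path, frame))


def test_user_table_total_mismatch_is_warning(tmp_path):
    with pytest.warns(UserWarning, match="totals differ"):
        ann = load_annotation(_write(tmp_path, _valid_frame()))
    assert len(ann) == 2


# ---------------------------------------------------------------------------
# categories
# ---------------------------------------------------------------------------

def _category_annotation():
    return pd.DataFrame(
        {
            "protein_id": ["mt1", "nucox1", "nucmito1", "cyto1"],
            "gene": ["g1", "g2", "g3", "g4"],
            "encoding": ["mitochondrial", "nuclear", "nuclear", "nuclear"],
            "complex": ["CIV", "CIV", "none", "none"],
            "module": ["", "", "", ""],
            "localization": ["mito", "mito", "mito", "non-mito"],
        }
    )


def test_category_assignment_is_a_partition():
    ann = _category_annotation()
    cats = assign_categories(ann.protein_id, ann)
    assert list(cats) == [
        CATEGORY_MT_OXPHOS,
        CATEGORY_NUC_OXPHOS,
        CATEGORY_NUC_MITO,
        CATEGORY_NUC_NONMITO,
    ]
    unknown = assign_categories(["ghost"], ann)
    assert list(unknown) == ["unannotated"]
    assert list(assign_categories(["ghost"], ann, unannotated_as_nonmito=True)) == [
        CATEGORY_NUC_NONMITO
    ]


def test_summarize_by_category_orders_planted_effects():
    scenario = default_psilac_scenario(23, n_proteins=120, n_mt=10, n_orphans=0)
    results = quantify_psilac(scenario.generate(), {"r1": "H", "r2": "M"})
    summary = summarize_by_category(results, scenario.annotation_table())
    medians = summary.set_index("category").median_log2_fc
    assert medians[CATEGORY_MT_OXPHOS] < medians[CATEGORY_NUC_NONMITO] - 0.5
    with pytest.raises(ValueError):
        summarize_by_category(results.iloc[:0], scenario.annotation_table())


def test_summarize_single_category():
    ann = _category_annotation()
    results = pd.DataFrame({"protein_id": ["cyto1"], "mean_log2_fc": [0.3]})
    summary = summarize_by_category(results, ann)
    assert list(summary.category) == [CATEGORY_NUC_NONMITO]
    assert summary.n.iloc[0] == 1


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def test_module_summary_basics(annotation):
    # one quantified protein per module: median equals that value
    ciii = annotation[(annotation["complex"] == "CIII") & (annotation.module != "")]
    one_per_module = ciii.groupby("module").head(1)
    results = pd.DataFrame(
        {
            "protein_id": one_per_module.protein_id.to_numpy(),
            "mean_log2_fc": np.arange(len(one_per_module), dtype=float),
        }
    )
    summary = summarize_by_module(results, annotation, "CIII")
    expected = dict(zip(one_per_module.module, results.mean_log2_fc))
    for _, row in summary.iterrows():
        assert row.n_quantified == 1
        assert row.median_log2_fc == expected[row.module]
    with pytest.raises(ValueError, match="CVII"):
        summarize_by_module(results, annotation, "CVII")


def test_module_summary_reports_empty_modules_and_row_order_invariance(annotation):
    results = pd.DataFrame(
        {"protein_id": ["UQCRB", "UQCRQ"], "mean_log2_fc": [-1.0, -0.6]}
    )
    summary = summarize_by_module(results, annotation, "CIII")
    sub3 = summary[summary.module == "CIII subcomplex 3"].iloc[0]
    assert sub3.n_quantified == 0 and np.isnan(sub3.median_log2_fc)
    shuffled = summarize_by_module(results.iloc[::-1], annotation, "CIII")
    pd.testing.assert_frame_equal(summary, shuffled)


def test_module_summary_detects_planted_subcomplex_effect(annotation):
    """CIII subcomplex-1 nuclear subunits planted low vs the rest."""
    rng = np.random.default_rng(5)
    ciii = annotation[annotation["complex"] == "CIII"]
    values = {}
    for _, row in ciii.iterrows():
        low = row.module == "CIII subcomplex 1" and row.encoding == "nuclear"
        values[row.protein_id] = rng.normal(-1.2 if low else 0.0, 0.1)
    results = pd.DataFrame(
        {"protein_id": list(values), "mean_log2_fc": list(values.values())}
    )
    summary = summarize_by_module(results, annotation, "CIII").set_index("module")
    assert (
        summary.loc["CIII subcomplex 1", "median_log2_fc"]
        < summary.loc["CIII subcomplex 2", "median_log2_fc"] - 0.5
    )
    assert summary.loc["CIII subcomplex 1", "n_mito"] == 1


# ---------------------------------------------------------------------------
# cross-experiment correlation
# ---------------------------------------------------------------------------

def test_category_correlation_identity_and_sign(annotation):
    rng = np.random.default_rng(11)
    ids = annotation.protein_id.to_numpy()
    a = pd.DataFrame({"protein_id": ids, "mean_log2_fc": rng.normal(size=len(ids))})
    b = a.copy()
    out = category_correlation(a, b, annotation)
    assert np.allclose(out.pearson_r, 1.0)
    b_neg = a.copy()
    b_neg["mean_log2_fc"] = -b_neg["mean_log2_fc"]
    out_neg = category_correlation(a, b_neg, annotation)
    assert np.allclose(out_neg.pearson_r, -1.0)


def test_planted_effects_drive_cross_experiment_correlation():
    import dataclasses

    sc1 = default_psilac_scenario(41, n_proteins=150, n_mt=13, n_orphans=20)
    # independent repeat of the same ground truth with fresh noise
    sc2 = dataclasses.replace(sc1, noise=dataclasses.replace(sc1.noise, seed=4242))
    res1 = quantify_psilac(sc1.generate(), {"r1": "H", "r2": "M"})
    res2 = quantify_psilac(sc2.generate(), {"r1": "H", "r2": "M"})
    ann = sc1.annotation_table()
    # orphans are nuclear mito proteins in the scenario annotation; MT are OXPHOS
    out = category_correlation(res1, res2, ann).set_index("category")
    assert out.loc[CATEGORY_NUC_MITO, "pearson_r"] > out.loc[CATEGORY_NUC_NONMITO, "pearson_r"]


def test_small_categories_skipped_with_warning(annotation):
    ids = ["P03901", "P00156"]  # two shared proteins only
    a = pd.DataFrame({"protein_id": ids, "mean_log2_fc": [0.1, 0.2]})
    with pytest.warns(UserWarning, match="skipped"):
        out = category_correlation(a, a, annotation)
    assert out.empty
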