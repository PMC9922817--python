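"""OXPHOS complex/module annotation and per-group fold-change summaries.

The five OXPHOS complexes (CI-CV) are assembled from 13 mitochondrially
encoded subunits plus nuclear-encoded partners; assembly proceeds through
subcomplex intermediates ("modules"). Summaries at complex, module and
category granularity let the drug response of nuclear subunits be read
against the modules they share with mitochondrially encoded subunits.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["protein_id", "gene", "encoding", "complex", "module"]
VALID_COMPLEX_LABELS = {"CI", "CII", "CIII", "CIV", "CV", "none"}

#: expected subunit totals of the packaged reference annotation
EXPECTED_COMPLEX_TOTALS = {"CI": 45, "CII": 4, "CIII": 11, "CIV": 21, "CV": 17}
EXPECTED_N_MITOCHONDRIAL = 13

CATEGORY_MT_OXPHOS = "MT-encoded OXPHOS"
CATEGORY_NUC_OXPHOS = "nuclear OXPHOS"
CATEGORY_NUC_MITO = "nuclear mito"
CATEGORY_NUC_NONMITO = "nuclear non-mito"
CATEGORY_UNANNOTATED = "unannotated"


def packaged_annotation_path():
    return resources.files("mitopulse.data") / "oxphos_annotation.tsv"


def load_annotation(path: Optional[str] = None, strict_totals: bool = False) -> pd.DataFrame:
    """Load and validate an OXPHOS annotation table.

    Without a path, the packaged reference annotation is loaded. Validation
    rejects duplicate protein ids, unknown complex or encoding labels and
    module labels shared between complexes, reporting row numbers. A
    mismatch against the packaged complex totals is a warning for
    user-supplied tables (``strict_totals=False``) and an error otherwise.
    """
    if path is None:
        with resources.as_file(packaged_annotation_path()) as p:
            ann = pd.read_csv(p, sep="\t", comment="#", dtype=str)
        strict_totals = True
    else:
        ann = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation is missing column(s) {missing}")
    ann = ann.fillna({"module": ""})
    if "uncertain" in ann.columns:
        ann["uncertain"] = ann["uncertain"].fillna("0").astype(int)

    dupes = ann.loc[ann["protein_id"].duplicated(), "protein_id"].tolist()
    if dupes:
        raise ValueError(f"duplicate protein id(s) in annotation: {sorted(set(dupes))}")
    bad_complex = ann.loc[~ann["complex"].isin(VALID_COMPLEX_LABELS)]
    if not bad_complex.empty:
        rows = (bad_complex.index + 2).tolist()  # 1-based incl. header
        raise ValueError(
            f"unknown complex label(s) {sorted(bad_complex['complex'].unique())} at row(s) {rows}"
        )
    bad_enc = ann.loc[~ann["encoding"].isin(["mitochondrial", "nuclear"])]
    if not bad_enc.empty:
        raise ValueError(
            f"unknown encoding label(s) {sorted(bad_enc['encoding'].unique())}"
        )
    # every named module must belong to exactly one complex
    named = ann[ann["module"] != ""]
    module_complexes = named.groupby("module")["complex"].nunique()
    shared = module_complexes[module_complexes > 1].index.tolist()
    if shared:
        raise ValueError(f"module label(s) assigned to multiple complexes: {shared}")

    totals = ann[ann["complex"] != "none"].groupby("complex").size().to_dict()
    n_mito = int((ann["encoding"] == "mitochondrial").sum())
    mismatches = {
        c: (totals.get(c, 0), expected)
        for c, expected in EXPECTED_COMPLEX_TOTALS.items()
        if totals.get(c, 0) != expected
    }
    if n_mito != EXPECTED_N_MITOCHONDRIAL:
        mismatches["mitochondrial"] = (n_mito, EXPECTED_N_MITOCHONDRIAL)
    if mismatches:
        msg = f"annotation totals differ from the packaged reference: {mismatches}"
        if strict_totals:
            raise ValueError(msg)
        warnings.warn(msg)
    return ann


def assign_categories(
    protein_ids: Iterable[str],
    annotation: pd.DataFrame,
    unannotated_as_nonmito: bool = False,
) -> pd.Series:
    """Partition proteins into the four reporting categories.

    Categories: MT-encoded OXPHOS subunits; nuclear-encoded OXPHOS
    subunits; nuclear-encoded mitochondrial (non-OXPHOS) proteins; and
    nuclear-encoded non-mitochondrial proteins. Mitochondrial localization
    of non-OXPHOS proteins is taken from an optional ``localization``
    column (``mito`` / ``non-mito``). Proteins absent from the annotation
    fall in an ``unannotated`` bucket unless ``unannotated_as_nonmito``.
    """
    ann = annotation.set_index("protein_id")
    has_loc = "localization" in ann.columns

    def categorize(pid: str) -> str:
        if pid not in ann.index:
            return CATEGORY_NUC_NONMITO if unannotated_as_nonmito else CATEGORY_UNANNOTATED
        row = ann.loc[pid]
        if row["encoding"] == "mitochondrial":
            return CATEGORY_MT_OXPHOS
        if row["complex"] != "none":
            return CATEGORY_NUC_OXPHOS
        loc = row["localization"] if has_loc else ""
        if loc == "mito":
            return CATEGORY_NUC_MITO
        if loc == "non-mito":
            return CATEGORY_NUC_NONMITO
        return CATEGORY_NUC_NONMITO if unannotated_as_nonmito else CATEGORY_UNANNOTATED

    ids = list(protein_ids)
    return pd.Series([categorize(p) for p in ids], index=ids, name="category")


def _quartile_summary(values: np.ndarray) -> dict:
    return {
        "n": int(values.size),
        "median_log2_fc": float(np.median(values)) if values.size else np.nan,
        "q1_log2_fc": float(np.percentile(values, 25)) if values.size else np.nan,
        "q3_log2_fc": float(np.percentile(values, 75)) if values.size else np.nan,
    }


def summarize_by_category(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    unannotated_as_nonmito: bool = False,
) -> pd.DataFrame:
    """Fold-change summary per reporting category.

    ``results`` must carry ``protein_id`` and ``mean_log2_fc``. Categories
    with no quantified protein are omitted.
    """
    if results.empty:
        raise ValueError("empty results table")
    categories = assign_categories(
        results["protein_id"], annotation, unannotated_as_nonmito
    )
    merged = results.assign(category=categories.to_numpy())
    rows = []
    order = [
        CATEGORY_MT_OXPHOS,
        CATEGORY_NUC_OXPHOS,
        CATEGORY_NUC_MITO,
        CATEGORY_NUC_NONMITO,
        CATEGORY_UNANNOTATED,
    ]
    for cat in order:
        values = merged.loc[merged["category"] == cat, "mean_log2_fc"].dropna().to_numpy()
        if values.size == 0:
            continue
        rows.append({"category": cat, **_quartile_summary(values)})
    return pd.DataFrame(rows)


def summarize_by_module(
    results: pd.DataFrame, annotation: pd.DataFrame, complex_label: str
) -> pd.DataFrame:
    """Per-module fold-change summary for one OXPHOS complex.

    Modules with no quantified protein are reported with ``n = 0``. Output
    is ordered by module label and invariant to input row order.
    """
    if complex_label not in VALID_COMPLEX_LABELS - {"none"}:
        raise ValueError(f"unknown complex {complex_label!r}")
    sub = annotation[annotation["complex"] == complex_label]
    if sub.empty:
        raise ValueError(f"annotation has no proteins for {complex_label}")
    values = results.set_index("protein_id")["mean_log2_fc"]
    rows = []
    for module, members in sub[sub["module"] != ""].groupby("module"):
        quantified = members[members["protein_id"].isin(values.index)]
        vals = values.loc[quantified["protein_id"]].dropna()
        summary = _quartile_summary(vals.to_numpy())
        rows.append(
            {
                "complex": complex_label,
                "module": module,
                "n_quantified": summary.pop("n"),
                **summary,
                "n_mito": int((quantified["encoding"] == "mitochondrial").sum()),
                "n_nuclear": int((quantified["encoding"] == "nuclear").sum()),
            }
        )
    return pd.DataFrame(rows).sort_values("module", kind="mergesort").reset_index(drop=True)


def category_correlation(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    annotation: pd.DataFrame,
    unannotated_as_nonmito: bool = False,
) -> pd.DataFrame:
    """Per-category Pearson correlation of fold changes across two experiments.

    Mean log2 fold changes are paired over the proteins shared by both
    results tables; categories with fewer than 3 shared proteins are
    skipped with a warning.
    """
    a = results_a.set_index("protein_id")["mean_log2_fc"]
    b = results_b.set_index("protein_id")["mean_log2_fc"]
    shared = a.index.intersection(b.index)
    categories = assign_categories(shared, annotation, unannotated_as_nonmito)
    rows = []
    for cat, ids in categories.groupby(categories):
        pids = ids.index
        if len(pids) < 3:
            warnings.warn(f"category {cat!r} has only {len(pids)} shared proteins; skipped")
            continue
        x, y = a.loc[pids].to_numpy(), b.loc[pids].to_numpy()
        r, _ = stats.pearsonr(x, y)
        rows.append({"category": cat, "n": len(pids), "pearson_r": float(r)})
    return pd.DataFrame(rows)
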