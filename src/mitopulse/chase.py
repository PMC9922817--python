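"""Pulse-chase degradation analysis and drug-sensitivity classification.

In the pulse-chase design, newly synthesized protein is pulse-labeled heavy
(H) and then chased into medium (M) label with drug or vehicle. The H/L
ratio (new over pre-existing protein) falls when the new cohort is degraded
during the chase, so the **degradation score**

    log2( H/L under drug  /  H/L under vehicle )

is negative for proteins whose newly made molecules are destabilized by the
drug; the analogous **synthesis score** on M/L reads out the drug's direct
effect on synthesis during the chase window.

Proteins are classified from the separate pSILAC experiment's mean
log2 H/M: ``unchanged`` when >= -0.5 and ``CAP-sensitive`` when < -0.5
(boundary inclusive on the unchanged side). The group comparison asks, with
a one-sided Wilcoxon rank-sum test, whether drug-sensitive proteins' new
cohorts are less stable than unchanged ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

UNCHANGED = "unchanged"
CAP_SENSITIVE = "CAP-sensitive"
UNASSIGNED = "unassigned"

#: classification boundary on mean log2 H/M from the pSILAC experiment
CLASSIFICATION_THRESHOLD = -0.5

#: largest combined group size for which the exact rank-sum null is used
EXACT_WILCOXON_MAX_N = 12


def classify_cap_sensitivity(log2_hm: float) -> str:
    """Classify a protein by its pSILAC mean log2 H/M.

    ``>= -0.5`` is ``unchanged`` (boundary inclusive), ``< -0.5`` is
    ``CAP-sensitive``; a missing value is ``unassigned``.
    """
    if log2_hm is None or (isinstance(log2_hm, float) and math.isnan(log2_hm)):
        return UNASSIGNED
    if not math.isfinite(log2_hm):
        raise ValueError(f"log2 H/M must be finite, got {log2_hm}")
    return UNCHANGED if log2_hm >= CLASSIFICATION_THRESHOLD else CAP_SENSITIVE


def degradation_score(hl_cap: float, hl_dmso: float) -> float:
    """log2 of the drug-to-vehicle H/L ratio; negative = new cohort lost faster.

    Non-positive input ratios give NaN (missing score) rather than an error.
    """
    if hl_cap <= 0 or hl_dmso <= 0 or not (math.isfinite(hl_cap) and math.isfinite(hl_dmso)):
        return math.nan
    return math.log2(hl_cap / hl_dmso)


def synthesis_score(ml_cap: float, ml_dmso: float) -> float:
    """log2 of the drug-to-vehicle M/L ratio; negative = synthesis inhibited."""
    return degradation_score(ml_cap, ml_dmso)


def wilcoxon_one_sided(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "less",
) -> float:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``alternative='less'`` tests that group A values are stochastically
    smaller than group B. The exact null distribution is used when the
    combined sample size is at most 12 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def _condition_ratios(
    evidence: pd.DataFrame, condition: str, numerator: str, min_peptides: int = 1
) -> pd.Series:
    """Per-protein median log2(numerator/L) for one chase condition."""
    sub = evidence[evidence["condition"] == condition]
    num = pd.to_numeric(sub[f"intensity_{numerator}"], errors="coerce")
    den = pd.to_numeric(sub["intensity_L"], errors="coerce")
    ok = (num > 0) & (den > 0)
    frame = pd.DataFrame(
        {"protein_id": sub["protein_id"][ok], "log2_ratio": np.log2(num[ok] / den[ok])}
    )
    grouped = frame.groupby("protein_id")["log2_ratio"]
    medians = grouped.median()
    counts = grouped.size()
    return medians[counts >= min_peptides]


def chase_scores(
    evidence: pd.DataFrame,
    psilac_log2_hm: Optional[Mapping[str, float]] = None,
    drug_condition: str = "CAP",
    vehicle_condition: str = "DMSO",
    normalize: bool = True,
    min_peptides: int = 1,
) -> pd.DataFrame:
    """Per-protein synthesis and degradation scores from chase evidence.

    Peptide H/L and M/L ratios are median-aggregated per protein within
    each condition; by default each condition's log2 ratios are
    median-centered (the same mixing-error correction as the pSILAC
    pipeline — flagged here because chase ratios share one lysate, so the
    correction is a convention rather than a necessity). Scores are the
    difference of drug minus vehicle log2 ratios. When a pSILAC
    ``protein_id -> mean log2 H/M`` mapping is supplied, each protein is
    classified; proteins without a pSILAC value are ``unassigned``.
    """
    present = set(evidence["condition"].unique())
    for cond in (drug_condition, vehicle_condition):
        if cond not in present:
            raise ValueError(f"condition {cond!r} not present in evidence")
    pieces = {}
    for cond in (drug_condition, vehicle_condition):
        for channel, label in (("H", "hl"), ("M", "ml")):
            series = _condition_ratios(evidence, cond, channel, min_peptides)
            if normalize and not series.empty:
                series = series - series.median()
            pieces[f"{label}_{cond}"] = series
    table = pd.DataFrame(pieces)
    table.index.name = "protein_id"
    table = table.reset_index()
    table["degradation_score"] = (
        table[f"hl_{drug_condition}"] - table[f"hl_{vehicle_condition}"]
    )
    table["synthesis_score"] = (
        table[f"ml_{drug_condition}"] - table[f"ml_{vehicle_condition}"]
    )
    if psilac_log2_hm is not None:
        table["category"] = [
            classify_cap_sensitivity(psilac_log2_hm.get(pid, math.nan))
            for pid in table["protein_id"]
        ]
    else:
        table["category"] = UNASSIGNED
    return table


def chase_group_comparison(scores: pd.DataFrame) -> pd.DataFrame:
    """Compare CAP-sensitive against unchanged proteins, one-sided.

    For both the degradation and the synthesis score, tests that the
    CAP-sensitive group's scores are smaller than the unchanged group's.
    Returns one row per score with group sizes and the Wilcoxon p-value.
    """
    rows = []
    for score_col in ("degradation_score", "synthesis_score"):
        sub = scores.dropna(subset=[score_col])
        sensitive = sub.loc[sub["category"] == CAP_SENSITIVE, score_col].to_numpy()
        unchanged = sub.loc[sub["category"] == UNCHANGED, score_col].to_numpy()
        if sensitive.size == 0:
            raise ValueError(f"no {CAP_SENSITIVE!r} proteins with a {score_col}")
        if unchanged.size == 0:
            raise ValueError(f"no {UNCHANGED!r} proteins with a {score_col}")
        p = wilcoxon_one_sided(sensitive, unchanged, alternative="less")
        rows.append(
            {
                "score": score_col,
                "n_sensitive": int(sensitive.size),
                "n_unchanged": int(unchanged.size),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
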