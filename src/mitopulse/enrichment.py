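"""Term-enrichment testing: one-sided hypergeometric (Fisher) + BH FDR.

A deliberately plain over-representation analysis: for each term, the
number of foreground hits ``k`` out of a foreground of size ``K`` is
compared against ``m`` background hits in a universe of ``N`` proteins,
with the one-sided enrichment p-value ``P[X >= k]`` for
``X ~ Hypergeometric(N, m, K)``; p-values are adjusted by the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int
    K: int
    m: int
    N: int
    odds_ratio: float
    p: float
    fdr: float


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in the input order.

    Step-up: with sorted p-values, ``q_i = min_{j >= i} p_(j) * m / j``,
    clipped at 1. All inputs must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[~((p > 0) & (p <= 1))]
        raise ValueError(f"p-values must be in (0, 1]; offending values: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    terms: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided enrichment of annotation terms in a foreground set.

    Parameters
    ----------
    foreground, background
        Protein identifier sets; the foreground must be a subset of the
        background (the background defines the universe ``N``).
    terms
        Long-format table with columns ``term_id``, ``term_name`` (optional)
        and ``protein_id``.

    Returns
    -------
    One row per term intersecting the background, with ``k``, ``K``, ``m``,
    ``N``, the sample odds ratio, hypergeometric ``p`` and BH ``fdr``,
    sorted by p-value. Terms with no foreground hit are reported with
    ``p = 1``.
    """
    fg = set(foreground)
    bg = set(background)
    offenders = sorted(fg - bg)
    if offenders:
        raise ValueError(
            f"foreground is not a subset of the background; offenders: {offenders[:10]}"
        )
    required = {"term_id", "protein_id"}
    if not required.issubset(terms.columns):
        raise ValueError(f"terms table must have columns {sorted(required)}")
    has_names = "term_name" in terms.columns
    N, K = len(bg), len(fg)
    rows = []
    for term_id, group in terms.groupby("term_id", sort=True):
        members = set(group["protein_id"]) & bg
        m = len(members)
        if m == 0:
            continue
        k = len(members & fg)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, m, K))
        a, b = k, K - k
        c, d = m - k, N - K - (m - k)
        odds = np.inf if (b == 0 or c == 0) and a * d > 0 else (
            0.0 if a * d == 0 else (a * d) / (b * c)
        )
        rows.append(
            {
                "term_id": term_id,
                "term_name": group["term_name"].iloc[0] if has_names else term_id,
                "k": k,
                "K": K,
                "m": m,
                "N": N,
                "odds_ratio": odds,
                "p": min(p, 1.0),
            }
        )
    if not rows:
        raise ValueError("no term overlaps the background universe")
    result = pd.DataFrame(rows)
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    return result.sort_values("p", kind="mergesort").reset_index(drop=True)
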