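"""In-silico protease digestion and observable-peptide accounting.

Implements site prediction for trypsin, lysC and chymotrypsin (and any
combination), exhaustive enumeration of digestion products with missed
cleavages, the 6-30-residue "theoretically observable" window used for
shotgun-MS detectability, and the iBAQ divisor (protein intensity per
observable peptide).

Cleavage specificities
----------------------
* trypsin      : after K or R, suppressed before proline (optional rule)
* lysC         : after K, regardless of a following proline
* chymotrypsin : after the aromatic essential residues F, W or Y,
                 suppressed before proline (optional rule)

Chymotrypsin is deliberately restricted to F/W/Y (no L/M cleavage): in a
pulse-SILAC context the labels ride on essential amino acids, and the
aromatic specificity is what makes chymotryptic peptides quantifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Sequence

import pandas as pd

from .proteins import ProteinRecord, validate_sequence

PROTEASES = ("trypsin", "lysc", "chymotrypsin")

#: residues each protease cuts after
_CUT_AFTER = {
    "trypsin": frozenset("KR"),
    "lysc": frozenset("K"),
    "chymotrypsin": frozenset("FWY"),
}

#: proteases whose cut is suppressed when the next residue is proline
_PROLINE_SENSITIVE = frozenset({"trypsin", "chymotrypsin"})


@dataclass(frozen=True)
class DigestSpec:
    """Protease rule set and peptide-length window.

    ``min_len``/``max_len`` define the theoretically observable window
    (default 6-30 residues). ``proline_rule`` suppresses trypsin and
    chymotrypsin cuts before proline; lysC always ignores it.
    """

    proteases: FrozenSet[str]
    missed_cleavages: int = 0
    min_len: int = 6
    max_len: int = 30
    proline_rule: bool = True

    def __post_init__(self) -> None:
        proteases = frozenset(self.proteases)
        if not proteases:
            raise ValueError("at least one protease is required")
        unknown = proteases - set(PROTEASES)
        if unknown:
            raise ValueError(f"unknown protease(s): {sorted(unknown)}")
        object.__setattr__(self, "proteases", proteases)
        if self.missed_cleavages < 0 or self.missed_cleavages > 10:
            raise ValueError("missed_cleavages must be in [0, 10]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")

    @property
    def label(self) -> str:
        return "+".join(sorted(self.proteases))


@dataclass(frozen=True)
class PeptideInterval:
    """A digestion product located on its parent sequence (1-based, inclusive)."""

    parent_id: str
    start: int
    end: int
    sequence: str
    n_missed: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match coordinates")

    def __len__(self) -> int:
        return self.end - self.start + 1


def cleavage_sites(
    sequence: str,
    proteases: Iterable[str],
    proline_rule: bool = True,
) -> list[int]:
    """Predicted cut positions (1-based, after-residue) for a protease set.

    A combined set cuts at the union of each protease's sites. The position
    ``i`` means a cut between residues ``i`` and ``i+1``; the C-terminus is
    never reported as a site.
    """
    seq = validate_sequence(sequence)
    proteases = frozenset(proteases)
    unknown = proteases - set(PROTEASES)
    if unknown:
        raise ValueError(f"unknown protease(s): {sorted(unknown)}")
    sites: set[int] = set()
    for prot in proteases:
        targets = _CUT_AFTER[prot]
        suppress = proline_rule and prot in _PROLINE_SENSITIVE
        for i in range(len(seq) - 1):  # never cut after the last residue
            if seq[i] in targets and not (suppress and seq[i + 1] == "P"):
                sites.add(i + 1)
    return sorted(sites)


def digest(protein: ProteinRecord, spec: DigestSpec) -> list[PeptideInterval]:
    """All digestion products with up to ``spec.missed_cleavages`` missed sites.

    With 0 missed cleavages the products partition the sequence. With ``m``
    missed cleavages every run of up to ``m + 1`` adjacent fully-cleaved
    fragments is also produced. No length filter is applied here; see
    :func:`observable_peptides`.
    """
    sites = cleavage_sites(protein.sequence, spec.proteases, spec.proline_rule)
    bounds = [0] + sites + [len(protein.sequence)]
    peptides: list[PeptideInterval] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(spec.missed_cleavages + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            start0, end0 = bounds[i], bounds[j]
            peptides.append(
                PeptideInterval(
                    parent_id=protein.id,
                    start=start0 + 1,
                    end=end0,
                    sequence=protein.sequence[start0:end0],
                    n_missed=m,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def observable_peptides(protein: ProteinRecord, spec: DigestSpec) -> list[PeptideInterval]:
    """Digestion products within the observable length window, ordered by (start, end)."""
    return [
        p for p in digest(protein, spec) if spec.min_len <= len(p) <= spec.max_len
    ]


def observable_count_matrix(
    proteins: Sequence[ProteinRecord],
    specs: Sequence[DigestSpec],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Protein x digestion-protocol matrix of observable-peptide counts.

    Rows are protein ids, columns are protocol labels (defaulting to the
    sorted protease-set label of each spec).
    """
    if not len(proteins) or not len(specs):
        raise ValueError("proteins and specs must be non-empty")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein id(s): {dupes}")
    if labels is None:
        labels = [s.label for s in specs]
    if len(labels) != len(specs):
        raise ValueError("labels and specs length mismatch")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate spec label(s) in {list(labels)}")
    data = {
        label: [len(observable_peptides(p, spec)) for p in proteins]
        for label, spec in zip(labels, specs)
    }
    return pd.DataFrame(data, index=pd.Index(ids, name="protein_id"))


def ibaq(protein_intensity: float, n_observable: int) -> float:
    """iBAQ value: total protein intensity per theoretically observable peptide.

    Returns NaN (an undefined iBAQ, distinct from a numeric error) when the
    protein has no observable peptides.
    """
    if protein_intensity < 0:
        raise ValueError("protein intensity must be nonnegative")
    if n_observable == 0:
        return math.nan
    if n_observable < 0:
        raise ValueError("n_observable must be >= 0")
    return protein_intensity / n_observable


def peptide_table(peptides: Iterable[PeptideInterval]) -> pd.DataFrame:
    """Flatten peptide intervals into the standard output table."""
    return pd.DataFrame(
        [
            {
                "protein_id": p.parent_id,
                "start": p.start,
                "end": p.end,
                "length": len(p),
                "n_missed": p.n_missed,
                "sequence": p.sequence,
            }
            for p in peptides
        ],
        columns=["protein_id", "start", "end", "length", "n_missed", "sequence"],
    )
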