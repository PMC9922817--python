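"""Protein records and FASTA input/output.

A :class:`ProteinRecord` is the unit of quantification throughout the
package: an accession, a validated amino-acid sequence, the encoding genome
(mitochondrial or nuclear) and optional OXPHOS complex/module annotations.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

VALID_ENCODINGS = ("mitochondrial", "nuclear")
VALID_COMPLEXES = ("CI", "CII", "CIII", "CIV", "CV", "none")


class SequenceError(ValueError):
    """A protein sequence contains a residue outside the canonical 20."""


def validate_sequence(sequence: str, protein_id: str = "<sequence>") -> str:
    """Validate an amino-acid sequence.

    Rejects the ambiguity/nonstandard codes (B, J, O, U, X, Z) and anything
    else outside the 20 canonical residues, naming the offending character
    and its 1-based position. Returns the upper-cased sequence.
    """
    if not sequence:
        raise SequenceError(f"{protein_id}: empty sequence")
    seq = sequence.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"{protein_id}: invalid residue {ch!r} at position {pos}; "
                "only the 20 canonical amino acids are accepted"
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its genome-of-origin and complex annotation.

    Parameters
    ----------
    id
        Accession (unique within a collection).
    gene
        Gene symbol.
    sequence
        Amino-acid sequence over the 20 canonical residues.
    encoding
        ``"mitochondrial"`` or ``"nuclear"``.
    complex_
        OXPHOS complex (``CI`` .. ``CV``) or ``"none"``.
    module
        Optional assembly-module / subcomplex label.
    """

    id: str
    sequence: str
    gene: str = ""
    encoding: str = "nuclear"
    complex_: str = "none"
    module: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, self.id))
        if self.encoding not in VALID_ENCODINGS:
            raise ValueError(
                f"{self.id}: encoding must be one of {VALID_ENCODINGS}, got {self.encoding!r}"
            )
        if self.complex_ not in VALID_COMPLEXES:
            raise ValueError(
                f"{self.id}: complex must be one of {VALID_COMPLEXES}, got {self.complex_!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _accession_from_header(header_token: str) -> str:
    # UniProt convention: db|ACCESSION|ENTRY_NAME; otherwise the raw token.
    parts = header_token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_token


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA into validated records.

    Accessions follow the UniProt pipe convention (``sp|P03901|NU4LM_HUMAN``
    yields ``P03901``) when present, otherwise the first whitespace-delimited
    header token. Duplicate accessions and invalid residues are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise ValueError(f"{path}: no FASTA records found")
    for rec in parsed:
        acc = _accession_from_header(rec.id)
        if acc in seen:
            raise ValueError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        records.append(ProteinRecord(id=acc, sequence=str(rec.seq), gene=_gene_from_description(rec.description)))
    return records


def _gene_from_description(description: str) -> str:
    for token in description.split():
        if token.startswith("GN="):
            return token[3:]
    return ""


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA (atomic write-temp-then-rename)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"GN={r.gene}" if r.gene else "")
        for r in records
    ]
    path = str(path)
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            SeqIO.write(seqrecords, handle, "fasta")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def check_unique_ids(records: Iterable[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate protein id {r.id!r}")
        seen.add(r.id)
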