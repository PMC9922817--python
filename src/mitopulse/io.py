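"""Tab-separated table input/output and evidence-dialect handling.

All tables are UTF-8 TSV with one header row; comment lines start with
``#``. Writes are atomic (write to a temp file in the target directory,
then rename). Missing intensities are empty cells, never zeros — except
under the MaxQuant dialect, where a stored 0 means "not quantified" and is
mapped to missing on read.
"""

from __future__ import annotations

import hashlib
import logging
import os
import tempfile
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .simulate import EVIDENCE_COLUMNS

logger = logging.getLogger(__name__)

#: MaxQuant-style evidence column mapping to the native schema
MAXQUANT_COLUMN_MAP = {
    "Sequence": "peptide_sequence",
    "Proteins": "protein_id",
    "Experiment": "replicate_id",
    "Intensity L": "intensity_L",
    "Intensity M": "intensity_M",
    "Intensity H": "intensity_H",
}

_INTENSITY_COLUMNS = ["intensity_L", "intensity_M", "intensity_H"]


def write_table(
    frame: pd.DataFrame,
    path: str | os.PathLike,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> None:
    """Atomically write a TSV with a provenance header comment."""
    path = str(path)
    header = f"# mitopulse {__version__}"
    if seed is not None:
        header += f" seed={seed}"
    if config_hash is not None:
        header += f" config={config_hash}"
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(header + "\n")
            frame.to_csv(handle, sep="\t", index=False, na_rep="")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(config: Mapping) -> str:
    """Stable short hash of a flat configuration mapping."""
    canonical = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def read_evidence(
    path: str | os.PathLike,
    column_map: Optional[Mapping[str, str]] = None,
    zero_is_missing: Optional[bool] = None,
) -> pd.DataFrame:
    """Read a peptide-level SILAC evidence table.

    ``column_map`` maps source columns to the native schema (use
    :data:`MAXQUANT_COLUMN_MAP` for MaxQuant-style files); without it the
    file must already carry the native columns. Empty cells become missing
    values. Zeros become missing only when ``zero_is_missing`` is true,
    which defaults to true exactly when a column map is supplied (the
    MaxQuant convention stores unquantified channels as 0). Rows with a
    negative intensity are rejected and tallied in the log.
    """
    raw = pd.read_csv(path, sep="\t", comment="#")
    if column_map:
        missing_src = [c for c in column_map if c not in raw.columns]
        if missing_src:
            raise ValueError(f"{path}: mapped column(s) not found: {missing_src}")
        raw = raw.rename(columns=dict(column_map))
    missing_cols = [c for c in EVIDENCE_COLUMNS if c not in raw.columns and c != "condition"]
    if missing_cols:
        raise ValueError(f"{path}: required column(s) missing: {missing_cols}")
    if "condition" not in raw.columns:
        raw["condition"] = "pooled"
    if zero_is_missing is None:
        zero_is_missing = column_map is not None
    for col in _INTENSITY_COLUMNS:
        raw[col] = pd.to_numeric(raw[col], errors="raise")
        if zero_is_missing:
            raw.loc[raw[col] == 0, col] = pd.NA
    negative = (raw[_INTENSITY_COLUMNS] < 0).any(axis=1)
    if negative.any():
        logger.warning("%s: rejected %d row(s) with negative intensity", path, int(negative.sum()))
        raw = raw[~negative]
    return raw[EVIDENCE_COLUMNS + [c for c in raw.columns if c not in EVIDENCE_COLUMNS]]
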