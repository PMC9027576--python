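"""CSV schemas and validated readers/writers for every pipeline table.

All on-disk artifacts are plain comma-separated text: pedigree, pen
assignment, interaction records, lesion counts, trait tables, posterior
chains, summary tables and selection reports.  Readers validate required
headers and report problems at column level; unknown extra columns are
preserved with a warning.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from pigsna.network import InteractionRecord
from pigsna.pedigree import Pedigree

SCHEMAS = {
    "pedigree": ["animal", "sire", "dam"],
    "animals": ["animal", "pen", "litter", "sex", "line", "batch", "weight"],
    "interactions": ["pen", "initiator", "receiver", "kind", "duration"],
    "lesions": ["animal", "region", "timepoint", "count"],
    "traits": ["animal", "pen"],
    "ebv": ["animal"],
}


class SchemaError(ValueError):
    """A table is missing required columns or cannot be parsed."""


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema."""
    required = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{schema} file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: cannot parse as CSV ({exc})") from exc
    if len(frame.columns) == 1 and "," not in frame.columns[0] and len(required) > 1:
        raise SchemaError(
            f"{path}: line 1 has a single column {frame.columns[0]!r}; "
            "wrong delimiter?"
        )
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in frame.columns if c not in required]
    if extra and schema in ("pedigree", "animals", "interactions", "lesions"):
        known_extra = {"generation"}
        unknown = [c for c in extra if c not in known_extra]
        if unknown:
            warnings.warn(f"{path}: unknown column(s) {unknown} preserved", stacklevel=2)
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_pedigree(path: str | Path) -> Pedigree:
    return Pedigree.from_frame(read_table(path, "pedigree"))


def write_pedigree(pedigree: Pedigree, path: str | Path) -> Path:
    return write_table(pedigree.to_frame(), path)


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    frame = read_table(path, "interactions")
    return [
        InteractionRecord(
            int(r.pen), int(r.initiator), int(r.receiver), str(r.kind),
            float(r.duration) if np.isfinite(r.duration) else None,
        )
        for r in frame.itertuples()
    ]


def write_interactions(records: list[InteractionRecord], path: str | Path) -> Path:
    frame = pd.DataFrame(
        [
            (r.pen_id, r.initiator_id, r.receiver_id, r.kind,
             r.duration if r.duration is not None else np.nan)
            for r in records
        ],
        columns=SCHEMAS["interactions"],
    )
    return write_table(frame, path)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
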