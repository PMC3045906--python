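"""Proteome FASTA and organism-manifest I/O, plus class-label derivation.

Each organism is one multi-FASTA file of protein sequences. The manifest is a
TSV with one row per organism carrying the environmental metadata from which
the three classification labels are derived:

* domain of life: ``bacteria`` vs ``archaea`` (given directly);
* halophilicity: binary ``halophile`` / ``non-halophile`` (given directly, or
  derivable from a tolerated-NaCl range);
* thermophilicity: derived from the optimal growth temperature range
  (``temp_min``, ``temp_max`` in degrees C) against a 55 C threshold —
  mesophile if the entire range lies in the mesophilic region, thermophile if
  it lies entirely in the thermophilic region, mesothermophile if it straddles
  the threshold.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import CANONICAL_RESIDUES

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["organism_id", "domain", "temp_min", "temp_max", "halophile", "fasta_path"]

CASES = ("domain_of_life", "halophilicity", "thermophilicity")

THERMO_CLASSES = ("mesophile", "mesothermophile", "thermophile")


class FastaFormatError(ValueError):
    """Raised for empty or malformed proteome FASTA files."""


class DatasetError(ValueError):
    """Raised when a classification case is degenerate (fewer than 2 classes)."""


@dataclass
class ProteomeRecord:
    """One organism's set of sanitized protein sequences."""

    organism_id: str
    sequences: list[str]
    removed_characters: Counter = field(default_factory=Counter)

    @property
    def n_proteins(self) -> int:
        return len(self.sequences)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FastaFormatError(f"proteome {self.organism_id!r} has no sequences")
        if any(len(s) == 0 for s in self.sequences):
            raise ValueError("empty sequence in ProteomeRecord after sanitization")


@dataclass(frozen=True)
class ClassScheme:
    """Thresholds defining the class labels.

    thermophile_threshold separates the mesophilic from the thermophilic
    temperature region (default 55 C, strictly-above defines thermophilic).
    halophile_nacl_molarity is the optional tolerated-NaCl cutoff for deriving
    a binary halophilicity label from a NaCl range (default 2.0 M).
    """

    thermophile_threshold: float = 55.0
    halophile_nacl_molarity: float = 2.0

    def __post_init__(self) -> None:
        if self.thermophile_threshold <= 0:
            raise ValueError("thermophile_threshold must be positive")


_CANON = set(CANONICAL_RESIDUES)


def sanitize_sequence(seq: str) -> tuple[str, Counter]:
    """Uppercase and strip every character outside the 20 canonical residues.

    Returns the cleaned sequence and a count of removed characters
    (ambiguity codes B/J/O/U/X/Z, stops, gaps, whitespace, ...).
    """
    up = seq.upper()
    removed: Counter = Counter(c for c in up if c not in _CANON)
    clean = "".join(c for c in up if c in _CANON)
    return clean, removed


def read_fasta(path: str | Path, organism_id: str | None = None) -> ProteomeRecord:
    """Read one organism's protein multi-FASTA into a sanitized record.

    Sequences are uppercased; non-canonical characters are removed and
    counted. A sequence that becomes empty after sanitization is dropped with
    a warning.
    """
    path = Path(path)
    if organism_id is None:
        organism_id = path.stem
    sequences: list[str] = []
    removed: Counter = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        clean, rem = sanitize_sequence(str(rec.seq))
        removed.update(rem)
        if not clean:
            logger.warning("dropping sequence %s: empty after sanitization", rec.id)
            continue
        sequences.append(clean)
    if not sequences:
        raise FastaFormatError(f"no usable sequences in {path}")
    return ProteomeRecord(organism_id=organism_id, sequences=sequences, removed_characters=removed)


def write_fasta(record: ProteomeRecord, path: str | Path) -> None:
    """Write a proteome as standard multi-FASTA, 60-column wrapped, headers
    ``>orgID|proteinN`` (1-based)."""
    records = [
        SeqRecord(Seq(s), id=f"{record.organism_id}|protein{i + 1}", description="")
        for i, s in enumerate(record.sequences)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def assign_thermo_class(
    temp_min: float | None, temp_max: float | None, scheme: ClassScheme = ClassScheme()
) -> str:
    """Classify a growth-temperature range against the thermophile threshold.

    mesophile iff temp_max <= threshold; thermophile iff temp_min > threshold;
    mesothermophile iff temp_min <= threshold < temp_max; unknown if the range
    is missing. A range touching the threshold (max == 55) is mesophile, since
    the thermophilic region is defined as strictly above the threshold.
    """
    if temp_min is None or temp_max is None or math.isnan(temp_min) or math.isnan(temp_max):
        return "unknown"
    if temp_min > temp_max:
        raise ValueError(f"temp_min {temp_min} > temp_max {temp_max}")
    t = scheme.thermophile_threshold
    if temp_max <= t:
        return "mesophile"
    if temp_min > t:
        return "thermophile"
    return "mesothermophile"


def halophile_from_nacl(
    nacl_max_molarity: float | None, scheme: ClassScheme = ClassScheme()
) -> str:
    """Optional rule deriving the binary halophilicity label from a tolerated
    NaCl range: halophile iff the tolerated maximum reaches the configured
    molarity."""
    if nacl_max_molarity is None or math.isnan(nacl_max_molarity):
        return ""
    return "halophile" if nacl_max_molarity >= scheme.halophile_nacl_molarity else "non-halophile"


def read_manifest(path: str | Path, scheme: ClassScheme = ClassScheme()) -> pd.DataFrame:
    """Read the organism manifest TSV and derive ``thermo_class``.

    Columns: organism_id, domain, temp_min, temp_max, halophile, fasta_path;
    missing values are empty fields.
    """
    df = pd.read_csv(path, sep="\t", dtype={"organism_id": str, "domain": str, "halophile": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if df["organism_id"].duplicated().any():
        dupes = df.loc[df["organism_id"].duplicated(), "organism_id"].tolist()
        raise ValueError(f"duplicate organism ids {dupes}")
    return derive_thermo_class(df, scheme)


def derive_thermo_class(manifest: pd.DataFrame, scheme: ClassScheme = ClassScheme()) -> pd.DataFrame:
    df = manifest.copy()
    df["thermo_class"] = [
        assign_thermo_class(
            None if pd.isna(lo) else float(lo),
            None if pd.isna(hi) else float(hi),
            scheme,
        )
        for lo, hi in zip(df["temp_min"], df["temp_max"])
    ]
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


_CASE_COLUMN = {
    "domain_of_life": "domain",
    "halophilicity": "halophile",
    "thermophilicity": "thermo_class",
}


def build_case_labels(manifest: pd.DataFrame, case: str) -> pd.DataFrame:
    """Return ``organism_id``/``label`` rows for one classification case.

    Organisms whose label for the case is missing or ``unknown`` are excluded
    (so the invariant |case organisms| + |excluded| = |manifest| holds).
    """
    if case not in _CASE_COLUMN:
        raise ValueError(f"unknown case {case!r}; expected one of {CASES}")
    df = manifest if "thermo_class" in manifest.columns else derive_thermo_class(manifest)
    col = _CASE_COLUMN[case]
    labels = df[col].astype("string")
    keep = labels.notna() & (labels != "") & (labels != "unknown")
    out = pd.DataFrame(
        {"organism_id": df.loc[keep, "organism_id"], "label": labels[keep].astype(str)}
    ).reset_index(drop=True)
    counts = out["label"].value_counts()
    if len(counts) < 2:
        raise DatasetError(
            f"case {case!r} has {len(counts)} represented class(es); need at least 2"
        )
    return out
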