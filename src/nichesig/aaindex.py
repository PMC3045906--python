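"""Amino-acid index (physico-chemical scale) tables.

An amino-acid index maps each of the 20 canonical residues to a real-valued
property (hydrophilicity, beta-turn propensity, volume, ...). The bundled
default table holds 48 AAindex scales, including the structural and
hydrophilicity scales whose proteome means turn out most discriminative for
environmental adaptation (normalized frequency of extended structure,
normalized frequency of beta-turn, information measure for loop, Chou-Fasman
coil parameter, Hopp-Woods hydrophilicity, Grantham polarity). The table is
fully user-replaceable: any TSV with columns ``index_code``, ``description``
and the 20 one-letter residue columns is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabets import CANONICAL_RESIDUES


@dataclass(frozen=True)
class AAIndexTable:
    """A set of amino-acid scales.

    Attributes
    ----------
    codes : list of str
        Unique index codes (AAindex accessions for the bundled table).
    descriptions : dict
        Human-readable description per code.
    matrix : ndarray, shape (n_indices, 20)
        Scale values, residue columns ordered as `CANONICAL_RESIDUES`.
    """

    codes: tuple[str, ...]
    descriptions: dict[str, str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if len(self.codes) != len(set(self.codes)):
            raise ValueError("index codes must be unique")
        if self.matrix.shape != (len(self.codes), 20):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.codes)} codes x 20 residues"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("index table contains non-finite values")

    def __len__(self) -> int:
        return len(self.codes)

    def values_for(self, code: str) -> dict[str, float]:
        """Residue -> value mapping for one index."""
        row = self.matrix[self.codes.index(code)]
        return dict(zip(CANONICAL_RESIDUES, row.tolist()))

    @classmethod
    def from_mapping(
        cls, entries: dict[str, dict[str, float]], descriptions: dict[str, str] | None = None
    ) -> "AAIndexTable":
        """Build a table from ``{code: {residue: value}}``; every entry must
        define all 20 canonical residues."""
        codes = tuple(entries)
        mat = np.empty((len(codes), 20), dtype=float)
        for i, code in enumerate(codes):
            vals = entries[code]
            missing = set(CANONICAL_RESIDUES) - set(vals)
            if missing:
                raise ValueError(f"index {code} missing residues {sorted(missing)}")
            mat[i] = [vals[aa] for aa in CANONICAL_RESIDUES]
        desc = {c: (descriptions or {}).get(c, "") for c in codes}
        return cls(codes=codes, descriptions=desc, matrix=mat)


def read_index_table(path: str | Path) -> AAIndexTable:
    """Read an index table from TSV (``index_code``, ``description``, 20 residue
    columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = [aa for aa in CANONICAL_RESIDUES if aa not in df.columns]
    if missing:
        raise ValueError(f"index table missing residue columns {missing}")
    codes = tuple(df["index_code"].astype(str))
    desc = dict(zip(codes, df.get("description", pd.Series([""] * len(df))).astype(str)))
    mat = df[list(CANONICAL_RESIDUES)].to_numpy(dtype=float)
    return AAIndexTable(codes=codes, descriptions=desc, matrix=mat)


def write_index_table(table: AAIndexTable, path: str | Path) -> None:
    df = pd.DataFrame(table.matrix, columns=list(CANONICAL_RESIDUES))
    df.insert(0, "description", [table.descriptions[c] for c in table.codes])
    df.insert(0, "index_code", list(table.codes))
    df.to_csv(path, sep="\t", index=False)


def default_index_table() -> AAIndexTable:
    """The bundled 48-scale AAindex selection."""
    with resources.as_file(
        resources.files("nichesig.data") / "aaindex_default.tsv"
    ) as p:
        return read_index_table(p)
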