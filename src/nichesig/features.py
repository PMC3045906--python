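"""Physico-chemical proteome descriptors.

Features are computed per protein and averaged (unweighted arithmetic mean
over proteins) to proteome level. With the bundled 48-scale index table the
full set has 79 features:

* 20 residue frequencies f(aa);
* 48 amino-acid-index means (mean scale value over the protein's residues,
  equal to the composition-weighted scale value);
* isoelectric point (bisection on the Henderson-Hasselbalch net charge);
* protein length (residues; the proteome value is the mean protein size);
* 8 frequency ratios: f(charged)/f(non-charged), f(charged)/f(all),
  f(polar)/f(non-polar), f(polar)/f(all),
  f(disorder-promoting)/f(order-promoting), f(disorder-promoting)/f(all),
  f(neg)/f(pos), and f(neg)/f(all) — the last is the "negative charge";
* "charge": the total charged fraction f(D,E,K,R). (The net-charge balance is
  carried by the f(neg)/f(pos) ratio; positive charge f(K)+f(R) is available
  on the per-protein record.)

All descriptors are order-independent functions of residue counts, so the
implementation works on a per-protein count matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aaindex import AAIndexTable, default_index_table
from .alphabets import (
    CANONICAL_RESIDUES,
    DEFAULT_PKA,
    DEFAULT_RESIDUE_SETS,
    PKaSet,
    ResidueSetDefinitions,
)
from .proteome_io import ProteomeRecord

logger = logging.getLogger(__name__)

COMPOSITION_CODES = tuple(f"comp_{aa}" for aa in CANONICAL_RESIDUES)
RATIO_CODES = (
    "ratio_charged_noncharged",
    "ratio_charged_all",
    "ratio_polar_nonpolar",
    "ratio_polar_all",
    "ratio_disorder_order",
    "ratio_disorder_all",
    "ratio_neg_pos",
    "negative_charge",  # f(neg)/f(all) = f(D)+f(E)
)

# ASCII -> residue index lookup (-1 marks non-canonical; inputs are assumed
# pre-sanitized so -1 never occurs in practice).
_LOOKUP = np.full(128, -1, dtype=np.int8)
for _i, _aa in enumerate(CANONICAL_RESIDUES):
    _LOOKUP[ord(_aa)] = _i


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    idx = _LOOKUP[arr]
    if np.any(idx < 0):
        bad = sorted({chr(c) for c in arr[idx < 0]})
        raise ValueError(f"non-canonical residues {bad}; sanitize first")
    return idx.astype(np.int64)


def residue_counts(sequence: str) -> np.ndarray:
    """Counts of the 20 canonical residues, order `CANONICAL_RESIDUES`."""
    if not sequence:
        raise ValueError("empty sequence")
    return np.bincount(_encode(sequence), minlength=20).astype(float)


def residue_composition(sequence: str) -> np.ndarray:
    """Residue frequencies f(aa) = count(aa)/length; sums to 1."""
    counts = residue_counts(sequence)
    return counts / counts.sum()


def counts_matrix(record: ProteomeRecord) -> np.ndarray:
    """(n_proteins, 20) residue-count matrix for a proteome."""
    blob = "".join(record.sequences)
    idx = _encode(blob)
    lengths = np.fromiter((len(s) for s in record.sequences), dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    # one-hot reduction per protein segment
    onehot = np.zeros((idx.size, 20))
    onehot[np.arange(idx.size), idx] = 1.0
    return np.add.reduceat(onehot, starts, axis=0)


def index_mean(sequence: str, index_values: dict[str, float]) -> float:
    """Mean scale value over the sequence's residues (= sum f(aa)*value(aa))."""
    comp = residue_composition(sequence)
    undefined = [aa for aa, f in zip(CANONICAL_RESIDUES, comp) if f > 0 and aa not in index_values]
    if undefined:
        raise ValueError(f"index does not define residues present: {undefined}")
    vals = np.array([index_values.get(aa, 0.0) for aa in CANONICAL_RESIDUES])
    return float(comp @ vals)


def net_charge(counts: np.ndarray, pH: np.ndarray | float, pka: PKaSet = DEFAULT_PKA) -> np.ndarray:
    """Henderson-Hasselbalch net charge Z(pH) for count vectors.

    counts: (..., 20); pH: scalar or broadcastable array. Includes one free
    N- and C-terminus per protein. Z is monotonically non-increasing in pH.
    """
    counts = np.asarray(counts, dtype=float)
    pH = np.asarray(pH, dtype=float)
    z = 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    z = z - 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    for aa, pk in pka.positive.items():
        z = z + counts[..., CANONICAL_RESIDUES.index(aa)] / (1.0 + 10.0 ** (pH - pk))
    for aa, pk in pka.negative.items():
        z = z - counts[..., CANONICAL_RESIDUES.index(aa)] / (1.0 + 10.0 ** (pk - pH))
    return z


def isoelectric_point_from_counts(
    counts: np.ndarray, pka: PKaSet = DEFAULT_PKA, tol: float = 1e-4
) -> np.ndarray:
    """pI by bisection of Z(pH) on [0, 14] to within ``tol`` pH units.

    The termini guarantee Z(0) > 0 > Z(14), and monotonicity of Z gives a
    unique crossing.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    lo = np.zeros(counts.shape[0])
    hi = np.full(counts.shape[0], 14.0)
    while np.max(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        pos = net_charge(counts, mid, pka) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def isoelectric_point(sequence: str, pka: PKaSet = DEFAULT_PKA, tol: float = 1e-4) -> float:
    """Isoelectric point of one sanitized sequence (pH units)."""
    return float(isoelectric_point_from_counts(residue_counts(sequence), pka, tol)[0])


def _set_mask(residues: frozenset[str]) -> np.ndarray:
    return np.array([aa in residues for aa in CANONICAL_RESIDUES], dtype=float)


def ratio_features(
    composition: np.ndarray,
    sets: ResidueSetDefinitions = DEFAULT_RESIDUE_SETS,
    length: float | None = None,
) -> np.ndarray:
    """The eight frequency-ratio features (see module docstring for order).

    A zero denominator gets a pseudocount of 1/(length+1) — or 1e-9 when the
    length is unknown — so the feature matrix stays complete; occurrences are
    logged. Since f(all) = 1, the /f(all) ratios are plain set frequencies.
    """
    comp = np.atleast_2d(np.asarray(composition, dtype=float))
    eps = 1.0 / (float(length) + 1.0) if length is not None else 1e-9

    def frac(residues: frozenset[str]) -> np.ndarray:
        return comp @ _set_mask(residues)

    charged = frac(sets.charged)
    polar = frac(sets.polar)
    nonpolar = frac(sets.non_polar)
    dis = frac(sets.disorder_promoting)
    order = frac(sets.order_promoting)
    neg = frac(sets.negatively_charged)
    pos = frac(sets.positively_charged)

    def safe_div(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
        zero = den == 0
        if np.any(zero):
            logger.debug("zero denominator in %s for %d protein(s); pseudocount applied",
                         name, int(zero.sum()))
        return num / np.where(zero, eps, den)

    out = np.stack(
        [
            safe_div(charged, 1.0 - charged, "charged/non-charged"),
            charged,
            safe_div(polar, nonpolar, "polar/non-polar"),
            polar,
            safe_div(dis, order, "disorder/order"),
            dis,
            safe_div(neg, pos, "neg/pos"),
            neg,
        ],
        axis=-1,
    )
    return out[0] if np.asarray(composition).ndim == 1 else out


@dataclass(frozen=True)
class PerProteinFeatures:
    """Descriptor bundle for one protein."""

    composition: np.ndarray
    index_means: dict[str, float]
    isoelectric_point: float
    length: int
    ratios: np.ndarray
    negative_charge: float  # f(D)+f(E)
    positive_charge: float  # f(K)+f(R)
    charge: float  # f(D)+f(E)+f(K)+f(R)

    def __post_init__(self) -> None:
        if abs(self.composition.sum() - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not (0.0 < self.isoelectric_point < 14.0):
            raise ValueError("isoelectric point out of (0, 14)")


def feature_codes(table: AAIndexTable) -> list[str]:
    """Column order of the full feature set for a given index table."""
    return (
        list(COMPOSITION_CODES)
        + list(table.codes)
        + ["pI", "protein_length"]
        + list(RATIO_CODES)
        + ["charge"]
    )


def protein_features(
    sequence: str,
    table: AAIndexTable | None = None,
    sets: ResidueSetDefinitions = DEFAULT_RESIDUE_SETS,
    pka: PKaSet = DEFAULT_PKA,
) -> PerProteinFeatures:
    """All descriptors for one sanitized protein sequence."""
    table = table if table is not None else default_index_table()
    counts = residue_counts(sequence)
    length = int(counts.sum())
    comp = counts / length
    idx_means = dict(zip(table.codes, (comp @ table.matrix.T).tolist()))
    ratios = ratio_features(comp, sets, length=length)
    neg = float(comp @ _set_mask(sets.negatively_charged))
    pos = float(comp @ _set_mask(sets.positively_charged))
    chg = float(comp @ _set_mask(sets.charged))
    return PerProteinFeatures(
        composition=comp,
        index_means=idx_means,
        isoelectric_point=isoelectric_point(sequence, pka),
        length=length,
        ratios=ratios,
        negative_charge=neg,
        positive_charge=pos,
        charge=chg,
    )


def proteome_features(
    record: ProteomeRecord,
    table: AAIndexTable | None = None,
    sets: ResidueSetDefinitions = DEFAULT_RESIDUE_SETS,
    pka: PKaSet = DEFAULT_PKA,
) -> pd.Series:
    """Proteome-level feature vector: unweighted mean over proteins.

    Every feature — including pI and length — is computed per protein and
    averaged, never recomputed on the pooled residue counts (with unequal
    protein lengths the two differ).
    """
    table = table if table is not None else default_index_table()
    if record.n_proteins < 1:
        raise ValueError("empty proteome")
    counts = counts_matrix(record)
    lengths = counts.sum(axis=1)
    comps = counts / lengths[:, None]
    idx_means = comps @ table.matrix.T  # (n_prot, n_idx)
    pis = isoelectric_point_from_counts(counts, pka)
    ratios = ratio_features(comps, sets, length=float(lengths.min()))
    charge = comps @ _set_mask(sets.charged)
    vec = np.concatenate(
        [
            comps.mean(axis=0),
            idx_means.mean(axis=0),
            [pis.mean(), lengths.mean()],
            ratios.mean(axis=0),
            [charge.mean()],
        ]
    )
    return pd.Series(vec, index=feature_codes(table), name=record.organism_id)


def build_feature_matrix(
    records: list[ProteomeRecord],
    table: AAIndexTable | None = None,
    sets: ResidueSetDefinitions = DEFAULT_RESIDUE_SETS,
    pka: PKaSet = DEFAULT_PKA,
) -> pd.DataFrame:
    """Organisms x features matrix (rows indexed by organism_id)."""
    table = table if table is not None else default_index_table()
    rows = [proteome_features(r, table, sets, pka) for r in records]
    df = pd.DataFrame(rows)
    df.index.name = "organism_id"
    if df.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return df


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="organism_id")


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="organism_id")
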