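"""Canonical amino-acid alphabet, residue-class definitions and pKa sets.

Residue classes back the eight frequency-ratio features (charged/non-charged,
polar/non-polar, disorder/order-promoting, negative/positive). Histidine is
treated as neutral at physiological pH, so it is not in the charged sets;
its content is carried separately by the composition features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 canonical residues, alphabetical one-letter order. All composition
#: vectors and index tables use this ordering.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}

#: Characters removed during sanitization (ambiguity codes, rare residues,
#: stops and gap symbols).
NON_CANONICAL: frozenset[str] = frozenset("BJOUXZ*-.")


@dataclass(frozen=True)
class ResidueSetDefinitions:
    """Residue classes used by the ratio features.

    Defaults: acidic/negative {D,E}; basic/positive {K,R}; charged is their
    union; polar/non-polar partition the alphabet; disorder- and
    order-promoting sets follow the Dunker convention.
    """

    negatively_charged: frozenset[str] = frozenset("DE")
    positively_charged: frozenset[str] = frozenset("KR")
    charged: frozenset[str] = frozenset("DEKR")
    acidic: frozenset[str] = frozenset("DE")
    basic: frozenset[str] = frozenset("KR")
    polar: frozenset[str] = frozenset("RNDCQEHKSTY")
    non_polar: frozenset[str] = frozenset("AGILMFPWV")
    disorder_promoting: frozenset[str] = frozenset("ARGQSPEK")
    order_promoting: frozenset[str] = frozenset("WCFIYVLN")

    def __post_init__(self) -> None:
        all20 = frozenset(CANONICAL_RESIDUES)
        if not (self.positively_charged | self.negatively_charged) <= self.charged:
            raise ValueError("positive/negative sets must be subsets of charged")
        if self.polar & self.non_polar:
            raise ValueError("polar and non-polar sets overlap")
        if self.polar | self.non_polar != all20:
            raise ValueError("polar and non-polar sets must cover all 20 residues")


DEFAULT_RESIDUE_SETS = ResidueSetDefinitions()


@dataclass(frozen=True)
class PKaSet:
    """pKa values for ionizable groups used by the isoelectric-point model.

    Defaults are the EMBOSS values. ``positive`` groups contribute
    +1/(1+10^(pH-pKa)) to net charge, ``negative`` groups -1/(1+10^(pKa-pH)).
    """

    n_terminus: float = 8.6
    c_terminus: float = 3.6
    positive: dict[str, float] = field(
        default_factory=lambda: {"K": 10.8, "R": 12.5, "H": 6.5}
    )
    negative: dict[str, float] = field(
        default_factory=lambda: {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
    )


DEFAULT_PKA = PKaSet()
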