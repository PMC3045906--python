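"""Synthetic proteome generator with planted environmental signatures.

Generates per-organism protein FASTA files plus a manifest with known ground
truth, so the whole pipeline (feature extraction, redundancy reduction,
classification, importance) is testable without downloading real proteomes.

The model: each organism belongs to a composite class (domain | halophilicity
| thermophilicity). A class tilts a baseline amino-acid distribution by
per-residue multiplicative factors (renormalized to the simplex) and sets a
lognormal protein-length distribution. Proteins are i.i.d. residue draws —
the downstream descriptors are order-independent compositions and means, so
sequence order carries no signal. A small per-organism lognormal jitter on
the residue frequencies emulates between-organism variation (lineage, GC
pressure) and keeps the classification task non-trivial.

Planted effect directions follow what is reported for real proteomes:
halophiles enriched in acidic residues (Glu more than Asp) and depleted in
Lys/Phe/Gln; thermophiles enriched in Val/Tyr/Glu and depleted in Gln;
archaea with shorter proteins, less His/Gln and more Glu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabets import AA_TO_INDEX, CANONICAL_RESIDUES
from .proteome_io import MANIFEST_COLUMNS, ProteomeRecord, write_fasta, write_manifest


class ConfigurationError(ValueError):
    """A requested class has no effect profile."""


class EmptyDatasetError(ValueError):
    """Zero organisms requested."""


#: Baseline residue frequencies (approximate averages over annotated
#: proteomes, normalized to sum 1), order `CANONICAL_RESIDUES`.
BASELINE_FREQUENCIES: np.ndarray = np.array(
    [
        0.0826, 0.0138, 0.0546, 0.0672, 0.0387,  # A C D E F
        0.0708, 0.0227, 0.0593, 0.0583, 0.0965,  # G H I K L
        0.0241, 0.0406, 0.0472, 0.0393, 0.0553,  # M N P Q R
        0.0660, 0.0535, 0.0687, 0.0110, 0.0292,  # S T V W Y
    ]
)
BASELINE_FREQUENCIES = BASELINE_FREQUENCIES / BASELINE_FREQUENCIES.sum()

# Effect multipliers per label dimension; magnitudes are tunable model
# parameters (only the directions are constrained by observations on real
# proteomes). Halophile D/E multipliers are ~2 so that, after
# renormalization, the acidic fraction roughly doubles.
DOMAIN_EFFECTS: dict[str, dict[str, float]] = {
    "bacteria": {},
    "archaea": {"H": 0.70, "Q": 0.78, "E": 1.22},
}
HALO_EFFECTS: dict[str, dict[str, float]] = {
    "non-halophile": {},
    "halophile": {"E": 2.35, "D": 2.15, "K": 0.60, "F": 0.75, "Q": 0.85},
}
THERMO_EFFECTS: dict[str, dict[str, float]] = {
    "mesophile": {},
    "mesothermophile": {"V": 1.17, "Y": 1.18, "E": 1.14, "Q": 0.81},
    "thermophile": {"V": 1.38, "Y": 1.40, "E": 1.30, "Q": 0.65},
}

#: Median protein length by domain (residues); archaeal proteins are shorter.
LENGTH_LOG_MEAN = {"bacteria": math.log(300.0), "archaea": math.log(255.0)}
LENGTH_LOG_SD = 0.45
MIN_PROTEIN_LENGTH = 30


def make_label(domain: str, halophile: str, thermo: str) -> str:
    return f"{domain}|{halophile}|{thermo}"


def split_label(label: str) -> tuple[str, str, str]:
    """Parse a composite class label, tolerating partial labels (missing
    dimensions default to bacteria / non-halophile / mesophile)."""
    parts = label.split("|")
    domain, halo, thermo = "bacteria", "non-halophile", "mesophile"
    for p in parts:
        if p in DOMAIN_EFFECTS:
            domain = p
        elif p in HALO_EFFECTS:
            halo = p
        elif p in THERMO_EFFECTS:
            thermo = p
    return domain, halo, thermo


@dataclass(frozen=True)
class ClassEffectProfile:
    """Compositional and length effects for one class.

    composition_multipliers tilt the baseline frequencies multiplicatively
    (then renormalized); lengths are lognormal(length_log_mean,
    length_log_sd) truncated below at `MIN_PROTEIN_LENGTH` residues.
    """

    class_label: str
    composition_multipliers: dict[str, float]
    length_log_mean: float
    length_log_sd: float = LENGTH_LOG_SD
    proteins_per_organism: int = 300

    def __post_init__(self) -> None:
        bad = {aa: m for aa, m in self.composition_multipliers.items() if m <= 0}
        if bad:
            raise ValueError(f"multipliers must be strictly positive: {bad}")
        unknown = set(self.composition_multipliers) - set(CANONICAL_RESIDUES)
        if unknown:
            raise ValueError(f"unknown residues in multipliers: {sorted(unknown)}")
        if self.length_log_sd <= 0:
            raise ValueError("length_log_sd must be positive")
        if self.proteins_per_organism < 1:
            raise ValueError("proteins_per_organism must be >= 1")

    def tilted_frequencies(self, baseline: np.ndarray) -> np.ndarray:
        """Baseline frequencies tilted by the multipliers, renormalized to
        the simplex (sums to 1 within 1e-12)."""
        mult = np.ones(20)
        for aa, m in self.composition_multipliers.items():
            mult[AA_TO_INDEX[aa]] = m
        tilted = baseline * mult
        return tilted / tilted.sum()


def default_profiles(proteins_per_organism: int = 300) -> list[ClassEffectProfile]:
    """Effect profiles for every {domain} x {halophilicity} x {thermophilicity}
    combination, combining the per-dimension multipliers multiplicatively."""
    profiles = []
    for domain in ("bacteria", "archaea"):
        for halo in ("non-halophile", "halophile"):
            for thermo in ("mesophile", "mesothermophile", "thermophile"):
                mult: dict[str, float] = {}
                for effects in (DOMAIN_EFFECTS[domain], HALO_EFFECTS[halo], THERMO_EFFECTS[thermo]):
                    for aa, m in effects.items():
                        mult[aa] = mult.get(aa, 1.0) * m
                profiles.append(
                    ClassEffectProfile(
                        class_label=make_label(domain, halo, thermo),
                        composition_multipliers=mult,
                        length_log_mean=LENGTH_LOG_MEAN[domain],
                        proteins_per_organism=proteins_per_organism,
                    )
                )
    return profiles


@dataclass(frozen=True)
class SimulationConfig:
    """Dataset sizes, baseline composition, effect profiles and seed.

    organism_jitter_sd is the log-sd of the per-organism multiplicative
    frequency jitter (0 disables between-organism variation).
    """

    n_organisms_per_class: dict[str, int]
    effect_profiles: tuple[ClassEffectProfile, ...]
    seed: int
    baseline_frequencies: np.ndarray = field(
        default_factory=lambda: BASELINE_FREQUENCIES.copy()
    )
    organism_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        base = np.asarray(self.baseline_frequencies, dtype=float)
        if base.shape != (20,) or np.any(base < 0) or abs(base.sum() - 1.0) > 1e-9:
            raise ValueError("baseline_frequencies must be a nonnegative 20-vector summing to 1")
        have = {p.class_label for p in self.effect_profiles}
        missing = set(self.n_organisms_per_class) - have
        if missing:
            raise ConfigurationError(f"classes without an effect profile: {sorted(missing)}")
        if sum(self.n_organisms_per_class.values()) == 0:
            raise EmptyDatasetError("zero organisms requested")
        if any(n < 0 for n in self.n_organisms_per_class.values()):
            raise ValueError("negative organism count")

    def profile_for(self, label: str) -> ClassEffectProfile:
        for p in self.effect_profiles:
            if p.class_label == label:
                return p
        raise ConfigurationError(f"no profile for class {label!r}")


def default_config(case: str = "full", seed: int = 0, proteins_per_organism: int = 300,
                   n_per_class: int | None = None) -> SimulationConfig:
    """Desk-scale default configurations for each study design.

    Two-class cases use 32 organisms per class; the three-temperature-class
    case uses 32/16/16; ``full`` mixes labels so all three cases are
    represented.
    """
    b_nh_m = make_label("bacteria", "non-halophile", "mesophile")
    b_h_m = make_label("bacteria", "halophile", "mesophile")
    a_nh_m = make_label("archaea", "non-halophile", "mesophile")
    b_nh_mt = make_label("bacteria", "non-halophile", "mesothermophile")
    b_nh_t = make_label("bacteria", "non-halophile", "thermophile")
    a_nh_t = make_label("archaea", "non-halophile", "thermophile")
    n = n_per_class
    if case == "halophilicity":
        counts = {b_nh_m: n or 32, b_h_m: n or 32}
    elif case == "domain_of_life":
        counts = {b_nh_m: n or 32, a_nh_m: n or 32}
    elif case == "thermophilicity":
        counts = {b_nh_m: n or 32, b_nh_mt: (n or 32) // 2, b_nh_t: (n or 32) // 2}
    elif case == "full":
        m = n or 16
        counts = {
            b_nh_m: m, b_h_m: m, a_nh_m: m // 2, a_nh_t: m // 2,
            b_nh_mt: m // 2, b_nh_t: m // 2,
        }
    else:
        raise ValueError(f"unknown case {case!r}")
    return SimulationConfig(
        n_organisms_per_class=counts,
        effect_profiles=tuple(default_profiles(proteins_per_organism)),
        seed=seed,
    )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for parameter-recovery checks."""

    labels: dict[str, str]  # organism_id -> class label
    target_frequencies: dict[str, np.ndarray]  # class label -> 20-vector
    length_log_mean: dict[str, float]
    tilted_residues: dict[str, dict[str, float]]  # class -> residue -> multiplier

    def discriminative_residues(self, label_a: str, label_b: str, min_ratio: float = 1.05
                                ) -> dict[str, int]:
        """Residues whose target frequency differs between two classes by more
        than ``min_ratio`` (+1 if relatively enriched in ``label_a``, -1 if
        depleted). Ratios are divided by their median over the 20 residues,
        so the uniform depletion that simplex renormalization imposes on
        untilted residues does not register as an effect."""
        fa = self.target_frequencies[label_a]
        fb = self.target_frequencies[label_b]
        ratios = fa / fb
        rel = ratios / np.median(ratios)
        out: dict[str, int] = {}
        for aa, r in zip(CANONICAL_RESIDUES, rel):
            if r > min_ratio:
                out[aa] = 1
            elif r < 1.0 / min_ratio:
                out[aa] = -1
        return out


def _sample_growth_range(thermo: str, rng: np.random.Generator,
                         threshold: float = 55.0) -> tuple[float, float]:
    """Growth-temperature range consistent with the thermophilicity label,
    sampled uniformly inside the label's region so derivation code is
    exercised nontrivially."""
    if thermo == "mesophile":
        lo = rng.uniform(4.0, threshold - 15.0)
        hi = rng.uniform(lo + 5.0, threshold)
    elif thermo == "thermophile":
        lo = rng.uniform(threshold + 1.0, threshold + 25.0)
        hi = rng.uniform(lo + 5.0, threshold + 60.0)
    elif thermo == "mesothermophile":
        lo = rng.uniform(15.0, threshold)
        hi = rng.uniform(threshold + 1.0, threshold + 35.0)
    else:
        raise ValueError(f"unknown thermo class {thermo!r}")
    return round(lo, 1), round(hi, 1)


def _sample_lengths(profile: ClassEffectProfile, rng: np.random.Generator) -> np.ndarray:
    raw = rng.lognormal(profile.length_log_mean, profile.length_log_sd,
                        size=profile.proteins_per_organism)
    return np.maximum(np.rint(raw).astype(int), MIN_PROTEIN_LENGTH)


def _sample_proteome(freqs: np.ndarray, lengths: np.ndarray,
                     rng: np.random.Generator) -> list[str]:
    total = int(lengths.sum())
    residues = rng.choice(np.frombuffer(CANONICAL_RESIDUES.encode(), dtype="S1"),
                          size=total, p=freqs)
    blob = residues.tobytes().decode()
    seqs, pos = [], 0
    for ln in lengths:
        seqs.append(blob[pos:pos + ln])
        pos += ln
    return seqs


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[ProteomeRecord], pd.DataFrame, GroundTruth]:
    """Generate proteomes, manifest and ground truth.

    Fully reproducible given ``config.seed`` (byte-identical files on rerun).
    If ``out_dir`` is given, writes one FASTA per organism plus
    ``manifest.tsv`` and fills the manifest's ``fasta_path`` column.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteomeRecord] = []
    rows: list[dict] = []
    labels: dict[str, str] = {}
    target_freqs: dict[str, np.ndarray] = {}
    length_means: dict[str, float] = {}
    tilts: dict[str, dict[str, float]] = {}

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    counter = 0
    for label in sorted(config.n_organisms_per_class):
        n_org = config.n_organisms_per_class[label]
        profile = config.profile_for(label)
        domain, halo, thermo = split_label(label)
        class_freqs = profile.tilted_frequencies(np.asarray(config.baseline_frequencies))
        target_freqs[label] = class_freqs
        length_means[label] = profile.length_log_mean
        tilts[label] = dict(profile.composition_multipliers)
        slug = label.replace("|", ".").replace("non-halophile", "nonhalo").replace(
            "halophile", "halo").replace("mesothermophile", "mesothermo")
        for _ in range(n_org):
            counter += 1
            org_id = f"org{counter:04d}_{slug}"
            if config.organism_jitter_sd > 0:
                jitter = rng.lognormal(0.0, config.organism_jitter_sd, size=20)
                freqs = class_freqs * jitter
                freqs = freqs / freqs.sum()
            else:
                freqs = class_freqs
            lengths = _sample_lengths(profile, rng)
            seqs = _sample_proteome(freqs, lengths, rng)
            rec = ProteomeRecord(organism_id=org_id, sequences=seqs)
            records.append(rec)
            labels[org_id] = label
            t_lo, t_hi = _sample_growth_range(thermo, rng)
            fasta_path = ""
            if out_path is not None:
                fasta_path = f"{org_id}.fasta"
                write_fasta(rec, out_path / fasta_path)
            rows.append(
                {
                    "organism_id": org_id,
                    "domain": domain,
                    "temp_min": t_lo,
                    "temp_max": t_hi,
                    "halophile": halo,
                    "fasta_path": fasta_path,
                }
            )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.tsv")
    truth = GroundTruth(
        labels=labels,
        target_frequencies=target_freqs,
        length_log_mean=length_means,
        tilted_residues=tilts,
    )
    return records, manifest, truth
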