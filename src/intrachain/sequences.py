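"""Synuclein sequences, labeled constructs, and per-residue physico-chemical profiles.

The three human synucleins (alpha, beta, gamma) are bundled as wild-type
one-letter sequences.  Each dye-labeled construct is a ~25-residue segment
delimited by the two residues that are mutated to cysteine for labeling;
property calculations below always use the wild-type segment inclusive of
both endpoints.

Per-residue scores:

* **Zimmerman bulkiness** — steric bulk of the side chain.  Reported here
  normalized to the glycine value (3.40), so poly-glycine scores 1.0.
* **Kyte–Doolittle hydropathy** — mean raw scale value per residue.
* **Net charge per residue** — Henderson–Hasselbalch side-chain charges at a
  given pH, summed over the segment and divided by its length.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio import SeqIO

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

#: Canonical lengths of the wild-type human synucleins.
SYNUCLEIN_LENGTHS = {"alphaS": 140, "betaS": 134, "gammaS": 127}

#: Zimmerman steric bulkiness scale (arbitrary units; glycine = 3.40).
ZIMMERMAN_BULKINESS = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
    "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
}

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9,
    "A": 1.8, "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3,
    "P": -1.6, "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5,
    "K": -3.9, "R": -4.5,
}


class SequenceError(ValueError):
    """Unknown protein, construct, or residue letter."""


@dataclass(frozen=True)
class ProteinRecord:
    """A wild-type synuclein sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError("empty sequence")
        bad = set(self.sequence) - AA_LETTERS
        if bad:
            raise SequenceError(f"non-canonical residue letters: {sorted(bad)}")
        expected = SYNUCLEIN_LENGTHS.get(self.protein_id)
        if expected is not None and len(self.sequence) != expected:
            raise SequenceError(
                f"{self.protein_id}: expected {expected} residues, got {len(self.sequence)}"
            )


@dataclass(frozen=True)
class ConstructDef:
    """A labeled segment: residues ``start``..``end`` (1-based, inclusive).

    The two endpoint residues are the positions mutated to cysteine for dye
    attachment in the experimental constructs.
    """

    protein_id: str
    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise SequenceError(f"invalid range {self.start}..{self.end}")

    @property
    def label_positions(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ResidueScale:
    """A per-residue scale with an optional divisor applied to the mean."""

    name: str
    values: dict
    normalizer: float = 1.0

    def __post_init__(self) -> None:
        missing = AA_LETTERS - set(self.values)
        if missing:
            raise SequenceError(f"scale {self.name} missing letters: {sorted(missing)}")


BULKINESS = ResidueScale("bulkiness", ZIMMERMAN_BULKINESS, normalizer=3.40)
HYDROPHOBICITY = ResidueScale("hydrophobicity", KYTE_DOOLITTLE, normalizer=1.0)


@dataclass(frozen=True)
class ChargeModel:
    """Side-chain pKa set for Henderson–Hasselbalch net-charge estimates.

    Defaults are standard free-side-chain values; chain termini are excluded
    by default because segment charge here refers to an internal stretch of
    a full-length protein.
    """

    pka: dict = field(default_factory=lambda: {
        "D": 3.65, "E": 4.25, "H": 6.00, "C": 8.30,
        "Y": 10.07, "K": 10.53, "R": 12.48,
    })
    include_termini: bool = False
    pka_nterm: float = 9.00
    pka_cterm: float = 3.55

    ACIDIC = frozenset("DECY")
    BASIC = frozenset("HKR")

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.pka.values()):
            raise SequenceError("pKa values must be positive")

    def residue_charge(self, letter: str, ph: float) -> float:
        pka = self.pka.get(letter)
        if pka is None:
            return 0.0
        if letter in self.ACIDIC:
            return -1.0 / (1.0 + 10.0 ** (pka - ph))
        return 1.0 / (1.0 + 10.0 ** (ph - pka))


def _data_path(name: str):
    return importlib.resources.files("intrachain.data") / name


@lru_cache(maxsize=1)
def load_proteins() -> dict:
    """Bundled wild-type synuclein records keyed by protein_id."""
    records = {}
    with importlib.resources.as_file(_data_path("synucleins.fasta")) as path:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = ProteinRecord(rec.id, str(rec.seq))
    return records


@lru_cache(maxsize=1)
def load_constructs() -> dict:
    """Bundled construct definitions keyed by (protein_id, label)."""
    with importlib.resources.as_file(_data_path("constructs.csv")) as path:
        table = pd.read_csv(path)
    return {
        (row.protein_id, row.label): ConstructDef(row.protein_id, row.label,
                                                  int(row.start), int(row.end))
        for row in table.itertuples()
    }


def get_segment(protein_id: str, construct_label: str) -> str:
    """Wild-type residues of a construct, endpoints included."""
    proteins = load_proteins()
    if protein_id not in proteins:
        raise SequenceError(f"unknown protein {protein_id!r}")
    construct = load_constructs().get((protein_id, construct_label))
    if construct is None:
        raise SequenceError(f"construct {construct_label!r} not defined for {protein_id}")
    seq = proteins[protein_id].sequence
    if construct.end > len(seq):
        raise SequenceError("construct range exceeds protein length")
    return seq[construct.start - 1:construct.end]


def percent_identity(segment_a: str, segment_b: str) -> int:
    """Ungapped position-wise identity between equal-length segments, in percent.

    Rounded to the nearest integer percent.  Homologous ranges must be
    supplied at equal length; no alignment is performed.
    """
    if len(segment_a) != len(segment_b):
        raise SequenceError(
            "segments differ in length; supply equal-length homologous ranges "
            "(ungapped position-wise comparison)"
        )
    if not segment_a:
        raise SequenceError("empty segments")
    matches = sum(a == b for a, b in zip(segment_a, segment_b))
    return round(100.0 * matches / len(segment_a))


def mean_scale(segment: str, scale: ResidueScale) -> float:
    """Mean scale value per residue, divided by the scale's normalizer."""
    if not segment:
        raise SequenceError("empty segment")
    total = 0.0
    for letter in segment:
        if letter not in scale.values:
            raise SequenceError(f"residue {letter!r} not covered by scale {scale.name}")
        total += scale.values[letter]
    return (total / len(segment)) / scale.normalizer


def charge_per_residue(segment: str, ph: float,
                       charge_model: ChargeModel | None = None) -> tuple[float, float]:
    """(net, \\|net\\|) charge per residue of a segment at the given pH."""
    if not (0.0 < ph < 14.0):
        raise SequenceError(f"pH {ph} outside (0, 14)")
    if not segment:
        raise SequenceError("empty segment")
    bad = set(segment) - AA_LETTERS
    if bad:
        raise SequenceError(f"non-canonical residue letters: {sorted(bad)}")
    model = charge_model or ChargeModel()
    net = sum(model.residue_charge(letter, ph) for letter in segment)
    if model.include_termini:
        net += 1.0 / (1.0 + 10.0 ** (ph - model.pka_nterm))
        net += -1.0 / (1.0 + 10.0 ** (model.pka_cterm - ph))
    per = net / len(segment)
    return per, abs(per)


def construct_properties(protein_id: str, construct_label: str, ph: float = 7.4,
                         charge_model: ChargeModel | None = None) -> dict:
    """All per-residue properties of one construct at one pH, as a flat dict."""
    segment = get_segment(protein_id, construct_label)
    net, absolute = charge_per_residue(segment, ph, charge_model)
    return {
        "protein_id": protein_id,
        "construct": construct_label,
        "ph": ph,
        "n_residues": len(segment),
        "net_charge_per_residue": net,
        "abs_charge_per_residue": absolute,
        "bulkiness_per_residue": mean_scale(segment, BULKINESS),
        "hydrophobicity_per_residue": mean_scale(segment, HYDROPHOBICITY),
    }
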