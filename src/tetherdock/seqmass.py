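"""Construct sequence properties, tryptic digestion, and cross-linked peptide masses.

Covers the in-silico protein chemistry of the study pipeline: molecular
weight (average and monoisotopic), the 280 nm extinction coefficient by
Trp/Tyr/cystine increments, the isoelectric point under the Bjellqvist
charge model, trypsin digestion with missed cleavages, and the theoretical
mass / m-over-z of a cross-linker-bridged tryptic peptide pair (with fixed
carbamidomethylation of non-bridged cysteines).

Construct helpers encode the two purified constructs of the study:

* DID: residues 142-380 of human DIAPH1 (UniProt O60610) behind the
  expression tag ``MGSSERSHHHHHHSGSE``;
* cytosolic MFN2: human MFN2 (UniProt O95140) with residues 1-19 and
  401-705 deleted (GTPase + HD1/2 domains).

Full-length parent sequences are supplied by the caller (e.g. downloaded
once from UniProt as FASTA); they are not bundled.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "ProteinConstruct",
    "SequenceProperties",
    "Peptide",
    "CrossLinkedPeptidePair",
    "sequence_properties",
    "isoelectric_point",
    "net_charge",
    "tryptic_peptides",
    "peptides_covering",
    "crosslinked_pair_mass",
    "ng_to_pmol",
    "read_fasta",
    "DID_TAG",
    "did_domain",
    "did_construct",
    "mfn2_domain",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
PROTON_MASS = 1.007276  # Da, monoisotopic
CARBAMIDOMETHYL = 57.02146  # Da, fixed Cys modification (iodoacetamide)

#: N-terminal expression/purification tag of the DID construct
DID_TAG = "MGSSERSHHHHHHSGSE"

# Bjellqvist pKa set as used by the ExPASy ProtParam tool: side chains plus
# residue-specific terminal pKa values.
_PK_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
_PK_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PK_NTERM_DEFAULT = 7.5
_PK_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_PK_CTERM_DEFAULT = 3.55
_PK_CTERM = {"D": 4.55, "E": 4.75}

_EPS_TRP = 5500.0
_EPS_TYR = 1490.0
_EPS_CYSTINE = 125.0


def _check_sequence(seq: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    for i, aa in enumerate(seq, start=1):
        if aa not in VALID_AA:
            raise ValueError(f"invalid amino acid {aa!r} at position {i}")
    return seq


@dataclasses.dataclass(frozen=True)
class ProteinConstruct:
    """A (possibly tagged or spliced) protein construct sequence.

    ``parent_numbers`` maps each construct position (0-based index) to the
    residue number in the parent protein's numbering; tag residues carry
    number 0.  For contiguous constructs it is derived from
    ``numbering_offset`` (position 1 -> offset + 1).
    """

    name: str
    sequence: str
    numbering_offset: int = 0
    parent_numbers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence))
        if self.parent_numbers is not None and len(self.parent_numbers) != len(self.sequence):
            raise ValueError("parent_numbers length must match sequence length")

    def numbers(self) -> tuple[int, ...]:
        if self.parent_numbers is not None:
            return self.parent_numbers
        return tuple(self.numbering_offset + i for i in range(1, len(self.sequence) + 1))

    def position_of(self, parent_number: int) -> int:
        """1-based construct position of a parent residue number."""
        try:
            return self.numbers().index(parent_number) + 1
        except ValueError:
            raise KeyError(f"parent residue {parent_number} not in construct {self.name}")

    def residue_at(self, parent_number: int) -> str:
        return self.sequence[self.position_of(parent_number) - 1]


@dataclasses.dataclass(frozen=True)
class SequenceProperties:
    mw_average: float
    mw_monoisotopic: float
    eps280_reduced: float
    eps280_cystine: float
    pI: float


@dataclasses.dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide; ``start``/``end`` are 1-based inclusive
    positions in the parent sequence."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end before start")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("span inconsistent with sequence length")

    @property
    def mass_mono(self) -> float:
        return float(_pmass.fast_mass(self.sequence))


@dataclasses.dataclass(frozen=True)
class CrossLinkedPeptidePair:
    pepA: Peptide
    pepB: Peptide
    linker_name: str
    fixed_mod_mass: float
    mass_mono: float

    def mz(self, z: int) -> float:
        return (self.mass_mono + z * PROTON_MASS) / z

    @property
    def mz_table(self) -> dict[int, float]:
        return {z: self.mz(z) for z in (1, 2, 3, 4)}


# ---------------------------------------------------------------------------
# Properties


def molecular_weight(sequence: str, average: bool = True) -> float:
    """Protein MW in Da (residue masses + one water)."""
    seq = _check_sequence(sequence)
    return float(_pmass.calculate_mass(sequence=seq, average=average))


def extinction_280(sequence: str) -> tuple[float, float]:
    """(reduced, all-cystine) molar extinction coefficients at 280 nm.

    Increments: Trp 5500, Tyr 1490, cystine 125 M^-1 cm^-1; under the
    cystine convention every cysteine pair is assumed disulfide-bonded.
    """
    seq = _check_sequence(sequence)
    w, y, c = seq.count("W"), seq.count("Y"), seq.count("C")
    reduced = _EPS_TRP * w + _EPS_TYR * y
    return reduced, reduced + _EPS_CYSTINE * (c // 2)


def net_charge(sequence: str, pH: float) -> float:
    """Net charge under the Bjellqvist fixed-pKa model at a given pH."""
    seq = _check_sequence(sequence)
    pos = [(_PK_NTERM.get(seq[0], _PK_NTERM_DEFAULT), 1)]
    neg = [(_PK_CTERM.get(seq[-1], _PK_CTERM_DEFAULT), 1)]
    for aa, pk in _PK_POSITIVE.items():
        n = seq.count(aa)
        if n:
            pos.append((pk, n))
    for aa, pk in _PK_NEGATIVE.items():
        n = seq.count(aa)
        if n:
            neg.append((pk, n))
    charge = sum(n / (1.0 + 10.0 ** (pH - pk)) for pk, n in pos)
    charge -= sum(n / (1.0 + 10.0 ** (pk - pH)) for pk, n in neg)
    return charge


def isoelectric_point(sequence: str, tol: float = 0.01) -> float:
    """pH of zero net charge, found by bisection on [0, 14].

    The termini are always ionizable, so the charge is strictly decreasing
    in pH and a unique root exists.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol / 10.0:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 4)


def sequence_properties(construct: ProteinConstruct | str) -> SequenceProperties:
    """MW (both conventions), extinction coefficients, and pI of a construct."""
    seq = construct.sequence if isinstance(construct, ProteinConstruct) else construct
    reduced, cystine = extinction_280(seq)
    return SequenceProperties(
        mw_average=molecular_weight(seq, average=True),
        mw_monoisotopic=molecular_weight(seq, average=False),
        eps280_reduced=reduced,
        eps280_cystine=cystine,
        pI=isoelectric_point(seq),
    )


def ng_to_pmol(mass_ng: float, construct: ProteinConstruct | str) -> float:
    """Convert a protein mass in ng to pmol using the average MW."""
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    seq = construct.sequence if isinstance(construct, ProteinConstruct) else construct
    return mass_ng / molecular_weight(seq, average=True) * 1000.0


# ---------------------------------------------------------------------------
# Digestion


def tryptic_peptides(sequence: str, max_missed: int = 0) -> list[Peptide]:
    """Tryptic digest: cleave C-terminal to K/R except before P.

    Returns every peptide with at most ``max_missed`` internal missed
    cleavage sites, ordered by start position then length.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = _check_sequence(sequence)
    # cleavage points: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(1, len(seq)):
        if seq[i - 1] in "KR" and seq[i] != "P":
            cuts.append(i)
    cuts.append(len(seq))
    out: list[Peptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 1 + max_missed + 1, len(cuts))):
            start, end = cuts[i], cuts[j]
            out.append(
                Peptide(
                    sequence=seq[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def peptides_covering(
    construct: ProteinConstruct, parent_resnum: int, max_missed: int = 2
) -> list[Peptide]:
    """Tryptic peptides of a construct that span a given parent residue."""
    pos = construct.position_of(parent_resnum)
    return [
        p for p in tryptic_peptides(construct.sequence, max_missed)
        if p.start <= pos <= p.end
    ]


# ---------------------------------------------------------------------------
# Cross-linked peptide masses


def _crosslink_site(pep: Peptide, end_chemistry: str) -> int:
    """Position (1-based within peptide) of the linker-reactive residue.

    Amine ends react with lysine side chains (a C-terminal tryptic K is the
    cleaved site, not a bridged one, so it is excluded unless it is the only
    K); sulfhydryl ends react with cysteine.
    """
    if end_chemistry == "amine":
        ks = [i + 1 for i, aa in enumerate(pep.sequence) if aa == "K"]
        internal = [i for i in ks if i != len(pep.sequence)]
        candidates = internal or ks
    elif end_chemistry == "sulfhydryl":
        candidates = [i + 1 for i, aa in enumerate(pep.sequence) if aa == "C"]
    else:
        raise ValueError(f"unknown end chemistry {end_chemistry!r}")
    if len(candidates) != 1:
        raise ValueError(
            f"peptide {pep.sequence} must contain exactly one reactive residue "
            f"for a {end_chemistry} linker end, found {len(candidates)}"
        )
    return candidates[0]


def crosslinked_pair_mass(
    pepA: Peptide,
    pepB: Peptide,
    linker,
    carbamidomethyl: bool = True,
) -> CrossLinkedPeptidePair:
    """Theoretical monoisotopic mass of a linker-bridged tryptic peptide pair.

    mass = mono(pepA) + mono(pepB) + bridge + fixed modifications, where the
    bridge is the linker reagent minus both leaving groups.  With
    ``carbamidomethyl`` every cysteine except a sulfhydryl-bridged one
    carries +57.02146 Da.
    """
    endA, endB = linker.end_chemistry
    # try both end orderings for heterobifunctional linkers
    try:
        siteA = _crosslink_site(pepA, endA)
        siteB = _crosslink_site(pepB, endB)
    except ValueError:
        siteA = _crosslink_site(pepA, endB)
        siteB = _crosslink_site(pepB, endA)
        endA, endB = endB, endA
    n_cys = pepA.sequence.count("C") + pepB.sequence.count("C")
    bridged_cys = int(endA == "sulfhydryl") + int(endB == "sulfhydryl")
    mod_mass = CARBAMIDOMETHYL * max(0, n_cys - bridged_cys) if carbamidomethyl else 0.0
    total = pepA.mass_mono + pepB.mass_mono + linker.bridge_mass_mono + mod_mass
    return CrossLinkedPeptidePair(
        pepA=pepA,
        pepB=pepB,
        linker_name=linker.name,
        fixed_mod_mass=mod_mass,
        mass_mono=total,
    )


# ---------------------------------------------------------------------------
# Construct definitions and FASTA input


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence} (Bio.SeqIO)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def did_domain(full_diaph1: str) -> ProteinConstruct:
    """Untagged DID domain: DIAPH1 residues 142-380 (UniProt numbering)."""
    seq = _check_sequence(full_diaph1)
    if len(seq) < 380:
        raise ValueError("full-length DIAPH1 sequence required (>= 380 residues)")
    return ProteinConstruct("DID", seq[141:380], numbering_offset=141)


def did_construct(full_diaph1: str) -> ProteinConstruct:
    """Expressed DID construct: N-terminal tag + DIAPH1 142-380."""
    dom = did_domain(full_diaph1)
    numbers = tuple([0] * len(DID_TAG)) + dom.numbers()
    return ProteinConstruct(
        "DID_tagged", DID_TAG + dom.sequence, parent_numbers=numbers
    )


def mfn2_domain(full_mfn2: str) -> ProteinConstruct:
    """Cytosolic MFN2 construct body: residues 20-400 + 706-end (1-19 and
    401-705 deleted), GTPase plus helical domains."""
    seq = _check_sequence(full_mfn2)
    if len(seq) < 706:
        raise ValueError("full-length MFN2 sequence required (>= 706 residues)")
    part1 = seq[19:400]
    part2 = seq[705:]
    numbers = tuple(range(20, 401)) + tuple(range(706, len(seq) + 1))
    return ProteinConstruct("MFN2_cytosolic", part1 + part2, parent_numbers=numbers)
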