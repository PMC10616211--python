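"""Cross-linker chemistry, cross-link records, and distance restraints.

A chemical cross-linker covalently bridges two reactive side chains; the
spacer arm length bounds the through-space distance of the bridged residue
pair and becomes the upper bound of an *unambiguous interaction restraint*
(UIR).  Interface residue lists (e.g. from an NMR-mapped binding surface)
become *ambiguous interaction restraints* (AIRs) evaluated with the usual
r^-6-pooled effective distance.

A docked model "follows" a restraint when its violation does not exceed the
bound correction (default 5.0 A), inclusive at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy.spatial.distance import cdist

from .structio import AtomSelection, Structure

__all__ = [
    "CrossLinker",
    "CrossLink",
    "DistanceRestraint",
    "ViolationReport",
    "builtin_linkers",
    "uirs_from_crosslinks",
    "airs_from_actives",
    "effective_distance",
    "evaluate_restraints",
    "read_crosslinks_csv",
    "write_crosslinks_csv",
    "read_restraints_tsv",
    "write_restraints_tsv",
]

AMINE = "amine"
SULFHYDRYL = "sulfhydryl"

#: residue types reactive toward each end chemistry
_REACTIVE_AA = {AMINE: {"K"}, SULFHYDRYL: {"C"}}
#: side-chain atom carrying the reactive group
_REACTIVE_ATOM = {("K", AMINE): "NZ", ("C", SULFHYDRYL): "SG"}

class ChemistryError(ValueError):
    """Cross-link residue chemistry incompatible with the linker ends."""


@dataclasses.dataclass(frozen=True)
class CrossLinker:
    """A bifunctional cross-linking reagent.

    ``spacer`` is the spacer arm length in Angstrom (the maximal
    through-linker distance between the two reactive atoms).
    ``bridge_formula`` is the net elemental composition added to the mass of
    the two bridged peptides (reagent minus both leaving groups).
    """

    name: str
    end_chemistry: tuple[str, str]
    spacer: float
    bridge_formula: str

    def __post_init__(self) -> None:
        if self.spacer <= 0:
            raise ValueError("spacer must be positive")
        for end in self.end_chemistry:
            if end not in (AMINE, SULFHYDRYL):
                raise ValueError(f"unknown end chemistry {end!r}")
        if self.bridge_mass_mono > self.bridge_mass_avg + 0.5:
            raise ValueError("monoisotopic bridge mass exceeds average + 0.5 Da")

    @property
    def bridge_mass_mono(self) -> float:
        return float(_pmass.calculate_mass(formula=self.bridge_formula))

    @property
    def bridge_mass_avg(self) -> float:
        return float(_pmass.calculate_mass(formula=self.bridge_formula, average=True))

    @property
    def homobifunctional(self) -> bool:
        return self.end_chemistry[0] == self.end_chemistry[1]


def builtin_linkers() -> dict[str, CrossLinker]:
    """The seven reagents of the cross-linking panel, keyed by name.

    Amine-to-amine: DSG 7.7, BS3 11.4, BS(PEG)5 21.7, BS(PEG)9 35.8 A.
    Amine-to-sulfhydryl: KMUS 16.3, SMCC 8.3, SMPB 11.6 A.
    Bridge formulas are the parent di-acid (NHS esters) or maleimido acid
    minus the water lost on amide/thioether formation.
    """
    defs = [
        ("DSG", (AMINE, AMINE), 7.7, "C5H4O2"),
        ("BS3", (AMINE, AMINE), 11.4, "C8H10O2"),
        ("BS(PEG)5", (AMINE, AMINE), 21.7, "C14H22O7"),
        ("BS(PEG)9", (AMINE, AMINE), 35.8, "C22H38O11"),
        ("KMUS", (AMINE, SULFHYDRYL), 16.3, "C15H21NO3"),
        ("SMCC", (AMINE, SULFHYDRYL), 8.3, "C12H13NO3"),
        ("SMPB", (AMINE, SULFHYDRYL), 11.6, "C14H11NO3"),
    ]
    return {name: CrossLinker(name, chem, spacer, formula) for name, chem, spacer, formula in defs}


@dataclasses.dataclass(frozen=True)
class CrossLink:
    """An identified residue-pair cross-link between two proteins.

    Residues are given in the numbering of the protein they belong to;
    ``aaA``/``aaB`` are one-letter codes (``K``, ``C``) or ``"nterm"`` for a
    protein N-terminus.  ``decoy`` marks simulated false-positive
    identifications.
    """

    proteinA: str
    residueA: int
    aaA: str
    proteinB: str
    residueB: int
    aaB: str
    linker: str
    decoy: bool = False

    def validate_chemistry(self, linker: CrossLinker) -> tuple[str, str]:
        """Check residue/end compatibility; return the two end chemistries
        in (A, B) order.  Raises :class:`ChemistryError` on mismatch."""

        def compatible(aa: str, end: str) -> bool:
            if aa == "nterm":
                return end == AMINE
            return aa in _REACTIVE_AA[end]

        e1, e2 = linker.end_chemistry
        if compatible(self.aaA, e1) and compatible(self.aaB, e2):
            return e1, e2
        if compatible(self.aaA, e2) and compatible(self.aaB, e1):
            return e2, e1
        raise ChemistryError(
            f"{self.linker} ({'-'.join(linker.end_chemistry)}) cannot bridge "
            f"{self.aaA}{self.residueA} and {self.aaB}{self.residueB}"
        )


@dataclasses.dataclass(frozen=True)
class DistanceRestraint:
    """A distance bound between two atom selections.

    UIRs are evaluated as the minimum reactive-atom distance; AIRs as the
    r^-6 effective distance over all atom pairs.  ``symmetry_group`` ties
    together the symmetry-equivalent copies of one experimental restraint:
    in grouped (ambiguous-copy) evaluation a restraint group is followed when
    its best copy is.
    """

    kind: str                      # "UIR" | "AIR"
    selA: AtomSelection
    selB: AtomSelection
    lower: float = 0.0
    upper: float = 0.0
    correction: float = 5.0
    symmetry_group: str = ""
    rid: str = ""
    #: extra slack added to the upper bound when a side falls back to CA
    fallback_slack: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("UIR", "AIR"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.upper < self.lower:
            raise ValueError("upper bound below lower bound")


@dataclasses.dataclass
class RestraintRecord:
    rid: str
    kind: str
    symmetry_group: str
    distance: float
    violation: float
    followed: bool


@dataclasses.dataclass
class ViolationReport:
    """Per-restraint distances/violations plus summary counts.

    ``records`` lists every restraint copy separately.  ``grouped_followed``
    summarizes symmetry groups with the permissive any-copy rule.
    """

    records: list[RestraintRecord]
    correction: float

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_followed(self) -> int:
        return sum(r.followed for r in self.records)

    def grouped_followed(self) -> dict[str, bool]:
        out: dict[str, bool] = {}
        for r in self.records:
            key = r.symmetry_group or r.rid
            out[key] = out.get(key, False) or r.followed
        return out

    def to_dict(self) -> dict:
        return {
            "correction": self.correction,
            "n_total": self.n_total,
            "n_followed": self.n_followed,
            "records": [dataclasses.asdict(r) for r in self.records],
            "groups_followed": self.grouped_followed(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# Restraint generation


def _reactive_selection(chain: str, resnum: int, aa: str, end: str) -> AtomSelection:
    """Selection for the reactive atom of one cross-linked residue.

    Falls back to CA when the side-chain atom is absent (coarse models);
    evaluation then widens the bound by ``fallback_slack`` per side.
    """
    if aa == "nterm":
        atom = "N"
    else:
        atom = _REACTIVE_ATOM[(aa, end)]
    return AtomSelection(
        chains=frozenset({chain}),
        residues=frozenset({resnum}),
        atoms=frozenset({atom}),
        fallback_atoms=frozenset({"CA"}),
    )


def uirs_from_crosslinks(
    links: Sequence[CrossLink],
    assembly: Mapping[str, Sequence[str]],
    correction: float = 5.0,
    linkers: Mapping[str, CrossLinker] | None = None,
    fallback_slack: float = 1.0,
) -> list[DistanceRestraint]:
    """Expand cross-links into UIRs over all symmetry-equivalent chain pairs.

    ``assembly`` maps each protein name to the chain ids of its copies in
    the docked assembly.  When both proteins have the same copy number the
    copies are paired in register (copy i of A with copy i of B): under the
    assembly's exact symmetry the off-register pairings describe the same
    physical restraint with the copy labels swapped, and admitting them as
    alternatives would let one copy satisfy different links against
    different partners (unphysical bridging).  With unequal copy numbers
    every pairing is generated.  All restraints of one link share a
    ``symmetry_group`` (grouped evaluation is satisfied through any copy).
    The upper bound of every restraint equals the linker's spacer arm
    length exactly; the lower bound is 0.
    """
    linkers = linkers or builtin_linkers()
    out: list[DistanceRestraint] = []
    for li, link in enumerate(links):
        if link.linker not in linkers:
            raise KeyError(f"unknown linker {link.linker!r}")
        lk = linkers[link.linker]
        endA, endB = link.validate_chemistry(lk)
        if link.proteinA not in assembly or link.proteinB not in assembly:
            raise KeyError(f"link proteins {link.proteinA}/{link.proteinB} not in assembly map")
        chainsA = list(assembly[link.proteinA])
        chainsB = list(assembly[link.proteinB])
        if len(chainsA) == len(chainsB):
            pairings = list(zip(chainsA, chainsB))
        else:
            pairings = [(ca, cb) for ca in chainsA for cb in chainsB]
        for ca, cb in pairings:
                group = f"L{li}"
                out.append(
                    DistanceRestraint(
                        kind="UIR",
                        selA=_reactive_selection(ca, link.residueA, link.aaA, endA),
                        selB=_reactive_selection(cb, link.residueB, link.aaB, endB),
                        lower=0.0,
                        upper=lk.spacer,
                        correction=correction,
                        symmetry_group=group,
                        rid=f"L{li}.{ca}{link.residueA}-{cb}{link.residueB}",
                        fallback_slack=fallback_slack,
                    )
                )
    return out


def airs_from_actives(
    activesA: Sequence[tuple[str, int]],
    activesB: Sequence[tuple[str, int]],
    upper: float = 2.0,
    correction: float = 5.0,
    both_sides: bool = False,
) -> list[DistanceRestraint]:
    """One AIR per active residue of side A against all active atoms of B.

    With ``both_sides`` the symmetric B-anchored restraints are added too.
    """
    if not activesA or not activesB:
        raise ValueError("active residue lists must be non-empty")

    def union_sel(actives: Sequence[tuple[str, int]]) -> list[AtomSelection]:
        return [
            AtomSelection(chains=frozenset({c}), residues=frozenset({r}))
            for c, r in actives
        ]

    def one_side(anchor: Sequence[tuple[str, int]], other: Sequence[tuple[str, int]],
                 tag: str) -> list[DistanceRestraint]:
        other_chains = frozenset(c for c, _ in other)
        other_res = frozenset(r for _, r in other)
        target = AtomSelection(chains=other_chains, residues=other_res)
        result = []
        for c, r in anchor:
            result.append(
                DistanceRestraint(
                    kind="AIR",
                    selA=AtomSelection(chains=frozenset({c}), residues=frozenset({r})),
                    selB=target,
                    lower=0.0,
                    upper=upper,
                    correction=correction,
                    symmetry_group=f"A{tag}.{c}{r}",
                    rid=f"A{tag}.{c}{r}",
                )
            )
        return result

    out = one_side(activesA, activesB, "a")
    if both_sides:
        out += one_side(activesB, activesA, "b")
    return out


# ---------------------------------------------------------------------------
# Evaluation


def effective_distance(coordsA: np.ndarray, coordsB: np.ndarray) -> float:
    """Ambiguous-restraint effective distance ``(sum d_ij^-6)^(-1/6)``.

    Always less than or equal to the minimum pair distance; coincident atoms
    give 0.
    """
    A = np.asarray(coordsA, dtype=float).reshape(-1, 3)
    B = np.asarray(coordsB, dtype=float).reshape(-1, 3)
    if A.size == 0 or B.size == 0:
        raise ValueError("empty coordinate group")
    d = cdist(A, B)
    if (d == 0).any():
        return 0.0
    with np.errstate(over="ignore"):
        inv6 = (d ** -6).sum()
    if np.isinf(inv6):
        return 0.0
    return float(inv6 ** (-1.0 / 6.0))


def measure_restraint(s: Structure, r: DistanceRestraint) -> tuple[float, float]:
    """Measured distance and the effective upper bound for one restraint.

    For UIRs the distance is the minimum reactive-atom distance; a CA
    fallback on either side widens the upper bound by ``fallback_slack``
    per side.  For AIRs the distance is the r^-6 effective distance.
    """
    a = r.selA.resolve(s)
    b = r.selB.resolve(s)
    if r.kind == "AIR":
        return effective_distance(s.xyz[a], s.xyz[b]), r.upper
    d = float(cdist(s.xyz[a], s.xyz[b]).min())
    upper = r.upper
    upper += r.fallback_slack * (r.selA.used_fallback(s) + r.selB.used_fallback(s))
    return d, upper


def evaluate_restraints(
    s: Structure,
    restraints: Sequence[DistanceRestraint],
    correction: float = 5.0,
) -> ViolationReport:
    """Measure every restraint against assembly coordinates.

    violation = max(0, d - upper, lower - d); a restraint is *followed* when
    violation <= correction (inclusive, encoding the "at or below" rule).
    """
    records: list[RestraintRecord] = []
    for i, r in enumerate(restraints):
        try:
            d, upper = measure_restraint(s, r)
        except Exception as exc:
            raise ValueError(f"restraint {r.rid or i}: {exc}") from exc
        violation = max(0.0, d - upper, r.lower - d)
        records.append(
            RestraintRecord(
                rid=r.rid or f"r{i}",
                kind=r.kind,
                symmetry_group=r.symmetry_group,
                distance=d,
                violation=violation,
                followed=violation <= correction,
            )
        )
    return ViolationReport(records=records, correction=correction)


# ---------------------------------------------------------------------------
# File dialects


_LINK_COLS = [
    "protein", "residue_number", "residue_aa",
    "protein2", "residue_number2", "residue_aa2", "linker", "decoy",
]


def write_crosslinks_csv(links: Sequence[CrossLink], path: str | Path) -> None:
    rows = [
        (l.proteinA, l.residueA, l.aaA, l.proteinB, l.residueB, l.aaB, l.linker, l.decoy)
        for l in links
    ]
    pd.DataFrame(rows, columns=_LINK_COLS).to_csv(path, index=False)


def read_crosslinks_csv(path: str | Path) -> list[CrossLink]:
    df = pd.read_csv(path)
    if "decoy" not in df.columns:
        df["decoy"] = False
    return [
        CrossLink(
            proteinA=str(r.protein), residueA=int(r.residue_number), aaA=str(r.residue_aa),
            proteinB=str(r.protein2), residueB=int(r.residue_number2), aaB=str(r.residue_aa2),
            linker=str(r.linker), decoy=bool(r.decoy),
        )
        for r in df.itertuples()
    ]


def _sel_fields(sel: AtomSelection) -> tuple[str, str, str]:
    chain = sorted(sel.chains)[0] if sel.chains else ""
    res = ",".join(str(x) for x in sorted(sel.residues)) if sel.residues else ""
    atom = ",".join(sorted(sel.atoms)) if sel.atoms else "*"
    return chain, res, atom


def write_restraints_tsv(restraints: Sequence[DistanceRestraint], path: str | Path) -> None:
    rows = []
    for r in restraints:
        ca, ra, aa = _sel_fields(r.selA)
        cb, rb, ab = _sel_fields(r.selB)
        rows.append((r.kind, ca, ra, aa, cb, rb, ab, r.lower, r.upper, r.symmetry_group))
    pd.DataFrame(
        rows,
        columns=["kind", "chainA", "resA", "atomA", "chainB", "resB", "atomB",
                 "lower", "upper", "group"],
    ).to_csv(path, sep="\t", index=False)


def read_restraints_tsv(path: str | Path) -> list[DistanceRestraint]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for i, r in df.iterrows():
        def sel(chain, res, atom):
            atoms = None if atom in ("*", "", None) or pd.isna(atom) else frozenset(str(atom).split(","))
            residues = frozenset(int(x) for x in str(res).split(",")) if not pd.isna(res) else None
            return AtomSelection(
                chains=frozenset({str(chain)}),
                residues=residues,
                atoms=atoms,
                fallback_atoms=frozenset({"CA"}) if atoms else None,
            )
        out.append(
            DistanceRestraint(
                kind=str(r["kind"]),
                selA=sel(r["chainA"], r["resA"], r["atomA"]),
                selB=sel(r["chainB"], r["resB"], r["atomB"]),
                lower=float(r["lower"]),
                upper=float(r["upper"]),
                symmetry_group=str(r["group"]),
                rid=f"r{i}",
            )
        )
    return out
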