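"""Structure I/O and rigid-body geometry.

Thin array-based view over PDB coordinate files (parsed with gemmi) plus the
geometric primitives the restraint and docking layers are built on: atom
selections, cross-set distances, contact-based interface detection, and
Kabsch least-squares superposition.

Conventions
-----------
* Residue numbering is preserved verbatim from the input file; callers that
  need UniProt numbering apply a per-chain integer offset themselves.
* Distances use every atom present.  Input models are typically
  hydrogen-free, so no hydrogen filtering is applied.
* Boundary comparisons are inclusive (``<=``).
* Alternate locations: the highest-occupancy altloc is kept, first wins on a
  tie.  Insertion codes are appended to the residue number to form the
  residue key (e.g. ``"52A"``).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Structure",
    "AtomSelection",
    "Superposition",
    "read_structure",
    "write_structure",
    "min_distance",
    "max_pair_distance",
    "interface_residues",
    "superpose",
    "kabsch",
]

_PDB_SERIAL_LIMIT = 99_999


class EmptyStructureError(ValueError):
    """Raised when a coordinate file contains no atom records."""


class EmptySelectionError(ValueError):
    """Raised when a selection resolves to zero atoms but atoms are required."""


@dataclasses.dataclass
class Structure:
    """Ordered flat atom table of one coordinate model.

    All fields are parallel arrays of length ``n_atoms``.  ``xyz`` is an
    ``(n, 3)`` float array in Angstroms.
    """

    chain: np.ndarray        # dtype object, short chain ids
    resnum: np.ndarray       # int residue numbers as given in the source
    icode: np.ndarray        # dtype object, insertion codes ('' if none)
    resname: np.ndarray      # dtype object, 3-letter residue names
    atomname: np.ndarray     # dtype object
    element: np.ndarray      # dtype object
    xyz: np.ndarray          # (n, 3) float64, Angstrom

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = self.xyz.shape[0]
        if n == 0:
            raise EmptyStructureError("structure must contain at least one atom")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        for name in ("chain", "resnum", "icode", "resname", "atomname", "element"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"field {name} length {arr.shape[0]} != {n} atoms")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def residue_key(self, i: int) -> tuple[str, str]:
        """(chain, resnum+icode) token identifying the residue of atom *i*."""
        return str(self.chain[i]), f"{self.resnum[i]}{self.icode[i]}"

    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(str(c), None)
        return list(seen)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            chain=self.chain[idx],
            resnum=self.resnum[idx],
            icode=self.icode[idx],
            resname=self.resname[idx],
            atomname=self.atomname[idx],
            element=self.element[idx],
            xyz=self.xyz[idx],
        )

    def with_xyz(self, xyz: np.ndarray) -> "Structure":
        return dataclasses.replace(self, xyz=np.asarray(xyz, dtype=float))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return self.with_xyz(self.xyz @ np.asarray(rotation).T + np.asarray(translation))

    def concat(self, other: "Structure") -> "Structure":
        return Structure(
            chain=np.concatenate([self.chain, other.chain]),
            resnum=np.concatenate([self.resnum, other.resnum]),
            icode=np.concatenate([self.icode, other.icode]),
            resname=np.concatenate([self.resname, other.resname]),
            atomname=np.concatenate([self.atomname, other.atomname]),
            element=np.concatenate([self.element, other.element]),
            xyz=np.vstack([self.xyz, other.xyz]),
        )

    def renamed_chain(self, mapping: dict[str, str]) -> "Structure":
        new = np.array([mapping.get(str(c), str(c)) for c in self.chain], dtype=object)
        return dataclasses.replace(self, chain=new)


_RANGE_RE = re.compile(r"^(-?\d+)-(-?\d+)$")


@dataclasses.dataclass(frozen=True)
class AtomSelection:
    """Predicate over (chain, residue number, atom name).

    ``None`` fields match everything.  ``residues`` is a frozenset of ints;
    ``atoms`` a frozenset of atom-name tokens.  ``fallback_atoms`` is tried,
    per residue, when none of ``atoms`` is present (used for the Calpha
    fallback of reactive-atom restraints).
    """

    chains: frozenset[str] | None = None
    residues: frozenset[int] | None = None
    atoms: frozenset[str] | None = None
    fallback_atoms: frozenset[str] | None = None

    @staticmethod
    def parse(token: str) -> "AtomSelection":
        """Parse ``"chain[:resspec[:atom]]"`` tokens, e.g. ``"A:142-380:CA"``.

        ``resspec`` is a comma list of numbers and inclusive ranges.
        """
        parts = token.split(":")
        chains = frozenset({parts[0]}) if parts[0] else None
        residues = None
        atoms = None
        if len(parts) >= 2 and parts[1]:
            nums: set[int] = set()
            for piece in parts[1].split(","):
                m = _RANGE_RE.match(piece)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    nums.update(range(lo, hi + 1))
                else:
                    nums.add(int(piece))
            residues = frozenset(nums)
        if len(parts) >= 3 and parts[2]:
            atoms = frozenset(parts[2].split(","))
        return AtomSelection(chains=chains, residues=residues, atoms=atoms)

    def _mask(self, s: Structure, atoms: frozenset[str] | None) -> np.ndarray:
        mask = np.ones(s.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(s.chain.astype(str), list(self.chains))
        if self.residues is not None:
            mask &= np.isin(s.resnum, list(self.residues))
        if atoms is not None:
            mask &= np.isin(s.atomname.astype(str), list(atoms))
        return mask

    def resolve(self, s: Structure, required: bool = True) -> np.ndarray:
        """Atom indices matching the selection (fallback applied if needed)."""
        idx = np.flatnonzero(self._mask(s, self.atoms))
        if idx.size == 0 and self.fallback_atoms is not None:
            idx = np.flatnonzero(self._mask(s, self.fallback_atoms))
        if required and idx.size == 0:
            raise EmptySelectionError(f"selection resolves to no atoms: {self}")
        return idx

    def used_fallback(self, s: Structure) -> bool:
        return (
            self.fallback_atoms is not None
            and np.flatnonzero(self._mask(s, self.atoms)).size == 0
            and np.flatnonzero(self._mask(s, self.fallback_atoms)).size > 0
        )


@dataclasses.dataclass(frozen=True)
class Superposition:
    """Proper rigid transform minimizing RMSD of mobile onto target."""

    rotation: np.ndarray   # (3,3), det +1
    translation: np.ndarray
    rmsd: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB I/O


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a coordinate file into a :class:`Structure`.

    Only the first model is read.  For each (chain, residue, atom name) the
    highest-occupancy altloc is kept (first wins on ties).
    """
    if format != "pdb":
        raise ValueError(f"unsupported format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    rows: dict[tuple[str, int, str, str], tuple[float, tuple]] = {}
    order: list[tuple[str, int, str, str]] = []
    if len(st) == 0:
        raise EmptyStructureError(f"no atom records in {path}")
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(), atom.name)
                occ = float(atom.occ)
                row = (
                    chain.name,
                    res.seqid.num,
                    res.seqid.icode.strip(),
                    res.name,
                    atom.name,
                    atom.element.name.upper(),
                    (atom.pos.x, atom.pos.y, atom.pos.z),
                )
                if key not in rows:
                    rows[key] = (occ, row)
                    order.append(key)
                elif occ > rows[key][0]:
                    rows[key] = (occ, row)
    if not order:
        raise EmptyStructureError(f"no atom records in {path}")
    data = [rows[k][1] for k in order]
    return Structure(
        chain=np.array([d[0] for d in data], dtype=object),
        resnum=np.array([d[1] for d in data], dtype=int),
        icode=np.array([d[2] for d in data], dtype=object),
        resname=np.array([d[3] for d in data], dtype=object),
        atomname=np.array([d[4] for d in data], dtype=object),
        element=np.array([d[5] for d in data], dtype=object),
        xyz=np.array([d[6] for d in data], dtype=float),
    )


def _to_gemmi(structure: Structure, coord_sets: Iterable[np.ndarray]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "tetherdock"
    for mi, xyz in enumerate(coord_sets, start=1):
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if xyz.shape[0] != structure.n_atoms:
            raise ValueError("coordinate set length does not match structure")
        # gemmi's add_* methods copy their argument, so the hierarchy must
        # be assembled bottom-up (atoms -> residue -> chain -> model)
        model = gemmi.Model(mi)
        chains: list[gemmi.Chain] = []
        cur_chain: gemmi.Chain | None = None
        cur_res: gemmi.Residue | None = None
        prev_chain = prev_res = None
        for i in range(structure.n_atoms):
            cid = str(structure.chain[i])
            rkey = (cid, int(structure.resnum[i]), str(structure.icode[i]))
            if cid != prev_chain:
                if cur_chain is not None:
                    if cur_res is not None:
                        cur_chain.add_residue(cur_res)
                        cur_res = None
                    chains.append(cur_chain)
                cur_chain = gemmi.Chain(cid)
                prev_chain, prev_res = cid, None
            if rkey != prev_res:
                if cur_res is not None:
                    cur_chain.add_residue(cur_res)
                cur_res = gemmi.Residue()
                cur_res.name = str(structure.resname[i])
                cur_res.seqid = gemmi.SeqId(int(structure.resnum[i]), str(structure.icode[i]) or " ")
                prev_res = rkey
            atom = gemmi.Atom()
            atom.name = str(structure.atomname[i])
            atom.element = gemmi.Element(str(structure.element[i]))
            atom.pos = gemmi.Position(*xyz[i])
            atom.occ = 1.0
            cur_res.add_atom(atom)
        if cur_res is not None:
            cur_chain.add_residue(cur_res)
        if cur_chain is not None:
            chains.append(cur_chain)
        for ch in chains:
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(
    structure: Structure,
    path: str | Path,
    models: Sequence[np.ndarray] | None = None,
) -> None:
    """Write PDB v3.3-style ATOM records.

    With ``models`` given (a list of ``(n, 3)`` coordinate sets), each set is
    wrapped in a MODEL/ENDMDL block.  Atom counts beyond the fixed-width PDB
    serial field are refused rather than silently wrapped.
    """
    coord_sets = [structure.xyz] if models is None else list(models)
    if structure.n_atoms > _PDB_SERIAL_LIMIT:
        raise ValueError(
            f"{structure.n_atoms} atoms exceed the PDB serial limit ({_PDB_SERIAL_LIMIT})"
        )
    st = _to_gemmi(structure, coord_sets)
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


# ---------------------------------------------------------------------------
# Distance geometry


def _pairwise(s: Structure, selA: AtomSelection, selB: AtomSelection) -> np.ndarray:
    a = selA.resolve(s)
    b = selB.resolve(s)
    return cdist(s.xyz[a], s.xyz[b])


def min_distance(s: Structure, selA: AtomSelection, selB: AtomSelection) -> float:
    """Minimum Euclidean distance over all cross pairs, in Angstrom."""
    return float(_pairwise(s, selA, selB).min())


def max_pair_distance(s: Structure, selA: AtomSelection, selB: AtomSelection) -> float:
    """Maximum Euclidean distance over all cross pairs (assembly span)."""
    return float(_pairwise(s, selA, selB).max())


def interface_residues(
    s: Structure,
    groupA: AtomSelection,
    groupB: AtomSelection,
    cutoff: float = 5.0,
) -> list[tuple[str, int]]:
    """Residues of ``groupA`` with any atom within ``cutoff`` of ``groupB``.

    The boundary is inclusive.  Order follows first appearance in the file.
    """
    a = groupA.resolve(s)
    b = groupB.resolve(s)
    if np.intersect1d(a, b).size:
        raise ValueError("interface groups must be disjoint")
    close = cdist(s.xyz[a], s.xyz[b]).min(axis=1) <= cutoff
    out: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for i in a[close]:
        key = (str(s.chain[i]), int(s.resnum[i]))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


# ---------------------------------------------------------------------------
# Superposition


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation + translation mapping mobile onto target.

    SVD sign correction guarantees det(R) = +1 even when the unconstrained
    optimum is a reflection.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Kabsch superposition of two equal-length point sets (n >= 3)."""
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ValueError("point sets must have equal shapes")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points")
    centered = mobile - mobile.mean(axis=0)
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    R, t = kabsch(mobile, target)
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
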