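"""Synthetic fixtures: C2 toy complexes, planted cross-links, binding plates.

The toy assembly emulates the topology of the modeled tetramer: a
homodimeric receptor (two identical Calpha-bead chains related by an exact
two-fold about z) with one ligand chain docked against each receptor
monomer, the second ligand copy generated by the same C2 operation.  Chains
are smoothed self-avoiding random walks with a 3.8 A virtual bond — fast,
clash-free, and sufficient for geometry and scoring tests; they are not
protein folds.

Cross-links are planted on lysine (or cysteine) bead pairs whose
ground-truth distance is within the linker's spacer arm, mimicking a
cross-linking MS experiment on the complex; decoys model false-positive
identifications.  Binding plates simulate the one-site total+nonspecific
model with Gaussian noise.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .binding import BindingCurve, total_binding
from .restraints import CrossLink, builtin_linkers
from .structio import Structure
from .symdock import C2_Z, DockingConfig, PoseC2, _Scorer, make_c2_assembly

__all__ = [
    "ToyComplexSpec",
    "PlantedCrossLinkSpec",
    "SimBindingSpec",
    "make_toy_tetramer",
    "plant_crosslinks",
    "simulate_binding_plate",
]

_BOND = 3.8          # A, consecutive Calpha distance
_SELF_AVOID = 3.5    # A, minimal non-bonded bead distance
#: bead residue alphabet with realistic charge/reactive content
_ALPHABET = ["ALA", "GLY", "SER", "LEU", "LYS", "LYS", "ASP", "GLU", "ARG", "CYS"]


@dataclasses.dataclass(frozen=True)
class ToyComplexSpec:
    seed: int = 7
    n_res_receptor_chain: int = 30
    n_res_ligand: int = 24
    # target closest approach of the bodies; 6.0 A is flush contact for
    # 3.0 A Calpha beads, so the planted assembly is clash-free under the
    # docking scorer as well as under the 3.5 A hard-sphere audit
    contact_offset: float = 6.0

    def __post_init__(self) -> None:
        if self.n_res_receptor_chain < 10 or self.n_res_ligand < 10:
            raise ValueError("chain lengths must be >= 10 residues")


@dataclasses.dataclass(frozen=True)
class PlantedCrossLinkSpec:
    linker: str = "DSG"
    n_true: int = 4
    n_decoy: int = 0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true < 1:
            raise ValueError("need at least one true link")


@dataclasses.dataclass(frozen=True)
class SimBindingSpec:
    Kd: float = 0.7       # nM
    Bmax: float = 1.0
    NS: float = 0.01      # per nM
    B0: float = 0.05
    X: tuple[float, ...] = tuple(np.geomspace(0.001, 100.0, 12))
    noise_sd: float = 0.02   # fraction of Bmax
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(x < 0 for x in self.X):
            raise ValueError("concentrations must be >= 0")


# ---------------------------------------------------------------------------
# Toy complex


def _smooth_walk(rng: np.random.Generator, n: int, max_tries: int = 200) -> np.ndarray:
    """Self-avoiding smoothed random walk of n beads, centered at origin."""
    for _ in range(max_tries):
        pts = [np.zeros(3)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(30):
                trial_dir = direction + 0.8 * rng.normal(size=3)
                trial_dir /= np.linalg.norm(trial_dir)
                cand = pts[-1] + _BOND * trial_dir
                prior = np.array(pts[:-1]) if len(pts) > 1 else None
                if prior is None or cdist(cand[None], prior).min() >= _SELF_AVOID:
                    pts.append(cand)
                    direction = trial_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            arr = np.array(pts)
            return arr - arr.mean(axis=0)
    raise RuntimeError("failed to generate a self-avoiding chain")


def _bead_structure(
    xyz: np.ndarray, chain: str, resnames: Sequence[str], start_resnum: int = 1
) -> Structure:
    n = xyz.shape[0]
    return Structure(
        chain=np.array([chain] * n, dtype=object),
        resnum=np.arange(start_resnum, start_resnum + n),
        icode=np.array([""] * n, dtype=object),
        resname=np.array(list(resnames), dtype=object),
        atomname=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        xyz=xyz,
    )


def _min_cross(a: np.ndarray, b: np.ndarray) -> float:
    return float(cdist(a, b).min())


def make_toy_tetramer(
    spec: ToyComplexSpec, max_attempts: int = 1000
) -> tuple[Structure, Structure, Structure, PoseC2]:
    """Generate a clash-free C2 toy tetramer with a known ligand pose.

    Returns ``(assembly, receptor, ligand, pose)`` where ``receptor`` is the
    prepared two-chain dimer (chains A/B, exactly symmetric about z),
    ``ligand`` the single-chain ligand in its local frame (centroid at the
    origin), and ``pose`` the ground-truth placement such that
    ``make_c2_assembly(receptor, ligand, pose)`` reproduces ``assembly``
    exactly.  Interface bead pairs are deliberately labeled lysine so that a
    cross-linking experiment on the complex has reactive sites to find.
    """
    rng = np.random.default_rng(spec.seed)
    lig_names_pool = rng.choice(_ALPHABET, size=spec.n_res_ligand)
    rec_names_pool = rng.choice(_ALPHABET, size=spec.n_res_receptor_chain)

    for _ in range(max_attempts):
        rec_walk = _smooth_walk(rng, spec.n_res_receptor_chain)
        # push chain A off the axis until the dimer is clash-free
        for dx in np.arange(6.0, 80.0, 1.0):
            a_xyz = rec_walk + np.array([dx, 0.0, 0.0])
            b_xyz = a_xyz @ C2_Z.T
            if _min_cross(a_xyz, b_xyz) >= _SELF_AVOID:
                break
        else:
            continue

        lig_walk = _smooth_walk(rng, spec.n_res_ligand)
        rec_both = np.vstack([a_xyz, b_xyz])
        reach = builtin_linkers()["DSG"].spacer

        # try several orientations/approach directions against chain A and
        # keep the snuggest: a docked interface is a patch, not a point, so
        # we require several bead pairs in cross-linking range anchored on
        # well-separated ligand beads
        # packing-only scorer (clash + contact reward, no restraints) used
        # to settle candidate placements into local contact optima, so the
        # ground truth is a genuinely docked, snug configuration
        rec_struct = _bead_structure(a_xyz, "A", ["ALA"] * a_xyz.shape[0]).concat(
            _bead_structure(b_xyz, "B", ["ALA"] * b_xyz.shape[0])
        )
        lig_struct = _bead_structure(lig_walk, "L", ["ALA"] * lig_walk.shape[0])
        pack_cfg = DockingConfig(w_r=0.0, w_c=1.0, w_e=0.0, w_contact=0.05)
        packer = _Scorer(rec_struct, lig_struct, [], pack_cfg)

        best = None   # (quality, R, t)
        for _ in range(80):
            R = Rotation.from_quat(_random_quat(rng)).as_matrix()
            lig_rot = lig_walk @ R.T
            target = a_xyz[rng.integers(a_xyz.shape[0])]
            direction = target + rng.normal(scale=3.0, size=3)
            nrm = np.linalg.norm(direction)
            if nrm < 1e-6:
                continue
            direction /= nrm
            r_far = (
                np.linalg.norm(rec_both, axis=1).max()
                + np.linalg.norm(lig_rot, axis=1).max()
                + 5.0
            )
            placed = None
            for radius in np.arange(r_far, 0.0, -0.25):
                t = direction * radius
                c1 = lig_rot + t
                dmin = min(_min_cross(c1, rec_both), _min_cross(c1, c1 @ C2_Z.T))
                if dmin < _SELF_AVOID:
                    break
                if dmin <= spec.contact_offset:
                    placed = t
                    break
            if placed is None:
                continue

            # settle into the nearest packing optimum (nestled, not tangent)
            from scipy.optimize import minimize as _minimize

            def pack_obj(x, R0=R, t0=placed):
                Rx = Rotation.from_rotvec(x[:3]).as_matrix() @ R0
                return packer.breakdown(lig_walk @ Rx.T + t0 + x[3:]).total

            res = _minimize(
                pack_obj, np.zeros(6), method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-6,
                         "initial_simplex": np.vstack(
                             [np.zeros(6)] + [np.eye(6)[i] * s for i, s in
                                              enumerate([0.25, 0.25, 0.25, 2.0, 2.0, 2.0])])},
            )
            R_s = Rotation.from_rotvec(res.x[:3]).as_matrix() @ R
            t_s = placed + res.x[3:]
            c1 = lig_walk @ R_s.T + t_s
            dmin = min(_min_cross(c1, rec_both), _min_cross(c1, c1 @ C2_Z.T))
            if dmin < _SELF_AVOID:
                continue
            d = cdist(a_xyz, c1)
            ii, jj = np.nonzero(d <= reach)
            lig_anchors = np.unique(jj)
            rec_anchors = np.unique(ii)
            if ii.size < 4 or lig_anchors.size < 3 or rec_anchors.size < 3:
                continue
            spread_l = float(cdist(c1[lig_anchors], c1[lig_anchors]).max())
            spread_r = float(cdist(a_xyz[rec_anchors], a_xyz[rec_anchors]).max())
            # a usable interface must offer orientation information (anchors
            # spread on both sides); among usable candidates the native pose
            # is the packing-energy optimum, as a native complex would be
            if spread_l < 10.0 or spread_r < 8.0:
                continue
            quality = (-res.fun, R_s, t_s)
            if best is None or quality[0] > best[0]:
                best = quality
        if best is None:
            continue
        _, R, placed = best
        c1 = lig_walk @ R.T + placed

        # global clash audit
        bodies = [a_xyz, b_xyz, c1, c1 @ C2_Z.T]
        ok = all(
            _min_cross(bodies[i], bodies[j]) >= _SELF_AVOID
            for i in range(4) for j in range(i + 1, 4)
        )
        if not ok:
            continue

        # label interface pairs as lysine so cross-links can be planted,
        # covering as many distinct ligand anchor beads as possible
        rec_names = list(rec_names_pool)
        lig_names = list(lig_names_pool)
        d = cdist(a_xyz, c1)
        ii, jj = np.nonzero(d <= reach)
        if ii.size < 4:
            continue
        covered: set[int] = set()
        n_tagged = 0
        for k in np.argsort(d[ii, jj]):
            i, j = int(ii[k]), int(jj[k])
            if j in covered and n_tagged >= 12:
                continue
            rec_names[i] = "LYS"
            lig_names[j] = "LYS"
            covered.add(j)
            n_tagged += 1
            if n_tagged >= 12 and len(covered) >= 6:
                break

        receptor = _bead_structure(a_xyz, "A", rec_names).concat(
            _bead_structure(b_xyz, "B", rec_names)
        )
        ligand = _bead_structure(lig_walk, "L", lig_names)
        pose = PoseC2.from_matrix(R, placed)
        assembly = make_c2_assembly(receptor, ligand, pose)
        return assembly, receptor, ligand, pose
    raise RuntimeError(f"clash-free placement failed after {max_attempts} attempts")


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    u1, u2, u3 = rng.uniform(size=3)
    return np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )


# ---------------------------------------------------------------------------
# Planted cross-links


def plant_crosslinks(
    receptor: Structure,
    ligand: Structure,
    pose: PoseC2,
    spec: PlantedCrossLinkSpec,
    receptor_protein: str = "REC",
    ligand_protein: str = "LIG",
) -> list[CrossLink]:
    """Sample cross-links consistent with the ground-truth assembly.

    True links connect reactive bead pairs (lysines for amine ends,
    cysteines for sulfhydryl ends) whose ground-truth distance — minimized
    over symmetry-equivalent copy pairings — is within the linker spacer.
    Decoys are sampled from reactive pairs that violate the spacer and are
    labeled as such.  Links are spread by greedy farthest-point selection on
    the receptor side.
    """
    rng = np.random.default_rng(spec.seed)
    lk = builtin_linkers()[spec.linker]
    chains = receptor.chains()
    iA = np.flatnonzero(receptor.chain.astype(str) == chains[0])
    recA = receptor.xyz[iA]
    rec_res = receptor.resnum[iA]
    rec_names = receptor.resname[iA]
    c1 = pose.apply(ligand.xyz)

    endA, endB = lk.end_chemistry
    react = {"amine": "LYS", "sulfhydryl": "CYS"}
    rec_ok = np.flatnonzero(rec_names.astype(str) == react[endA])
    lig_ok = np.flatnonzero(ligand.resname.astype(str) == react[endB])
    if rec_ok.size == 0 or lig_ok.size == 0:
        raise ValueError("no reactive residues available for this linker")

    # links are planted in register (chain A with ligand copy 1; the B/D
    # pair realizes the identical distance by symmetry), matching the
    # register pairing convention of the restraint generator
    dmin = cdist(recA[rec_ok], c1[lig_ok])
    ti, tj = np.nonzero(dmin <= lk.spacer - spec.jitter)
    if ti.size < spec.n_true:
        raise ValueError(
            f"only {ti.size} candidate pairs within {lk.spacer} A, need {spec.n_true}"
        )

    # greedy farthest-point spread over the joint (receptor, ligand) anchors;
    # links on clumped anchors carry almost no orientation information, so
    # the selection maximizes the worst-case anchor separation
    start = int(rng.integers(ti.size))
    chosen: list[int] = [start]
    while len(chosen) < spec.n_true:
        best, best_gain = None, -1.0
        for k in range(ti.size):
            if k in chosen:
                continue
            gain = min(
                min(
                    float(np.linalg.norm(recA[rec_ok[ti[k]]] - recA[rec_ok[ti[c]]])),
                    float(np.linalg.norm(c1[lig_ok[tj[k]]] - c1[lig_ok[tj[c]]])),
                )
                for c in chosen
            )
            if gain > best_gain:
                best, best_gain = k, gain
        chosen.append(best)

    links: list[CrossLink] = []
    aa_of = {"LYS": "K", "CYS": "C"}
    for k in chosen:
        i = int(rec_ok[ti[k]])
        j = int(lig_ok[tj[k]])
        links.append(
            CrossLink(
                proteinA=receptor_protein,
                residueA=int(rec_res[i]),
                aaA=aa_of[str(rec_names[i])],
                proteinB=ligand_protein,
                residueB=int(ligand.resnum[j]),
                aaB=aa_of[str(ligand.resname[j])],
                linker=spec.linker,
            )
        )

    if spec.n_decoy:
        fi, fj = np.nonzero(dmin > lk.spacer + 5.0)
        if fi.size < spec.n_decoy:
            raise ValueError("too few distant pairs to sample decoys")
        pick = rng.choice(fi.size, size=spec.n_decoy, replace=False)
        for k in pick:
            i = int(rec_ok[fi[k]])
            j = int(lig_ok[fj[k]])
            links.append(
                CrossLink(
                    proteinA=receptor_protein,
                    residueA=int(rec_res[i]),
                    aaA=aa_of[str(rec_names[i])],
                    proteinB=ligand_protein,
                    residueB=int(ligand.resnum[j]),
                    aaB=aa_of[str(ligand.resname[j])],
                    linker=spec.linker,
                    decoy=True,
                )
            )
    return links


# ---------------------------------------------------------------------------
# Binding plates


def simulate_binding_plate(spec: SimBindingSpec) -> list[BindingCurve]:
    """Simulate replicate saturation curves with Gaussian signal noise."""
    rng = np.random.default_rng(spec.seed)
    X = np.asarray(spec.X, dtype=float)
    clean = total_binding(X, spec.Kd, spec.Bmax, spec.NS, spec.B0)
    out = []
    for _ in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd * spec.Bmax, size=X.size)
        out.append(BindingCurve(X=X, Y=clean + noise))
    return out
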