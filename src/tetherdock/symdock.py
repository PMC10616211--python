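"""Restrained rigid-body docking of a C2-symmetric A2B2 assembly.

The receptor is a homodimer whose two-fold axis is placed on z (see
:func:`prepare_receptor`); a single rigid ligand copy is searched over 6
degrees of freedom and the second copy is generated exactly by the C2
operation, so every candidate assembly is symmetric by construction.

Scoring combines a flat-bottom quadratic penalty on cross-link-derived
distance restraints (evaluated ambiguously over symmetry copies), a
soft-sphere clash term, and an optional Debye-Hueckel screened-Coulomb term
parameterized by ionic strength.  Search is multi-start (uniform random
rigid placements, Shoemake quaternions) followed by Nelder-Mead refinement;
solutions are single-linkage clustered on symmetry-aware ligand RMSD and
clusters are ranked by their best-scoring member.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, squareform
from scipy.spatial.transform import Rotation

from .restraints import DistanceRestraint, ViolationReport, evaluate_restraints
from .structio import Structure, rmsd as _plain_rmsd

__all__ = [
    "PoseC2",
    "ScoreBreakdown",
    "DockingConfig",
    "DockingResult",
    "prepare_receptor",
    "make_c2_assembly",
    "score_pose",
    "dock",
    "cluster_poses",
    "ligand_rmsd",
    "interface_rmsd",
]

#: 180-degree rotation about z — the C2 operation of the assembly frame
C2_Z = np.diag([-1.0, -1.0, 1.0])

_COULOMB = 332.0637  # kcal/mol * A / e^2
_RESIDUE_CHARGE = {"LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0}
_ELEMENT_RADIUS = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.1, "P": 1.8}
_CA_BEAD_RADIUS = 3.0  # coarse one-bead-per-residue bodies


@dataclasses.dataclass(frozen=True)
class PoseC2:
    """Rigid placement of ligand copy 1; copy 2 is its C2(z) image."""

    quaternion: tuple[float, float, float, float]  # (x, y, z, w), unit norm
    translation: tuple[float, float, float]

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("quaternion must be unit norm")

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_quat(self.quaternion).as_matrix()

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Coordinates of ligand copy 1."""
        return np.asarray(xyz) @ self.rotation.T + np.asarray(self.translation)

    def apply_copy2(self, xyz: np.ndarray) -> np.ndarray:
        """Coordinates of ligand copy 2 = C2(z) of copy 1 (exact)."""
        return self.apply(xyz) @ C2_Z.T

    @staticmethod
    def identity() -> "PoseC2":
        return PoseC2((0.0, 0.0, 0.0, 1.0), (0.0, 0.0, 0.0))

    @staticmethod
    def from_matrix(R: np.ndarray, t: np.ndarray) -> "PoseC2":
        q = Rotation.from_matrix(R).as_quat()
        q = q / np.linalg.norm(q)
        return PoseC2(tuple(float(x) for x in q), tuple(float(x) for x in t))


@dataclasses.dataclass(frozen=True)
class ScoreBreakdown:
    """Energy terms of one pose.

    ``e_restraint`` (flat-bottom quadratic, A^2) and ``e_clash`` (soft-sphere
    overlap) are non-negative; ``e_contact`` is the attractive short-range
    contact reward (<= 0, a smooth stand-in for the van der Waals well /
    buried-surface term of all-atom docking scores) and ``e_elec`` the
    optional screened-Coulomb term (either sign).
    """

    e_restraint: float
    e_clash: float
    e_elec: float
    e_contact: float
    total: float


@dataclasses.dataclass(frozen=True)
class DockingConfig:
    n_starts: int = 64
    seed: int = 0
    refine_iterations: int = 500
    w_r: float = 10.0
    w_c: float = 1.0
    w_e: float = 0.0
    w_contact: float = 0.02
    cluster_cutoff: float = 7.5
    correction: float = 5.0
    ionic_strength: float = 0.3  # mol/L, Debye screening
    contact_sigma: float = 0.8   # A, width of the contact reward well

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster_cutoff must be positive")


@dataclasses.dataclass
class Cluster:
    members: list[int]
    representative: int
    representative_violations: int = 0


@dataclasses.dataclass
class DockingResult:
    poses: list[PoseC2]
    scores: list[ScoreBreakdown]
    reports: list[ViolationReport]
    clusters: list[Cluster]       # ranked ascending by representative total

    @property
    def best_pose(self) -> PoseC2:
        return self.poses[self.clusters[0].representative]

    @property
    def best_score(self) -> ScoreBreakdown:
        return self.scores[self.clusters[0].representative]


# ---------------------------------------------------------------------------
# Receptor preparation and assembly construction


def prepare_receptor(receptor: Structure, angle_tol_deg: float = 5.0) -> Structure:
    """Center the receptor dimer and align its two-fold axis to z.

    The C2 axis is computed from the Kabsch transform between the two chains
    (paired by atom order); the rotation angle must be within
    ``angle_tol_deg`` of 180 degrees.  After preparation, applying a
    180-degree rotation about z maps chain 1 onto chain 2.
    """
    from .structio import kabsch

    chains = receptor.chains()
    if len(chains) != 2:
        raise ValueError(f"receptor must have exactly 2 chains, got {chains}")
    i1 = np.flatnonzero(receptor.chain.astype(str) == chains[0])
    i2 = np.flatnonzero(receptor.chain.astype(str) == chains[1])
    if i1.size != i2.size:
        raise ValueError("receptor chains have different atom counts")
    X1, X2 = receptor.xyz[i1], receptor.xyz[i2]
    R, t = kabsch(X1, X2)
    angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))
    if abs(angle - 180.0) > angle_tol_deg:
        raise ValueError(
            f"inter-chain rotation is {angle:.1f} deg, not a two-fold within "
            f"{angle_tol_deg} deg"
        )
    # rotation axis of R (eigenvector for eigenvalue +1); sign canonicalized
    # so preparing an already-prepared receptor is the identity
    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    for comp in (2, 1, 0):
        if abs(axis[comp]) > 1e-8:
            if axis[comp] < 0:
                axis = -axis
            break
    # a point on the axis: least-squares solution of (I - R) p = t
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t, rcond=None)
    centroid = receptor.xyz.mean(axis=0)
    on_axis = p + axis * np.dot(centroid - p, axis)
    # orthonormal frame with z = axis
    z = axis
    seed = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = seed - z * np.dot(seed, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    frame = np.vstack([x, y, z])
    prepared = receptor.with_xyz((receptor.xyz - on_axis) @ frame.T)
    # verify the prepared dimer is self-consistent under C2(z)
    check = _plain_rmsd(prepared.xyz[i1] @ C2_Z.T, prepared.xyz[i2])
    if check > 1.0:
        raise ValueError(f"receptor not two-fold self-consistent (RMSD {check:.2f} A)")
    return prepared


def make_c2_assembly(
    receptor: Structure,
    ligand: Structure,
    pose: PoseC2,
    ligand_chains: tuple[str, str] = ("C", "D"),
) -> Structure:
    """Receptor dimer + two ligand copies related by the exact C2 operation.

    The receptor must already be prepared (C2 axis on z).  Ligand chain ids
    are rewritten to ``ligand_chains``.
    """
    lc = ligand.chains()
    if len(lc) != 1:
        raise ValueError("ligand must be a single chain")
    copy1 = ligand.renamed_chain({lc[0]: ligand_chains[0]}).with_xyz(pose.apply(ligand.xyz))
    copy2 = ligand.renamed_chain({lc[0]: ligand_chains[1]}).with_xyz(pose.apply_copy2(ligand.xyz))
    return receptor.concat(copy1).concat(copy2)


# ---------------------------------------------------------------------------
# Scoring


def _body_radii(s: Structure, idx: np.ndarray) -> np.ndarray:
    names = s.atomname[idx].astype(str)
    if np.all(names == "CA"):
        return np.full(idx.size, _CA_BEAD_RADIUS)
    return np.array([_ELEMENT_RADIUS.get(str(e).upper(), 1.7) for e in s.element[idx]])


def _residue_charges(s: Structure, idx: np.ndarray) -> np.ndarray:
    """One formal charge per charged residue, carried on its first atom."""
    q = np.zeros(idx.size)
    seen: set[tuple[str, int]] = set()
    for k, i in enumerate(idx):
        key = (str(s.chain[i]), int(s.resnum[i]))
        if key in seen:
            continue
        seen.add(key)
        q[k] = _RESIDUE_CHARGE.get(str(s.resname[i]), 0.0)
    return q


class _Scorer:
    """Pose objective compiled against a fixed receptor/ligand/restraint set.

    Restraints are resolved once against a template assembly; during search
    only ligand copy-1 coordinates are rebuilt.  Restraint distances are
    pooled per ``symmetry_group`` with a min (any-copy ambiguity), so a
    ground-truth pose that satisfies each experimental link through one copy
    pairing scores zero.
    """

    def __init__(
        self,
        receptor: Structure,
        ligand: Structure,
        restraints: Sequence[DistanceRestraint],
        config: DockingConfig,
        ligand_chains: tuple[str, str] = ("C", "D"),
    ) -> None:
        self.receptor = receptor
        self.ligand = ligand
        self.config = config
        self.ligand_chains = ligand_chains
        self.rx = receptor.xyz
        self.lx = ligand.xyz
        n_r, n_l = self.rx.shape[0], self.lx.shape[0]
        template = make_c2_assembly(receptor, ligand, PoseC2.identity(), ligand_chains)
        self.template = template

        # restraint compilation: selections resolve once to global template
        # indices (layout: receptor atoms, then copy1, then copy2); each
        # evaluation rebuilds the assembly coordinate array in that layout
        self.groups: dict[str, list[tuple]] = {}
        for i, r in enumerate(restraints):
            a = r.selA.resolve(template)
            b = r.selB.resolve(template)
            upper = r.upper
            if r.kind == "UIR":
                upper += r.fallback_slack * (
                    r.selA.used_fallback(template) + r.selB.used_fallback(template)
                )
            key = r.symmetry_group or (r.rid or f"r{i}")
            self.groups.setdefault(key, []).append((a, b, upper, r.kind))

        # clash
        self.radii_r = _body_radii(template, np.arange(n_r))
        self.radii_l = _body_radii(template, np.arange(n_r, n_r + n_l))
        self.rsum_lr = self.radii_l[:, None] + self.radii_r[None, :]
        self.rsum_ll = self.radii_l[:, None] + self.radii_l[None, :]

        # electrostatics
        self.q_r = _residue_charges(template, np.arange(n_r))
        self.q_l = _residue_charges(template, np.arange(n_r, n_r + n_l))
        self.kappa = np.sqrt(max(config.ionic_strength, 0.0)) / 3.04  # 1/A at 298 K
        self.qq_lr = np.outer(self.q_l, self.q_r)
        self.qq_ll = np.outer(self.q_l, self.q_l)
        self._have_charge = np.any(self.qq_lr) or np.any(self.qq_ll)

    def breakdown(self, copy1: np.ndarray) -> ScoreBreakdown:
        cfg = self.config
        copy2 = copy1 @ C2_Z.T
        full = np.vstack([self.rx, copy1, copy2])

        e_rest = 0.0
        for members in self.groups.values():
            upper = members[0][2]
            kind = members[0][3]
            if kind == "AIR":
                # r^-6 pooling across all member copies
                inv6 = 0.0
                for a, b, upper, _ in members:
                    d = cdist(full[a], full[b])
                    if (d == 0).any():
                        inv6 = np.inf
                        break
                    inv6 += float((d ** -6).sum())
                deff = 0.0 if np.isinf(inv6) else inv6 ** (-1.0 / 6.0)
                e_rest += max(0.0, deff - upper) ** 2
                continue
            dmin = np.inf
            for a, b, upper, _ in members:
                if a.size == 1 and b.size == 1:
                    d = float(np.linalg.norm(full[a[0]] - full[b[0]]))
                else:
                    d = float(cdist(full[a], full[b]).min())
                dmin = min(dmin, d)
            e_rest += max(0.0, dmin - upper) ** 2

        d_lr = cdist(copy1, self.rx)
        over_lr = np.maximum(0.0, self.rsum_lr - d_lr)
        d_ll = cdist(copy1, copy2)
        over_ll = np.maximum(0.0, self.rsum_ll - d_ll)
        # receptor is exactly C2-symmetric, so the copy2/receptor term equals
        # the copy1/receptor term and is counted by doubling
        e_clash = float(2.0 * (over_lr ** 2).sum() + (over_ll ** 2).sum())

        e_contact = 0.0
        if cfg.w_contact != 0.0:
            s2 = 2.0 * cfg.contact_sigma ** 2
            g_lr = np.exp(-((d_lr - (self.rsum_lr + 0.5)) ** 2) / s2)
            g_ll = np.exp(-((d_ll - (self.rsum_ll + 0.5)) ** 2) / s2)
            e_contact = -float(2.0 * g_lr.sum() + g_ll.sum())

        e_elec = 0.0
        if cfg.w_e != 0.0 and self._have_charge:
            with np.errstate(divide="ignore"):
                s_lr = self.qq_lr * np.exp(-self.kappa * d_lr) / np.maximum(d_lr, 1e-3)
                s_ll = self.qq_ll * np.exp(-self.kappa * d_ll) / np.maximum(d_ll, 1e-3)
            e_elec = float(_COULOMB / 80.0 * (2.0 * s_lr.sum() + s_ll.sum()))

        total = (cfg.w_r * e_rest + cfg.w_c * e_clash + cfg.w_e * e_elec
                 + cfg.w_contact * e_contact)
        return ScoreBreakdown(e_rest, e_clash, e_elec, e_contact, total)

    def score_pose(self, pose: PoseC2) -> ScoreBreakdown:
        return self.breakdown(pose.apply(self.lx))

    def group_violations(self, pose: PoseC2) -> int:
        """Number of restraint groups with any (strict) bound violation."""
        copy1 = pose.apply(self.lx)
        copy2 = copy1 @ C2_Z.T
        full = np.vstack([self.rx, copy1, copy2])
        n = 0
        for members in self.groups.values():
            kind = members[0][3]
            if kind == "AIR":
                inv6 = 0.0
                upper = members[0][2]
                for a, b, upper, _ in members:
                    d = cdist(full[a], full[b])
                    inv6 += np.inf if (d == 0).any() else float((d ** -6).sum())
                deff = 0.0 if np.isinf(inv6) else inv6 ** (-1.0 / 6.0)
                n += deff > upper
                continue
            dmin = np.inf
            upper = members[0][2]
            for a, b, upper, _ in members:
                dmin = min(dmin, float(cdist(full[a], full[b]).min()))
            n += dmin > upper
        return n


def score_pose(
    receptor: Structure,
    ligand: Structure,
    pose: PoseC2,
    restraints: Sequence[DistanceRestraint],
    config: DockingConfig | None = None,
) -> ScoreBreakdown:
    """Energy breakdown of one C2 pose (restraint + clash [+ electrostatic])."""
    config = config or DockingConfig()
    return _Scorer(receptor, ligand, restraints, config).score_pose(pose)


# ---------------------------------------------------------------------------
# Search


def _shoemake_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion (Shoemake subgroup algorithm)."""
    u1, u2, u3 = rng.uniform(size=3)
    return np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )


def dock(
    receptor: Structure,
    ligand: Structure,
    restraints: Sequence[DistanceRestraint],
    config: DockingConfig | None = None,
) -> DockingResult:
    """Multi-start restrained rigid-body docking with exact C2 symmetry.

    ``n_starts`` random placements (uniform orientations; centroid sampled
    in a shell around the receptor) are each refined by derivative-free
    Nelder-Mead over the 6 rigid degrees of freedom of ligand copy 1.
    Results are clustered (single linkage on symmetry-aware ligand RMSD) and
    clusters ranked by their best-scoring member.  Deterministic given
    (seed, config).
    """
    config = config or DockingConfig()
    if not restraints and config.w_c == 0.0:
        raise ValueError("need at least one restraint or a clash term")
    receptor = prepare_receptor(receptor)
    scorer = _Scorer(receptor, ligand, restraints, config)
    rng = np.random.default_rng(config.seed)

    lig_centroid = ligand.xyz.mean(axis=0)
    r_rec = float(np.linalg.norm(receptor.xyz, axis=1).max())
    r_lig = float(np.linalg.norm(ligand.xyz - lig_centroid, axis=1).max())

    lx = ligand.xyz

    def objective(x: np.ndarray, R0: np.ndarray, t0: np.ndarray) -> float:
        R = Rotation.from_rotvec(x[:3]).as_matrix() @ R0
        t = t0 + x[3:]
        copy1 = lx @ R.T + t
        return scorer.breakdown(copy1).total

    poses: list[PoseC2] = []
    scores: list[ScoreBreakdown] = []
    step = np.array([0.4, 0.4, 0.4, 4.0, 4.0, 4.0])
    for _ in range(config.n_starts):
        q = _shoemake_quaternion(rng)
        R0 = Rotation.from_quat(q).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = (r_rec + r_lig) * rng.uniform(0.6, 1.2)
        t0 = direction * radius - R0 @ lig_centroid

        x0 = np.zeros(6)
        simplex = np.vstack([x0] + [x0 + np.eye(6)[i] * step[i] for i in range(6)])
        res = minimize(
            objective,
            x0,
            args=(R0, t0),
            method="Nelder-Mead",
            options={
                "maxiter": config.refine_iterations * 4,
                "maxfev": config.refine_iterations * 4,
                "initial_simplex": simplex,
                "xatol": 1e-3,
                "fatol": 1e-6,
                "adaptive": True,
            },
        )
        R = Rotation.from_rotvec(res.x[:3]).as_matrix() @ R0
        t = t0 + res.x[3:]
        pose = PoseC2.from_matrix(R, t)
        poses.append(pose)
        scores.append(scorer.score_pose(pose))

    if not poses:
        return DockingResult([], [], [], [])

    violations = [scorer.group_violations(p) for p in poses]
    clusters = cluster_poses(
        poses, ligand, scores, cutoff=config.cluster_cutoff, violations=violations
    )
    reports = [
        evaluate_restraints(
            make_c2_assembly(receptor, ligand, p), restraints, correction=config.correction
        )
        for p in poses
    ]
    return DockingResult(poses=poses, scores=scores, reports=reports, clusters=clusters)


# ---------------------------------------------------------------------------
# Clustering and pose metrics


def _sym_ligand_rmsd_matrix(coords: list[np.ndarray]) -> np.ndarray:
    n = len(coords)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = min(
                _plain_rmsd(coords[i], coords[j]),
                _plain_rmsd(coords[i], coords[j] @ C2_Z.T),
            )
    return M


def _pose_sort_key(
    pose: PoseC2, score: ScoreBreakdown, violations: int = 0
) -> tuple:
    return (violations, score.total, score.e_restraint, pose.quaternion, pose.translation)


def cluster_poses(
    poses: Sequence[PoseC2],
    ligand: Structure,
    scores: Sequence[ScoreBreakdown],
    cutoff: float = 7.5,
    violations: Sequence[int] | None = None,
) -> list[Cluster]:
    """Single-linkage clusters on pairwise symmetry-aware ligand RMSD.

    Representatives and cluster ranking follow (fewest violated restraint
    groups, lowest total, lowest restraint energy, lexicographic pose) —
    solutions with the least violations are preferred, then energy.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    viol = list(violations) if violations is not None else [0] * len(poses)
    coords = [p.apply(ligand.xyz) for p in poses]

    def key(i: int) -> tuple:
        return _pose_sort_key(poses[i], scores[i], viol[i])

    if len(poses) == 1:
        return [Cluster(members=[0], representative=0, representative_violations=viol[0])]
    M = _sym_ligand_rmsd_matrix(coords)
    Z = linkage(squareform(M, checks=False), method="single")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    clusters: list[Cluster] = []
    for lab in np.unique(labels):
        members = [int(i) for i in np.flatnonzero(labels == lab)]
        rep = min(members, key=key)
        clusters.append(
            Cluster(members=members, representative=rep,
                    representative_violations=viol[rep])
        )
    clusters.sort(key=lambda c: key(c.representative))
    return clusters


def ligand_rmsd(poseA: PoseC2, poseB: PoseC2, ligand_xyz: np.ndarray) -> float:
    """RMSD between ligand copy-1 placements, minimized over the C2 swap."""
    a = np.asarray(ligand_xyz) @ poseA.rotation.T + poseA.translation
    b = np.asarray(ligand_xyz) @ poseB.rotation.T + poseB.translation
    return min(_plain_rmsd(a, b), _plain_rmsd(a, b @ C2_Z.T))


def interface_rmsd(
    pose: PoseC2,
    ref_pose: PoseC2,
    ligand_xyz: np.ndarray,
    receptor_xyz: np.ndarray,
    cutoff: float = 10.0,
) -> float:
    """Ligand RMSD restricted to reference-interface ligand atoms.

    Interface atoms are ligand atoms within ``cutoff`` of the receptor in
    the reference pose; the C2 pose degeneracy is minimized over.
    """
    ref1 = np.asarray(ligand_xyz) @ ref_pose.rotation.T + ref_pose.translation
    near = cdist(ref1, receptor_xyz).min(axis=1) <= cutoff
    if not near.any():
        near = np.ones(ref1.shape[0], dtype=bool)
    cand = np.asarray(ligand_xyz) @ pose.rotation.T + pose.translation
    return min(
        _plain_rmsd(cand[near], ref1[near]),
        _plain_rmsd(cand[near] @ C2_Z.T, ref1[near]),
    )
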