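"""Rigid transforms, Kabsch superposition, cyclic symmetry and ring building.

Everything here operates on :class:`~msring.model.StructureModel` objects and
plain numpy arrays.  A cyclic Cn ring is represented by :class:`RingModel`,
which attaches tier annotations (name, symmetry order, axis, member chains)
to a structure.  Coaxial tiers with different orders (the 23/11/34 symmetry
mismatch of the MS-ring) coexist in a single :class:`RingModel`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model import StructureModel, select, write_structure, read_structure

__all__ = [
    "RigidTransform",
    "SymmetryAxis",
    "Tier",
    "RingModel",
    "kabsch_superpose",
    "cn_operators",
    "fit_symmetry_axis",
    "build_cn_ring",
    "resymmetrize",
    "ring_diameter",
    "canonical_frame_transform",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation followed by translation: x -> R x + t (Å)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def apply_model(self, model: StructureModel) -> StructureModel:
        return model.with_coords(self.apply(model.coords()))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def is_identity(self, atol: float = 1e-9) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=atol) and np.allclose(
            self.translation, 0.0, atol=atol
        )


@dataclass(frozen=True)
class SymmetryAxis:
    """Line in space: a point on the axis plus a unit direction."""

    point: np.ndarray  # (3,) Å
    direction: np.ndarray  # (3,), |direction| = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("axis direction is a zero vector")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)

    @classmethod
    def z_axis(cls) -> "SymmetryAxis":
        return cls(np.zeros(3), np.array([0.0, 0.0, 1.0]))

    def radial_distances(self, coords: np.ndarray) -> np.ndarray:
        """Perpendicular distance of each point from the axis, Å."""
        rel = np.atleast_2d(coords) - self.point
        along = rel @ self.direction
        perp = rel - np.outer(along, self.direction)
        return np.linalg.norm(perp, axis=1)

    def axial_heights(self, coords: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(coords) - self.point) @ self.direction

    def transformed(self, t: RigidTransform) -> "SymmetryAxis":
        return SymmetryAxis(t.apply(self.point), t.rotation @ self.direction)


@dataclass
class Tier:
    """One symmetric tier of a ring model."""

    name: str
    order: int
    reference_chain: str
    axis: SymmetryAxis
    member_chains: list[str]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "order": self.order,
            "reference_chain": self.reference_chain,
            "axis": {
                "point": self.axis.point.tolist(),
                "direction": self.axis.direction.tolist(),
            },
            "member_chains": list(self.member_chains),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tier":
        return cls(
            d["name"],
            int(d["order"]),
            d["reference_chain"],
            SymmetryAxis(np.array(d["axis"]["point"]), np.array(d["axis"]["direction"])),
            list(d["member_chains"]),
        )


@dataclass
class RingModel:
    """A structure plus its tier annotations.

    Serialized as mmCIF (one chain per subunit) plus a JSON sidecar with the
    tier metadata, so the pair round-trips losslessly.
    """

    model: StructureModel
    tiers: list[Tier] = field(default_factory=list)

    def tier(self, name: str) -> Tier:
        for t in self.tiers:
            if t.name == name:
                return t
        raise KeyError(f"no tier named {name!r}; have {[t.name for t in self.tiers]}")

    def tier_model(self, name: str) -> StructureModel:
        t = self.tier(name)
        chains = set(t.member_chains)
        atoms = [a for a in self.model.atoms if a.chain_id in chains]
        return StructureModel(atoms, self.model.metadata, self.model.domains)

    @property
    def total_subunits(self) -> int:
        return sum(len(t.member_chains) for t in self.tiers)

    def merged_with(self, other: "RingModel") -> "RingModel":
        return RingModel(
            self.model.merged_with(other.model), self.tiers + other.tiers
        )

    def save(self, cif_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        cif_path = Path(cif_path)
        write_structure(self.model, cif_path)
        sidecar = Path(sidecar_path) if sidecar_path else cif_path.with_suffix(".tiers.json")
        sidecar.write_text(
            json.dumps({"tiers": [t.to_dict() for t in self.tiers]}, indent=1)
        )

    @classmethod
    def load(cls, cif_path: str | Path, sidecar_path: str | Path | None = None) -> "RingModel":
        cif_path = Path(cif_path)
        sidecar = Path(sidecar_path) if sidecar_path else cif_path.with_suffix(".tiers.json")
        model = read_structure(cif_path)
        tiers = [Tier.from_dict(d) for d in json.loads(sidecar.read_text())["tiers"]]
        return cls(model, tiers)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float, bool]:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Correspondence is by order.  Returns ``(transform, rmsd, degenerate)``
    where the transform maps *mobile* onto *target* with minimal RMSD and
    ``degenerate`` flags (near-)collinear point sets whose rotation about
    the common line is undetermined.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must have matching (N, 3) shapes, got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise ValueError("at least 3 paired points are required")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    # collinearity: rank of the centered mobile set < 2 leaves a free rotation
    sv = np.linalg.svd(P0, compute_uv=False)
    degenerate = bool(sv[1] < 1e-8 * max(sv[0], 1.0))
    return RigidTransform(R, t), rmsd, degenerate


# ---------------------------------------------------------------------------
# Cyclic symmetry
# ---------------------------------------------------------------------------

def rotation_about_axis(angle_deg: float, axis: SymmetryAxis) -> RigidTransform:
    """Proper rotation by ``angle_deg`` about an arbitrary axis line."""
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis.direction).as_matrix()
    t = axis.point - R @ axis.point
    return RigidTransform(R, t)


def cn_operators(n: int, axis: SymmetryAxis) -> list[RigidTransform]:
    """The n rotation operators of the cyclic group Cn about ``axis``.

    Operator k rotates by 360·k/n degrees; operator 0 is the identity.
    """
    if n < 1:
        raise ValueError(f"symmetry order must be >= 1, got {n}")
    return [rotation_about_axis(360.0 * k / n, axis) for k in range(n)]


def fit_symmetry_axis(
    ring: StructureModel, member_chains: Sequence[str] | None = None
) -> SymmetryAxis:
    """Best-fit cyclic axis from per-chain centroids.

    The axis passes through the centroid of the chain centroids with
    direction equal to the normal of their best-fit plane, oriented so the
    mean N→C vector of the members has positive projection (ties the two
    antiparallel normals to the chain topology).
    """
    chains = list(member_chains) if member_chains is not None else ring.chain_ids
    if len(chains) < 3:
        raise ValueError(f"need >= 3 member chains to fit an axis, got {len(chains)}")
    cents = []
    nc_vectors = []
    for cid in chains:
        sub = select(ring, chain=cid)
        cents.append(sub.centroid())
        coords = sub.coords()
        nc_vectors.append(coords[-1] - coords[0])
    cents = np.stack(cents)
    if np.max(np.linalg.norm(cents - cents[0], axis=1)) < 1e-6:
        raise ValueError("chain centroids coincide; axis is degenerate")
    center = cents.mean(axis=0)
    _, _, Vt = np.linalg.svd(cents - center)
    normal = Vt[2]
    mean_nc = np.mean(nc_vectors, axis=0)
    if np.dot(normal, mean_nc) < 0:
        normal = -normal
    return SymmetryAxis(center, normal)


def canonical_frame_transform(axis: SymmetryAxis, center: np.ndarray) -> RigidTransform:
    """Transform that puts ``axis`` along +z and ``center`` at the origin."""
    z = np.array([0.0, 0.0, 1.0])
    d = axis.direction
    R, _ = Rotation.align_vectors(z[None, :], d[None, :])
    Rm = R.as_matrix()
    return RigidTransform(Rm, -Rm @ np.asarray(center, dtype=float))


def _member_chain_id(tier_name: str, index: int, orig_chain: str, multi: bool) -> str:
    prefix = tier_name[:1].upper()
    base = f"{prefix}{index:02d}"
    return f"{base}{orig_chain}" if multi else base


def build_cn_ring(
    subunit: StructureModel,
    n: int,
    axis: SymmetryAxis,
    tier_name: str = "ring",
    existing: StructureModel | None = None,
) -> RingModel:
    """Replicate a subunit n times by the Cn operators about ``axis``.

    Copy 0 equals the input subunit exactly (identity operator).  Generated
    chain ids are deterministic: tier letter + zero-padded copy index
    (+ original chain id when the subunit has several chains).
    """
    if n < 1:
        raise ValueError(f"ring order must be >= 1, got {n}")
    if not subunit.chain_ids:
        raise ValueError("subunit has no chains")
    ops = cn_operators(n, axis)
    multi = len(subunit.chain_ids) > 1
    parts: list[StructureModel] = []
    members: list[str] = []
    taken = set(existing.chain_ids) if existing is not None else set()
    for k, op in enumerate(ops):
        mapping = {
            c: _member_chain_id(tier_name, k, c, multi) for c in subunit.chain_ids
        }
        for new_id in mapping.values():
            if new_id in taken:
                raise ValueError(f"chain id collision: {new_id!r}")
            taken.add(new_id)
        copy = op.apply_model(subunit).renamed_chains(mapping)
        parts.append(copy)
        members.append(mapping[subunit.chain_ids[0]] if not multi else list(mapping.values())[0])
    merged = parts[0]
    for p in parts[1:]:
        merged = merged.merged_with(p)
    tier = Tier(tier_name, n, members[0], axis, members)
    return RingModel(merged, [tier])


def resymmetrize(ring: RingModel, tier_name: str, new_n: int) -> RingModel:
    """Regenerate a tier at a new cyclic order, keeping the reference pose.

    The reference subunit's coordinates (radius, height, orientation) are
    preserved bitwise; the remaining ``new_n − 1`` copies are regenerated by
    the C(new_n) operators about the tier axis.  Other tiers are untouched.
    """
    if new_n < 1:
        raise ValueError(f"ring order must be >= 1, got {new_n}")
    t = ring.tier(tier_name)
    ref_atoms = [a for a in ring.model.atoms if a.chain_id == t.reference_chain]
    if not ref_atoms:
        raise ValueError(f"reference chain {t.reference_chain!r} missing from model")
    reference = StructureModel(ref_atoms, ring.model.metadata, ring.model.domains)
    other_atoms = [
        a for a in ring.model.atoms if a.chain_id not in set(t.member_chains)
    ]
    rebuilt = build_cn_ring(
        reference.renamed_chains({t.reference_chain: t.reference_chain}),
        new_n,
        t.axis,
        tier_name,
        existing=StructureModel(other_atoms) if other_atoms else None,
    )
    # keep the reference chain id literal so resymmetrization is traceable
    new_tier = rebuilt.tier(tier_name)
    tiers = [new_tier if x.name == tier_name else x for x in ring.tiers]
    model = StructureModel(
        other_atoms + rebuilt.model.atoms, ring.model.metadata, ring.model.domains
    )
    return RingModel(model, tiers)


def ring_diameter(
    ring: RingModel, tier_name: str, mode: str = "external"
) -> float:
    """Tier diameter in nm from heavy-atom radial extent.

    ``external`` is twice the maximum heavy-atom distance from the tier
    axis; ``internal`` twice the minimum.  Reported in nm to 0.1.
    """
    if mode not in ("external", "internal"):
        raise ValueError(f"mode must be external or internal, got {mode!r}")
    t = ring.tier(tier_name)
    sub = ring.tier_model(tier_name)
    heavy = [a for a in sub.atoms if a.is_heavy]
    if not heavy:
        raise ValueError(f"tier {tier_name!r} has no heavy atoms")
    coords = np.stack([a.position for a in heavy])
    r = t.axis.radial_distances(coords)
    radius = r.max() if mode == "external" else r.min()
    return float(round(2.0 * radius / 10.0, 1))  # Å -> nm
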