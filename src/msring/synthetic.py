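"""Synthetic fixtures: toy subunits, planted rings, noisy maps, homolog pairs.

Every generator is bit-reproducible from its (spec, seed) arguments.  The
toy subunit is a reduced CA/CB model of a two-domain protein with a hinge
linker, standing in for the FliF N-terminal periplasmic fragment (D1 +
linker + D2).  Planted ring maps provide ground truth for every detection
and fitting step: the planted order, radius and poses are stored alongside
the map.

Also provided are clearly-labelled *synthetic stand-ins* for reference
objects that would otherwise require downloads: a two-chain crystal-like
dimer with a planted inter-chain RMSD, a homolog sequence pair with a
planted percent identity, and reference rings built at published diameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    RigidTransform,
    RingModel,
    SymmetryAxis,
    build_cn_ring,
    kabsch_superpose,
    ring_diameter,
    rotation_about_axis,
)
from .density import DensityMap, add_noise, simulate_map
from .model import AtomRecord, DomainAnnotation, StructureModel

__all__ = [
    "ToySubunitSpec",
    "make_toy_subunit",
    "make_planted_ring_map",
    "make_homolog_template_rings",
    "make_synthetic_crystal_dimer",
    "make_synthetic_homolog_sequences",
    "make_reference_ring_standin",
]

_SHAPES = ("helix-bundle", "sheet-slab", "blob")

# 20 standard residues cycled through toy chains so sequences are nontrivial
_TOY_RESIDUES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass(frozen=True)
class ToySubunitSpec:
    """Parameters of a reduced two-domain subunit with a hinge linker."""

    n_residues_d1: int = 20
    n_residues_d2: int = 26
    shape: str = "helix-bundle"
    hinge_angle: float = 0.0  # degrees, rotation of D2 about the junction pivot
    seed: int = 0
    first_residue: int = 58  # author numbering of the first D1 residue

    def __post_init__(self) -> None:
        if self.n_residues_d1 < 5 or self.n_residues_d2 < 5:
            raise ValueError("each domain needs at least 5 residues")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")


def _domain_trace(n: int, shape: str, rng: np.random.Generator) -> np.ndarray:
    """CA trace of one compact domain, centered at the origin."""
    if shape == "helix-bundle":
        # two antiparallel helix-like strands, rise 1.5 Å, radius 2.3 Å
        half = (n + 1) // 2
        t = np.arange(n, dtype=float)
        coords = np.zeros((n, 3))
        up = t < half
        coords[:, 2] = np.where(up, t * 1.5, (n - 1 - t) * 1.5)
        phase = t * 100.0 * math.pi / 180.0
        offset = np.where(up, -4.0, 4.0)
        coords[:, 0] = 2.3 * np.cos(phase) + offset
        coords[:, 1] = 2.3 * np.sin(phase)
    elif shape == "sheet-slab":
        per_strand = max(5, n // 3 + 1)
        coords = np.zeros((n, 3))
        for i in range(n):
            strand, k = divmod(i, per_strand)
            z = k * 3.4 if strand % 2 == 0 else (per_strand - 1 - k) * 3.4
            coords[i] = (strand * 4.8, 1.1 * (-1) ** k, z)
    else:  # blob: self-avoiding-ish random walk, 3.8 Å steps
        coords = np.zeros((n, 3))
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(1, n):
            direction = direction + 0.8 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            # bias back toward the centroid to stay compact
            pull = coords[:i].mean(axis=0) - coords[i - 1]
            npull = np.linalg.norm(pull)
            if npull > 6.0:
                direction = 0.6 * direction + 0.4 * pull / npull
                direction /= np.linalg.norm(direction)
            coords[i] = coords[i - 1] + 3.8 * direction
    coords = coords + rng.normal(scale=0.15, size=coords.shape)
    return coords - coords.mean(axis=0)


def _cb_position(ca: np.ndarray, prev_ca: np.ndarray, next_ca: np.ndarray) -> np.ndarray:
    """Pseudo-CB 1.53 Å from CA, perpendicular to the local chain direction."""
    chain = next_ca - prev_ca
    nc = np.linalg.norm(chain)
    chain = chain / nc if nc > 1e-9 else np.array([1.0, 0.0, 0.0])
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, chain)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    side = np.cross(chain, ref)
    side /= np.linalg.norm(side)
    return ca + 1.53 * side


def make_toy_subunit(spec: ToySubunitSpec) -> StructureModel:
    """Build a deterministic CA/CB two-domain subunit with a 1-residue linker.

    Domain D1 occupies residues ``first_residue .. first_residue+n1-1``, a
    single linker residue follows, then D2.  ``hinge_angle`` rotates every
    D2 atom about an axis through the first D2 CA (the D1/D2 junction
    pivot), perpendicular to the D1→D2 displacement; D1 and linker atoms
    are unaffected, which makes hinge construction exactly invertible.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_residues_d1, spec.n_residues_d2
    d1 = _domain_trace(n1, spec.shape, rng)
    d2 = _domain_trace(n2, spec.shape, rng)
    # chain-continuous layout along +x: D1, one linker residue 3.8 Å past
    # D1's last CA, then D2 with its *first* CA 3.8 Å past the linker.  D2 is
    # spun about z so its bulk points away from D1.
    linker_ca = d1[-1] + np.array([3.8, 0.0, 0.0])
    linker_ca[1:] = 0.0
    d2 = d2 - d2[0]
    bulk = d2[1:].mean(axis=0)
    ang = math.atan2(bulk[1], bulk[0])
    c, s = math.cos(-ang), math.sin(-ang)
    spin = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    d2 = d2 @ spin.T
    d2 = d2 + linker_ca + np.array([3.8, 0.0, 0.0])

    if spec.hinge_angle != 0.0:
        # hinge axis through the first D2 CA (the D1/D2 boundary pivot used
        # by the hinge refit), perpendicular to the D1->D2 line
        axis = SymmetryAxis(d2[0].copy(), np.array([0.0, 0.0, 1.0]))
        op = rotation_about_axis(spec.hinge_angle, axis)
        d2 = op.apply(d2)

    res0 = spec.first_residue
    atoms: list[AtomRecord] = []

    def _append_domain(coords: np.ndarray, start_res: int) -> None:
        n = len(coords)
        for i, ca in enumerate(coords):
            res = start_res + i
            name = _TOY_RESIDUES[res % len(_TOY_RESIDUES)]
            atoms.append(
                AtomRecord("C", "CA", res, name, "A", ca)
            )
            prev_ca = coords[max(i - 1, 0)]
            next_ca = coords[min(i + 1, n - 1)]
            if name != "GLY":
                atoms.append(
                    AtomRecord("C", "CB", res, name, "A", _cb_position(ca, prev_ca, next_ca))
                )

    _append_domain(d1, res0)
    linker_res = res0 + n1
    lname = _TOY_RESIDUES[linker_res % len(_TOY_RESIDUES)]
    atoms.append(AtomRecord("C", "CA", linker_res, lname, "A", linker_ca))
    if lname != "GLY":
        atoms.append(
            AtomRecord("C", "CB", linker_res, lname, "A",
                       _cb_position(linker_ca, d1[-1], d2[0]))
        )
    _append_domain(d2, linker_res + 1)

    domains = [
        DomainAnnotation("D1", res0, res0 + n1 - 1, "Aa"),
        DomainAnnotation("D2", linker_res + 1, linker_res + n2, "Aa"),
    ]
    return StructureModel(
        atoms,
        metadata=f"toy subunit seed={spec.seed} shape={spec.shape} hinge={spec.hinge_angle}",
        domains=domains,
    )


def hinge_pivot_residue(subunit: StructureModel) -> int:
    """Residue index of the hinge pivot: first residue of the D2 domain."""
    for d in subunit.domains:
        if d.name == "D2":
            return d.residue_start
    raise ValueError("subunit has no D2 domain annotation")


def make_planted_ring_map(
    subunit: StructureModel,
    n: int,
    radius: float,
    resolution: float = 8.6,
    noise_snr: float | None = None,
    seed: int = 0,
    voxel_size: float = 2.0,
    padding: float = 12.0,
    tier_name: str = "ring",
) -> tuple[RingModel, DensityMap]:
    """Plant a Cn ring at a given radius and simulate its (optionally noisy) map.

    The subunit is first moved so its centroid sits at ``(radius, 0, 0)``
    with the ring axis along +z through the origin, then replicated by the
    Cn operators.  ``noise_snr`` of ``None`` gives a noise-free map.  The
    returned :class:`RingModel` stores the ground-truth poses.
    """
    if radius <= subunit.radius_of_gyration():
        raise ValueError(
            f"ring radius {radius} Å must exceed the subunit radius of gyration "
            f"({subunit.radius_of_gyration():.1f} Å)"
        )
    placed = RigidTransform(
        np.eye(3), np.array([radius, 0.0, 0.0]) - subunit.centroid()
    ).apply_model(subunit)
    axis = SymmetryAxis.z_axis()
    ring = build_cn_ring(placed, n, axis, tier_name=tier_name)
    dmap = simulate_map(ring.model, resolution, voxel_size=voxel_size, padding=padding)
    if noise_snr is not None:
        rng = np.random.default_rng(seed)
        dmap = add_noise(dmap, noise_snr, rng)
    return ring, dmap


def make_homolog_template_rings(
    seed: int = 0,
    inner_n: int = 24,
    outer_n: int = 24,
    inner_radius: float = 50.0,
    outer_radius: float = 110.0,
    subunit: StructureModel | None = None,
    jitter_rms: float = 1.2,
) -> tuple[RingModel, RingModel]:
    """Two coaxial template rings of toy homolog subunits (default C24/C24).

    Emulates the concentric injectisome-like double ring used as the
    structural template of a tentative model build.  The inner-template
    subunit is a coordinate-jittered homolog of the toy D1 domain placed at
    ``inner_radius``, and the outer one a jittered homolog of D2 at
    ``outer_radius`` — homologous template folds are what makes the
    domain-onto-template superposition meaningful, exactly as the real
    templates are structural homologs of the subunit's domains.  Radii are
    chosen so the inner and outer tiers of the resulting 48-subunit
    tentative model do not interpenetrate radially.
    """
    if inner_radius >= outer_radius:
        raise ValueError("inner template radius must be smaller than the outer one")
    if subunit is None:
        subunit = make_toy_subunit(ToySubunitSpec(seed=seed))
    from .model import select  # local import to avoid a cycle at module load

    d1 = select(subunit, residue_range=_domain_named(subunit, "D1"))
    d2 = select(subunit, residue_range=_domain_named(subunit, "D2"))
    rng_inner = np.random.default_rng((seed, 1))
    rng_outer = np.random.default_rng((seed, 2))
    axis = SymmetryAxis.z_axis()
    rings = []
    for dom, radius, rng, tier in (
        (d1, inner_radius, rng_inner, "tmpl_inner"),
        (d2, outer_radius, rng_outer, "tmpl_outer"),
    ):
        coords = dom.coords() + rng.normal(scale=jitter_rms / np.sqrt(3.0), size=(len(dom), 3))
        homolog = dom.with_coords(coords)
        placed = RigidTransform(
            np.eye(3), np.array([radius, 0.0, 0.0]) - homolog.centroid()
        ).apply_model(homolog)
        n = inner_n if tier == "tmpl_inner" else outer_n
        rings.append(build_cn_ring(placed, n, axis, tier_name=tier))
    return rings[0], rings[1]


def _domain_named(model: StructureModel, name: str) -> DomainAnnotation:
    for d in model.domains:
        if d.name == name:
            return d
    raise ValueError(f"model has no domain annotation {name!r}")


def _single_domain_atoms(coords: np.ndarray, first_res: int) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    n = len(coords)
    for i, ca in enumerate(coords):
        res = first_res + i
        name = _TOY_RESIDUES[res % len(_TOY_RESIDUES)]
        atoms.append(AtomRecord("C", "CA", res, name, "A", ca))
        if name != "GLY":
            atoms.append(
                AtomRecord(
                    "C", "CB", res, name, "A",
                    _cb_position(ca, coords[max(i - 1, 0)], coords[min(i + 1, n - 1)]),
                )
            )
    return atoms


# ---------------------------------------------------------------------------
# Synthetic stand-ins for downloadable reference objects
# ---------------------------------------------------------------------------

def make_synthetic_crystal_dimer(
    target_rmsd: float = 0.694, seed: int = 0, n_residues: int = 40
) -> StructureModel:
    """Synthetic stand-in for a crystal asymmetric unit with two chains.

    Two copies (chains A, B) of a toy domain; chain B carries a planted
    non-rigid deformation whose rigid-body-removed CA RMSD equals
    ``target_rmsd`` exactly, then an arbitrary rigid placement.  Stands in
    for a deposited two-molecule asymmetric unit that cannot be downloaded
    in this environment; the planted RMSD is the quantity a superposition
    must recover.
    """
    rng = np.random.default_rng(seed)
    trace = _domain_trace(n_residues, "blob", rng)
    disp = rng.normal(size=trace.shape)
    # remove the rigid component of the displacement so Kabsch cannot undo it
    deformed = trace + disp
    t, _, _ = kabsch_superpose(deformed, trace)
    deformed = t.apply(deformed)
    resid = deformed - trace
    resid *= target_rmsd / np.sqrt(np.mean(np.sum(resid**2, axis=1)))
    chain_b_coords = trace + resid
    # iterate once: rescaling re-introduces a tiny rigid component
    t2, r2, _ = kabsch_superpose(chain_b_coords, trace)
    chain_b_coords = t2.apply(chain_b_coords)
    resid = chain_b_coords - trace
    resid *= target_rmsd / np.sqrt(np.mean(np.sum(resid**2, axis=1)))
    chain_b_coords = trace + resid
    # arbitrary rigid placement of chain B in the "crystal"
    place = rotation_about_axis(
        73.0, SymmetryAxis(np.array([5.0, -3.0, 2.0]), np.array([0.3, 0.9, 0.3]))
    )
    chain_b_coords = place.apply(chain_b_coords) + np.array([18.0, 4.0, -9.0])
    atoms = []
    for cid, coords in (("A", trace), ("B", chain_b_coords)):
        for i, ca in enumerate(coords):
            name = _TOY_RESIDUES[i % len(_TOY_RESIDUES)]
            atoms.append(AtomRecord("C", "CA", 58 + i, name, cid, ca))
    return StructureModel(
        atoms, metadata=f"synthetic crystal-dimer stand-in, planted CA RMSD {target_rmsd}"
    )


def make_synthetic_homolog_sequences(
    length: int = 156, identity_percent: float = 44.0, seed: int = 0
) -> tuple[str, str]:
    """Synthetic stand-in for a homolog sequence pair at a planted identity.

    Returns two equal-length sequences whose gapless identity equals
    ``round(identity_percent * length / 100) / length``; with the defaults,
    69 matches over 156 positions, i.e. 44% to the nearest integer.  Stands
    in for a pair of database sequences unavailable offline.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq_a = rng.choice(alphabet, size=length)
    seq_b = seq_a.copy()
    n_match = int(round(identity_percent * length / 100.0))
    mutate = rng.choice(length, size=length - n_match, replace=False)
    for pos in mutate:
        choices = alphabet[alphabet != seq_a[pos]]
        seq_b[pos] = rng.choice(choices)
    return "".join(seq_a), "".join(seq_b)


def make_reference_ring_standin(
    order: int,
    external_diameter_nm: float,
    seed: int = 0,
    n_residues: int = 18,
    tier_name: str = "ref",
) -> RingModel:
    """Synthetic stand-in for a deposited homolog ring at a published size.

    Builds a Cn ring of a toy subunit and adjusts the placement radius so
    the heavy-atom external diameter equals ``external_diameter_nm``.
    Stands in for deposited ring structures (e.g. the C24 injectisome inner
    ring, the C34 S-ring, the C30 sporulation-channel ring) that cannot be
    downloaded in this environment.
    """
    rng = np.random.default_rng(seed)
    sub = StructureModel(
        _single_domain_atoms(_domain_trace(n_residues, "blob", rng), 1),
        metadata=f"synthetic reference-ring stand-in C{order}",
    )
    target_radius = external_diameter_nm * 10.0 / 2.0  # nm -> Å
    axis = SymmetryAxis.z_axis()
    r0 = max(target_radius - 20.0, sub.radius_of_gyration() + 1.0)
    placed = RigidTransform(
        np.eye(3), np.array([r0, 0.0, 0.0]) - sub.centroid()
    ).apply_model(sub)
    ring = build_cn_ring(placed, order, axis, tier_name=tier_name)
    measured = ring_diameter(ring, tier_name, "external") * 10.0 / 2.0  # Å radius
    shift = target_radius - measured
    placed = RigidTransform(np.eye(3), np.array([shift, 0.0, 0.0])).apply_model(placed)
    return build_cn_ring(placed, order, axis, tier_name=tier_name)
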