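"""End-to-end MS-ring model building and validation.

The procedure mirrors the hybrid-modelling route for the periplasmic
MS-ring: a tentative concentric double ring is built by superposing the
two domains of a subunit independently onto the inner and outer subunits of
a C24/C24 template double ring (48 placements); the inner tier is then
resymmetrized to C23 against the density, the outer tier pruned to 11
equiangular members and resymmetrized to C11 with a hinge refit of D2
against D1 in the 11-fold-averaged map; finally the M-ring tiers are joined
with the C34 S-ring, giving 23 + 11 = 34 subunits and a 68-strand collar.
Validation covers steric clashes, interface crosslink distances, tier
diameters, self-consistent symmetry detection and linker reach.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .density import (
    DensityMap,
    cn_average,
    detect_symmetry,
    simulate_map,
)
from .fitting import FitConfig, FitResult, hinge_refit, rigid_fit
from .geometry import (
    RigidTransform,
    RingModel,
    SymmetryAxis,
    Tier,
    build_cn_ring,
    kabsch_superpose,
    resymmetrize,
    ring_diameter,
    rotation_about_axis,
)
from .model import StructureModel, select

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "build_tentative_double_ring",
    "prune_tier",
    "derive_inner_ring",
    "derive_middle_ring",
    "assemble_msring",
    "validate",
    "tier_shell",
    "run_pipeline",
]

# Extended-chain contour length per residue, Å (trans backbone).  Used for
# the linker-reach feasibility check: 13 residues at 3.63 Å/residue span up
# to ~47 Å, comfortably more than the ~30 Å gap they must bridge.
EXTENDED_CONTOUR_PER_RESIDUE = 3.63


@dataclass
class PipelineConfig:
    """Symmetry orders, thresholds and search settings for a pipeline run."""

    inner_n: int = 23
    middle_n: int = 11
    sring_n: int = 34
    middle_phase_deg: float = 0.0
    sring_phase_deg: float = 0.0
    clash_cutoff: float = 2.2  # Å, heavy-atom interchain distance
    crosslink_cutoff: float = 7.0  # Å, CB–CB across the interface
    crosslink_pairs: list[tuple[int, int]] = field(default_factory=lambda: [(156, 200)])
    linker_n_residues: int = 13
    linker_required_span: float = 30.0  # Å
    linker_contour_per_residue: float = EXTENDED_CONTOUR_PER_RESIDUE
    resolution: float = 8.6  # Å, for simulated maps and fit scoring
    voxel_size: float = 3.0  # Å, for self-consistency detection maps
    detection_n_max: int = 40
    confidence_threshold: float = 1.5
    hinge: FitConfig = field(default_factory=lambda: FitConfig(coarse_extent=0.0))
    rigid: FitConfig = field(default_factory=lambda: FitConfig(coarse_extent=0.0))
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["crosslink_pairs"] = [list(p) for p in self.crosslink_pairs]
        return d


@dataclass
class ValidationReport:
    """Structured validation record for an assembled ring model."""

    subunit_counts: dict[str, int]
    total_subunits: int
    detected_symmetry: dict[str, dict]  # tier -> {fold, confidence, ambiguous}
    external_diameter_nm: dict[str, float]
    internal_diameter_nm: dict[str, float]
    clash_count: int
    crosslink_distances: list[dict]  # {pair, chains, distance, compatible}
    linker_reach: dict  # {n_residues, required_span, max_span, feasible}
    collar_strand_count: int | None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        d = json.loads(text)
        return cls(**d)


# ---------------------------------------------------------------------------
# Tentative double ring
# ---------------------------------------------------------------------------

def _ca_coords(model: StructureModel) -> np.ndarray:
    cas = [a.position for a in model.atoms if a.atom_name == "CA"]
    if len(cas) < 3:
        raise ValueError("need at least 3 CA atoms for superposition")
    return np.stack(cas)


def _paired(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # order-based correspondence; trim to the common length when the toy
    # domain and template subunit differ in residue count
    n = min(len(a), len(b))
    return a[:n], b[:n]


def build_tentative_double_ring(
    subunit_d1d2: StructureModel,
    template_inner: RingModel,
    template_outer: RingModel,
) -> RingModel:
    """Place the full subunit on both template rings, domain-anchored.

    D1 is superposed onto every inner-template subunit and D2 onto every
    outer-template subunit, independently; each superposition transform then
    carries the *whole* subunit, so the inner tier is D1-anchored and the
    outer tier D2-anchored.  With C24/C24 templates this yields the
    48-subunit (24 + 24) tentative model.
    """
    t_in = template_inner.tiers[0]
    t_out = template_outer.tiers[0]
    if len(t_in.member_chains) != len(t_out.member_chains):
        raise ValueError(
            f"template tier counts differ: {len(t_in.member_chains)} vs "
            f"{len(t_out.member_chains)}"
        )
    d1 = select(subunit_d1d2, residue_range=_domain(subunit_d1d2, "D1"))
    d2 = select(subunit_d1d2, residue_range=_domain(subunit_d1d2, "D2"))
    d1_ca, d2_ca = _ca_coords(d1), _ca_coords(d2)

    parts: list[StructureModel] = []
    inner_members: list[str] = []
    outer_members: list[str] = []
    for tier, anchor_ca, ring, members, prefix in (
        (t_in, d1_ca, template_inner, inner_members, "I"),
        (t_out, d2_ca, template_outer, outer_members, "O"),
    ):
        for k, chain in enumerate(tier.member_chains):
            tmpl_ca = _ca_coords(select(ring.model, chain=chain))
            a, b = _paired(anchor_ca, tmpl_ca)
            transform, _, _ = kabsch_superpose(a, b)
            new_id = f"{prefix}{k:02d}"
            placed = transform.apply_model(subunit_d1d2).renamed_chains(
                {subunit_d1d2.chain_ids[0]: new_id}
            )
            parts.append(placed)
            members.append(new_id)
    merged = parts[0]
    for p in parts[1:]:
        merged = merged.merged_with(p)
    tiers = [
        Tier("inner", t_in.order, inner_members[0], t_in.axis, inner_members),
        Tier("outer", t_out.order, outer_members[0], t_out.axis, outer_members),
    ]
    return RingModel(merged, tiers)


def _domain(model: StructureModel, name: str):
    for d in model.domains:
        if d.name == name:
            return d
    raise ValueError(f"model has no domain annotation {name!r}")


# ---------------------------------------------------------------------------
# Tier derivation
# ---------------------------------------------------------------------------

def prune_tier(ring: RingModel, tier_name: str, keep_n: int, phase_deg: float = 0.0) -> RingModel:
    """Keep the ``keep_n`` members closest to ideal equiangular positions.

    Ideal azimuths start at the reference subunit's azimuth plus
    ``phase_deg`` and advance by 360/keep_n; for each ideal position the
    nearest unused member survives.  The reference member always survives
    (phase 0 puts the first ideal position on it).
    """
    t = ring.tier(tier_name)
    if keep_n > len(t.member_chains):
        raise ValueError(
            f"cannot keep {keep_n} of {len(t.member_chains)} members"
        )
    axis = t.axis
    d = axis.direction
    u = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 0.5:
        u = np.cross(d, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(d, u)

    def azimuth(chain: str) -> float:
        c = select(ring.model, chain=chain).centroid() - axis.point
        return float(np.degrees(np.arctan2(np.dot(c, v), np.dot(c, u))))

    az = {c: azimuth(c) for c in t.member_chains}
    ref_az = az[t.reference_chain]
    kept: list[str] = []
    used: set[str] = set()
    for k in range(keep_n):
        ideal = ref_az + phase_deg + 360.0 * k / keep_n
        best = min(
            (c for c in t.member_chains if c not in used),
            key=lambda c: abs((az[c] - ideal + 180.0) % 360.0 - 180.0),
        )
        kept.append(best)
        used.add(best)
    atoms = [
        a
        for a in ring.model.atoms
        if a.chain_id not in set(t.member_chains) or a.chain_id in used
    ]
    new_tier = Tier(t.name, keep_n, t.reference_chain, t.axis, kept)
    tiers = [new_tier if x.name == tier_name else x for x in ring.tiers]
    return RingModel(StructureModel(atoms, ring.model.metadata, ring.model.domains), tiers)


def derive_inner_ring(
    tentative: RingModel,
    n: int,
    dmap: DensityMap | None = None,
    config: PipelineConfig | None = None,
) -> tuple[RingModel, FitResult | None]:
    """Resymmetrize the inner tier to Cn; optionally rigid-fit into a map.

    The reference subunit's pose is preserved and the other n−1 copies
    regenerated by the Cn operators, so a 24-mer template tier becomes the
    23-mer inner ring without disturbing the anchor subunit.  When a map is
    given, the whole resymmetrized ring is fitted into it as one rigid body
    and the fit recorded.
    """
    config = config or PipelineConfig()
    only_inner = RingModel(
        tentative.tier_model("inner"),
        [tentative.tier("inner")],
    )
    ring = resymmetrize(only_inner, "inner", n)
    fit: FitResult | None = None
    if dmap is not None:
        fit = rigid_fit(ring.model, dmap, config=config.rigid)
        moved = fit.transform.apply_model(ring.model)
        tier = ring.tier("inner")
        ring = RingModel(
            moved,
            [Tier(tier.name, tier.order, tier.reference_chain,
                  tier.axis.transformed(fit.transform), list(tier.member_chains))],
        )
    return ring, fit


def _resymmetrized_outer(
    tentative: RingModel, n: int, phase_deg: float = 0.0
) -> RingModel:
    """Prune the outer tier to n equiangular members and resymmetrize."""
    pruned = prune_tier(
        RingModel(tentative.tier_model("outer"), [tentative.tier("outer")]),
        "outer",
        n,
        phase_deg,
    )
    return resymmetrize(pruned, "outer", n)


def synthesize_middle_map(
    tentative: RingModel,
    n: int,
    hinge_angle_deg: float = 0.0,
    config: PipelineConfig | None = None,
    voxel_size: float = 2.0,
) -> DensityMap:
    """Simulate a middle-region map from the tentative model's own outer tier.

    The outer tier is pruned and resymmetrized to Cn; optionally the
    reference subunit's D2 is rotated by ``hinge_angle_deg`` about the
    domain-junction pivot (axis along the tier axis) before propagation, so
    the map carries a known, recoverable hinge.  Used as the synthetic
    stand-in for the experimental middle-region density.
    """
    config = config or PipelineConfig()
    ring = _resymmetrized_outer(tentative, n, config.middle_phase_deg)
    tier = ring.tier("outer")
    reference = select(ring.model, chain=tier.reference_chain)
    if hinge_angle_deg != 0.0:
        d2_ann = _domain(reference, "D2")
        pivot_ca = next(
            a.position for a in reference.atoms
            if a.residue_index == d2_ann.residue_start and a.atom_name == "CA"
        )
        op = rotation_about_axis(
            hinge_angle_deg, SymmetryAxis(pivot_ca, tier.axis.direction)
        )
        atoms = []
        for a in reference.atoms:
            if d2_ann.residue_start <= a.residue_index <= d2_ann.residue_end:
                atoms.append(a.moved_to(op.apply(a.position[None, :])[0]))
            else:
                atoms.append(a)
        reference = StructureModel(atoms, reference.metadata, reference.domains)
    planted = build_cn_ring(reference, n, tier.axis, tier_name="middle")
    return simulate_map(
        planted.model, config.resolution, voxel_size=voxel_size, padding=12.0
    )


def derive_middle_ring(
    tentative: RingModel,
    n: int,
    dmap: DensityMap,
    config: PipelineConfig | None = None,
) -> tuple[RingModel, FitResult]:
    """Prune the outer tier to n equiangular members, resymmetrize, hinge-refit.

    The map is Cn-averaged about the tier axis first; the reference
    subunit's D2 is then hinge-refit against its fixed D1 in the averaged
    density, and the refit subunit re-propagated by the Cn operators.
    """
    config = config or PipelineConfig()
    ring = _resymmetrized_outer(tentative, n, config.middle_phase_deg)
    tier = ring.tier("outer")
    averaged = cn_average(dmap, n, tier.axis)

    reference = select(ring.model, chain=tier.reference_chain)
    d2_ann = _domain(reference, "D2")
    # the fixed body is everything up to the D2 boundary (D1 plus linker),
    # so no density is left unexplained to bias the hinge search
    fixed = select(
        reference,
        residue_range=(reference.residue_indices()[0], d2_ann.residue_start - 1),
    )
    d2 = select(reference, residue_range=d2_ann)
    refit_sub, fit, _linker_ok = hinge_refit(
        fixed, d2, d2_ann.residue_start, averaged, config=config.hinge
    )
    rebuilt = build_cn_ring(refit_sub, n, tier.axis, tier_name="middle")
    return rebuilt, fit


def assemble_msring(
    inner: RingModel, middle: RingModel, sring: RingModel
) -> RingModel:
    """Join the three tiers into one coaxial model.

    Tier axes must agree within 2°; chain ids must be disjoint.  Tier
    symmetry annotations (23/11/34 with defaults) are retained.
    """
    tiers = [inner, middle, sring]
    base = inner.tiers[0].axis.direction
    for r in tiers[1:]:
        d = r.tiers[0].axis.direction
        angle = np.degrees(np.arccos(np.clip(abs(float(np.dot(base, d))), -1.0, 1.0)))
        if angle > 2.0:
            raise ValueError(f"tier axes diverge by {angle:.1f}° (> 2°); tiers must be coaxial")
    out = inner
    for r in tiers[1:]:
        out = out.merged_with(r)
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def tier_shell(
    ring: RingModel, tier_name: str, radial_margin: float = 6.0, axial_margin: float = 6.0
) -> tuple[float, float, float, float]:
    """Cylindrical shell bounds enclosing one tier, relative to its axis.

    Per-tier shells keep the rotational spectrum of one tier from mixing
    with coaxial tiers at other radii.
    """
    t = ring.tier(tier_name)
    coords = ring.tier_model(tier_name).coords()
    r = t.axis.radial_distances(coords)
    z = t.axis.axial_heights(coords)
    r_min = max(float(r.min()) - radial_margin, 2.0)
    return (r_min, float(r.max()) + radial_margin,
            float(z.min()) - axial_margin, float(z.max()) + axial_margin)


def _crosslink_atom(model: StructureModel, chain: str, residue: int):
    """CB of the residue, CA for glycine; None when the residue is absent."""
    cb = ca = None
    for a in model.atoms:
        if a.chain_id == chain and a.residue_index == residue:
            if a.atom_name == "CB":
                cb = a
            elif a.atom_name == "CA":
                ca = a
    if cb is not None:
        return cb
    if ca is not None and ca.residue_name == "GLY":
        return ca
    return ca  # fall back to CA when the model has no side chains here


def validate(ring: RingModel, config: PipelineConfig | None = None) -> ValidationReport:
    """Compute the validation report for an assembled ring model.

    Covers per-tier subunit counts, self-consistent symmetry detection on a
    map simulated from the model itself, external/internal diameters,
    heavy-atom interchain clashes, interface crosslink distances across
    adjacent inner-ring chains, the linker-reach feasibility check, and the
    collar strand count (2 antiparallel strands per S-ring subunit).
    """
    config = config or PipelineConfig()
    counts = {t.name: len(t.member_chains) for t in ring.tiers}
    # the S-ring tier is formed by the D3 domains of the same subunits whose
    # D1-D2 form the M-ring tiers, so the subunit total counts M-ring tiers only
    if "inner" in counts and "middle" in counts:
        total = counts["inner"] + counts["middle"]
    else:
        total = sum(counts.values())

    detected: dict[str, dict] = {}
    ext: dict[str, float] = {}
    inn: dict[str, float] = {}
    for t in ring.tiers:
        ext[t.name] = ring_diameter(ring, t.name, "external")
        inn[t.name] = ring_diameter(ring, t.name, "internal")
        tier_map = simulate_map(
            ring.tier_model(t.name),
            config.resolution,
            voxel_size=config.voxel_size,
            padding=10.0,
        )
        shell = tier_shell(ring, t.name)
        det = detect_symmetry(
            tier_map,
            t.axis,
            shell,
            candidates=range(2, config.detection_n_max + 1),
            n_max=config.detection_n_max,
            confidence_threshold=config.confidence_threshold,
        )
        detected[t.name] = {
            "fold": det.best_fold,
            "confidence": round(det.confidence, 3),
            "ambiguous": det.ambiguous,
        }

    # clashes: heavy-atom interchain pairs below the cutoff, via a KD-tree
    heavy = [a for a in ring.model.atoms if a.is_heavy]
    coords = np.stack([a.position for a in heavy])
    chain_of = np.array([a.chain_id for a in heavy])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(config.clash_cutoff, output_type="ndarray")
    clash_count = int(np.sum(chain_of[pairs[:, 0]] != chain_of[pairs[:, 1]])) if len(pairs) else 0

    # crosslink screen across adjacent inner-ring chains
    crosslinks: list[dict] = []
    inner_tiers = [t for t in ring.tiers if t.name == "inner"] or ring.tiers[:1]
    t0 = inner_tiers[0]
    members = t0.member_chains
    for res_a, res_b in config.crosslink_pairs:
        for i, chain in enumerate(members):
            nxt = members[(i + 1) % len(members)]
            atom_a = _crosslink_atom(ring.model, chain, res_a)
            atom_b = _crosslink_atom(ring.model, nxt, res_b)
            if atom_a is None or atom_b is None:
                crosslinks.append(
                    {"pair": [res_a, res_b], "chains": [chain, nxt],
                     "distance": None, "compatible": None, "missing": True}
                )
                continue
            dist = float(np.linalg.norm(atom_a.position - atom_b.position))
            crosslinks.append(
                {"pair": [res_a, res_b], "chains": [chain, nxt],
                 "distance": round(dist, 2),
                 "compatible": bool(dist <= config.crosslink_cutoff),
                 "missing": False}
            )

    max_span = config.linker_n_residues * config.linker_contour_per_residue
    linker = {
        "n_residues": config.linker_n_residues,
        "required_span": config.linker_required_span,
        "max_span": round(max_span, 2),
        "feasible": bool(max_span >= config.linker_required_span),
    }

    sring_tiers = [t for t in ring.tiers if t.name == "sring"]
    collar = 2 * sring_tiers[0].order if sring_tiers else None

    return ValidationReport(
        subunit_counts=counts,
        total_subunits=total,
        detected_symmetry=detected,
        external_diameter_nm=ext,
        internal_diameter_nm=inn,
        clash_count=clash_count,
        crosslink_distances=crosslinks,
        linker_reach=linker,
        collar_strand_count=collar,
        provenance={"config": config.to_dict()},
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig | None = None,
    subunit: StructureModel | None = None,
    template_inner: RingModel | None = None,
    template_outer: RingModel | None = None,
    inner_map: DensityMap | None = None,
    middle_map: DensityMap | None = None,
    sring: RingModel | None = None,
    detect_orders: bool = False,
) -> tuple[RingModel, ValidationReport]:
    """Run the full model-building procedure and validate the result.

    Any input left as None is generated synthetically from ``config.seed``
    (toy subunit, C24/C24 templates, planted-order maps, toy S-ring), so the
    pipeline runs end to end without external data.  With ``detect_orders``
    the inner/middle symmetry orders are taken from rotational-spectrum
    detection on the provided maps instead of the configured values.
    """
    from . import synthetic  # deferred: synthetic depends on density/geometry

    config = config or PipelineConfig()
    rng_seed = config.seed
    if subunit is None:
        subunit = synthetic.make_toy_subunit(synthetic.ToySubunitSpec(seed=rng_seed))
    if template_inner is None or template_outer is None:
        template_inner, template_outer = synthetic.make_homolog_template_rings(seed=rng_seed)

    tentative = build_tentative_double_ring(subunit, template_inner, template_outer)

    inner_n, middle_n = config.inner_n, config.middle_n
    if middle_map is None:
        # synthetic middle-region density from the tentative model's own
        # outer tier at the expected order (no planted hinge by default)
        middle_map = synthesize_middle_map(tentative, config.middle_n, config=config)
    if detect_orders:
        inner_ring_tmp = RingModel(
            tentative.tier_model("inner"), [tentative.tier("inner")]
        )
        if inner_map is not None:
            shell = tier_shell(inner_ring_tmp, "inner")
            det = detect_symmetry(
                inner_map, tentative.tier("inner").axis, shell,
                candidates=range(2, config.detection_n_max + 1),
                n_max=config.detection_n_max,
            )
            inner_n = det.best_fold
        shell_mid = tier_shell(
            RingModel(tentative.tier_model("outer"), [tentative.tier("outer")]), "outer"
        )
        det_mid = detect_symmetry(
            middle_map, tentative.tier("outer").axis, shell_mid,
            candidates=range(2, config.detection_n_max + 1),
            n_max=config.detection_n_max,
        )
        middle_n = det_mid.best_fold

    inner_ring, inner_fit = derive_inner_ring(tentative, inner_n, inner_map, config)
    middle_ring, middle_fit = derive_middle_ring(tentative, middle_n, middle_map, config)

    if sring is None:
        # toy S-ring: C34 at 110 Å centroid radius (≈24 nm external diameter),
        # raised 40 Å along the axis — the S-ring sits above the M-ring plane
        sring_sub = synthetic.make_toy_subunit(
            synthetic.ToySubunitSpec(seed=rng_seed + 7, n_residues_d1=12, n_residues_d2=12)
        )
        placed = RigidTransform(
            np.eye(3), np.array([110.0, 0.0, 0.0]) - sring_sub.centroid()
        ).apply_model(sring_sub)
        phase = rotation_about_axis(
            config.sring_phase_deg, SymmetryAxis(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        )
        sring = build_cn_ring(
            phase.apply_model(placed), config.sring_n,
            SymmetryAxis(np.zeros(3), np.array([0.0, 0.0, 1.0])), tier_name="sring",
        )
        lift = RigidTransform(np.eye(3), np.array([0.0, 0.0, 40.0]))
        sring = RingModel(
            lift.apply_model(sring.model),
            [Tier(t.name, t.order, t.reference_chain,
                  t.axis.transformed(lift), list(t.member_chains))
             for t in sring.tiers],
        )

    full = assemble_msring(inner_ring, middle_ring, sring)
    report = validate(full, config)
    report.provenance.update(
        {
            "inner_n": inner_n,
            "middle_n": middle_n,
            "sring_n": config.sring_n,
            "detect_orders": detect_orders,
            "inner_fit_score": None if inner_fit is None else round(inner_fit.score, 4),
            "middle_fit_score": round(middle_fit.score, 4),
            "seed": config.seed,
        }
    )
    return full, report
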