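"""Rigid-body and hinge fitting of atomic models into density maps.

The search is fully deterministic: a coarse orientation grid around the
starting pose, each grid point refined by coordinate descent (rotations
about the model centroid, then translations, with step halving), scored by
real-space correlation of the model's simulated map against the target over
a model-proximal mask.  Determinism is what makes every fit in the pipeline
reproducible bit-for-bit from its configuration.

The hinge refit reorients one domain (D2) about a pivot atom at the domain
junction while the other domain (D1) stays fixed — the step that turns the
template-derived subunit conformation into the middle-region conformation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .density import DensityMap, real_space_correlation, simulate_map
from .geometry import RigidTransform
from .model import StructureModel

__all__ = ["FitConfig", "FitResult", "rigid_fit", "hinge_refit"]


@dataclass(frozen=True)
class FitConfig:
    """Deterministic fit-search parameters.

    All angles in degrees, distances in Å.  ``coarse_step`` spaces the
    orientation grid around the start; ``coarse_extent`` bounds it (one-sided).
    Local refinement halves the rotation step from ``rot_step_init`` down to
    ``rot_step_min`` and the translation step from ``trans_step_init`` down
    to ``trans_step_min``.  ``mask_radius`` defines the model-proximal
    scoring mask; plain correlation over the whole box would be dominated
    by empty space.
    """

    resolution: float = 8.6
    coarse_step: float = 10.0
    coarse_extent: float = 0.0  # 0 disables the coarse grid (local refine only)
    rot_step_init: float = 4.0
    rot_step_min: float = 0.25
    trans_step_init: float = 2.0
    trans_step_min: float = 0.1
    mask_radius: float = 4.0
    support_halo: float = 8.0  # Å; target density this close to the model must be explained
    score_floor: float = 0.2
    n_refine: int = 3  # how many best coarse poses get local refinement
    search: bool = True
    polish: bool = True  # final deterministic Powell polish on the 6-dof pose
    polish_maxiter: int = 50

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        return cls(**d)


@dataclass
class FitResult:
    """Outcome of one deterministic fit."""

    transform: RigidTransform
    score: float
    n_evaluations: int
    converged: bool
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "rotation": self.transform.rotation.tolist(),
            "translation": self.transform.translation.tolist(),
            "score": self.score,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "seed": self.seed,
        }


class _Scorer:
    """Masked real-space correlation of a posed model against a target map.

    The mask is the union of the model-proximal region (voxels within
    ``mask_radius`` of any posed atom) and the *nearby* part of the target's
    support (voxels above 10% of the target maximum, within ``support_halo``
    of the model).  The proximal part keeps empty box corners from diluting
    the score; the nearby-support part penalizes poses that leave adjacent
    target density unexplained, without punishing a subunit fit for distant
    density belonging to its symmetry mates.
    """

    def __init__(
        self,
        model: StructureModel,
        target: DensityMap,
        config: FitConfig,
        frozen_mask: np.ndarray | None = None,
    ):
        self.model = model
        self.coords0 = model.coords()
        self.target = target
        self.config = config
        self.n_evaluations = 0
        self.support = target.grid > 0.1 * float(target.grid.max())
        # a frozen mask (rigid fits) keeps the score surface smooth: a mask
        # rebuilt per pose jumps as atoms cross voxel boundaries and can
        # create false plateaus during refinement
        self.frozen_mask = frozen_mask

    def score_coords(self, coords: np.ndarray) -> float:
        self.n_evaluations += 1
        posed = self.model.with_coords(coords)
        sim = simulate_map(
            posed,
            self.config.resolution,
            voxel_size=self.target.voxel_size,
            origin=self.target.origin,
            shape=self.target.shape,
        )
        if self.frozen_mask is not None:
            mask = self.frozen_mask
        else:
            mask = _proximity_mask(coords, self.target, self.config.mask_radius)
            halo = _proximity_mask(coords, self.target, self.config.support_halo)
            mask |= self.support & halo
        if mask.sum() < 8:
            return -1.0
        try:
            return real_space_correlation(sim, self.target, mask)
        except ValueError:
            return -1.0

    def score(self, t: RigidTransform) -> float:
        return self.score_coords(t.apply(self.coords0))


def _proximity_mask(coords: np.ndarray, dmap: DensityMap, radius: float) -> np.ndarray:
    """Boolean mask of voxels within ``radius`` Å of any atom."""
    mask = np.zeros(dmap.shape, dtype=bool)
    r_vox = radius / dmap.voxel_size
    reach = int(math.ceil(r_vox))
    frac = dmap.xyz_to_index(coords)
    offs = np.arange(-reach, reach + 1)
    cube = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    cube = cube[np.linalg.norm(cube, axis=1) <= r_vox + 0.5]
    for f in frac:
        cells = np.round(f).astype(int) + cube
        ok = np.all((cells >= 0) & (cells < np.array(dmap.shape)), axis=1)
        cells = cells[ok]
        mask[cells[:, 0], cells[:, 1], cells[:, 2]] = True
    return mask


def _rotation_about_point(rotvec_deg: np.ndarray, point: np.ndarray) -> RigidTransform:
    R = Rotation.from_rotvec(np.radians(rotvec_deg)).as_matrix()
    return RigidTransform(R, point - R @ point)


def _local_refine(
    scorer: _Scorer,
    start: RigidTransform,
    start_score: float,
    pivot: np.ndarray,
    config: FitConfig,
    refine_translation: bool = True,
) -> tuple[RigidTransform, float]:
    """Coordinate descent: rotations about ``pivot``, then translations.

    Steps halve until both fall below their minima; each accepted move must
    improve the score, so refinement is monotone by construction.
    """
    best, best_score = start, start_score
    axes = np.eye(3)
    # the halving schedule is repeated until a full cycle brings no gain:
    # coupled rotation/translation ridges can stall a single descent pass
    # once both steps shrink, and a fresh pass at the initial steps escapes
    for _cycle in range(4):
        cycle_start_score = best_score
        rot_step = config.rot_step_init
        trans_step = config.trans_step_init if refine_translation else 0.0
        while rot_step >= config.rot_step_min or (
            refine_translation and trans_step >= config.trans_step_min
        ):
            improved = True
            while improved:
                improved = False
                if refine_translation and trans_step >= config.trans_step_min:
                    for ax, sign in itertools.product(range(3), (+1, -1)):
                        shift = np.zeros(3)
                        shift[ax] = sign * trans_step
                        cand = RigidTransform(np.eye(3), shift).compose(best)
                        s = scorer.score(cand)
                        if s > best_score:
                            best, best_score = cand, s
                            improved = True
                if rot_step >= config.rot_step_min:
                    for ax, sign in itertools.product(range(3), (+1, -1)):
                        cand = _rotation_about_point(
                            sign * rot_step * axes[ax], pivot
                        ).compose(best)
                        s = scorer.score(cand)
                        if s > best_score:
                            best, best_score = cand, s
                            improved = True
            rot_step /= 2.0
            trans_step /= 2.0
        if best_score <= cycle_start_score + 1e-9:
            break
    return best, best_score


def _is_local_optimum(
    scorer: _Scorer, pose: RigidTransform, score: float, pivot: np.ndarray, config: FitConfig
) -> bool:
    """All 6 coordinate perturbations at the final step size reduce the score."""
    for ax, sign in itertools.product(range(3), (+1, -1)):
        cand = _rotation_about_point(
            sign * config.rot_step_min * np.eye(3)[ax], pivot
        ).compose(pose)
        if scorer.score(cand) > score + 1e-12:
            return False
        shift = np.zeros(3)
        shift[ax] = sign * config.trans_step_min
        cand = RigidTransform(np.eye(3), shift).compose(pose)
        if scorer.score(cand) > score + 1e-12:
            return False
    return True


def rigid_fit(
    model: StructureModel,
    dmap: DensityMap,
    start: RigidTransform | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit a model into a map as a single rigid body.

    A coarse orientation grid (step ``coarse_step``, one-sided extent
    ``coarse_extent``) around the start pose is scored; the best
    ``n_refine`` poses are locally refined and the overall best returned.
    With ``search=False`` the start pose is returned exactly, unscathed.
    """
    start = start or RigidTransform.identity()
    config = config or FitConfig()
    coords_start = start.apply(model.coords())
    frac = (coords_start - dmap.origin) / dmap.voxel_size
    inside = np.all((frac >= 0) & (frac < np.array(dmap.shape)), axis=1)
    if not inside.any():
        raise ValueError("model lies entirely outside the map grid at the start pose")

    # mask frozen from the start pose, dilated to cover the search range
    dilation = config.trans_step_init + config.coarse_extent / 4.0
    frozen = _proximity_mask(coords_start, dmap, config.mask_radius + dilation)
    support = dmap.grid > 0.1 * float(dmap.grid.max())
    halo = _proximity_mask(coords_start, dmap, config.support_halo + dilation)
    frozen |= support & halo
    scorer = _Scorer(model, dmap, config, frozen_mask=frozen)
    if not config.search:
        return FitResult(start, scorer.score(start), scorer.n_evaluations, True)

    pivot = coords_start.mean(axis=0)
    candidates: list[tuple[float, RigidTransform]] = []
    steps: list[float] = [0.0]
    k = 1
    while k * config.coarse_step <= config.coarse_extent + 1e-9:
        steps.extend([k * config.coarse_step, -k * config.coarse_step])
        k += 1
    for ax, ay, az in itertools.product(steps, steps, steps):
        rv = np.array([ax, ay, az])
        cand = _rotation_about_point(rv, pivot).compose(start)
        candidates.append((scorer.score(cand), cand))
    candidates.sort(key=lambda sc: -sc[0])

    best_pose, best_score = candidates[0][1], candidates[0][0]
    for s0, pose in candidates[: config.n_refine]:
        pose_r, score_r = _local_refine(scorer, pose, s0, pivot, config)
        if score_r > best_score:
            best_pose, best_score = pose_r, score_r
    if config.polish:
        best_pose, best_score = _powell_polish(
            scorer, best_pose, best_score, pivot, config
        )
    converged = best_score >= config.score_floor and _is_local_optimum(
        scorer, best_pose, best_score, pivot, config
    )
    return FitResult(best_pose, best_score, scorer.n_evaluations, converged)


def _powell_polish(
    scorer: _Scorer,
    pose: RigidTransform,
    score: float,
    pivot: np.ndarray,
    config: FitConfig,
) -> tuple[RigidTransform, float]:
    """Deterministic Powell descent on the 6-dof pose delta.

    Coordinate descent along fixed axes can stall in curved rotation/
    translation valleys of the correlation surface; Powell's direction-set
    updates follow them to the optimum.  Parameters are (rotation-vector
    degrees about the pivot, translation Å) relative to the current pose.
    """
    from scipy.optimize import minimize

    def as_transform(x: np.ndarray) -> RigidTransform:
        delta = _rotation_about_point(x[:3], pivot).compose(
            RigidTransform(np.eye(3), x[3:])
        )
        return delta.compose(pose)

    res = minimize(
        lambda x: -scorer.score(as_transform(x)),
        np.zeros(6),
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-10, "maxiter": config.polish_maxiter},
    )
    polished, polished_score = as_transform(res.x), float(-res.fun)
    if polished_score > score:
        return polished, polished_score
    return pose, score


def hinge_refit(
    d1: StructureModel,
    d2: StructureModel,
    pivot_residue: int,
    dmap: DensityMap,
    config: FitConfig | None = None,
    axis_grid_step: float = 30.0,
    angle_max: float = 45.0,
    angle_step: float = 5.0,
    linker_cutoff: float = 4.5,
) -> tuple[StructureModel, FitResult, bool]:
    """Reorient D2 about the junction pivot to match the map; D1 stays fixed.

    The search grids rotation-axis directions on a sphere (``axis_grid_step``
    polar/azimuthal spacing) and rotation magnitudes up to ``angle_max``,
    then locally refines the best rotation (no translation: the hinge is a
    pure rotation about the pivot CA).  Returns the rebuilt D1+D2 model, the
    fit result (transform = D2 rotation about the pivot), and a linker-
    geometry flag: True when the D1/D2 junction CA–CA distance stays within
    ``linker_cutoff`` Å (a continuous backbone remains plausible).
    """
    config = config or FitConfig()
    pivot_atoms = [
        a for a in d2.atoms if a.residue_index == pivot_residue and a.atom_name == "CA"
    ]
    if not pivot_atoms:
        pivot_atoms = [
            a for a in d1.atoms if a.residue_index == pivot_residue and a.atom_name == "CA"
        ]
    if not pivot_atoms:
        raise ValueError(f"pivot residue {pivot_residue} has no CA in either domain")
    pivot = pivot_atoms[0].position

    d1_coords = d1.coords()

    scorer = _ScorerTwoDomain(d1, d2, dmap, config)
    # spherical grid of axis directions x rotation magnitudes
    best = RigidTransform.identity()
    best_score = scorer.score(best)
    if config.search:
        polar = np.arange(0.0, 180.0 + 1e-9, axis_grid_step)
        azim = np.arange(0.0, 360.0, axis_grid_step)
        angles = np.arange(angle_step, angle_max + 1e-9, angle_step)
        seen_axes: list[np.ndarray] = []
        for th in polar:
            for ph in azim if 0.0 < th < 180.0 else [0.0]:
                d = np.array([
                    math.sin(math.radians(th)) * math.cos(math.radians(ph)),
                    math.sin(math.radians(th)) * math.sin(math.radians(ph)),
                    math.cos(math.radians(th)),
                ])
                if any(np.allclose(d, e) for e in seen_axes):
                    continue
                seen_axes.append(d)
                for ang in angles:
                    cand = _rotation_about_point(ang * d, pivot)
                    s = scorer.score(cand)
                    if s > best_score:
                        best, best_score = cand, s
        best, best_score = _local_refine(
            scorer, best, best_score, pivot, config, refine_translation=False
        )
    d2_new = d2.with_coords(best.apply(d2.coords()))
    # d1 untouched by contract
    assert np.array_equal(d1.coords(), d1_coords)
    result = FitResult(best, best_score, scorer.n_evaluations, best_score >= config.score_floor)

    # linker geometry: distance between the last D1 CA and first D2 CA
    d1_cas = [a for a in d1.atoms if a.atom_name == "CA"]
    d2_cas = [a for a in d2_new.atoms if a.atom_name == "CA"]
    linker_ok = True
    if d1_cas and d2_cas:
        gap = float(np.linalg.norm(d2_cas[0].position - d1_cas[-1].position))
        linker_ok = gap <= linker_cutoff
    refit = StructureModel(d1.atoms + d2_new.atoms, d1.metadata, d1.domains)
    return refit, result, linker_ok


class _ScorerTwoDomain(_Scorer):
    """Scores D1 (fixed) + D2 under a candidate rotation, jointly.

    D1 and D2 may share a chain id (they are disjoint residue ranges of one
    subunit), so plain atom concatenation is well-formed.
    """

    def __init__(
        self, d1: StructureModel, d2: StructureModel, target: DensityMap, config: FitConfig
    ):
        self.d1_coords = d1.coords()
        self.d2_coords = d2.coords()
        super().__init__(StructureModel(d1.atoms + d2.atoms), target, config)

    def score(self, t: RigidTransform) -> float:
        coords = np.vstack([self.d1_coords, t.apply(self.d2_coords)])
        return self.score_coords(coords)
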