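"""Superposition, cyclic operators, ring building, resymmetrization, diameters."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from msring.geometry import (
    RigidTransform,
    RingModel,
    SymmetryAxis,
    build_cn_ring,
    cn_operators,
    fit_symmetry_axis,
    kabsch_superpose,
    resymmetrize,
    ring_diameter,
    rotation_about_axis,
)
from msring.model import AtomRecord, StructureModel, select

RNG = np.random.default_rng(42)


def _random_points(n=10):
    return RNG.normal(scale=8.0, size=(n, 3))


# -- rigid transforms --------------------------------------------------------

def test_rigid_transform_invariants():
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 2.0, np.zeros(3))
    with pytest.raises(ValueError, match="improper"):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    t = RigidTransform(Rotation.from_euler("z", 30, degrees=True).as_matrix(), [1, 2, 3])
    roundtrip = t.compose(t.inverse())
    assert roundtrip.is_identity(atol=1e-12)


# -- Kabsch ------------------------------------------------------------------

def test_kabsch_identity_and_known_rotation():
    pts = _random_points()
    t, rmsd, degen = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert t.is_identity(atol=1e-9) and not degen

    true = RigidTransform(
        Rotation.from_rotvec(np.radians(37.0) * np.array([0, 0, 1.0])).as_matrix(),
        np.array([5.0, -2.0, 9.0]),
    )
    t2, rmsd2, _ = kabsch_superpose(pts, true.apply(pts))
    assert rmsd2 < 1e-9
    np.testing.assert_allclose(t2.rotation, true.rotation, atol=1e-9)
    np.testing.assert_allclose(t2.translation, true.translation, atol=1e-8)


def test_kabsch_preconditions_and_degenerate_flag():
    with pytest.raises(ValueError, match="3"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
    _, _, degen = kabsch_superpose(line, line)
    assert degen


def _oracle_rmsd(mobile, target, grid_deg=10.0):
    """Independent superposition oracle: rotation grid + local polish.

    Scans SO(3) on a Euler grid, then polishes the best rotation with
    Nelder-Mead on the rotation vector; translation is the centroid shift.
    """
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)

    def rmsd_of(R):
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    best, best_rv = np.inf, None
    for a, b, c in itertools.product(
        np.arange(0, 360, grid_deg),
        np.arange(0, 180 + 1e-9, grid_deg),
        np.arange(0, 360, grid_deg),
    ):
        rot = Rotation.from_euler("zyz", [a, b, c], degrees=True)
        v = rmsd_of(rot.as_matrix())
        if v < best:
            best, best_rv = v, rot.as_rotvec()
    res = minimize(
        lambda rv: rmsd_of(Rotation.from_rotvec(rv).as_matrix()),
        best_rv,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    return min(best, float(res.fun))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kabsch_matches_rotation_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    mobile = rng.normal(scale=6.0, size=(10, 3))
    target = rng.normal(scale=6.0, size=(10, 3))
    _, rmsd, _ = kabsch_superpose(mobile, target)
    assert abs(rmsd - _oracle_rmsd(mobile, target)) <= 1e-3


# -- Cn operators ------------------------------------------------------------

def test_cn_operator_basics():
    axis = SymmetryAxis.z_axis()
    assert cn_operators(1, axis)[0].is_identity(atol=1e-12)
    ops4 = cn_operators(4, axis)
    for k, op in enumerate(ops4):
        expected = Rotation.from_euler("z", 90.0 * k, degrees=True).as_matrix()
        np.testing.assert_allclose(op.rotation, expected, atol=1e-12)
    with pytest.raises(ValueError):
        cn_operators(0, axis)


def test_cn_operator_group_structure():
    """Closure, identity and inverses, brute force for n <= 12 (off-axis)."""
    axis = SymmetryAxis(np.array([3.0, -1.0, 2.0]), np.array([0.2, 0.3, 0.93]))
    for n in range(1, 13):
        ops = cn_operators(n, axis)
        for k, m in itertools.product(range(n), repeat=2):
            prod = ops[k].compose(ops[m])
            expect = ops[(k + m) % n]
            np.testing.assert_allclose(prod.rotation, expect.rotation, atol=1e-9)
            np.testing.assert_allclose(prod.translation, expect.translation, atol=1e-7)
        for k in range(n):
            inv = ops[k].inverse()
            expect = ops[(n - k) % n]
            np.testing.assert_allclose(inv.rotation, expect.rotation, atol=1e-9)


# -- axis fitting ------------------------------------------------------------

def _circle_model(n=8, radius=30.0):
    atoms = []
    for k in range(n):
        ang = 2 * np.pi * k / n
        c = np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0])
        for j, off in enumerate([np.zeros(3), np.array([1.5, 0, 0]), np.array([0, 0, 2.0])]):
            atoms.append(AtomRecord("C", ["CA", "CB", "C"][j], j + 1, "ALA", f"C{k}", c + off))
    return StructureModel(atoms)


def test_fit_axis_recovers_circle_and_transforms_covariantly():
    m = _circle_model()
    axis = fit_symmetry_axis(m)
    assert abs(abs(float(np.dot(axis.direction, [0, 0, 1]))) - 1.0) < 1e-6
    np.testing.assert_allclose(axis.point[:2], [0.5, 0.0], atol=1e-6)  # centroid offset from CB/C

    t = RigidTransform(
        Rotation.from_euler("xy", [35, 20], degrees=True).as_matrix(), np.array([4.0, 5.0, 6.0])
    )
    axis2 = fit_symmetry_axis(t.apply_model(m))
    expected = axis.transformed(t)
    assert abs(float(np.dot(axis2.direction, expected.direction))) > 1 - 1e-9
    np.testing.assert_allclose(
        axis2.radial_distances(t.apply(m.coords())),
        axis.radial_distances(m.coords()),
        atol=1e-6,
    )


def test_fit_axis_needs_three_chains():
    m = _circle_model(n=2)
    with pytest.raises(ValueError, match="3"):
        fit_symmetry_axis(m)


# -- ring building -----------------------------------------------------------

def test_build_ring_n1_and_mates_superpose(subunit):
    axis = SymmetryAxis.z_axis()
    solo = build_cn_ring(subunit, 1, axis, tier_name="t")
    np.testing.assert_array_equal(solo.model.coords(), subunit.coords())

    ring = build_cn_ring(subunit, 34, axis, tier_name="s")
    assert len(ring.model.chain_ids) == 34
    ops = cn_operators(34, axis)
    ref = select(ring.model, chain=ring.tiers[0].member_chains[0]).coords()
    for k, cid in enumerate(ring.tiers[0].member_chains):
        mate = select(ring.model, chain=cid).coords()
        back = ops[k].inverse().apply(mate)
        assert np.sqrt(np.mean(np.sum((back - ref) ** 2, axis=1))) < 1e-6


def test_build_ring_spacing_and_collision(subunit):
    axis = SymmetryAxis.z_axis()
    placed = RigidTransform(np.eye(3), np.array([60.0, 0, 0]) - subunit.centroid()).apply_model(subunit)
    ring = build_cn_ring(placed, 23, axis, tier_name="inner")
    cents = np.stack(
        [select(ring.model, chain=c).centroid() for c in ring.tiers[0].member_chains]
    )
    ang = np.degrees(np.arctan2(cents[:, 1], cents[:, 0]))
    gaps = np.diff(np.unwrap(np.radians(ang))) * 180 / np.pi
    np.testing.assert_allclose(gaps, 360.0 / 23, atol=1e-6)
    with pytest.raises(ValueError, match="collision"):
        build_cn_ring(placed, 3, axis, tier_name="inner", existing=ring.model)


def test_build_then_fit_axis_recovers_direction(subunit):
    direction = np.array([0.1, -0.2, 0.97])
    direction /= np.linalg.norm(direction)
    axis = SymmetryAxis(np.array([2.0, 1.0, -3.0]), direction)
    shifted = RigidTransform(np.eye(3), np.array([50.0, 0, 0])).apply_model(subunit)
    for n in (3, 5, 11):
        ring = build_cn_ring(shifted, n, axis, tier_name="t")
        fitted = fit_symmetry_axis(ring.model, ring.tiers[0].member_chains)
        cosang = abs(float(np.dot(fitted.direction, direction)))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 0.5


# -- resymmetrization --------------------------------------------------------

@pytest.fixture()
def ring24(subunit):
    placed = RigidTransform(np.eye(3), np.array([62.0, 0, 0]) - subunit.centroid()).apply_model(subunit)
    return build_cn_ring(placed, 24, SymmetryAxis.z_axis(), tier_name="inner")


def test_resymmetrize_identity(ring24):
    same = resymmetrize(ring24, "inner", 24)
    np.testing.assert_allclose(same.model.coords(), ring24.model.coords(), atol=1e-9)


def test_resymmetrize_24_to_23_preserves_reference(ring24):
    t = ring24.tiers[0]
    ref_before = select(ring24.model, chain=t.reference_chain).coords()
    out = resymmetrize(ring24, "inner", 23)
    assert len(out.tier("inner").member_chains) == 23
    ref_after = select(out.model, chain=out.tier("inner").reference_chain).coords()
    np.testing.assert_array_equal(ref_before, ref_after)  # bitwise
    # diameters barely move when only angular spacing changes
    d24 = ring_diameter(ring24, "inner", "external")
    d23 = ring_diameter(out, "inner", "external")
    assert abs(d24 - d23) < 0.1


def test_resymmetrize_24_to_11(ring24):
    out = resymmetrize(ring24, "inner", 11)
    assert len(out.tier("inner").member_chains) == 11
    cents = np.stack(
        [select(out.model, chain=c).centroid() for c in out.tier("inner").member_chains]
    )
    ang = np.degrees(np.arctan2(cents[:, 1], cents[:, 0]))
    gaps = np.diff(np.unwrap(np.radians(ang))) * 180 / np.pi
    np.testing.assert_allclose(gaps, 360.0 / 11, atol=1e-6)


# -- diameters ---------------------------------------------------------------

def test_ring_diameter_definition():
    atoms = [AtomRecord("C", "CA", 1, "ALA", f"C{k}", np.array([80.0, 0, 0])) for k in range(1)]
    atoms += [AtomRecord("C", "CA", 1, "ALA", "D0", np.array([0.0, 40.0, 0]))]
    m = StructureModel(atoms)
    from msring.geometry import Tier

    ring = RingModel(m, [Tier("t", 2, "C0", SymmetryAxis.z_axis(), ["C0", "D0"])])
    assert ring_diameter(ring, "t", "external") == pytest.approx(16.0)
    assert ring_diameter(ring, "t", "internal") == pytest.approx(8.0)
    with pytest.raises(ValueError):
        ring_diameter(ring, "t", "sideways")


def test_ring_model_save_load_roundtrip(tmp_path, ring24):
    p = tmp_path / "ring.cif"
    ring24.save(p)
    back = RingModel.load(p)
    assert back.tier("inner").order == 24
    assert back.tier("inner").member_chains == ring24.tier("inner").member_chains
    np.testing.assert_allclose(back.model.coords(), ring24.model.coords(), atol=5e-4)
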