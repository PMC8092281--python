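"""Map I/O, simulation, rotation, averaging, spectra and symmetry detection."""

import math

import numpy as np
import pytest

from msring.density import (
    DensityMap,
    add_noise,
    cn_average,
    detect_symmetry,
    read_map,
    real_space_correlation,
    rotate_map,
    rotational_power_spectrum,
    simulate_map,
    write_map,
)
from msring.geometry import SymmetryAxis
from msring.model import AtomRecord, StructureModel
from msring.synthetic import ToySubunitSpec, make_planted_ring_map, make_toy_subunit

Z_AXIS = SymmetryAxis.z_axis()


def _carbon(pos, chain="A", res=1):
    return AtomRecord("C", "CA", res, "ALA", chain, np.asarray(pos, dtype=float))


# -- container and I/O -------------------------------------------------------

def test_densitymap_invariants():
    with pytest.raises(ValueError):
        DensityMap(np.zeros((4, 4, 4)), 2.0)
    with pytest.raises(ValueError):
        DensityMap(np.zeros((16, 16, 16)), -1.0)
    bad = np.zeros((16, 16, 16))
    bad[0, 0, 0] = np.inf
    with pytest.raises(ValueError):
        DensityMap(bad, 1.0)


def test_map_roundtrip_exact(tmp_path):
    rng = np.random.default_rng(0)
    m = DensityMap(rng.random((16, 16, 16)).astype(np.float32), 2.0, np.array([1.0, 2.0, 3.0]))
    p = tmp_path / "m.mrc"
    write_map(m, p)
    back = read_map(p)
    np.testing.assert_array_equal(back.grid, m.grid)
    assert back.voxel_size == pytest.approx(2.0)
    np.testing.assert_allclose(back.origin, m.origin)


def test_read_map_corrupt(tmp_path):
    p = tmp_path / "bad.mrc"
    p.write_bytes(b"this is not a density map")
    with pytest.raises((ValueError, FileNotFoundError)):
        read_map(p)


# -- simulation --------------------------------------------------------------

def test_single_atom_map_peak_and_integral():
    m = simulate_map(StructureModel([_carbon([5.0, 6.0, 7.0])]), resolution=6.0,
                     voxel_size=1.5, padding=12.0)
    peak = np.unravel_index(np.argmax(m.grid), m.shape)
    np.testing.assert_allclose(m.index_to_xyz(peak), [5.0, 6.0, 7.0], atol=1.5)
    # each atom integrates to its atomic number (carbon: 6)
    assert m.integral() == pytest.approx(6.0, rel=0.01)


def test_simulate_nyquist_guard():
    with pytest.raises(ValueError, match="Nyquist"):
        simulate_map(StructureModel([_carbon([0, 0, 0])]), resolution=3.0, voxel_size=2.0)


def test_simulate_linearity():
    a = StructureModel([_carbon([0.0, 0, 0])])
    b = StructureModel([_carbon([14.0, 0, 0], chain="B")])
    both = StructureModel(a.atoms + b.atoms)
    origin, shape = np.array([-10.0, -10, -10]), (20, 20, 20)
    kw = dict(resolution=6.0, voxel_size=2.0, origin=origin, shape=shape)
    m_ab = simulate_map(both, **kw)
    m_a = simulate_map(a, **kw)
    m_b = simulate_map(b, **kw)
    assert float(np.max(np.abs(m_ab.grid - (m_a.grid + m_b.grid)))) < 1e-6


def test_translated_model_shifts_peak():
    shift = np.array([6.0, -4.0, 2.0])
    a = StructureModel([_carbon([0.0, 0, 0])])
    b = a.with_coords(a.coords() + shift)
    origin, shape = np.array([-20.0, -20, -20]), (24, 24, 24)
    kw = dict(resolution=6.0, voxel_size=2.0, origin=origin, shape=shape)
    pa = np.unravel_index(np.argmax(simulate_map(a, **kw).grid), shape)
    pb = np.unravel_index(np.argmax(simulate_map(b, **kw).grid), shape)
    np.testing.assert_allclose((np.array(pb) - np.array(pa)) * 2.0, shift, atol=2.0)


def test_ring_map_self_correlates_under_cn_rotation(c11_ring_and_map):
    _, dmap = c11_ring_and_map
    rotated = rotate_map(dmap, 360.0 / 11, Z_AXIS)
    assert real_space_correlation(dmap, rotated) >= 0.99


# -- rotation and averaging --------------------------------------------------

def test_rotate_identity_and_full_turn(c11_ring_and_map):
    _, dmap = c11_ring_and_map
    same = rotate_map(dmap, 0.0, Z_AXIS)
    np.testing.assert_array_equal(same.grid, dmap.grid)
    full = rotate_map(dmap, 360.0, Z_AXIS)
    assert real_space_correlation(dmap, full) >= 0.999


def test_four_quarter_turns_are_identity(c11_ring_and_map):
    _, dmap = c11_ring_and_map
    out = dmap
    for _ in range(4):
        out = rotate_map(out, 90.0, Z_AXIS)
    assert real_space_correlation(dmap, out) >= 0.995


def test_cn_average_identity_idempotence_symmetry(c11_ring_and_map):
    _, dmap = c11_ring_and_map
    assert np.array_equal(cn_average(dmap, 1, Z_AXIS).grid, dmap.grid)
    avg = cn_average(dmap, 11, Z_AXIS)
    # output is C11-symmetric and averaging is idempotent
    assert real_space_correlation(avg, rotate_map(avg, 360.0 / 11, Z_AXIS)) >= 0.999
    assert real_space_correlation(avg, cn_average(avg, 11, Z_AXIS)) >= 0.999


@pytest.mark.parametrize("n", [5, 11, 23])
def test_cn_average_variance_reduction(n):
    """Averaging n rotated copies of seeded noise cuts its variance ~n-fold.

    The noise field is lightly smoothed first (1 voxel) so that trilinear
    interpolation preserves its variance and the measurement isolates the
    averaging effect; the annulus keeps to radii where successive rotations
    are separated by more than the noise correlation length.
    """
    from scipy import ndimage

    rng = np.random.default_rng(17)
    shape = (64, 64, 16)
    origin = -2.0 * (np.array(shape) - 1) / 2.0
    noise = ndimage.gaussian_filter(rng.normal(0, 1.0, shape), 1.0).astype(np.float32)
    noisy = DensityMap(noise, 2.0, origin)
    avg = cn_average(noisy, n, Z_AXIS)
    idx = np.indices(shape).reshape(3, -1).T
    xyz = origin + 2.0 * idx
    r = np.linalg.norm(xyz[:, :2], axis=1)
    inside = (r < 50.0) & (r > 24.0)
    ratio = float(avg.grid.reshape(-1)[inside].var() / noisy.grid.reshape(-1)[inside].var())
    assert ratio == pytest.approx(1.0 / n, rel=0.2)


def test_averaging_noisy_planted_map_recovers_clean(subunit):
    ring, clean = make_planted_ring_map(subunit, 11, 55.0, seed=5)
    _, noisy = make_planted_ring_map(subunit, 11, 55.0, noise_snr=1.0, seed=5)
    before = real_space_correlation(noisy, clean)
    after = real_space_correlation(cn_average(noisy, 11, Z_AXIS), clean)
    assert after > before


# -- correlation -------------------------------------------------------------

def test_correlation_bounds_and_errors(c11_ring_and_map):
    _, dmap = c11_ring_and_map
    assert real_space_correlation(dmap, dmap) == pytest.approx(1.0)
    neg = DensityMap(-dmap.grid, dmap.voxel_size, dmap.origin)
    assert real_space_correlation(dmap, neg) == pytest.approx(-1.0)
    flat = DensityMap(np.ones_like(dmap.grid), dmap.voxel_size, dmap.origin)
    with pytest.raises(ValueError, match="constant"):
        real_space_correlation(dmap, flat)


def test_correlation_with_seeded_noise_is_reproducible(c11_ring_and_map):
    _, dmap = c11_ring_and_map
    vals = []
    for _ in range(2):
        noisy = add_noise(dmap, snr=1.0, rng=np.random.default_rng(123))
        vals.append(real_space_correlation(dmap, noisy))
    assert abs(vals[0] - vals[1]) < 1e-6


# -- spectra -----------------------------------------------------------------

def _painted_cos_map(fold, shape=(64, 64, 16), voxel=2.0):
    """Analytic density cos(fold*theta) on a cylindrical band."""
    origin = -voxel * (np.array(shape) - 1) / 2.0
    idx = np.indices(shape).astype(float)
    xyz = origin[:, None, None, None] + voxel * idx
    r = np.hypot(xyz[0], xyz[1])
    theta = np.arctan2(xyz[1], xyz[0])
    band = ((r > 30.0) & (r < 45.0)).astype(np.float32)
    grid = band * (1.0 + np.cos(fold * theta)).astype(np.float32)
    return DensityMap(grid, voxel, origin)


def test_spectrum_of_painted_cosine_concentrates_at_fold():
    dmap = _painted_cos_map(23)
    spec = rotational_power_spectrum(dmap, Z_AXIS, (28.0, 47.0, -8.0, 8.0), n_max=40)
    assert spec.power.sum() == pytest.approx(spec.power[0] + spec.power[1] + 1.0, abs=1e-9)
    assert int(spec.fold_numbers[2:][np.argmax(spec.power[2:])]) == 23
    assert spec.power_at(23) > 0.95


def test_spectrum_of_uniform_shell_is_flat_zero():
    shape = (48, 48, 16)
    origin = -2.0 * (np.array(shape) - 1) / 2.0
    idx = np.indices(shape).astype(float)
    xyz = origin[:, None, None, None] + 2.0 * idx
    r = np.hypot(xyz[0], xyz[1])
    grid = ((r > 20.0) & (r < 35.0)).astype(np.float32)
    dmap = DensityMap(grid, 2.0, origin)
    spec = rotational_power_spectrum(dmap, Z_AXIS, (22.0, 33.0, -6.0, 6.0), n_max=20)
    assert float(spec.power[2:].sum()) < 1e-4 or float(spec.power[2:].max()) < 0.2


def test_spectrum_empty_shell_errors(c11_ring_and_map):
    _, dmap = c11_ring_and_map
    with pytest.raises(ValueError):
        rotational_power_spectrum(dmap, Z_AXIS, (40.0, 30.0, -5.0, 5.0))


# -- detection ---------------------------------------------------------------

def test_noise_free_detection_sweep():
    """Detected fold equals the planted order for every n in 3..40."""
    blob = make_toy_subunit(ToySubunitSpec(seed=9, n_residues_d1=5, n_residues_d2=5))
    for n in range(3, 41):
        radius = max(22.0, n * 13.0 / (2 * math.pi))
        _, dmap = make_planted_ring_map(blob, n, radius, voxel_size=2.5, resolution=8.6)
        det = detect_symmetry(
            dmap, Z_AXIS, (radius - 12.0, radius + 12.0, -10.0, 10.0),
            candidates=range(2, 41), n_max=40,
        )
        assert det.best_fold == n, f"planted C{n} detected as C{det.best_fold}"


@pytest.mark.parametrize("n,radius", [(11, 55.0), (23, 62.0), (34, 85.0)])
def test_planted_noisy_detection(subunit, n, radius):
    _, dmap = make_planted_ring_map(subunit, n, radius, noise_snr=1.0, seed=7)
    det = detect_symmetry(
        dmap, Z_AXIS, (radius - 15.0, radius + 15.0, -12.0, 12.0),
        candidates=range(2, 41), n_max=40,
    )
    assert det.best_fold == n and not det.ambiguous


def test_asymmetric_blob_is_flagged_ambiguous():
    rng = np.random.default_rng(3)
    atoms = [
        _carbon(rng.normal(scale=18.0, size=3), res=i + 1) for i in range(40)
    ]
    dmap = simulate_map(StructureModel(atoms), resolution=8.6, voxel_size=2.0, padding=16.0)
    center = dmap.center()
    axis = SymmetryAxis(center, np.array([0.0, 0.0, 1.0]))
    det = detect_symmetry(dmap, axis, (5.0, 30.0, -15.0, 15.0), candidates=range(2, 41))
    assert det.ambiguous
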