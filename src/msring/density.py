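"""Density-map container, I/O, simulation, averaging and symmetry detection.

A :class:`DensityMap` is a cubic-voxel 3D grid with an origin, matching the
MRC/CCP4 2014 convention (mode 2, float32).  Maps are either read from disk
(via gemmi, which normalizes axis order) or simulated from an atomic model
by stamping an isotropic Gaussian per atom.

The rotational power spectrum decomposes the density on cylindrical shells
into angular Fourier components; the dominant fold among candidate orders
identifies the cyclic symmetry of a tier.  This is the data-driven step that
assigns C23/C11/C34 to the MS-ring tiers from medium-resolution maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage

from .geometry import SymmetryAxis, rotation_about_axis
from .model import StructureModel

__all__ = [
    "DensityMap",
    "RotationalSpectrum",
    "SymmetryDetection",
    "read_map",
    "write_map",
    "simulate_map",
    "rotate_map",
    "cn_average",
    "rotational_power_spectrum",
    "detect_symmetry",
    "real_space_correlation",
    "add_noise",
]

# Small periodic-table excerpt: elements that occur in protein models.
ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34, "FE": 26,
    "MG": 12, "ZN": 30, "CA": 20, "MN": 25, "X": 6,
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class DensityMap:
    """Regular 3D density grid with cubic voxels.

    ``grid[i, j, k]`` sits at Cartesian position
    ``origin + voxel_size * (i, j, k)`` (axes x, y, z in index order).
    """

    grid: np.ndarray
    voxel_size: float  # Å per voxel edge
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    provenance: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if min(self.grid.shape) < 8:
            raise ValueError(f"grid dimensions must be >= 8, got {self.grid.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def index_to_xyz(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + self.voxel_size * np.asarray(idx, dtype=float)

    def xyz_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional grid indices of Cartesian points."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def interpolate(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points; outside -> 0."""
        idx = self.xyz_to_index(np.atleast_2d(xyz)).T
        return ndimage.map_coordinates(
            self.grid, idx, order=1, mode="constant", cval=0.0
        )

    def center(self) -> np.ndarray:
        return self.index_to_xyz((np.array(self.shape) - 1) / 2.0)

    def integral(self) -> float:
        return float(self.grid.sum(dtype=np.float64) * self.voxel_size**3)

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy(), self.provenance)


@dataclass
class RotationalSpectrum:
    """Angular Fourier power over a cylindrical shell, per fold number.

    Power is normalized so the total over folds >= 2 sums to 1 (fold 0 is
    the mean, fold 1 mostly reflects axis miscentering; both are excluded
    from the normalization and from detection).
    """

    fold_numbers: np.ndarray
    power: np.ndarray
    shell: tuple[float, float, float, float]  # (r_min, r_max, z_min, z_max) Å

    def __post_init__(self) -> None:
        self.fold_numbers = np.asarray(self.fold_numbers, dtype=int)
        self.power = np.asarray(self.power, dtype=float)
        if not np.all(np.isfinite(self.power)):
            raise ValueError("spectrum power must be finite")

    def power_at(self, fold: int) -> float:
        hit = np.nonzero(self.fold_numbers == fold)[0]
        if len(hit) == 0:
            raise KeyError(f"fold {fold} not in spectrum")
        return float(self.power[hit[0]])

    def to_dict(self) -> dict:
        return {
            "fold_numbers": self.fold_numbers.tolist(),
            "power": self.power.tolist(),
            "shell": list(self.shell),
        }


@dataclass
class SymmetryDetection:
    """Outcome of cyclic-symmetry detection on one shell."""

    best_fold: int
    confidence: float  # power ratio best / second-best
    ambiguous: bool
    spectrum: RotationalSpectrum

    def to_dict(self) -> dict:
        return {
            "best_fold": self.best_fold,
            "confidence": self.confidence,
            "ambiguous": self.ambiguous,
            "spectrum": self.spectrum.to_dict(),
        }


# ---------------------------------------------------------------------------
# I/O (MRC/CCP4 2014, mode 2)
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map; axis order is normalized on read.

    Non-cubic voxels are resampled onto the smallest cubic spacing with a
    warning in the provenance string.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as MRC/CCP4: {exc}") from exc
    ccp4.setup(float("nan"))  # reorder axes to X, Y, Z and fill full cell
    arr = np.array(ccp4.grid, copy=True)
    arr = np.nan_to_num(arr, nan=0.0)
    cell = ccp4.grid.unit_cell
    nx, ny, nz = arr.shape
    spacings = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    provenance = f"read from {path.name}"
    if np.ptp(spacings) > 1e-4 * spacings.mean():
        target = float(spacings.min())
        zoom = spacings / target
        arr = ndimage.zoom(arr, zoom, order=1)
        spacings = np.array([target] * 3)
        provenance += " [resampled to cubic voxels]"
    voxel = float(spacings.mean())
    # origin: prefer explicit ORIGIN header, else the start indices
    origin = np.array([ccp4.header_float(50), ccp4.header_float(51), ccp4.header_float(52)])
    if np.allclose(origin, 0.0):
        start = np.array([ccp4.header_i32(5), ccp4.header_i32(6), ccp4.header_i32(7)])
        origin = start * voxel
    return DensityMap(arr, voxel, origin, provenance)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a map in MRC/CCP4 2014 format, mode 2 (float32)."""
    path = Path(path)
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.shape
    a, b, c = (np.array([nx, ny, nz]) * dmap.voxel_size).tolist()
    grid.set_unit_cell(gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    ccp4.set_header_float(50, float(dmap.origin[0]))
    ccp4.set_header_float(51, float(dmap.origin[1]))
    ccp4.set_header_float(52, float(dmap.origin[2]))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_map(
    model: StructureModel,
    resolution: float,
    voxel_size: float = 2.0,
    padding: float = 10.0,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> DensityMap:
    """Simulate density from a model: one isotropic Gaussian per atom.

    The Gaussian FWHM equals the nominal ``resolution`` and the amplitude is
    proportional to the atomic number Z, normalized so each atom integrates
    to Z (so the map integral equals the model's total atomic number).  The
    grid either encloses the model with ``padding`` on all sides or uses the
    caller's explicit ``origin``/``shape`` (for scoring against a fixed
    target grid).
    """
    if len(model) == 0:
        raise ValueError("cannot simulate a map from an empty model")
    if resolution < 2.0 * voxel_size:
        raise ValueError(
            f"resolution {resolution} Å violates Nyquist for voxel {voxel_size} Å "
            f"(needs resolution >= {2 * voxel_size})"
        )
    coords = model.coords()
    if origin is None or shape is None:
        lo = coords.min(axis=0) - padding
        hi = coords.max(axis=0) + padding
        n = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 8)
        origin = lo
        shape = tuple(int(x) for x in n)
    grid = np.zeros(shape, dtype=np.float64)
    sigma = resolution * _FWHM_TO_SIGMA
    # stamp radius: 4 sigma captures > 99.99% of each Gaussian's mass
    reach = int(math.ceil(4.0 * sigma / voxel_size))
    # normalized 3D Gaussian sampled at voxel centers; amplitude Z / (2πσ²)^{3/2}
    norm = (2.0 * math.pi * sigma * sigma) ** -1.5
    axes_cache: dict[tuple[int, ...], np.ndarray] = {}
    zs = np.array([ATOMIC_NUMBER.get(a.element.upper(), 6) for a in model.atoms], dtype=float)
    frac = (coords - origin) / voxel_size
    for (fx, fy, fz), z_number in zip(frac, zs):
        i0 = max(int(math.floor(fx)) - reach, 0)
        i1 = min(int(math.floor(fx)) + reach + 2, shape[0])
        j0 = max(int(math.floor(fy)) - reach, 0)
        j1 = min(int(math.floor(fy)) + reach + 2, shape[1])
        k0 = max(int(math.floor(fz)) - reach, 0)
        k1 = min(int(math.floor(fz)) + reach + 2, shape[2])
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        gx = np.exp(-((np.arange(i0, i1) - fx) * voxel_size) ** 2 / (2 * sigma * sigma))
        gy = np.exp(-((np.arange(j0, j1) - fy) * voxel_size) ** 2 / (2 * sigma * sigma))
        gz = np.exp(-((np.arange(k0, k1) - fz) * voxel_size) ** 2 / (2 * sigma * sigma))
        grid[i0:i1, j0:j1, k0:k1] += (
            z_number * norm * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    return DensityMap(
        grid.astype(np.float32),
        voxel_size,
        np.asarray(origin, dtype=float),
        provenance=f"simulated at {resolution} Å from {len(model)} atoms",
    )


def add_noise(dmap: DensityMap, snr: float, rng: np.random.Generator) -> DensityMap:
    """Add white Gaussian noise at a given signal-to-noise ratio.

    SNR convention: noise std = (RMS of the noise-free density over its
    support, voxels above 5% of the maximum) / snr.
    """
    support = dmap.grid > 0.05 * float(dmap.grid.max())
    signal_rms = float(np.sqrt(np.mean(dmap.grid[support].astype(np.float64) ** 2)))
    sigma = signal_rms / snr
    noisy = dmap.grid + rng.normal(0.0, sigma, size=dmap.shape).astype(np.float32)
    return DensityMap(
        noisy, dmap.voxel_size, dmap.origin.copy(),
        dmap.provenance + f" [+noise snr={snr}]",
    )


# ---------------------------------------------------------------------------
# Rotation, averaging, correlation
# ---------------------------------------------------------------------------

def rotate_map(dmap: DensityMap, angle_deg: float, axis: SymmetryAxis) -> DensityMap:
    """Rotate a map about an arbitrary axis (trilinear; outside -> 0)."""
    if angle_deg % 360.0 == 0.0:
        return dmap.copy()
    # output voxel at x comes from input at T^{-1} x
    inv = rotation_about_axis(-angle_deg, axis)
    # index-space affine: idx_in = (R (idx_out*v + o) + t - o) / v
    R = inv.rotation
    offset = (R @ dmap.origin + inv.translation - dmap.origin) / dmap.voxel_size
    out = ndimage.affine_transform(
        dmap.grid, R, offset=offset, order=1, mode="constant", cval=0.0
    )
    return DensityMap(out, dmap.voxel_size, dmap.origin.copy(), dmap.provenance)


def cn_average(dmap: DensityMap, n: int, axis: SymmetryAxis) -> DensityMap:
    """Impose Cn symmetry by averaging the n rotated copies of a map."""
    if n < 1:
        raise ValueError(f"symmetry order must be >= 1, got {n}")
    if n == 1:
        return dmap.copy()
    acc = np.zeros(dmap.shape, dtype=np.float64)
    for k in range(n):
        acc += rotate_map(dmap, 360.0 * k / n, axis).grid
    return DensityMap(
        (acc / n).astype(np.float32),
        dmap.voxel_size,
        dmap.origin.copy(),
        dmap.provenance + f" [C{n} averaged]",
    )


def real_space_correlation(
    a: DensityMap, b: DensityMap, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of two maps over unmasked voxels.

    The maps must share grid geometry; ``mask`` is an optional boolean array
    selecting the voxels to correlate.  A constant map has no defined
    correlation and raises.
    """
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if abs(a.voxel_size - b.voxel_size) > 1e-6:
        raise ValueError("voxel sizes differ")
    x = a.grid.astype(np.float64).ravel()
    y = b.grid.astype(np.float64).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        x, y = x[m], y[m]
    if len(x) < 2:
        raise ValueError("fewer than 2 voxels to correlate")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant map")
    return float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * sx * sy))


# ---------------------------------------------------------------------------
# Rotational power spectrum and symmetry detection
# ---------------------------------------------------------------------------

def rotational_power_spectrum(
    dmap: DensityMap,
    axis: SymmetryAxis,
    shell: tuple[float, float, float, float],
    n_max: int = 40,
) -> RotationalSpectrum:
    """Angular Fourier power of the density on a cylindrical shell.

    ``shell`` is (r_min, r_max, z_min, z_max) in Å, radii measured from the
    axis and heights along it (relative to the axis point).  Density is
    resampled on rings with at least ``4 * n_max`` angular samples; per-ring
    power spectra are accumulated over the shell, weighted by ring radius
    (annulus area), and normalized so folds >= 2 sum to 1.
    """
    r_min, r_max, z_min, z_max = shell
    if not (r_max > r_min >= 0.0 and z_max >= z_min):
        raise ValueError(f"invalid shell bounds {shell}")
    step = dmap.voxel_size
    radii = np.arange(r_min + step / 2, r_max, step)
    heights = np.arange(z_min + step / 2, z_max + step / 2, step)
    if len(radii) == 0 or len(heights) == 0:
        raise ValueError(f"shell {shell} is empty at voxel size {step}")
    # angular sampling must resolve n_max and stay below the arc-length
    # limit at the innermost radius
    m = max(4 * n_max, 64)
    m = int(2 ** math.ceil(math.log2(m)))
    if n_max >= m // 2:
        raise ValueError(f"n_max {n_max} exceeds angular sampling limit {m // 2}")
    theta = 2.0 * math.pi * np.arange(m) / m
    # orthonormal frame (u, v, d) with d the axis direction
    d = axis.direction
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, d)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, seed)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    circle = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v  # (m, 3)
    folds = np.arange(0, n_max + 1)
    acc = np.zeros(n_max + 1, dtype=np.float64)
    for r in radii:
        ring_dirs = r * circle
        for z in heights:
            pts = axis.point + z * d + ring_dirs
            vals = dmap.interpolate(pts)
            spec = np.fft.rfft(vals)
            power = np.abs(spec[: n_max + 1]) ** 2 / (m * m)
            acc += r * power  # annulus-area weight
    total = acc[2:].sum()
    if total > 0:
        out = acc.copy()
        out[2:] /= total
    else:
        out = acc
    return RotationalSpectrum(folds, out, (r_min, r_max, z_min, z_max))


def detect_symmetry(
    dmap: DensityMap,
    axis: SymmetryAxis,
    shell: tuple[float, float, float, float],
    candidates: range | list[int] | None = None,
    n_max: int = 40,
    confidence_threshold: float = 1.5,
) -> SymmetryDetection:
    """Identify the cyclic order of a map region by its rotational spectrum.

    ``best_fold`` is the argmax of spectral power among the candidate folds
    (default 2..n_max); ties break toward the smaller fold.  ``confidence``
    is the power ratio of the best to second-best candidate; below the
    threshold the result is flagged ambiguous rather than returned as firm.
    A true Cn map concentrates power at multiples of n (never at proper
    divisors), so the plain argmax identifies n itself.
    """
    if candidates is None:
        candidates = range(2, n_max + 1)
    candidates = [int(c) for c in candidates]
    if any(c < 2 for c in candidates):
        raise ValueError("candidate folds must be >= 2")
    n_max = max(n_max, max(candidates))
    spectrum = rotational_power_spectrum(dmap, axis, shell, n_max=n_max)
    powers = np.array([spectrum.power_at(c) for c in candidates])
    order = np.argsort(powers)[::-1]
    # stable tie-break toward the smaller fold
    best_idx = min(
        (i for i in range(len(candidates)) if powers[i] == powers[order[0]]),
        key=lambda i: candidates[i],
    )
    best = candidates[best_idx]
    rest = [p for i, p in enumerate(powers) if i != best_idx]
    second = max(rest) if rest else 0.0
    confidence = float(powers[best_idx] / second) if second > 0 else float("inf")
    return SymmetryDetection(
        best_fold=best,
        confidence=confidence,
        ambiguous=bool(confidence < confidence_threshold),
        spectrum=spectrum,
    )
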