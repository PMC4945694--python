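"""Synthetic voxelized nuclear masks.

Generates binary voxel phantoms of ellipsoidal cell nuclei on an
anisotropic lattice mimicking confocal z-stacks (default in-plane pixel
0.207 µm, slice spacing 1.0 µm), together with population samples whose
group statistics follow the three nuclear configurations observed in
engineered-niche cultures (spread / half-spread / roundish).

The voxel membership rule is center inclusion: a voxel is foreground iff
its center lies inside the rotated ellipsoid.  Populations are drawn from
truncated normals on the major semi-axis and on the elongation (b/a) and
flatness (c/a) shape indices, which guarantees a >= b >= c by construction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

DEFAULT_SPACING = (0.207, 0.207, 1.0)  # µm, (dx, dy, dz)

#: Group-level defaults: major semi-axis a (mean, SD) in µm are the measured
#: population values; elongation/flatness index means are qualitative readings
#: of the published scatter regions and are exposed as configuration, not used
#: as reference values anywhere.
GROUP_DEFAULTS = {
    "spread": dict(a_mean=7.89, a_sd=1.41, elong_mean=0.90, elong_sd=0.05,
                   flat_mean=0.45, flat_sd=0.08),
    "half_spread": dict(a_mean=7.85, a_sd=1.30, elong_mean=0.80, elong_sd=0.05,
                        flat_mean=0.65, flat_sd=0.08),
    "roundish": dict(a_mean=5.30, a_sd=0.73, elong_mean=0.95, elong_sd=0.03,
                     flat_mean=0.90, flat_sd=0.05),
}


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Regular anisotropic voxel lattice.

    ``shape`` is the number of voxels along (X, Y, Z); ``spacing`` the voxel
    edge lengths in µm.  Voxel centers sit at ``(i + 0.5) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (µm)")

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid along each axis, µm."""
        return np.asarray(self.shape, float) * np.asarray(self.spacing, float)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def centers(self, axis: int) -> np.ndarray:
        return (np.arange(self.shape[axis]) + 0.5) * self.spacing[axis]


@dataclasses.dataclass
class VoxelGrid:
    """Binary nuclear mask on a :class:`GridSpec` lattice, indexed [x, y, z]."""

    grid: GridSpec
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != tuple(self.grid.shape):
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}")

    @property
    def foreground_volume(self) -> float:
        """Foreground voxel count times voxel volume, µm³."""
        return float(self.mask.sum()) * self.grid.voxel_volume


@dataclasses.dataclass(frozen=True)
class GroupSpec:
    """Statistical description of one nuclear-configuration group."""

    label: str
    a_mean: float
    a_sd: float
    elong_mean: float
    elong_sd: float
    flat_mean: float
    flat_sd: float
    n: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.label not in ("spread", "half_spread", "roundish"):
            raise ValueError(f"unknown group label {self.label!r}")
        if self.a_mean <= 0 or min(self.a_sd, self.elong_sd, self.flat_sd) < 0:
            raise ValueError("means must be > 0 and SDs >= 0")
        if not (0 < self.flat_mean <= self.elong_mean <= 1):
            raise ValueError("need 0 < flatness <= elongation <= 1")
        if self.n < 1:
            raise ValueError("group size n must be >= 1")

    @classmethod
    def from_label(cls, label: str, n: int = 1, seed: int = 0, **overrides) -> "GroupSpec":
        params = dict(GROUP_DEFAULTS[label])
        params.update(overrides)
        return cls(label=label, n=n, seed=seed, **params)


def _rotation_matrix(orientation) -> np.ndarray:
    R = np.eye(3) if orientation is None else np.asarray(orientation, float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("orientation must be a 3x3 rotation matrix")
    return R


def make_ellipsoid_mask(semi_axes, orientation=None, centroid=None,
                        grid: GridSpec | None = None) -> VoxelGrid:
    """Voxelize a solid ellipsoid by the center-inclusion rule.

    Parameters
    ----------
    semi_axes : (a, b, c) in µm, all > 0 (any order; the solid is the same).
    orientation : 3x3 rotation mapping body axes to lab axes, or None.
    centroid : ellipsoid center in µm; defaults to the grid center.
    grid : target lattice; defaults to a lattice auto-sized to the ellipsoid
        with a one-voxel margin at default confocal spacing.

    The ellipsoid must fit entirely inside the grid extent, otherwise a
    ``ValueError`` reports the offending axis.
    """
    s = np.asarray(semi_axes, float)
    if s.shape != (3,) or np.any(s <= 0):
        raise ValueError("semi_axes must be three positive lengths")
    R = _rotation_matrix(orientation)
    # half-extent of the rotated ellipsoid's axis-aligned bounding box
    half = np.sqrt(((R * s[None, :]) ** 2).sum(axis=1))
    if grid is None:
        sp = np.asarray(DEFAULT_SPACING)
        shape = tuple(int(np.ceil(2 * (h + 2 * d) / d)) for h, d in zip(half, sp))
        grid = GridSpec(shape, tuple(sp))
    c = grid.extent / 2 if centroid is None else np.asarray(centroid, float)
    lo, hi = c - half, c + half
    for ax, name in enumerate("XYZ"):
        if lo[ax] < -1e-9 or hi[ax] > grid.extent[ax] + 1e-9:
            raise ValueError(
                f"ellipsoid exceeds grid bounds along {name}: needs "
                f"[{lo[ax]:.3f}, {hi[ax]:.3f}] µm inside [0, {grid.extent[ax]:.3f}] µm")

    # restrict the test to the bounding sub-box of voxel centers
    idx = []
    for ax in range(3):
        cc = grid.centers(ax)
        i0 = int(np.searchsorted(cc, lo[ax] - grid.spacing[ax]))
        i1 = int(np.searchsorted(cc, hi[ax] + grid.spacing[ax]))
        idx.append((i0, i1, cc[i0:i1]))
    X, Y, Z = np.meshgrid(idx[0][2], idx[1][2], idx[2][2], indexing="ij")
    pts = np.stack([X - c[0], Y - c[1], Z - c[2]], axis=-1)
    body = pts @ R  # (x-c) . R == R^T (x-c) row-wise
    inside = ((body / s) ** 2).sum(axis=-1) <= 1.0

    mask = np.zeros(grid.shape, bool)
    mask[idx[0][0]:idx[0][1], idx[1][0]:idx[1][1], idx[2][0]:idx[2][1]] = inside
    return VoxelGrid(grid, mask)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled normal truncated to (lo, hi]."""
    if sd == 0:
        if not (lo < mean <= hi):
            raise ValueError("degenerate mean outside truncation interval")
        return np.full(size, float(mean))
    out = np.empty(size)
    need = np.ones(size, bool)
    while need.any():
        draw = rng.normal(mean, sd, int(need.sum()))
        ok = (draw > lo) & (draw <= hi)
        pos = np.flatnonzero(need)[ok]
        out[pos] = draw[ok]
        need[pos] = False
    return out


def _random_rotation(rng) -> np.ndarray:
    """Haar-uniform rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(Rm))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def sample_population(spec: GroupSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``spec.n`` nuclei as (semi_axes, orientation) tuples.

    The major semi-axis is a normal truncated at a > 0; elongation and
    flatness indices are truncated to (0, 1]; semi-axes are re-sorted
    descending so every tuple satisfies a >= b >= c > 0.  Identical specs
    (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    a = _truncated_normal(rng, spec.a_mean, spec.a_sd, 0.0, np.inf, spec.n)
    elo = _truncated_normal(rng, spec.elong_mean, spec.elong_sd, 0.0, 1.0, spec.n)
    fla = _truncated_normal(rng, spec.flat_mean, spec.flat_sd, 0.0, 1.0, spec.n)
    out = []
    for i in range(spec.n):
        axes = np.sort(np.array([a[i], a[i] * elo[i], a[i] * fla[i]]))[::-1]
        out.append((axes, _random_rotation(rng)))
    return out


def perturb_mask(v: VoxelGrid, flip_rate: float, seed: int = 0) -> VoxelGrid:
    """Emulate residual segmentation noise.

    Each voxel is independently flipped with probability ``flip_rate``; a
    single majority-vote cleanup pass over the 6-neighborhood (plus the voxel
    itself) then removes isolated speckle, mimicking the manual artifact
    removal step of a segmentation pipeline.  Deterministic under fixed seed.
    """
    if not (0 <= flip_rate < 0.5):
        raise ValueError("flip_rate must be in [0, 0.5)")
    if flip_rate == 0:
        return VoxelGrid(v.grid, v.mask.copy())
    rng = np.random.default_rng(seed)
    flipped = v.mask ^ (rng.random(v.mask.shape) < flip_rate)
    # majority vote over 6-neighborhood + self (7 votes, threshold 4);
    # zero padding so out-of-grid neighbors count as background
    m = flipped.astype(np.int8)
    p = np.pad(m, 1)
    votes = (p[1:-1, 1:-1, 1:-1]
             + p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
             + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
             + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:])
    return VoxelGrid(v.grid, votes >= 4)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF stacks (one page per Z slice) + YAML sidecar


def write_mask(v: VoxelGrid, path, truth: dict | None = None) -> None:
    """Write a mask as an 8-bit (0/255) multi-page TIFF plus a YAML sidecar
    carrying the voxel spacing and optional ground-truth parameters."""
    import tifffile

    path = Path(path)
    stack = (v.mask.transpose(2, 1, 0).astype(np.uint8)) * 255  # (Z, Y, X)
    tifffile.imwrite(path, stack)
    meta = {"spacing_um": [float(s) for s in v.grid.spacing],
            "shape_xyz": [int(s) for s in v.grid.shape]}
    if truth:
        meta["truth"] = truth
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_mask(path) -> VoxelGrid:
    """Read a TIFF mask written by :func:`write_mask` (YAML sidecar required
    for the spacing; defaults to confocal spacing if absent)."""
    import tifffile

    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    mask = (stack > 0).transpose(2, 1, 0)  # back to [x, y, z]
    spacing = DEFAULT_SPACING
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        spacing = tuple(meta.get("spacing_um", DEFAULT_SPACING))
    return VoxelGrid(GridSpec(mask.shape, spacing), mask)
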