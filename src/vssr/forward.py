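"""Spherical-conductor MEG forward model.

Magnetic fields of current dipoles in a homogeneous conducting sphere
(Sarvas closed form), sampled by an array of planar gradiometers, and
lead-field construction on a regular volumetric source grid.  The same
forward solutions are shared by the cohort simulator and the LCMV
beamformer, so forward/inverse consistency is exact up to noise.

Conventions
-----------
* All positions are in meters in a single head-centered frame.
* Dipole moments are in A·m; gradiometer outputs are in T/m (Tesla per
  meter), i.e. the finite difference of the field component along the
  coil orientation across the gradiometer baseline, divided by the
  baseline.
* Source orientations are restricted to the two tangential directions:
  the radial component of a dipole in a spherical conductor is
  externally silent, so a third column would only ill-condition the
  beamformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU0_OVER_4PI = 1e-7  # μ0 / 4π in T·m/A

__all__ = [
    "HeadModel",
    "SensorArray",
    "SourceGrid",
    "LeadField",
    "default_sensor_array",
    "sarvas_field",
    "sarvas_dipole_field",
    "tangential_basis",
    "build_grid",
    "occipital_slab_grid",
    "build_leadfield",
]


@dataclass(frozen=True)
class HeadModel:
    """Single-sphere volume conductor."""

    sphere_center: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    sphere_radius: float = 0.09

    def __post_init__(self):
        object.__setattr__(
            self, "sphere_center",
            np.asarray(self.sphere_center, dtype=float))
        if not self.sphere_radius > 0:
            raise ValueError("sphere_radius must be > 0")


@dataclass(frozen=True)
class SensorArray:
    """Helmet of planar gradiometers.

    ``coil_position`` (n, 3) and ``coil_orientation`` (n, 3, unit norm)
    define each channel; the channel output is the two-point finite
    difference of B·orientation across ``gradiometer_baseline`` along
    the orientation direction.
    """

    channel_id: list[str]
    coil_position: np.ndarray
    coil_orientation: np.ndarray
    gradiometer_baseline: float = 0.0168

    def __post_init__(self):
        object.__setattr__(self, "coil_position",
                           np.asarray(self.coil_position, dtype=float))
        ori = np.asarray(self.coil_orientation, dtype=float)
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("coil orientations must be unit-norm")
        object.__setattr__(self, "coil_orientation", ori)
        if len(self.channel_id) != len(set(self.channel_id)):
            raise ValueError("channel ids must be unique")
        if len(self.channel_id) != self.coil_position.shape[0]:
            raise ValueError("channel_id / coil_position length mismatch")

    @property
    def n_channels(self) -> int:
        return self.coil_position.shape[0]


def _cap_points(n_sites: int, radius: float, max_polar: float) -> np.ndarray:
    """Fibonacci lattice on a spherical cap (helmet-like coverage)."""
    k = np.arange(n_sites)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    # uniform in cos(theta) between cos(max_polar) and 1
    cos_t = 1.0 - (1.0 - np.cos(max_polar)) * (k + 0.5) / n_sites
    theta = np.arccos(cos_t)
    phi = golden * k
    return radius * np.column_stack([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])


def default_sensor_array(n_sites: int = 102,
                         helmet_radius: float = 0.102,
                         head: HeadModel | None = None) -> SensorArray:
    """204 planar gradiometers: 102 helmet sites × 2 orthogonal axes.

    Mirrors the layout of a MEGIN-style array at the fidelity the
    pipeline needs: paired orthogonal planar gradiometers on a
    spherical cap above a 9 cm head sphere.
    """
    head = head or HeadModel()
    pts = _cap_points(n_sites, helmet_radius, max_polar=2.0)
    pts = pts + head.sphere_center
    positions, orientations, ids = [], [], []
    for i, p in enumerate(pts):
        radial = (p - head.sphere_center)
        radial /= np.linalg.norm(radial)
        t1, t2 = tangential_basis(radial)
        for ax, t in (("a", t1), ("b", t2)):
            positions.append(p)
            orientations.append(t)
            ids.append(f"MEG{i:03d}{ax}")
    return SensorArray(ids, np.array(positions), np.array(orientations))


def tangential_basis(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``radial`` and to each other.

    Deterministic: uses ẑ as reference, falling back to x̂ near the
    poles so the basis is defined everywhere except at zero radius.
    """
    radial = np.asarray(radial, dtype=float)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(radial @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(ref, radial)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(radial, t1)
    t2 /= np.linalg.norm(t2)
    return t1, t2


def sarvas_field(dipole_position: np.ndarray,
                 dipole_moment: np.ndarray,
                 points: np.ndarray,
                 head: HeadModel) -> np.ndarray:
    """Magnetic field B (Tesla) of a current dipole in a sphere.

    Closed-form solution for the field outside a spherically symmetric
    conductor; independent of the conductivity profile.  ``points`` is
    (n, 3); returns (n, 3).
    """
    c = head.sphere_center
    r0 = np.asarray(dipole_position, dtype=float) - c
    q = np.asarray(dipole_moment, dtype=float)
    r = np.atleast_2d(points) - c

    if np.linalg.norm(r0) >= head.sphere_radius:
        raise ValueError("dipole must lie strictly inside the sphere")

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("field point coincides with the dipole")
    r0_dot_r = r @ r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)

    F = a * (rn * a + rn ** 2 - r0_dot_r)
    gF_coef_r = a ** 2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn
    gF_coef_r0 = a + 2.0 * rn + a_dot_r / a
    grad_F = gF_coef_r[:, None] * r - gF_coef_r0[:, None] * r0[None, :]

    q_x_r0 = np.cross(q, r0)
    B = (F[:, None] * q_x_r0[None, :] - (r @ q_x_r0)[:, None] * grad_F)
    return MU0_OVER_4PI * B / (F ** 2)[:, None]


def sarvas_dipole_field(dipole_position: np.ndarray,
                        dipole_moment: np.ndarray,
                        head: HeadModel,
                        sensors: SensorArray) -> np.ndarray:
    """Planar-gradiometer signal (T/m) of one dipole, per channel.

    Each channel measures the two-point finite difference of the field
    component along its coil orientation, taken across the gradiometer
    baseline centered on the coil position.
    """
    half = 0.5 * sensors.gradiometer_baseline * sensors.coil_orientation
    p_plus = sensors.coil_position + half
    p_minus = sensors.coil_position - half
    b_plus = sarvas_field(dipole_position, dipole_moment, p_plus, head)
    b_minus = sarvas_field(dipole_position, dipole_moment, p_minus, head)
    diff = np.einsum("ij,ij->i", b_plus - b_minus, sensors.coil_orientation)
    return diff / sensors.gradiometer_baseline


@dataclass(frozen=True)
class SourceGrid:
    """Regular axis-aligned lattice of candidate source locations."""

    spacing: float
    voxel_coords: np.ndarray      # (n_inside, 3) — inside voxels only
    shape: tuple[int, int, int]   # lattice extent
    ijk: np.ndarray               # (n_inside, 3) integer lattice indices

    @property
    def n_voxels(self) -> int:
        return self.voxel_coords.shape[0]

    def nearest_voxel(self, point: np.ndarray) -> int:
        d = np.linalg.norm(self.voxel_coords - np.asarray(point), axis=1)
        return int(np.argmin(d))


def build_grid(head: HeadModel, spacing: float = 0.004,
               margin: float = 0.005,
               bounds: np.ndarray | None = None) -> SourceGrid:
    """Lattice covering the sphere interior (minus ``margin`` at the rim).

    ``bounds`` ((3, 2) min/max per axis, head frame) optionally
    restricts the lattice to a sub-volume, e.g. an occipital slab for
    reduced-resolution localization runs.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    R = head.sphere_radius - margin
    c = head.sphere_center
    axes = []
    for d in range(3):
        lo, hi = -R, R
        if bounds is not None:
            lo, hi = max(lo, bounds[d][0] - c[d]), min(hi, bounds[d][1] - c[d])
        n_lo = int(np.floor(lo / spacing))
        n_hi = int(np.ceil(hi / spacing))
        axes.append(np.arange(n_lo, n_hi + 1))
    I, J, K = np.meshgrid(*axes, indexing="ij")
    ijk = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    coords = ijk * spacing + c
    inside = np.linalg.norm(coords - c, axis=1) <= R
    if bounds is not None:
        for d in range(3):
            inside &= (coords[:, d] >= bounds[d][0]) & (coords[:, d] <= bounds[d][1])
    if not np.any(inside):
        raise ValueError("grid has no voxels inside the head")
    shape = tuple(len(ax) for ax in axes)
    ijk_in = ijk[inside] - np.array([ax[0] for ax in axes])
    return SourceGrid(spacing, coords[inside], shape, ijk_in)


def occipital_slab_grid(head: HeadModel, spacing: float = 0.01) -> SourceGrid:
    """Reduced grid over the posterior (occipital) part of the volume."""
    c = head.sphere_center
    bounds = np.array([
        [c[0] - 0.05, c[0] + 0.05],
        [c[1] - 0.09, c[1] - 0.03],   # posterior: negative y
        [c[2] - 0.03, c[2] + 0.05],
    ])
    return build_grid(head, spacing=spacing, bounds=bounds)


@dataclass(frozen=True)
class LeadField:
    """Forward solutions: (n_voxels, n_channels, 2) in T/m per A·m.

    Column k of voxel v is the gradiometer signal of a unit dipole at
    the voxel along tangential direction ``orientations[v, k]``.
    """

    matrix: np.ndarray        # (n_voxels, n_channels, 2)
    orientations: np.ndarray  # (n_voxels, 2, 3)
    grid: SourceGrid
    head: HeadModel
    sensors: SensorArray


def build_leadfield(grid: SourceGrid, head: HeadModel,
                    sensors: SensorArray) -> LeadField:
    """Two-column (tangential) lead field for every grid voxel.

    Deterministic for fixed inputs.  A voxel at the sphere center has
    no defined tangential plane and gets an all-zero lead field (it is
    silent anyway).
    """
    if grid.n_voxels == 0:
        raise ValueError("empty source grid")
    n_ch = sensors.n_channels
    L = np.zeros((grid.n_voxels, n_ch, 2))
    oris = np.zeros((grid.n_voxels, 2, 3))
    c = head.sphere_center
    for v, pos in enumerate(grid.voxel_coords):
        radial = pos - c
        rn = np.linalg.norm(radial)
        if rn < 1e-9:
            continue  # silent center voxel
        t1, t2 = tangential_basis(radial / rn)
        oris[v, 0], oris[v, 1] = t1, t2
        L[v, :, 0] = sarvas_dipole_field(pos, t1, head, sensors)
        L[v, :, 1] = sarvas_dipole_field(pos, t2, head, sensors)
    return LeadField(L, oris, grid, head, sensors)
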