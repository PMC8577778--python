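"""Synthetic inputs with known ground truth.

Two generators stand in for the study's physical inputs:

* :func:`synth_spectrum` emulates open-coaxial-probe permittivity
  measurements: a Debye model evaluated on the probe's frequency grid
  with independent multiplicative (truncated-normal) noise on the real
  part and the conductivity.  Probe uncertainty budgets are quoted in
  percent, so relative noise is the natural model.
* :func:`make_phantom` builds a parametric mosquito-like phantom from
  analytic solids — spherical head, spherical thorax, prolate-ellipsoid
  abdomen, optional cylindrical proboscis and up to six cylindrical
  legs — aligned along a grid axis.  It emits both a watertight surface
  mesh and a body-part-labeled voxel mask.  Default dimensions target a
  male mosquito (body length 3.5 mm, volume 0.8 mm^3), the scale where
  millimeter-wave resonance effects appear.

Homogeneous-sphere phantoms for the analytic Mie oracle come from
:func:`make_sphere_phantom`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.stats import truncnorm
from skimage import measure

from aedosim.dielectric import (
    DebyeParameters,
    PermittivitySpectrum,
    dak_tl_grid,
    evaluate_debye,
)
from aedosim.geometry import LABELS, VoxelModel

__all__ = [
    "NoiseModel",
    "PhantomSpec",
    "PhantomError",
    "synth_spectrum",
    "make_phantom",
    "make_sphere_phantom",
]


class PhantomError(ValueError):
    """Raised for infeasible phantom specifications."""


@dataclass(frozen=True)
class NoiseModel:
    """Relative measurement noise: independent multiplicative factors
    ``1 + sd * z`` with ``z`` standard normal truncated at +-4 sd."""

    relative_sd_eps: float = 0.0
    relative_sd_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd_eps < 0 or self.relative_sd_sigma < 0:
            raise ValueError("noise standard deviations must be nonnegative")


def synth_spectrum(
    params: DebyeParameters,
    grid=None,
    noise: NoiseModel | None = None,
    sigma_params: DebyeParameters | None = None,
    temperature: float = 22.0,
) -> PermittivitySpectrum:
    """Generate a synthetic permittivity spectrum from a Debye truth model.

    ``params`` supplies eps_real (and sigma unless ``sigma_params`` is
    given).  With ``noise=None`` or zero standard deviations the output
    equals the model evaluation exactly; a fixed seed reproduces the
    spectrum bit for bit.
    """
    freqs = dak_tl_grid() if grid is None else np.asarray(grid, dtype=float)
    eps_real, _, _ = evaluate_debye(params, freqs)
    _, _, sigma = evaluate_debye(sigma_params or params, freqs)
    eps_real = np.asarray(eps_real, dtype=float).copy()
    sigma = np.asarray(sigma, dtype=float).copy()
    if noise is not None and (noise.relative_sd_eps or noise.relative_sd_sigma):
        rng = np.random.default_rng(noise.seed)
        if noise.relative_sd_eps:
            z = truncnorm.rvs(-4, 4, size=freqs.size, random_state=rng)
            eps_real *= 1.0 + noise.relative_sd_eps * z
        if noise.relative_sd_sigma:
            z = truncnorm.rvs(-4, 4, size=freqs.size, random_state=rng)
            sigma *= 1.0 + noise.relative_sd_sigma * z
    return PermittivitySpectrum(
        frequencies=freqs,
        eps_real=eps_real,
        sigma=np.clip(sigma, 0.0, None),
        temperature=temperature,
        provenance="synthetic",
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a parametric mosquito-like phantom.

    ``body_length`` is the trunk extent (head front to abdomen tip)
    along the alignment axis; ``total_volume`` is the whole-phantom
    target including legs and proboscis.  ``part_fractions`` divides the
    body length into head/thorax/abdomen sections.  All lengths in
    meters, volumes in m^3.
    """

    body_length: float = 3.5e-3
    total_volume: float = 0.8e-9
    n_legs: int = 6
    leg_radius: float = 50e-6
    leg_length: float = 3.0e-3
    part_fractions: tuple[float, float, float] = (0.115, 0.20, 0.685)
    proboscis: bool = True
    proboscis_radius: float = 40e-6
    proboscis_length: float = 0.7e-3
    axis: int = 0

    def __post_init__(self):
        if not 1e-3 <= self.body_length <= 10e-3:
            raise PhantomError("body_length must lie in [1, 10] mm")
        if self.n_legs not in range(7):
            raise PhantomError("n_legs must be 0..6")
        if abs(sum(self.part_fractions) - 1.0) > 1e-9:
            raise PhantomError("part fractions must sum to 1")
        if min(self.part_fractions) <= 0:
            raise PhantomError("part fractions must be positive")
        if self.axis not in (0, 1, 2):
            raise PhantomError("axis must be 0, 1 or 2")
        if self.total_volume <= 0:
            raise PhantomError("total_volume must be positive")


@dataclass
class _Solids:
    """Analytic solids of a phantom, built along +x; label order matters."""

    spheres: list = field(default_factory=list)     # (center, radius, label)
    ellipsoids: list = field(default_factory=list)  # (center, (a,b,c), label)
    cylinders: list = field(default_factory=list)   # (start, direction, length, radius, label)


_LEG_SPRAWL = math.radians(55.0)
_LEG_TILT = math.radians(35.0)
_OVERLAP_FRACTION = 0.04  # axial overlap between adjacent trunk solids


def _build_solids(spec: PhantomSpec) -> _Solids:
    L = spec.body_length
    fh, ft, fa = spec.part_fractions
    delta = _OVERLAP_FRACTION * L

    r_h = fh * L / 2.0
    head_c = np.array([r_h, 0.0, 0.0])
    r_t = (ft * L + delta) / 2.0
    thorax_c = np.array([fh * L - delta + r_t, 0.0, 0.0])
    a_ab = (fa * L + delta) / 2.0
    abd_c = np.array([L - a_ab, 0.0, 0.0])

    v_legs = spec.n_legs * math.pi * spec.leg_radius**2 * spec.leg_length
    v_prob = math.pi * spec.proboscis_radius**2 * spec.proboscis_length if spec.proboscis else 0.0
    v_head = 4.0 / 3.0 * math.pi * r_h**3
    v_thorax = 4.0 / 3.0 * math.pi * r_t**3
    v_abd = spec.total_volume - v_legs - v_prob - v_head - v_thorax
    if v_abd <= 0:
        raise PhantomError(
            f"infeasible spec: head/thorax/appendages already exceed the "
            f"volume target ({spec.total_volume * 1e9:.3f} mm^3)"
        )
    b_ab = math.sqrt(v_abd * 3.0 / (4.0 * math.pi * a_ab))
    if b_ab > a_ab:
        raise PhantomError(
            f"infeasible spec: abdomen would be oblate (b={b_ab * 1e3:.2f} mm "
            f"> a={a_ab * 1e3:.2f} mm); increase body_length or reduce volume"
        )

    s = _Solids()
    s.spheres.append((head_c, r_h, LABELS["head"]))
    s.spheres.append((thorax_c, r_t, LABELS["thorax"]))
    s.ellipsoids.append((abd_c, (a_ab, b_ab, b_ab), LABELS["abdomen"]))
    for leg in range(spec.n_legs):
        side = 1.0 if leg % 2 == 0 else -1.0
        alpha = (-_LEG_SPRAWL, 0.0, _LEG_SPRAWL)[leg // 2]
        d = np.array(
            [
                math.sin(alpha) * math.cos(_LEG_TILT),
                side * math.cos(alpha) * math.cos(_LEG_TILT),
                -math.sin(_LEG_TILT),
            ]
        )
        start = thorax_c + d * (0.95 * r_t)
        s.cylinders.append((start, d, spec.leg_length, spec.leg_radius, LABELS["legs"]))
    if spec.proboscis:
        s.cylinders.append(
            (
                head_c,
                np.array([-1.0, 0.0, 0.0]),
                r_h + spec.proboscis_length,
                spec.proboscis_radius,
                LABELS["other"],
            )
        )
    return s


def _solids_bbox(s: _Solids) -> tuple[np.ndarray, np.ndarray]:
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for c, r, _ in s.spheres:
        lo = np.minimum(lo, c - r)
        hi = np.maximum(hi, c + r)
    for c, (a, b, cc), _ in s.ellipsoids:
        r = np.array([a, b, cc])
        lo = np.minimum(lo, c - r)
        hi = np.maximum(hi, c + r)
    for start, d, ln, r, _ in s.cylinders:
        for p in (start, start + d * ln):
            lo = np.minimum(lo, p - r)
            hi = np.maximum(hi, p + r)
    return lo, hi


def _rasterize(s: _Solids, h: float, padding: int = 1):
    lo, hi = _solids_bbox(s)
    origin = lo - padding * h
    shape = tuple(int(math.ceil((hi[a] - lo[a]) / h)) + 2 * padding for a in range(3))
    x = origin[0] + (np.arange(shape[0]) + 0.5) * h
    y = origin[1] + (np.arange(shape[1]) + 0.5) * h
    z = origin[2] + (np.arange(shape[2]) + 0.5) * h
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    labels = np.zeros(shape, dtype=np.uint8)

    def paint(mask, label):
        labels[mask & (labels == 0)] = label

    for c, r, label in s.spheres:
        paint((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r * r, label)
    for c, (a, b, cc), label in s.ellipsoids:
        paint(
            ((X - c[0]) / a) ** 2 + ((Y - c[1]) / b) ** 2 + ((Z - c[2]) / cc) ** 2 <= 1.0,
            label,
        )
    for start, d, ln, r, label in s.cylinders:
        px = X - start[0]
        py = Y - start[1]
        pz = Z - start[2]
        t = px * d[0] + py * d[1] + pz * d[2]
        d2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
        paint((t >= 0.0) & (t <= ln) & (d2 <= r * r), label)
    return origin, labels


def _extract_mesh(labels: np.ndarray, origin: np.ndarray, h: float) -> trimesh.Trimesh:
    vol = np.pad((labels != 0).astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=(h, h, h))
    # marching_cubes indexes voxel centers; padding shifted them by one.
    verts = verts + (origin - 0.5 * h)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    return mesh


def make_phantom(
    spec: PhantomSpec, h: float = 25e-6
) -> tuple[trimesh.Trimesh, VoxelModel]:
    """Build a mosquito-like phantom: watertight mesh plus labeled voxels.

    Deterministic: the same spec and pitch always produce identical
    output.  The achieved trunk extent equals ``spec.body_length`` to
    within one voxel and the voxelized volume tracks ``total_volume``
    (discretization keeps it within a few percent at the default 25 um
    pitch).
    """
    if not h > 0:
        raise PhantomError("voxel pitch must be positive")
    solids = _build_solids(spec)
    origin, labels = _rasterize(solids, h)
    mesh = _extract_mesh(labels, origin, h)
    if spec.axis != 0:
        order = {1: (1, 0, 2), 2: (2, 1, 0)}[spec.axis]
        labels = np.transpose(labels, order)
        origin = origin[list(order)]
        perm = np.zeros((3, 3))
        for new, old in enumerate(order):
            perm[new, old] = 1.0
        mesh.apply_transform(
            np.vstack([np.hstack([perm, np.zeros((3, 1))]), [0, 0, 0, 1]])
        )
    model = VoxelModel(
        spacing=h,
        origin=origin,
        occupancy=labels != 0,
        labels=labels,
        body_axis=spec.axis,
    )
    return mesh, model


def make_sphere_phantom(
    radius: float, h: float = 25e-6, subdivisions: int = 4
) -> tuple[trimesh.Trimesh, VoxelModel]:
    """Homogeneous sphere phantom for the analytic scattering oracle.

    The sphere is centered on a voxel center: the voxelization is then
    symmetric under the axis permutations/reflections of the plane-wave
    protocol and its volume is nearly unbiased (a vertex-centered sphere
    can be off by >10% at coarse pitch).
    """
    if radius <= 0 or h <= 0:
        raise PhantomError("radius and pitch must be positive")
    n = 2 * (int(math.ceil(radius / h)) + 1) + 1
    origin = np.full(3, -n * h / 2.0)
    shape = (n, n, n)
    c = origin[0] + (np.arange(n) + 0.5) * h
    X = c[:, None, None]
    Y = c[None, :, None]
    Z = c[None, None, :]
    occ = X * X + Y * Y + Z * Z <= radius * radius
    labels = np.where(occ, np.uint8(LABELS["other"]), np.uint8(0))
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    model = VoxelModel(spacing=h, origin=origin, occupancy=occ, labels=labels)
    return mesh, model
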