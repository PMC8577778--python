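"""Voxel geometry: STL I/O, voxelization, morphometrics and model editing.

Insect surface models arrive as triangulated STL meshes (assumed to be in
millimeters unless stated otherwise — insect-scale models are
conventionally exported in mm).  They are discretized on a uniform
isotropic grid by voxel-center parity ray casting: a voxel is occupied
iff its center lies inside the closed surface, decided by counting
surface crossings of a +x ray with a deterministic epsilon jitter on
degenerate hits.

Morphometrics follow the conventions of whole-insect dosimetry studies:
volume is the occupied voxel count times h^3; the body length is the
occupied extent along a declared body axis (restricted to the trunk
labels head/thorax/abdomen when labels are available, since anatomical
pronotum-to-abdomen-tip measurement cannot be automated on an unlabeled
scan); the diagonal is the space diagonal of the bounding box of all
occupied voxels, which — unlike body length — is sensitive to legs.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "TRUNK_LABELS",
    "VoxelModel",
    "ModelMetrics",
    "VoxelRegion",
    "GeometryError",
    "read_stl",
    "write_stl",
    "voxelize",
    "model_metrics",
    "partition_parts",
    "remove_parts",
    "resample",
    "write_lgrid",
    "read_lgrid",
]

#: Body-part label legend.
LABELS = {"air": 0, "head": 1, "thorax": 2, "abdomen": 3, "legs": 4, "other": 5}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
#: Labels making up the trunk (used for body-length measurement).
TRUNK_LABELS = (LABELS["head"], LABELS["thorax"], LABELS["abdomen"])


class GeometryError(ValueError):
    """Raised for malformed meshes, empty models or invalid regions."""


@dataclass
class VoxelModel:
    """A uniform boolean/labeled occupancy grid.

    ``spacing`` is the isotropic voxel pitch in meters, ``origin`` the
    world coordinate of the grid corner (voxel ``(0,0,0)`` spans
    ``origin .. origin + spacing``).  ``labels`` (uint8, same shape) is
    nonzero exactly where ``occupancy`` is true.
    """

    spacing: float
    origin: np.ndarray
    occupancy: np.ndarray
    labels: np.ndarray | None = None
    body_axis: int = 0

    def __post_init__(self):
        if not self.spacing > 0:
            raise GeometryError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise GeometryError("occupancy must be a 3D array")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.uint8)
            if self.labels.shape != self.occupancy.shape:
                raise GeometryError("labels and occupancy shapes differ")
            if np.any((self.labels != 0) != self.occupancy):
                raise GeometryError("labels must be nonzero exactly on occupied voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        """Occupied volume in m^3."""
        return self.n_occupied * self.spacing**3

    def centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def copy(self) -> "VoxelModel":
        return VoxelModel(
            spacing=self.spacing,
            origin=self.origin.copy(),
            occupancy=self.occupancy.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            body_axis=self.body_axis,
        )


@dataclass(frozen=True)
class ModelMetrics:
    """Morphometrics in the units conventionally reported (mm, mm^3)."""

    volume_mm3: float
    body_length_mm: float
    bbox_diagonal_mm: float

    def __post_init__(self):
        if min(self.volume_mm3, self.body_length_mm, self.bbox_diagonal_mm) < 0:
            raise GeometryError("metrics must be nonnegative")
        if self.body_length_mm > self.bbox_diagonal_mm + 1e-9:
            raise GeometryError("body length cannot exceed the bounding-box diagonal")


@dataclass
class VoxelRegion:
    """A view of a :class:`VoxelModel` restricted to a region.

    ``region_volume`` is the geometric volume of the selecting region
    (box volume for box selectors, occupied volume for label selectors);
    ``occupied_volume`` is the volume of occupied voxels inside it.
    Both in m^3.
    """

    name: str
    mask: np.ndarray = field(repr=False)
    region_volume: float
    occupied_volume: float


# --- STL I/O ---------------------------------------------------------------

def read_stl(path) -> trimesh.Trimesh:
    """Read an ASCII or binary STL file.

    Raises :class:`GeometryError` naming the offending byte offset for
    truncated binary files.
    """
    with open(path, "rb") as fh:
        head = fh.read(84)
        if len(head) >= 5 and head[:5] == b"solid":
            # Probably ASCII; binary files may also start with 'solid',
            # so only treat as ASCII if a facet keyword appears early.
            fh.seek(0)
            blob = fh.read(4096)
            if b"facet" in blob or b"endsolid" in blob:
                mesh = trimesh.load_mesh(path, file_type="stl")
                return _as_single_mesh(mesh)
        if len(head) < 84:
            raise GeometryError(
                f"truncated STL header: expected 84 bytes, file ends at byte {len(head)}"
            )
        (n_tri,) = struct.unpack("<I", head[80:84])
        expected = 84 + 50 * n_tri
        fh.seek(0, 2)
        size = fh.tell()
        if size < expected:
            raise GeometryError(
                f"truncated binary STL: {n_tri} facets imply {expected} bytes, "
                f"file ends at byte {size}"
            )
    mesh = trimesh.load_mesh(path, file_type="stl")
    return _as_single_mesh(mesh)


def _as_single_mesh(mesh) -> trimesh.Trimesh:
    if isinstance(mesh, trimesh.Scene):
        mesh = trimesh.util.concatenate(list(mesh.geometry.values()))
    if len(mesh.faces) == 0:
        raise GeometryError("STL file contains no facets")
    return mesh


def write_stl(mesh: trimesh.Trimesh, path, ascii: bool = False) -> None:
    """Write a mesh as STL (binary by default)."""
    data = trimesh.exchange.stl.export_stl_ascii(mesh) if ascii else trimesh.exchange.stl.export_stl(mesh)
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)


# --- Voxelization ----------------------------------------------------------

def _boundary_edges(mesh: trimesh.Trimesh) -> np.ndarray:
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    return unique[counts == 1]


def voxelize(
    mesh: trimesh.Trimesh,
    h: float,
    padding: int = 1,
    strict: bool = True,
) -> VoxelModel:
    """Voxelize a closed triangulated surface on a uniform grid.

    A voxel is occupied iff its center is inside the surface, decided by
    parity ray casting along +x.  The grid covers the mesh bounding box
    with at least ``padding`` empty voxels on every side.
    """
    if not h > 0:
        raise GeometryError("voxel pitch must be positive")
    tris = np.asarray(mesh.triangles, dtype=float)
    if tris.size == 0:
        raise GeometryError("cannot voxelize an empty mesh")
    if strict and not mesh.is_watertight:
        bad = _boundary_edges(mesh)
        raise GeometryError(
            f"mesh is not watertight ({len(bad)} boundary edges, first few: "
            f"{bad[:5].tolist()}); pass strict=False for tolerant voxelization"
        )

    bmin = tris.reshape(-1, 3).min(axis=0)
    bmax = tris.reshape(-1, 3).max(axis=0)
    origin = bmin - padding * h
    shape = tuple(int(math.ceil((bmax[a] - bmin[a]) / h)) + 2 * padding for a in range(3))
    ny, nz = shape[1], shape[2]
    # Deterministic sub-epsilon jitter avoids rays hitting edges/vertices.
    yc = origin[1] + (np.arange(ny) + 0.5) * h + 1.0e-6 * h
    zc = origin[2] + (np.arange(nz) + 0.5) * h + 0.618e-6 * h
    xc = origin[0] + (np.arange(shape[0]) + 0.5) * h

    crossings: dict[int, list[float]] = {}
    for v0, v1, v2 in tris:
        y0, z0 = v0[1], v0[2]
        d1y, d1z = v1[1] - y0, v1[2] - z0
        d2y, d2z = v2[1] - y0, v2[2] - z0
        denom = d1y * d2z - d2y * d1z
        if denom == 0.0:
            continue  # projection-degenerate: zero-measure crossing
        lo_y = min(v0[1], v1[1], v2[1])
        hi_y = max(v0[1], v1[1], v2[1])
        lo_z = min(v0[2], v1[2], v2[2])
        hi_z = max(v0[2], v1[2], v2[2])
        j0 = np.searchsorted(yc, lo_y, side="left")
        j1 = np.searchsorted(yc, hi_y, side="right")
        k0 = np.searchsorted(zc, lo_z, side="left")
        k1 = np.searchsorted(zc, hi_z, side="right")
        if j0 >= j1 or k0 >= k1:
            continue
        yy = yc[j0:j1, None] - y0
        zz = zc[None, k0:k1] - z0
        u = (yy * d2z - d2y * zz) / denom
        v = (d1y * zz - yy * d1z) / denom
        inside = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not inside.any():
            continue
        x = v0[0] + u * (v1[0] - v0[0]) + v * (v2[0] - v0[0])
        jj, kk = np.nonzero(inside)
        cols = (jj + j0) * nz + (kk + k0)
        xs = x[jj, kk]
        for c, xv in zip(cols.tolist(), xs.tolist()):
            crossings.setdefault(c, []).append(xv)

    occ = np.zeros(shape, dtype=bool)
    for col, xs in crossings.items():
        xs = sorted(xs)
        if len(xs) % 2:
            if strict:
                raise GeometryError(
                    f"odd crossing count in ray column {divmod(col, nz)}; "
                    "surface is not closed along +x"
                )
            xs = xs[:-1]
        j, k = divmod(col, nz)
        for a in range(0, len(xs), 2):
            i0 = np.searchsorted(xc, xs[a], side="left")
            i1 = np.searchsorted(xc, xs[a + 1], side="left")
            occ[i0:i1, j, k] = True
    return VoxelModel(spacing=h, origin=origin, occupancy=occ)


# --- Morphometrics ---------------------------------------------------------

def _occupied_extent(mask: np.ndarray, axis: int, h: float) -> float:
    proj = np.any(mask, axis=tuple(a for a in range(3) if a != axis))
    idx = np.nonzero(proj)[0]
    if idx.size == 0:
        return 0.0
    return float(idx[-1] - idx[0] + 1) * h


def model_metrics(v: VoxelModel, axis: int | None = None) -> ModelMetrics:
    """Volume, body length and bounding-box diagonal of a voxel model."""
    if v.n_occupied == 0:
        raise GeometryError("cannot compute metrics of an empty model")
    axis = v.body_axis if axis is None else axis
    h = v.spacing
    volume = v.volume
    if v.labels is not None:
        trunk = np.isin(v.labels, TRUNK_LABELS)
        if not trunk.any():
            trunk = v.occupancy
    else:
        trunk = v.occupancy
    body_length = _occupied_extent(trunk, axis, h)
    extents = np.array([_occupied_extent(v.occupancy, a, h) for a in range(3)])
    diagonal = float(np.linalg.norm(extents))
    return ModelMetrics(
        volume_mm3=volume * 1e9,
        body_length_mm=body_length * 1e3,
        bbox_diagonal_mm=diagonal * 1e3,
    )


# --- Partitioning and editing ----------------------------------------------

def _box_mask(v: VoxelModel, box) -> tuple[np.ndarray, float]:
    (lo, hi) = np.asarray(box[0], dtype=float), np.asarray(box[1], dtype=float)
    if np.any(hi <= lo):
        raise GeometryError(f"degenerate box {box}")
    dom_lo = v.origin
    dom_hi = v.origin + np.array(v.shape) * v.spacing
    if np.any(lo < dom_lo - 1e-12) or np.any(hi > dom_hi + 1e-12):
        raise GeometryError(f"box {box} lies outside the voxel domain")
    mask = np.ones(v.shape, dtype=bool)
    for a in range(3):
        c = v.centers(a)
        sel = (c >= lo[a]) & (c < hi[a])
        shp = [1, 1, 1]
        shp[a] = -1
        mask &= sel.reshape(shp)
    return mask, float(np.prod(hi - lo))


def _selector_mask(v: VoxelModel, selector) -> tuple[str, np.ndarray, float]:
    """Resolve a label name/int or an axis-aligned box into a mask.

    Returns (name, mask, region_volume).
    """
    if isinstance(selector, str):
        if selector not in LABELS:
            raise GeometryError(f"unknown label {selector!r}")
        selector = LABELS[selector]
    if isinstance(selector, (int, np.integer)):
        if v.labels is None:
            raise GeometryError("model has no labels; use box selectors")
        mask = v.labels == selector
        return LABEL_NAMES.get(int(selector), str(selector)), mask, float(mask.sum()) * v.spacing**3
    mask, box_volume = _box_mask(v, selector)
    return f"box{np.asarray(selector[0]).tolist()}", mask, box_volume


def partition_parts(v: VoxelModel, selectors) -> list[VoxelRegion]:
    """Partition a model into regions by label or axis-aligned box selectors."""
    regions = []
    for sel in selectors:
        name, mask, region_volume = _selector_mask(v, sel)
        occ = mask & v.occupancy
        regions.append(
            VoxelRegion(
                name=name,
                mask=occ,
                region_volume=region_volume,
                occupied_volume=float(occ.sum()) * v.spacing**3,
            )
        )
    return regions


def remove_parts(v: VoxelModel, selectors) -> tuple[VoxelModel, float]:
    """Clear the selected voxels; returns the edited model and the
    remaining volume fraction relative to the input."""
    out = v.copy()
    for sel in selectors:
        _, mask, _ = _selector_mask(v, sel)
        out.occupancy[mask] = False
        if out.labels is not None:
            out.labels[mask] = 0
    before = v.n_occupied
    fraction = out.n_occupied / before if before else 0.0
    return out, fraction


def resample(v: VoxelModel, h_new: float, padding: int = 1) -> VoxelModel:
    """Resample a voxel model onto a coarser/finer grid (nearest neighbor)."""
    if not h_new > 0:
        raise GeometryError("spacing must be positive")
    idx = np.nonzero(v.occupancy)
    if idx[0].size == 0:
        raise GeometryError("cannot resample an empty model")
    lo = v.origin + np.array([i.min() for i in idx]) * v.spacing
    hi = v.origin + (np.array([i.max() for i in idx]) + 1) * v.spacing
    origin = lo - padding * h_new
    shape = tuple(int(math.ceil((hi[a] - lo[a]) / h_new)) + 2 * padding for a in range(3))
    src = v.labels if v.labels is not None else v.occupancy.astype(np.uint8)
    coords = []
    for a in range(3):
        c = origin[a] + (np.arange(shape[a]) + 0.5) * h_new
        i = np.floor((c - v.origin[a]) / v.spacing).astype(int)
        valid = (i >= 0) & (i < v.shape[a])
        coords.append((np.clip(i, 0, v.shape[a] - 1), valid))
    lab = src[np.ix_(coords[0][0], coords[1][0], coords[2][0])].copy()
    for a in range(3):
        shp = [1, 1, 1]
        shp[a] = -1
        lab *= coords[a][1].reshape(shp).astype(np.uint8)
    return VoxelModel(
        spacing=h_new,
        origin=origin,
        occupancy=lab != 0,
        labels=lab if v.labels is not None else None,
        body_axis=v.body_axis,
    )


# --- Labeled-grid container -------------------------------------------------

def write_lgrid(v: VoxelModel, path) -> None:
    """Write a labeled grid as a compact text container.

    Line 1 is a JSON header (spacing, origin, shape, label legend and
    body axis); line 2 is the label volume flattened in C order and
    run-length encoded as ``value:count`` tokens.
    """
    labels = v.labels if v.labels is not None else v.occupancy.astype(np.uint8)
    flat = labels.ravel(order="C")
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    tokens = [f"{int(flat[s])}:{int(e - s)}" for s, e in zip(starts, ends)]
    header = {
        "format": "aedosim-lgrid",
        "version": 1,
        "spacing_m": v.spacing,
        "origin_m": v.origin.tolist(),
        "shape": list(v.shape),
        "body_axis": v.body_axis,
        "labeled": v.labels is not None,
        "legend": {str(k): n for n, k in LABELS.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        fh.write(" ".join(tokens) + "\n")


def read_lgrid(path) -> VoxelModel:
    """Read a labeled grid written by :func:`write_lgrid`."""
    with open(path, "r", encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        body = fh.readline().split()
    if header.get("format") != "aedosim-lgrid":
        raise GeometryError(f"{path} is not an aedosim labeled-grid file")
    shape = tuple(header["shape"])
    values = np.empty(int(np.prod(shape)), dtype=np.uint8)
    pos = 0
    for tok in body:
        val, cnt = tok.split(":")
        cnt = int(cnt)
        values[pos : pos + cnt] = np.uint8(int(val))
        pos += cnt
    if pos != values.size:
        raise GeometryError(f"run-length payload covers {pos} of {values.size} voxels")
    labels = values.reshape(shape, order="C")
    return VoxelModel(
        spacing=float(header["spacing_m"]),
        origin=np.asarray(header["origin_m"], dtype=float),
        occupancy=labels != 0,
        labels=labels if header.get("labeled", True) else None,
        body_axis=int(header.get("body_axis", 0)),
    )
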