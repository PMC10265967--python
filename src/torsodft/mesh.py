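"""Region-labeled tetrahedral meshes: voxelization and file I/O.

Meshing strategy: a structured cubic lattice of spacing ``h`` covers the
phantom; each cell whose centroid lies inside the torso is split into the
six Kuhn tetrahedra sharing the cell's main diagonal (a conforming,
orientation-consistent decomposition), and the cell's centroid label is
assigned to all six. Boundaries are therefore stair-stepped; the union of
tetrahedra tiles the kept cells exactly, so the total mesh volume equals
(number of kept cells) * h^3.

File formats: openCARP text meshes (.pts/.elem/.lon, 0-based indices) and
legacy ASCII VTK unstructured grids (for visualization).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .phantom import ALL_LABELS, TorsoPhantom


class MeshingError(RuntimeError):
    pass


class MeshFormatError(ValueError):
    """Malformed mesh file; message carries the offending line number."""


# the six Kuhn tetrahedra of the unit cube, corners numbered with bits
# (x -> 1, y -> 2, z -> 4); every tet shares the 0-7 main diagonal.
_KUHN_PATHS = [(1, 2), (1, 4), (2, 1), (2, 4), (4, 1), (4, 2)]
KUHN_TETS = np.array([[0, a, a | b, 7] for a, b in _KUHN_PATHS], dtype=np.int64)


@dataclass
class FEMesh:
    """Tetrahedral mesh with per-element region labels and optional fibres."""

    nodes: np.ndarray                 # (n, 3) mm
    tets: np.ndarray                  # (m, 4) int, 0-based
    labels: np.ndarray                # (m,) int, index into label_names
    label_names: list[str]
    fibers: np.ndarray | None = None  # (m, 3) unit vectors, NaN where absent
    electrode_nodes: dict[str, np.ndarray] = field(default_factory=dict)
    h: float | None = None            # lattice spacing if voxel-meshed
    node_ijk: np.ndarray | None = None  # (n, 3) lattice indices if voxel-meshed

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        """Signed-positive tet volumes (mm^3)."""
        p = self.nodes[self.tets]
        v = np.einsum("ij,ij->i",
                      np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                      p[:, 3] - p[:, 0]) / 6.0
        return np.abs(v)

    def label_id(self, name: str) -> int:
        return self.label_names.index(name)

    def element_mask(self, *names: str) -> np.ndarray:
        ids = [self.label_names.index(n) for n in names if n in self.label_names]
        return np.isin(self.labels, ids)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)


def mesh_from_labeler(label_at, bounds, label_names: list[str], h: float,
                      chunk: int = 2_000_000) -> FEMesh:
    """Voxel-mesh any labeled geometry.

    ``label_at(points) -> int array`` assigns a label id per point (0 means
    outside: those cells are dropped); ``bounds = (lo, hi)`` is the region
    to cover with the lattice.
    """
    if h <= 0:
        raise MeshingError("lattice spacing h must be positive")

    lo, hi = bounds
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    n_cells = np.maximum(1, np.ceil((hi - lo) / h).astype(int))
    nx, ny, nz = n_cells

    # label all cell centroids (chunked to bound memory)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    cell_ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centroids = lo + (cell_ijk + 0.5) * h
    lab = np.empty(len(centroids), dtype=np.int32)
    for s in range(0, len(centroids), chunk):
        lab[s:s + chunk] = label_at(centroids[s:s + chunk])
    keep = lab > 0
    cell_ijk = cell_ijk[keep]
    cell_lab = lab[keep]
    if len(cell_ijk) == 0:
        raise MeshingError("no cells inside the phantom at this spacing")

    # global grid-node ids of each cell's 8 corners, then compress
    def node_gid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ci, cj, ck = cell_ijk.T
    corners = np.empty((len(cell_ijk), 8), dtype=np.int64)
    for b in range(8):
        corners[:, b] = node_gid(ci + (b & 1), cj + ((b >> 1) & 1),
                                 ck + ((b >> 2) & 1))
    used, inv = np.unique(corners.ravel(), return_inverse=True)
    corners_local = inv.reshape(corners.shape).astype(np.int32)

    gi = used // ((ny + 1) * (nz + 1))
    gj = (used // (nz + 1)) % (ny + 1)
    gk = used % (nz + 1)
    node_ijk = np.column_stack([gi, gj, gk]).astype(np.int32)
    nodes = lo + node_ijk * h

    tets = corners_local[:, KUHN_TETS].reshape(-1, 4)
    labels = np.repeat(cell_lab, 6).astype(np.int32)

    return FEMesh(nodes=nodes, tets=tets, labels=labels,
                  label_names=list(label_names), h=float(h),
                  node_ijk=node_ijk)


def mesh_from_solids(solids, label_names: list[str], h: float,
                     bounds=None) -> FEMesh:
    """Voxel-mesh an ordered list of (label, solid) by painter's algorithm.

    ``label_names[0]`` is the outside label; cells resolving to it are
    dropped from the mesh.
    """
    def label_at(pts):
        out = np.zeros(len(pts), dtype=np.int32)
        for lab, solid in solids:
            idx = label_names.index(lab)
            blo, bhi = solid.bounds()
            cand = np.all((pts >= blo - 1e-9) & (pts <= bhi + 1e-9), axis=1)
            if cand.any():
                inside = solid.contains(pts[cand])
                out[np.flatnonzero(cand)[inside]] = idx
        return out

    if bounds is None:
        los, his = zip(*(s.bounds() for _, s in solids))
        bounds = (np.min(los, axis=0), np.max(his, axis=0))
    return mesh_from_labeler(label_at, bounds, label_names, h)


def capture_electrode_nodes(mesh: FEMesh, electrodes,
                            h: float | None = None) -> None:
    """Fill ``mesh.electrode_nodes`` by point-in-solid tests.

    ``electrodes`` is an object with ``.electrodes`` (or a plain list),
    each carrying ``name`` and ``capture_solid(h)``. Node sets of distinct
    electrodes are kept disjoint (first electrode wins). ``h`` is the
    capture spacing; for imported meshes without lattice metadata it is
    estimated from a typical edge length.
    """
    elist = getattr(electrodes, "electrodes", electrodes)
    if h is None:
        h = mesh.h
    if h is None:
        sample = mesh.tets[:1000]
        e01 = np.linalg.norm(mesh.nodes[sample[:, 0]] - mesh.nodes[sample[:, 1]],
                             axis=1)
        h = float(np.median(e01))
    nodes = mesh.nodes
    taken = np.zeros(len(nodes), dtype=bool)
    for el in elist:
        solid = el.capture_solid(h)
        blo, bhi = solid.bounds()
        cand = np.flatnonzero(np.all((nodes >= blo - h) & (nodes <= bhi + h),
                                     axis=1))
        sel = cand[solid.contains(nodes[cand])]
        sel = sel[~taken[sel]]  # node sets of distinct electrodes disjoint
        if len(sel) == 0:
            raise MeshingError(
                f"electrode {el.name!r} captured no mesh nodes at h={h}")
        taken[sel] = True
        mesh.electrode_nodes[el.name] = np.sort(sel)


def tetrahedralize(phantom: TorsoPhantom, electrodes=None,
                   h: float = 2.5) -> FEMesh:
    """Voxelize a phantom (and optionally an electrode set) at spacing h."""
    bounds = phantom.solids[0][1].bounds()
    mesh = mesh_from_labeler(phantom.label_at, bounds, phantom.labels, h)
    if electrodes is not None:
        capture_electrode_nodes(mesh, electrodes)
    return mesh


# ---------------------------------------------------------------------------
# openCARP text format


def write_mesh(mesh: FEMesh, path: str, fmt: str = "carp") -> None:
    """Write a mesh; ``fmt`` is 'carp' (basename -> .pts/.elem/.lon) or 'vtk'."""
    if fmt == "carp":
        _write_carp(mesh, path)
    elif fmt == "vtk":
        write_vtk(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def read_mesh(path: str, fmt: str = "carp",
              label_map: dict[int, str] | None = None) -> FEMesh:
    """Read a mesh written by :func:`write_mesh` (or by openCARP tooling).

    ``label_map`` translates integer region tags to label names; absent
    entries become ``region_<tag>``.
    """
    if fmt == "carp":
        return _read_carp(path, label_map)
    if fmt == "vtk":
        return _read_vtk(path, label_map)
    raise ValueError(f"unknown mesh format {fmt!r}")


def _write_carp(mesh: FEMesh, base: str) -> None:
    with open(base + ".pts", "w") as fh:
        fh.write(f"{mesh.n_nodes}\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")  # round-trips float64 exactly
    with open(base + ".elem", "w") as fh:
        fh.write(f"{mesh.n_elements}\n")
        rows = np.column_stack([mesh.tets, mesh.labels])
        for r in rows:
            fh.write(f"Tt {r[0]} {r[1]} {r[2]} {r[3]} {r[4]}\n")
    if mesh.fibers is not None:
        with open(base + ".lon", "w") as fh:
            fh.write("1\n")
            fib = np.where(np.isnan(mesh.fibers), 0.0, mesh.fibers)
            np.savetxt(fh, fib, fmt="%.17g")


def _read_carp(base: str, label_map: dict[int, str] | None) -> FEMesh:
    pts_path = base + ".pts"
    with open(pts_path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MeshFormatError(f"{pts_path}: line 1: empty file")
    try:
        n = int(lines[0])
    except ValueError:
        raise MeshFormatError(f"{pts_path}: line 1: expected node count") from None
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != n:
        raise MeshFormatError(
            f"{pts_path}: line {len(lines)}: header says {n} nodes, "
            f"found {len(body)} coordinate lines")
    nodes = np.loadtxt(pts_path, skiprows=1, ndmin=2)

    elem_path = base + ".elem"
    with open(elem_path) as fh:
        elines = fh.read().splitlines()
    try:
        m = int(elines[0])
    except (IndexError, ValueError):
        raise MeshFormatError(f"{elem_path}: line 1: expected element count") from None
    ebody = [ln for ln in elines[1:] if ln.strip()]
    if len(ebody) != m:
        raise MeshFormatError(
            f"{elem_path}: line {len(elines)}: header says {m} elements, "
            f"found {len(ebody)} element lines")
    tets = np.empty((m, 4), dtype=np.int32)
    tags = np.empty(m, dtype=np.int64)
    for i, ln in enumerate(ebody):
        parts = ln.split()
        if parts[0] != "Tt":
            raise MeshFormatError(
                f"{elem_path}: line {i + 2}: unsupported element type "
                f"{parts[0]!r} (only tetrahedra 'Tt' are supported)")
        if len(parts) != 6:
            raise MeshFormatError(
                f"{elem_path}: line {i + 2}: expected 'Tt n0 n1 n2 n3 tag'")
        tets[i] = [int(p) for p in parts[1:5]]
        tags[i] = int(parts[5])
    if tets.min() < 0 or tets.max() >= n:
        raise MeshFormatError(f"{elem_path}: node index out of range")

    uniq = np.unique(tags)
    if label_map is None:
        # round-trip case: tags written by _write_carp index ALL_LABELS
        if uniq.min() >= 0 and uniq.max() < len(ALL_LABELS):
            label_names = list(ALL_LABELS)
            labels = tags.astype(np.int32)
        else:
            label_map = {}
            label_names = [f"region_{t}" for t in uniq]
            labels = np.searchsorted(uniq, tags).astype(np.int32)
    if label_map is not None:
        label_names = [label_map.get(int(t), f"region_{t}") for t in uniq]
        labels = np.searchsorted(uniq, tags).astype(np.int32)

    fibers = None
    lon_path = base + ".lon"
    if os.path.exists(lon_path):
        with open(lon_path) as fh:
            first = fh.readline().split()
        nfib = int(first[0])
        if nfib != 1:
            raise MeshFormatError(
                f"{lon_path}: line 1: only one fibre vector per element supported")
        fibers = np.loadtxt(lon_path, skiprows=1, ndmin=2)
        if fibers.shape != (m, 3):
            raise MeshFormatError(
                f"{lon_path}: expected {m} fibre lines, found {fibers.shape[0]}")
        zero = np.linalg.norm(fibers, axis=1) < 1e-12
        fibers[zero] = np.nan
    return FEMesh(nodes=nodes, tets=tets, labels=labels,
                  label_names=label_names, fibers=fibers)


# ---------------------------------------------------------------------------
# legacy ASCII VTK unstructured grid


def write_vtk(mesh: FEMesh, path: str,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with region labels (+extra fields)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntorsodft mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.10g")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {m * 5}\n")
        np.savetxt(fh, np.column_stack([np.full(m, 4), mesh.tets]), fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10), fmt="%d")  # VTK_TETRA
        cd = {"region": mesh.labels}
        if cell_data:
            cd.update(cell_data)
        fh.write(f"CELL_DATA {m}\n")
        for name, arr in cd.items():
            arr = np.asarray(arr)
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%d" if kind == "int" else "%.10g")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr, float), fmt="%.10g")


def _read_vtk(path: str, label_map: dict[int, str] | None) -> FEMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0

    def expect(prefix):
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or not lines[i].upper().startswith(prefix):
            raise MeshFormatError(f"{path}: line {i + 1}: expected {prefix}")
        out = lines[i].split()
        i += 1
        return out

    expect("# VTK")
    i += 1  # title line
    expect("ASCII")
    expect("DATASET UNSTRUCTURED_GRID")
    n = int(expect("POINTS")[1])
    nodes = np.array([[float(x) for x in lines[i + r].split()] for r in range(n)])
    i += n
    m = int(expect("CELLS")[1])
    cells = np.array([[int(x) for x in lines[i + r].split()] for r in range(m)])
    i += m
    if np.any(cells[:, 0] != 4):
        raise MeshFormatError(f"{path}: only tetrahedral cells supported")
    tets = cells[:, 1:5].astype(np.int32)
    expect("CELL_TYPES")
    i += m
    tags = np.zeros(m, dtype=np.int64)
    for j in range(i, len(lines)):
        if lines[j].startswith("SCALARS region"):
            tags = np.array([int(lines[j + 2 + r]) for r in range(m)])
            break
    uniq = np.unique(tags)
    if label_map is None and uniq.min() >= 0 and uniq.max() < len(ALL_LABELS):
        label_names = list(ALL_LABELS)
        labels = tags.astype(np.int32)
    else:
        lm = label_map or {}
        label_names = [lm.get(int(t), f"region_{t}") for t in uniq]
        labels = np.searchsorted(uniq, tags).astype(np.int32)
    return FEMesh(nodes=nodes, tets=tets, labels=labels, label_names=label_names)
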