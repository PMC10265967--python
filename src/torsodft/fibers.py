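"""Rule-based myocardial fibre architecture.

Fibres follow the classic transmural helix rule: the helix angle
interpolates linearly with normalized wall depth from ``alpha_endo`` at the
endocardium (default +60 degrees) to ``alpha_epi`` at the epicardium
(default -60 degrees), measured from the local circumferential direction
toward the long axis. Fibre vectors are tangential to the wall by
construction (no transmural component).

For phantom-derived meshes the transmural depth comes from the analytic
endo/epi shells; for imported meshes a Laplace-Dirichlet depth solve
(endocardium 0, epicardium 1) is provided.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import phantom as ph
from .mesh import FEMesh
from .phantom import TorsoPhantom

__all__ = ["assign_fibers", "assign_fibers_laplace", "transmural_depth_laplace"]


def _helix_vectors(e_t, long_axis, depth, alpha_endo, alpha_epi):
    """Unit fibre vectors from transmural direction, long axis and depth."""
    z = long_axis / np.linalg.norm(long_axis)
    e_t = e_t / np.maximum(np.linalg.norm(e_t, axis=1, keepdims=True), 1e-30)
    e_c = np.cross(np.broadcast_to(z, e_t.shape), e_t)
    nc = np.linalg.norm(e_c, axis=1, keepdims=True)
    degenerate = nc[:, 0] < 1e-8  # transmural direction parallel to long axis
    e_c = np.where(degenerate[:, None], [1.0, 0.0, 0.0], e_c / np.maximum(nc, 1e-30))
    e_l = np.cross(e_t, e_c)
    alpha = np.deg2rad(alpha_endo + np.clip(depth, 0.0, 1.0)
                       * (alpha_epi - alpha_endo))
    f = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    return f / np.linalg.norm(f, axis=1, keepdims=True)


def _lv_depth_and_dir(local, cav, epi):
    """Depth in [0,1] and outward transmural direction for LV wall points.

    ``local`` are heart-frame coordinates; the profile radii of the
    analytic shells give the wall fraction at the point's height.
    """
    z = local[:, 2]
    rho = np.linalg.norm(local[:, :2], axis=1)
    r_en = np.asarray(cav.radius_at(z))
    r_ep = np.asarray(epi.radius_at(z))
    thick = r_ep - r_en
    thin = thick < 1e-6
    depth = np.where(thin, 0.5, (rho - r_en) / np.where(thin, 1.0, thick))
    e_t = np.zeros_like(local)
    safe = rho > 1e-9
    e_t[safe, 0] = local[safe, 0] / rho[safe]
    e_t[safe, 1] = local[safe, 1] / rho[safe]
    e_t[~safe, 0] = 1.0
    return depth, e_t, thin


def assign_fibers(mesh: FEMesh, phantom: TorsoPhantom,
                  alpha_endo: float = 60.0, alpha_epi: float = -60.0) -> FEMesh:
    """Assign helix-rule fibres on LV/RV wall elements of a phantom mesh.

    Non-myocardial elements (including scar) carry NaN fibres. Returns the
    mesh with ``mesh.fibers`` filled in.
    """
    lm = phantom.landmarks
    R = lm["frame"]
    hc = np.asarray(lm["heart_center"])
    fib = np.full((mesh.n_elements, 3), np.nan)
    cent = mesh.centroids()

    lv = mesh.element_mask(ph.LV_WALL)
    rv = mesh.element_mask(ph.RV_WALL)
    if not (lv.any() or rv.any()):
        raise ValueError("mesh has no myocardial elements")

    n_thin = 0
    if lv.any():
        local = (cent[lv] - hc) @ R
        depth, e_t_local, thin = _lv_depth_and_dir(local, lm["lv_cavity"],
                                                   lm["lv_epi"])
        n_thin += int(thin.sum())
        e_t = e_t_local @ R.T
        f = _helix_vectors(e_t, R[:, 2], depth, alpha_endo, alpha_epi)
        f[thin] = _helix_vectors(e_t[thin], R[:, 2], np.full(thin.sum(), 0.5),
                                 0.0, 0.0)  # circumferential fallback
        fib[np.flatnonzero(lv)] = f

    if rv.any():
        semi_in = lm["rv_semi"]
        semi_out = semi_in + phantom.params.rv_wall_thickness
        local = (cent[rv] - hc - (R @ lm["rv_center_local"])) @ R
        g_in = np.linalg.norm(local / semi_in, axis=1)
        g_out = np.linalg.norm(local / semi_out, axis=1)
        denom = np.maximum(g_in - g_out, 1e-9)
        depth = np.clip((g_in - 1.0) / denom, 0.0, 1.0)
        e_t_local = local / semi_in**2
        e_t = e_t_local @ R.T
        fib[np.flatnonzero(rv)] = _helix_vectors(e_t, R[:, 2], depth,
                                                 alpha_endo, alpha_epi)

    if n_thin:
        warnings.warn(
            f"{n_thin} myocardial elements too thin for a transmural depth; "
            "fell back to circumferential fibres", RuntimeWarning)
    mesh.fibers = fib
    return mesh


def transmural_depth_laplace(mesh: FEMesh, endo_labels=(ph.BLOOD,),
                             wall_labels=ph.MYOCARDIUM_LABELS) -> np.ndarray:
    """Per-node transmural depth on the myocardium by a Laplace solve.

    Nodes of wall elements touching blood-pool elements are clamped to 0
    (endocardium), wall-boundary nodes touching any other region (or the
    torso surface) to 1 (epicardium); the interior solves Laplace's
    equation on the wall subgraph. Intended for imported meshes without
    analytic shells.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    wall = mesh.element_mask(*wall_labels)
    endo_el = mesh.element_mask(*endo_labels)
    wall_nodes = np.unique(mesh.tets[wall])
    on_wall = np.zeros(mesh.n_nodes, bool)
    on_wall[wall_nodes] = True

    touch = np.zeros(mesh.n_nodes, dtype=np.int8)  # 1 endo, 2 epi
    endo_nodes = np.unique(mesh.tets[endo_el])
    other = ~wall & ~endo_el
    other_nodes = np.unique(mesh.tets[other]) if other.any() else np.array([], int)
    touch[np.intersect1d(endo_nodes, wall_nodes)] = 1
    epi_pick = np.intersect1d(other_nodes, wall_nodes)
    touch[epi_pick[touch[epi_pick] == 0]] = 2
    # nodes on the open mesh boundary of the wall count as epicardial too
    # (free wall facing a meshing boundary)

    # graph Laplacian on wall elements
    rows, cols = [], []
    tw = mesh.tets[wall]
    for a in range(4):
        for b in range(a + 1, 4):
            rows.append(tw[:, a])
            cols.append(tw[:, b])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    ones = np.ones(len(rows))
    A = sp.coo_matrix((ones, (rows, cols)), shape=(mesh.n_nodes,) * 2)
    A = (A + A.T).tocsr()
    L = sp.diags(np.asarray(A.sum(axis=1)).ravel()) - A

    d = np.full(mesh.n_nodes, np.nan)
    fixed = (touch > 0) & on_wall
    d[fixed] = (touch[fixed] == 2).astype(float)
    free = on_wall & ~fixed
    if free.any():
        fi = np.flatnonzero(free)
        xi = np.flatnonzero(fixed)
        rhs = -(L[fi][:, xi] @ d[xi])
        d[fi] = spla.spsolve(L[fi][:, fi].tocsc(), rhs)
    return d


def assign_fibers_laplace(mesh: FEMesh, long_axis=(0.0, 0.0, 1.0),
                          alpha_endo: float = 60.0,
                          alpha_epi: float = -60.0) -> FEMesh:
    """Helix-rule fibres for imported meshes using the Laplace depth."""
    depth_n = transmural_depth_laplace(mesh)
    wall = mesh.element_mask(*ph.MYOCARDIUM_LABELS)
    fib = np.full((mesh.n_elements, 3), np.nan)
    idx = np.flatnonzero(wall)
    tw = mesh.tets[idx]
    dep = np.nanmean(depth_n[tw], axis=1)
    # transmural direction: P1 gradient of the depth field per element
    p = mesh.nodes[tw]
    J = np.swapaxes(p[:, 1:] - p[:, :1], 1, 2)
    Jinv = np.linalg.inv(J)
    G = np.empty((len(tw), 3, 4))
    G[:, :, 1:] = np.swapaxes(Jinv, 1, 2)
    G[:, :, 0] = -G[:, :, 1:].sum(axis=2)
    dn = np.where(np.isnan(depth_n[tw]), dep[:, None], depth_n[tw])
    e_t = np.einsum("eij,ej->ei", G, dn)
    nrm = np.linalg.norm(e_t, axis=1)
    flat = nrm < 1e-9
    if flat.any():
        warnings.warn(f"{int(flat.sum())} wall elements with flat depth; "
                      "fell back to circumferential fibres", RuntimeWarning)
        e_t[flat] = [1.0, 0.0, 0.0]
    fib[idx] = _helix_vectors(e_t, np.asarray(long_axis, float), dep,
                              alpha_endo, alpha_epi)
    mesh.fibers = fib
    return mesh
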