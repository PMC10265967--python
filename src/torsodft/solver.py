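"""Finite-element solution of the shock-field Laplace problem.

The quasi-static shock field solves  div( sigma grad Ve ) = 0  over the
torso, with Dirichlet values on electrode node sets (shock coil at the
applied voltage, grounds at 0 V) and natural no-flux conditions on the
torso surface. Conductivities are isotropic per region except in the
ventricular myocardium, where the tensor is rank-1 anisotropic about the
local fibre axis.

Performance notes: on voxel lattices all tetrahedra are congruent to six
reference shapes, so element matrices are precomputed per shape; large
lattice systems are solved by conjugate gradients preconditioned with a
geometric multigrid hierarchy built on the lattice (Galerkin-coarsened,
damped-Jacobi smoothed), small or unstructured systems by a sparse direct
factorization.

Units: lengths mm, conductivities S/mm internally (inputs in S/m),
potentials V, E-fields V/mm, currents A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import phantom as ph
from .electrodes import ElectrodeSet
from .mesh import KUHN_TETS, FEMesh

__all__ = [
    "ConductivityMap",
    "FieldSolution",
    "SolverError",
    "myocardial_tensor",
    "assemble_stiffness",
    "solve_shock",
    "electrode_currents",
    "export_field_vtk",
]


class SolverError(RuntimeError):
    pass


#: Region conductivities (S/m): resistive volume-conductor table plus
#: assumed wall values for the great vessels and scar (flagged assumptions).
DEFAULT_REGION_SIGMA = {
    ph.BATH: 0.24725,
    ph.SKIN: 0.117,
    ph.BONE: 0.05,
    ph.KIDNEY: 0.1667,
    ph.LIVER: 0.1667,
    ph.STOMACH: 0.1,
    ph.SPLEEN: 0.1,
    ph.LUNG: 0.0714,
    ph.LA_WALL: 0.25,
    ph.RA_WALL: 0.25,
    ph.AORTA_WALL: 0.25,   # not tabulated; atrial-wall-like tissue assumed
    ph.SVC_WALL: 0.25,     # not tabulated; atrial-wall-like tissue assumed
    ph.BLOOD: 0.6667,
    ph.SCAR: 0.05,         # assumed low-conductivity (bone-like) scar tissue
}


@dataclass(frozen=True)
class ConductivityMap:
    """Region conductivities and the myocardial anisotropy model.

    ``myocardium_mode`` selects how the intra/extracellular eigenvalue
    pairs combine into the effective tensor of the static solve:
    ``"bulk"`` sums them (monodomain-bath equivalent,
    sigma_l = sigma_il + sigma_el, sigma_t = sigma_it + sigma_et);
    ``"extracellular"`` uses the extracellular values only.
    """

    region_sigma: dict = field(default_factory=lambda: dict(DEFAULT_REGION_SIGMA))
    sigma_il: float = 0.174
    sigma_el: float = 0.625
    sigma_it: float = 0.019
    sigma_et: float = 0.236
    myocardium_mode: str = "bulk"

    @property
    def sigma_long(self) -> float:
        """Effective longitudinal myocardial conductivity (S/m)."""
        if self.myocardium_mode == "bulk":
            return self.sigma_il + self.sigma_el
        if self.myocardium_mode == "extracellular":
            return self.sigma_el
        raise ValueError(f"unknown myocardium_mode {self.myocardium_mode!r}")

    @property
    def sigma_trans(self) -> float:
        if self.myocardium_mode == "bulk":
            return self.sigma_it + self.sigma_et
        if self.myocardium_mode == "extracellular":
            return self.sigma_et
        raise ValueError(f"unknown myocardium_mode {self.myocardium_mode!r}")

    def isotropic_lookup(self, label_names: list[str]) -> np.ndarray:
        """Per-label isotropic conductivity in S/mm (myocardium -> NaN)."""
        out = np.empty(len(label_names))
        for i, name in enumerate(label_names):
            if name in ph.MYOCARDIUM_LABELS:
                out[i] = np.nan
            elif name == ph.EXTERIOR:
                out[i] = 0.0
            else:
                try:
                    out[i] = self.region_sigma[name] * 1e-3
                except KeyError:
                    raise SolverError(f"no conductivity for region {name!r}") from None
        return out


def myocardial_tensor(fibre: np.ndarray, sigma: ConductivityMap) -> np.ndarray:
    """3x3 conductivity tensor (S/mm) for a unit fibre direction."""
    f = np.asarray(fibre, float)
    n = np.linalg.norm(f)
    if n < 1e-12:
        raise SolverError("zero fibre vector")
    f = f / n
    sl = sigma.sigma_long * 1e-3
    st = sigma.sigma_trans * 1e-3
    return st * np.eye(3) + (sl - st) * np.outer(f, f)


# ---------------------------------------------------------------------------
# element geometry


def _lattice_reference(h: float):
    """Shape-function gradients G (6,3,4) and volume of the six Kuhn tets."""
    corners = np.array([[b & 1, (b >> 1) & 1, (b >> 2) & 1] for b in range(8)],
                       dtype=float) * h
    G = np.empty((6, 3, 4))
    for t, tet in enumerate(KUHN_TETS):
        p = corners[tet]
        J = (p[1:] - p[0]).T        # 3x3
        Jinv = np.linalg.inv(J)
        G[t, :, 1:] = Jinv.T
        G[t, :, 0] = -Jinv.T.sum(axis=1)
    vol = h**3 / 6.0
    return G, vol


def _general_gradients(mesh: FEMesh):
    """Per-element shape gradients (m,3,4) and volumes for arbitrary tets."""
    p = mesh.nodes[mesh.tets]
    J = np.swapaxes(p[:, 1:] - p[:, :1], 1, 2)  # (m,3,3) columns p_i - p_0
    det = np.linalg.det(J)
    if np.any(np.abs(det) < 1e-14):
        raise SolverError("degenerate tetrahedron in mesh")
    Jinv = np.linalg.inv(J)
    G = np.empty((len(p), 3, 4))
    G[:, :, 1:] = np.swapaxes(Jinv, 1, 2)
    G[:, :, 0] = -G[:, :, 1:].sum(axis=2)
    return G, np.abs(det) / 6.0


def _element_sigma(mesh: FEMesh, sigma: ConductivityMap):
    """(iso (m,) S/mm with NaN on myocardium, myocardial mask)."""
    lookup = sigma.isotropic_lookup(mesh.label_names)
    iso = lookup[mesh.labels]
    myo = np.isnan(iso)
    return iso, myo


def element_tensors(mesh: FEMesh, sigma: ConductivityMap) -> np.ndarray:
    """Conductivity tensor (m,3,3) per element, S/mm."""
    iso, myo = _element_sigma(mesh, sigma)
    m = mesh.n_elements
    T = np.zeros((m, 3, 3))
    T[~myo] = np.eye(3) * iso[~myo, None, None]
    if myo.any():
        sl, st = sigma.sigma_long * 1e-3, sigma.sigma_trans * 1e-3
        if mesh.fibers is None:
            # no fibre architecture: trace-equivalent isotropic myocardium
            T[myo] = np.eye(3) * ((sl + 2 * st) / 3.0)
        else:
            f = mesh.fibers[myo]
            bad = ~np.isfinite(f).all(axis=1)
            f = np.where(bad[:, None], 0.0, f)
            ff = np.einsum("ei,ej->eij", f, f)
            Tm = st * np.eye(3)[None] + (sl - st) * ff
            Tm[bad] = np.eye(3) * ((sl + 2 * st) / 3.0)
            T[myo] = Tm
    return T


def assemble_stiffness(mesh: FEMesh, sigma: ConductivityMap,
                       chunk: int = 600_000) -> sp.csr_matrix:
    """Global P1 stiffness matrix (n x n, SPD up to the constant nullspace)."""
    n = mesh.n_nodes
    T = element_tensors(mesh, sigma)
    if mesh.h is not None:
        G, vol = _lattice_reference(mesh.h)
        types = np.tile(np.arange(6), mesh.n_elements // 6 + 1)[:mesh.n_elements]
        Ge = G[types]
        vols = np.full(mesh.n_elements, vol)
    else:
        Ge, vols = _general_gradients(mesh)

    K = sp.csr_matrix((n, n))
    m = mesh.n_elements
    for s in range(0, m, chunk):
        e = slice(s, min(s + chunk, m))
        # K_e = vol * G^T T G   (4x4 per element)
        ke = np.einsum("eai,eab,ebj,e->eij", Ge[e], T[e], Ge[e], vols[e],
                       optimize=True)
        rows = np.repeat(mesh.tets[e], 4, axis=1).ravel()
        cols = np.tile(mesh.tets[e], (1, 4)).ravel()
        K = K + sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


# ---------------------------------------------------------------------------
# geometric multigrid on the voxel lattice


def _pack_ijk(ijk: np.ndarray) -> np.ndarray:
    return (ijk[:, 0].astype(np.int64) << 42) | (ijk[:, 1].astype(np.int64) << 21) \
        | ijk[:, 2].astype(np.int64)


def _prolongation(ijk: np.ndarray):
    """Trilinear prolongation from the even-index sub-lattice.

    Returns (P, coarse_ijk): coarse points are the lattice nodes whose
    indices are all even; fine nodes interpolate from their up-to-8 coarse
    neighbours with renormalized trilinear weights.
    """
    even = np.all(ijk % 2 == 0, axis=1)
    coarse_idx = np.flatnonzero(even)
    coarse_ijk = ijk[coarse_idx] // 2
    keys = _pack_ijk(coarse_ijk)
    order = np.argsort(keys)
    skeys = keys[order]

    half = ijk / 2.0
    lo = np.floor(half).astype(np.int64)
    rows, cols, vals = [], [], []
    for bits in range(8):
        off = np.array([(bits >> d) & 1 for d in range(3)])
        cand = lo + off
        w = np.prod(1.0 - np.abs(cand - half), axis=1)
        nz = w > 1e-12
        k = _pack_ijk(cand[nz])
        pos = np.searchsorted(skeys, k)
        pos = np.clip(pos, 0, len(skeys) - 1)
        hit = skeys[pos] == k
        rows.append(np.flatnonzero(nz)[hit])
        cols.append(order[pos[hit]])
        vals.append(w[nz][hit])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    P = sp.coo_matrix((vals, (rows, cols)), shape=(len(ijk), len(coarse_idx))).tocsr()
    # renormalize rows whose stencil was clipped at the domain boundary
    rs = np.asarray(P.sum(axis=1)).ravel()
    rs[rs < 1e-12] = 1.0
    P = sp.diags(1.0 / rs) @ P
    return P, coarse_ijk


class LatticeMultigrid:
    """Galerkin multigrid hierarchy on a voxel lattice, used inside PCG.

    Built once per stiffness matrix on all nodes; per-configuration
    Dirichlet sets are handled by slicing each level to its free nodes
    (a coarse node is constrained when its fine counterpart is).
    """

    def __init__(self, K: sp.csr_matrix, ijk: np.ndarray,
                 coarse_size: int = 3000, max_levels: int = 8):
        self.Ks = [K]
        self.Ps = []
        self.fine_of_coarse = []  # fine-node index of each coarse node
        cur_ijk = ijk
        while self.Ks[-1].shape[0] > coarse_size and len(self.Ks) < max_levels:
            P, cijk = _prolongation(cur_ijk)
            even = np.flatnonzero(np.all(cur_ijk % 2 == 0, axis=1))
            Kc = (P.T @ self.Ks[-1] @ P).tocsr()
            self.Ks.append(Kc)
            self.Ps.append(P)
            self.fine_of_coarse.append(even)
            cur_ijk = cijk

    def preconditioner(self, free_mask: np.ndarray):
        """LinearOperator V-cycle for the system restricted to free nodes."""
        Ks, Ps = [], []
        mask = free_mask
        for lvl, K in enumerate(self.Ks):
            idx = np.flatnonzero(mask)
            Ks.append(K[idx][:, idx].tocsr())
            if lvl < len(self.Ps):
                cmask = mask[self.fine_of_coarse[lvl]]
                P = self.Ps[lvl][idx][:, np.flatnonzero(cmask)].tocsr()
                Ps.append(P)
                mask = cmask
        diags = [np.maximum(K.diagonal(), 1e-300) for K in Ks]
        coarse_lu = spla.splu(Ks[-1].tocsc() +
                              1e-10 * sp.eye(Ks[-1].shape[0], format="csc"))
        omega = 0.8
        nu = 2

        def vcycle(level, b):
            K, d = Ks[level], diags[level]
            if level == len(Ks) - 1:
                return coarse_lu.solve(b)
            x = omega * b / d
            for _ in range(nu - 1):
                x += omega * (b - K @ x) / d
            r = b - K @ x
            x = x + Ps[level] @ vcycle(level + 1, Ps[level].T @ r)
            for _ in range(nu):
                x += omega * (b - K @ x) / d
            return x

        nfree = Ks[0].shape[0]
        return spla.LinearOperator((nfree, nfree), matvec=lambda b: vcycle(0, b))


# ---------------------------------------------------------------------------
# solve


@dataclass
class FieldSolution:
    """Potential and field of one shock solve."""

    ve: np.ndarray              # (n,) V
    e_vec: np.ndarray           # (m,3) V/mm, E = -grad Ve
    e_mag: np.ndarray           # (m,) V/mm
    v_applied: float
    dirichlet: dict             # electrode name -> applied potential (V)
    residual: float             # relative residual of the linear solve
    currents: dict = field(default_factory=dict)  # electrode name -> A


def _dirichlet_from_electrodes(mesh: FEMesh, electrodes, v_applied: float):
    """Map electrode name -> potential. Accepts ElectrodeSet or dict."""
    if isinstance(electrodes, dict):
        return dict(electrodes)
    if isinstance(electrodes, ElectrodeSet):
        out = {electrodes.shock.name: float(v_applied)}
        for g in electrodes.grounds:
            out[g.name] = 0.0
        return out
    raise TypeError("electrodes must be an ElectrodeSet or a name->voltage dict")


def solve_shock(mesh: FEMesh, sigma: ConductivityMap, electrodes,
                v_applied: float = 10.0, K: sp.csr_matrix | None = None,
                mg: LatticeMultigrid | None = None,
                direct_threshold: int = 40_000,
                rtol: float = 1e-8, maxiter: int = 400) -> FieldSolution:
    """Solve the shock-field problem with Dirichlet electrode node sets.

    ``K`` and ``mg`` allow reusing the assembled stiffness matrix and the
    multigrid hierarchy across configurations on the same mesh.
    """
    voltages = _dirichlet_from_electrodes(mesh, electrodes, v_applied)
    n = mesh.n_nodes
    fixed = np.zeros(n, dtype=bool)
    u = np.zeros(n)
    for name, value in voltages.items():
        try:
            nodes = mesh.electrode_nodes[name]
        except KeyError:
            raise SolverError(f"mesh has no node set for electrode {name!r}") from None
        if len(nodes) == 0:
            raise SolverError(f"electrode {name!r} has an empty node set")
        fixed[nodes] = True
        u[nodes] = value
    if not fixed.any():
        raise SolverError("no Dirichlet nodes: system is singular")
    if not any(v == 0.0 for v in voltages.values()):
        raise SolverError("no ground electrode (no zero-potential node set)")

    if K is None:
        K = assemble_stiffness(mesh, sigma)
    free = ~fixed
    idx = np.flatnonzero(free)
    Kff = K[idx][:, idx].tocsr()
    b = -(K[idx][:, np.flatnonzero(fixed)] @ u[fixed])

    nfree = len(idx)
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        uf = np.zeros(nfree)
        res = 0.0
    elif nfree <= direct_threshold or mesh.node_ijk is None:
        if nfree <= direct_threshold:
            uf = spla.splu(Kff.tocsc()).solve(b)
        else:  # large unstructured system: diagonal-preconditioned CG
            M = spla.LinearOperator((nfree, nfree),
                                    matvec=lambda r: r / Kff.diagonal())
            uf, info = spla.cg(Kff, b, rtol=rtol, maxiter=20 * maxiter, M=M)
            if info != 0:
                raise SolverError(f"CG did not converge (info={info})")
        res = np.linalg.norm(b - Kff @ uf) / bnorm
    else:
        if mg is None:
            mg = LatticeMultigrid(K, mesh.node_ijk)
        M = mg.preconditioner(free)
        uf, info = spla.cg(Kff, b, rtol=rtol, maxiter=maxiter, M=M)
        res = np.linalg.norm(b - Kff @ uf) / bnorm
        if info != 0 and res > 10 * rtol:
            raise SolverError(
                f"multigrid-CG did not converge: relative residual {res:.2e}")
    u[idx] = uf

    # element fields from linear shape-function gradients
    if mesh.h is not None:
        G, _ = _lattice_reference(mesh.h)
        types = np.tile(np.arange(6), mesh.n_elements // 6 + 1)[:mesh.n_elements]
        grad = np.einsum("eij,ej->ei", G[types], u[mesh.tets], optimize=True)
    else:
        G, _ = _general_gradients(mesh)
        grad = np.einsum("eij,ej->ei", G, u[mesh.tets], optimize=True)
    e_vec = -grad
    return FieldSolution(ve=u, e_vec=e_vec, e_mag=np.linalg.norm(e_vec, axis=1),
                         v_applied=float(v_applied), dirichlet=voltages,
                         residual=res)


# ---------------------------------------------------------------------------
# electrode currents


def nodal_field(mesh: FEMesh, e_vec: np.ndarray,
                exclude: np.ndarray | None = None) -> np.ndarray:
    """Volume-weighted average of incident element fields at each node.

    ``exclude`` masks elements left out of the average (e.g. electrode
    interiors, where the constrained potential makes the field vanish).
    """
    vols = mesh.volumes()
    if exclude is not None:
        vols = np.where(exclude, 0.0, vols)
    num = np.zeros((mesh.n_nodes, 3))
    den = np.zeros(mesh.n_nodes)
    w = vols[:, None] * e_vec
    for c in range(4):
        np.add.at(num, mesh.tets[:, c], w)
        np.add.at(den, mesh.tets[:, c], vols)
    den[den == 0] = 1.0
    return num / den[:, None]


def _surface_current(mesh: FEMesh, sol: FieldSolution,
                     sigma: ConductivityMap, nodes: np.ndarray) -> float:
    """Surface-integrated flux: sum over electrode surface triangles of
    area * (sigma_surrounding * mean nodal E) . outward normal."""
    inset = np.zeros(mesh.n_nodes, dtype=bool)
    inset[nodes] = True
    incount = inset[mesh.tets].sum(axis=1)
    inner = np.flatnonzero(incount == 4)       # electrode-interior elements
    if len(inner) == 0:
        raise SolverError("electrode has no interior elements (no surface)")
    cand = np.flatnonzero(incount >= 3)        # possible face neighbours

    FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    iso, _ = _element_sigma(mesh, sigma)

    def face_keys(elems):
        f = mesh.tets[elems][:, FACES]         # (e,4,3)
        return np.sort(f, axis=2), f

    sk_in, faces_in = face_keys(inner)
    key_in = sk_in.reshape(-1, 3)
    # faces of inner elements, keyed
    import collections
    owner = collections.defaultdict(list)
    for row, (e, kf) in enumerate(zip(np.repeat(inner, 4),
                                      map(tuple, key_in))):
        owner[kf].append((e, row))
    sk_c, _ = face_keys(cand)
    neigh = collections.defaultdict(list)
    for e, kf in zip(np.repeat(cand, 4), map(tuple, sk_c.reshape(-1, 3))):
        neigh[kf].append(e)

    # recover the surface field from tissue-side elements only: inside the
    # electrode the potential is constrained and the element field vanishes
    excl = np.zeros(mesh.n_elements, dtype=bool)
    excl[inner] = True
    En = nodal_field(mesh, sol.e_vec, exclude=excl)
    total = 0.0
    inner_set = set(inner.tolist())
    faces_flat = faces_in.reshape(-1, 3)
    for kf, owners in owner.items():
        if len(owners) != 1:
            continue  # internal to the electrode
        e_own, row = owners[0]
        outside = [e for e in neigh[kf] if e not in inner_set]
        tri = faces_flat[row]
        p = mesh.nodes[tri]
        nvec = 0.5 * np.cross(p[1] - p[0], p[2] - p[0])
        # orient away from the owning element's centroid
        cent = mesh.nodes[mesh.tets[e_own]].mean(axis=0)
        if (p.mean(axis=0) - cent) @ nvec < 0:
            nvec = -nvec
        if not outside:
            continue  # domain boundary: no-flux
        s_out = iso[outside[0]]
        if np.isnan(s_out):  # myocardial neighbour: project tensor flux
            s_out = sigma.sigma_trans * 1e-3
        Ebar = En[tri].mean(axis=0)
        total += s_out * (Ebar @ nvec)
    return total


def electrode_currents(sol: FieldSolution, mesh: FEMesh,
                       sigma: ConductivityMap, electrodes,
                       K: sp.csr_matrix | None = None,
                       method: str = "residual") -> dict[str, float]:
    """Total current through each electrode (A), positive out of the shock.

    ``method="residual"`` sums the stiffness-residual reactions over each
    electrode's nodes (variationally consistent, conserves charge to solver
    tolerance). ``method="surface"`` integrates sigma times the recovered
    nodal E-field over the electrode surface triangles.
    """
    voltages = sol.dirichlet
    out = {}
    if method == "residual":
        if K is None:
            K = assemble_stiffness(mesh, sigma)
        r = K @ sol.ve
        for name in voltages:
            out[name] = float(r[mesh.electrode_nodes[name]].sum())
    elif method == "surface":
        for name in voltages:
            out[name] = float(_surface_current(mesh, sol, sigma,
                                               mesh.electrode_nodes[name]))
    else:
        raise ValueError(f"unknown current method {method!r}")
    sol.currents.update(out)
    return out


def export_field_vtk(sol: FieldSolution, mesh: FEMesh, path: str) -> None:
    """Write the solution to a legacy VTK file for inspection."""
    from .mesh import write_vtk
    write_vtk(mesh, path, point_data={"Ve": sol.ve},
              cell_data={"E_mag": sol.e_mag})
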