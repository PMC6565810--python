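"""Laplace-Beltrami eigenmodes of a triangular surface mesh.

Solves the Helmholtz eigenproblem ``laplacian(m_j) = -k_j^2 m_j`` by linear
finite elements (cotangent stiffness, lumped barycentric mass) as a
generalized symmetric eigenproblem ``K m = k^2 M m``.  The resulting modes
are the spatial basis of the neural-field superposition model: mode 1 is
constant over the surface, mode 2 of a two-lobed brain-like mesh is the
left-right antisymmetric pattern, and modes 3-4 capture long-wavelength
anteroposterior structure.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, diags
from scipy.sparse.linalg import eigsh

__all__ = [
    "LaplaceOperator",
    "EigenmodeBasis",
    "assemble_laplace_beltrami",
    "solve_eigenmodes",
    "classify_symmetry",
    "parcel_weight_matrix",
    "parcel_mode_values",
]


@dataclass
class LaplaceOperator:
    """Discrete Laplace-Beltrami: cotangent stiffness + lumped mass."""

    stiffness: csr_matrix  # (V, V), symmetric PSD, constant null space
    mass: csr_matrix       # (V, V), diagonal, positive


@dataclass
class EigenmodeBasis:
    """Ordered eigenmode basis.

    ``modes`` are mass-orthonormal (``m_i^T M m_j = delta_ij``) and carry a
    fixed sign convention: the entry of largest absolute value is positive
    (ties broken by lowest vertex index).  ``eigenfrequencies`` are stored
    metadata only — the fitted model is the stationary superposition, not
    the travelling-wave dynamics.
    """

    modes: np.ndarray          # (V, J)
    eigenvalues: np.ndarray    # (J,), 1/mm^2, ascending, k_1^2 ~ 0
    vertex_areas: np.ndarray   # (V,) mm^2 (diagonal of the mass matrix)
    symmetry: list | None = None   # per-mode labels
    mesh_checksum: str | None = None
    eigenfrequencies: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return self.modes.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def total_area(self) -> float:
        return float(self.vertex_areas.sum())

    def save(self, path: str) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            fh["modes"] = self.modes
            fh["eigenvalues"] = self.eigenvalues
            fh["vertex_areas"] = self.vertex_areas
            if self.symmetry is not None:
                fh["labels"] = np.array(self.symmetry, dtype="S16")
            if self.mesh_checksum is not None:
                fh.attrs["mesh_checksum"] = self.mesh_checksum

    @classmethod
    def load(cls, path: str) -> "EigenmodeBasis":
        import h5py
        with h5py.File(path, "r") as fh:
            labels = ([x.decode() for x in fh["labels"][...]]
                      if "labels" in fh else None)
            return cls(fh["modes"][...], fh["eigenvalues"][...],
                       fh["vertex_areas"][...], labels,
                       fh.attrs.get("mesh_checksum"))


def mesh_checksum(mesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.faces).tobytes())
    return h.hexdigest()[:16]


def assemble_laplace_beltrami(mesh) -> LaplaceOperator:
    """Cotangent stiffness and lumped (barycentric) mass matrices.

    Degenerate (zero-area) triangles are rejected with their face index.
    """
    verts, faces = mesh.vertices, mesh.faces
    areas = mesh.face_areas()
    bad = np.flatnonzero(areas <= 1e-12 * np.median(areas))
    if bad.size:
        raise ValueError(f"degenerate triangle at face index {bad[0]}")

    rows, cols, vals = [], [], []
    for k in range(3):
        i = faces[:, k]
        j = faces[:, (k + 1) % 3]
        o = faces[:, (k + 2) % 3]           # vertex opposite edge (i, j)
        u = verts[i] - verts[o]
        v = verts[j] - verts[o]
        cot = (u * v).sum(1) / (2.0 * areas)  # cos/sin via cross = 2*area
        w = 0.5 * cot
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    n = mesh.n_vertices
    K = coo_matrix((np.concatenate(vals),
                    (np.concatenate(rows), np.concatenate(cols))),
                   shape=(n, n)).tocsr()
    K = 0.5 * (K + K.T)  # enforce exact symmetry
    M = diags(mesh.vertex_areas()).tocsr()
    return LaplaceOperator(K, M)


def solve_eigenmodes(op: LaplaceOperator, n_modes: int,
                     shift: float = 1e-8) -> EigenmodeBasis:
    """Smallest ``n_modes`` eigenpairs of ``K m = k^2 M m``.

    Shift-invert around ``-shift`` handles the singular stiffness at
    ``k^2 = 0``; a fixed Lanczos start vector makes the solve deterministic.
    """
    n = op.stiffness.shape[0]
    if not 1 <= n_modes <= n:
        raise ValueError("n_modes must be in [1, n_vertices]")
    v0 = np.full(n, 1.0 / np.sqrt(n))
    try:
        vals, vecs = eigsh(op.stiffness, k=n_modes, M=op.mass,
                           sigma=-shift, which="LM", v0=v0)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise RuntimeError(
            f"eigenmode solver failed (n_modes={n_modes}, shift={shift}): {exc}"
        ) from exc
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    vals = np.where(np.abs(vals) < 1e-10, np.abs(vals), vals)

    areas = op.mass.diagonal()
    # exact mass-orthonormalization + sign convention
    for j in range(n_modes):
        v = vecs[:, j]
        v = v / np.sqrt(v @ (areas * v))
        imax = int(np.argmax(np.abs(v)))
        if v[imax] < 0:
            v = -v
        vecs[:, j] = v
    omega = np.sqrt(np.maximum(vals, 0.0))  # dispersion metadata only
    return EigenmodeBasis(vecs, vals, areas, eigenfrequencies=omega)


def classify_symmetry(basis: EigenmodeBasis, mesh, tol: float = 0.1) -> EigenmodeBasis:
    """Label each mode symmetric / antisymmetric / unclassified.

    A mode is symmetric when its mirror image differs by less than ``tol``
    in relative norm, antisymmetric when its mirror image is its negation
    within the same tolerance.
    """
    if mesh.mirror_map is None:
        raise ValueError("mesh has no mirror_map")
    labels = []
    for j in range(basis.n_modes):
        m = basis.modes[:, j]
        mm = m[mesh.mirror_map]
        nrm = np.linalg.norm(m)
        if np.linalg.norm(mm - m) / nrm < tol:
            labels.append("symmetric")
        elif np.linalg.norm(mm + m) / nrm < tol:
            labels.append("antisymmetric")
        else:
            labels.append("unclassified")
    basis.symmetry = labels
    return basis


def export_mode_ply(basis: EigenmodeBasis, mesh, mode: int, path: str) -> None:
    """Write one mode as a PLY with the scalar mapped to vertex color.

    Diverging map: negative values toward blue, positive toward red.
    """
    m = basis.modes[:, mode]
    scale = np.abs(m).max() or 1.0
    x = m / scale
    rgba = np.empty((len(m), 4), dtype=np.uint8)
    rgba[:, 0] = np.clip(255 * (0.5 + 0.5 * x), 0, 255)
    rgba[:, 2] = np.clip(255 * (0.5 - 0.5 * x), 0, 255)
    rgba[:, 1] = np.clip(255 * (1.0 - np.abs(x)), 0, 255)
    rgba[:, 3] = 255
    tm = mesh.to_trimesh()
    tm.visual.vertex_colors = rgba
    tm.export(path)


def parcel_weight_matrix(parcellation, vertex_areas: np.ndarray) -> csr_matrix:
    """Sparse (P, V) area-weighted averaging matrix; rows sum to one."""
    v2p = parcellation.vertex_to_parcel
    P = parcellation.n_parcels
    sizes = np.bincount(v2p, weights=vertex_areas, minlength=P)
    if np.any(sizes == 0):
        raise ValueError("empty parcel")
    w = vertex_areas / sizes[v2p]
    V = len(v2p)
    return coo_matrix((w, (v2p, np.arange(V))), shape=(P, V)).tocsr()


def parcel_mode_values(basis: EigenmodeBasis, parcellation) -> np.ndarray:
    """(P, J) matrix of area-weighted mean mode values per parcel."""
    if parcellation.n_vertices != basis.n_vertices:
        raise ValueError("basis and parcellation come from different meshes")
    W = parcel_weight_matrix(parcellation, basis.vertex_areas)
    return np.asarray(W @ basis.modes)
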