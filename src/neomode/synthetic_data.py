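"""Synthetic study materials: meshes, parcellations, cohorts, leakage, outcomes.

This module generates everything the downstream analysis needs so that the
full pipeline — eigenmode decomposition, envelope connectivity, network
statistics and mode-weight fitting — can be exercised end-to-end without any
recorded EEG.  The generative model for cortical activity is the stationary
mode superposition

    Y(r, t) = sum_j a_j m_j(r) cos(2 pi nu t) cos(2 pi omega t) + sigma eta(r, t)

projected onto a bilaterally symmetric 58-parcel scheme (29 left-right
pairs), per subject and sleep state (active sleep AS / quiet sleep QS), with
group structure (extremely preterm EP vs healthy control HC) expressed as
group-by-state differences in the mode weights a_j.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

__all__ = [
    "SurfaceMesh",
    "Parcellation",
    "CohortSpec",
    "SubjectRecord",
    "CohortDataset",
    "LeakageOperator",
    "make_sphere_mesh",
    "make_bihemispheric_mesh",
    "make_symmetric_parcellation",
    "simulate_cohort",
    "make_toy_leakage_operator",
    "simulate_outcomes",
]

STATES = ("AS", "QS")
GROUPS = ("EP", "HC")

#: Default group-by-state mean mode weights (a1, a3, a4) at unit noise SD.
#: QS carries more energy in the uniform first mode than AS, and the
#: AS-to-QS difference is attenuated in the preterm group; the two
#: anteroposterior modes move weakly in the opposite direction.  Mode 1
#: dominates (low-order modes carry most of the energy), which also keeps
#: subjects inside the well-conditioned region of the moment-matching fit.
DEFAULT_MODE_WEIGHT_MEANS = {
    ("HC", "AS"): (0.22, 0.050, 0.040),
    ("HC", "QS"): (0.37, 0.040, 0.030),
    ("EP", "AS"): (0.24, 0.045, 0.035),
    ("EP", "QS"): (0.30, 0.040, 0.030),
}

#: Between-subject SD of the (a1, a3, a4) weights.
DEFAULT_MODE_WEIGHT_SD = (0.04, 0.015, 0.015)


# ---------------------------------------------------------------------------
# Surface meshes
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated surface with an optional left-right vertex pairing.

    ``mirror_map`` is an involution: ``mirror_map[mirror_map[v]] == v`` and
    vertex ``mirror_map[v]`` sits at the x-negated position of vertex ``v``.
    """

    vertices: np.ndarray  # (V, 3) float, mm
    faces: np.ndarray     # (F, 3) int
    mirror_map: np.ndarray | None = None  # (V,) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (one third of each incident triangle)."""
        fa = self.face_areas()
        va = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(va, self.faces[:, k], fa / 3.0)
        return va

    def surface_area(self) -> float:
        return float(self.face_areas().sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def vertex_adjacency(self, weighted: bool = True):
        """Sparse vertex adjacency; weights are Euclidean edge lengths."""
        e = self.edges()
        w = (np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
             if weighted else np.ones(len(e)))
        n = self.n_vertices
        m = coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]],
                                      np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
        return m.tocsr()

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.vertex_adjacency(weighted=False),
                                         directed=False)
        return n_comp == 1

    def check_mirror_involution(self, tol: float = 1e-6) -> bool:
        if self.mirror_map is None:
            return False
        mm = self.mirror_map
        if not np.array_equal(mm[mm], np.arange(self.n_vertices)):
            return False
        flipped = self.vertices.copy()
        flipped[:, 0] *= -1.0
        scale = max(1.0, np.abs(self.vertices).max())
        return bool(np.allclose(self.vertices[mm], flipped, atol=tol * scale))

    # -- I/O ---------------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def save(self, path: str) -> None:
        """Write as PLY (binary little-endian) or OFF, by extension."""
        self.to_trimesh().export(path)

    @classmethod
    def load(cls, path: str, rebuild_mirror_map: bool = False) -> "SurfaceMesh":
        tm = trimesh.load_mesh(path, process=False)
        mesh = cls(np.asarray(tm.vertices), np.asarray(tm.faces))
        if rebuild_mirror_map:
            mesh.mirror_map = _mirror_map_from_coords(mesh.vertices)
        return mesh


def _mirror_map_from_coords(vertices: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    flipped = vertices.copy()
    flipped[:, 0] *= -1.0
    tree = cKDTree(vertices)
    dist, idx = tree.query(flipped)
    scale = max(1.0, np.abs(vertices).max())
    if np.any(dist > tol * scale):
        raise ValueError("mesh is not mirror-symmetric within tolerance")
    return idx.astype(np.int64)


def make_sphere_mesh(subdivisions: int, radius: float) -> SurfaceMesh:
    """Closed icosphere: ``10 * 4**s + 2`` vertices, all at ``radius``."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def make_bihemispheric_mesh(
    lobe_semi_axes: tuple[float, float, float] = (60.0, 45.0, 40.0),
    gap: float = 6.0,
    subdivisions: int = 3,
) -> SurfaceMesh:
    """Two mirrored ellipsoid lobes joined by a thin medial bridge.

    Stand-in for a smooth term-age cortical surface: each hemisphere is an
    icosphere scaled to ``lobe_semi_axes`` (mm) and offset by
    ``+/-(gap/2 + a_x)`` along x.  The innermost vertex of each lobe is
    removed and the two exposed rings are stitched with a band of triangles,
    so the mesh is a single connected component (this keeps the first
    eigenmode global and the second left-right antisymmetric).
    ``mirror_map`` pairs every vertex with its x-negated twin.
    """
    ax, ay, az = (float(s) for s in lobe_semi_axes)
    if min(ax, ay, az) <= 0:
        raise ValueError("semi-axes must be positive")
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(sphere.vertices) * np.array([ax, ay, az])
    verts[:, 0] += gap / 2.0 + ax
    faces = np.asarray(sphere.faces)

    # innermost (most medial) vertex of the right lobe and its neighbour ring
    apex = int(np.argmin(verts[:, 0]))
    ring = _ordered_neighbour_ring(faces, verts, apex)

    keep = np.ones(len(verts), dtype=bool)
    keep[apex] = False
    new_index = np.cumsum(keep) - 1
    faces_kept = faces[~np.any(faces == apex, axis=1)]
    faces_r = new_index[faces_kept]
    verts_r = verts[keep]
    ring_r = new_index[ring]

    nR = len(verts_r)
    verts_l = verts_r.copy()
    verts_l[:, 0] *= -1.0
    faces_l = faces_r[:, ::-1] + nR  # reversed winding keeps outward normals
    ring_l = ring_r + nR

    band = []
    m = len(ring_r)
    for i in range(m):
        a, b = ring_r[i], ring_r[(i + 1) % m]
        al, bl = ring_l[i], ring_l[(i + 1) % m]
        band.append([a, al, b])
        band.append([b, al, bl])
    all_verts = np.vstack([verts_r, verts_l])
    all_faces = np.vstack([faces_r, faces_l, np.asarray(band, dtype=np.int64)])

    tm = trimesh.Trimesh(all_verts, all_faces, process=False)
    trimesh.repair.fix_normals(tm)

    mirror = np.r_[np.arange(nR) + nR, np.arange(nR)]
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), mirror)
    if not mesh.check_mirror_involution():
        raise RuntimeError("bihemispheric construction lost mirror symmetry")
    return mesh


def _ordered_neighbour_ring(faces: np.ndarray, verts: np.ndarray,
                            apex: int) -> np.ndarray:
    """Neighbours of ``apex`` ordered cyclically by angle about the x axis."""
    inc = faces[np.any(faces == apex, axis=1)]
    nbrs = np.unique(inc[inc != apex])
    rel = verts[nbrs] - verts[apex]
    ang = np.arctan2(rel[:, 2], rel[:, 1])
    return nbrs[np.argsort(ang)]


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

@dataclass
class Parcellation:
    """Vertex-to-parcel labelling with 29 bilaterally symmetric pairs.

    Parcels ``0..n_pairs-1`` live on the right hemisphere (x > 0) and parcel
    ``p + n_pairs`` is the mirror twin of parcel ``p``.
    """

    vertex_to_parcel: np.ndarray   # (V,) int
    parcel_pairs: np.ndarray       # (n_pairs, 2) int
    centroids: np.ndarray          # (n_parcels, 3) float mm

    @property
    def n_parcels(self) -> int:
        return len(self.centroids)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_to_parcel)

    def parcel_sizes(self) -> np.ndarray:
        return np.bincount(self.vertex_to_parcel, minlength=self.n_parcels)

    def hemisphere_of(self) -> np.ndarray:
        """0 for right-hemisphere parcels, 1 for left."""
        n_pairs = len(self.parcel_pairs)
        return (np.arange(self.n_parcels) >= n_pairs).astype(int)

    # -- I/O ---------------------------------------------------------------
    def save(self, tsv_path: str, json_path: str) -> None:
        import pandas as pd
        pd.DataFrame({"vertex_id": np.arange(self.n_vertices),
                      "parcel_id": self.vertex_to_parcel}
                     ).to_csv(tsv_path, sep="\t", index=False)
        with open(json_path, "w") as fh:
            json.dump({"parcel_pairs": self.parcel_pairs.tolist(),
                       "centroids": self.centroids.tolist()}, fh)

    @classmethod
    def load(cls, tsv_path: str, json_path: str) -> "Parcellation":
        import pandas as pd
        df = pd.read_csv(tsv_path, sep="\t")
        with open(json_path) as fh:
            meta = json.load(fh)
        return cls(df["parcel_id"].to_numpy(),
                   np.asarray(meta["parcel_pairs"], dtype=np.int64),
                   np.asarray(meta["centroids"], dtype=float))


def make_symmetric_parcellation(mesh: SurfaceMesh, n_pairs: int = 29) -> Parcellation:
    """Farthest-point seeded geodesic parcels on one hemisphere, mirrored.

    Seeds are placed on the right hemisphere by farthest-point sampling of
    geodesic (graph) distance, each right vertex is assigned to its nearest
    seed, and the labelling is mirrored through ``mirror_map``.  All parcels
    are spatially contiguous and mirrored parcels have equal vertex counts.
    """
    if mesh.mirror_map is None:
        raise ValueError("mesh must carry a mirror_map")
    right = np.flatnonzero(mesh.vertices[:, 0] > 0)
    if n_pairs > len(right):
        raise ValueError("too many pairs for vertex count")
    adj = mesh.vertex_adjacency()[np.ix_(right, right)]

    # farthest-point seeding, deterministic start at the most lateral vertex
    seeds = [int(np.argmax(mesh.vertices[right, 0]))]
    d_to_seeds = dijkstra(adj, indices=seeds[0], directed=False)
    for _ in range(1, n_pairs):
        nxt = int(np.argmax(d_to_seeds))
        seeds.append(nxt)
        d_to_seeds = np.minimum(d_to_seeds,
                                dijkstra(adj, indices=nxt, directed=False))
    dmat = dijkstra(adj, indices=seeds, directed=False)
    label_right = np.argmin(dmat, axis=0)

    v2p = np.full(mesh.n_vertices, -1, dtype=np.int64)
    v2p[right] = label_right
    v2p[mesh.mirror_map[right]] = label_right + n_pairs
    if np.any(v2p < 0):
        raise RuntimeError("unassigned vertices (mid-plane vertex present?)")

    va = mesh.vertex_areas()
    n_parcels = 2 * n_pairs
    centroids = np.empty((n_parcels, 3))
    for p in range(n_parcels):
        sel = v2p == p
        w = va[sel]
        centroids[p] = (mesh.vertices[sel] * w[:, None]).sum(0) / w.sum()
    pairs = np.column_stack([np.arange(n_pairs), np.arange(n_pairs) + n_pairs])
    return Parcellation(v2p, pairs, centroids)


# ---------------------------------------------------------------------------
# Leakage operator
# ---------------------------------------------------------------------------

@dataclass
class LeakageOperator:
    """Parcel-to-parcel mixing emulating source-reconstruction cross-talk."""

    mixing: np.ndarray  # (P, P), rows sum to 1
    spread: float       # mm

    def apply(self, parcel_ts: np.ndarray) -> np.ndarray:
        return self.mixing @ parcel_ts


def make_toy_leakage_operator(parcellation: Parcellation, spread: float,
                              seed: int = 0, jitter: float = 0.0) -> LeakageOperator:
    """Gaussian centroid-distance mixing kernel, rows normalized to one.

    ``spread = 0`` gives the identity; ``spread -> inf`` approaches uniform
    ``1/P`` rows.  Optional log-normal ``jitter`` on the off-diagonal weights
    mimics idiosyncrasies of a real inverse operator.
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    P = parcellation.n_parcels
    if spread == 0:
        return LeakageOperator(np.eye(P), 0.0)
    d = np.linalg.norm(parcellation.centroids[:, None, :]
                       - parcellation.centroids[None, :, :], axis=-1)
    w = np.exp(-0.5 * (d / spread) ** 2)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = np.exp(rng.normal(0.0, jitter, size=(P, P)))
        off = ~np.eye(P, dtype=bool)
        w[off] *= noise[off]
    w /= w.sum(axis=1, keepdims=True)
    return LeakageOperator(w, float(spread))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    Mode-weight means are per (group, state) triples ``(a1, a3, a4)`` at unit
    noise SD; between-subject variation is a normal truncated at zero
    (weights are amplitudes).  All randomness flows from ``seed`` through
    per-subject derived seeds, so single subjects are independently
    reproducible.
    """

    n_per_group: dict = field(default_factory=lambda: {"EP": 42, "HC": 52})
    states: tuple = STATES
    mode_weight_means: dict = field(
        default_factory=lambda: dict(DEFAULT_MODE_WEIGHT_MEANS))
    mode_weight_sd: tuple = DEFAULT_MODE_WEIGHT_SD
    noise_sd: float = 1.0
    duration: float = 300.0
    fs: float = 100.0
    age_mean: float = 41.1   # conceptional age at recording, weeks
    age_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("subject counts must be positive")
        n_samp = self.duration * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration x rate must be integral")
        for key, trip in self.mode_weight_means.items():
            if any(a < 0 for a in trip):
                raise ValueError(f"negative mode weight mean for {key}")


@dataclass
class SubjectRecord:
    subject: str
    group: str
    age: float
    timeseries: dict            # state -> (n_parcels, n_samples) array
    true_params: dict | None    # state -> {"a": (a1,a3,a4), "sigma": float}


@dataclass
class CohortDataset:
    subjects: list
    spec: CohortSpec | None = None

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def manifest(self):
        import pandas as pd
        rows = []
        for s in self.subjects:
            for state in s.timeseries:
                row = {"subject": s.subject, "group": s.group, "state": state,
                       "age": s.age}
                if s.true_params is not None:
                    tp = s.true_params[state]
                    row.update({"true_a1": tp["a"][0], "true_a3": tp["a"][1],
                                "true_a4": tp["a"][2], "true_sigma": tp["sigma"]})
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, directory: str) -> None:
        """One ``.npz`` array container per subject x state + manifest TSV.

        The sidecar JSON records sampling rate, channel naming and units so
        the containers are self-describing.
        """
        import os
        os.makedirs(directory, exist_ok=True)
        for s in self.subjects:
            for state, ts in s.timeseries.items():
                stem = os.path.join(directory, f"{s.subject}_{state}")
                np.savez(stem + ".npz", data=ts)
                with open(stem + ".json", "w") as fh:
                    json.dump({"fs_hz": self.spec.fs if self.spec else None,
                               "units": "uV",
                               "channels": [f"parcel_{i:02d}"
                                            for i in range(ts.shape[0])]}, fh)
        self.manifest().to_csv(os.path.join(directory, "manifest.tsv"),
                               sep="\t", index=False)


def _draw_weights(rng: np.random.Generator, means, sd) -> np.ndarray:
    """Truncated-normal (at zero) draw of the (a1, a3, a4) triple."""
    means = np.asarray(means, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), means.shape)
    if np.all(sd == 0):
        return means.copy()
    a = np.where(sd > 0, (0.0 - means) / np.where(sd > 0, sd, 1.0), -np.inf)
    out = truncnorm.rvs(a, np.inf, loc=means, scale=np.where(sd > 0, sd, 1e-12),
                        random_state=rng)
    return np.where(sd > 0, out, means)


def simulate_cohort(spec: CohortSpec, basis, parcellation: Parcellation,
                    keep_true_params: bool = True) -> CohortDataset:
    """Generate a multi-subject cohort of parcel time series.

    Per subject and state, subject-level weights are drawn around the
    (group, state) means and the mode-superposition field is simulated and
    projected onto parcels (an exact parcel-level shortcut of the
    vertex-level simulation; see :mod:`neomode.neural_field_model`).
    Deterministic given ``spec.seed``.
    """
    from . import neural_field_model as nfm
    from .eigenmodes import parcel_weight_matrix

    if basis.n_vertices != parcellation.n_vertices:
        raise ValueError("basis and parcellation come from different meshes")
    W = parcel_weight_matrix(parcellation, basis.vertex_areas)
    parcel_modes = nfm.unit_rms_parcel_modes(basis, W)
    noise_scale = nfm.parcel_noise_scale(n_parcels=parcellation.n_parcels)

    subjects = []
    idx = 0
    for group in sorted(spec.n_per_group):
        for k in range(spec.n_per_group[group]):
            sid = f"{group}{k:03d}"
            rng_age = np.random.default_rng([spec.seed, idx, 999])
            age = float(rng_age.normal(spec.age_mean, spec.age_sd))
            ts, tps = {}, {}
            for s_i, state in enumerate(spec.states):
                rng = np.random.default_rng([spec.seed, idx, s_i])
                a = _draw_weights(rng, spec.mode_weight_means[(group, state)],
                                  spec.mode_weight_sd)
                params = nfm.ModelParams(a=(a[0], 0.0, a[1], a[2]),
                                         sigma=spec.noise_sd,
                                         duration=spec.duration, fs=spec.fs)
                ts[state] = nfm.simulate_parcel_timeseries(
                    params, parcel_modes, noise_scale, rng)
                tps[state] = {"a": tuple(a), "sigma": spec.noise_sd}
            subjects.append(SubjectRecord(sid, group, age, ts,
                                          tps if keep_true_params else None))
            idx += 1
    return CohortDataset(subjects, spec)


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def simulate_outcomes(cohort: CohortDataset, connectivity_change: np.ndarray,
                      coupling: float, noise_sd: float, seed: int = 0,
                      age_effect: float = 0.0, intercept: float = 50.0,
                      social_coupling_ratio: float = 0.5):
    """Synthetic developmental-outcome scores for the EP subjects.

    ``score = intercept + coupling * change + age_effect * age + noise`` for
    the visual score; the social-emotional score uses
    ``coupling * social_coupling_ratio``.  Stands in for a structured
    developmental assessment at two years; the default negative coupling
    mirrors the expected sign of the connectivity-outcome association.
    Returns a DataFrame (one row per EP subject) with the generating
    parameters stored in ``.attrs``.
    """
    import pandas as pd
    ep = [s for s in cohort.subjects if s.group == "EP"]
    change = np.asarray(connectivity_change, dtype=float)
    if len(change) != len(ep):
        raise ValueError("one connectivity_change value per EP subject required")
    rng = np.random.default_rng(seed)
    ages = np.array([s.age for s in ep])
    visual = (intercept + coupling * change + age_effect * ages
              + rng.normal(0.0, noise_sd, len(ep)))
    social = (intercept + coupling * social_coupling_ratio * change
              + age_effect * ages + rng.normal(0.0, noise_sd, len(ep)))
    out = pd.DataFrame({"subject": [s.subject for s in ep],
                        "visual": visual, "social_emotional": social,
                        "conceptional_age": ages})
    out.attrs["generating"] = {"coupling": coupling, "noise_sd": noise_sd,
                               "age_effect": age_effect, "intercept": intercept,
                               "social_coupling_ratio": social_coupling_ratio,
                               "seed": seed}
    return out
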