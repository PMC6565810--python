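"""Shared fixtures: one standard synthetic geometry and its derived objects.

The heavy objects (eigenmode basis, pairwise response table, fit grid) are
session-scoped so the model-fit and end-to-end tests amortize their cost.
"""

import numpy as np
import pytest

from neomode import connectivity as conn
from neomode import eigenmodes as em
from neomode import neural_field_model as nfm
from neomode import synthetic_data as sd


@pytest.fixture(scope="session")
def mesh():
    return sd.make_bihemispheric_mesh(subdivisions=3)


@pytest.fixture(scope="session")
def basis(mesh):
    op = em.assemble_laplace_beltrami(mesh)
    b = em.solve_eigenmodes(op, 6)
    return em.classify_symmetry(b, mesh)


@pytest.fixture(scope="session")
def parcellation(mesh):
    return sd.make_symmetric_parcellation(mesh, 29)


@pytest.fixture(scope="session")
def parcel_modes(basis, parcellation):
    W = em.parcel_weight_matrix(parcellation, basis.vertex_areas)
    return nfm.unit_rms_parcel_modes(basis, W)


@pytest.fixture(scope="session")
def response_table_300():
    """Pairwise coupling surface at the reference 300 s record length."""
    return nfm.build_pair_response_table(u_max=2.5, duration=300.0,
                                         n_u=26, n_reps=12, seed=7)


@pytest.fixture(scope="session")
def fit_grid(response_table_300, parcel_modes):
    ev = nfm.ModelMomentEvaluator(response_table_300, parcel_modes,
                                  np.ones(parcel_modes.shape[0]))
    return nfm.precompute_fit_grid(ev)


@pytest.fixture(scope="session")
def alpha_band():
    from neomode.signal_filters import CANONICAL_BANDS
    return CANONICAL_BANDS["alpha"]


def make_edge_cohort(rng, n_ep, n_hc, n_parcels=20, state_shift=None,
                     group_shift=None, interaction_edges=None,
                     interaction_size=0.0, noise_sd=1.0):
    """Synthetic edge-weight cohort (no time series) for NBS tests.

    Weights are Gaussian around zero; optional per-edge state shifts,
    group shifts, and a group-dependent state shift on a chosen edge set.
    """
    from neomode.netstats import ConnectivityCohort
    n = n_ep + n_hc
    E = n_parcels * (n_parcels - 1) // 2
    groups = np.array(["EP"] * n_ep + ["HC"] * n_hc)
    W = rng.normal(0.0, noise_sd, size=(n, 2, E))
    if state_shift is not None:
        W[:, 0, :] += state_shift            # AS gets the shift
    if interaction_edges is not None:
        hc = groups == "HC"
        W[np.ix_(hc, [0], interaction_edges)] += interaction_size
    if group_shift is not None:
        ep = groups == "EP"
        W[ep] += group_shift
    return ConnectivityCohort(W, groups, conn.edge_pairs(n_parcels),
                              n_parcels)


def connected_edge_subset(n_parcels, n_edges, rng=None):
    """Indices (into canonical edge order) of a connected planted subnetwork."""
    pairs = conn.edge_pairs(n_parcels)
    lookup = {(i, j): k for k, (i, j) in enumerate(pairs)}
    nodes = [0, 1]
    chosen = [lookup[(0, 1)]]
    rng = rng or np.random.default_rng(0)
    while len(chosen) < n_edges:
        a = int(rng.choice(nodes))
        b = int(rng.integers(0, n_parcels))
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        k = lookup[key]
        if k not in chosen:
            chosen.append(k)
            if b not in nodes:
                nodes.append(b)
    return np.array(sorted(chosen))
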