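"""Edge-wise contrasts, the network-based statistic, and effect-size grids.

The network-based statistic (NBS) controls family-wise error at the level
of connected components of suprathreshold edges: edge-wise t statistics are
thresholded (|t| >= h, positive and negative tails searched separately),
connected components are found in the parcel graph induced by the surviving
edges, and the size (edge count) of the largest component is compared with
its permutation null distribution (group / state labels randomized while
respecting the within-subject pairing).

Spectral fingerprints repeat the NBS contrast over the 21 x 15 grid of
(carrier, amplitude) band pairs and report the effect size of the largest
component as Cohen's d = mean component t / sqrt(total degrees of freedom);
grid cells without suprathreshold edges are null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import connectivity as conn
from . import signal_filters as sf

__all__ = [
    "ContrastSpec",
    "ConnectivityCohort",
    "NBSComponent",
    "NBSResult",
    "EffectGrid",
    "edge_statistics",
    "nbs",
    "cohens_d",
    "spectral_fingerprint",
]

CONTRAST_KINDS = ("sleep_main", "group_main", "interaction")


@dataclass
class ContrastSpec:
    """What to contrast and how to assess it."""

    kind: str = "sleep_main"
    threshold: float = 3.0       # edge-wise |t| height threshold
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    paired_groups: bool = False  # the two-sample contrasts read as paired

    def __post_init__(self):
        if self.kind not in CONTRAST_KINDS:
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass
class ConnectivityCohort:
    """Stack of per-subject, per-state edge-weight vectors.

    ``weights[subject, state, edge]`` with states ordered (AS, QS) and
    edges in canonical (retained) order.
    """

    weights: np.ndarray            # (N, 2, E)
    groups: np.ndarray             # (N,) 'EP' / 'HC'
    edge_index: np.ndarray         # (E, 2) parcel indices
    n_parcels: int
    subjects: list | None = None
    states: tuple = ("AS", "QS")

    def __post_init__(self):
        if self.weights.ndim != 3 or self.weights.shape[1] != 2:
            raise ValueError("weights must be (subjects, 2 states, edges)")
        if len(self.groups) != self.weights.shape[0]:
            raise ValueError("one group label per subject required")

    @property
    def n_subjects(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return self.weights.shape[2]

    @classmethod
    def from_matrices(cls, matrices: dict, groups, n_parcels: int,
                      mask: conn.EdgeMask | None = None,
                      subjects=None) -> "ConnectivityCohort":
        """Build from {subject: {state: ConnectivityMatrix}}."""
        subs = list(matrices) if subjects is None else subjects
        pairs = conn.edge_pairs(n_parcels)
        keep = mask.retain if mask is not None else np.ones(len(pairs), bool)
        W = np.stack([
            np.stack([matrices[s][st].edge_vector()[keep] for st in ("AS", "QS")])
            for s in subs])
        return cls(W, np.asarray([groups[s] for s in subs]), pairs[keep],
                   n_parcels, subs)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t over axis 0 of (N, E) differences."""
    n = diffs.shape[0]
    m = diffs.mean(0)
    sd = diffs.std(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t over axis 0; (n1, E) vs (n2, E)."""
    n1, n2 = x.shape[0], y.shape[0]
    v1 = x.var(0, ddof=1)
    v2 = y.var(0, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(0) - y.mean(0)) / (sp * np.sqrt(1 / n1 + 1 / n2))
    return np.where(sp == 0, 0.0, t)


def _contrast_data(cohort: ConnectivityCohort, kind: str):
    """Reduce the cohort to the exchangeable units of the contrast."""
    W = cohort.weights
    ep = cohort.groups == "EP"
    if kind == "sleep_main":
        return W[:, 0, :] - W[:, 1, :], None          # AS - QS per subject
    if kind == "group_main":
        return W.mean(axis=1), ep                     # state-averaged
    return W[:, 0, :] - W[:, 1, :], ep                # interaction


def edge_statistics(cohort: ConnectivityCohort, contrast: ContrastSpec
                    ) -> np.ndarray:
    """Per-edge t values for the requested contrast.

    sleep_main: paired t on (AS - QS) across all subjects;
    group_main: two-sample t (EP vs HC) on state-averaged weights;
    interaction: two-sample t on per-subject (AS - QS) differences.
    """
    data, ep = _contrast_data(cohort, contrast.kind)
    if ep is None:
        if data.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        return _paired_t(data)
    if min(ep.sum(), (~ep).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    return _two_sample_t(data[ep], data[~ep])


def contrast_df(cohort: ConnectivityCohort, kind: str) -> int:
    """Total degrees of freedom of the contrast's t statistic."""
    n = cohort.n_subjects
    return n - 1 if kind == "sleep_main" else n - 2


def cohens_d(mean_t: float, df: int) -> float:
    """Effect size: mean component t divided by sqrt(total df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(mean_t) / np.sqrt(df)


# ---------------------------------------------------------------------------
# NBS
# ---------------------------------------------------------------------------

@dataclass
class NBSComponent:
    edges: np.ndarray       # indices into the cohort edge list
    size: int               # edge count
    p_fwer: float
    mean_t: float
    sign: int               # +1 / -1 tail


@dataclass
class NBSResult:
    components: list
    t_values: np.ndarray
    null_max_size: dict     # sign -> (n_permutations,) array
    contrast: ContrastSpec
    df: int

    def significant(self, alpha: float | None = None) -> list:
        a = self.contrast.alpha if alpha is None else alpha
        return [c for c in self.components if c.p_fwer < a]

    def largest(self) -> NBSComponent | None:
        return max(self.components, key=lambda c: c.size, default=None)

    def to_json(self, path: str) -> None:
        out = {"contrast": self.contrast.kind,
               "threshold": self.contrast.threshold,
               "n_permutations": self.contrast.n_permutations,
               "df": self.df,
               "components": [{"size": c.size, "p_fwer": c.p_fwer,
                               "mean_t": c.mean_t, "sign": c.sign,
                               "edges": c.edges.tolist()}
                              for c in self.components],
               "null_max_size": {str(k): np.asarray(v).tolist()
                                 for k, v in self.null_max_size.items()}}
        with open(path, "w") as fh:
            json.dump(out, fh)


def _components_of(sel: np.ndarray, edge_index: np.ndarray, n_parcels: int):
    """Connected components (lists of edge indices) of suprathreshold edges."""
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return []
    e = edge_index[idx]
    A = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                   shape=(n_parcels, n_parcels))
    _, labels = connected_components(A + A.T, directed=False)
    comp_of_edge = labels[e[:, 0]]
    comps = []
    for c in np.unique(comp_of_edge):
        comps.append(idx[comp_of_edge == c])
    return comps


def _max_component_size(sel, edge_index, n_parcels) -> int:
    comps = _components_of(sel, edge_index, n_parcels)
    return max((len(c) for c in comps), default=0)


def _permuted_stats(cohort: ConnectivityCohort, contrast: ContrastSpec,
                    rng: np.random.Generator):
    """Generator of per-permutation edge t vectors."""
    data, ep = _contrast_data(cohort, contrast.kind)
    n = data.shape[0]
    if ep is None:
        # within-subject state-label swaps = sign flips of the differences
        d2 = data ** 2
        ss = d2.sum(0)
        for _ in range(contrast.n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n)
            m = (signs @ data) / n
            sd = np.sqrt(np.maximum(ss / n - m ** 2, 0.0) * n / (n - 1))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = m / (sd / np.sqrt(n))
            yield np.where(sd == 0, 0.0, t)
    else:
        n_ep = int(ep.sum())
        for _ in range(contrast.n_permutations):
            perm = rng.permutation(n)
            pep = np.zeros(n, dtype=bool)
            pep[perm[:n_ep]] = True
            yield _two_sample_t(data[pep], data[~pep])


def nbs(cohort: ConnectivityCohort, contrast: ContrastSpec,
        t_values: np.ndarray | None = None) -> NBSResult:
    """Network-based statistic with permutation FWER control.

    Both tails are searched separately (|t| >= threshold on each sign) and
    each observed component is compared against the null distribution of
    the maximum component size from its own tail.  p values carry the +1
    correction and are never exactly zero.
    """
    if t_values is None:
        t_values = edge_statistics(cohort, contrast)
    rng = np.random.default_rng(contrast.seed)
    E, n_p = cohort.edge_index, cohort.n_parcels
    h = contrast.threshold

    null = {+1: np.zeros(contrast.n_permutations, dtype=int),
            -1: np.zeros(contrast.n_permutations, dtype=int)}
    for k, t_perm in enumerate(_permuted_stats(cohort, contrast, rng)):
        null[+1][k] = _max_component_size(t_perm >= h, E, n_p)
        null[-1][k] = _max_component_size(t_perm <= -h, E, n_p)

    comps = []
    for sign in (+1, -1):
        sel = t_values >= h if sign > 0 else t_values <= -h
        for edges in _components_of(sel, E, n_p):
            size = len(edges)
            p = (1 + int((null[sign] >= size).sum())) / (1 + contrast.n_permutations)
            comps.append(NBSComponent(edges, size, p,
                                      float(t_values[edges].mean()), sign))
    comps.sort(key=lambda c: (-c.size, c.p_fwer))
    return NBSResult(comps, t_values, null, contrast,
                     contrast_df(cohort, contrast.kind))


# ---------------------------------------------------------------------------
# Spectral fingerprints
# ---------------------------------------------------------------------------

@dataclass
class EffectGrid:
    """(carrier, amplitude) grid of Cohen's d; NaN marks null cells."""

    d: np.ndarray                   # (21, 15)
    carrier_hz: np.ndarray
    amplitude_hz: np.ndarray
    contrast: ContrastSpec | None = None

    def argmax_cell(self):
        if np.all(np.isnan(self.d)):
            return None
        k = np.nanargmax(np.abs(self.d))
        i, j = np.unravel_index(k, self.d.shape)
        return self.carrier_hz[i], self.amplitude_hz[j]

    def save_tsv(self, path: str) -> None:
        import pandas as pd
        ci, aj = np.meshgrid(np.arange(len(self.carrier_hz)),
                             np.arange(len(self.amplitude_hz)), indexing="ij")
        pd.DataFrame({"carrier_hz": self.carrier_hz[ci.ravel()],
                      "amplitude_hz": self.amplitude_hz[aj.ravel()],
                      "cohens_d": self.d.ravel()}
                     ).to_csv(path, sep="\t", index=False)


def bandpair_connectivity_stack(cohort_ts, banks: sf.FilterBankSpec,
                                fs: float = 100.0,
                                mask: conn.EdgeMask | None = None,
                                window_s: float = 2.0,
                                orthogonalize: bool = True,
                                fs_env: float = 2.0,
                                normalize: bool = True):
    """Connectivity weights for every (carrier, amplitude) band pair.

    ``cohort_ts`` iterates subject records with ``timeseries[state]``
    arrays.  Returns ``weights[cell, subject, state, edge]`` (float32) plus
    the retained edge index; carrier filtering and envelope extraction are
    done once per carrier and reused across the 15 amplitude bands, with
    envelopes decimated to ``fs_env`` before amplitude filtering.
    """
    subjects = list(cohort_ts)
    n_c, n_a = len(banks.carrier), len(banks.amplitude)
    P = subjects[0].timeseries["AS"].shape[0]
    pairs = conn.edge_pairs(P)
    keep = mask.retain if mask is not None else np.ones(len(pairs), bool)
    kp = np.flatnonzero(keep)
    i_e, j_e = pairs[kp, 0], pairs[kp, 1]
    out = np.zeros((n_c * n_a, len(subjects), 2, len(kp)), dtype=np.float32)

    for si, rec in enumerate(subjects):
        for st_i, state in enumerate(("AS", "QS")):
            pts = rec.timeseries[state]
            for ci, cband in enumerate(banks.carrier):
                Xf = sf.trim_edges(sf.apply_band(pts, cband, fs), fs)
                if orthogonalize:
                    env_ref, env_res, fs_e = conn.residual_envelope_stack(
                        Xf, fs, window_s, fs_env)
                else:
                    env = sf.hilbert_envelope(Xf)
                    env_ref, fs_e = sf.decimate_envelope(env, fs, fs_env)
                    env_res = None
                for ai, aband in enumerate(banks.amplitude):
                    er = sf.apply_band(env_ref, aband, fs_e)
                    if env_res is None:
                        ern = er - er.mean(-1, keepdims=True)
                        nrm = np.linalg.norm(ern, axis=-1)
                        nrm[nrm == 0] = 1.0
                        ern = ern / nrm[:, None]
                        W = ern @ ern.T
                        vals = W[i_e, j_e]
                    else:
                        es = sf.apply_band(env_res, aband, fs_e)
                        a = conn._safe_corr_rows(er[i_e], es[i_e, j_e])
                        b = conn._safe_corr_rows(er[j_e], es[j_e, i_e])
                        vals = 0.5 * (a + b)
                    if normalize:
                        tot = np.abs(vals).sum()
                        if tot > 0:
                            vals = vals / tot
                    out[ci * n_a + ai, si, st_i] = vals
    return out, pairs[kp]


def spectral_fingerprint(cohort_ts, banks: sf.FilterBankSpec,
                         contrast: ContrastSpec, groups=None,
                         fs: float = 100.0, mask: conn.EdgeMask | None = None,
                         orthogonalize: bool = True,
                         stack=None) -> EffectGrid:
    """Cohen's d of the largest NBS component at each of the 315 band pairs.

    ``contrast.threshold`` defaults should be 2.5 for fingerprints; cells
    with no suprathreshold edges are null (NaN).  A precomputed ``stack``
    from :func:`bandpair_connectivity_stack` may be passed to amortize the
    filtering across several contrasts.
    """
    subjects = list(cohort_ts)
    if groups is None:
        groups = np.array([s.group for s in subjects])
    if stack is None:
        stack = bandpair_connectivity_stack(cohort_ts, banks, fs, mask,
                                            orthogonalize=orthogonalize)
    weights, edge_index = stack
    P = subjects[0].timeseries["AS"].shape[0]
    n_c, n_a = len(banks.carrier), len(banks.amplitude)
    d = np.full((n_c, n_a), np.nan)
    for ci in range(n_c):
        for ai in range(n_a):
            W = weights[ci * n_a + ai].astype(float)
            cc = ConnectivityCohort(W, np.asarray(groups), edge_index, P)
            res = nbs(cc, contrast)
            big = res.largest()
            if big is not None:
                d[ci, ai] = cohens_d(big.mean_t, res.df)
    return EffectGrid(d, np.array([b.f for b in banks.carrier]),
                      np.array([b.f for b in banks.amplitude]), contrast)
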