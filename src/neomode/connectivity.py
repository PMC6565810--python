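"""Orthogonalized amplitude-envelope correlation networks.

Pairwise functional coupling between parcels is the Pearson correlation of
amplitude envelopes after leakage suppression: within non-overlapping 2 s
windows one signal's least-squares projection on the other is removed, the
Hilbert envelope of the residual is correlated with the envelope of the
reference, and the two directions are averaged.  A 58-parcel recording
yields (58 x 57)/2 = 1653 unordered edges.

The edge-reliability mask rejects parcel pairs whose coupling cannot be
distinguished from reconstruction cross-talk: synchronized parcel pairs are
pushed through a leakage operator and their recovered coupling is compared
with a pooled surrogate distribution from non-synchronized pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import signal_filters as sf

__all__ = [
    "ConnectivityMatrix",
    "EdgeMask",
    "EdgeLengthTable",
    "edge_count",
    "edge_pairs",
    "orthogonalize_window",
    "envelope_correlation",
    "connectivity_matrix",
    "derive_edge_mask",
    "normalize_connectivity",
    "edge_length_distribution",
]


def edge_count(n_parcels: int) -> int:
    """Number of unordered parcel pairs: n(n-1)/2."""
    return n_parcels * (n_parcels - 1) // 2


def edge_pairs(n_parcels: int) -> np.ndarray:
    """(E, 2) upper-triangle parcel index pairs in canonical order."""
    i, j = np.triu_indices(n_parcels, 1)
    return np.column_stack([i, j])


@dataclass
class ConnectivityMatrix:
    """Symmetric parcel-by-parcel weight matrix with pipeline provenance.

    Masked-out entries are NaN; ``retained_values`` returns the finite
    upper-triangle weights in canonical edge order.
    """

    weights: np.ndarray
    band: str = ""
    masked: bool = False
    normalized: bool = False

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]

    def edge_vector(self) -> np.ndarray:
        i, j = np.triu_indices(self.n_parcels, 1)
        return self.weights[i, j]

    def retained_values(self) -> np.ndarray:
        v = self.edge_vector()
        return v[np.isfinite(v)]

    def save_tsv(self, path: str) -> None:
        import pandas as pd
        pairs = edge_pairs(self.n_parcels)
        pd.DataFrame({"parcel_i": pairs[:, 0], "parcel_j": pairs[:, 1],
                      "weight": self.edge_vector()}
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class EdgeMask:
    """Binary edge-reliability template, shared by every subject matrix."""

    retain: np.ndarray            # (E,) bool, canonical edge order
    meta: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.retain.sum())

    @property
    def n_edges(self) -> int:
        return len(self.retain)

    def excluded_percent(self) -> float:
        return 100.0 * (self.n_edges - self.n_retained) / self.n_edges

    def apply(self, C: ConnectivityMatrix) -> ConnectivityMatrix:
        W = C.weights.copy()
        i, j = np.triu_indices(C.n_parcels, 1)
        drop = ~self.retain
        W[i[drop], j[drop]] = np.nan
        W[j[drop], i[drop]] = np.nan
        return ConnectivityMatrix(W, C.band, True, C.normalized)

    def save(self, tsv_path: str, json_path: str | None = None) -> None:
        import pandas as pd
        pairs = edge_pairs(int((1 + np.sqrt(1 + 8 * self.n_edges)) / 2))
        pd.DataFrame({"parcel_i": pairs[:, 0], "parcel_j": pairs[:, 1],
                      "retain": self.retain.astype(int)}
                     ).to_csv(tsv_path, sep="\t", index=False)
        if json_path:
            with open(json_path, "w") as fh:
                json.dump(self.meta, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# Estimator primitives
# ---------------------------------------------------------------------------

def _window_view(x: np.ndarray, w: int) -> np.ndarray:
    """Reshape the last axis into (n_windows, w), dropping the remainder."""
    n_win = x.shape[-1] // w
    return x[..., :n_win * w].reshape(x.shape[:-1] + (n_win, w))


def orthogonalize_window(x: np.ndarray, y: np.ndarray, fs: float,
                         window_s: float = 2.0) -> np.ndarray:
    """Residual of ``y`` after projecting out ``x`` in non-overlapping windows.

    Within each complete window the least-squares projection of ``y`` on
    ``x`` is removed; windows are concatenated and a trailing partial window
    is dropped.  A window where ``x`` is identically zero leaves ``y``
    untouched (no projection defined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    w = int(round(window_s * fs))
    if x.shape[-1] < w:
        raise ValueError("window does not fit the series")
    xw, yw = _window_view(x, w), _window_view(y, w)
    denom = (xw * xw).sum(-1)
    coef = np.divide((xw * yw).sum(-1), denom,
                     out=np.zeros_like(denom), where=denom > 0)
    return (yw - coef[..., None] * xw).reshape(y.shape[:-1] + (-1,))


def _orthogonalize_batch(X: np.ndarray, ref: np.ndarray, w: int) -> np.ndarray:
    """Residuals of every row of ``X`` on ``ref`` in windows of ``w``."""
    Xw = _window_view(X, w)
    rw = _window_view(ref, w)
    denom = (rw * rw).sum(-1)
    coef = np.divide((Xw * rw).sum(-1), denom,
                     out=np.zeros(Xw.shape[:-1]), where=denom > 0)
    return (Xw - coef[..., None] * rw).reshape(X.shape[0], -1)


def _safe_corr_rows(A: np.ndarray, B: np.ndarray,
                    warn: bool = False) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows contribute 0."""
    A = A - A.mean(-1, keepdims=True)
    B = B - B.mean(-1, keepdims=True)
    na = np.linalg.norm(A, axis=-1)
    nb = np.linalg.norm(B, axis=-1)
    denom = na * nb
    bad = denom == 0
    if warn and np.any(bad):
        warnings.warn("constant envelope encountered; contributing 0")
    return np.divide((A * B).sum(-1), denom,
                     out=np.zeros_like(denom), where=~bad)


def _maybe_amp_filter(env: np.ndarray, fs: float, amp_band,
                      fs_env: float = 2.0):
    """Decimate envelopes and band-pass into the amplitude band."""
    if amp_band is None:
        return env
    env_d, fs_d = sf.decimate_envelope(env, fs, fs_env)
    return sf.apply_band(env_d, amp_band, fs_d)


def envelope_correlation(x: np.ndarray, y: np.ndarray, fs: float,
                         amp_band=None, window_s: float = 2.0,
                         orthogonalize: bool = True) -> float:
    """Direction-averaged orthogonalized envelope correlation in [-1, 1].

    Mean of ``corr(env(x), env(y orth x))`` and ``corr(env(y), env(x orth y))``.
    With ``amp_band`` the envelopes are band-passed into that (slow)
    amplitude band before correlating.  Collinear inputs (residual
    identically zero) and constant envelopes contribute 0.  With
    ``orthogonalize=False`` the plain envelope correlation is returned
    (used by the model-fitting pipeline, whose coupling is zero-lag
    coherent by construction and would otherwise be projected out).
    """
    if not orthogonalize:
        ex = _maybe_amp_filter(sf.hilbert_envelope(np.asarray(x, float)),
                               fs, amp_band)
        ey = _maybe_amp_filter(sf.hilbert_envelope(np.asarray(y, float)),
                               fs, amp_band)
        return float(_safe_corr_rows(ex[None], ey[None], warn=True)[0])
    vals = []
    for a, b in ((x, y), (y, x)):
        resid = orthogonalize_window(a, b, fs, window_s)
        env_ref = sf.hilbert_envelope(np.asarray(a, float)[: resid.shape[-1]])
        env_res = sf.hilbert_envelope(resid)
        env_ref = _maybe_amp_filter(env_ref, fs, amp_band)
        env_res = _maybe_amp_filter(env_res, fs, amp_band)
        vals.append(float(_safe_corr_rows(env_ref[None], env_res[None],
                                          warn=True)[0]))
    return 0.5 * (vals[0] + vals[1])


def batch_envelope_correlation(X: np.ndarray, Y: np.ndarray, fs: float,
                               window_s: float = 2.0, amp_band=None,
                               orthogonalize: bool = True) -> np.ndarray:
    """Envelope correlation for many (x, y) pairs at once; rows are pairs."""
    if not orthogonalize:
        ex = _maybe_amp_filter(sf.hilbert_envelope(X), fs, amp_band)
        ey = _maybe_amp_filter(sf.hilbert_envelope(Y), fs, amp_band)
        return _safe_corr_rows(ex, ey)
    w = int(round(window_s * fs))
    n = (X.shape[-1] // w) * w
    X, Y = X[..., :n], Y[..., :n]
    out = np.zeros(X.shape[0])
    for A, B in ((X, Y), (Y, X)):
        Bw = _window_view(B, w)
        Aw = _window_view(A, w)
        denom = (Aw * Aw).sum(-1)
        coef = np.divide((Aw * Bw).sum(-1), denom,
                         out=np.zeros_like(denom), where=denom > 0)
        resid = (Bw - coef[..., None] * Aw).reshape(B.shape)
        env_ref = _maybe_amp_filter(sf.hilbert_envelope(A), fs, amp_band)
        env_res = _maybe_amp_filter(sf.hilbert_envelope(resid), fs, amp_band)
        out += _safe_corr_rows(env_ref, env_res)
    return out / 2.0


# ---------------------------------------------------------------------------
# Full matrices
# ---------------------------------------------------------------------------

def residual_envelope_stack(Xf: np.ndarray, fs: float, window_s: float = 2.0,
                            fs_env: float | None = None):
    """Reference and residual envelopes for all ordered parcel pairs.

    ``Xf`` is the band-limited (n_parcels, T) array.  Returns
    ``(env_ref, env_res, fs_env)`` where ``env_ref[i]`` is the envelope of
    parcel ``i`` and ``env_res[i, j]`` the envelope of parcel ``j``
    orthogonalized to parcel ``i``.  With ``fs_env`` the envelopes are
    decimated (used by the double-filter-bank pipeline).
    """
    P, T = Xf.shape
    w = int(round(window_s * fs))
    n = (T // w) * w
    Xf = Xf[:, :n]
    env_ref = sf.hilbert_envelope(Xf)
    if fs_env is not None:
        env_ref, fs_e = sf.decimate_envelope(env_ref, fs, fs_env)
    else:
        fs_e = fs
    Te = env_ref.shape[-1]
    env_res = np.empty((P, P, Te))
    for i in range(P):
        resid = _orthogonalize_batch(Xf, Xf[i], w)
        er = sf.hilbert_envelope(resid)
        if fs_env is not None:
            er, _ = sf.decimate_envelope(er, fs, fs_env)
        env_res[i] = er
    return env_ref, env_res, fs_e


def _matrix_from_envelopes(env_ref: np.ndarray, env_res: np.ndarray) -> np.ndarray:
    P = env_ref.shape[0]
    C_dir = np.zeros((P, P))
    for i in range(P):
        C_dir[i] = _safe_corr_rows(np.broadcast_to(env_ref[i], env_res[i].shape),
                                   env_res[i])
    C = 0.5 * (C_dir + C_dir.T)
    np.fill_diagonal(C, 0.0)
    return C


def connectivity_matrix(pts: np.ndarray, band, fs: float = 100.0,
                        amp_band=None, window_s: float = 2.0,
                        mask: EdgeMask | None = None, normalize: bool = False,
                        edge_trim_s: float = sf.EDGE_TRIM_S,
                        orthogonalize: bool = True,
                        expected_parcels: int | None = 58) -> ConnectivityMatrix:
    """Full envelope-correlation matrix for one parcel recording.

    Pipeline: band-pass into ``band`` -> drop filter transients -> windowed
    orthogonalization -> Hilbert envelopes (optionally band-passed into
    ``amp_band``) -> Pearson, averaged over both directions; then the
    reliability ``mask`` and global normalization if requested.
    ``orthogonalize=False`` selects the plain envelope correlation used by
    the model-fitting pipeline.
    """
    pts = np.asarray(pts, float)
    if expected_parcels is not None and pts.shape[0] != expected_parcels:
        raise ValueError(f"expected {expected_parcels} parcels, got {pts.shape[0]}")
    Xf = sf.apply_band(pts, band, fs)
    Xf = sf.trim_edges(Xf, fs, edge_trim_s)
    if not orthogonalize:
        env = sf.hilbert_envelope(Xf)
        if amp_band is not None:
            env, fs_e = sf.decimate_envelope(env, fs, 2.0)
            env = sf.apply_band(env, amp_band, fs_e)
        env = env - env.mean(-1, keepdims=True)
        nrm = np.linalg.norm(env, axis=-1)
        nrm[nrm == 0] = 1.0
        W = (env / nrm[:, None]) @ (env / nrm[:, None]).T
        np.fill_diagonal(W, 0.0)
    else:
        fs_env = 2.0 if amp_band is not None else None
        env_ref, env_res, fs_e = residual_envelope_stack(Xf, fs, window_s,
                                                         fs_env)
        if amp_band is not None:
            env_ref = sf.apply_band(env_ref, amp_band, fs_e)
            env_res = sf.apply_band(env_res, amp_band, fs_e)
        W = _matrix_from_envelopes(env_ref, env_res)
    name = band.name if hasattr(band, "name") else f"f={band.f:g}Hz"
    C = ConnectivityMatrix(W, band=name)
    if mask is not None:
        C = mask.apply(C)
    if normalize:
        C = normalize_connectivity(C)
    return C


def normalize_connectivity(C: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide every weight by the global sum of retained |weights|.

    Scale invariant and idempotent; signs are preserved.
    """
    total = np.nansum(np.abs(C.edge_vector()))
    if total == 0:
        raise ValueError("all-zero connectivity matrix cannot be normalized")
    return ConnectivityMatrix(C.weights / total, C.band, C.masked, True)


# ---------------------------------------------------------------------------
# Edge-reliability mask
# ---------------------------------------------------------------------------

def _alpha_noise(rng, shape, fs, lo=8.0, hi=13.0, trim_s=2.0):
    """Unit-variance alpha-band noise with filter transients discarded."""
    pad = int(round(trim_s * fs))
    x = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    x = sf.apply_bandpass(x, lo, hi, fs)
    x = x[..., pad:pad + shape[-1]]
    return x / x.std(axis=-1, keepdims=True)


def derive_edge_mask(parcellation, leak, n_iter: int = 500,
                     percentile: float = 99.0, seed: int = 0,
                     duration: float = 30.0, fs: float = 100.0,
                     modulation_freq: float = 0.1, modulation_depth: float = 0.8,
                     n_surrogate_pairs: int = 100, window_s: float = 2.0,
                     per_edge: bool = False) -> EdgeMask:
    """Edge-reliability template from synchronized-pair simulations.

    In every iteration each parcel pair in turn is given a shared slow
    amplitude modulation on independent alpha carriers, parcel signals are
    mixed through the leakage operator, and the pair's envelope correlation
    is recovered.  Surrogate couplings come from mixed but non-synchronized
    parcels; edges whose mean recovered coupling does not exceed the
    ``percentile``-th surrogate percentile (pooled across all iterations by
    default, or per edge with ``per_edge=True``) are rejected.  The same
    mask is applied to every subject matrix.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    P = parcellation.n_parcels
    pairs = edge_pairs(P)
    E = len(pairs)
    B = leak.mixing
    T = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(T) / fs

    recovered = np.zeros((n_iter, E))
    surrogates = []
    ii, jj = pairs[:, 0], pairs[:, 1]
    for it in range(n_iter):
        S = _alpha_noise(rng, (P, T), fs)
        base = B @ S
        # surrogate pool: couplings among mixed, non-synchronized parcels
        sel = rng.choice(E, size=min(n_surrogate_pairs, E), replace=False)
        surr = batch_envelope_correlation(base[ii[sel]], base[jj[sel]],
                                          fs, window_s)
        surrogates.append(np.column_stack([sel, surr]))
        # synchronized pairs: common modulator, independent carriers
        phase = rng.uniform(0, 2 * np.pi, size=(E, 1))
        mod = 1.0 + modulation_depth * np.cos(2 * np.pi * modulation_freq * t
                                              + phase)
        u = mod * _alpha_noise(rng, (E, T), fs)
        v = mod * _alpha_noise(rng, (E, T), fs)
        du, dv = u - S[ii], v - S[jj]
        row_i = base[ii] + B[ii, ii, None] * du + B[ii, jj, None] * dv
        row_j = base[jj] + B[jj, jj, None] * dv + B[jj, ii, None] * du
        recovered[it] = batch_envelope_correlation(row_i, row_j, fs, window_s)

    surr_all = np.vstack(surrogates)
    mean_recovered = recovered.mean(axis=0)
    if per_edge:
        thresh = np.full(E, np.nan)
        for e in range(E):
            vals = surr_all[surr_all[:, 0] == e, 1]
            thresh[e] = (np.percentile(vals, percentile) if len(vals)
                         else np.percentile(surr_all[:, 1], percentile))
    else:
        thresh = np.percentile(surr_all[:, 1], percentile)
    retain = mean_recovered > thresh
    meta = {"n_iter": n_iter, "percentile": percentile,
            "operator_spread_mm": leak.spread, "seed": seed,
            "duration_s": duration, "per_edge": per_edge,
            "n_retained": int(retain.sum()), "n_edges": E}
    return EdgeMask(retain, meta)


# ---------------------------------------------------------------------------
# Edge lengths
# ---------------------------------------------------------------------------

@dataclass
class EdgeLengthTable:
    """Euclidean centroid distances of an edge set with a KDE summary."""

    lengths: np.ndarray                  # (E,) mm
    kde: object | None = None            # gaussian_kde (None for 1 edge)

    def density(self, grid: np.ndarray) -> np.ndarray:
        if self.kde is None:
            # single edge: one Gaussian kernel at that distance
            bw = max(1.0, 0.1 * self.lengths[0])
            return stats.norm.pdf(grid, self.lengths[0], bw)
        return self.kde(grid)

    def mean_length(self) -> float:
        return float(self.lengths.mean())


def edge_length_distribution(edges: np.ndarray, parcellation) -> EdgeLengthTable:
    """Centroid-distance lengths + Silverman-bandwidth Gaussian KDE."""
    edges = np.asarray(edges)
    if edges.size == 0:
        raise ValueError("empty edge set")
    c = parcellation.centroids
    lengths = np.linalg.norm(c[edges[:, 0]] - c[edges[:, 1]], axis=1)
    kde = (stats.gaussian_kde(lengths, bw_method="silverman")
           if len(lengths) > 1 and lengths.std() > 0 else None)
    return EdgeLengthTable(lengths, kde)
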