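"""Group-level inference: mixed ANOVA, partial correlations, asymmetry tests.

Mode weights fitted per subject and sleep state are compared with a
mixed-design (split-plot) ANOVA: group (EP vs HC) between subjects, sleep
state (AS vs QS) within subjects, plus their interaction.  Connectivity
changes between states are related to developmental outcome scores by
partial Pearson correlation controlling for conceptional age at recording,
with Benjamini-Hochberg FDR over the family of outcome-by-band tests.
Hemispheric symmetry of the networks is checked with paired Wilcoxon
signed-rank tests on within-hemisphere aggregate connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaTable",
    "PartialCorrResult",
    "AsymmetryResult",
    "mixed_anova",
    "partial_pearson",
    "bh_fdr",
    "hemispheric_asymmetry",
    "brain_behavior",
    "connectivity_change",
]


@dataclass
class AnovaEffect:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq: float          # classic: SS_effect / SS_total
    eta_sq_partial: float


@dataclass
class AnovaTable:
    between: AnovaEffect
    within: AnovaEffect
    interaction: AnovaEffect

    def as_frame(self) -> pd.DataFrame:
        rows = [vars(e) for e in (self.between, self.within, self.interaction)]
        return pd.DataFrame(rows)


def mixed_anova(values: pd.DataFrame, dv: str = "value",
                subject: str = "subject", within: str = "state",
                between: str = "group") -> AnovaTable:
    """Mixed-design ANOVA for a two-state, two-group table.

    ``values`` is long format with one row per subject x state.  Sums of
    squares follow the standard split-plot partition; the within-effect
    denominator df is (N - g)(k - 1).  Both classic eta squared
    (SS_effect / SS_total) and partial eta squared are reported, since the
    two conventions differ materially for large subject variance.
    """
    df = values[[subject, within, between, dv]].copy()
    if df[[subject, within]].duplicated().any():
        raise ValueError("duplicate subject x state cells")
    wide = df.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells: every subject needs every state")
    states = list(wide.columns)
    k = len(states)
    groups = df.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.loc[wide.index]
    glabels = groups.unique()
    g = len(glabels)
    N = wide.shape[0]

    y = wide.to_numpy()
    grand = y.mean()
    subj_means = y.mean(axis=1)
    state_means = y.mean(axis=0)
    group_means = np.array([y[groups.values == gl].mean() for gl in glabels])
    n_g = np.array([(groups.values == gl).sum() for gl in glabels])

    ss_total = ((y - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = (k * n_g * (group_means - grand) ** 2).sum()
    ss_subj_err = ss_between_subj - ss_group
    ss_within_total = ss_total - ss_between_subj
    ss_state = N * ((state_means - grand) ** 2).sum()
    cell_means = np.array([[y[groups.values == gl][:, s].mean()
                            for s in range(k)] for gl in glabels])
    ss_cells = (n_g[:, None] * (cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_state
    ss_err_within = ss_within_total - ss_state - ss_inter

    df_group, df_state = g - 1, k - 1
    df_inter = df_group * df_state
    df_subj_err = N - g
    df_err_within = (N - g) * (k - 1)

    tol = 1e-12 * max(ss_total, 1.0)

    def effect(name, ss, dfn, ss_err, dfe):
        ms, mse = ss / dfn, ss_err / dfe
        if mse <= tol:
            F = 0.0 if ms <= tol else np.inf
        else:
            F = ms / mse
        p = stats.f.sf(F, dfn, dfe) if np.isfinite(F) else 0.0
        return AnovaEffect(name, float(F), dfn, dfe, float(p),
                           float(ss / ss_total) if ss_total > 0 else 0.0,
                           float(ss / (ss + ss_err)) if ss + ss_err > 0 else 0.0)

    return AnovaTable(
        between=effect("group", ss_group, df_group, ss_subj_err, df_subj_err),
        within=effect("state", ss_state, df_state, ss_err_within, df_err_within),
        interaction=effect("group_x_state", ss_inter, df_inter,
                           ss_err_within, df_err_within))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrResult:
    r: float
    p: float
    ci95: tuple
    n: int
    covariates: int = 1

    def as_dict(self) -> dict:
        return {"R": self.r, "p": self.p, "ci_lo": self.ci95[0],
                "ci_hi": self.ci95[1], "n": self.n}


def partial_pearson(x, y, z) -> PartialCorrResult:
    """Partial Pearson correlation of x and y controlling for z.

    Residual-regression form: correlate the residuals of x and y after
    regressing each on z (with intercept).  The p value uses the
    t distribution with n - 3 df; the 95% CI comes from the Fisher z
    transform with SE 1/sqrt(n - 4).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = len(x)
    if not (len(y) == n and len(z) == n):
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    Z = np.column_stack([np.ones(n), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValueError("zero residual variance")
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    dof = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r ** 2))
        p = 2 * stats.t.sf(abs(t), dof)
    if abs(r) == 1.0 or n <= 4:
        ci = (r, r)
    else:
        zr = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 4)
        ci = tuple(np.tanh([zr - 1.959964 * se, zr + 1.959964 * se]))
    return PartialCorrResult(r, float(p), ci, n)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Hemispheric asymmetry
# ---------------------------------------------------------------------------

@dataclass
class AsymmetryResult:
    """Left-right aggregate-connectivity comparison per group x state."""

    table: pd.DataFrame     # group, state, left, right, W, p, p_fdr, shapiro_p


def _wilcoxon_p(diffs: np.ndarray) -> tuple:
    """Two-tailed signed-rank p; all-zero differences give p = 1."""
    d = diffs[diffs != 0]
    if len(d) == 0:
        return 0.0, 1.0
    mode = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, correction=(mode == "approx"), method=mode)
    return float(res.statistic), float(res.pvalue)


def hemisphere_edge_sets(edge_index: np.ndarray, n_pairs: int = 29):
    """Indices of within-right and within-left edges (parcel id < / >= n_pairs)."""
    right = (edge_index < n_pairs).all(axis=1)
    left = (edge_index >= n_pairs).all(axis=1)
    return np.flatnonzero(right), np.flatnonzero(left)


def hemispheric_asymmetry(cohort, n_pairs: int = 29) -> AsymmetryResult:
    """Wilcoxon tests of left vs right within-hemisphere mean connectivity.

    One paired two-tailed signed-rank test per group x state (four tests),
    BH-FDR adjusted jointly; a Shapiro-Wilk normality p value of the
    left-right differences is recorded as the rationale for the
    non-parametric choice.
    """
    r_idx, l_idx = hemisphere_edge_sets(cohort.edge_index, n_pairs)
    if len(r_idx) == 0 or len(l_idx) == 0:
        raise ValueError("no within-hemisphere edges (unpaired parcels?)")
    rows = []
    for gl in ("EP", "HC"):
        sel = cohort.groups == gl
        for st_i, state in enumerate(cohort.states):
            right = cohort.weights[sel, st_i][:, r_idx].mean(axis=1)
            left = cohort.weights[sel, st_i][:, l_idx].mean(axis=1)
            d = left - right
            W, p = _wilcoxon_p(d)
            sh_p = (stats.shapiro(d).pvalue if len(d) >= 3
                    and np.ptp(d) > 0 else np.nan)
            rows.append({"group": gl, "state": state,
                         "left": left.mean(), "right": right.mean(),
                         "W": W, "p": p, "shapiro_p": sh_p})
    tab = pd.DataFrame(rows)
    tab["p_fdr"] = bh_fdr(tab["p"].to_numpy())
    return AsymmetryResult(tab)


# ---------------------------------------------------------------------------
# Brain-behavior coupling
# ---------------------------------------------------------------------------

def connectivity_change(cohort, edge_set: np.ndarray) -> np.ndarray:
    """Per-subject AS-minus-QS mean weight over an edge set (indices)."""
    if len(edge_set) == 0:
        raise ValueError("empty edge set")
    w = cohort.weights[:, :, edge_set].mean(axis=2)
    return w[:, 0] - w[:, 1]


def brain_behavior(changes_by_band: dict, outcomes: pd.DataFrame,
                   score_columns=("visual", "social_emotional"),
                   age_column: str = "conceptional_age") -> pd.DataFrame:
    """Partial correlations of connectivity changes with outcome scores.

    ``changes_by_band`` maps band name to a per-EP-subject vector of
    AS-minus-QS mean connectivity over the interaction network.  Each
    (band, score) pair is tested with a partial Pearson correlation
    controlling for conceptional age; the whole family is BH-FDR adjusted
    (six tests in the reference design: two scores x three bands).
    """
    rows = []
    age = outcomes[age_column].to_numpy()
    for band, change in changes_by_band.items():
        change = np.asarray(change, float)
        if len(change) != len(outcomes):
            raise ValueError("one change value per outcome row required")
        for score in score_columns:
            res = partial_pearson(change, outcomes[score].to_numpy(), age)
            rows.append({"band": band, "score": score, **res.as_dict()})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out
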