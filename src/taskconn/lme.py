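"""Linear mixed-effects contrasts on connectivity summaries.

The central model is a subject-random-intercept LMM on Fisher-z connectivity
with fixed effects for stimulation condition (stim/sham), cognitive task
(retrieval/rest), stimulation group (PMN-targeted/PFC-targeted), their
interactions, and a tSNR nuisance covariate. Factors use +/- 1/2 sum-to-zero
contrasts so the three-way beta is the difference of
(stim - sham, retrieval) - (stim - sham, rest) between the two groups on the
Fisher-z scale. Estimation is REML (statsmodels MixedLM); denominator degrees
of freedom use a Satterthwaite approximation computed from the closed-form
REML likelihood of the random-intercept model, with a residual-df fallback
flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMEResult",
    "design_matrix",
    "fit_lme",
    "edge_interaction_tests",
    "fdr_bh",
    "THREEWAY_TERM",
    "TWOWAY_TERM",
]

THREEWAY_TERM = "condition:task:group"
TWOWAY_TERM = "condition:task"

_CODES = {
    "condition": {"stim": 0.5, "sham": -0.5},
    "task": {"retrieval": 0.5, "rest": -0.5},
    "group": {"PMN": 0.5, "PFC": -0.5},
    "order": {"stim_first": 0.5, "sham_first": -0.5},
}


def _code(table: pd.DataFrame, factor: str) -> np.ndarray:
    mapping = _CODES[factor]
    col = table[factor].map(mapping)
    if col.isna().any():
        bad = sorted(set(table.loc[col.isna(), factor]))
        raise ValueError(f"unknown {factor} level(s) {bad}; "
                         f"expected {sorted(mapping)}")
    return col.to_numpy(dtype=float)


def design_matrix(table: pd.DataFrame, model: str = "threeway",
                  include_order: bool = False,
                  hierarchy: str = "full") -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix with sum-to-zero (+/- 1/2) factor coding.

    ``model="threeway"`` includes group terms; ``model="twoway"`` is meant for
    a single group's rows and drops group entirely. ``hierarchy="full"``
    includes all lower-order interactions beneath the three-way term;
    ``hierarchy="mains_plus_threeway"`` keeps only main effects plus the
    three-way product.
    """
    n = len(table)
    cond = _code(table, "condition")
    task = _code(table, "task")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    if model == "threeway":
        group = _code(table, "group")
        cols["condition"] = cond
        cols["task"] = task
        cols["group"] = group
        if hierarchy == "full":
            cols["condition:task"] = cond * task
            cols["condition:group"] = cond * group
            cols["task:group"] = task * group
        elif hierarchy != "mains_plus_threeway":
            raise ValueError("hierarchy must be 'full' or 'mains_plus_threeway'")
        cols[THREEWAY_TERM] = cond * task * group
    elif model == "twoway":
        cols["condition"] = cond
        cols["task"] = task
        cols[TWOWAY_TERM] = cond * task
    else:
        raise ValueError("model must be 'threeway' or 'twoway'")
    if include_order:
        order = _code(table, "order")
        cols["order"] = order
        cols["order:condition"] = order * cond
    if "tsnr" in table.columns and table["tsnr"].notna().all():
        tsnr = table["tsnr"].to_numpy(dtype=float)
        cols["tsnr"] = tsnr - tsnr.mean()
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def _drop_degenerate(X: np.ndarray, names: list[str]):
    """Drop all-zero / collinearity-degenerate columns (e.g. constant tSNR)."""
    keep, kept_names, dropped = [], [], []
    for j, name in enumerate(names):
        col = X[:, j]
        candidate = X[:, keep + [j]] if keep else col[:, None]
        if np.linalg.norm(col) < 1e-12 or \
                np.linalg.matrix_rank(candidate) <= len(keep):
            dropped.append(name)
        else:
            keep.append(j)
            kept_names.append(name)
    return X[:, keep], kept_names, dropped


@dataclass
class LMEResult:
    """Fixed-effect table plus variance components for one LMM fit."""

    terms: pd.DataFrame          # term, beta, se, t, df, p
    random_intercept_var: float
    residual_var: float
    n_obs: int
    converged: bool
    df_method: str               # 'satterthwaite' | 'residual' | 'ols'
    dropped_terms: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r}; have {self.terms['term'].tolist()}")
        return row.iloc[0]


# --- closed-form REML machinery for the random-intercept model -------------

def _subject_blocks(subjects: np.ndarray):
    _, inverse = np.unique(subjects, return_inverse=True)
    return [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]


def _gls_pieces(theta, X, y, blocks):
    """Accumulate X'V^-1 X, X'V^-1 y, y'V^-1 y, log|V| for V = se2 I + su2 J."""
    su2, se2 = theta
    p = X.shape[1]
    M = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    logdetV = 0.0
    for idx in blocks:
        ni = idx.size
        Xi, yi = X[idx], y[idx]
        denom = se2 + ni * su2
        w = su2 / denom
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        M += (Xi.T @ Xi - w * np.outer(sx, sx)) / se2
        Xty += (Xi.T @ yi - w * sx * sy) / se2
        yty += (yi @ yi - w * sy * sy) / se2
        logdetV += (ni - 1) * np.log(se2) + np.log(denom)
    return M, Xty, yty, logdetV


def _reml_loglik(theta, X, y, blocks) -> float:
    if min(theta) <= 0:
        return -np.inf
    M, Xty, yty, logdetV = _gls_pieces(theta, X, y, blocks)
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(M, Xty)
    quad = yty - beta @ Xty
    return -0.5 * (logdetV + logdetM + quad)


def _coef_var(theta, X, y, blocks) -> np.ndarray:
    M, _, _, _ = _gls_pieces(theta, X, y, blocks)
    return np.diag(np.linalg.inv(M))


def _satterthwaite_df(theta, X, y, blocks) -> np.ndarray | None:
    """Per-coefficient Satterthwaite df via the delta method on Var(beta_j).

    df_j = 2 f_j^2 / (g_j' A g_j) with f_j = [ (X'V^-1 X)^-1 ]_jj, g_j its
    gradient in the variance parameters theta = (sigma_u^2, sigma_e^2), and A
    the inverse REML observed information. Returns None when the information
    matrix is not positive definite (caller falls back to residual df).
    """
    theta = np.asarray(theta, dtype=float)
    steps = np.maximum(1e-4 * theta, 1e-8)
    # observed information by central differences
    H = np.zeros((2, 2))
    for a in range(2):
        for b in range(a, 2):
            ea = np.eye(2)[a] * steps[a]
            eb = np.eye(2)[b] * steps[b]
            fpp = _reml_loglik(theta + ea + eb, X, y, blocks)
            fpm = _reml_loglik(theta + ea - eb, X, y, blocks)
            fmp = _reml_loglik(theta - ea + eb, X, y, blocks)
            fmm = _reml_loglik(theta - ea - eb, X, y, blocks)
            if not all(np.isfinite([fpp, fpm, fmp, fmm])):
                return None
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * steps[a] * steps[b])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(A) <= 0):
        return None
    f0 = _coef_var(theta, X, y, blocks)
    grads = np.empty((X.shape[1], 2))
    for a in range(2):
        ea = np.eye(2)[a] * steps[a]
        grads[:, a] = (_coef_var(theta + ea, X, y, blocks)
                       - _coef_var(theta - ea, X, y, blocks)) / (2 * steps[a])
    var_f = np.einsum("ja,ab,jb->j", grads, A, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * f0 ** 2 / var_f
    df[~np.isfinite(df) | (df <= 0)] = np.nan
    return df


def _ols_result(X, names, y, dropped) -> LMEResult:
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid / dof)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    terms = pd.DataFrame({"term": names, "beta": beta, "se": se, "t": t,
                          "df": float(dof), "p": pvals})
    return LMEResult(terms=terms, random_intercept_var=0.0,
                     residual_var=sigma2, n_obs=n, converged=True,
                     df_method="ols", dropped_terms=dropped)


def fit_lme(table: pd.DataFrame, model: str = "threeway",
            include_order: bool = False, df_method: str = "satterthwaite",
            hierarchy: str = "full") -> LMEResult:
    """REML fit of the subject-random-intercept model on a long table.

    ``table`` must have columns subject, condition, task, value (plus group
    for the three-way model, order when ``include_order``, and optionally
    tsnr). Non-convergence falls back to OLS with ``converged=False``; a
    random-intercept variance pinned at the zero boundary also reduces to OLS
    (flagged via ``df_method='ols'``).
    """
    table = table.reset_index(drop=True)
    y = table["value"].to_numpy(dtype=float)
    X, names = design_matrix(table, model=model, include_order=include_order,
                             hierarchy=hierarchy)
    X, names, dropped = _drop_degenerate(X, names)
    subjects = table["subject"].to_numpy()
    counts = pd.Series(subjects).value_counts()
    if (counts < 2).any():
        raise ValueError("every subject needs >= 2 rows")
    blocks = _subject_blocks(subjects)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = MixedLM(y, X, groups=subjects).fit(reml=True)
            converged = bool(getattr(fit, "converged", True))
        except Exception:
            fit, converged = None, False
    if fit is None:
        res = _ols_result(X, names, y, dropped)
        res.converged = False
        return res

    su2 = float(np.asarray(fit.cov_re).ravel()[0])
    se2 = float(fit.scale)
    if su2 < 1e-8 * se2:  # boundary: GLS degenerates to OLS
        res = _ols_result(X, names, y, dropped)
        res.converged = converged
        return res

    theta = np.array([su2, se2])
    M, Xty, _, _ = _gls_pieces(theta, X, y, blocks)
    Minv = np.linalg.inv(M)
    beta = Minv @ Xty
    se = np.sqrt(np.diag(Minv))
    t = beta / se
    n, p = X.shape
    resid_df = float(n - p - (len(blocks) - 1))
    if resid_df <= 0:
        resid_df = float(n - p)
    used_method = "residual"
    df = np.full(p, resid_df)
    if df_method == "satterthwaite":
        sat = _satterthwaite_df(theta, X, y, blocks)
        if sat is not None:
            good = np.isfinite(sat)
            df = np.where(good, np.clip(sat, 1.0, n - 1.0), resid_df)
            used_method = "satterthwaite"
    elif df_method != "residual":
        raise ValueError("df_method must be 'satterthwaite' or 'residual'")
    pvals = 2 * stats.t.sf(np.abs(t), df)
    terms = pd.DataFrame({"term": names, "beta": beta, "se": se, "t": t,
                          "df": df, "p": pvals})
    return LMEResult(terms=terms, random_intercept_var=su2, residual_var=se2,
                     n_obs=n, converged=converged, df_method=used_method,
                     dropped_terms=dropped)


def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p, rejection flags) at level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def edge_interaction_tests(matrices, scans: pd.DataFrame, members,
                           model: str = "threeway", q: float = 0.05,
                           hierarchy: str = "full") -> pd.DataFrame:
    """Per-edge interaction tests across all within-network region pairs.

    Fits :func:`fit_lme` to each pair's Fisher-z values and FDR-corrects the
    interaction p-values across the tested pairs (one network's pairs form
    one FDR family). Non-convergent edges are flagged and excluded from FDR.
    """
    if len(matrices) != len(scans):
        raise ValueError("one matrix per scan row required")
    term = THREEWAY_TERM if model == "threeway" else TWOWAY_TERM
    members = list(members)
    rows = []
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            r1, r2 = members[a], members[b]
            table = scans.copy()
            table["value"] = [m.values[m.index(r1), m.index(r2)]
                              for m in matrices]
            res = fit_lme(table, model=model, hierarchy=hierarchy)
            row = res.term(term)
            rows.append({"region_a": r1, "region_b": r2,
                         "beta": row["beta"], "t": row["t"], "df": row["df"],
                         "p": row["p"], "converged": res.converged,
                         "n_obs": res.n_obs})
    out = pd.DataFrame(rows)
    ok = out["converged"].to_numpy()
    if (~ok).any():
        warnings.warn(f"{(~ok).sum()} non-convergent edges excluded from FDR",
                      RuntimeWarning, stacklevel=2)
    p_adj = np.full(len(out), np.nan)
    sig = np.zeros(len(out), dtype=bool)
    if ok.any():
        adj, rej = fdr_bh(out.loc[ok, "p"].to_numpy(), q=q)
        p_adj[ok] = adj
        sig[ok] = rej
    out["p_fdr"] = p_adj
    out["significant"] = sig
    return out
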