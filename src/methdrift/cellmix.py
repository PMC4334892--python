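"""Reference-based blood cell-type deconvolution and adjusted DMR analysis.

A sample's methylation over a panel of discriminating CpGs is projected
onto purified cell-type reference profiles by constrained least squares

    w* = argmin ||y - M w||^2   s.t.  w >= 0,  sum(w) <= 1,

the classical reference-based deconvolution estimator.  The residual
1 - sum(w) is reported as the "unexplained" fraction.  Estimated
fractions can then be appended as covariates to the per-cluster age
regressions to adjust for cell-composition changes.

The quadratic program is solved exactly by enumerating active sets:
with six cell types there are at most 2^6 support sets times two states
of the sum constraint, and the global optimum of the convex problem is
the best feasible equality-constrained solution among them.  This keeps
the estimator deterministic and free of iterative-solver tolerances.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from methdrift import dmr as _dmr

CELL_TYPES = ("CD8T", "CD4T", "NK", "B", "Mono", "Gran")


def _solve_support(M: np.ndarray, y: np.ndarray, support: tuple[int, ...], sum_active: bool):
    """Least squares restricted to a support, optionally with sum(w) = 1."""
    Ms = M[:, support]
    k = len(support)
    if not sum_active:
        w_s, *_ = np.linalg.lstsq(Ms, y, rcond=None)
    else:
        # KKT system for min ||y - Ms w||^2 s.t. 1'w = 1
        A = Ms.T @ Ms
        ones = np.ones(k)
        kkt = np.block([[A, ones[:, None]], [ones[None, :], np.zeros((1, 1))]])
        rhs = np.concatenate([Ms.T @ y, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            return None
        w_s = sol[:k]
    w = np.zeros(M.shape[1])
    w[list(support)] = w_s
    return w


def estimate_fractions_single(y: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Exact constrained projection of one sample onto the reference panel."""
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    K = M.shape[1]
    best_w, best_obj = np.zeros(K), float(np.dot(y, y))
    for size in range(1, K + 1):
        for support in combinations(range(K), size):
            for sum_active in (False, True):
                w = _solve_support(M, y, support, sum_active)
                if w is None:
                    continue
                if np.any(w < -1e-10) or w.sum() > 1 + 1e-10:
                    continue
                r = y - M @ w
                obj = float(r @ r)
                if obj < best_obj - 1e-15:
                    best_obj, best_w = obj, w
    return np.clip(best_w, 0.0, None)


def estimate_fractions(
    sample_betas: pd.DataFrame, panel: pd.DataFrame
) -> pd.DataFrame:
    """Estimate cell-type fractions for every sample.

    Parameters
    ----------
    sample_betas
        Beta values over the panel CpGs: index = CpG id, columns =
        sample ids.  Only CpGs present in the panel are used; the panel
        must be fully covered.
    panel
        Reference profiles: index = CpG id, one column per cell type
        (mean beta of the purified population).

    Returns
    -------
    DataFrame
        Samples x cell types, plus an ``unexplained`` column 1 - sum(w).
    """
    missing = panel.index.difference(sample_betas.index)
    if len(missing) > 0:
        raise KeyError(f"panel CpGs missing from sample betas: {list(missing)[:5]}")
    M = panel.to_numpy(dtype=float)
    if M.shape[0] < M.shape[1]:
        raise ValueError("need at least as many panel CpGs as cell types")
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("reference panel is rank-deficient")
    Y = sample_betas.loc[panel.index].to_numpy(dtype=float)
    out = np.empty((Y.shape[1], M.shape[1]))
    for i in range(Y.shape[1]):
        out[i] = estimate_fractions_single(Y[:, i], M)
    frac = pd.DataFrame(out, index=sample_betas.columns, columns=panel.columns)
    frac["unexplained"] = 1.0 - out.sum(axis=1)
    return frac


def adjusted_dmr_analysis(
    cluster_betas: pd.DataFrame,
    age: np.ndarray,
    covariates: pd.DataFrame | None,
    fractions: pd.DataFrame,
    reference_type: str = "Gran",
    clusters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Age-DMR regression with cell fractions appended as covariates.

    One fraction column (``reference_type``, granulocytes by default) is
    dropped so the near-sum-to-one composition does not make the design
    collinear; estimates are used raw, without renormalisation.
    """
    frac_cols = [c for c in fractions.columns if c not in (reference_type, "unexplained")]
    missing = [s for s in cluster_betas.columns if s not in fractions.index]
    if missing:
        raise KeyError(f"fractions missing for samples: {missing[:5]}")
    add = fractions.loc[cluster_betas.columns, frac_cols].reset_index(drop=True)
    if covariates is not None:
        cov = pd.concat([covariates.reset_index(drop=True), add], axis=1)
    else:
        cov = add
    return _dmr.dmr_table(cluster_betas, age, cov, clusters=clusters)


def fraction_age_trends(fractions: pd.DataFrame, age: np.ndarray) -> pd.DataFrame:
    """Per-cell-type OLS of estimated fraction on age (slope per year, p)."""
    age = np.asarray(age, dtype=float)
    if len(age) < 10:
        raise ValueError("need at least 10 samples for fraction-age trends")
    cols = [c for c in fractions.columns if c != "unexplained"]
    Y = fractions[cols].to_numpy(dtype=float).T  # types x samples
    res = _dmr.fit_age_models(Y, age)
    res.index = pd.Index(cols, name="cell_type")
    return res.rename(columns={"coef": "slope_per_year"})[["slope_per_year", "t", "p"]]
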