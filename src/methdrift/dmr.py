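"""Per-cluster linear-model age association and DMR selection.

Each cluster's mean beta is regressed on age with ordinary least
squares, adjusting for supplied covariates (categoricals are
dummy-encoded).  The age coefficient's t-statistic and two-sided
p-value define the differential-methylation evidence; multiple testing
is controlled with Benjamini-Hochberg.  DMRs can be selected as a top
fraction by p-value, by FDR, or by Bonferroni.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"

#: nominal-p threshold above which a cluster is treated as not
#: age-associated (used for the neutral gene class downstream)
NON_DMR_P = 0.8


@dataclass
class DMRStat:
    """Age-association statistics for one cluster."""

    cluster_id: str
    coef: float  # beta units per year
    t: float
    p: float
    direction: str
    q: float = float("nan")

    @property
    def coef_per_10yr(self) -> float:
        return 10.0 * self.coef


def build_design(
    age: np.ndarray, covariates: pd.DataFrame | None = None
) -> tuple[np.ndarray, list[str]]:
    """Build the OLS design matrix [intercept, age, covariates...].

    Categorical covariates are dummy-encoded dropping the first level.
    Perfectly collinear covariate columns are dropped with a logged
    notice (mirroring plate/ethnicity-style confounding among the
    adjustment variables); collinearity that involves the age column
    itself is an error.
    """
    age = np.asarray(age, dtype=float)
    n = len(age)
    cols = [np.ones(n), age]
    names = ["intercept", "age"]
    if covariates is not None and covariates.shape[1] > 0:
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        for name in enc.columns:
            cols.append(enc[name].to_numpy(dtype=float))
            names.append(str(name))
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if np.linalg.matrix_rank(X[:, :2]) < 2:
            raise ValueError("age is collinear with the intercept (constant ages)")
        keep = [0, 1]
        kept_names = ["intercept", "age"]
        dropped = []
        for j in range(2, X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
                kept_names.append(names[j])
            else:
                dropped.append(names[j])
        logger.info("dropping collinear covariate columns: %s", dropped)
        X = X[:, keep]
        names = kept_names
    return X, names


def fit_age_models(
    Y: np.ndarray, age: np.ndarray, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Vectorized OLS of many cluster beta vectors on age plus covariates.

    Parameters
    ----------
    Y
        Array of shape (n_clusters, n_samples).
    age
        Ages in years, length n_samples.
    covariates
        Optional per-sample covariates (columns may be categorical).

    Returns
    -------
    DataFrame
        Columns ``coef`` (per year), ``t``, ``p``, ``direction``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X, _ = build_design(age, covariates)
    n, k = X.shape
    if n <= k + 2:
        raise ValueError(f"too few samples ({n}) for {k} design columns")
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T  # (k, n)
    B = Y @ pinv.T  # (m, k)
    resid = Y - B @ X.T
    dof = n - k
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    coef = B[:, 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    # exact fits: zero residual variance -> +/-inf sentinel unless the
    # coefficient itself is (numerically) zero, in which case t = 0
    scale = np.maximum(np.abs(Y).max(axis=1), 1.0)
    exact = rss <= (1e-24 * scale**2 * n)
    zero_coef = np.abs(coef) <= 1e-12 * scale
    t = np.where(exact & ~zero_coef, np.sign(coef) * np.inf, t)
    t = np.where(zero_coef & (exact | ~np.isfinite(t)), 0.0, t)
    coef = np.where(exact & zero_coef, 0.0, coef)

    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(t == 0.0, 1.0, p)

    return pd.DataFrame(
        {
            "coef": coef,
            "t": t,
            "p": p,
            "direction": np.where(coef > 0, HYPER, HYPO),
        }
    )


def fit_age_model(
    y: np.ndarray,
    age: np.ndarray,
    covariates: pd.DataFrame | None = None,
    cluster_id: str = "",
) -> DMRStat:
    """OLS age model for a single cluster beta vector."""
    res = fit_age_models(np.asarray(y, dtype=float)[None, :], age, covariates)
    row = res.iloc[0]
    return DMRStat(
        cluster_id=cluster_id,
        coef=float(row["coef"]),
        t=float(row["t"]),
        p=float(row["p"]),
        direction=str(row["direction"]),
    )


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties kept)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def dmr_table(
    cluster_betas: pd.DataFrame,
    age: np.ndarray,
    covariates: pd.DataFrame | None = None,
    clusters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit all clusters and attach q-values and (optionally) cluster metadata."""
    res = fit_age_models(cluster_betas.to_numpy(), age, covariates)
    res.insert(0, "cluster_id", cluster_betas.index.to_numpy())
    res["q"] = bh_fdr(res["p"].to_numpy())
    if clusters is not None:
        meta = clusters.set_index("cluster_id")[["chrom", "start", "end", "region_class"]]
        res = res.join(meta, on="cluster_id")
    return res


def select_dmrs(stats_df: pd.DataFrame, rule: str, threshold: float) -> pd.DataFrame:
    """Select DMRs by one of three rules.

    ``top_fraction``: the ceil(f*N) clusters with smallest p (ties broken
    by larger \\|t\\|, then cluster_id); ``fdr``: q < threshold;
    ``bonferroni``: p < threshold / N.
    """
    if len(stats_df) == 0:
        raise ValueError("empty statistics table")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if rule == "top_fraction":
        k = math.ceil(threshold * len(stats_df))
        order = stats_df.assign(_abs_t=stats_df["t"].abs()).sort_values(
            ["p", "_abs_t", "cluster_id"], ascending=[True, False, True]
        )
        return order.head(k).drop(columns="_abs_t")
    if rule == "fdr":
        return stats_df[stats_df["q"] < threshold]
    if rule == "bonferroni":
        return stats_df[stats_df["p"] < threshold / len(stats_df)]
    raise ValueError(f"unknown selection rule: {rule}")


def class_enrichment_probability(
    selection: pd.DataFrame, clusters: pd.DataFrame
) -> dict[str, float]:
    """P(a randomly picked cluster of class c is a selected DMR).

    Computed as (#selected in class) / (#clusters in class); classes
    with zero clusters are omitted with a warning.
    """
    totals = clusters["region_class"].value_counts()
    if "region_class" in selection.columns:
        sel_cls = selection["region_class"]
    else:
        sel_cls = clusters.set_index("cluster_id")["region_class"].loc[
            selection["cluster_id"]
        ]
    counts = sel_cls.value_counts()
    out = {}
    for cls in totals.index:
        if totals[cls] == 0:
            logger.warning("class %s has zero clusters; probability undefined", cls)
            continue
        out[str(cls)] = counts.get(cls, 0) / totals[cls]
    return out


def direction_fractions(
    selection: pd.DataFrame, by_class: bool = False
) -> pd.DataFrame:
    """Fractions of hyper/hypo DMRs, overall or within each region class."""
    def frac(df: pd.DataFrame) -> pd.Series:
        n = len(df)
        n_hyper = int((df["direction"] == HYPER).sum())
        return pd.Series(
            {"hyper": n_hyper / n if n else 0.0, "hypo": (n - n_hyper) / n if n else 0.0}
        )

    if by_class:
        return selection.groupby("region_class", observed=True).apply(
            frac, include_groups=False
        )
    return frac(selection).to_frame().T
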