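"""Transcription-factor binding-site enrichment among age-DMRs.

ChIP-seq peak sets (ENCODE narrowPeak, 0-based half-open) are mapped to
region clusters: a cluster carries a factor's flag iff at least one of
its member-probe CpGs lies within a peak of that factor.  Enrichment of
flags among hyper- or hypo-methylated DMRs is tested with a one-tailed
Fisher exact test against the tested-cluster background, redundant
profiles are removed by Jaccard overlap, and the retained binary
profiles jointly explain the per-cluster age t-statistics in a
multivariate OLS (intercept plus one coefficient per factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from methdrift.dmr import bh_fdr

logger = logging.getLogger(__name__)

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal", "pvalue", "qvalue", "summit",
]


@dataclass
class PeakSet:
    """A factor's ChIP-seq peaks (0-based half-open intervals)."""

    tf_name: str
    lab_tag: str
    intervals: pd.DataFrame  # narrowPeak columns

    @property
    def label(self) -> str:
        return f"{self.tf_name}.{self.lab_tag}" if self.lab_tag else self.tf_name


def read_narrowpeak(path, tf_name: str = "", lab_tag: str = "") -> PeakSet:
    """Parse a 10-column narrowPeak (BED6+4) file.

    Header/track/browser/comment lines are skipped; coordinates are kept
    0-based half-open.  A wrong column count or malformed coordinates
    raise with the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from e
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "name": fields[3],
                    "score": int(fields[4]),
                    "strand": fields[5],
                    "signal": float(fields[6]),
                    "pvalue": float(fields[7]),
                    "qvalue": float(fields[8]),
                    "summit": int(fields[9]),
                }
            )
    df = pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)
    return PeakSet(tf_name=tf_name, lab_tag=lab_tag, intervals=df)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    """Write a PeakSet back to narrowPeak (round-trips with the reader)."""
    peaks.intervals[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class TFProfile:
    """Binary binding profile b_f over clusters.

    ``flags[r]`` is 1 iff at least one member-probe CpG of cluster r
    lies inside a peak: a probe at 1-based position p overlaps the
    half-open peak [s, e) iff s < p <= e.
    """

    tf_name: str
    flags: pd.Series  # index = cluster_id, values in {0, 1}
    probe_overlap_fraction: float = float("nan")

    @property
    def flagged(self) -> set:
        return set(self.flags.index[self.flags == 1])


def map_profiles(
    peaks: PeakSet, probes: pd.DataFrame, clusters: pd.DataFrame
) -> TFProfile:
    """Map a peak set to a binary cluster profile.

    ``probes`` needs probe_id/chrom/pos; ``clusters`` the usual cluster
    table.  Also records the fraction of probe CpGs falling within a
    peak (a per-factor genome-wide overlap rate).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, g in peaks.intervals.groupby("chrom"):
        # probe pos p (1-based) overlaps [s, e) iff s + 1 <= p <= e
        trees[chrom] = IntervalTree.from_tuples(
            (s + 1, e + 1) for s, e in zip(g["start"], g["end"]) if s + 1 < e + 1
        )
    probe_hit = {}
    for pid, chrom, pos in zip(probes["probe_id"], probes["chrom"], probes["pos"]):
        tree = trees.get(chrom)
        probe_hit[pid] = bool(tree and tree.overlaps_point(pos))
    flags = pd.Series(
        [int(any(probe_hit.get(p, False) for p in pids)) for pids in clusters["probe_ids"]],
        index=pd.Index(clusters["cluster_id"], name="cluster_id"),
    )
    frac = float(np.mean(list(probe_hit.values()))) if probe_hit else float("nan")
    return TFProfile(tf_name=peaks.label, flags=flags, probe_overlap_fraction=frac)


@dataclass
class TFEnrichment:
    """One-tailed Fisher enrichment of a factor's flags in a DMR set."""

    tf_name: str
    set_label: str
    odds_ratio: float
    p: float
    table: tuple[int, int, int, int]  # a, b, c, d
    q: float = float("nan")


def fisher_enrichment(
    selection: set,
    profile: TFProfile,
    background: set,
    set_label: str = "",
    tail: str = "greater",
) -> TFEnrichment:
    """Fisher exact test of profile flags in selection vs background.

    2x2 table over the tested-cluster background: a = selected & flagged,
    b = selected & unflagged, c = unselected & flagged, d = rest.  The
    sample odds ratio ad/bc is reported (inf when bc = 0).
    """
    if not background:
        raise ValueError("empty background cluster set")
    if not selection <= background:
        raise ValueError("selection must be a subset of the background")
    flagged = profile.flagged & background
    a = len(selection & flagged)
    b = len(selection) - a
    c = len(flagged) - a
    d = len(background) - a - b - c
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=tail)[1])
    return TFEnrichment(profile.tf_name, set_label, odds, p, (a, b, c, d))


def enrichment_table(
    selection: set,
    profiles: list[TFProfile],
    background: set,
    set_label: str = "",
    tail: str = "greater",
) -> pd.DataFrame:
    """Fisher enrichment for many factors with BH adjustment across them."""
    res = [fisher_enrichment(selection, pr, background, set_label, tail) for pr in profiles]
    qs = bh_fdr(np.array([r.p for r in res]))
    rows = []
    for r, q in zip(res, qs):
        r.q = float(q)
        rows.append(
            {
                "tf_name": r.tf_name,
                "set_label": r.set_label,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "q": r.q,
                "band": significance_band(r.p),
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def significance_band(p: float) -> str:
    """Heatmap significance banding used for reporting."""
    if p < 1e-10:
        return "p<1e-10"
    if p < 1e-5:
        return "p<1e-5"
    if p < 0.01:
        return "p<0.01"
    return "ns"


def jaccard_filter(
    profiles: list[TFProfile], threshold: float = 0.7
) -> tuple[list[TFProfile], pd.DataFrame]:
    """Drop redundant binding profiles by pairwise Jaccard overlap.

    J(f, g) = |flags_f & flags_g| / |flags_f | flags_g|.  If J exceeds
    the threshold the profile with fewer flagged clusters is dropped
    (ties: lexicographically larger name); identical duplicates always
    collapse.  Zero-flag profiles are dropped with a warning (their
    Jaccard is undefined).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    live = []
    for pr in profiles:
        if len(pr.flagged) == 0:
            logger.warning("profile %s has no flagged clusters; dropped", pr.tf_name)
        else:
            live.append(pr)
    names = [p.tf_name for p in live]
    sets = [p.flagged for p in live]
    n = len(live)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            J[i, j] = J[j, i] = inter / union if union else 0.0
    matrix = pd.DataFrame(J, index=names, columns=names)

    dropped = set()
    order = sorted(range(n), key=lambda i: (-len(sets[i]), names[i]))
    for ai in range(n):
        i = order[ai]
        if i in dropped:
            continue
        for aj in range(ai + 1, n):
            j = order[aj]
            if j in dropped:
                continue
            if matrix.iloc[i, j] > threshold or sets[i] == sets[j]:
                dropped.add(j)
    retained = [live[i] for i in range(n) if i not in dropped]
    return retained, matrix


@dataclass
class MultivariateTFResult:
    """OLS of cluster age t-statistics on retained binding profiles."""

    coefficients: pd.DataFrame  # index tf (plus intercept); alpha, t, p
    r_squared: float


def multivariate_tf_regression(
    t_stats: pd.Series, profiles: list[TFProfile]
) -> MultivariateTFResult:
    """Fit t_r = alpha0 + sum_f b_fr alpha_f + eps across clusters.

    The per-factor coefficient t-statistics measure each factor's
    association with age-DMRs independently of co-binding factors.
    Residual collinearity among profiles is an error naming the
    offending ones.
    """
    idx = t_stats.index
    B = np.column_stack([pr.flags.reindex(idx).to_numpy(dtype=float) for pr in profiles])
    names = [pr.tf_name for pr in profiles]
    X = np.column_stack([np.ones(len(idx)), B])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j - 1])
        raise ValueError(f"collinear TF profiles after filtering: {bad}")
    y = t_stats.to_numpy(dtype=float)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else float("nan")
    coef = pd.DataFrame(
        {"alpha": beta, "t": t, "p": p}, index=pd.Index(["intercept"] + names, name="term")
    )
    return MultivariateTFResult(coefficients=coef, r_squared=r2)
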