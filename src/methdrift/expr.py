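"""CpG-island promoter methylation and baseline gene expression.

Island clusters are linked to genes when a member probe falls within
200 bp of the transcription start site (strand-aware) or inside the
first exon.  Genes are classed by the age-DMR status of their most
TSS-proximal linked cluster (age-hypomethylated / non-age-DMR /
age-hypermethylated), and baseline expression is compared across the
three classes with Wilcoxon rank-sum tests between neighbouring classes
plus a linear trend over the ordinal class code.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from methdrift.dmr import HYPER, NON_DMR_P
from methdrift.regions import ISLAND

logger = logging.getLogger(__name__)

AGE_HYPO = "AgeHypoM"
NON_DMR = "NonAgeDMR"
AGE_HYPER = "AgeHyperM"
CLASS_ORDER = (AGE_HYPO, NON_DMR, AGE_HYPER)
#: ordinal codes used in the trend regression
CLASS_CODE = {AGE_HYPO: 0, NON_DMR: 1, AGE_HYPER: 2}

TSS_WINDOW_BP = 200


def link_genes(
    clusters: pd.DataFrame, probes: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Link island clusters to genes via TSS proximity or first exon.

    ``genes`` needs gene_id, chrom, strand, tss, exon_start, exon_end
    (1-based inclusive first-exon interval).  A probe links iff it lies
    within 200 bp upstream-through-TSS on the gene's strand, or inside
    the first exon.  Returns one row per (gene, cluster) link with the
    minimal probe-TSS distance and link type.
    """
    pos_by_probe = probes.set_index("probe_id")[["chrom", "pos"]]
    isl = clusters[clusters["region_class"] == ISLAND]
    rows = []
    for _, gene in genes.iterrows():
        if pd.isna(gene["tss"]):
            logger.warning("gene %s has no TSS; skipped", gene["gene_id"])
            continue
        tss = int(gene["tss"])
        strand = gene["strand"]
        lo, hi = (tss - TSS_WINDOW_BP, tss) if strand == "+" else (tss, tss + TSS_WINDOW_BP)
        for _, cl in isl[isl["chrom"] == gene["chrom"]].iterrows():
            # cheap span prefilter before the per-probe scan
            if cl["end"] < min(lo, gene["exon_start"]) - 1 or cl["start"] > max(
                hi, gene["exon_end"]
            ) + 1:
                continue
            best_d, link_type = None, None
            for pid in cl["probe_ids"]:
                p = int(pos_by_probe.loc[pid, "pos"])
                in_tss = lo <= p <= hi
                in_exon = gene["exon_start"] <= p <= gene["exon_end"]
                if in_tss or in_exon:
                    d = abs(p - tss)
                    if best_d is None or d < best_d:
                        best_d = d
                        link_type = "TSS200" if in_tss else "first_exon"
            if best_d is not None:
                rows.append(
                    {
                        "gene_id": gene["gene_id"],
                        "cluster_id": cl["cluster_id"],
                        "link_type": link_type,
                        "tss_distance": best_d,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "cluster_id", "link_type", "tss_distance"])


def assign_gene_classes(
    links: pd.DataFrame,
    stats_df: pd.DataFrame,
    selection: pd.DataFrame,
    non_dmr_p: float = NON_DMR_P,
) -> pd.DataFrame:
    """Class each linked gene by its most TSS-proximal cluster's DMR status.

    A gene is AgeHyperM/AgeHypoM if that cluster is in the DMR selection
    (direction by coefficient sign), NonAgeDMR if its nominal p exceeds
    ``non_dmr_p``, and unclassed (omitted) otherwise.
    """
    if links.empty:
        return pd.DataFrame(columns=["gene_id", "cluster_id", "gene_class"])
    st = stats_df.set_index("cluster_id")
    selected = set(selection["cluster_id"])
    best = links.sort_values(["gene_id", "tss_distance", "cluster_id"]).groupby("gene_id").head(1)
    rows = []
    for _, ln in best.iterrows():
        cid = ln["cluster_id"]
        if cid not in st.index:
            continue
        if cid in selected:
            cls = AGE_HYPER if st.loc[cid, "direction"] == HYPER else AGE_HYPO
        elif st.loc[cid, "p"] > non_dmr_p:
            cls = NON_DMR
        else:
            continue
        rows.append({"gene_id": ln["gene_id"], "cluster_id": cid, "gene_class": cls})
    return pd.DataFrame(rows, columns=["gene_id", "cluster_id", "gene_class"])


def gene_class_expression_test(
    assignments: pd.DataFrame, expression: pd.DataFrame
) -> dict:
    """Compare per-gene mean expression across the three DMR classes.

    Returns Wilcoxon rank-sum p-values for the neighbouring-class
    comparisons (AgeHypoM vs NonAgeDMR, NonAgeDMR vs AgeHyperM), the
    OLS trend of mean expression on the ordinal class code, and the
    class means.  Comparisons lacking a class are skipped.
    """
    mean_expr = expression.mean(axis=1)
    by_class = {}
    for cls in CLASS_ORDER:
        gids = assignments.loc[assignments["gene_class"] == cls, "gene_id"]
        vals = mean_expr.reindex(gids).dropna().to_numpy()
        if len(vals) >= 2:
            by_class[cls] = vals

    out: dict = {
        "class_n": {c: len(v) for c, v in by_class.items()},
        "class_means": {c: float(v.mean()) for c, v in by_class.items()},
        "wilcoxon": {},
    }
    for a, b in ((AGE_HYPO, NON_DMR), (NON_DMR, AGE_HYPER)):
        if a in by_class and b in by_class:
            try:
                w = stats.mannwhitneyu(by_class[a], by_class[b], alternative="two-sided",
                                       method="exact")
            except ValueError:
                w = stats.mannwhitneyu(by_class[a], by_class[b], alternative="two-sided")
            out["wilcoxon"][f"{a}_vs_{b}"] = float(w.pvalue)
    if len(by_class) >= 2:
        x = np.concatenate([np.full(len(v), CLASS_CODE[c]) for c, v in by_class.items()])
        y = np.concatenate(list(by_class.values()))
        fit = stats.linregress(x, y)
        out["trend"] = {"slope": float(fit.slope), "p": float(fit.pvalue)}
    return out


def dmr_expression_association(
    meth_t: pd.Series, expr_t: pd.Series, links: pd.DataFrame
) -> dict:
    """Rank correlation between methylation and expression age statistics.

    ``meth_t`` is indexed by cluster_id, ``expr_t`` by gene_id; each
    linked gene contributes its most TSS-proximal cluster's statistic.
    """
    best = links.sort_values(["gene_id", "tss_distance", "cluster_id"]).groupby("gene_id").head(1)
    pairs = [
        (meth_t[c], expr_t[g])
        for g, c in zip(best["gene_id"], best["cluster_id"])
        if c in meth_t.index and g in expr_t.index
    ]
    if len(pairs) < 10:
        raise ValueError("need at least 10 linked genes")
    m, e = np.array(pairs).T
    rho, p = stats.spearmanr(m, e)
    return {"rho": float(rho), "p": float(p), "n": len(pairs)}
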