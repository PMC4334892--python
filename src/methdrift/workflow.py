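"""End-to-end pipeline: simulate -> regions -> dmr -> cellmix -> blocks -> tfbs -> expr.

Runs the full drift analysis on a synthetic cohort (or a dataset bundle
loaded from disk), writing one report per stage as plain-text TSV/JSON.
Every report carries the configuration hash and seed in a comment
header, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from methdrift import blocks as _blocks
from methdrift import cellmix as _cellmix
from methdrift import dmr as _dmr
from methdrift import expr as _expr
from methdrift import regions as _regions
from methdrift import simulate as _simulate
from methdrift import tfbs as _tfbs

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.8g"


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published analysis."""

    seed: int = 0
    # synthetic cohort
    n_samples: int = 150
    n_chromosomes: int = 4
    probes_per_chromosome: int = 1200
    n_blocks: int = 6
    # regions
    max_gap: int = 500
    max_width: int = 1500
    # dmr
    top_frac: float = 0.05
    fdr: float = 0.05
    cgi_dmr_fdr: float = 0.001  # flagging hyperM CGIs for block enrichment
    # blocks
    block_max_gap: int = 250_000
    span_bp: int = 250_000
    min_regions: int = 7
    block_cutoff: float = 0.005  # |smoothed coef per 10yr|
    n_boot: int = 500
    block_fwer_threshold: float = 0.05
    extra_block_hypo: float = 0.05  # second-cohort planted shift
    # tfbs
    jaccard_threshold: float = 0.7
    # expr
    tss_window: int = 200
    # stage toggles
    stages: tuple[str, ...] = ("regions", "dmr", "cellmix", "blocks", "tfbs", "expr")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: _simulate.SyntheticDataset
    tables: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT)


def _write_json(obj, path: Path, cfg: PipelineConfig) -> None:
    payload = {"config_hash": cfg.hash(), "seed": cfg.seed, "result": obj}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=float))


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path = "methdrift_out",
    dataset: _simulate.SyntheticDataset | None = None,
) -> PipelineResult:
    """Run the enabled stages in dependency order and write reports."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        sim_cfg = _simulate.SimConfig(
            n_samples=cfg.n_samples,
            n_chromosomes=cfg.n_chromosomes,
            probes_per_chromosome=cfg.probes_per_chromosome,
            n_blocks=cfg.n_blocks,
            seed=cfg.seed,
        )
        dataset = _simulate.generate_dataset(sim_cfg)
    res = PipelineResult(config=cfg, dataset=dataset)
    _write_json(
        {"n_probes": len(dataset.probes), "n_samples": len(dataset.samples)},
        out / "run_manifest.json",
        cfg,
    )
    if not cfg.stages:
        return res

    # ---- regions
    clusters = _regions.make_clusters(dataset.probes, cfg.max_gap, cfg.max_width)
    cluster_betas = _regions.summarize_clusters(dataset.betas, clusters)
    logger.info("regions: %d probes -> %d clusters", len(dataset.probes), len(clusters))
    res.tables["clusters"] = clusters
    if "regions" in cfg.stages:
        _write(clusters.drop(columns=["probe_ids"]), out / "clusters.tsv", cfg)
    if set(cfg.stages) <= {"regions"}:
        return res

    age = dataset.samples["age"].to_numpy()
    covariates = dataset.samples[["sex", "plate"]]

    # ---- dmr (unadjusted)
    stats_df = _dmr.dmr_table(cluster_betas, age, covariates, clusters=clusters)
    selection = _dmr.select_dmrs(stats_df, "top_fraction", cfg.top_frac)
    res.tables["dmr_stats"] = stats_df
    res.tables["dmr_selection"] = selection
    if "dmr" in cfg.stages:
        enr = _dmr.class_enrichment_probability(selection, clusters)
        frac = _dmr.direction_fractions(selection, by_class=True)
        _write(_stats_export(stats_df), out / "dmr_stats.tsv", cfg)
        _write(_stats_export(selection), out / "dmr_top.tsv", cfg)
        _write_json(
            {
                "class_enrichment": enr,
                "direction_fractions": frac.to_dict(),
                "n_fdr_significant": int((stats_df["q"] < cfg.fdr).sum()),
            },
            out / "dmr_summary.json",
            cfg,
        )
        planted = set(dataset.truth.planted_dmr_clusters["cluster_id"])
        if planted:
            recall = len(planted & set(selection["cluster_id"])) / len(planted)
            res.metrics["planted_dmr_recall"] = recall
        logger.info("dmr: %d clusters tested, %d selected", len(stats_df), len(selection))

    # ---- cellmix
    adj_stats = None
    if "cellmix" in cfg.stages:
        fractions = _cellmix.estimate_fractions(dataset.betas, dataset.panel)
        trends = _cellmix.fraction_age_trends(fractions, age)
        adj_stats = _cellmix.adjusted_dmr_analysis(
            cluster_betas, age, covariates, fractions, clusters=clusters
        )
        adj_sel = _dmr.select_dmrs(adj_stats, "top_fraction", cfg.top_frac)
        top_ids = set(selection["cluster_id"])
        retained = adj_stats[adj_stats["cluster_id"].isin(top_ids) & (adj_stats["q"] < cfg.fdr)]
        res.tables["fractions"] = fractions
        res.tables["adjusted_stats"] = adj_stats
        res.metrics["top_dmr_adjusted_retention"] = len(retained) / max(len(top_ids), 1)
        _write(fractions, out / "cell_fractions.csv", cfg, index=True)
        _write(trends, out / "fraction_age_trends.tsv", cfg, index=True)
        _write(_stats_export(adj_stats), out / "dmr_stats_adjusted.tsv", cfg)
        _write_json(
            {
                "direction_fractions_adjusted": _dmr.direction_fractions(
                    adj_sel, by_class=True
                ).to_dict(),
                "top_dmr_adjusted_retention": res.metrics["top_dmr_adjusted_retention"],
            },
            out / "cellmix_summary.json",
            cfg,
        )
        logger.info("cellmix: fractions for %d samples", len(fractions))

    # ---- blocks
    if "blocks" in cfg.stages:
        osc = clusters[clusters["region_class"] == _regions.OPEN_SEA]
        cands, scan, _coefs = _blocks.detect_blocks(
            cluster_betas,
            osc,
            age,
            covariates,
            max_gap=cfg.block_max_gap,
            span_bp=cfg.span_bp,
            min_regions=cfg.min_regions,
            cutoff=cfg.block_cutoff,
        )
        scored = _blocks.block_fwer(
            cands, cluster_betas, scan, age, covariates, n_boot=cfg.n_boot, seed=cfg.seed
        )
        sig = [b for b in scored if b.fwer < cfg.block_fwer_threshold]
        # CGI enrichment inside significant blocks
        cgi = clusters[clusters["region_class"] == _regions.ISLAND].copy()
        hyper_flag = (
            (stats_df["q"] < cfg.cgi_dmr_fdr) & (stats_df["direction"] == _dmr.HYPER)
        )
        flag_map = dict(zip(stats_df["cluster_id"], hyper_flag))
        cgi["hyper_dmr"] = cgi["cluster_id"].map(flag_map).fillna(False)
        p_genome = float(cgi["hyper_dmr"].mean()) if len(cgi) else 0.0
        enrich = []
        if 0 < p_genome < 1:
            enrich = [
                _blocks.cgi_block_enrichment(b, cgi, p_genome) for b in sig
            ]
        # cross-cohort comparison against length-matched random blocks
        betas2, sheet2 = _simulate.generate_second_cohort(dataset, cfg.extra_block_hypo)
        cross = ks = None
        if sig:
            lengths = np.array([b.length for b in sig])
            pool = _blocks.candidate_windows(scan, lengths, exclude=sig)
            rand = _blocks.matched_random_blocks(sig, pool, seed=cfg.seed)
            obs_df = pd.DataFrame(
                [{"chrom": b.chrom, "start": b.start, "end": b.end} for b in sig]
            )
            bn = betas2.loc[:, (sheet2["group"] == "normal").to_numpy()]
            bc = betas2.loc[:, (sheet2["group"] == "cancer").to_numpy()]
            cross = _blocks.cross_cohort_block_test(obs_df, bn, bc, dataset.probes)
            rand_cross = _blocks.cross_cohort_block_test(rand, bn, bc, dataset.probes)
            ks = _blocks.ks_block_shift(
                cross["t"].to_numpy(), rand_cross["t"].to_numpy()
            )
        res.tables["blocks"] = scored
        res.metrics["n_blocks_significant"] = len(sig)
        block_df = pd.DataFrame(
            [
                {
                    "block_id": b.block_id,
                    "chrom": b.chrom,
                    "start": b.start,
                    "end": b.end,
                    "length_mb": b.length / 1e6,
                    "n_regions": len(b.cluster_ids),
                    "direction": b.direction,
                    "area": b.area,
                    "mean_smoothed_coef": b.mean_smoothed_coef,
                    "fwer": b.fwer,
                    "fwer_label": b.fwer_label,
                }
                for b in scored
            ]
        )
        _write(block_df, out / "blocks.tsv", cfg)
        _write_bed(scored, out / "blocks.bed", cfg)
        if enrich:
            enr_df = pd.DataFrame([e.__dict__ for e in enrich])
            valid = enr_df["p_binom"].notna()
            enr_df.loc[valid, "q"] = _dmr.bh_fdr(enr_df.loc[valid, "p_binom"].to_numpy())
            _write(enr_df, out / "block_cgi_enrichment.tsv", cfg)
        if cross is not None:
            _write(cross, out / "block_cross_cohort.tsv", cfg)
            _write_json(
                {"ks_statistic": ks[0], "ks_p": ks[1]}, out / "block_ks.json", cfg
            )
            res.metrics["cross_cohort_ks_p"] = ks[1]
        # recovery vs ground truth
        planted_iv = dataset.truth.planted_block_intervals
        if len(planted_iv) and sig:
            jac = [
                max(
                    _interval_jaccard((b.chrom, b.start, b.end), (r.chrom, r.start, r.end))
                    for r in planted_iv.itertuples()
                )
                for b in sig
            ]
            res.metrics["block_best_jaccard_mean"] = float(np.mean(jac))
        logger.info("blocks: %d candidates, %d significant", len(scored), len(sig))

    # ---- tfbs
    if "tfbs" in cfg.stages:
        profiles = [
            _tfbs.map_profiles(ps, dataset.probes, clusters) for ps in dataset.peaks
        ]
        background = set(stats_df["cluster_id"])
        hyper_sel = set(selection.loc[selection["direction"] == _dmr.HYPER, "cluster_id"])
        hypo_sel = set(selection.loc[selection["direction"] == _dmr.HYPO, "cluster_id"])
        tabs = []
        for label, sel in (("hyperDMR", hyper_sel), ("hypoDMR", hypo_sel)):
            if sel:
                tabs.append(_tfbs.enrichment_table(sel, profiles, background, label))
        enr_all = pd.concat(tabs, ignore_index=True) if tabs else pd.DataFrame()
        retained, jmat = _tfbs.jaccard_filter(profiles, cfg.jaccard_threshold)
        t_series = pd.Series(
            stats_df["t"].to_numpy(), index=stats_df["cluster_id"].to_numpy()
        )
        finite = np.isfinite(t_series.to_numpy())
        mv = _tfbs.multivariate_tf_regression(t_series[finite], retained)
        res.tables["tf_enrichment"] = enr_all
        res.tables["tf_multivariate"] = mv.coefficients
        overlap = pd.DataFrame(
            {
                "tf_name": [p.tf_name for p in profiles],
                "probe_overlap_fraction": [p.probe_overlap_fraction for p in profiles],
            }
        )
        _write(enr_all, out / "tf_enrichment.tsv", cfg)
        _write(jmat, out / "tf_jaccard.tsv", cfg, index=True)
        _write(mv.coefficients, out / "tf_multivariate.tsv", cfg, index=True)
        _write(overlap, out / "tf_overlap_fractions.tsv", cfg)
        logger.info("tfbs: %d profiles, %d retained", len(profiles), len(retained))

    # ---- expr
    if "expr" in cfg.stages:
        links = _expr.link_genes(clusters, dataset.probes, dataset.genes)
        assign = _expr.assign_gene_classes(links, stats_df, selection)
        test = _expr.gene_class_expression_test(assign, dataset.expression)
        res.tables["gene_links"] = links
        res.tables["gene_classes"] = assign
        res.metrics["expr_trend_p"] = test.get("trend", {}).get("p")
        _write(links, out / "gene_links.tsv", cfg)
        _write(assign, out / "gene_classes.tsv", cfg)
        _write_json(test, out / "expression_class_test.json", cfg)
        logger.info("expr: %d links, %d classed genes", len(links), len(assign))

    _write_json(res.metrics, out / "metrics.json", cfg)
    return res


def _stats_export(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Fixed-column-order stats table for export."""
    out = stats_df.copy()
    out["coef_per_10yr"] = 10.0 * out["coef"]
    cols = [
        c
        for c in ["cluster_id", "chrom", "start", "end", "region_class",
                  "coef_per_10yr", "t", "p", "q", "direction"]
        if c in out.columns
    ]
    return out[cols]


def _write_bed(blocks_list, path: Path, cfg: PipelineConfig) -> None:
    """Blocks as BED (0-based half-open), score = scaled area capped at 1000."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash()} seed={cfg.seed}\n")
        for b in blocks_list:
            score = min(int(round(1000 * b.area)), 1000)
            fh.write(
                f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.block_id}\t{score}\t.\n"
            )


def _interval_jaccard(a: tuple, b: tuple) -> float:
    """Jaccard overlap of two (chrom, start, end) 1-based inclusive intervals."""
    if a[0] != b[0]:
        return 0.0
    inter = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if inter <= 0:
        return 0.0
    union = (a[2] - a[1] + 1) + (b[2] - b[1] + 1) - inter
    return inter / union


def load_config_file(path: str | Path) -> dict:
    """Parse a plain-text ``key = value`` configuration file.

    Values are parsed as JSON where possible (numbers, lists, booleans),
    falling back to strings; blank lines and ``#`` comments are ignored.
    """
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, _, val = line.partition("=")
        val = val.strip()
        try:
            out[key.strip()] = json.loads(val)
        except json.JSONDecodeError:
            out[key.strip()] = val
    return out
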