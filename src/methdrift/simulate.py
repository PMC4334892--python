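"""Synthetic 450k-style cohort generator.

Emulates the statistical structure of a large whole-blood methylation
aging cohort so that every downstream stage is testable without
external data:

* probe geography with CpG-island clumps (4-10 probes), 2 kb shores and
  2 kb shelves, and open-sea probes spaced 500 bp - 50 kb apart;
* six blood cell types mixed per sample from a Dirichlet whose
  granulocyte mean increases with age (lymphocytes decline);
* linear-in-age drift planted at a subset of clusters: hypermethylation
  on low-baseline CpG islands, hypomethylation at scattered open-sea
  clusters, plus contiguous 1-3 Mb hypomethylated blocks;
* ChIP-seq-style peak sets where "enriched" factors preferentially
  cover planted hypermethylated island clusters;
* baseline gene expression drawn lower for hyper-targeted genes than
  for hypo-targeted genes.

Drift is anchored at the youngest age of the cohort (beta values grow
or shrink from that baseline), which keeps planted betas inside [0, 1]
without truncation; ordinary-least-squares age slopes are unaffected by
the anchor choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from methdrift import regions as _regions
from methdrift import tfbs as _tfbs
from methdrift.cellmix import CELL_TYPES

MYELOID = ("Gran", "Mono")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_samples: int = 200
    age_range: tuple[float, float] = (19.0, 101.0)
    n_chromosomes: int = 4
    probes_per_chromosome: int = 1500
    n_cell_types: int = 6
    granulocyte_age_slope: float = 0.001  # proportion per year
    drift_island_frac: float = 0.20  # fraction of island clusters planted
    island_hyper_frac: float = 0.85  # hyper share among planted islands
    drift_opensea_frac: float = 0.05  # scattered open-sea hypo clusters
    drift_effect: float = 0.05  # beta per 10 years (planted clusters)
    n_blocks: int = 8
    block_length: tuple[int, int] = (1_000_000, 3_000_000)
    block_effect: float = -0.05  # beta per 10 years, negative
    noise_sd: float = 0.02
    cell_specific_frac: float = 0.20  # of eligible non-island probes
    cell_specific_delta: tuple[float, float] = (0.1, 0.3)
    n_panel_cpgs_per_type: int = 20
    dirichlet_concentration: float = 200.0
    n_tfs: int = 8
    enriched_tf_frac: float = 0.25
    tf_cover_enriched: float = 0.30  # of planted hyper clusters
    tf_cover_background: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        for name in ("drift_island_frac", "island_hyper_frac", "drift_opensea_frac",
                     "cell_specific_frac", "enriched_tf_frac", "tf_cover_enriched",
                     "tf_cover_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.block_effect > 0:
            raise ValueError("block_effect must be <= 0 (blocks are hypomethylated)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.n_cell_types != len(CELL_TYPES):
            raise ValueError(f"generator models the {len(CELL_TYPES)} blood cell types")


@dataclass
class GroundTruth:
    """Planted signal locations, the oracle for recovery tests."""

    planted_dmr_clusters: pd.DataFrame  # cluster_id, direction, kind
    planted_block_intervals: pd.DataFrame  # chrom, start, end
    enriched_tf_ids: list[str]
    true_cell_fractions: pd.DataFrame  # samples x cell types
    gene_class_labels: pd.DataFrame  # gene_id, label


@dataclass
class SyntheticDataset:
    """Full fixture bundle produced by :func:`generate_dataset`."""

    config: SimConfig
    probes: pd.DataFrame  # probe_id, chrom, pos, region_class
    islands: pd.DataFrame  # chrom, start, end (1-based inclusive)
    clusters: pd.DataFrame
    betas: pd.DataFrame  # probes x samples
    samples: pd.DataFrame  # sample_id, age, sex, plate
    panel: pd.DataFrame  # panel CpGs x cell types
    peaks: list  # list[tfbs.PeakSet]
    genes: pd.DataFrame
    expression: pd.DataFrame  # genes x samples
    truth: GroundTruth
    # internals reused by generate_second_cohort
    probe_means: np.ndarray = field(repr=False, default=None)  # probes x cell types
    probe_delta_per_year: np.ndarray = field(repr=False, default=None)


def null_config(**overrides) -> SimConfig:
    """A global-null configuration: no drift, no blocks, no composition signal.

    Cell-type-specific probes are also disabled: the shared mixture
    noise they carry is correlated across clusters, which (while
    leaving each cluster's p-value marginally uniform) breaks the
    independence a genome-wide uniformity check assumes.
    """
    base = dict(
        drift_effect=0.0,
        block_effect=0.0,
        n_blocks=0,
        granulocyte_age_slope=0.0,
        cell_specific_frac=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def _build_geography(cfg: SimConfig, rng: np.random.Generator):
    """Lay probes on chromosomes: island clumps with flanks, open-sea runs."""
    probe_rows, island_rows = [], []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 10_000
        n_left = cfg.probes_per_chromosome
        pid = 0
        while n_left > 0:
            # island clump of 4-10 probes ~100 bp apart
            k_isl = min(int(rng.integers(4, 11)), n_left)
            isl_start = pos
            for _ in range(k_isl):
                probe_rows.append((chrom, pos))
                pos += int(rng.integers(60, 160))
            isl_end = pos - 1
            island_rows.append((chrom, isl_start, isl_end))
            n_left -= k_isl
            if n_left <= 0:
                break
            # one shore and one shelf probe downstream of the island
            for off in (int(rng.integers(200, 2000)), int(rng.integers(2100, 4000))):
                if n_left <= 0:
                    break
                probe_rows.append((chrom, isl_end + off))
                n_left -= 1
            pos = isl_end + 4001 + int(rng.integers(500, 5000))
            # open-sea run, gaps 500 bp - 50 kb
            k_os = min(int(rng.integers(6, 12)), n_left)
            for _ in range(k_os):
                probe_rows.append((chrom, pos))
                pos += int(rng.integers(500, 50_001))
                n_left -= 1
            pos += int(rng.integers(5_000, 20_000))
        # probes were appended out of positional order (flanks); sort below
    probes = pd.DataFrame(probe_rows, columns=["chrom", "pos"]).sort_values(
        ["chrom", "pos"], kind="mergesort"
    )
    probes = probes.reset_index(drop=True)
    probes.insert(0, "probe_id", [f"cg{i:07d}" for i in range(len(probes))])
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return probes, islands


#: planted blocks are kept at least this far apart so that distinct
#: blocks stay distinct under 250 kb smoothing (closer ones would be a
#: single contiguous hypomethylated region, not two)
BLOCK_SEPARATION_BP = 500_000


def _plant_blocks(cfg: SimConfig, clusters: pd.DataFrame, rng: np.random.Generator):
    """Choose non-overlapping, well-separated 1-3 Mb intervals rich in open-sea clusters."""
    osc = clusters[clusters["region_class"] == _regions.OPEN_SEA]
    chrom_span = {c: (g["start"].min(), g["end"].max()) for c, g in osc.groupby("chrom")}
    chroms = sorted(chrom_span)
    intervals: list[tuple[str, int, int]] = []
    attempts = 0
    while len(intervals) < cfg.n_blocks:
        attempts += 1
        if attempts > 200 * cfg.n_blocks:
            raise ValueError(
                "cannot place requested blocks without overlap within chromosome bounds"
            )
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        lo, hi = chrom_span[chrom]
        L = int(rng.integers(cfg.block_length[0], cfg.block_length[1] + 1))
        if hi - lo < L:
            continue
        start = int(rng.integers(lo, hi - L + 1))
        end = start + L - 1
        sep = BLOCK_SEPARATION_BP
        if any(c == chrom and start - sep <= e and end + sep >= s for c, s, e in intervals):
            continue
        inside = osc[(osc["chrom"] == chrom) & (osc["start"] >= start) & (osc["end"] <= end)]
        if len(inside) < 8:
            continue
        intervals.append((chrom, start, end))
    return pd.DataFrame(sorted(intervals), columns=["chrom", "start", "end"])


def generate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic fixture bundle (deterministic per seed)."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    probes, islands = _build_geography(cfg, rng)
    probes = _regions.classify_probes(probes, islands)
    clusters = _regions.make_clusters(probes)
    cl_by_id = clusters.set_index("cluster_id")
    probe_cluster = {}
    for cid, pids in zip(clusters["cluster_id"], clusters["probe_ids"]):
        for p in pids:
            probe_cluster[p] = cid
    probes = probes.assign(cluster_id=probes["probe_id"].map(probe_cluster))

    n_probes = len(probes)
    is_island = (probes["region_class"] == _regions.ISLAND).to_numpy()
    is_open = (probes["region_class"] == _regions.OPEN_SEA).to_numpy()

    # --- baselines per island cluster (low/high bimodal) and other probes
    isl_clusters = clusters[clusters["region_class"] == _regions.ISLAND]
    isl_ids = list(isl_clusters["cluster_id"])
    isl_low = {cid: bool(rng.random() < 0.6) for cid in isl_ids}
    isl_base = {
        cid: float(rng.uniform(0.05, 0.15) if low else rng.uniform(0.6, 0.9))
        for cid, low in isl_low.items()
    }
    baseline = np.empty(n_probes)
    cls_arr = probes["region_class"].to_numpy()
    cid_arr = probes["cluster_id"].to_numpy()
    for j in range(n_probes):
        if cls_arr[j] == _regions.ISLAND:
            baseline[j] = isl_base[cid_arr[j]] + rng.normal(0, 0.01)
        elif cls_arr[j] == _regions.SHORE_SHELF:
            baseline[j] = rng.uniform(0.3, 0.7)
        else:
            baseline[j] = rng.uniform(0.6, 0.9)
    baseline = np.clip(baseline, 0.02, 0.98)

    # --- planted drift clusters
    low_ids = [c for c in isl_ids if isl_low[c]]
    high_ids = [c for c in isl_ids if not isl_low[c]]
    n_drift_isl = int(round(cfg.drift_island_frac * len(isl_ids)))
    n_hyper = int(round(cfg.island_hyper_frac * n_drift_isl))
    n_hypo_isl = n_drift_isl - n_hyper
    hyper_isl = list(rng.choice(low_ids, size=min(n_hyper, len(low_ids)), replace=False))
    hypo_isl = list(rng.choice(high_ids, size=min(n_hypo_isl, len(high_ids)), replace=False))

    block_intervals = (
        _plant_blocks(cfg, clusters, rng)
        if cfg.n_blocks > 0 and cfg.block_effect != 0
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def in_block(chrom, start, end):
        return any(
            r.chrom == chrom and start >= r.start and end <= r.end
            for r in block_intervals.itertuples()
        )

    def near_block(chrom, start, end, margin=BLOCK_SEPARATION_BP):
        return any(
            r.chrom == chrom and start <= r.end + margin and end >= r.start - margin
            for r in block_intervals.itertuples()
        )

    osc = clusters[clusters["region_class"] == _regions.OPEN_SEA]
    # scattered drift stays clear of planted blocks so a block's edges
    # are not blurred by adjacent single-cluster drift
    os_outside = [
        r.cluster_id for r in osc.itertuples() if not near_block(r.chrom, r.start, r.end)
    ]
    n_drift_os = int(round(cfg.drift_opensea_frac * len(osc)))
    hypo_os = list(rng.choice(os_outside, size=min(n_drift_os, len(os_outside)), replace=False))

    if cfg.drift_effect == 0:
        hyper_isl, hypo_isl, hypo_os = [], [], []

    delta_cluster: dict[str, float] = {}
    for cid in hyper_isl:
        delta_cluster[cid] = cfg.drift_effect / 10.0
    for cid in hypo_isl + hypo_os:
        delta_cluster[cid] = -cfg.drift_effect / 10.0
    block_cluster_ids = [
        r.cluster_id for r in osc.itertuples() if in_block(r.chrom, r.start, r.end)
    ]
    for cid in block_cluster_ids:
        delta_cluster[cid] = cfg.block_effect / 10.0

    delta = np.array([delta_cluster.get(c, 0.0) for c in cid_arr])

    # --- cell-type-specific probes (myeloid vs lymphoid contrast),
    #     never inside planted clusters so planted effects stay clean
    eligible = ~is_island & (delta == 0.0)

    # --- deconvolution panel: open-sea probes outside planted clusters,
    #     given one-vs-rest discriminating reference profiles
    panel_pool = np.flatnonzero(eligible & is_open)
    n_panel = cfg.n_panel_cpgs_per_type * len(CELL_TYPES)
    if len(panel_pool) < n_panel:
        raise ValueError("not enough eligible open-sea probes for the reference panel")
    panel_idx = rng.choice(panel_pool, size=n_panel, replace=False)

    remaining = np.flatnonzero(eligible)
    remaining = remaining[~np.isin(remaining, panel_idx)]
    n_cs = min(int(round(cfg.cell_specific_frac * int(eligible.sum()))), len(remaining))
    cs_idx = rng.choice(remaining, size=n_cs, replace=False)
    M = np.tile(baseline[:, None], (1, len(CELL_TYPES)))  # probes x cell types
    myeloid_cols = [CELL_TYPES.index(c) for c in MYELOID]
    lymph_cols = [k for k in range(len(CELL_TYPES)) if k not in myeloid_cols]
    d_cs = rng.uniform(*cfg.cell_specific_delta, size=n_cs) * rng.choice([-1, 1], size=n_cs)
    for i, j in enumerate(cs_idx):
        M[j, myeloid_cols] = np.clip(baseline[j] + d_cs[i], 0.02, 0.98)
        M[j, lymph_cols] = np.clip(baseline[j] - d_cs[i], 0.02, 0.98)
    for k in range(len(CELL_TYPES)):
        rows = panel_idx[k * cfg.n_panel_cpgs_per_type : (k + 1) * cfg.n_panel_cpgs_per_type]
        M[rows, :] = 0.15
        M[rows, k] = 0.85
    panel = pd.DataFrame(
        M[panel_idx],
        index=pd.Index(probes["probe_id"].to_numpy()[panel_idx], name="cpg_id"),
        columns=list(CELL_TYPES),
    )

    # --- samples: ages uniform, sex/plate categorical, small plate offsets
    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=cfg.n_samples)
    sex = rng.choice(["F", "M"], size=cfg.n_samples)
    plate = rng.choice(["p1", "p2", "p3"], size=cfg.n_samples)
    plate_offset = dict(zip(["p1", "p2", "p3"], rng.normal(0, 0.003, size=3)))
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(cfg.n_samples)],
            "age": ages,
            "sex": sex,
            "plate": plate,
        }
    )

    W = _draw_fractions(cfg, ages, rng)
    true_fractions = pd.DataFrame(W, index=samples["sample_id"], columns=list(CELL_TYPES))

    betas = _compose_betas(cfg, M, delta, W, ages, plate, plate_offset, rng)
    betas_df = pd.DataFrame(betas, index=probes["probe_id"], columns=samples["sample_id"])

    # --- TF peak sets
    n_enriched = int(round(cfg.enriched_tf_frac * cfg.n_tfs))
    peaks, enriched_ids = _make_peaks(cfg, n_enriched, clusters, cl_by_id, hyper_isl, rng)

    # --- genes and expression
    genes, gene_labels = _make_genes(isl_clusters, hyper_isl, hypo_isl, rng)
    expression = _make_expression(cfg, genes, gene_labels, rng)

    planted = pd.DataFrame(
        [(c, "hyper", "island") for c in sorted(hyper_isl)]
        + [(c, "hypo", "island") for c in sorted(hypo_isl)]
        + [(c, "hypo", "open_sea") for c in sorted(hypo_os)],
        columns=["cluster_id", "direction", "kind"],
    )
    truth = GroundTruth(
        planted_dmr_clusters=planted,
        planted_block_intervals=block_intervals,
        enriched_tf_ids=enriched_ids,
        true_cell_fractions=true_fractions,
        gene_class_labels=gene_labels,
    )
    return SyntheticDataset(
        config=cfg,
        probes=probes,
        islands=islands,
        clusters=clusters,
        betas=betas_df,
        samples=samples,
        panel=panel,
        peaks=peaks,
        genes=genes,
        expression=expression,
        truth=truth,
        probe_means=M,
        probe_delta_per_year=delta,
    )


def _draw_fractions(cfg: SimConfig, ages: np.ndarray, rng: np.random.Generator):
    """Dirichlet mixtures around an age-dependent mean composition."""
    base = np.array([0.08, 0.15, 0.05, 0.07, 0.05, 0.60])  # CD8T CD4T NK B Mono Gran
    gran, mono = CELL_TYPES.index("Gran"), CELL_TYPES.index("Mono")
    lymph = [k for k in range(len(CELL_TYPES)) if k not in (gran, mono)]
    mid = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    W = np.empty((len(ages), len(CELL_TYPES)))
    for i, a in enumerate(ages):
        mean = base.copy()
        shift = cfg.granulocyte_age_slope * (a - mid)
        mean[gran] += 0.9 * shift
        mean[mono] += 0.1 * shift
        mean[lymph] -= shift * base[lymph] / base[lymph].sum()
        mean = np.clip(mean, 0.005, None)
        mean /= mean.sum()
        W[i] = rng.dirichlet(cfg.dirichlet_concentration * mean)
    return W


def _compose_betas(cfg, M, delta, W, ages, plate, plate_offset, rng):
    """beta = mixture of cell-type means + anchored age drift + noise."""
    base = W @ M.T  # samples x probes
    drift = np.outer(ages - cfg.age_range[0], delta)
    noise = (
        rng.normal(0.0, cfg.noise_sd, size=base.shape) if cfg.noise_sd > 0 else 0.0
    )
    poff = np.array([plate_offset[p] for p in plate])[:, None]
    return np.clip(base + drift + noise + poff, 0.0, 1.0).T  # probes x samples


def _make_peaks(cfg, n_enriched, clusters, cl_by_id, hyper_isl, rng):
    peaks, enriched_ids = [], []
    all_ids = list(clusters["cluster_id"])
    hyper_set = set(hyper_isl)
    bg_ids = [c for c in all_ids if c not in hyper_set]
    for f in range(cfg.n_tfs):
        enriched = f < n_enriched
        name = f"TF{f + 1}"
        covered: list[str] = []
        if enriched and hyper_isl:
            k = int(round(cfg.tf_cover_enriched * len(hyper_isl)))
            covered += list(rng.choice(sorted(hyper_set), size=k, replace=False))
            enriched_ids.append(f"{name}.lab1")
        k_bg = int(round(cfg.tf_cover_background * len(bg_ids)))
        covered += list(rng.choice(bg_ids, size=k_bg, replace=False))
        rows = []
        for cid in covered:
            cl = cl_by_id.loc[cid]
            # centre the peak on a member probe so the CpG falls inside it
            pos = int(cl["start"]) if rng.random() < 0.5 else int(cl["end"])
            rows.append(
                {
                    "chrom": cl["chrom"],
                    "start": pos - 51,
                    "end": pos + 50,
                    "name": ".",
                    "score": 0,
                    "strand": ".",
                    "signal": 0.0,
                    "pvalue": -1.0,
                    "qvalue": -1.0,
                    "summit": -1,
                }
            )
        df = pd.DataFrame(rows, columns=_tfbs.NARROWPEAK_COLUMNS).sort_values(
            ["chrom", "start"]
        ).reset_index(drop=True)
        peaks.append(_tfbs.PeakSet(tf_name=name, lab_tag="lab1", intervals=df))
    return peaks, enriched_ids


def _make_genes(isl_clusters, hyper_isl, hypo_isl, rng):
    hyper_set, hypo_set = set(hyper_isl), set(hypo_isl)
    rows, labels = [], []
    for gi, cl in enumerate(isl_clusters.itertuples()):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = cl.start + 100
            exon = (tss + 1, tss + 300)
        else:
            tss = cl.end - 100
            exon = (tss - 300, tss - 1)
        gid = f"G{gi:05d}"
        rows.append(
            {
                "gene_id": gid,
                "chrom": cl.chrom,
                "strand": strand,
                "tss": tss,
                "exon_start": exon[0],
                "exon_end": exon[1],
            }
        )
        if cl.cluster_id in hyper_set:
            lab = "hyper-target"
        elif cl.cluster_id in hypo_set:
            lab = "hypo-target"
        else:
            lab = "neutral"
        labels.append({"gene_id": gid, "label": lab})
    return pd.DataFrame(rows), pd.DataFrame(labels)


#: baseline log2-expression means per gene class: hyper-targeted genes sit
#: lowest, hypo-targeted highest, neutral in between (wide spread)
EXPR_BASELINE = {"hyper-target": (4.0, 1.0), "hypo-target": (9.0, 1.0), "neutral": (7.0, 2.0)}


def _make_expression(cfg, genes, gene_labels, rng):
    lab = gene_labels.set_index("gene_id")["label"]
    base = np.array([rng.normal(*EXPR_BASELINE[lab[g]]) for g in genes["gene_id"]])
    E = base[:, None] + rng.normal(0, 0.5, size=(len(genes), cfg.n_samples))
    return pd.DataFrame(
        E, index=pd.Index(genes["gene_id"], name="gene_id"),
        columns=[f"E{i:04d}" for i in range(cfg.n_samples)],
    )


def generate_second_cohort(
    dataset: SyntheticDataset,
    extra_block_hypo: float,
    n_per_group: int = 50,
    seed: int | None = None,
):
    """Generate an age-matched normal/"cancer" two-group cohort.

    Cancer samples receive ``extra_block_hypo`` additional
    hypomethylation at probes inside planted block intervals only.  The
    design is idealized age matching: every sample sits at the cohort
    mid-age, so within-group variance reflects measurement noise and
    cell-mixture variation rather than age drift, and any normal/cancer
    difference at block probes is the planted shift.

    Returns (betas, sample sheet with a ``group`` column).
    """
    cfg = dataset.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    ages = np.full(2 * n_per_group, 0.5 * (cfg.age_range[0] + cfg.age_range[1]))
    group = np.array(["normal"] * n_per_group + ["cancer"] * n_per_group)
    W = _draw_fractions(cfg, ages, rng)

    in_block = np.zeros(len(dataset.probes), dtype=bool)
    for r in dataset.truth.planted_block_intervals.itertuples():
        in_block |= (
            (dataset.probes["chrom"] == r.chrom)
            & (dataset.probes["pos"] >= r.start)
            & (dataset.probes["pos"] <= r.end)
            & (dataset.probes["region_class"] == _regions.OPEN_SEA)
        ).to_numpy()

    base = W @ dataset.probe_means.T
    drift = np.outer(ages - cfg.age_range[0], dataset.probe_delta_per_year)
    extra = np.outer(group == "cancer", in_block) * extra_block_hypo
    noise = rng.normal(0, cfg.noise_sd, size=base.shape) if cfg.noise_sd > 0 else 0.0
    betas = np.clip(base + drift - extra + noise, 0.0, 1.0).T
    sample_ids = [f"N{i:04d}" for i in range(n_per_group)] + [
        f"C{i:04d}" for i in range(n_per_group)
    ]
    betas_df = pd.DataFrame(betas, index=dataset.probes["probe_id"], columns=sample_ids)
    sheet = pd.DataFrame({"sample_id": sample_ids, "age": ages, "group": group})
    return betas_df, sheet


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the fixture bundle as plain-text files (TSV/CSV/narrowPeak/JSON)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.probes.drop(columns=["cluster_id"]).to_csv(
        out / "probe_annotation.tsv", sep="\t", index=False
    )
    isl = dataset.islands.copy()
    isl["start"] -= 1  # BED 0-based half-open
    isl.to_csv(out / "islands.bed", sep="\t", index=False, header=False)
    dataset.betas.to_csv(out / "betas.tsv", sep="\t", float_format="%.6g")
    dataset.samples.to_csv(out / "samples.csv", index=False)
    dataset.panel.to_csv(out / "cell_reference_panel.tsv", sep="\t", float_format="%.6g")
    for ps in dataset.peaks:
        _tfbs.write_narrowpeak(ps, out / f"{ps.label}.narrowPeak")
    dataset.genes.to_csv(out / "gene_annotation.tsv", sep="\t", index=False)
    dataset.expression.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")
    truth = {
        "planted_dmr_clusters": dataset.truth.planted_dmr_clusters.to_dict("records"),
        "planted_block_intervals": dataset.truth.planted_block_intervals.to_dict("records"),
        "enriched_tf_ids": dataset.truth.enriched_tf_ids,
        "gene_class_labels": dataset.truth.gene_class_labels.to_dict("records"),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    (out / "sim_config.json").write_text(json.dumps(asdict(dataset.config), indent=1))
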