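"""Mega-base hypomethylated block detection with bootstrap FWER.

Open-sea clusters are grouped along each chromosome with a large gap
rule (default 250 kb), their per-10-year age coefficients are smoothed
with a tricube-weighted running mean over a 250 kb window, and maximal
runs of smoothed coefficients beyond a cutoff become candidate blocks,
scored by their area (sum of |smoothed coefficient|).  Significance is
assessed by a residual bootstrap under the no-age null: each bootstrap
rebuilds the genome-wide maximum candidate area, and a block's
family-wise error rate is the fraction of bootstraps whose maximum
reaches its area.

The module also tests enrichment of age-hypermethylated CpG-island
clusters within block spans (binomial tail against the genome-wide
rate), draws random length-matched non-significant blocks, and compares
block-level methylation between two cohorts (t / Wilcoxon per block,
Kolmogorov-Smirnov across blocks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from methdrift import dmr as _dmr
from methdrift.regions import OPEN_SEA

logger = logging.getLogger(__name__)


def group_opensea(clusters: pd.DataFrame, max_gap: int = 250_000) -> pd.DataFrame:
    """Group open-sea clusters into chromosome-wise runs with gaps <= max_gap.

    The gap between consecutive clusters is measured start-to-end
    (next cluster's start minus previous cluster's end); a gap of
    exactly ``max_gap`` still merges.

    Returns a copy of ``clusters`` with an added ``group_id`` column.
    """
    if not (clusters["region_class"] == OPEN_SEA).all():
        raise ValueError("group_opensea expects only open-sea clusters")
    clusters = clusters.sort_values(["chrom", "start"]).copy()
    gids = []
    gid = -1
    prev_chrom, prev_end = None, None
    for chrom, start, end in zip(clusters["chrom"], clusters["start"], clusters["end"]):
        if chrom != prev_chrom or (start - prev_end) > max_gap:
            gid += 1
        gids.append(gid)
        prev_chrom, prev_end = chrom, end
    clusters["group_id"] = gids
    return clusters


def smoothing_matrix(positions: np.ndarray, span_bp: int = 250_000) -> np.ndarray:
    """Row-normalised tricube weight matrix for a running weighted mean.

    The window spans ``span_bp`` in total (half-width span_bp / 2);
    weights are tricube in the scaled distance.
    """
    pos = np.asarray(positions, dtype=float)
    h = span_bp / 2.0
    d = np.abs(pos[:, None] - pos[None, :]) / h
    w = np.where(d < 1.0, (1.0 - d**3) ** 3, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def smooth_coefficients(
    coefs: np.ndarray,
    positions: np.ndarray,
    span_bp: int = 250_000,
    min_regions: int = 7,
) -> np.ndarray:
    """Locally weighted running mean of coefficients within one group.

    Groups with fewer than ``min_regions`` members pass through
    unsmoothed (too few points for a meaningful local fit).
    """
    coefs = np.asarray(coefs, dtype=float)
    if len(coefs) < min_regions:
        return coefs.copy()
    return smoothing_matrix(positions, span_bp) @ coefs


@dataclass
class Block:
    """A maximal run of open-sea clusters beyond the coefficient cutoff."""

    block_id: str
    chrom: str
    start: int
    end: int
    cluster_ids: list[str]
    direction: str  # hyper / hypo
    area: float  # sum of |smoothed coef per 10yr| over the run
    mean_smoothed_coef: float
    fwer: float = float("nan")
    n_boot: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def fwer_label(self) -> str:
        if self.n_boot and self.fwer == 0.0:
            return f"< {1.0 / self.n_boot:g}"
        return f"{self.fwer:g}" if np.isfinite(self.fwer) else "NA"


def find_blocks(
    smoothed: np.ndarray,
    positions_start: np.ndarray,
    positions_end: np.ndarray,
    cluster_ids: list[str],
    chrom: str,
    cutoff: float,
) -> list[Block]:
    """Maximal same-sign runs of smoothed coefficients beyond +-cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    smoothed = np.asarray(smoothed, dtype=float)
    sign = np.where(smoothed > cutoff, 1, np.where(smoothed < -cutoff, -1, 0))
    blocks: list[Block] = []
    i = 0
    n = len(smoothed)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sign[j + 1] == sign[i]:
            j += 1
        seg = smoothed[i : j + 1]
        blocks.append(
            Block(
                block_id=f"{chrom}:{int(positions_start[i])}-{int(positions_end[j])}",
                chrom=chrom,
                start=int(positions_start[i]),
                end=int(positions_end[j]),
                cluster_ids=list(cluster_ids[i : j + 1]),
                direction=_dmr.HYPER if sign[i] > 0 else _dmr.HYPO,
                area=float(np.abs(seg).sum()),
                mean_smoothed_coef=float(seg.mean()),
            )
        )
        i = j + 1
    return blocks


@dataclass
class BlockScan:
    """Grouped open-sea clusters with precomputed smoothing operators."""

    grouped: pd.DataFrame
    span_bp: int
    min_regions: int
    cutoff: float
    _ops: list[dict] = field(default_factory=list)

    @classmethod
    def prepare(
        cls,
        opensea_clusters: pd.DataFrame,
        max_gap: int = 250_000,
        span_bp: int = 250_000,
        min_regions: int = 7,
        cutoff: float = 0.005,
    ) -> "BlockScan":
        grouped = group_opensea(opensea_clusters, max_gap)
        scan = cls(grouped=grouped, span_bp=span_bp, min_regions=min_regions, cutoff=cutoff)
        for gid, g in grouped.groupby("group_id"):
            mid = ((g["start"] + g["end"]) / 2.0).to_numpy()
            op = {
                "chrom": g["chrom"].iloc[0],
                "cluster_ids": list(g["cluster_id"]),
                "start": g["start"].to_numpy(),
                "end": g["end"].to_numpy(),
                "idx": grouped.index.get_indexer(g.index),
                "S": smoothing_matrix(mid, span_bp) if len(g) >= min_regions else None,
            }
            scan._ops.append(op)
        return scan

    def smooth(self, coefs_per_10yr: np.ndarray) -> np.ndarray:
        out = np.empty_like(coefs_per_10yr, dtype=float)
        for op in self._ops:
            seg = coefs_per_10yr[op["idx"]]
            out[op["idx"]] = seg if op["S"] is None else op["S"] @ seg
        return out

    def scan_blocks(self, coefs_per_10yr: np.ndarray) -> list[Block]:
        blocks: list[Block] = []
        for op in self._ops:
            seg = coefs_per_10yr[op["idx"]]
            sm = seg if op["S"] is None else op["S"] @ seg
            blocks.extend(
                find_blocks(sm, op["start"], op["end"], op["cluster_ids"], op["chrom"], self.cutoff)
            )
        return blocks


def detect_blocks(
    opensea_betas: pd.DataFrame,
    opensea_clusters: pd.DataFrame,
    age: np.ndarray,
    covariates: pd.DataFrame | None = None,
    max_gap: int = 250_000,
    span_bp: int = 250_000,
    min_regions: int = 7,
    cutoff: float = 0.005,
) -> tuple[list[Block], BlockScan, np.ndarray]:
    """Fit cluster age coefficients and scan for candidate blocks.

    Returns the candidate blocks, the prepared scan (reusable by the
    bootstrap), and the per-cluster coefficients per 10 years, all in
    the scan's (chrom, start)-sorted cluster order.
    """
    scan = BlockScan.prepare(opensea_clusters, max_gap, span_bp, min_regions, cutoff)
    Y = opensea_betas.loc[scan.grouped["cluster_id"]].to_numpy()
    res = _dmr.fit_age_models(Y, age, covariates)
    coefs10 = 10.0 * res["coef"].to_numpy()
    return scan.scan_blocks(coefs10), scan, coefs10


def block_fwer(
    candidates: list[Block],
    opensea_betas: pd.DataFrame,
    scan: BlockScan,
    age: np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> list[Block]:
    """Residual-bootstrap FWER for candidate blocks.

    The null model excludes age: bootstrap data are (null fitted values
    + residual vectors resampled across samples with replacement), the
    age coefficients are refit, smoothed, and scanned, and the
    genome-wide maximum candidate area is recorded per bootstrap.  A
    block's FWER is the fraction of bootstrap maxima reaching its area;
    a count of zero is reported as the bound "< 1/n_boot".
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    Y = opensea_betas.loc[scan.grouped["cluster_id"]].to_numpy(dtype=float)
    n = Y.shape[1]

    X_full, _ = _dmr.build_design(age, covariates)
    # null design: drop the age column
    X0 = np.delete(X_full, 1, axis=1)
    H0 = X0 @ np.linalg.inv(X0.T @ X0) @ X0.T
    fitted0 = Y @ H0.T
    resid0 = Y - fitted0
    # age-coefficient extractor for the full design: coef = Y @ a
    a = (np.linalg.inv(X_full.T @ X_full) @ X_full.T)[1]

    boot_max = np.zeros(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Yb = fitted0 + resid0[:, idx]
        coefs10 = 10.0 * (Yb @ a)
        blocks_b = scan.scan_blocks(coefs10)
        boot_max[b] = max((blk.area for blk in blocks_b), default=0.0)

    out = []
    for blk in candidates:
        count = int((boot_max >= blk.area).sum())
        out.append(
            Block(
                **{
                    **blk.__dict__,
                    "fwer": count / n_boot,
                    "n_boot": n_boot,
                }
            )
        )
    return out


@dataclass
class BlockEnrichment:
    """Binomial enrichment of age-hyperM CGI clusters within a block span."""

    block_id: str
    n_cgi: int
    obs: int
    exp: float
    p_binom: float
    note: str = ""


def cgi_block_enrichment(
    block: Block, cgi_clusters: pd.DataFrame, p_genome: float, min_cgi: int = 5
) -> BlockEnrichment:
    """Test whether flagged CGI clusters are enriched inside a block.

    ``cgi_clusters`` needs columns chrom, start, end and a boolean
    ``hyper_dmr`` flag; a CGI cluster is inside the block iff its
    midpoint lies within the block span.  p = P(Bin(n_cgi, p_genome) >= obs).
    """
    if not (0 < p_genome < 1):
        raise ValueError("p_genome must lie in (0, 1)")
    sub = cgi_clusters[cgi_clusters["chrom"] == block.chrom]
    mid = (sub["start"] + sub["end"]) / 2.0
    inside = sub[(mid >= block.start) & (mid <= block.end)]
    n_cgi = len(inside)
    if n_cgi == 0:
        return BlockEnrichment(block.block_id, 0, 0, 0.0, float("nan"), note="no CGIs")
    obs = int(inside["hyper_dmr"].sum())
    p = float(stats.binom.sf(obs - 1, n_cgi, p_genome))
    note = "few CGIs" if n_cgi < min_cgi else ""
    return BlockEnrichment(block.block_id, n_cgi, obs, n_cgi * p_genome, p, note)


def candidate_windows(
    scan: BlockScan,
    target_lengths: np.ndarray,
    exclude: list[Block] | None = None,
) -> pd.DataFrame:
    """Enumerate open-sea cluster windows approximating target lengths.

    For every group and start cluster, one window per distinct target
    length is built by extending to the last cluster within that span.
    Windows overlapping any ``exclude`` block are discarded.  Serves as
    the candidate pool for length-matched random block sampling.
    """
    excl = [(b.chrom, b.start, b.end) for b in (exclude or [])]
    rows = []
    for op in scan._ops:
        starts, ends = op["start"], op["end"]
        for L in np.unique(np.asarray(target_lengths, dtype=int)):
            stop = np.searchsorted(starts, starts + L, side="right") - 1
            for i, j in enumerate(stop):
                if j < i:
                    continue
                s, e = int(starts[i]), int(ends[j])
                if any(c == op["chrom"] and s <= ce and e >= cs for c, cs, ce in excl):
                    continue
                rows.append(
                    {
                        "chrom": op["chrom"],
                        "start": s,
                        "end": e,
                        "n_clusters": int(j - i + 1),
                        "length": e - s + 1,
                    }
                )
    return pd.DataFrame(rows).drop_duplicates(["chrom", "start", "end"]).reset_index(drop=True)


def matched_random_blocks(
    observed: list[Block], candidates: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Sample random blocks matched to observed block lengths by decile.

    Candidates are sampled without replacement, stratified by the
    observed length-distribution deciles, the same total count as
    ``observed``; a stratum short of candidates borrows from the
    nearest stratum with a warning.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    obs_len = np.array([b.length for b in observed], dtype=float)
    edges = np.quantile(obs_len, np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf
    obs_bin = np.clip(np.searchsorted(edges, obs_len, side="right") - 1, 0, 9)
    cand_bin = np.clip(
        np.searchsorted(edges, candidates["length"].to_numpy(dtype=float), side="right") - 1,
        0,
        9,
    )
    taken: list[int] = []
    available = {b: list(np.flatnonzero(cand_bin == b)) for b in range(10)}
    for b in range(10):
        rng.shuffle(available[b])
    for b in range(10):
        need = int((obs_bin == b).sum())
        pool = available[b]
        while need > 0 and pool:
            taken.append(pool.pop())
            need -= 1
        if need > 0:
            logger.warning("stratum %d short of candidates; borrowing from neighbours", b)
            for off in range(1, 10):
                for nb in (b - off, b + off):
                    if 0 <= nb <= 9:
                        pool = available[nb]
                        while need > 0 and pool:
                            taken.append(pool.pop())
                            need -= 1
                if need == 0:
                    break
        if need > 0:
            raise ValueError("not enough candidate blocks to match observed lengths")
    return candidates.iloc[sorted(taken)].reset_index(drop=True)


def block_mean_betas(
    block_chrom: str,
    block_start: int,
    block_end: int,
    betas: pd.DataFrame,
    probes: pd.DataFrame,
) -> np.ndarray | None:
    """Per-sample mean beta over open-sea probes inside a block span."""
    sel = probes[
        (probes["chrom"] == block_chrom)
        & (probes["pos"] >= block_start)
        & (probes["pos"] <= block_end)
        & (probes["region_class"] == OPEN_SEA)
    ]
    pids = [p for p in sel["probe_id"] if p in betas.index]
    if not pids:
        return None
    return betas.loc[pids].mean(axis=0).to_numpy()


def cross_cohort_block_test(
    blocks_df: pd.DataFrame,
    betas_a: pd.DataFrame,
    betas_b: pd.DataFrame,
    probes: pd.DataFrame,
) -> pd.DataFrame:
    """Two-cohort comparison of block-level methylation.

    For each block (rows of ``blocks_df`` with chrom/start/end), the
    per-sample mean beta over open-sea probes within the span is
    computed in each cohort; a two-sample t statistic (cohort B minus
    cohort A) and a two-sided Wilcoxon rank-sum p are reported.  Blocks
    with no covered probes are skipped with a warning.
    """
    rows = []
    for _, blk in blocks_df.iterrows():
        va = block_mean_betas(blk["chrom"], blk["start"], blk["end"], betas_a, probes)
        vb = block_mean_betas(blk["chrom"], blk["start"], blk["end"], betas_b, probes)
        if va is None or vb is None:
            logger.warning("block %s:%s-%s has no open-sea probes; skipped",
                           blk["chrom"], blk["start"], blk["end"])
            continue
        t, p_t = stats.ttest_ind(vb, va)
        try:
            w = stats.mannwhitneyu(vb, va, alternative="two-sided", method="exact")
        except ValueError:
            w = stats.mannwhitneyu(vb, va, alternative="two-sided")
        rows.append(
            {
                "chrom": blk["chrom"],
                "start": blk["start"],
                "end": blk["end"],
                "t": float(t),
                "p_t": float(p_t),
                "p_wilcoxon": float(w.pvalue),
            }
        )
    return pd.DataFrame(rows)


def ks_block_shift(
    observed_t: np.ndarray, random_t: np.ndarray, alternative: str = "greater"
) -> tuple[float, float]:
    """KS comparison of observed-block vs random-block t statistics.

    ``alternative='greater'`` tests for the observed distribution being
    shifted toward more negative statistics (its empirical CDF lying
    above the random one).
    """
    res = stats.ks_2samp(observed_t, random_t, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
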