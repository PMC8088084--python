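"""Sliding-window detection of large regions enriched in sex-biased genes.

Each scaffold is split into 100 kb bins; 2 Mb windows (20 bins, stepping
one bin) receive the mean reassigned log2FC of their member genes (a gene
belongs to the bin containing its midpoint).  The null is built by
shuffling the reassigned log2FC values across gene positions *within five
expression strata* (baseMean quantile bins), because lowly expressed genes
carry systematically wilder fold changes: an unstratified shuffle would
mix those into highly expressed neighbourhoods and miscalibrate the null.
Windows whose observed mean falls beyond the configured empirical quantile
of their own permutation distribution are called male- (high tail) or
female-enriched (low tail), and contiguous same-direction calls are merged
into regions.

Empirical p-values use the add-one rule, p = (1 + #{null >= obs})/(n+1),
so the attainable floor is 1/(n_perm+1); the caller's effective alpha is
max(1 - quantile_cutoff, that floor) and both are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class RegionScanConfig:
    bin_size: int = 100_000
    window_bins: int = 20  # 2 Mb windows
    step_bins: int = 1
    n_strata: int = 5
    n_perm: int = 100_000
    quantile_cutoff: float = 0.9999
    divide_by_independent: bool = False  # optionally Bonferroni-scale alpha
    n_independent: int | None = None  # auto: floor(total length / window span)
    min_genes_per_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bins < 1:
            raise ValueError("window_bins must be >= 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0.5 < self.quantile_cutoff < 1:
            raise ValueError("quantile_cutoff must be in (0.5, 1)")

    @property
    def window_span(self) -> int:
        return self.bin_size * self.window_bins


@dataclass
class NullDistribution:
    n_perm: int
    counts_ge: np.ndarray  # per window: #{perm mean >= observed}
    counts_le: np.ndarray
    upper_tail: np.ndarray  # (k, n_windows) largest permuted means, sorted desc
    lower_tail: np.ndarray  # (k, n_windows) smallest, sorted asc
    strata_edges: np.ndarray
    observed: np.ndarray  # observed window means the counts refer to

    def upper_quantile(self, q: float) -> np.ndarray:
        """Exact empirical quantile per window for q above 1 - tail fraction."""
        k = self.upper_tail.shape[0]
        rank = int(np.ceil((1.0 - q) * self.n_perm))
        rank = max(1, rank)
        if rank > k:
            raise ValueError(f"quantile {q} below stored tail ({k} values)")
        return self.upper_tail[rank - 1]

    def lower_quantile(self, q: float) -> np.ndarray:
        k = self.lower_tail.shape[0]
        rank = max(1, int(np.ceil(q * self.n_perm)))
        if rank > k:
            raise ValueError(f"quantile {q} above stored tail ({k} values)")
        return self.lower_tail[rank - 1]


def assign_bins(
    annotation: pd.DataFrame,
    cfg: RegionScanConfig,
    scaffold_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Map each gene to the bin containing its midpoint.

    Bins are half-open [k*bin, (k+1)*bin) in 0-based bp, per scaffold.
    """
    mid = (annotation["start"].to_numpy() + annotation["end"].to_numpy()) // 2
    if scaffold_lengths is not None:
        lengths = annotation["scaffold"].map(scaffold_lengths).to_numpy()
        if (mid >= lengths).any():
            bad = annotation.loc[mid >= lengths, "gene_id"].iloc[0]
            raise ValueError(f"gene {bad} midpoint beyond scaffold length")
    out = annotation[["gene_id", "scaffold"]].copy()
    out["bin"] = mid // cfg.bin_size
    return out


def _scaffold_layout(
    bin_map: pd.DataFrame,
    scaffold_lengths: pd.Series,
    cfg: RegionScanConfig,
):
    """Per-scaffold gene bin arrays and window bookkeeping."""
    layout = []
    for scaffold, grp in bin_map.groupby("scaffold", sort=True):
        length = int(scaffold_lengths[scaffold])
        n_bins = length // cfg.bin_size
        n_windows = (n_bins - cfg.window_bins) // cfg.step_bins + 1
        if n_windows <= 0:
            logger.info("scaffold %s shorter than one window; skipped", scaffold)
            continue
        layout.append(
            {
                "scaffold": scaffold,
                "gene_idx": grp.index.to_numpy(),
                "bins": grp["bin"].to_numpy(dtype=int),
                "n_bins": n_bins,
                "n_windows": n_windows,
            }
        )
    return layout


def _window_stats_from_values(values: np.ndarray, layout, cfg: RegionScanConfig):
    """(means, counts) over all windows for one profile of gene values."""
    means = []
    counts = []
    for sc in layout:
        bin_sum = np.bincount(sc["bins"], weights=values[sc["gene_idx"]], minlength=sc["n_bins"])[: sc["n_bins"]]
        bin_cnt = np.bincount(sc["bins"], minlength=sc["n_bins"])[: sc["n_bins"]]
        csum = np.concatenate(([0.0], np.cumsum(bin_sum)))
        ccnt = np.concatenate(([0], np.cumsum(bin_cnt)))
        starts = np.arange(sc["n_windows"]) * cfg.step_bins
        ends = starts + cfg.window_bins
        wsum = csum[ends] - csum[starts]
        wcnt = ccnt[ends] - ccnt[starts]
        with np.errstate(invalid="ignore"):
            wmean = np.where(wcnt > 0, wsum / np.maximum(wcnt, 1), np.nan)
        means.append(wmean)
        counts.append(wcnt)
    if not means:
        return np.empty(0), np.empty(0, dtype=int)
    return np.concatenate(means), np.concatenate(counts)


def compute_window_means(
    values: pd.Series,
    bin_map: pd.DataFrame,
    scaffold_lengths: pd.Series,
    cfg: RegionScanConfig,
) -> pd.DataFrame:
    """Observed WindowStat table for one reassigned-log2FC profile.

    ``values`` is indexed by gene_id (reassign_log2fc output).  Windows
    truncated by the scaffold end are dropped; windows with fewer than
    ``min_genes_per_window`` genes are kept but flagged unusable.
    """
    vals = values.reindex(bin_map["gene_id"])
    if vals.isna().any():
        raise ValueError("adjusted log2FC missing for some genes in the bin map")
    arr = np.zeros(len(bin_map))
    arr[:] = vals.to_numpy(dtype=float)
    layout = _scaffold_layout(bin_map.reset_index(drop=True), scaffold_lengths, cfg)
    means, counts = _window_stats_from_values(arr, layout, cfg)
    rows = []
    i = 0
    for sc in layout:
        for w in range(sc["n_windows"]):
            start_bin = w * cfg.step_bins
            rows.append(
                {
                    "scaffold": sc["scaffold"],
                    "start": start_bin * cfg.bin_size,
                    "end": (start_bin + cfg.window_bins) * cfg.bin_size,
                    "n_genes": int(counts[i]),
                    "mean_log2fc": float(means[i]) if counts[i] > 0 else np.nan,
                    "usable": bool(counts[i] >= cfg.min_genes_per_window),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def build_strata(base_mean: pd.Series, n_strata: int = 5) -> pd.Series:
    """Expression stratum (0-based) per gene from baseMean quantiles.

    Edges at probabilities k/n_strata; values equal to an edge fall in the
    lower stratum.  Unexpressed genes enter with baseMean 0 and land in the
    bottom stratum.
    """
    vals = base_mean.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("baseMean must be >= 0")
    edges = np.quantile(vals, [k / n_strata for k in range(1, n_strata)])
    if len(np.unique(edges)) < len(edges):
        logger.info("degenerate strata: tied quantile edges")
    labels = np.searchsorted(edges, vals, side="left")
    return pd.Series(labels, index=base_mean.index, name="stratum")


def stratified_shuffle(
    vals: np.ndarray, stratum_idx: list[np.ndarray], rng: np.random.Generator,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """One within-stratum shuffle of ``vals`` (the permutation primitive)."""
    if out is None:
        out = vals.copy()
    for idx in stratum_idx:
        out[idx] = vals[idx][rng.permutation(len(idx))]
    return out


def permute_profiles(
    values: pd.Series,
    strata: pd.Series,
    bin_map: pd.DataFrame,
    scaffold_lengths: pd.Series,
    cfg: RegionScanConfig,
    tail_fraction: float = 0.005,
) -> NullDistribution:
    """Stratified-permutation null of every window mean.

    Each iteration independently shuffles the reassigned log2FC values
    across gene positions within each expression stratum and rescans all
    windows.  Memory stays bounded: only per-window tail values (top and
    bottom ``tail_fraction``) and exceedance counts against the observed
    means are retained, which keeps quantile queries in the calling range
    exact.
    """
    bin_map = bin_map.reset_index(drop=True)
    vals = values.reindex(bin_map["gene_id"]).to_numpy(dtype=float)
    strat = strata.reindex(bin_map["gene_id"]).to_numpy()
    if np.isnan(vals).any():
        raise ValueError("values missing for some genes")
    layout = _scaffold_layout(bin_map, scaffold_lengths, cfg)
    observed, _ = _window_stats_from_values(vals, layout, cfg)
    obs_filled = np.nan_to_num(observed, nan=0.0)
    n_windows = len(observed)
    stratum_idx = [np.flatnonzero(strat == s) for s in np.unique(strat)]
    rng = np.random.default_rng(cfg.seed)

    k = max(1, int(np.ceil(cfg.n_perm * tail_fraction)))
    counts_ge = np.zeros(n_windows, dtype=np.int64)
    counts_le = np.zeros(n_windows, dtype=np.int64)
    upper = np.full((0, n_windows), -np.inf)
    lower = np.full((0, n_windows), np.inf)
    chunk = 500
    done = 0
    perm_vals = vals.copy()
    while done < cfg.n_perm:
        m = min(chunk, cfg.n_perm - done)
        block = np.empty((m, n_windows))
        for it in range(m):
            stratified_shuffle(vals, stratum_idx, rng, out=perm_vals)
            block[it], _ = _window_stats_from_values(perm_vals, layout, cfg)
        block = np.nan_to_num(block, nan=0.0)
        counts_ge += (block >= obs_filled).sum(axis=0)
        counts_le += (block <= obs_filled).sum(axis=0)
        upper = np.sort(np.vstack([upper, block]), axis=0)[::-1][:k]
        lower = np.sort(np.vstack([lower, block]), axis=0)[:k]
        done += m
    return NullDistribution(
        n_perm=cfg.n_perm,
        counts_ge=counts_ge,
        counts_le=counts_le,
        upper_tail=upper,
        lower_tail=lower,
        strata_edges=np.quantile(
            values.to_numpy(dtype=float), [s / cfg.n_strata for s in range(1, cfg.n_strata)]
        ),
        observed=observed,
    )


def call_enriched_windows(
    windows: pd.DataFrame,
    null: NullDistribution,
    cfg: RegionScanConfig,
    total_length: int | None = None,
) -> pd.DataFrame:
    """Per-window empirical p-values and enrichment calls.

    Upper p = (1 + #{perm >= obs})/(n_perm + 1); male-enriched when upper p
    <= the effective alpha (1 - quantile_cutoff, floored at the attainable
    minimum 1/(n_perm+1); optionally divided by the number of independent
    windows).  Female calls mirror on the lower tail.  Windows below the
    gene minimum are never called.
    """
    out = windows.copy()
    n = null.n_perm
    out["p_upper"] = (1 + null.counts_ge) / (n + 1)
    out["p_lower"] = (1 + null.counts_le) / (n + 1)
    alpha = 1.0 - cfg.quantile_cutoff
    n_indep = cfg.n_independent
    if n_indep is None and total_length is not None:
        n_indep = max(1, total_length // cfg.window_span)
    if cfg.divide_by_independent:
        if n_indep is None:
            raise ValueError("divide_by_independent needs total_length or n_independent")
        alpha = alpha / n_indep
    effective_alpha = max(alpha, 1.0 / (n + 1))
    call = np.full(len(out), "none", dtype=object)
    usable = out["usable"].to_numpy(dtype=bool)
    call[(out["p_upper"] <= effective_alpha) & usable & (out["mean_log2fc"] > 0)] = "male"
    call[(out["p_lower"] <= effective_alpha) & usable & (out["mean_log2fc"] < 0)] = "female"
    out["call"] = call
    out.attrs["configured_alpha"] = 1.0 - cfg.quantile_cutoff
    out.attrs["effective_alpha"] = effective_alpha
    out.attrs["n_independent"] = n_indep
    return out


def merge_regions(
    called: pd.DataFrame,
    bin_map: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge overlapping/adjacent same-direction significant windows.

    Returns one row per region (scaffold, start, end, direction, number of
    member windows, and — when the annotation and per-gene labels are
    supplied — the member genes biased in the region's direction).
    """
    sig = called[called["call"] != "none"].sort_values(["scaffold", "call", "start"])
    regions = []
    for (scaffold, direction), grp in sig.groupby(["scaffold", "call"], sort=True):
        cur_start = cur_end = None
        members = 0
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, members = row["start"], row["end"], 1
            elif row["start"] <= cur_end:  # overlap or touch
                cur_end = max(cur_end, row["end"])
                members += 1
            else:
                regions.append((scaffold, cur_start, cur_end, direction, members))
                cur_start, cur_end, members = row["start"], row["end"], 1
        if cur_start is not None:
            regions.append((scaffold, cur_start, cur_end, direction, members))
    out = pd.DataFrame(
        regions, columns=["scaffold", "start", "end", "direction", "n_windows"]
    )
    if not out.empty and labels is not None and annotation is not None:
        gene_lists = []
        for _, r in out.iterrows():
            mid = (annotation["start"] + annotation["end"]) // 2
            in_region = (
                (annotation["scaffold"] == r["scaffold"])
                & (mid >= r["start"])
                & (mid < r["end"])
            )
            genes = annotation.loc[in_region, "gene_id"]
            biased = [g for g in genes if labels.get(g) == r["direction"]]
            gene_lists.append(",".join(biased))
        out["biased_genes"] = gene_lists
    elif not out.empty:
        out["biased_genes"] = ""
    else:
        out["biased_genes"] = pd.Series(dtype=object)
    return out.sort_values(["scaffold", "start"]).reset_index(drop=True)
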