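"""Runs of consecutive same-direction sex-biased genes and their null.

Genes are ordered along each scaffold and maximal runs of >= 2 consecutive
genes with the same bias direction are recorded; any unbiased/unexpressed
gene or a gene of the opposite direction breaks a run, and runs never span
scaffold boundaries.  Significance comes from a label-permutation null:
the observed label multiset is shuffled over all gene positions (scaffold
structure preserved), the clustered proportion and size spectrum are
recomputed each iteration, and the observed values are compared with the
central 95% fluctuation interval of the iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# integer codes for fast run detection
_CODE = {"male": 1, "female": 2}
MAX_SIZE_TRACKED = 12  # cluster sizes aggregated above this


@dataclass
class ClusterNullConfig:
    n_iter: int = 1000
    interval: float = 0.95
    seed: int = 0
    universe: str = "all_genes"  # or "expressed_genes"

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")


@dataclass
class ClusterSummary:
    """Observed (or one iteration's) clustering summary per direction."""

    proportion: dict[str, float]  # clustered biased genes / total biased genes
    size_hist: dict[str, np.ndarray]  # index s = count of clusters of size s
    n_biased: dict[str, int]
    undefined: set[str] = field(default_factory=set)


@dataclass
class ClusterNull:
    mean_proportion: dict[str, float]
    interval_proportion: dict[str, tuple[float, float]]
    mean_hist: dict[str, np.ndarray]
    interval_hist: dict[str, tuple[np.ndarray, np.ndarray]]
    n_iter: int
    n_biased: dict[str, int]


def _encode(labels: np.ndarray) -> np.ndarray:
    codes = np.zeros(len(labels), dtype=np.int8)
    codes[labels == "male"] = _CODE["male"]
    codes[labels == "female"] = _CODE["female"]
    return codes


def _runs(codes: np.ndarray, scaffold_key: np.ndarray):
    """(run_code, run_length) for maximal constant runs within scaffolds."""
    if len(codes) == 0:
        return np.empty(0, dtype=np.int8), np.empty(0, dtype=int)
    key = scaffold_key.astype(np.int64) * 4 + codes
    change = np.flatnonzero(np.diff(key) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(codes)]))
    return codes[starts], ends - starts


def find_clusters(order: pd.DataFrame) -> pd.DataFrame:
    """Maximal runs of >= 2 same-direction biased genes.

    ``order`` has columns (scaffold, gene_id, label) sorted by position
    within scaffold.  Returns one row per cluster: scaffold, start index
    (within the scaffold's gene order), size, direction, gene_ids.
    """
    records = []
    for scaffold, grp in order.groupby("scaffold", sort=True):
        labels = grp["label"].to_numpy()
        codes = _encode(labels)
        run_codes, run_lens = _runs(codes, np.zeros(len(codes), dtype=np.int64))
        pos = 0
        for code, length in zip(run_codes, run_lens):
            if code != 0 and length >= 2:
                direction = "male" if code == _CODE["male"] else "female"
                records.append(
                    {
                        "scaffold": scaffold,
                        "start_index": pos,
                        "size": int(length),
                        "direction": direction,
                        "gene_ids": ",".join(grp["gene_id"].iloc[pos : pos + length]),
                    }
                )
            pos += length
    return pd.DataFrame(
        records, columns=["scaffold", "start_index", "size", "direction", "gene_ids"]
    )


def _summary_from_codes(
    codes: np.ndarray, scaffold_key: np.ndarray
) -> tuple[dict[str, int], dict[str, np.ndarray]]:
    """Clustered gene counts and size histograms per direction (fast path)."""
    run_codes, run_lens = _runs(codes, scaffold_key)
    out_genes = {}
    out_hist = {}
    for direction, code in _CODE.items():
        lens = run_lens[(run_codes == code) & (run_lens >= 2)]
        capped = np.minimum(lens, MAX_SIZE_TRACKED)
        hist = np.bincount(capped, minlength=MAX_SIZE_TRACKED + 1)
        out_genes[direction] = int(lens.sum())
        out_hist[direction] = hist
    return out_genes, out_hist


def cluster_summary(
    records: pd.DataFrame, n_biased: dict[str, int]
) -> ClusterSummary:
    """Clustered proportion and size histogram per direction.

    ``n_biased`` gives the total biased genes of each direction in the
    ordering universe (the denominator).
    """
    proportion = {}
    size_hist = {}
    undefined = set()
    for direction in _CODE:
        sub = records[records["direction"] == direction] if not records.empty else records
        sizes = sub["size"].to_numpy(dtype=int) if not records.empty else np.empty(0, dtype=int)
        capped = np.minimum(sizes, MAX_SIZE_TRACKED)
        hist = np.bincount(capped, minlength=MAX_SIZE_TRACKED + 1)
        total = n_biased.get(direction, 0)
        if total == 0:
            proportion[direction] = float("nan")
            undefined.add(direction)
        else:
            proportion[direction] = float(sizes.sum() / total)
        size_hist[direction] = hist
    return ClusterSummary(
        proportion=proportion, size_hist=size_hist, n_biased=dict(n_biased),
        undefined=undefined,
    )


def cluster_null(
    scaffold_sizes: list[int],
    n_biased: dict[str, int],
    cfg: ClusterNullConfig = ClusterNullConfig(),
) -> ClusterNull:
    """Permutation null of the clustered proportion and size spectrum.

    The label multiset (n male, n female, rest unbiased) is shuffled over
    the concatenated gene positions of all scaffolds each iteration;
    scaffold boundaries are preserved for run detection.
    """
    n_total = int(sum(scaffold_sizes))
    n_male = int(n_biased.get("male", 0))
    n_female = int(n_biased.get("female", 0))
    if n_male + n_female > n_total:
        raise ValueError("label counts exceed total genes")
    scaffold_key = np.repeat(np.arange(len(scaffold_sizes), dtype=np.int64), scaffold_sizes)
    rng = np.random.default_rng(cfg.seed)
    base = np.zeros(n_total, dtype=np.int8)
    base[:n_male] = _CODE["male"]
    base[n_male : n_male + n_female] = _CODE["female"]
    props = {d: np.empty(cfg.n_iter) for d in _CODE}
    hists = {d: np.empty((cfg.n_iter, MAX_SIZE_TRACKED + 1)) for d in _CODE}
    for it in range(cfg.n_iter):
        codes = base[rng.permutation(n_total)]
        genes, hist = _summary_from_codes(codes, scaffold_key)
        for d in _CODE:
            denom = {"male": n_male, "female": n_female}[d]
            props[d][it] = genes[d] / denom if denom else np.nan
            hists[d][it] = hist[d]
    lo_q, hi_q = (1 - cfg.interval) / 2, 1 - (1 - cfg.interval) / 2
    mean_p, int_p, mean_h, int_h = {}, {}, {}, {}
    for d in _CODE:
        arr = props[d]
        if np.isnan(arr).all():
            mean_p[d] = 0.0
            int_p[d] = (0.0, 0.0)
        else:
            mean_p[d] = float(np.nanmean(arr))
            int_p[d] = (float(np.nanquantile(arr, lo_q)), float(np.nanquantile(arr, hi_q)))
        mean_h[d] = hists[d].mean(axis=0)
        int_h[d] = (
            np.quantile(hists[d], lo_q, axis=0),
            np.quantile(hists[d], hi_q, axis=0),
        )
    return ClusterNull(
        mean_proportion=mean_p,
        interval_proportion=int_p,
        mean_hist=mean_h,
        interval_hist=int_h,
        n_iter=cfg.n_iter,
        n_biased={"male": n_male, "female": n_female},
    )


def test_cluster_enrichment(observed: ClusterSummary, null: ClusterNull) -> pd.DataFrame:
    """Flag observed proportions/size-class counts outside the null interval.

    One row per (direction, statistic): the clustered proportion plus each
    tracked cluster size class; ``significant`` means outside the 95%
    fluctuation interval, with the side reported.
    """
    for d in _CODE:
        if observed.n_biased.get(d, 0) != null.n_biased.get(d, 0):
            raise ValueError(
                f"label count mismatch for {d}: observed universe "
                f"{observed.n_biased.get(d)} vs null {null.n_biased.get(d)}"
            )
    rows = []
    for d in _CODE:
        obs_p = observed.proportion[d]
        lo, hi = null.interval_proportion[d]
        sig = (not np.isnan(obs_p)) and (obs_p < lo or obs_p > hi)
        rows.append(
            {
                "direction": d,
                "statistic": "clustered_proportion",
                "observed": obs_p,
                "null_mean": null.mean_proportion[d],
                "lower": lo,
                "upper": hi,
                "significant": bool(sig),
                "side": "above" if sig and obs_p > hi else ("below" if sig else "none"),
            }
        )
        for size in range(2, MAX_SIZE_TRACKED + 1):
            obs_c = float(observed.size_hist[d][size])
            lo_c = float(null.interval_hist[d][0][size])
            hi_c = float(null.interval_hist[d][1][size])
            sig_c = obs_c < lo_c or obs_c > hi_c
            rows.append(
                {
                    "direction": d,
                    "statistic": f"size_{size}",
                    "observed": obs_c,
                    "null_mean": float(null.mean_hist[d][size]),
                    "lower": lo_c,
                    "upper": hi_c,
                    "significant": bool(sig_c),
                    "side": "above" if sig_c and obs_c > hi_c else ("below" if sig_c else "none"),
                }
            )
    return pd.DataFrame(rows)
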