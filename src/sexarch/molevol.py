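"""dN/dS category comparisons and the label-permutation bootstrap.

Sequence-evolution rates (dN/dS per gene, per branch) are compared between
bias categories with two-sided rank-sum tests.  Because category sizes are
small relative to the gene pool, an observed p-value alone can mislead; the
bootstrap guard re-draws the category labels at random (preserving the
observed sizes, e.g. 253 male / 463 female) many times, recomputes the test
each time, and places the observed p against the lower tail of that null
p-value distribution.  The observed contrast is declared non-random only
when its p-value falls below the cutoff that (say) 99.95% of random
relabelings exceed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DndsBootstrapConfig:
    n_male: int = 253
    n_female: int = 463
    n_iter: int = 1000
    quantile: float = 0.9995
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")


@dataclass
class DndsComparison:
    statistic: float
    pvalue: float
    medians: dict[str, float]
    n: dict[str, int]
    n_excluded: int  # genes dropped for dS == 0


@dataclass
class BootstrapResult:
    pvalues_male: np.ndarray
    pvalues_female: np.ndarray
    cutoff_male: float
    cutoff_female: float
    n_iter: int
    seed: int

    def is_nonrandom(self, observed_p: float, direction: str = "male") -> bool:
        cutoff = self.cutoff_male if direction == "male" else self.cutoff_female
        return observed_p < cutoff


def _ratios(records: pd.DataFrame, species: str | None = None):
    sub = records if species is None else records[records["species"] == species]
    excluded = int((sub["dS"] == 0).sum())
    sub = sub[sub["dS"] > 0]
    ratio = (sub["dN"] / sub["dS"]) if "ratio" not in sub else sub["ratio"]
    return pd.Series(ratio.to_numpy(), index=sub["gene_id"].to_numpy()), excluded


def compare_dnds(
    records: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str] = ("male", "unbiased"),
    species: str | None = None,
) -> DndsComparison:
    """Two-sided rank-sum between two categories' dN/dS values.

    Genes with dS == 0 (ratio undefined) are excluded and counted.
    """
    ratio, excluded = _ratios(records, species)
    lab = labels.reindex(ratio.index)
    groups = []
    for cat in pair:
        vals = ratio[(lab == cat).to_numpy()].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 genes with defined ratio")
        groups.append(vals)
    a, b = groups
    if len(a) == len(b) and np.array_equal(np.sort(a), np.sort(b)):
        stat, p = float(len(a) * len(b) / 2), 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return DndsComparison(
        statistic=stat,
        pvalue=p,
        medians={pair[0]: float(np.median(a)), pair[1]: float(np.median(b))},
        n={pair[0]: len(a), pair[1]: len(b)},
        n_excluded=excluded,
    )


def label_bootstrap(
    records: pd.DataFrame,
    cfg: DndsBootstrapConfig = DndsBootstrapConfig(),
    species: str | None = None,
) -> BootstrapResult:
    """Null p-value distribution under random category labels.

    Each iteration labels ``n_male`` genes male-biased and ``n_female``
    female-biased (drawn without replacement from all genes with a defined
    ratio) and recomputes the male-vs-unbiased and female-vs-unbiased
    rank-sum p-values.  The cutoff is the empirical quantile below which
    only ``1 - quantile`` of bootstrap p-values fall; an observed p below
    it is unlikely under random labeling.
    """
    ratio, _ = _ratios(records, species)
    vals = ratio.to_numpy()
    n = len(vals)
    if cfg.n_male + cfg.n_female > n:
        raise ValueError("category sizes exceed number of genes with defined ratio")
    rng = np.random.default_rng(cfg.seed)
    p_male = np.empty(cfg.n_iter)
    p_female = np.empty(cfg.n_iter)
    for it in range(cfg.n_iter):
        perm = rng.permutation(n)
        male = vals[perm[: cfg.n_male]]
        female = vals[perm[cfg.n_male : cfg.n_male + cfg.n_female]]
        unbiased = vals[perm[cfg.n_male + cfg.n_female :]]
        if np.ptp(vals) == 0:
            p_male[it] = p_female[it] = 1.0
            continue
        p_male[it] = stats.mannwhitneyu(male, unbiased, alternative="two-sided").pvalue
        p_female[it] = stats.mannwhitneyu(female, unbiased, alternative="two-sided").pvalue
    q = 1.0 - cfg.quantile
    return BootstrapResult(
        pvalues_male=p_male,
        pvalues_female=p_female,
        cutoff_male=float(np.quantile(p_male, q)),
        cutoff_female=float(np.quantile(p_female, q)),
        n_iter=cfg.n_iter,
        seed=cfg.seed,
    )


def stratify_by_leg_bias(sex_labels: pd.Series, leg_labels: pd.Series) -> pd.Series:
    """Cross sex-bias with leg-bias into four-way categories.

    Produces labels like "male/leg-biased" or "unbiased/leg-unbiased";
    genes missing from either input are dropped.
    """
    common = sex_labels.index.intersection(leg_labels.index)
    sex = sex_labels.loc[common]
    leg = leg_labels.loc[common]
    leg_part = np.where(leg.isin(["leg3", "leg1", "male", "female"]), "leg-biased", "leg-unbiased")
    return pd.Series(
        [f"{s}/{l}" for s, l in zip(sex, leg_part)], index=common, name="category"
    )
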