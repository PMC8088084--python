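"""X/Y identification, dosage compensation and chromosome-level enrichment.

The X chromosome is found from male-only genomic coverage: in a male-
heterogametic system the X is hemizygous, so among the largest scaffolds it
is the unique one at roughly half the autosomal median depth.  A Y
candidate would show the same half coverage but carry exclusively
male-biased expressed genes.  Dosage compensation is assessed by comparing
per-gene male and female mean log2(FPKM) on the X, and the chromosomal
distribution of sex-biased genes by Fisher exact tests of X versus the 12
largest autosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COVERAGE_BAND = (0.35, 0.65)


@dataclass
class XAssignment:
    x_scaffold_id: str | None
    coverage_ratio: float | None
    y_candidates: list[str] = field(default_factory=list)
    diagnostics: pd.DataFrame | None = None

    @property
    def assigned(self) -> bool:
        return self.x_scaffold_id is not None


@dataclass
class FisherResult:
    table: np.ndarray  # 2x2 counts
    odds_ratio: float  # sample (unconditional) odds ratio
    pvalue: float
    direction: str  # "enriched" (OR>1), "depleted" (OR<1), "none"
    undefined_or: bool = False


def _coverage_ratios(coverage: pd.DataFrame, top_n: int) -> pd.DataFrame:
    top = coverage.sort_values("length", ascending=False).head(top_n).reset_index(drop=True)
    depths = top["mean_depth"].to_numpy(dtype=float)
    ratios = np.empty(len(top))
    for i in range(len(top)):
        others = np.delete(depths, i)
        med = np.median(others)
        ratios[i] = depths[i] / med if med > 0 else np.inf
    top = top.copy()
    top["ratio_to_others_median"] = ratios
    return top


def identify_x(
    coverage: pd.DataFrame,
    top_n: int = 13,
    band: tuple[float, float] = COVERAGE_BAND,
) -> XAssignment:
    """Assign the X among the ``top_n`` largest scaffolds by coverage ratio.

    The unique scaffold whose male depth relative to the median of the other
    large scaffolds falls inside ``band`` (default [0.35, 0.65], i.e. about
    half) is called X; zero or several candidates leave the assignment open
    with diagnostics attached.
    """
    if coverage.empty:
        raise ValueError("empty coverage table")
    if len(coverage) < 2:
        raise ValueError("need >= 2 scaffolds")
    top = _coverage_ratios(coverage, top_n)
    in_band = top[
        (top["ratio_to_others_median"] >= band[0])
        & (top["ratio_to_others_median"] <= band[1])
    ]
    if len(in_band) == 1:
        row = in_band.iloc[0]
        return XAssignment(
            x_scaffold_id=str(row["scaffold"]),
            coverage_ratio=float(row["ratio_to_others_median"]),
            diagnostics=top,
        )
    logger.info("X unassigned: %d scaffolds in coverage band", len(in_band))
    return XAssignment(x_scaffold_id=None, coverage_ratio=None, diagnostics=top)


def scan_y_candidates(
    coverage: pd.DataFrame,
    calls_by_leg: dict[int, pd.DataFrame],
    annotation: pd.DataFrame,
    x_id: str,
    top_n: int = 50,
    band: tuple[float, float] = COVERAGE_BAND,
) -> list[str]:
    """Scaffolds with X-like coverage whose expressed genes are all male-biased.

    Scans the ``top_n`` largest scaffolds (excluding the assigned X).  A
    candidate must carry at least one expressed gene, every expressed gene
    must be male-biased in at least one leg, and none may be female-biased
    in any leg.
    """
    top = _coverage_ratios(coverage, top_n)
    gene_scaffold = annotation.set_index("gene_id")["scaffold"]
    male_ever: set[str] = set()
    female_ever: set[str] = set()
    expressed_ever: set[str] = set()
    for calls in calls_by_leg.values():
        lab = calls.set_index("gene_id")["label"]
        expressed_ever |= set(lab.index[lab != "unexpressed"])
        male_ever |= set(lab.index[lab == "male"])
        female_ever |= set(lab.index[lab == "female"])
    candidates = []
    for _, row in top.iterrows():
        sc = str(row["scaffold"])
        if sc == x_id:
            continue
        if not band[0] <= row["ratio_to_others_median"] <= band[1]:
            continue
        genes = set(gene_scaffold.index[gene_scaffold == sc])
        expressed = genes & expressed_ever
        if not expressed:
            continue
        if expressed <= male_ever and not (expressed & female_ever):
            candidates.append(sc)
    return candidates


def test_dosage_compensation(
    fpkm: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    x_id: str,
    leg: int,
    fpkm_threshold: float = 2.0,
) -> tuple[float, float, int]:
    """Rank-sum of per-gene male vs female mean log2(FPKM) on the X, one leg.

    Genes enter if their FPKM exceeds the threshold in at least half of the
    leg's libraries; expression is averaged over replicates and lines per
    sex before testing, so the gene is the unit of observation.  Returns
    (statistic, two-sided p, number of X genes tested).
    """
    x_genes = annotation.loc[annotation["scaffold"] == x_id, "gene_id"]
    meta = samples.set_index("sample_id")
    leg_samples = meta.index[meta["leg"] == leg]
    sub = fpkm.loc[fpkm.index.intersection(x_genes), leg_samples.tolist()]
    ok = (sub > fpkm_threshold).sum(axis=1) >= sub.shape[1] / 2
    sub = sub[ok]
    n = len(sub)
    if n == 0:
        return float("nan"), float("nan"), 0
    if n < 5:
        logger.warning("only %d X genes pass the filter for leg %d", n, leg)
    sex = meta.loc[sub.columns, "sex"]
    mean_m = sub.loc[:, (sex == "M").to_numpy()].mean(axis=1)
    mean_f = sub.loc[:, (sex == "F").to_numpy()].mean(axis=1)
    log_m = np.log2(mean_m + 1e-9)
    log_f = np.log2(mean_f + 1e-9)
    if np.array_equal(log_m.to_numpy(), log_f.to_numpy()):
        return 0.0, 1.0, n
    res = stats.mannwhitneyu(log_m, log_f, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), n


def _fisher(table: np.ndarray) -> FisherResult:
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("negative counts in 2x2 table")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return FisherResult(table, float("nan"), 1.0, "none", undefined_or=True)
    a, b = table[0]
    c, d = table[1]
    undefined = b == 0 or c == 0
    sample_or = float("inf") if undefined and a * d > 0 else (
        float("nan") if undefined else a * d / (b * c)
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if undefined or sample_or > 1:
        direction = "enriched"
    elif sample_or < 1:
        direction = "depleted"
    else:
        direction = "none"
    return FisherResult(table, sample_or, float(p), direction, undefined_or=undefined)


def autosome_ids(annotation: pd.DataFrame, x_id: str, n: int = 12,
                 scaffold_lengths: pd.Series | None = None) -> list[str]:
    """The ``n`` largest non-X scaffolds (span from the annotation unless
    lengths are supplied)."""
    if scaffold_lengths is None:
        scaffold_lengths = annotation.groupby("scaffold")["end"].max()
    ranked = scaffold_lengths.drop(index=x_id, errors="ignore").sort_values(ascending=False)
    return list(ranked.index[:n])


def fisher_x_enrichment(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    x_id: str,
    direction: str,
    autosomes: list[str] | None = None,
    universe: str = "expressed",
) -> FisherResult:
    """Fisher exact test of direction-biased genes on X vs the autosomes.

    The universe is the leg's expressed genes (default) or all annotated
    genes on X plus the 12 largest autosomes; the 2x2 table crosses
    {direction-biased, not} with {X, autosome}.
    """
    if autosomes is None:
        autosomes = autosome_ids(annotation, x_id)
    gene_scaffold = annotation.set_index("gene_id")["scaffold"]
    sub = calls.copy()
    sub["scaffold"] = sub["gene_id"].map(gene_scaffold)
    sub = sub[sub["scaffold"].isin([x_id] + list(autosomes))]
    if universe == "expressed":
        sub = sub[sub["label"] != "unexpressed"]
    elif universe != "all":
        raise ValueError("universe must be 'expressed' or 'all'")
    on_x = sub["scaffold"] == x_id
    biased = sub["label"] == direction
    table = np.array(
        [
            [int((biased & on_x).sum()), int((biased & ~on_x).sum())],
            [int((~biased & on_x).sum()), int((~biased & ~on_x).sum())],
        ]
    )
    return _fisher(table)


@dataclass
class CrosstalkResult:
    fisher: FisherResult
    overlap_count: int
    n_sex_biased: int
    overlap_pct: float


def crosstalk_enrichment(
    sex_calls: pd.DataFrame,
    leg_calls: pd.DataFrame,
    sex_direction: str = "male",
    leg_direction: str = "leg3",
) -> CrosstalkResult:
    """Enrichment of leg-biased expression among one leg's sex-biased genes.

    Both call tables must cover the same expressed universe.  ``leg_calls``
    labels genes by the leg contrast within one sex ("male" there means
    third-leg-upregulated when the contrast is leg3-vs-leg1 encoded with
    positive = leg 3).  Reports the 2x2 Fisher test plus the overlap count
    and percentage of sex-biased genes (2 decimals).
    """
    from .expression import percentage

    sex_lab = sex_calls.set_index("gene_id")["label"]
    leg_lab = leg_calls.set_index("gene_id")["label"]
    sex_universe = set(sex_lab.index[sex_lab != "unexpressed"])
    leg_universe = set(leg_lab.index[leg_lab != "unexpressed"])
    if sex_universe != leg_universe:
        raise ValueError("sex and leg call tables cover different universes")
    universe = sorted(sex_universe)
    s = sex_lab.loc[universe] == sex_direction
    l = leg_lab.loc[universe] == leg_direction
    table = np.array(
        [
            [int((s & l).sum()), int((s & ~l).sum())],
            [int((~s & l).sum()), int((~s & ~l).sum())],
        ]
    )
    fisher = _fisher(table)
    overlap = int(table[0, 0])
    n_sex = int(s.sum())
    return CrosstalkResult(
        fisher=fisher,
        overlap_count=overlap,
        n_sex_biased=n_sex,
        overlap_pct=percentage(overlap, n_sex),
    )
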