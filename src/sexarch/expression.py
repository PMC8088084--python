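"""Expression quantification, filtering, bias calling and summaries.

The sex-bias caller applies the study's rule — linear fold change > 1.5
(|log2FC| > log2 1.5) at an adjusted p below 0.05 — on top of an expression
filter that keeps a gene in a leg only if it is not below 2 FPKM in more
than half of that leg's libraries and not below 2 mean FPKM in both sexes.
Calls are then collapsed into the "reassigned" log2FC vector (unexpressed
and unbiased genes set to zero) that the genome-architecture scans consume.

The differential-expression stage is a deliberately simple, pluggable
stand-in (median-of-ratios normalization, pseudo-count fold changes,
rank-sum p, Benjamini-Hochberg within contrast); externally computed DE
tables with the same columns are accepted everywhere downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LABELS = ("male", "female", "unbiased", "unexpressed")


@dataclass(frozen=True)
class ExpressionFilterConfig:
    fpkm_threshold: float = 2.0
    max_low_fraction: float = 0.5  # "more than half" of the leg's samples
    sex_mean_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.fpkm_threshold < 0 or self.sex_mean_threshold < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class BiasCallConfig:
    fc_threshold: float = 1.5  # linear fold change
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")

    @property
    def log2fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


@dataclass
class AbundanceMatrix:
    fpkm: pd.DataFrame
    tpm: pd.DataFrame
    gene_lengths: pd.Series


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray
    corrected: bool


def compute_abundance(counts: pd.DataFrame, gene_lengths: pd.Series) -> AbundanceMatrix:
    """FPKM and TPM from raw counts and gene lengths (bp).

    FPKM = count * 1e9 / (length * column_total);
    TPM  = length-normalized rate scaled to 1e6 per column.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (counts < 0).to_numpy().any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning("zero column totals: %s", list(totals.index[zero_cols]))
    safe_totals = totals.replace(0, np.nan)
    fpkm = counts.mul(1e9).div(lengths, axis=0).div(safe_totals, axis=1).fillna(0.0)
    rate = counts.div(lengths, axis=0)
    rate_totals = rate.sum(axis=0).replace(0, np.nan)
    tpm = rate.div(rate_totals, axis=1).mul(1e6).fillna(0.0)
    return AbundanceMatrix(fpkm=fpkm, tpm=tpm, gene_lengths=lengths)


def filter_expressed(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: ExpressionFilterConfig = ExpressionFilterConfig(),
) -> dict[int, set[str]]:
    """Expressed gene set per leg.

    A gene is kept in a leg unless its FPKM is strictly below the threshold
    in more than half of the leg's samples, or its mean FPKM is strictly
    below the sex-mean threshold in both sexes.
    """
    out: dict[int, set[str]] = {}
    for leg in sorted(samples["leg"].unique()):
        leg_samples = samples.loc[samples["leg"] == leg, "sample_id"]
        if leg_samples.empty:
            raise ValueError(f"leg {leg} absent from design")
        sub = fpkm[leg_samples.tolist()]
        n = sub.shape[1]
        low = (sub < cfg.fpkm_threshold).sum(axis=1)
        fail_low = low > cfg.max_low_fraction * n
        by_sex = samples.set_index("sample_id").loc[sub.columns, "sex"]
        mean_m = sub.loc[:, (by_sex == "M").to_numpy()].mean(axis=1)
        mean_f = sub.loc[:, (by_sex == "F").to_numpy()].mean(axis=1)
        fail_mean = (mean_m < cfg.sex_mean_threshold) & (mean_f < cfg.sex_mean_threshold)
        keep = ~(fail_low | fail_mean)
        out[int(leg)] = set(sub.index[keep])
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Reference is the per-gene geometric mean over all libraries, using only
    genes with strictly positive counts everywhere.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        logger.warning("no all-positive genes; size factors set to 1")
        return pd.Series(1.0, index=counts.columns)
    log_geo = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def run_de_standin(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, object],
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Simple differential-expression table for one contrast.

    ``contrast`` is ``("sex", leg)`` — male vs female within one leg, lines
    pooled (positive log2FC = male-biased) — or ``("leg", sex)`` — third vs
    first legs within one sex (positive = third-leg-biased).  Fold changes
    use a 0.5 pseudo-count on group means of normalized counts; p-values are
    two-sided rank-sum; padj is Benjamini-Hochberg within the contrast.
    """
    kind, level = contrast
    meta = samples.set_index("sample_id")
    if kind == "sex":
        cell = meta[meta["leg"] == level]
        group_a = cell.index[cell["sex"] == "M"]
        group_b = cell.index[cell["sex"] == "F"]
        name = f"sex_leg{level}"
    elif kind == "leg":
        cell = meta[meta["sex"] == level]
        group_a = cell.index[cell["leg"] == 3]
        group_b = cell.index[cell["leg"] == 1]
        name = f"leg3v1_{level}"
    else:
        raise ValueError(f"unknown contrast kind {kind!r}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    if sf is None:
        sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    a = norm[list(group_a)].to_numpy()
    b = norm[list(group_b)].to_numpy()
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    base_mean = norm[list(group_a) + list(group_b)].mean(axis=1).to_numpy()
    c = 0.5
    log2fc = np.log2((mean_a + c) / (mean_b + c))
    # exact null for small groups: the asymptotic p floor at n=6 vs 6 is too
    # coarse to survive BH across thousands of genes
    method = "exact" if min(a.shape[1], b.shape[1]) <= 8 else "auto"
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method=method)
    pvalue = np.asarray(res.pvalue, dtype=float)
    degenerate = (mean_a == 0) & (mean_b == 0)
    log2fc[degenerate] = 0.0
    pvalue[degenerate] = 1.0
    padj = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "contrast": name,
            "baseMean": base_mean,
            "log2FC": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "lines_pooled": kind == "sex",
        }
    )


def call_sex_bias(
    de: pd.DataFrame,
    expressed: set[str],
    cfg: BiasCallConfig = BiasCallConfig(),
    leg: int | None = None,
) -> pd.DataFrame:
    """Label every gene in the DE table for one leg.

    male if log2FC > log2(fc_threshold) with padj < alpha; female symmetric;
    unbiased otherwise; unexpressed if the gene failed the expression filter.
    """
    thr = cfg.log2fc_threshold
    padj = de["padj"].to_numpy(dtype=float)
    if np.isnan(padj).any():
        logger.warning("missing padj treated as 1 for %d genes", int(np.isnan(padj).sum()))
        padj = np.nan_to_num(padj, nan=1.0)
    lfc = de["log2FC"].to_numpy(dtype=float)
    sig = padj < cfg.alpha
    label = np.where(
        sig & (lfc > thr), "male", np.where(sig & (lfc < -thr), "female", "unbiased")
    )
    in_universe = de["gene_id"].isin(expressed).to_numpy()
    label = np.where(in_universe, label, "unexpressed")
    calls = pd.DataFrame(
        {
            "gene_id": de["gene_id"],
            "leg": leg if leg is not None else de.get("contrast", pd.Series(dtype=object)),
            "label": label,
            "log2FC": lfc,
            "padj": padj,
        }
    )
    return calls


def reassign_log2fc(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse calls to the adjusted (log2FC, p) pair used by the scans.

    Unexpressed genes get (0, 1); unbiased genes keep p but get log2FC 0;
    biased genes keep their original values.  Idempotent.
    """
    label = calls["label"].to_numpy()
    lfc = calls["log2FC"].to_numpy(dtype=float).copy()
    p = calls["padj"].to_numpy(dtype=float).copy()
    lfc[np.isin(label, ("unbiased", "unexpressed"))] = 0.0
    p[label == "unexpressed"] = 1.0
    out = calls.copy()
    out["reassigned_log2fc"] = lfc
    out["reassigned_p"] = p
    return out


def percentage(count: int, total: int) -> float:
    """Percentage rounded half-away-from-zero to 2 decimals."""
    if total == 0:
        return 0.0
    pct = Decimal(count) / Decimal(total) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_bias(calls_by_leg: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Per-leg expressed totals and biased counts with percentages."""
    rows = []
    for leg, calls in sorted(calls_by_leg.items()):
        expressed = calls["label"] != "unexpressed"
        n_exp = int(expressed.sum())
        n_male = int((calls["label"] == "male").sum())
        n_female = int((calls["label"] == "female").sum())
        rows.append(
            {
                "leg": leg,
                "n_expressed": n_exp,
                "n_male_biased": n_male,
                "pct_male_biased": percentage(n_male, n_exp),
                "n_female_biased": n_female,
                "pct_female_biased": percentage(n_female, n_exp),
            }
        )
    return pd.DataFrame(rows)


def bias_overlap(sets_by_leg: dict[int, set[str]]) -> dict[str, set[str]]:
    """All Venn cells over the per-leg biased gene sets.

    Keys are '&'-joined sorted leg names for each non-empty combination,
    e.g. ``"leg1&leg3"`` is the set biased in legs 1 and 3 but not in any
    other leg; ``"leg3_only"`` aliases the singleton cells.
    """
    legs = sorted(sets_by_leg)
    cells: dict[str, set[str]] = {}
    from itertools import combinations

    for r in range(1, len(legs) + 1):
        for combo in combinations(legs, r):
            inside = set.intersection(*(sets_by_leg[l] for l in combo))
            outside = set().union(*(sets_by_leg[l] for l in legs if l not in combo)) if len(combo) < len(legs) else set()
            cells["&".join(f"leg{l}" for l in combo)] = inside - outside
    for leg in legs:
        cells[f"leg{leg}_only"] = cells[f"leg{leg}"]
    return cells


def compare_bias_magnitude(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, direction: str
) -> tuple[float, float]:
    """Two-sided rank-sum on |log2FC| of direction-matched biased genes."""
    va = calls_a.loc[calls_a["label"] == direction, "log2FC"].abs().to_numpy()
    vb = calls_b.loc[calls_b["label"] == direction, "log2FC"].abs().to_numpy()
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("no biased genes on one side")
    res = stats.mannwhitneyu(va, vb, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def within_class_pca(
    matrix: pd.DataFrame,
    classes: pd.Series | None = None,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of samples (rows) with optional within-class correction.

    Corrected mode subtracts each sample's class mean before the
    decomposition, removing between-class (e.g. inbred-line) structure so
    the leading axes reflect within-class variation only.
    """
    X = matrix.to_numpy(dtype=float)
    corrected = classes is not None
    if corrected:
        cls = classes.reindex(matrix.index)
        if cls.isna().any():
            raise ValueError("class labels missing for some samples")
        for c in cls.unique():
            mask = (cls == c).to_numpy()
            X[mask] -= X[mask].mean(axis=0)
    if np.allclose(X - X.mean(axis=0), 0):
        k = n_components or min(X.shape)
        coords = pd.DataFrame(
            np.zeros((X.shape[0], k)), index=matrix.index,
            columns=[f"PC{i+1}" for i in range(k)],
        )
        return PcaResult(coords, np.zeros(k), corrected)
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    return PcaResult(
        coordinates=pd.DataFrame(
            coords, index=matrix.index, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
        ),
        variance_fraction=pca.explained_variance_ratio_,
        corrected=corrected,
    )
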