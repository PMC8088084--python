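"""Synthetic genomes, counts, coverage and dN/dS tables with planted structure.

The generator emulates the study design the downstream analyses assume: a
2 lines x 2 sexes x 3 legs x 3 replicates bulk RNA-seq experiment (36
libraries) quantified against a genome of 13 large scaffolds (12 autosomes
plus a half-coverage X) carrying roughly one gene every 20 kb.  Every planted
effect — per-leg sex-biased genes, leg-biased genes, a megabase-scale
male-enriched region, small runs of consecutive same-direction genes, X
feminization, and dN/dS category shifts — is recorded in a :class:`TruthSet`
so recovery can be scored exactly.

All randomness flows from one integer seed, split hierarchically so each
generator stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("M", "F")
LEGS = (1, 2, 3)

# stage offsets mixed into the seed so stages draw from disjoint streams
_STAGE_ANNOTATION = 1
_STAGE_COUNTS = 2
_STAGE_COVERAGE = 3
_STAGE_DNDS = 4


@dataclass(frozen=True)
class PlantedRegion:
    """A megabase-scale region seeded with same-direction sex-biased genes."""

    scaffold_index: int
    start: int
    end: int
    direction: str  # "male" or "female"
    effect_log2fc: float = 2.0
    n_genes: int = 30


@dataclass(frozen=True)
class PlantedCluster:
    """A short run of consecutive same-direction sex-biased genes."""

    scaffold_index: int
    start_gene_index: int  # index into the scaffold's ordered genes
    size: int  # 2-4 consecutive genes
    direction: str


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: 13 scaffolds of 5 Mb with ~1
    gene / 20 kb, a 36-sample design, per-leg bias fractions at the observed
    rates (leg 1: 1.80% male / 4.45% female ... leg 3: 6.02% / 11.47%), one
    planted 2 Mb male-enriched region, a handful of 2-4-gene clusters, a
    dosage-compensated half-coverage X whose female-bias density is tripled
    in leg 3, and gamma dN/dS with the male category's median shifted x1.3.
    """

    n_autosomes: int = 12
    scaffold_lengths: tuple[int, ...] | None = None  # default 5 Mb each
    default_scaffold_length: int = 5_000_000
    mean_gene_spacing: int = 20_000
    min_gene_spacing: int = 1_000
    mean_gene_length: int = 2_000

    lines: tuple[str, ...] = ("big", "small")
    n_replicates: int = 3

    nb_mean_log: float = math.log(100.0)  # log-mean of per-gene baseline
    nb_mean_sd: float = 1.2  # lognormal sd of per-gene baseline
    nb_dispersion: float = 0.1
    libsize_sd: float = 0.2  # lognormal sd of library-size factors

    # per-leg fractions of expressed-scale genes planted as biased
    frac_male_biased: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0180, 2: 0.0191, 3: 0.0602}
    )
    frac_female_biased: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0445, 2: 0.0397, 3: 0.1147}
    )
    effect_log2fc: float = 2.0

    frac_line_effect: float = 0.10
    line_effect_log2fc: float = 0.5
    frac_leg_biased: float = 0.05
    leg_effect_log2fc: float = 1.5

    planted_regions: tuple[PlantedRegion, ...] = (
        PlantedRegion(scaffold_index=1, start=1_000_000, end=3_000_000,
                      direction="male", effect_log2fc=2.0, n_genes=30),
    )
    planted_clusters: tuple[PlantedCluster, ...] = (
        PlantedCluster(scaffold_index=3, start_gene_index=40, size=3, direction="male"),
        PlantedCluster(scaffold_index=4, start_gene_index=60, size=2, direction="female"),
        PlantedCluster(scaffold_index=5, start_gene_index=25, size=4, direction="male"),
    )

    x_scaffold_index: int = 12  # last of the 13 scaffolds is the X
    x_feminization_factor: float = 3.0
    x_feminized_legs: tuple[int, ...] = (3,)
    x_male_downshift_log2fc: float = 0.0  # >0 breaks dosage compensation

    include_y_like: bool = False  # optional extra half-coverage scaffold
    y_like_length: int = 1_000_000

    coverage_depth: float = 100.0
    coverage_window: int = 10_000

    # per-category gamma (shape, scale) for dN/dS; male median = 1.3x unbiased
    dnds_gamma: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "unbiased": (2.0, 0.075),
            "male": (2.0, 0.0975),
            "female": (2.0, 0.075),
        }
    )
    dnds_n_male: int = 253
    dnds_n_female: int = 463
    dnds_species: tuple[str, ...] = ("M_longipes",)

    seed: int = 0

    def __post_init__(self) -> None:
        for frac_map in (self.frac_male_biased, self.frac_female_biased):
            for leg, f in frac_map.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"bias fraction for leg {leg} outside [0,1]: {f}")
        if not 0.0 <= self.frac_leg_biased <= 1.0:
            raise ValueError("frac_leg_biased outside [0,1]")
        for length in self.resolved_scaffold_lengths():
            if length < 0:
                raise ValueError("scaffold lengths must be >= 0")
        lengths = self.resolved_scaffold_lengths()
        for r in self.planted_regions:
            if not (0 <= r.start < r.end <= lengths[r.scaffold_index]):
                raise ValueError(f"planted region {r} outside scaffold bounds")
        spans: list[tuple[int, int, int]] = []
        for c in self.planted_clusters:
            span = (c.scaffold_index, c.start_gene_index, c.start_gene_index + c.size)
            for other in spans:
                if other[0] == span[0] and span[1] < other[2] and other[1] < span[2]:
                    raise ValueError("planted clusters overlap")
            spans.append(span)

    @property
    def n_scaffolds(self) -> int:
        return self.n_autosomes + 1 + (1 if self.include_y_like else 0)

    def resolved_scaffold_lengths(self) -> tuple[int, ...]:
        if self.scaffold_lengths is not None:
            return tuple(self.scaffold_lengths)
        lengths = [self.default_scaffold_length] * (self.n_autosomes + 1)
        if self.include_y_like:
            lengths.append(self.y_like_length)
        return tuple(lengths)

    def scaffold_names(self) -> tuple[str, ...]:
        n = len(self.resolved_scaffold_lengths())
        return tuple(f"scaffold_{i + 1}" for i in range(n))

    @property
    def x_scaffold(self) -> str:
        return self.scaffold_names()[self.x_scaffold_index]

    @property
    def y_like_scaffold(self) -> str | None:
        if not self.include_y_like:
            return None
        return self.scaffold_names()[-1]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class TruthSet:
    """Ground truth for every planted effect.

    ``bias_labels`` holds one label per gene per leg in
    {male, female, unbiased}; planted-region and planted-cluster members are
    included.  Leg-biased genes carry the "leg3" label (upregulated in third
    legs of both sexes).
    """

    bias_labels: pd.DataFrame  # index gene_id, columns leg1..leg3
    leg_bias: pd.Series  # gene_id -> {"leg3", "none"}
    regions: list[dict]
    clusters: list[dict]
    x_scaffold: str
    dnds_category: pd.Series | None = None  # filled by generate_dnds

    def labels_for_leg(self, leg: int) -> pd.Series:
        return self.bias_labels[f"leg{leg}"]

    def to_json(self, path) -> None:
        payload = {
            "bias_labels": {
                col: self.bias_labels[col].to_dict() for col in self.bias_labels
            },
            "leg_bias": self.leg_bias.to_dict(),
            "regions": self.regions,
            "clusters": self.clusters,
            "x_scaffold": self.x_scaffold,
            "dnds_category": (
                None if self.dnds_category is None else self.dnds_category.to_dict()
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        bias = pd.DataFrame(payload["bias_labels"])
        bias.index.name = "gene_id"
        dnds = payload.get("dnds_category")
        return cls(
            bias_labels=bias,
            leg_bias=pd.Series(payload["leg_bias"], name="leg_bias"),
            regions=payload["regions"],
            clusters=payload["clusters"],
            x_scaffold=payload["x_scaffold"],
            dnds_category=None if dnds is None else pd.Series(dnds, name="category"),
        )


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Place genes along each scaffold with exponential inter-gene gaps.

    Returns a DataFrame (gene_id, scaffold, start, end, strand) in 0-based
    half-open coordinates, sorted by (scaffold, start).  Gaps are drawn from
    an exponential around the configured mean spacing with a hard 1 kb
    minimum; genes never overlap and never extend past the scaffold end.
    """
    rng = config.rng(_STAGE_ANNOTATION)
    lengths = config.resolved_scaffold_lengths()
    names = config.scaffold_names()
    # mean inter-start distance ~= gene length + gap, so shrink the gap mean
    gap_mean = max(
        float(config.min_gene_spacing),
        config.mean_gene_spacing - config.mean_gene_length,
    )
    rows: list[tuple[str, str, int, int, str]] = []
    for scaffold, length in zip(names, lengths):
        if config.mean_gene_spacing >= length:
            logger.warning(
                "mean gene spacing %d >= scaffold %s length %d; scaffold left empty",
                config.mean_gene_spacing, scaffold, length,
            )
            continue
        pos = 0
        idx = 0
        while True:
            gap = max(config.min_gene_spacing, int(rng.exponential(gap_mean)))
            start = pos + gap
            gene_len = max(200, int(rng.gamma(4.0, config.mean_gene_length / 4.0)))
            end = start + gene_len
            if end > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"{scaffold}_g{idx + 1:04d}", scaffold, start, end, strand))
            pos = end
            idx += 1
    ann = pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])
    return ann.sort_values(["scaffold", "start"], kind="mergesort").reset_index(drop=True)


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for line in config.lines:
        for sex in SEXES:
            for leg in LEGS:
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{line}_{sex}_leg{leg}_r{rep}",
                            "sex": sex,
                            "leg": leg,
                            "line": line,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def _draw_biased_labels(
    rng: np.random.Generator,
    ann: pd.DataFrame,
    config: SimulationConfig,
    eligible: np.ndarray,
) -> pd.DataFrame:
    """Fraction-driven per-leg bias labels with X feminization weighting.

    Exactly round(frac * n_genes) genes get each label per leg; on feminized
    legs the female draw up-weights X genes by the feminization factor while
    keeping the total count fixed.
    """
    n_genes = len(ann)
    on_x = (ann["scaffold"] == config.x_scaffold).to_numpy()
    labels = pd.DataFrame(
        "unbiased", index=ann["gene_id"], columns=[f"leg{leg}" for leg in LEGS]
    )
    for leg in LEGS:
        n_male = round(config.frac_male_biased.get(leg, 0.0) * n_genes)
        n_female = round(config.frac_female_biased.get(leg, 0.0) * n_genes)
        pool = np.flatnonzero(eligible)
        male_idx = rng.choice(pool, size=n_male, replace=False)
        remaining = np.setdiff1d(pool, male_idx, assume_unique=False)
        weights = np.ones(len(remaining))
        if leg in config.x_feminized_legs and config.x_feminization_factor != 1.0:
            weights[on_x[remaining]] = config.x_feminization_factor
        weights /= weights.sum()
        female_idx = rng.choice(remaining, size=n_female, replace=False, p=weights)
        col = labels.columns[leg - 1]
        labels.iloc[male_idx, labels.columns.get_loc(col)] = "male"
        labels.iloc[female_idx, labels.columns.get_loc(col)] = "female"
    return labels


def generate_counts(
    annotation: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Negative-binomial counts for the full design, plus the truth record.

    A gene planted male-biased in leg L has its expected expression
    multiplied by 2**effect in male leg-L libraries (female-biased genes
    symmetric).  X genes are dosage-compensated (equal expectation in both
    sexes) unless ``x_male_downshift_log2fc`` is set.  Leg-biased genes are
    upshifted in third-leg libraries of both sexes; line-effect genes are
    upshifted in every library of the first line.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    if config.n_replicates < 2:
        raise ValueError("need >= 2 replicates per design cell for resampling")
    rng = config.rng(_STAGE_COUNTS)
    samples = make_sample_sheet(config)
    n_genes = len(annotation)
    n_samples = len(samples)
    gene_ids = annotation["gene_id"].to_numpy()
    scaffold = annotation["scaffold"].to_numpy()

    # planted regions/clusters claim genes first; fraction labels avoid them
    region_records: list[dict] = []
    cluster_records: list[dict] = []
    planted_mask = np.zeros(n_genes, dtype=bool)
    forced: dict[int, tuple[str, float]] = {}  # gene index -> (direction, effect)
    names = config.scaffold_names()
    mid = ((annotation["start"] + annotation["end"]) // 2).to_numpy()
    for region in config.planted_regions:
        sc = names[region.scaffold_index]
        in_region = np.flatnonzero(
            (scaffold == sc) & (mid >= region.start) & (mid < region.end)
        )
        if len(in_region) < region.n_genes:
            raise ValueError(
                f"planted region on {sc} holds {len(in_region)} genes, "
                f"needs {region.n_genes}"
            )
        chosen = rng.choice(in_region, size=region.n_genes, replace=False)
        for g in chosen:
            forced[int(g)] = (region.direction, region.effect_log2fc)
        planted_mask[chosen] = True
        region_records.append(
            {
                "scaffold": sc,
                "start": int(region.start),
                "end": int(region.end),
                "direction": region.direction,
                "effect_log2fc": region.effect_log2fc,
                "gene_ids": [str(gene_ids[g]) for g in sorted(chosen)],
            }
        )
    for cl in config.planted_clusters:
        sc = names[cl.scaffold_index]
        sc_idx = np.flatnonzero(scaffold == sc)
        if cl.start_gene_index + cl.size > len(sc_idx):
            raise ValueError(f"planted cluster {cl} beyond gene count of {sc}")
        members = sc_idx[cl.start_gene_index : cl.start_gene_index + cl.size]
        if planted_mask[members].any():
            raise ValueError(f"planted cluster {cl} collides with another planting")
        for g in members:
            forced[int(g)] = (cl.direction, config.effect_log2fc)
        planted_mask[members] = True
        cluster_records.append(
            {
                "scaffold": sc,
                "start_gene_index": int(cl.start_gene_index),
                "size": int(cl.size),
                "direction": cl.direction,
                "gene_ids": [str(gene_ids[g]) for g in members],
            }
        )

    labels = _draw_biased_labels(rng, annotation, config, eligible=~planted_mask)
    for g, (direction, _eff) in forced.items():
        labels.iloc[g, :] = direction

    # leg-biased genes (first vs third legs, both sexes), drawn independently
    n_leg_biased = round(config.frac_leg_biased * n_genes)
    leg_idx = rng.choice(n_genes, size=n_leg_biased, replace=False)
    leg_bias = pd.Series("none", index=annotation["gene_id"], name="leg_bias")
    leg_bias.iloc[leg_idx] = "leg3"

    # line-effect genes
    n_line = round(config.frac_line_effect * n_genes)
    line_idx = rng.choice(n_genes, size=n_line, replace=False)

    baseline = rng.lognormal(config.nb_mean_log, config.nb_mean_sd, size=n_genes)
    libsize = rng.lognormal(0.0, config.libsize_sd, size=n_samples)

    log2_shift = np.zeros((n_genes, n_samples))
    sex = samples["sex"].to_numpy()
    leg = samples["leg"].to_numpy()
    line = samples["line"].to_numpy()
    for li, leg_no in enumerate(LEGS):
        col = labels[f"leg{leg_no}"].to_numpy()
        male_genes = col == "male"
        female_genes = col == "female"
        effects = np.full(n_genes, config.effect_log2fc)
        for g, (_d, eff) in forced.items():
            effects[g] = eff
        m_cols = (sex == "M") & (leg == leg_no)
        f_cols = (sex == "F") & (leg == leg_no)
        log2_shift[np.ix_(male_genes, m_cols)] += effects[male_genes, None]
        log2_shift[np.ix_(female_genes, f_cols)] += effects[female_genes, None]
    log2_shift[np.ix_(leg_bias.to_numpy() == "leg3", leg == 3)] += config.leg_effect_log2fc
    log2_shift[np.ix_(np.isin(np.arange(n_genes), line_idx), line == config.lines[0])] += (
        config.line_effect_log2fc
    )
    if config.x_male_downshift_log2fc:
        on_x = scaffold == config.x_scaffold
        log2_shift[np.ix_(on_x, sex == "M")] -= config.x_male_downshift_log2fc
    if config.include_y_like:
        # Y-like scaffold: expressed genes exclusively male-biased
        on_y = scaffold == config.y_like_scaffold
        labels.loc[pd.Index(gene_ids[on_y]), :] = "male"
        log2_shift[np.ix_(on_y, sex == "M")] += config.effect_log2fc
        log2_shift[np.ix_(on_y, sex == "F")] -= 0.0

    mu = baseline[:, None] * libsize[None, :] * np.exp2(log2_shift)
    disp = config.nb_dispersion
    n_param = 1.0 / disp
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples["sample_id"]
    )
    truth = TruthSet(
        bias_labels=labels,
        leg_bias=leg_bias,
        regions=region_records,
        clusters=cluster_records,
        x_scaffold=config.x_scaffold,
    )
    return counts_df, samples, truth


def generate_coverage(annotation: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Male genomic coverage per scaffold: Poisson window depths averaged.

    Autosomes get expectation D; the X (hemizygous in males) gets D/2, as
    does the optional Y-like scaffold.
    """
    if not 0 <= config.x_scaffold_index < len(config.scaffold_names()):
        raise ValueError("x_scaffold_index out of range")
    rng = config.rng(_STAGE_COVERAGE)
    rows = []
    for scaffold, length in zip(config.scaffold_names(), config.resolved_scaffold_lengths()):
        half = scaffold == config.x_scaffold or (
            config.include_y_like and scaffold == config.y_like_scaffold
        )
        depth = config.coverage_depth / 2.0 if half else config.coverage_depth
        n_windows = max(1, length // config.coverage_window)
        mean_depth = float(rng.poisson(depth, size=n_windows).mean())
        rows.append({"scaffold": scaffold, "length": length, "mean_depth": mean_depth})
    return pd.DataFrame(rows)


def generate_dnds(
    config: SimulationConfig, gene_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene per-species dN/dS from category gammas plus category labels.

    Exactly ``dnds_n_male`` and ``dnds_n_female`` genes are drawn without
    replacement into the biased categories; the rest are unbiased.
    """
    for cat, (shape, scale) in config.dnds_gamma.items():
        if shape <= 0 or scale <= 0:
            raise ValueError(f"gamma parameters for {cat} must be positive")
    n = len(gene_ids)
    if config.dnds_n_male + config.dnds_n_female > n:
        raise ValueError("requested category sizes exceed gene count")
    rng = config.rng(_STAGE_DNDS)
    perm = rng.permutation(n)
    category = np.full(n, "unbiased", dtype=object)
    category[perm[: config.dnds_n_male]] = "male"
    category[perm[config.dnds_n_male : config.dnds_n_male + config.dnds_n_female]] = "female"
    labels = pd.Series(category, index=pd.Index(gene_ids, name="gene_id"), name="category")

    rows = []
    for species in config.dnds_species:
        ratio = np.empty(n)
        for cat, (shape, scale) in config.dnds_gamma.items():
            mask = category == cat
            ratio[mask] = rng.gamma(shape, scale, size=int(mask.sum()))
        ds = rng.gamma(2.0, 0.5, size=n) + 0.05
        dn = ratio * ds
        rows.append(
            pd.DataFrame(
                {"gene_id": list(gene_ids), "species": species, "dN": dn, "dS": ds}
            )
        )
    records = pd.concat(rows, ignore_index=True)
    records["ratio"] = records["dN"] / records["dS"]
    return records, labels


def generate_all(config: SimulationConfig):
    """Run every generator stage; returns (annotation, counts, samples,
    coverage, dnds, truth)."""
    ann = generate_annotation(config)
    counts, samples, truth = generate_counts(ann, config)
    coverage = generate_coverage(ann, config)
    dnds, dnds_labels = generate_dnds(config, ann["gene_id"].tolist())
    truth.dnds_category = dnds_labels
    return ann, counts, samples, coverage, dnds, truth
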