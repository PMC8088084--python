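"""End-to-end orchestration: synthesize/load, analyse, report.

Stages run in a fixed order, each reading only the files written by
earlier stages into the output directory, so any suffix of the pipeline
can be re-run.  A manifest (config echo, seed, per-stage status/runtime,
output checksums) is written even when a stage fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_io
from . import chromosome as chrom
from . import clusters as clus
from . import expression as expr
from . import molevol
from . import regions as reg
from . import report as report_mod
from .synthetic import SimulationConfig, TruthSet, generate_all

logger = logging.getLogger(__name__)

STAGES = (
    "synthesize",
    "abundance",
    "filter",
    "de",
    "bias_calls",
    "summaries",
    "chromosome",
    "regions",
    "clusters",
    "dnds",
)


@dataclass
class PipelineConfig:
    outdir: str = "sexarch_out"
    seed: int = 0
    synthetic: bool = True
    sim: SimulationConfig | None = None
    # file-mode inputs
    annotation_path: str | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    coverage_path: str | None = None
    dnds_path: str | None = None
    de_paths: dict[str, str] = field(default_factory=dict)  # optional external DE
    # analysis configs
    filter_cfg: expr.ExpressionFilterConfig = field(default_factory=expr.ExpressionFilterConfig)
    bias_cfg: expr.BiasCallConfig = field(default_factory=expr.BiasCallConfig)
    region_cfg: reg.RegionScanConfig = field(default_factory=reg.RegionScanConfig)
    cluster_cfg: clus.ClusterNullConfig = field(default_factory=clus.ClusterNullConfig)
    dnds_cfg: molevol.DndsBootstrapConfig = field(default_factory=molevol.DndsBootstrapConfig)
    region_legs: tuple[int, ...] = (1, 2, 3)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.synthetic and self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)
        # analysis seeds follow the global seed unless set explicitly
        if self.region_cfg.seed == 0:
            self.region_cfg.seed = self.seed
        if self.cluster_cfg.seed == 0:
            self.cluster_cfg.seed = self.seed
        if self.dnds_cfg.seed == 0:
            self.dnds_cfg.seed = self.seed

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("annotation_path", "counts_path", "samples_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name} missing or does not exist: {path}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim_raw = raw.pop("sim", None)
        kwargs = {}
        nested = {
            "filter_cfg": expr.ExpressionFilterConfig,
            "bias_cfg": expr.BiasCallConfig,
            "region_cfg": reg.RegionScanConfig,
            "cluster_cfg": clus.ClusterNullConfig,
            "dnds_cfg": molevol.DndsBootstrapConfig,
        }
        for key, val in raw.items():
            if key in nested and isinstance(val, dict):
                kwargs[key] = nested[key](**val)
            elif key == "region_legs" and isinstance(val, list):
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        if sim_raw is not None:
            from .synthetic import PlantedCluster, PlantedRegion

            if "planted_regions" in sim_raw:
                sim_raw["planted_regions"] = tuple(
                    PlantedRegion(**r) if isinstance(r, dict) else r
                    for r in sim_raw["planted_regions"]
                )
            if "planted_clusters" in sim_raw:
                sim_raw["planted_clusters"] = tuple(
                    PlantedCluster(**c) if isinstance(c, dict) else c
                    for c in sim_raw["planted_clusters"]
                )
            for key in ("frac_male_biased", "frac_female_biased"):
                if key in sim_raw:
                    sim_raw[key] = {int(k): v for k, v in sim_raw[key].items()}
            kwargs["sim"] = SimulationConfig(**sim_raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


class PipelineRun:
    """Holds paths and intermediate loading for one output directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        return self.outdir / name

    # ---- loading helpers (each stage reads upstream files only) ----
    def load_annotation(self) -> pd.DataFrame:
        return ann_io.read_annotation(self.path("annotation.gff3"))

    def load_counts(self) -> pd.DataFrame:
        return pd.read_csv(self.path("counts.tsv"), sep="\t", index_col=0)

    def load_samples(self) -> pd.DataFrame:
        return pd.read_csv(self.path("samples.tsv"), sep="\t")

    def load_fpkm(self) -> pd.DataFrame:
        return pd.read_csv(self.path("fpkm.tsv"), sep="\t", index_col=0)

    def load_expressed(self) -> dict[int, set[str]]:
        with open(self.path("expressed.json")) as fh:
            raw = json.load(fh)
        return {int(k): set(v) for k, v in raw.items()}

    def load_de(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.path(f"de_{name}.tsv"), sep="\t")

    def load_calls(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.path(f"calls_{name}.tsv"), sep="\t")

    def load_coverage(self) -> pd.DataFrame:
        return pd.read_csv(self.path("coverage.tsv"), sep="\t")

    def scaffold_lengths(self) -> pd.Series:
        cov = self.path("coverage.tsv")
        if cov.exists():
            df = self.load_coverage()
            return df.set_index("scaffold")["length"]
        return ann_io.scaffold_lengths(self.load_annotation())


# ---------------- stages ----------------

def stage_synthesize(run: PipelineRun) -> None:
    cfg = run.cfg
    if cfg.synthetic:
        ann, counts, samples, coverage, dnds, truth = generate_all(cfg.sim)
        truth.to_json(run.path("truth.json"))
        dnds = dnds.merge(
            truth.dnds_category.rename("category"), left_on="gene_id", right_index=True
        )
    else:
        ann = ann_io.read_annotation(cfg.annotation_path)
        counts = pd.read_csv(cfg.counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(cfg.samples_path, sep="\t")
        coverage = (
            pd.read_csv(cfg.coverage_path, sep="\t") if cfg.coverage_path else None
        )
        dnds = pd.read_csv(cfg.dnds_path, sep="\t") if cfg.dnds_path else None
    ann_io.write_gff3(ann, run.path("annotation.gff3"))
    ann_io.write_bed6(ann, run.path("annotation.bed"))
    _write_tsv(counts, run.path("counts.tsv"), index=True)
    _write_tsv(samples, run.path("samples.tsv"))
    if coverage is not None:
        _write_tsv(coverage, run.path("coverage.tsv"))
    if dnds is not None:
        _write_tsv(dnds, run.path("dnds.tsv"))


def stage_abundance(run: PipelineRun) -> None:
    ann = run.load_annotation()
    counts = run.load_counts()
    ab = expr.compute_abundance(counts, ann_io.gene_lengths(ann))
    _write_tsv(ab.fpkm, run.path("fpkm.tsv"), index=True)
    _write_tsv(ab.tpm, run.path("tpm.tsv"), index=True)


def stage_filter(run: PipelineRun) -> None:
    fpkm = run.load_fpkm()
    samples = run.load_samples()
    expressed = expr.filter_expressed(fpkm, samples, run.cfg.filter_cfg)
    with open(run.path("expressed.json"), "w") as fh:
        json.dump({str(k): sorted(v) for k, v in expressed.items()}, fh, indent=1)


def stage_de(run: PipelineRun) -> None:
    counts = run.load_counts()
    samples = run.load_samples()
    sf = expr.size_factors(counts)
    for leg in (1, 2, 3):
        name = f"sex_leg{leg}"
        if name in run.cfg.de_paths:
            de = pd.read_csv(run.cfg.de_paths[name], sep="\t")
        else:
            de = expr.run_de_standin(counts, samples, ("sex", leg), sf=sf)
        _write_tsv(de, run.path(f"de_{name}.tsv"))
    for sex in ("M", "F"):
        name = f"leg3v1_{sex}"
        if name in run.cfg.de_paths:
            de = pd.read_csv(run.cfg.de_paths[name], sep="\t")
        else:
            de = expr.run_de_standin(counts, samples, ("leg", sex), sf=sf)
        _write_tsv(de, run.path(f"de_{name}.tsv"))


def stage_bias_calls(run: PipelineRun) -> None:
    expressed = run.load_expressed()
    for leg in (1, 2, 3):
        de = run.load_de(f"sex_leg{leg}")
        calls = expr.call_sex_bias(de, expressed[leg], run.cfg.bias_cfg, leg=leg)
        calls = expr.reassign_log2fc(calls)
        _write_tsv(calls, run.path(f"calls_sex_leg{leg}.tsv"))
    # leg contrasts share the third-leg expressed universe (the tissue of
    # interest for the crosstalk test); relabel to leg3/leg1 directions
    for sex in ("M", "F"):
        de = run.load_de(f"leg3v1_{sex}")
        calls = expr.call_sex_bias(de, expressed[3], run.cfg.bias_cfg, leg=0)
        calls["label"] = calls["label"].map(
            {"male": "leg3", "female": "leg1"}
        ).fillna(calls["label"])
        calls = calls.rename(columns={"leg": "contrast"})
        calls["contrast"] = f"leg3v1_{sex}"
        _write_tsv(calls, run.path(f"calls_leg3v1_{sex}.tsv"))


def stage_summaries(run: PipelineRun) -> None:
    calls_by_leg = {leg: run.load_calls(f"sex_leg{leg}") for leg in (1, 2, 3)}
    summary = expr.summarize_bias(calls_by_leg)
    _write_tsv(summary, run.path("bias_summary.tsv"))
    overlap = {}
    for direction in ("male", "female"):
        sets = {
            leg: set(c.loc[c["label"] == direction, "gene_id"])
            for leg, c in calls_by_leg.items()
        }
        overlap[direction] = {
            k: sorted(v) for k, v in expr.bias_overlap(sets).items()
        }
    with open(run.path("overlap.json"), "w") as fh:
        json.dump(overlap, fh, indent=1)
    magnitude = {}
    for direction in ("male", "female"):
        for a, b in ((1, 3), (2, 3), (1, 2)):
            try:
                stat, p = expr.compare_bias_magnitude(
                    calls_by_leg[a], calls_by_leg[b], direction
                )
                magnitude[f"{direction}_leg{a}_vs_leg{b}"] = {"statistic": stat, "p": p}
            except ValueError:
                magnitude[f"{direction}_leg{a}_vs_leg{b}"] = None
    with open(run.path("magnitude.json"), "w") as fh:
        json.dump(magnitude, fh, indent=1)


def stage_chromosome(run: PipelineRun) -> None:
    ann = run.load_annotation()
    samples = run.load_samples()
    fpkm = run.load_fpkm()
    calls_by_leg = {leg: run.load_calls(f"sex_leg{leg}") for leg in (1, 2, 3)}
    out: dict = {"x_scaffold": None, "coverage_ratio": None, "y_candidates": [],
                 "dosage_p_by_leg": {}, "fisher_by_leg": {}, "crosstalk": []}
    cov_path = run.path("coverage.tsv")
    x_id = None
    if cov_path.exists():
        coverage = run.load_coverage()
        assignment = chrom.identify_x(coverage)
        out["x_scaffold"] = assignment.x_scaffold_id
        out["coverage_ratio"] = assignment.coverage_ratio
        x_id = assignment.x_scaffold_id
        if x_id is not None:
            out["y_candidates"] = chrom.scan_y_candidates(
                coverage, calls_by_leg, ann, x_id
            )
    if x_id is not None:
        autosomes = chrom.autosome_ids(ann, x_id, scaffold_lengths=run.scaffold_lengths())
        for leg in (1, 2, 3):
            _, p, _n = chrom.test_dosage_compensation(fpkm, ann, samples, x_id, leg)
            out["dosage_p_by_leg"][str(leg)] = None if np.isnan(p) else float(p)
            cell = {}
            for direction in ("male", "female"):
                res = chrom.fisher_x_enrichment(
                    calls_by_leg[leg], ann, x_id, direction, autosomes=autosomes
                )
                cell[f"{direction}_p"] = float(res.pvalue)
                cell[f"{direction}_or"] = (
                    None if res.undefined_or or not np.isfinite(res.odds_ratio)
                    else float(res.odds_ratio)
                )
            out["fisher_by_leg"][str(leg)] = cell
    for sex, sex_direction in (("M", "male"), ("F", "female")):
        leg_calls = run.load_calls(f"leg3v1_{sex}")
        try:
            res = chrom.crosstalk_enrichment(
                calls_by_leg[3], leg_calls, sex_direction=sex_direction,
                leg_direction="leg3",
            )
            out["crosstalk"].append(
                {
                    "leg": 3,
                    "sex_direction": sex_direction,
                    "overlap_count": res.overlap_count,
                    "n_sex_biased": res.n_sex_biased,
                    "overlap_pct": res.overlap_pct,
                    "pvalue": float(res.fisher.pvalue),
                }
            )
        except ValueError as exc:
            logger.warning("crosstalk skipped (%s)", exc)
    with open(run.path("chromosome.json"), "w") as fh:
        json.dump(out, fh, indent=1)


def stage_regions(run: PipelineRun) -> None:
    ann = run.load_annotation()
    lengths = run.scaffold_lengths()
    cfg = run.cfg.region_cfg
    bin_map = reg.assign_bins(ann, cfg, scaffold_lengths=lengths)
    total_length = int(lengths.sum())
    all_regions = []
    for leg in run.cfg.region_legs:
        calls = run.load_calls(f"sex_leg{leg}")
        de = run.load_de(f"sex_leg{leg}")
        values = calls.set_index("gene_id")["reassigned_log2fc"]
        base = de.set_index("gene_id")["baseMean"].copy()
        unexpressed = calls.loc[calls["label"] == "unexpressed", "gene_id"]
        base.loc[base.index.isin(unexpressed)] = 0.0
        strata = reg.build_strata(base, cfg.n_strata)
        windows = reg.compute_window_means(values, bin_map, lengths, cfg)
        null = reg.permute_profiles(values, strata, bin_map, lengths, cfg)
        called = reg.call_enriched_windows(windows, null, cfg, total_length=total_length)
        _write_tsv(called, run.path(f"windows_leg{leg}.tsv"))
        labels = calls.set_index("gene_id")["label"]
        merged = reg.merge_regions(called, labels=labels, annotation=ann)
        merged["leg"] = leg
        _write_tsv(merged, run.path(f"regions_leg{leg}.tsv"))
        with open(run.path(f"regions_leg{leg}.bed"), "w") as fh:
            for _, r in merged.iterrows():
                fh.write(f"{r['scaffold']}\t{r['start']}\t{r['end']}\t{r['direction']}\n")
        all_regions.append(merged)
    meta = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "configured_alpha": 1 - cfg.quantile_cutoff,
        "n_independent": max(1, total_length // cfg.window_span),
    }
    with open(run.path("regions.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def _thirteen_largest(lengths: pd.Series, n: int = 13) -> list[str]:
    return list(lengths.sort_values(ascending=False).index[:n])


def stage_clusters(run: PipelineRun) -> None:
    ann = run.load_annotation()
    lengths = run.scaffold_lengths()
    keep = set(_thirteen_largest(lengths))
    cfg = run.cfg.cluster_cfg
    results = {}
    for leg in (1, 2, 3):
        calls = run.load_calls(f"sex_leg{leg}")
        labels = calls.set_index("gene_id")["label"]
        order = ann[ann["scaffold"].isin(keep)][["scaffold", "gene_id", "start"]].copy()
        order["label"] = order["gene_id"].map(labels).fillna("unbiased")
        if cfg.universe == "expressed_genes":
            order = order[order["label"] != "unexpressed"]
        order = order.sort_values(["scaffold", "start"]).reset_index(drop=True)
        records = clus.find_clusters(order)
        _write_tsv(records, run.path(f"clusters_leg{leg}.tsv"))
        n_biased = {
            d: int((order["label"] == d).sum()) for d in ("male", "female")
        }
        observed = clus.cluster_summary(records, n_biased)
        sizes = order.groupby("scaffold").size().tolist()
        null = clus.cluster_null(sizes, n_biased, cfg)
        flags = clus.test_cluster_enrichment(observed, null)
        results[str(leg)] = {
            "observed_proportion": {
                d: (None if np.isnan(observed.proportion[d]) else observed.proportion[d])
                for d in ("male", "female")
            },
            "null_mean": null.mean_proportion,
            "interval": {d: list(null.interval_proportion[d]) for d in ("male", "female")},
            "flags": flags.to_dict(orient="records"),
            "n_biased": n_biased,
            "seed": cfg.seed,
        }
    with open(run.path("clusters.json"), "w") as fh:
        json.dump(results, fh, indent=1)


def stage_dnds(run: PipelineRun) -> None:
    path = run.path("dnds.tsv")
    if not path.exists():
        logger.info("no dN/dS table; stage skipped")
        with open(run.path("dnds.json"), "w") as fh:
            json.dump({"skipped": True}, fh)
        return
    records = pd.read_csv(path, sep="\t")
    if "category" in records.columns:
        labels = records.drop_duplicates("gene_id").set_index("gene_id")["category"]
    else:
        calls = run.load_calls("sex_leg3")
        labels = calls.set_index("gene_id")["label"].replace("unexpressed", "unbiased")
    cfg = run.cfg.dnds_cfg
    out = {}
    for pair in (("male", "unbiased"), ("female", "unbiased"), ("male", "female")):
        comp = molevol.compare_dnds(records, labels, pair)
        out["_vs_".join(pair)] = {
            "pvalue": comp.pvalue,
            "medians": comp.medians,
            "n": comp.n,
            "n_excluded": comp.n_excluded,
        }
    boot_cfg = molevol.DndsBootstrapConfig(
        n_male=min(cfg.n_male, int((labels == "male").sum()) or cfg.n_male),
        n_female=min(cfg.n_female, int((labels == "female").sum()) or cfg.n_female),
        n_iter=cfg.n_iter,
        quantile=cfg.quantile,
        seed=cfg.seed,
    )
    boot = molevol.label_bootstrap(records, boot_cfg)
    out["bootstrap"] = {
        "cutoff_male": boot.cutoff_male,
        "cutoff_female": boot.cutoff_female,
        "n_iter": boot.n_iter,
        "seed": boot.seed,
        "male_nonrandom": boot.is_nonrandom(out["male_vs_unbiased"]["pvalue"], "male"),
        "female_nonrandom": boot.is_nonrandom(out["female_vs_unbiased"]["pvalue"], "female"),
    }
    with open(run.path("dnds.json"), "w") as fh:
        json.dump(out, fh, indent=1)


_STAGE_FUNCS = {
    "synthesize": stage_synthesize,
    "abundance": stage_abundance,
    "filter": stage_filter,
    "de": stage_de,
    "bias_calls": stage_bias_calls,
    "summaries": stage_summaries,
    "chromosome": stage_chromosome,
    "regions": stage_regions,
    "clusters": stage_clusters,
    "dnds": stage_dnds,
}


def write_report(run: PipelineRun) -> report_mod.RunReport:
    """Consolidate stage outputs into the validated report."""
    summary = pd.read_csv(run.path("bias_summary.tsv"), sep="\t")
    with open(run.path("chromosome.json")) as fh:
        chrom_out = json.load(fh)
    regions_rows = []
    for leg in run.cfg.region_legs:
        p = run.path(f"regions_leg{leg}.tsv")
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            for _, r in df.iterrows():
                regions_rows.append(
                    report_mod.RegionRow(
                        scaffold=r["scaffold"], start=int(r["start"]), end=int(r["end"]),
                        direction=r["direction"], n_windows=int(r["n_windows"]), leg=leg,
                    )
                )
    cluster_rows = []
    cpath = run.path("clusters.json")
    if cpath.exists():
        with open(cpath) as fh:
            craw = json.load(fh)
        for leg, entry in craw.items():
            for d in ("male", "female"):
                sig = any(
                    f["significant"] and f["direction"] == d
                    and f["statistic"] == "clustered_proportion"
                    for f in entry["flags"]
                )
                cluster_rows.append(
                    report_mod.ClusterSection(
                        leg=int(leg), direction=d,
                        observed_proportion=entry["observed_proportion"][d],
                        null_mean=entry["null_mean"][d],
                        interval=tuple(entry["interval"][d]),
                        significant=sig,
                    )
                )
    dnds_rows = []
    dpath = run.path("dnds.json")
    if dpath.exists():
        with open(dpath) as fh:
            draw = json.load(fh)
        if not draw.get("skipped"):
            boot = draw.get("bootstrap", {})
            for pair_key, entry in draw.items():
                if pair_key == "bootstrap":
                    continue
                cut = non = None
                if pair_key == "male_vs_unbiased":
                    cut, non = boot.get("cutoff_male"), boot.get("male_nonrandom")
                elif pair_key == "female_vs_unbiased":
                    cut, non = boot.get("cutoff_female"), boot.get("female_nonrandom")
                dnds_rows.append(
                    report_mod.DndsSection(
                        pair=pair_key, pvalue=entry["pvalue"], medians=entry["medians"],
                        n_excluded=entry["n_excluded"], bootstrap_cutoff=cut, nonrandom=non,
                    )
                )
    report = report_mod.RunReport(
        seed=run.cfg.seed,
        config_hash=run.cfg.config_hash(),
        bias_summary=[
            report_mod.BiasSummaryRow(**row) for row in summary.to_dict(orient="records")
        ],
        crosstalk=[report_mod.CrosstalkSection(**c) for c in chrom_out.get("crosstalk", [])],
        x_chromosome=report_mod.XSection(
            x_scaffold=chrom_out.get("x_scaffold"),
            coverage_ratio=chrom_out.get("coverage_ratio"),
            y_candidates=chrom_out.get("y_candidates", []),
            dosage_p_by_leg=chrom_out.get("dosage_p_by_leg", {}),
            fisher_by_leg=chrom_out.get("fisher_by_leg", {}),
        ),
        regions=regions_rows,
        clusters=cluster_rows,
        dnds=dnds_rows,
    )
    with open(run.path("report.json"), "w") as fh:
        fh.write(report.model_dump_json(indent=1))
    with open(run.path("report.txt"), "w") as fh:
        fh.write(report_mod.render_text(report))
    return report


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write the manifest.

    Returns the manifest dict; raises after recording the failure point if
    any stage errors.
    """
    cfg.validate()
    run = PipelineRun(cfg)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": [],
    }
    failure: Exception | None = None
    for stage in STAGES:
        if stage not in stages:
            continue
        entry = {"name": stage, "status": "pending", "runtime_s": None, "outputs": {}}
        t0 = time.perf_counter()
        try:
            before = set(run.outdir.iterdir())
            _STAGE_FUNCS[stage](run)
            entry["status"] = "complete"
            new_or_touched = [
                p for p in run.outdir.iterdir()
                if p not in before or p.stat().st_mtime >= t0
            ]
            entry["outputs"] = {
                p.name: _sha256(p) for p in sorted(run.outdir.iterdir())
                if p.suffix in (".tsv", ".json", ".gff3", ".bed") and p.name != "manifest.json"
            }
        except Exception as exc:  # record failure point, skip downstream
            entry["status"] = f"failed: {exc}"
            failure = exc
        entry["runtime_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(entry)
        if failure is not None:
            break
    if failure is None and set(STAGES) <= set(stages):
        write_report(run)
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    if failure is not None:
        raise failure
    return manifest
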