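"""Consolidated run report: structure, validation and rendering.

The report is a single JSON document gathering the per-leg bias summary,
chromosome-level results, enriched regions, cluster significance and dN/dS
comparisons.  Its structure is pinned by pydantic models; the JSON schema
exported from them ships with the package (``schemas/report.schema.json``)
for consumers outside Python.
"""

from __future__ import annotations

from pydantic import BaseModel, Field


class BiasSummaryRow(BaseModel):
    leg: int
    n_expressed: int
    n_male_biased: int
    pct_male_biased: float
    n_female_biased: int
    pct_female_biased: float


class XSection(BaseModel):
    x_scaffold: str | None
    coverage_ratio: float | None
    y_candidates: list[str]
    dosage_p_by_leg: dict[str, float | None]
    fisher_by_leg: dict[str, dict[str, float | None]]  # leg -> {male_p, male_or, female_p, female_or}


class CrosstalkSection(BaseModel):
    leg: int
    sex_direction: str
    overlap_count: int
    n_sex_biased: int
    overlap_pct: float
    pvalue: float


class RegionRow(BaseModel):
    scaffold: str
    start: int
    end: int
    direction: str
    n_windows: int
    leg: int


class ClusterSection(BaseModel):
    leg: int
    direction: str
    observed_proportion: float | None
    null_mean: float | None
    interval: tuple[float, float]
    significant: bool


class DndsSection(BaseModel):
    pair: str
    pvalue: float
    medians: dict[str, float]
    n_excluded: int
    bootstrap_cutoff: float | None = None
    nonrandom: bool | None = None


class RunReport(BaseModel):
    seed: int
    config_hash: str
    bias_summary: list[BiasSummaryRow]
    crosstalk: list[CrosstalkSection] = Field(default_factory=list)
    x_chromosome: XSection | None = None
    regions: list[RegionRow] = Field(default_factory=list)
    clusters: list[ClusterSection] = Field(default_factory=list)
    dnds: list[DndsSection] = Field(default_factory=list)


def render_text(report: RunReport) -> str:
    lines = [f"sexarch run (seed {report.seed}, config {report.config_hash[:12]})", ""]
    lines.append("Sex-biased genes per leg:")
    for row in report.bias_summary:
        lines.append(
            f"  leg {row.leg}: {row.n_expressed} expressed; "
            f"{row.n_male_biased} male-biased ({row.pct_male_biased}%), "
            f"{row.n_female_biased} female-biased ({row.pct_female_biased}%)"
        )
    if report.crosstalk:
        lines.append("")
        lines.append("Sex x leg crosstalk:")
        for c in report.crosstalk:
            lines.append(
                f"  leg {c.leg} {c.sex_direction}-biased also leg-biased: "
                f"{c.overlap_count}/{c.n_sex_biased} ({c.overlap_pct}%), p={c.pvalue:.3g}"
            )
    if report.x_chromosome is not None:
        x = report.x_chromosome
        lines.append("")
        lines.append(
            f"X chromosome: {x.x_scaffold or 'unassigned'}"
            + (f" (coverage ratio {x.coverage_ratio:.2f})" if x.coverage_ratio else "")
        )
        if not x.y_candidates:
            lines.append("  no Y candidates found")
    lines.append("")
    if report.regions:
        lines.append(f"Enriched regions ({len(report.regions)}):")
        for r in report.regions:
            lines.append(
                f"  {r.scaffold}:{r.start}-{r.end} {r.direction} (leg {r.leg}, "
                f"{r.n_windows} windows)"
            )
    else:
        lines.append("Enriched regions: none called")
    if report.clusters:
        lines.append("")
        lines.append("Consecutive-gene clusters:")
        for c in report.clusters:
            flag = "SIGNIFICANT" if c.significant else "within null band"
            obs = "nan" if c.observed_proportion is None else f"{c.observed_proportion:.3f}"
            lines.append(
                f"  leg {c.leg} {c.direction}: clustered proportion {obs} "
                f"vs null [{c.interval[0]:.3f}, {c.interval[1]:.3f}] -> {flag}"
            )
    if report.dnds:
        lines.append("")
        lines.append("dN/dS comparisons:")
        for d in report.dnds:
            extra = ""
            if d.bootstrap_cutoff is not None:
                verdict = "non-random" if d.nonrandom else "not distinguishable from random labels"
                extra = f"; bootstrap cutoff {d.bootstrap_cutoff:.4g} -> {verdict}"
            lines.append(f"  {d.pair}: p={d.pvalue:.3g}{extra}")
    return "\n".join(lines) + "\n"
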