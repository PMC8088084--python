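"""Gene annotation I/O.

Internal coordinates are 0-based half-open everywhere in the package; GFF3
(1-based inclusive on disk) is converted at the boundary.  Only GFF3
records of type "gene" are used.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyranges as pr

COLUMNS = ["gene_id", "scaffold", "start", "end", "strand"]


def read_annotation(path, fmt: str | None = None) -> pd.DataFrame:
    """Read GFF3 or BED gene annotation into the internal frame.

    Format is inferred from the extension unless given.  Returns a frame
    with (gene_id, scaffold, start, end, strand) in 0-based half-open
    coordinates, sorted by (scaffold, start).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".gff3": "gff3", ".gff": "gff3", ".bed": "bed"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer annotation format from {path.name}")
    if fmt == "gff3":
        df = pr.read_gff3(str(path)).df  # pyranges converts to 0-based half-open
        df = df[df["Feature"] == "gene"]
        if "ID" not in df.columns:
            raise ValueError(f"{path}: GFF3 gene records lack ID attributes")
        out = pd.DataFrame(
            {
                "gene_id": df["ID"].astype(str),
                "scaffold": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "strand": df["Strand"].astype(str) if "Strand" in df else "+",
            }
        )
    elif fmt == "bed":
        df = pr.read_bed(str(path)).df
        out = pd.DataFrame(
            {
                "gene_id": df["Name"].astype(str),
                "scaffold": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "strand": df["Strand"].astype(str) if "Strand" in df else "+",
            }
        )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    if (out["start"] >= out["end"]).any():
        bad = out[out["start"] >= out["end"]].iloc[0]
        raise ValueError(f"{path}: empty interval for gene {bad['gene_id']}")
    return out.sort_values(["scaffold", "start"], kind="mergesort").reset_index(drop=True)


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write genes as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in annotation.iterrows():
            fh.write(
                f"{row['scaffold']}\tsexarch\tgene\t{row['start'] + 1}\t{row['end']}\t.\t"
                f"{row['strand']}\t.\tID={row['gene_id']}\n"
            )


def write_bed6(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in annotation.iterrows():
            fh.write(
                f"{row['scaffold']}\t{row['start']}\t{row['end']}\t{row['gene_id']}\t0\t"
                f"{row['strand']}\n"
            )


def gene_lengths(annotation: pd.DataFrame) -> pd.Series:
    """Effective gene length = annotated span (bp)."""
    return pd.Series(
        (annotation["end"] - annotation["start"]).to_numpy(),
        index=annotation["gene_id"],
        name="length",
    )


def scaffold_lengths(annotation: pd.DataFrame, known: pd.Series | None = None) -> pd.Series:
    """Scaffold lengths from a coverage/lengths table, else max gene end."""
    if known is not None:
        return known
    return annotation.groupby("scaffold")["end"].max()
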