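"""File formats and coordinate conventions.

All in-memory coordinates are 0-based half-open ``[start, end)``. Conversion
to/from 1-based closed GFF3 happens only here, through pyranges, so that no
other module ever adds or subtracts 1.

Formats handled:

* fragment maps  -> BED (0-based half-open)
* gene models    -> GFF3 (1-based closed, ``gene_id`` / ``gene_biotype``
  attributes)
* occupancy      -> bedGraph, one track file per fusion sample
* count matrices / tables -> TSV with a ``#`` header line naming units and
  the coordinate convention
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyranges as pr


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


FLOAT_FMT = "%.10g"

_BED_COLS = ["chrom", "start", "end", "fragment_id"]
_BEDGRAPH_COLS = ["chrom", "start", "end", "value"]


def _checked_read(path, names, ncols, dtypes, kind):
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < ncols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {ncols} tab-separated "
                    f"fields for {kind}, got {len(parts)}"
                )
            rows.append(parts[:ncols])
    df = pd.DataFrame(rows, columns=names)
    for col, dt in dtypes.items():
        try:
            df[col] = df[col].astype(dt)
        except ValueError as exc:
            raise ParseError(f"{path}: bad {col} column for {kind}: {exc}") from exc
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a BED4 fragment map into (chrom, start, end, fragment_id)."""
    df = _checked_read(path, _BED_COLS, 4,
                       {"start": "int64", "end": "int64"}, "BED")
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"]].index[0]
        raise ParseError(f"{path}: record {bad}: end <= start")
    return df[["fragment_id", "chrom", "start", "end"]]


def write_bed(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end", "fragment_id"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    """Read gene records from GFF3 into 0-based half-open coordinates.

    Returns columns (gene_id, chrom, start, end, strand, biotype).
    """
    g = pr.read_gff3(str(path)).df
    g = g[g["Feature"] == "gene"].copy()
    for col in ("gene_id", "gene_biotype"):
        if col not in g.columns:
            raise ParseError(f"{path}: gene records lack a {col} attribute")
    out = pd.DataFrame(
        {
            "gene_id": g["gene_id"].astype(str),
            "chrom": g["Chromosome"].astype(str),
            "start": g["Start"].astype("int64"),
            "end": g["End"].astype("int64"),
            "strand": g["Strand"].astype(str),
            "biotype": g["gene_biotype"].astype(str),
        }
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gff3(genes: pd.DataFrame, path) -> None:
    g = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": genes["chrom"],
                "Start": genes["start"],
                "End": genes["end"],
                "Strand": genes["strand"],
                "Feature": "gene",
                "gene_id": genes["gene_id"],
                "gene_biotype": genes["biotype"],
            }
        )
    )
    g.to_gff3(str(path))


def read_bedgraph(path) -> pd.DataFrame:
    df = _checked_read(path, _BEDGRAPH_COLS, 4,
                       {"start": "int64", "end": "int64", "value": "float64"},
                       "bedGraph")
    return df


def write_bedgraph(df: pd.DataFrame, path, track_name: str | None = None) -> None:
    """Write (chrom, start, end, value); 0-based half-open."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        df[["chrom", "start", "end", "value"]].to_csv(
            fh, sep="\t", header=False, index=False, float_format=FLOAT_FMT
        )


def write_table(df: pd.DataFrame, path, comment: str | None = None,
                index: bool = False) -> None:
    """Write a TSV with an optional leading ``#`` header naming units."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_tsv_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a count matrix TSV written by :func:`write_count_matrix`.

    Returns (fragments, counts) with counts indexed by fragment_id.
    """
    df = read_table(path)
    meta_cols = ["fragment_id", "chrom", "start", "end"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: count matrix lacks columns {missing}")
    fragments = df[meta_cols].copy()
    counts = df.drop(columns=["chrom", "start", "end"]).set_index("fragment_id")
    return fragments, counts


def write_count_matrix(fragments: pd.DataFrame, counts: pd.DataFrame, path) -> None:
    merged = fragments[["fragment_id", "chrom", "start", "end"]].merge(
        counts, left_on="fragment_id", right_index=True
    )
    write_table(
        merged, path,
        comment="raw reads per GATC fragment; coordinates 0-based half-open",
    )
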