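"""Readers and writers for the plain-text formats the pipeline touches.

bedGraph coverage tracks (0-based half-open), BED6/GFF3 gene annotations,
TSV tables, and TIFF image stacks.  Track identity (sample, fraction,
genome, strand) is carried in a file-naming convention because bedGraph has
no strand field: ``<sample>.<fraction>.<genome>.<strand>.bedgraph``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .drip import StrandedCoverage

logger = logging.getLogger(__name__)

_BEDGRAPH_COLS = ["chrom", "start", "end", "count"]


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph into a sorted, validated bin table.

    Intervals must be 0-based half-open, sorted within each chromosome, and
    non-overlapping; violations raise with the offending line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end} "
                    "(coordinates must be 0-based half-open)"
                )
            rows.append((chrom, start, end, float(value)))
    if not rows:
        logger.warning("empty bedGraph: %s", path)
        return pd.DataFrame(columns=_BEDGRAPH_COLS)
    df = pd.DataFrame(rows, columns=_BEDGRAPH_COLS)
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        bad = np.flatnonzero((np.diff(starts) <= 0) | (ends[:-1] > starts[1:]))
        if bad.size:
            raise ValueError(
                f"{path}: overlapping or unsorted intervals on {chrom} "
                f"near record {int(bad[0]) + 2}"
            )
    return df


def write_bedgraph(bins: pd.DataFrame, path) -> None:
    bins[_BEDGRAPH_COLS].to_csv(path, sep="\t", header=False, index=False)


def track_filename(sample_id: str, fraction: str, genome: str, strand: str) -> str:
    return f"{sample_id}.{fraction}.{genome}.{strand}.bedgraph"


def write_coverage(cov: StrandedCoverage, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / track_filename(cov.sample_id, cov.fraction, cov.genome, cov.strand)
    write_bedgraph(cov.bins, path)
    return path


def read_coverage(path, condition: str = "", treatment: str = "") -> StrandedCoverage:
    """Read a coverage track, parsing identity from the naming convention."""
    path = Path(path)
    parts = path.name.split(".")
    if len(parts) != 5 or parts[-1] != "bedgraph":
        raise ValueError(
            f"{path.name}: expected <sample>.<fraction>.<genome>.<strand>.bedgraph"
        )
    sample_id, fraction, genome, strand = parts[:4]
    return StrandedCoverage(
        sample_id=sample_id, condition=condition, treatment=treatment,
        fraction=fraction, genome=genome, strand=strand, bins=read_bedgraph(path),
    )


_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand"]


def read_genes(path) -> pd.DataFrame:
    """Read gene models from BED6 or GFF3 into 0-based half-open coordinates.

    GFF3's 1-based inclusive starts are converted (start - 1).  Strand is
    mandatory; duplicate gene ids are an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _read_gff3(path)
    else:
        genes = _read_bed6(path)
    dups = genes["gene_id"][genes["gene_id"].duplicated()]
    if not dups.empty:
        raise ValueError(f"duplicate gene ids: {sorted(dups.unique())}")
    if (genes["start"] >= genes["end"]).any():
        raise ValueError("gene with start >= end")
    return genes.reset_index(drop=True)


def _read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id", "score", "strand"])
    if df["strand"].isna().any() or (~df["strand"].isin(["+", "-"])).any():
        raise ValueError(f"{path}: BED6 strand column missing or invalid")
    return df[_GENE_COLS]


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, _type, start, end, _score, strand, _phase, attrs = parts
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand missing or invalid")
            gene_id = None
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    if k in ("ID", "gene_id", "Name"):
                        gene_id = v
                        break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: no ID attribute")
            rows.append((gene_id, chrom, int(start) - 1, int(end), strand))
    return pd.DataFrame(rows, columns=_GENE_COLS)


def write_genes_bed6(genes: pd.DataFrame, path) -> None:
    out = genes[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_stack_tiff(channels: dict, path) -> None:
    """Write channels as a multi-series TIFF (one series per channel)."""
    with tifffile.TiffWriter(path) as tif:
        for name, arr in channels.items():
            tif.write(np.asarray(arr, dtype=np.float32),
                      metadata={"channel": name})


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
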