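"""Readers and writers for the text formats the pipeline speaks.

Supported inputs are the two Bismark per-cytosine dialects:

* cytosine report: ``chrom  pos  strand  count_meth  count_unmeth  context
  trinucleotide`` (1-based positions; one row per cytosine, all contexts);
* coverage file: ``chrom  start  end  pct_meth  count_meth  count_unmeth``
  (1-based start == end for single cytosines; CpG-only by construction).

Only CG-context rows are retained from cytosine reports. All coordinates
stay 1-based in memory.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import SampleDesign, make_sites

_CYTOSINE_COLS = ["contig", "pos", "strand", "meth", "unmeth", "context", "tri"]
_COVERAGE_COLS = ["contig", "start", "end", "pct", "meth", "unmeth"]


def read_cytosine_report(path: str | os.PathLike, context: str = "CG") -> pd.DataFrame:
    """Parse one Bismark cytosine report into a count fragment.

    Returns a DataFrame with columns ``contig, pos, strand, meth, unmeth``
    holding only rows of the requested context (default CG). Malformed or
    negative-count rows raise with the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_CYTOSINE_COLS,
            dtype={"contig": str, "strand": str, "context": str, "tri": str},
            comment="#",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse as cytosine report: {exc}") from exc
    for col in ("pos", "meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            line = int(np.flatnonzero(bad | df[col].isna())[0]) + 1
            raise ValueError(f"{path}: malformed numeric field '{col}' at data line {line}")
        df[col] = vals.astype(np.int64)
    neg = (df["meth"] < 0) | (df["unmeth"] < 0)
    if neg.any():
        line = int(np.flatnonzero(neg)[0]) + 1
        raise ValueError(f"{path}: negative count at data line {line}")
    df = df[df["context"] == context]
    return df[["contig", "pos", "strand", "meth", "unmeth"]].reset_index(drop=True)


def read_coverage_file(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a Bismark coverage file; strand is unknown in this dialect ('+')."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=_COVERAGE_COLS,
                     dtype={"contig": str}, comment="#")
    for col in ("start", "meth", "unmeth"):
        if df[col].isna().any() or (pd.to_numeric(df[col], errors="coerce").isna()).any():
            line = int(np.flatnonzero(pd.to_numeric(df[col], errors="coerce").isna())[0]) + 1
            raise ValueError(f"{path}: malformed numeric field '{col}' at data line {line}")
    if ((df["meth"] < 0) | (df["unmeth"] < 0)).any():
        raise ValueError(f"{path}: negative counts")
    return pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": df["start"].astype(np.int64),
            "strand": "+",
            "meth": df["meth"].astype(np.int64),
            "unmeth": df["unmeth"].astype(np.int64),
        }
    )


def write_cytosine_report(fragment: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a count fragment as a CG-context cytosine report (CGN trinucleotide)."""
    out = fragment.copy()
    out["context"] = "CG"
    out["tri"] = "CGN"
    out[["contig", "pos", "strand", "meth", "unmeth", "context", "tri"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_sample_sheet(path: str | os.PathLike) -> SampleDesign:
    """Read a TSV of sample_id, pollutant, treatment, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pollutant": str,
                                            "treatment": str})
    return SampleDesign(df)


def write_sample_sheet(design: SampleDesign, path: str | os.PathLike) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def matrix_fragment(matrix, sample_id: str) -> pd.DataFrame:
    """Extract one sample's covered cells as a count fragment (for writing)."""
    j = matrix.sample_index([sample_id])[0]
    covered = ~np.isnan(matrix.total[:, j])
    sites = matrix.sites.loc[covered].reset_index(drop=True)
    return pd.DataFrame(
        {
            "contig": sites["contig"],
            "pos": sites["pos"],
            "strand": sites["strand"],
            "meth": matrix.meth[covered, j].astype(np.int64),
            "unmeth": (matrix.total[covered, j] - matrix.meth[covered, j]).astype(np.int64),
        }
    )


def write_feature_bed(assignment_table: pd.DataFrame, genes, path: str | os.PathLike) -> None:
    """Write gene feature intervals as BED (0-based half-open conversion here only)."""
    rows = []
    for g in genes:
        for label, iv in g.feature_intervals():
            if iv is None:
                continue
            start, end = iv
            rows.append((g.contig, start - 1, end, f"{g.gene_id}:{label}", 0, g.strand))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]).to_csv(
        path, sep="\t", header=False, index=False
    )
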