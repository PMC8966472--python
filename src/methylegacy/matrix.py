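"""Core containers: CpG site tables, methylome count matrices, sample designs.

A methylome is represented as an ordered table of CpG sites plus two
``(n_sites, n_samples)`` float arrays of methylated and total read counts.
Missing sample-by-site cells (a site not covered in a sample's report, or
masked by a coverage filter) are ``NaN`` in *both* arrays, which keeps
"absent" distinct from "covered by zero methylated reads".

Coordinates are 1-based inclusive throughout, matching the Bismark
cytosine-report and GFF3 dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

POLLUTANTS = ("Cd", "Gly", "Np")
TREATMENTS = ("control", "curtox", "switch")

SITE_COLUMNS = ["contig", "pos", "strand"]


def make_sites(contig, pos, strand) -> pd.DataFrame:
    """Build a canonical site table (contig, pos, strand), 1-based positions."""
    sites = pd.DataFrame(
        {
            "contig": pd.Series(contig, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "strand": pd.Series(strand, dtype=str),
        }
    )
    if (sites["pos"] < 1).any():
        raise ValueError("CpG positions must be >= 1 (1-based coordinates)")
    bad = ~sites["strand"].isin(["+", "-", "both"])
    if bad.any():
        raise ValueError(f"invalid strand values: {sorted(sites['strand'][bad].unique())}")
    if sites.duplicated(SITE_COLUMNS).any():
        raise ValueError("duplicate (contig, pos, strand) sites in methylome")
    return sites


@dataclass
class MethylomeMatrix:
    """Per-CpG, per-sample methylated/total read counts.

    Attributes
    ----------
    sites : pandas.DataFrame
        Ordered site table with columns ``contig``, ``pos``, ``strand``.
    meth, total : numpy.ndarray
        ``(n_sites, n_samples)`` float arrays; NaN marks a missing cell.
    samples : list of str
        Column order of the count arrays.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        n = len(self.sites)
        if self.meth.shape != (n, len(self.samples)) or self.total.shape != self.meth.shape:
            raise ValueError(
                f"count arrays must be (n_sites={n}, n_samples={len(self.samples)}); "
                f"got meth {self.meth.shape}, total {self.total.shape}"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        with np.errstate(invalid="ignore"):
            if np.any(self.meth > self.total) or np.any(self.meth < 0):
                raise ValueError("require 0 <= methylated <= total at every covered cell")
        # NaN-ness must agree between the two arrays
        if np.any(np.isnan(self.meth) != np.isnan(self.total)):
            raise ValueError("meth/total missingness masks disagree")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def subset_sites(self, mask_or_index) -> "MethylomeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MethylomeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            meth=self.meth[idx],
            total=self.total[idx],
            samples=list(self.samples),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylomeMatrix":
        j = self.sample_index(sample_ids)
        return MethylomeMatrix(
            sites=self.sites.copy(),
            meth=self.meth[:, j],
            total=self.total[:, j],
            samples=list(sample_ids),
        )

    def fraction(self) -> np.ndarray:
        """Per-cell methylation fraction; NaN where missing or zero coverage."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.meth / self.total
        return np.where(self.total > 0, f, np.nan)

    def pooled_fraction(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Read-pooled methylation fraction per site over a sample group."""
        j = slice(None) if sample_ids is None else self.sample_index(sample_ids)
        m = np.nansum(self.meth[:, j], axis=1)
        t = np.nansum(self.total[:, j], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, m / t, np.nan)


@dataclass
class SampleDesign:
    """Maps each sample to (pollutant, treatment, replicate).

    Controls are shared across pollutants: they carry pollutant ``water``
    and treatment ``control``. Each pollutant contributes ``curtox``
    (still exposed) and ``switch`` (returned to clean water) replicates.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "pollutant", "treatment", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        bad_t = ~self.table["treatment"].isin(TREATMENTS)
        if bad_t.any():
            raise ValueError(
                f"unknown treatments: {sorted(self.table['treatment'][bad_t].unique())}"
            )
        ctrl = self.table["treatment"] == "control"
        if not (self.table.loc[ctrl, "pollutant"] == "water").all():
            raise ValueError("control samples must have pollutant='water'")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def controls(self) -> list[str]:
        return list(self.table.loc[self.table["treatment"] == "control", "sample_id"])

    def group(self, pollutant: str, treatment: str) -> list[str]:
        if treatment == "control":
            return self.controls()
        sel = (self.table["pollutant"] == pollutant) & (self.table["treatment"] == treatment)
        return list(self.table.loc[sel, "sample_id"])

    def pollutants(self) -> list[str]:
        polls = self.table.loc[self.table["treatment"] != "control", "pollutant"]
        return sorted(polls.unique(), key=lambda p: (POLLUTANTS.index(p) if p in POLLUTANTS else 99, p))


def merge_samples(
    fragments: Mapping[str, pd.DataFrame], design: SampleDesign | None = None
) -> MethylomeMatrix:
    """Union single-sample count fragments into one matrix.

    Each fragment is a DataFrame with columns ``contig, pos, strand, meth,
    unmeth`` (as returned by :func:`methylegacy.io.read_cytosine_report`).
    Sites absent from a sample are missing (NaN), distinct from zero
    coverage.
    """
    ids = list(fragments)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    if design is not None:
        unknown = set(ids) - set(design.sample_ids)
        if unknown:
            raise ValueError(f"samples not in design: {sorted(unknown)}")
    frames = []
    for sid in ids:
        f = fragments[sid]
        frames.append(
            f.assign(total=f["meth"] + f["unmeth"]).set_index(SITE_COLUMNS)[["meth", "total"]]
        )
    merged = pd.concat(frames, axis=1, keys=ids, join="outer").sort_index(
        level=["contig", "pos", "strand"]
    )
    sites = merged.index.to_frame(index=False)
    meth = merged.xs("meth", axis=1, level=1).to_numpy(dtype=float)
    total = merged.xs("total", axis=1, level=1).to_numpy(dtype=float)
    return MethylomeMatrix(sites=make_sites(sites["contig"], sites["pos"], sites["strand"]),
                           meth=meth, total=total, samples=ids)


def destrand(matrix: MethylomeMatrix, enabled: bool = False) -> MethylomeMatrix:
    """Optionally merge symmetric CpG strand pairs by summing their counts.

    A pair is a ``+`` site at position p with a ``-`` site at p+1 on the
    same contig; the merged site sits at p with strand ``both``. Disabled
    by default (the merge is a comparability option, not part of the core
    analysis). Applying the merge twice is a no-op because ``both`` sites
    no longer pair.
    """
    if not enabled:
        return matrix
    sites = matrix.sites
    key = {}
    for i, (c, p, s) in enumerate(zip(sites["contig"], sites["pos"], sites["strand"])):
        key[(c, p, s)] = i
    consumed = np.zeros(len(sites), dtype=bool)
    out_rows, out_meth, out_total = [], [], []
    for i, (c, p, s) in enumerate(zip(sites["contig"], sites["pos"], sites["strand"])):
        if consumed[i]:
            continue
        if s == "+" and (c, p + 1, "-") in key:
            j = key[(c, p + 1, "-")]
            consumed[i] = consumed[j] = True
            out_rows.append((c, p, "both"))
            out_meth.append(np.nansum([matrix.meth[i], matrix.meth[j]], axis=0))
            out_total.append(np.nansum([matrix.total[i], matrix.total[j]], axis=0))
            # a pair missing in both members stays missing
            both_nan = np.isnan(matrix.total[i]) & np.isnan(matrix.total[j])
            out_meth[-1][both_nan] = np.nan
            out_total[-1][both_nan] = np.nan
        else:
            consumed[i] = True
            out_rows.append((c, p, s))
            out_meth.append(matrix.meth[i])
            out_total.append(matrix.total[i])
    rows = pd.DataFrame(out_rows, columns=SITE_COLUMNS)
    return MethylomeMatrix(
        sites=make_sites(rows["contig"], rows["pos"], rows["strand"]),
        meth=np.vstack(out_meth) if out_meth else np.empty((0, matrix.n_samples)),
        total=np.vstack(out_total) if out_total else np.empty((0, matrix.n_samples)),
        samples=list(matrix.samples),
    )
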