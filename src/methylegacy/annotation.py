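"""Gene models and CpG-to-feature assignment.

A gene model is an ordered exon chain; introns are the gaps between
consecutive exons, the promoter is the 2 kb immediately upstream of the
first exon (strand-aware), and the downstream region the 2 kb past the
last exon. Feature labels on a CpG may overlap (a site can sit in one
gene's exon and a neighbour's promoter); *intergenic* means no label at
all.

All coordinates are 1-based inclusive. Exon/intron ordinals count in the
direction of transcription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

FLANK_BP = 2000

FEATURES = ("promoter", "exon", "intron", "downstream")


@dataclass
class GeneModel:
    """One gene: exon chain plus derived introns and 2 kb flanks."""

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # genomic coords, ascending, non-overlapping
    contig_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model requires >=1 exon")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in exons:
            if a > b:
                raise ValueError(f"{self.gene_id}: exon coordinate inversion {a}>{b}")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 <= b0:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' in transcription direction."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns_tx_order(self) -> list[tuple[int, int]]:
        gaps = [
            (b0 + 1, a1 - 1)
            for (_, b0), (a1, _) in zip(self.exons, self.exons[1:])
            if a1 - b0 > 1
        ]
        return gaps if self.strand == "+" else gaps[::-1]

    def promoter(self) -> tuple[int, int] | None:
        """2 kb upstream of the first exon, clipped at contig edges."""
        if self.strand == "+":
            lo, hi = self.start - FLANK_BP, self.start - 1
            lo = max(lo, 1)
        else:
            lo, hi = self.end + 1, self.end + FLANK_BP
            if self.contig_length is not None:
                hi = min(hi, self.contig_length)
        return (lo, hi) if lo <= hi else None

    def downstream(self) -> tuple[int, int] | None:
        """2 kb downstream of the last exon, clipped at contig edges."""
        if self.strand == "+":
            lo, hi = self.end + 1, self.end + FLANK_BP
            if self.contig_length is not None:
                hi = min(hi, self.contig_length)
        else:
            lo, hi = self.start - FLANK_BP, self.start - 1
            lo = max(lo, 1)
        return (lo, hi) if lo <= hi else None

    def feature_intervals(self) -> list[tuple[str, tuple[int, int] | None]]:
        out: list[tuple[str, tuple[int, int] | None]] = [
            ("promoter", self.promoter()),
            ("downstream", self.downstream()),
        ]
        for k, iv in enumerate(self.exons_tx_order(), start=1):
            out.append((f"exon{k}", iv))
        for k, iv in enumerate(self.introns_tx_order(), start=1):
            out.append((f"intron{k}", iv))
        return out


def write_gff3(genes: Sequence[GeneModel], path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write gene/mRNA/exon records; one transcript per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig, length in sorted(contig_lengths.items()):
                fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig}\tmethylegacy\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\tmethylegacy\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\tmethylegacy\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon records into gene models.

    When a gene has several transcripts the first (longest if tied by
    order of appearance) defines the model. Exonless genes are skipped
    with a warning; coordinate inversions raise.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        return []
    contig_lengths = _sequence_regions(gff3_path)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        candidates = mrnas if mrnas else [gene]
        best, best_exons = None, None
        for t in candidates:
            exons = [(e.start, e.end) for e in db.children(t, featuretype="exon")]
            if not exons:
                continue
            span = sum(b - a + 1 for a, b in exons)
            if best is None or span > best:
                best, best_exons = span, exons
        if best_exons is None:
            warnings.warn(f"gene {gene.id} has no exons; skipped")
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=best_exons,
                contig_length=contig_lengths.get(gene.seqid),
            )
        )
    return genes


def _sequence_regions(gff3_path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
    return lengths


@dataclass
class FeatureAssignment:
    """Multi-label CpG-to-feature map.

    ``table`` is long-format: one row per (site, gene, feature instance)
    with columns ``site_idx, gene_id, feature`` (promoter / exon / intron /
    downstream), ``ordinal`` (1-based in transcription direction; 0 for
    flanks) and ``offset`` (bp of the site from the feature's 5' end in
    transcription direction). A site with no rows is intergenic.
    """

    n_sites: int
    table: pd.DataFrame = field(repr=False)

    def membership(self, feature: str) -> np.ndarray:
        mask = np.zeros(self.n_sites, dtype=bool)
        sel = self.table.loc[self.table["feature"] == feature, "site_idx"]
        mask[np.asarray(sel, dtype=int)] = True
        return mask

    @property
    def intergenic(self) -> np.ndarray:
        mask = np.ones(self.n_sites, dtype=bool)
        if len(self.table):
            mask[np.asarray(self.table["site_idx"].unique(), dtype=int)] = False
        return mask

    def labels(self, site_idx: int) -> set[str]:
        rows = self.table[self.table["site_idx"] == site_idx]
        if rows.empty:
            return {"intergenic"}
        out = set()
        for feat, ordinal in zip(rows["feature"], rows["ordinal"]):
            out.add(f"{feat}{int(ordinal)}" if feat in ("exon", "intron") else feat)
        return out

    def gene_sets(self) -> dict[int, set[str]]:
        """site_idx -> owning gene ids (empty dict entries omitted)."""
        out: dict[int, set[str]] = {}
        for sid, gid in zip(self.table["site_idx"], self.table["gene_id"]):
            out.setdefault(int(sid), set()).add(gid)
        return out


def assign_features(sites: pd.DataFrame, genes: Sequence[GeneModel]) -> FeatureAssignment:
    """Assign every CpG its (possibly overlapping) feature labels and genes."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.contig, IntervalTree())
        for k, iv in enumerate(g.exons_tx_order(), start=1):
            tree.addi(iv[0], iv[1] + 1, (g, "exon", k, iv))
        for k, iv in enumerate(g.introns_tx_order(), start=1):
            tree.addi(iv[0], iv[1] + 1, (g, "intron", k, iv))
        prom = g.promoter()
        if prom is not None:
            tree.addi(prom[0], prom[1] + 1, (g, "promoter", 0, prom))
        down = g.downstream()
        if down is not None:
            tree.addi(down[0], down[1] + 1, (g, "downstream", 0, down))
    rows = []
    for i, (contig, pos) in enumerate(zip(sites["contig"], sites["pos"])):
        tree = trees.get(contig)
        if tree is None:
            continue
        for hit in tree.at(int(pos)):
            g, feature, ordinal, (a, b) = hit.data
            offset = int(pos) - a if g.strand == "+" else b - int(pos)
            rows.append((i, g.gene_id, feature, ordinal, offset))
    table = pd.DataFrame(rows, columns=["site_idx", "gene_id", "feature", "ordinal", "offset"])
    return FeatureAssignment(n_sites=len(sites), table=table)
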