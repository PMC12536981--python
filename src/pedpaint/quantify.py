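"""Per-chromosome parental contribution percentages, at the nucleotide
and the gene level.

Genome-level percentages use only the informative regions — the union of
cluster spans, including Unknown clusters — as the denominator, never the
full chromosome length: in non-model genomes the total length is inflated
by repetitive and invariant regions that carry no ancestry signal.

Gene-level quantification intersects the post-merge ancestry blocks with
gene intervals from a GTF: a gene inherits the label whose clusters cover
the largest summed overlap, even for partial or nested overlaps; genes
overlapping nothing, or whose top two labels tie, are Unknown.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ancestry import LABELS, PARENT1, PARENT2, UNKNOWN
from .clustering import Cluster

logger = logging.getLogger(__name__)

GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "label", "overlap_bp")
_GENE_ID = re.compile(r'gene_id\s+"?([^";]+)"?')


@dataclass(frozen=True)
class ContributionRow:
    """Percentages of one individual's informative regions on one
    chromosome assigned to each ancestry. Pre-rounding the three
    percentages sum to exactly 100."""

    individual: str
    chrom: str
    parent1_pct: float
    parent2_pct: float
    unknown_pct: float


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a 1-based closed interval (strand is irrelevant here)."""

    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    chrom: str
    start: int
    end: int
    label: str
    overlap_bp: int


def _closed_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    # overlap of 1-based closed intervals [a,b] and [c,d]
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def genome_contributions(
    clusters: Sequence[Cluster], individual: str
) -> list[ContributionRow]:
    """Per-chromosome label percentages over the summed cluster spans.

    Chromosomes appear in first-seen cluster order. An empty cluster set
    yields an empty row set with a warning, not a crash.
    """
    if not clusters:
        logger.warning("individual %s has no clusters; no contributions computed", individual)
        return []
    spans: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for c in clusters:
        if c.chrom not in spans:
            spans[c.chrom] = {label: 0 for label in LABELS}
            order.append(c.chrom)
        spans[c.chrom][c.label] += c.span
    rows = []
    for chrom in order:
        total = sum(spans[chrom].values())
        rows.append(
            ContributionRow(
                individual=individual,
                chrom=chrom,
                parent1_pct=100.0 * spans[chrom][PARENT1] / total,
                parent2_pct=100.0 * spans[chrom][PARENT2] / total,
                unknown_pct=100.0 * spans[chrom][UNKNOWN] / total,
            )
        )
    return rows


def contributions_long(rows: Iterable[ContributionRow]) -> pd.DataFrame:
    """Tidy (individual, chrom, label, pct) frame for plotting and TSV."""
    records = []
    for r in rows:
        records.append((r.individual, r.chrom, PARENT1, r.parent1_pct))
        records.append((r.individual, r.chrom, PARENT2, r.parent2_pct))
        records.append((r.individual, r.chrom, UNKNOWN, r.unknown_pct))
    return pd.DataFrame(records, columns=["individual", "chrom", "label", "pct"])


def read_gtf(gtf: Path) -> list[GeneInterval]:
    """Extract gene intervals from a GTF.

    Rows with feature type ``gene`` are used when present; otherwise the
    per-``gene_id`` envelope of ``exon`` rows (or, failing that, of all
    rows) stands in, which tolerates minimal or pre-filtered GTFs. Lines
    without a parseable ``gene_id`` attribute are skipped and counted.
    Duplicate gene IDs among ``gene`` rows are an error.
    """
    path = Path(gtf)
    by_feature: dict[str, list[tuple[str, str, int, int]]] = {}
    skipped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s = fields[0], fields[1], fields[2], fields[3], fields[4]
            m = _GENE_ID.search(fields[8])
            if m is None:
                skipped += 1
                continue
            start, end = int(start_s), int(end_s)
            if start > end:
                raise ValueError(f"{path}: line {lineno}: start > end")
            by_feature.setdefault(feature, []).append((m.group(1), chrom, start, end))
    if skipped:
        logger.warning("%s: skipped %d lines without a gene_id attribute", path.name, skipped)

    if "gene" in by_feature:
        genes = []
        seen: set[str] = set()
        for gene_id, chrom, start, end in by_feature["gene"]:
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneInterval(gene_id, chrom, start, end))
        return genes

    rows = by_feature.get("exon")
    if rows is None:
        rows = [r for feature_rows in by_feature.values() for r in feature_rows]
    envelope: dict[str, list] = {}
    order: list[str] = []
    for gene_id, chrom, start, end in rows:
        if gene_id not in envelope:
            envelope[gene_id] = [chrom, start, end]
            order.append(gene_id)
        else:
            ent = envelope[gene_id]
            if ent[0] != chrom:
                raise ValueError(f"{path}: gene_id {gene_id!r} spans multiple chromosomes")
            ent[1] = min(ent[1], start)
            ent[2] = max(ent[2], end)
    return [GeneInterval(g, *envelope[g]) for g in order]


def gene_contributions(
    clusters: Sequence[Cluster], genes: Sequence[GeneInterval]
) -> tuple[list[GeneAssignment], pd.DataFrame]:
    """Assign each gene the label with the largest summed cluster overlap.

    Returns the per-gene assignments plus a tidy per-chromosome frame of
    gene-count percentages (chrom, label, pct, n_genes). ``overlap_bp``
    records the overlap of the assigned label's clusters with the gene
    (zero when the gene overlaps no cluster).
    """
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in gene set")
        seen.add(g.gene_id)

    by_chrom: dict[str, list[Cluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    starts: dict[str, list[int]] = {}
    for chrom, cs in by_chrom.items():
        cs.sort(key=lambda c: c.start)
        starts[chrom] = [c.start for c in cs]

    assignments: list[GeneAssignment] = []
    for gene in genes:
        overlaps = {label: 0 for label in LABELS}
        cs = by_chrom.get(gene.chrom, [])
        if cs:
            # clusters are disjoint and sorted; scan the window that can touch the gene
            idx = bisect_left(starts[gene.chrom], gene.start)
            if idx > 0:
                idx -= 1
            for c in cs[idx:]:
                if c.start > gene.end:
                    break
                overlaps[c.label] += _closed_overlap(gene.start, gene.end, c.start, c.end)
        ranked = sorted(overlaps.items(), key=lambda kv: kv[1], reverse=True)
        best_label, best = ranked[0]
        if best == 0 or (len(ranked) > 1 and ranked[1][1] == best):
            label = UNKNOWN  # no overlap, or a tie between the top two labels
        else:
            label = best_label
        assignments.append(
            GeneAssignment(gene.gene_id, gene.chrom, gene.start, gene.end,
                           label, overlaps[label])
        )

    counts: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for a in assignments:
        if a.chrom not in counts:
            counts[a.chrom] = {label: 0 for label in LABELS}
            order.append(a.chrom)
        counts[a.chrom][a.label] += 1
    records = []
    for chrom in order:
        total = sum(counts[chrom].values())
        for label in LABELS:
            records.append((chrom, label, 100.0 * counts[chrom][label] / total,
                            counts[chrom][label]))
    pct = pd.DataFrame(records, columns=["chrom", "label", "pct", "n_genes"])
    return assignments, pct


def gene_assignments_frame(
    assignments: Iterable[GeneAssignment], individual: Optional[str] = None
) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(a.gene_id, a.chrom, a.start, a.end, a.label, a.overlap_bp) for a in assignments],
        columns=list(GENE_COLUMNS),
    )
    if individual is not None:
        frame.insert(0, "individual", individual)
    return frame
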