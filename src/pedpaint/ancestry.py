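"""Assigning each offspring SNP a Parent1 / Parent2 / Unknown label.

The assignment is deterministic allele matching against the two parental
SNP panels — no statistical inference, no phasing. An offspring site is
labeled Parent1 when its allele equals parent 1's allele and differs from
parent 2's (symmetrically for Parent2); a site matching both parents is
uninformative and a site matching neither is unexplained, and both are
kept as Unknown so that they still count toward the informative-region
denominator used downstream. Sites absent from both parents are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .vcf_io import SnpCall

logger = logging.getLogger(__name__)

PARENT1 = "Parent1"
PARENT2 = "Parent2"
UNKNOWN = "Unknown"

#: The three ancestry categories; no other label value exists.
LABELS = (PARENT1, PARENT2, UNKNOWN)

_ABSENT = "."
COMPARISON_COLUMNS = ("chrom", "pos", "offspring", "parent1", "parent2", "label")


@dataclass(frozen=True)
class ComparisonRow:
    """One line of the human-readable offspring/parent comparison table."""

    chrom: str
    pos: int
    offspring_allele: str
    parent1_allele: Optional[str]
    parent2_allele: Optional[str]
    label: str


@dataclass(frozen=True)
class LabeledSnp:
    """A labeled offspring SNP, the unit consumed by clustering."""

    chrom: str
    pos: int
    label: str


@dataclass
class CompareStats:
    offspring_sites: int = 0
    absent_both_dropped: int = 0
    rows: int = 0
    label_counts: dict = field(default_factory=lambda: {l: 0 for l in LABELS})

    def as_dict(self) -> dict:
        return {
            "offspring_sites": self.offspring_sites,
            "absent_both_dropped": self.absent_both_dropped,
            "rows": self.rows,
            "label_counts": dict(self.label_counts),
        }


def assign_label(
    offspring_allele: str,
    parent1_allele: Optional[str] = None,
    parent2_allele: Optional[str] = None,
) -> str:
    """Label one site by which parental allele the offspring matches.

    At least one parent allele must be present (sites absent from both
    parents are discarded before labeling). A site present in only one
    parent is labeled with that parent when it matches and Unknown when
    it does not — the conservative reading for a mismatch the parents
    cannot explain.
    """
    if parent1_allele is None and parent2_allele is None:
        raise ValueError("at least one parental allele must be present")
    match1 = offspring_allele == parent1_allele
    match2 = offspring_allele == parent2_allele
    if match1 and not match2:
        return PARENT1
    if match2 and not match1:
        return PARENT2
    return UNKNOWN


def _checked_sorted(name: str, calls: Iterable[SnpCall]) -> Iterator[SnpCall]:
    last: Optional[tuple[str, int]] = None
    for call in calls:
        key = (call.chrom, call.pos)
        if last is not None and key <= last:
            raise ValueError(
                f"{name} SNP calls are not strictly sorted by (chrom, pos) "
                f"at {call.chrom}:{call.pos}; sort and deduplicate first"
            )
        last = key
        yield call


def build_comparison_table(
    offspring: Iterable[SnpCall],
    parent1: Iterable[SnpCall],
    parent2: Iterable[SnpCall],
    stats: Optional[CompareStats] = None,
) -> Iterator[ComparisonRow]:
    """Stream comparison rows for every offspring site present in >= 1 parent.

    All three inputs must be sorted by (chrom, pos) and deduplicated; the
    join is a row-by-row streaming merge, so the three call sets are never
    held in memory at once when the inputs are lazy. Rows come out sorted
    by (chrom, pos). Sites absent from both parents are dropped and counted.
    """
    if stats is None:
        stats = CompareStats()
    off_it = _checked_sorted("offspring", offspring)
    p1_it = _checked_sorted("parent1", parent1)
    p2_it = _checked_sorted("parent2", parent2)
    p1_cur = next(p1_it, None)
    p2_cur = next(p2_it, None)
    for off in off_it:
        key = (off.chrom, off.pos)
        stats.offspring_sites += 1
        while p1_cur is not None and (p1_cur.chrom, p1_cur.pos) < key:
            p1_cur = next(p1_it, None)
        while p2_cur is not None and (p2_cur.chrom, p2_cur.pos) < key:
            p2_cur = next(p2_it, None)
        a1 = p1_cur.allele if p1_cur is not None and (p1_cur.chrom, p1_cur.pos) == key else None
        a2 = p2_cur.allele if p2_cur is not None and (p2_cur.chrom, p2_cur.pos) == key else None
        if a1 is None and a2 is None:
            stats.absent_both_dropped += 1
            continue
        label = assign_label(off.allele, a1, a2)
        stats.rows += 1
        stats.label_counts[label] += 1
        yield ComparisonRow(off.chrom, off.pos, off.allele, a1, a2, label)


def labeled_snps(rows: Iterable[ComparisonRow]) -> list[LabeledSnp]:
    """Project comparison rows onto the (chrom, pos, label) triples
    consumed by clustering."""
    return [LabeledSnp(r.chrom, r.pos, r.label) for r in rows]


def write_comparison_table(rows: Iterable[ComparisonRow], path: Path) -> int:
    """Write the comparison table as TSV with a header row; absent
    parental alleles are encoded as ``.``. Returns the row count."""
    n = 0
    with open(path, "w") as handle:
        handle.write("\t".join(COMPARISON_COLUMNS) + "\n")
        for r in rows:
            handle.write(
                f"{r.chrom}\t{r.pos}\t{r.offspring_allele}\t"
                f"{r.parent1_allele or _ABSENT}\t{r.parent2_allele or _ABSENT}\t"
                f"{r.label}\n"
            )
            n += 1
    return n


def read_comparison_table(path: Path) -> list[ComparisonRow]:
    rows: list[ComparisonRow] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != COMPARISON_COLUMNS:
            raise ValueError(f"{path}: unexpected comparison table header {header}")
        for line in handle:
            chrom, pos, off, a1, a2, label = line.rstrip("\n").split("\t")
            rows.append(
                ComparisonRow(
                    chrom, int(pos), off,
                    None if a1 == _ABSENT else a1,
                    None if a2 == _ABSENT else a2,
                    label,
                )
            )
    return rows
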