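"""Two-pass clustering of labeled SNPs into ancestry blocks.

Pass 1 is a run-length grouping: maximal runs of consecutive SNPs sharing
one label become candidate clusters, and a candidate survives only when
its nucleotide span (end − start + 1) reaches the minimum cluster length
(the CLUSTER parameter). Runs break at label changes and chromosome
changes; the trailing run of each chromosome is subject to the same
filter. "Length" is always nucleotide span, never SNP count.

Pass 2 removes small intervening clusters — a short opposite-label block
sandwiched between two same-label blocks is treated as a false positive
rather than a genuine double recombination event: the small cluster is
deleted and its flanks merged into one continuous block. Immediately
adjacent same-label clusters (left behind where pass 1 discarded a
sub-threshold run) are coalesced by the same scan. The scan applies the
leftmost applicable rewrite and continues until a fixpoint, so the result
is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .ancestry import LABELS, LabeledSnp

logger = logging.getLogger(__name__)

CLUSTER_COLUMNS = ("individual", "chrom", "start", "end", "label", "n_snps", "span")


@dataclass(frozen=True)
class Cluster:
    """A contiguous same-ancestry genomic block, 1-based closed."""

    chrom: str
    start: int
    end: int
    label: str
    n_snps: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"cluster start {self.start} > end {self.end}")
        if self.n_snps < 1:
            raise ValueError("cluster must contain at least one SNP")

    @property
    def span(self) -> int:
        """Nucleotide span of the block (end − start + 1)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for the two passes, both in nucleotides.

    ``min_cluster_len``: pass 1 keeps runs with span >= this (default 10 nt,
    the scale of a biologically insignificant run).
    ``max_gap_cluster_len``: pass 2 removes intervening clusters with span
    strictly below this (default 1000 nt, the scale below which a genuine
    double-crossover tract is implausible in most systems).
    """

    min_cluster_len: int = 10
    max_gap_cluster_len: int = 1000

    def __post_init__(self) -> None:
        if self.min_cluster_len < 1 or self.max_gap_cluster_len < 1:
            raise ValueError("cluster length thresholds must be >= 1")


@dataclass
class ClusterStats:
    runs: int = 0
    discarded_short_runs: int = 0
    pass1_clusters: int = 0
    merged_clusters: int = 0


def cluster_pass1(
    snps: Iterable[LabeledSnp],
    params: Optional[ClusterParams] = None,
    stats: Optional[ClusterStats] = None,
) -> list[Cluster]:
    """Run-length group sorted labeled SNPs and filter by minimum span."""
    if params is None:
        params = ClusterParams()
    if stats is None:
        stats = ClusterStats()
    clusters: list[Cluster] = []
    cur: Optional[list] = None  # [chrom, label, start, end, n]
    last_key: Optional[tuple[str, int]] = None

    def _flush() -> None:
        if cur is None:
            return
        stats.runs += 1
        cluster = Cluster(cur[0], cur[2], cur[3], cur[1], cur[4])
        if cluster.span >= params.min_cluster_len:
            clusters.append(cluster)
            stats.pass1_clusters += 1
        else:
            stats.discarded_short_runs += 1

    for snp in snps:
        key = (snp.chrom, snp.pos)
        if last_key is not None and key <= last_key:
            raise ValueError(
                f"labeled SNPs must be strictly sorted by (chrom, pos); "
                f"violation at {snp.chrom}:{snp.pos}"
            )
        last_key = key
        if snp.label not in LABELS:
            raise ValueError(f"unknown ancestry label {snp.label!r} at {snp.chrom}:{snp.pos}")
        if cur is not None and snp.chrom == cur[0] and snp.label == cur[1]:
            cur[3] = snp.pos
            cur[4] += 1
        else:
            _flush()
            cur = [snp.chrom, snp.label, snp.pos, snp.pos, 1]
    _flush()
    return clusters


def _validate_chain(chrom: str, chain: list[Cluster]) -> None:
    for prev, nxt in zip(chain, chain[1:]):
        if nxt.start <= prev.end:
            raise ValueError(
                f"clusters overlap or are unsorted on {chrom}: "
                f"[{prev.start},{prev.end}] then [{nxt.start},{nxt.end}]"
            )


def merge_small_clusters(
    clusters: Iterable[Cluster],
    params: Optional[ClusterParams] = None,
    stats: Optional[ClusterStats] = None,
) -> list[Cluster]:
    """Pass 2: delete small intervening clusters and merge their flanks.

    Scanning each chromosome left to right, two rewrites apply, always at
    the leftmost applicable position:

    * coalesce: two adjacent clusters with the same label become one
      cluster spanning both (SNP counts summed);
    * merge: a cluster with span < ``max_gap_cluster_len`` flanked by two
      clusters sharing one label different from its own is deleted, and
      the flanks become one cluster from the left flank's start to the
      right flank's end (SNP counts of the two flanks summed — the deleted
      cluster's SNPs are gone).

    Rewrites repeat until a fixpoint; flank labels are never changed. The
    implementation resumes one position left of each rewrite, which visits
    rewrites in exactly leftmost-first order.
    """
    if params is None:
        params = ClusterParams()
    if stats is None:
        stats = ClusterStats()
    out: list[Cluster] = []
    chain: list[Cluster] = []

    def _process(chain: list[Cluster]) -> list[Cluster]:
        if not chain:
            return chain
        chrom = chain[0].chrom
        _validate_chain(chrom, chain)
        cs = list(chain)
        i = 0
        while i < len(cs):
            if i + 1 < len(cs) and cs[i].label == cs[i + 1].label:
                cs[i : i + 2] = [
                    Cluster(chrom, cs[i].start, cs[i + 1].end, cs[i].label,
                            cs[i].n_snps + cs[i + 1].n_snps)
                ]
                i = max(i - 1, 0)
                continue
            if i + 2 < len(cs):
                left, mid, right = cs[i], cs[i + 1], cs[i + 2]
                if (
                    mid.span < params.max_gap_cluster_len
                    and left.label == right.label
                    and mid.label != left.label
                ):
                    cs[i : i + 3] = [
                        Cluster(chrom, left.start, right.end, left.label,
                                left.n_snps + right.n_snps)
                    ]
                    i = max(i - 1, 0)
                    continue
            i += 1
        return cs

    for cluster in clusters:
        if chain and cluster.chrom != chain[0].chrom:
            out.extend(_process(chain))
            chain = []
        chain.append(cluster)
    out.extend(_process(chain))
    stats.merged_clusters = len(out)
    return out


def cluster_snps(
    snps: Iterable[LabeledSnp],
    params: Optional[ClusterParams] = None,
    stats: Optional[ClusterStats] = None,
) -> list[Cluster]:
    """Full two-pass clustering: run-length grouping + small-cluster merge."""
    if params is None:
        params = ClusterParams()
    return merge_small_clusters(cluster_pass1(snps, params, stats), params, stats)


def clusters_to_frame(clusters: Iterable[Cluster], individual: str) -> pd.DataFrame:
    """Tidy per-individual cluster table, the dataframe consumed by the
    painting and quantification steps."""
    rows = [
        (individual, c.chrom, c.start, c.end, c.label, c.n_snps, c.span)
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=list(CLUSTER_COLUMNS))


def write_cluster_table(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_cluster_table(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"individual": str, "chrom": str, "label": str})
    missing = set(CLUSTER_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: cluster table missing columns {sorted(missing)}")
    return frame


def frame_to_clusters(frame: pd.DataFrame) -> dict[str, list[Cluster]]:
    """Group a tidy cluster table back into per-individual cluster lists."""
    result: dict[str, list[Cluster]] = {}
    for individual, sub in frame.groupby("individual", sort=False):
        result[str(individual)] = [
            Cluster(str(r.chrom), int(r.start), int(r.end), str(r.label), int(r.n_snps))
            for r in sub.itertuples(index=False)
        ]
    return result
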