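"""Two-pass clustering: run-length grouping and small-cluster merging."""

from __future__ import annotations

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pedpaint.ancestry import LABELS, PARENT1, PARENT2, UNKNOWN, LabeledSnp
from pedpaint.clustering import (
    Cluster,
    ClusterParams,
    ClusterStats,
    cluster_pass1,
    cluster_snps,
    merge_small_clusters,
)

# ---------------------------------------------------------------------------
# independent oracles


def _rle_filter_oracle(snps, min_len):
    """Run-length encode (chrom, label) runs, then drop short spans."""
    runs = []
    for snp in snps:
        if runs and runs[-1][0] == snp.chrom and runs[-1][1] == snp.label:
            runs[-1][3] = snp.pos
            runs[-1][4] += 1
        else:
            runs.append([snp.chrom, snp.label, snp.pos, snp.pos, 1])
    return [
        Cluster(c, s, e, l, n)
        for c, l, s, e, n in runs
        if e - s + 1 >= min_len
    ]


def _naive_merge_oracle(clusters, max_gap):
    """Repeatedly apply the leftmost applicable rewrite, rescanning from
    the start of each chromosome chain after every change."""
    by_chrom = {}
    order = []
    for c in clusters:
        if c.chrom not in by_chrom:
            by_chrom[c.chrom] = []
            order.append(c.chrom)
        by_chrom[c.chrom].append(c)
    out = []
    for chrom in order:
        cs = list(by_chrom[chrom])
        changed = True
        while changed:
            changed = False
            for i in range(len(cs)):
                if i + 1 < len(cs) and cs[i].label == cs[i + 1].label:
                    cs[i : i + 2] = [
                        Cluster(chrom, cs[i].start, cs[i + 1].end, cs[i].label,
                                cs[i].n_snps + cs[i + 1].n_snps)
                    ]
                    changed = True
                    break
                if i + 2 < len(cs):
                    a, b, c = cs[i], cs[i + 1], cs[i + 2]
                    if b.span < max_gap and a.label == c.label != b.label:
                        cs[i : i + 3] = [
                            Cluster(chrom, a.start, c.end, a.label,
                                    a.n_snps + c.n_snps)
                        ]
                        changed = True
                        break
        out.extend(cs)
    return out


def _random_snps(rng, n, chroms=("chr1", "chr2"), max_pos=1_000_000):
    positions = {}
    for chrom in chroms:
        positions[chrom] = sorted(rng.sample(range(1, max_pos), n // len(chroms)))
    return [
        LabeledSnp(chrom, pos, rng.choice(LABELS))
        for chrom in chroms
        for pos in positions[chrom]
    ]


def _random_chain(rng, n_clusters, chrom="chr1"):
    clusters = []
    cursor = 1
    for _ in range(n_clusters):
        cursor += rng.randrange(1, 50)
        span = rng.randrange(1, 2000)
        clusters.append(
            Cluster(chrom, cursor, cursor + span - 1, rng.choice(LABELS),
                    rng.randrange(1, 30))
        )
        cursor += span
    return clusters


# ---------------------------------------------------------------------------
# pass 1


def test_pass1_single_run():
    snps = [LabeledSnp("chr1", p, PARENT1) for p in (100, 200, 300)]
    (cluster,) = cluster_pass1(snps, ClusterParams(min_cluster_len=10))
    assert cluster == Cluster("chr1", 100, 300, PARENT1, 3)


def test_pass1_discards_sub_threshold_runs():
    # a single-SNP run has span 1 and falls below a 10 nt threshold
    snps = [
        LabeledSnp("chr1", 100, PARENT1),
        LabeledSnp("chr1", 5000, PARENT2),
        LabeledSnp("chr1", 10_000, PARENT1),
        LabeledSnp("chr1", 20_000, PARENT1),
    ]
    stats = ClusterStats()
    out = cluster_pass1(snps, ClusterParams(min_cluster_len=10), stats)
    assert out == [Cluster("chr1", 10_000, 20_000, PARENT1, 2)]
    assert stats.discarded_short_runs == 2


def test_pass1_breaks_runs_at_chromosome_changes():
    snps = [LabeledSnp("chr1", 1, PARENT1), LabeledSnp("chr1", 50, PARENT1),
            LabeledSnp("chr2", 60, PARENT1), LabeledSnp("chr2", 120, PARENT1)]
    out = cluster_pass1(snps, ClusterParams(min_cluster_len=10))
    assert [(c.chrom, c.start, c.end) for c in out] == [("chr1", 1, 50), ("chr2", 60, 120)]


def test_pass1_threshold_is_inclusive():
    snps = [LabeledSnp("chr1", 1, PARENT1), LabeledSnp("chr1", 10, PARENT1)]
    assert cluster_pass1(snps, ClusterParams(min_cluster_len=10))  # span == 10 kept
    assert not cluster_pass1(snps, ClusterParams(min_cluster_len=11))


def test_pass1_rejects_unsorted_input():
    snps = [LabeledSnp("chr1", 50, PARENT1), LabeledSnp("chr1", 10, PARENT1)]
    with pytest.raises(ValueError, match="sorted"):
        cluster_pass1(snps)


def test_pass1_equals_rle_filter_oracle_on_random_snps():
    rng = random.Random(99)
    snps = _random_snps(rng, 10_000)
    for min_len in (1, 10, 500, 5000):
        got = cluster_pass1(snps, ClusterParams(min_cluster_len=min_len))
        assert got == _rle_filter_oracle(snps, min_len)
        for c in got:
            assert c.span >= min_len


# ---------------------------------------------------------------------------
# pass 2


def test_merge_worked_example_two_flanks_and_small_middle():
    clusters = [
        Cluster("chr1", 1, 10_000, PARENT1, 120),
        Cluster("chr1", 10_001, 10_100, PARENT2, 3),
        Cluster("chr1", 10_101, 20_100, PARENT1, 115),
    ]
    (merged,) = merge_small_clusters(clusters, ClusterParams(max_gap_cluster_len=101))
    assert merged.label == PARENT1
    assert (merged.start, merged.end, merged.span) == (1, 20_100, 20_100)
    assert merged.n_snps == 235  # flank SNPs only; the removed cluster's are gone


def test_merge_is_noop_on_large_alternating_clusters():
    clusters = [
        Cluster("chr1", 1, 5000, PARENT1, 10),
        Cluster("chr1", 5001, 10_000, PARENT2, 10),
        Cluster("chr1", 10_001, 15_000, PARENT1, 10),
    ]
    assert merge_small_clusters(clusters, ClusterParams(max_gap_cluster_len=1000)) == clusters


def test_merge_threshold_is_strict():
    def chain(mid_span):
        return [
            Cluster("chr1", 1, 10_000, PARENT1, 10),
            Cluster("chr1", 10_001, 10_000 + mid_span, PARENT2, 2),
            Cluster("chr1", 10_001 + mid_span, 20_000 + mid_span, PARENT1, 10),
        ]
    assert len(merge_small_clusters(chain(99), ClusterParams(max_gap_cluster_len=100))) == 1
    assert len(merge_small_clusters(chain(100), ClusterParams(max_gap_cluster_len=100))) == 3


def test_merge_handles_unknown_small_clusters_like_parental_ones():
    clusters = [
        Cluster("chr1", 1, 10_000, PARENT1, 10),
        Cluster("chr1", 10_001, 10_050, UNKNOWN, 1),
        Cluster("chr1", 10_051, 20_000, PARENT1, 10),
    ]
    (merged,) = merge_small_clusters(clusters, ClusterParams(max_gap_cluster_len=1000))
    assert merged.label == PARENT1


def test_merge_rejects_overlapping_clusters():
    clusters = [Cluster("chr1", 1, 100, PARENT1, 2), Cluster("chr1", 50, 200, PARENT2, 2)]
    with pytest.raises(ValueError, match="overlap"):
        merge_small_clusters(clusters)


def test_merge_equals_naive_rewrite_oracle_on_random_chains():
    rng = random.Random(4242)
    params = ClusterParams(max_gap_cluster_len=1000)
    for _ in range(1000):
        chain = _random_chain(rng, rng.randrange(0, 15))
        assert merge_small_clusters(chain, params) == _naive_merge_oracle(chain, 1000)


def test_merge_is_idempotent_and_monotone():
    rng = random.Random(7)
    params = ClusterParams(max_gap_cluster_len=1500)
    for _ in range(200):
        chain = _random_chain(rng, rng.randrange(0, 12))
        once = merge_small_clusters(chain, params)
        assert merge_small_clusters(once, params) == once
        assert len(once) <= len(chain)
        # converged chains never have same-label neighbours
        for a, b in zip(once, once[1:]):
            assert a.chrom != b.chrom or a.label != b.label
        assert sum(c.n_snps for c in once) <= sum(c.n_snps for c in chain)


@given(st.data())
def test_limit_case_is_pure_run_length_encoding(data):
    """min_cluster_len = max_gap_cluster_len = 1 keeps every run intact."""
    labels = data.draw(st.lists(st.sampled_from(LABELS), min_size=1, max_size=60))
    snps = [LabeledSnp("chr1", 10 * (i + 1), label) for i, label in enumerate(labels)]
    params = ClusterParams(min_cluster_len=1, max_gap_cluster_len=1)
    out = cluster_snps(snps, params)
    collapsed = [labels[0]] + [b for a, b in zip(labels, labels[1:]) if a != b]
    assert [c.label for c in out] == collapsed
    assert sum(c.n_snps for c in out) == len(labels)


def test_full_pipeline_parent_symmetry_through_both_passes():
    rng = random.Random(31)
    snps = _random_snps(rng, 2000)
    swap = {PARENT1: PARENT2, PARENT2: PARENT1, UNKNOWN: UNKNOWN}
    swapped = [LabeledSnp(s.chrom, s.pos, swap[s.label]) for s in snps]
    params = ClusterParams(min_cluster_len=10, max_gap_cluster_len=1000)
    fwd = cluster_snps(snps, params)
    rev = cluster_snps(swapped, params)
    assert [
        (c.chrom, c.start, c.end, swap[c.label], c.n_snps) for c in fwd
    ] == [(c.chrom, c.start, c.end, c.label, c.n_snps) for c in rev]
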