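"""Synthetic crosses with known recombination ground truth.

The generator emulates the regime the pipeline targets: haploid or fully
homozygous diploid parents whose genomes differ at randomly placed SNP
sites, and offspring formed by piecewise copying of parental haplotypes
switching at known crossover positions. SNP sites are placed by a
Poisson draw per chromosome with uniform positions; crossovers are
uniform with no interference model. Every parental SNP site appears in
the offspring VCF, homozygous for the transmitted allele except where
noise is injected:

* heterozygous-call noise emits the site as 0/1 (dropped by the caller);
* mismatched-allele noise substitutes a fourth base carried by neither
  parent (labeled Unknown by the caller).

A truth table (BED-like TSV, converted to 1-based closed coordinates to
match the pipeline) records, per offspring and chromosome, the exact
parental segments tiling [1, chrom_len].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .ancestry import PARENT1, PARENT2, UNKNOWN
from .clustering import Cluster

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_PARENT_LABEL = {1: PARENT1, 2: PARENT2}
TRUTH_COLUMNS = ("offspring", "chrom", "start", "end", "label")


@dataclass(frozen=True)
class CrossConfig:
    """Study conditions for one simulated cross.

    Defaults describe a small fungal-scale genome: 3 chromosomes of 5 Mb,
    1 SNP per kb between the parents, 4 surviving offspring, 2 crossovers
    per chromosome, and no call noise. All rates are fractions in [0, 1];
    a fixed seed makes every output byte-identical across runs.
    """

    n_chroms: int = 3
    chrom_len: int = 5_000_000
    snp_density: float = 1.0  # expected SNPs per kb
    n_offspring: int = 4
    crossovers_per_chrom: Union[int, Sequence[int]] = 2
    het_noise_rate: float = 0.0
    mismatch_noise_rate: float = 0.0
    seed: int = 0
    gene_spacing: int = 10_000
    gene_length: int = 2_000

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_len, self.n_offspring) < 1:
            raise ValueError("counts must be >= 1")
        for rate in (self.het_noise_rate, self.mismatch_noise_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("noise rates must lie in [0, 1]")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")

    def crossovers(self, chrom_index: int) -> int:
        if isinstance(self.crossovers_per_chrom, int):
            return self.crossovers_per_chrom
        return int(self.crossovers_per_chrom[chrom_index])


@dataclass(frozen=True)
class TruthSegment:
    """One ground-truth parental segment, 1-based closed."""

    offspring: str
    chrom: str
    start: int
    end: int
    label: str  # Parent1 or Parent2


@dataclass
class SimulatedCross:
    """Paths and in-memory ground truth for one simulated cross."""

    parent1_vcf: Path
    parent2_vcf: Path
    offspring_vcfs: dict[str, Path]
    gtf: Path
    truth_tsv: Path
    truth: list[TruthSegment]
    chrom_names: list[str]
    config: CrossConfig


def _vcf_header(chrom_names: Sequence[str], chrom_len: int, sample: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=pedpaint-simulate"]
    for name in chrom_names:
        lines.append(f"##contig=<ID={name},length={chrom_len}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    return "\n".join(lines) + "\n"


def simulate_cross(cfg: CrossConfig, out_dir: Path) -> SimulatedCross:
    """Write parent VCFs, offspring VCFs, a toy GTF and the truth table.

    Parents carry distinct non-reference alleles at every SNP site, so
    every site is informative. Each offspring chromosome starts from a
    randomly chosen parent and switches at crossover positions drawn
    uniformly without replacement.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]

    # Per-chromosome site panels: positions plus ref / parent1 / parent2 /
    # spare alleles (the spare base is the mismatch-noise substitute).
    panels: dict[str, dict[str, np.ndarray]] = {}
    for chrom in chrom_names:
        expected = cfg.chrom_len * cfg.snp_density / 1000.0
        n_sites = max(1, int(rng.poisson(expected)))
        n_sites = min(n_sites, cfg.chrom_len)
        pos = np.sort(rng.choice(cfg.chrom_len, size=n_sites, replace=False)) + 1
        # column k of this 4x n permutation matrix picks ref/a1/a2/spare
        perm = np.argsort(rng.random((n_sites, 4)), axis=1)
        panels[chrom] = {
            "pos": pos,
            "ref": _BASES[perm[:, 0]],
            "p1": _BASES[perm[:, 1]],
            "p2": _BASES[perm[:, 2]],
            "spare": _BASES[perm[:, 3]],
        }

    parent_paths = {1: out_dir / "parent1.vcf", 2: out_dir / "parent2.vcf"}
    for parent, path in parent_paths.items():
        with open(path, "w") as handle:
            handle.write(_vcf_header(chrom_names, cfg.chrom_len, f"parent{parent}"))
            for chrom in chrom_names:
                panel = panels[chrom]
                allele = panel["p1"] if parent == 1 else panel["p2"]
                for p, ref, alt in zip(panel["pos"], panel["ref"], allele):
                    handle.write(
                        f"{chrom}\t{p}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t1/1\n"
                    )

    truth: list[TruthSegment] = []
    offspring_vcfs: dict[str, Path] = {}
    for o in range(cfg.n_offspring):
        name = f"offspring{o + 1}"
        path = out_dir / f"{name}.vcf"
        offspring_vcfs[name] = path
        with open(path, "w") as handle:
            handle.write(_vcf_header(chrom_names, cfg.chrom_len, name))
            for ci, chrom in enumerate(chrom_names):
                panel = panels[chrom]
                k = cfg.crossovers(ci)
                if k > 0:
                    # breakpoints are the first positions of new segments
                    breaks = np.sort(
                        rng.choice(cfg.chrom_len - 1, size=min(k, cfg.chrom_len - 1),
                                   replace=False)
                    ) + 2
                else:
                    breaks = np.array([], dtype=int)
                first = int(rng.integers(1, 3))
                bounds = np.concatenate(([1], breaks, [cfg.chrom_len + 1]))
                for s in range(len(bounds) - 1):
                    parent = first if s % 2 == 0 else 3 - first
                    truth.append(
                        TruthSegment(name, chrom, int(bounds[s]),
                                     int(bounds[s + 1]) - 1, _PARENT_LABEL[parent])
                    )
                # source parent of every site: segment index is the count of
                # breakpoints at or below the position
                seg_idx = np.searchsorted(breaks, panel["pos"], side="right")
                from_p1 = (seg_idx % 2 == 0) == (first == 1)
                allele = np.where(from_p1, panel["p1"], panel["p2"])
                n_sites = len(panel["pos"])
                mismatch = rng.random(n_sites) < cfg.mismatch_noise_rate
                het = rng.random(n_sites) < cfg.het_noise_rate
                allele = np.where(mismatch, panel["spare"], allele)
                for i in range(n_sites):
                    gt = "0/1" if het[i] else "1/1"
                    handle.write(
                        f"{chrom}\t{panel['pos'][i]}\t.\t{panel['ref'][i]}\t"
                        f"{allele[i]}\t.\t.\t.\tGT\t{gt}\n"
                    )

    gtf_path = out_dir / "genes.gtf"
    with open(gtf_path, "w") as handle:
        for chrom in chrom_names:
            g = 0
            start = 1
            while start + cfg.gene_length - 1 <= cfg.chrom_len:
                end = start + cfg.gene_length - 1
                gene_id = f"{chrom}_g{g + 1:04d}"
                handle.write(
                    f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\t"
                    f'gene_id "{gene_id}";\n'
                )
                g += 1
                start += cfg.gene_spacing

    truth_tsv = out_dir / "truth.tsv"
    write_truth(truth, truth_tsv)
    logger.info(
        "simulated cross: %d chroms x %d bp, %d offspring, seed %d",
        cfg.n_chroms, cfg.chrom_len, cfg.n_offspring, cfg.seed,
    )
    return SimulatedCross(
        parent1_vcf=parent_paths[1], parent2_vcf=parent_paths[2],
        offspring_vcfs=offspring_vcfs, gtf=gtf_path, truth_tsv=truth_tsv,
        truth=truth, chrom_names=chrom_names, config=cfg,
    )


def write_truth(truth: Sequence[TruthSegment], path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(TRUTH_COLUMNS) + "\n")
        for seg in truth:
            handle.write(
                f"{seg.offspring}\t{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.label}\n"
            )


def load_truth(path: Path) -> list[TruthSegment]:
    segments: list[TruthSegment] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth table header {header}")
        for line in handle:
            offspring, chrom, start, end, label = line.rstrip("\n").split("\t")
            segments.append(TruthSegment(offspring, chrom, int(start), int(end), label))
    return segments


# ---------------------------------------------------------------------------
# Evaluation helpers against the truth set


_LABEL_CODE = {UNKNOWN: 0, PARENT1: 1, PARENT2: 2}


def _truth_array(segments: Sequence[TruthSegment], chrom_len: int) -> np.ndarray:
    arr = np.zeros(chrom_len, dtype=np.int8)
    for seg in segments:
        arr[seg.start - 1 : seg.end] = _LABEL_CODE[seg.label]
    return arr


def per_base_accuracy(
    clusters: Sequence[Cluster],
    truth: Sequence[TruthSegment],
    offspring: str,
    chrom_len: int,
) -> float:
    """Fraction of cluster-covered bases whose label matches the truth.

    The denominator is the bases the pipeline assigned (union of cluster
    spans); bases outside any cluster — chromosome ends beyond the
    terminal SNPs and the inter-SNP windows around true breakpoints,
    which are below SNP resolution — are not counted either way.
    """
    truth_by_chrom: dict[str, list[TruthSegment]] = {}
    for seg in truth:
        if seg.offspring == offspring:
            truth_by_chrom.setdefault(seg.chrom, []).append(seg)
    arrays = {
        chrom: _truth_array(segs, chrom_len) for chrom, segs in truth_by_chrom.items()
    }
    covered = 0
    correct = 0
    for c in clusters:
        arr = arrays.get(c.chrom)
        if arr is None:
            continue
        window = arr[c.start - 1 : c.end]
        covered += len(window)
        correct += int((window == _LABEL_CODE[c.label]).sum())
    if covered == 0:
        return 0.0
    return correct / covered


def recovered_breakpoint_counts(clusters: Sequence[Cluster]) -> dict[str, int]:
    """Number of label transitions between consecutive clusters, per
    chromosome — the pipeline's estimate of the crossover count."""
    counts: dict[str, int] = {}
    prev: Optional[Cluster] = None
    for c in clusters:
        if prev is not None and prev.chrom == c.chrom and prev.label != c.label:
            counts[c.chrom] = counts.get(c.chrom, 0) + 1
        counts.setdefault(c.chrom, counts.get(c.chrom, 0))
        prev = c
    return counts


def true_breakpoint_counts(
    truth: Sequence[TruthSegment], offspring: str
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seg in truth:
        if seg.offspring == offspring:
            counts[seg.chrom] = counts.get(seg.chrom, 0) + 1
    return {chrom: n - 1 for chrom, n in counts.items()}
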