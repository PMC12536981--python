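"""End-to-end orchestration: VCFs → comparison tables → clusters → figures.

The CLI subcommands are thin wrappers over :func:`run_base` and
:func:`run_paint`; both are importable so the whole workflow is scriptable
without a shell. Everything here is deterministic — the only randomness
in the package lives in :mod:`pedpaint.simdata`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import ancestry, clustering, paint, quantify, vcf_io
from .clustering import ClusterParams

logger = logging.getLogger(__name__)


def individual_name(vcf: Path) -> str:
    """Individual ID from a VCF file name (``x.vcf`` / ``x.vcf.gz`` → ``x``)."""
    name = Path(vcf).name
    for suffix in (".vcf.gz", ".vcf"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return Path(vcf).stem


@dataclass
class BaseRunResult:
    cluster_table: pd.DataFrame
    cluster_table_path: Path
    comparison_paths: dict[str, Path]
    cluster_paths: dict[str, Path]
    summary_path: Path
    summary: dict


def run_base(
    offspring_vcfs: Sequence[Path],
    parent1_vcf: Path,
    parent2_vcf: Path,
    out_dir: Path,
    params: Optional[ClusterParams] = None,
) -> BaseRunResult:
    """Label and cluster every offspring against the two parents.

    Writes, per offspring, ``<name>.compare.tsv`` and ``<name>.clusters.tsv``;
    plus the combined ``clusters.tsv`` consumed by painting/quantification
    and a machine-readable ``summary.json`` with the counts at every
    filtering stage.
    """
    if params is None:
        params = ClusterParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    p1_stats, p2_stats = vcf_io.ReadStats(), vcf_io.ReadStats()
    parent1 = vcf_io.read_snp_calls(parent1_vcf, p1_stats)
    parent2 = vcf_io.read_snp_calls(parent2_vcf, p2_stats)

    frames: list[pd.DataFrame] = []
    comparison_paths: dict[str, Path] = {}
    cluster_paths: dict[str, Path] = {}
    per_individual: dict[str, dict] = {}
    for vcf in offspring_vcfs:
        name = individual_name(vcf)
        if name in per_individual:
            raise ValueError(f"duplicate individual name {name!r} among offspring VCFs")
        read_stats = vcf_io.ReadStats()
        calls = vcf_io.read_snp_calls(vcf, read_stats)
        cmp_stats = ancestry.CompareStats()
        rows = list(ancestry.build_comparison_table(calls, parent1, parent2, cmp_stats))
        cmp_path = out_dir / f"{name}.compare.tsv"
        ancestry.write_comparison_table(rows, cmp_path)
        comparison_paths[name] = cmp_path

        cl_stats = clustering.ClusterStats()
        clusters = clustering.cluster_snps(ancestry.labeled_snps(rows), params, cl_stats)
        frame = clustering.clusters_to_frame(clusters, name)
        cl_path = out_dir / f"{name}.clusters.tsv"
        clustering.write_cluster_table(frame, cl_path)
        cluster_paths[name] = cl_path
        frames.append(frame)

        per_individual[name] = {
            "read": read_stats.as_dict(),
            "compare": cmp_stats.as_dict(),
            "clusters": {
                "runs": cl_stats.runs,
                "discarded_short_runs": cl_stats.discarded_short_runs,
                "pass1_clusters": cl_stats.pass1_clusters,
                "merged_clusters": cl_stats.merged_clusters,
            },
        }

    combined = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(clustering.CLUSTER_COLUMNS))
    )
    combined_path = out_dir / "clusters.tsv"
    clustering.write_cluster_table(combined, combined_path)

    summary = {
        "params": {
            "min_cluster_len": params.min_cluster_len,
            "max_gap_cluster_len": params.max_gap_cluster_len,
        },
        "parent1": p1_stats.as_dict(),
        "parent2": p2_stats.as_dict(),
        "individuals": per_individual,
    }
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return BaseRunResult(
        cluster_table=combined,
        cluster_table_path=combined_path,
        comparison_paths=comparison_paths,
        cluster_paths=cluster_paths,
        summary_path=summary_path,
        summary=summary,
    )


def run_paint(
    cluster_table: Path | pd.DataFrame,
    out_dir: Path,
    gtf: Optional[Path] = None,
    genome: bool = True,
    genes: bool = False,
    spec: Optional[paint.PaintSpec] = None,
) -> dict[str, list[Path]]:
    """Paint chromosomes and quantify contributions from a cluster table.

    Always renders the composite painting; optionally the genome-percentage
    (per-nucleotide) and gene-percentage barplots with their TSVs.
    Returns a mapping of output kind → written paths.
    """
    if genes and gtf is None:
        raise ValueError("gene-level quantification requires a GTF file")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = paint.PaintSpec()
    frame = (
        clustering.read_cluster_table(cluster_table)
        if not isinstance(cluster_table, pd.DataFrame)
        else cluster_table
    )
    by_individual = clustering.frame_to_clusters(frame)
    outputs: dict[str, list[Path]] = {}
    outputs["painting"] = paint.paint_chromosomes(frame, spec, out_dir / "painting")

    if genome:
        rows = []
        for name, clusters in by_individual.items():
            rows.extend(quantify.genome_contributions(clusters, name))
        pct = quantify.contributions_long(rows)
        pct_path = out_dir / "genome_pct.tsv"
        pct.to_csv(pct_path, sep="\t", index=False, float_format="%.1f")
        outputs["genome_pct_tsv"] = [pct_path]
        outputs["genome_pct_plot"] = paint.plot_contributions(
            pct, spec, out_dir / "genome_pct", value_label="Genome%"
        )

    if genes:
        gene_set = quantify.read_gtf(gtf)
        assign_frames = []
        pct_frames = []
        for name, clusters in by_individual.items():
            assignments, pct = quantify.gene_contributions(clusters, gene_set)
            assign_frames.append(quantify.gene_assignments_frame(assignments, name))
            pct.insert(0, "individual", name)
            pct_frames.append(pct)
        gene_table = pd.concat(assign_frames, ignore_index=True)
        gene_pct = pd.concat(pct_frames, ignore_index=True)
        gene_path = out_dir / "genes.tsv"
        gene_pct_path = out_dir / "gene_pct.tsv"
        gene_table.to_csv(gene_path, sep="\t", index=False)
        gene_pct.to_csv(gene_pct_path, sep="\t", index=False, float_format="%.1f")
        outputs["genes_tsv"] = [gene_path]
        outputs["gene_pct_tsv"] = [gene_pct_path]
        outputs["gene_pct_plot"] = paint.plot_contributions(
            gene_pct, spec, out_dir / "gene_pct", value_label="Gene%"
        )
    return outputs
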