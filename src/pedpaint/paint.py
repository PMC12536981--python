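"""Chromosome paintings and contribution barplots.

Plots are pure consumers of the tidy tables the pipeline writes (every
table that is plotted is also saved as TSV, so custom downstream plotting
never requires re-running the pipeline). Rendering is deterministic:
fixed DPI, no timestamps embedded, identical tables give identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")  # headless + byte-stable output

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.patches import Patch

from .ancestry import LABELS, PARENT1, PARENT2, UNKNOWN

logger = logging.getLogger(__name__)

#: Fixed per-label colors (Parent1 blue, Parent2 red, Unknown gray); one
#: color per label across every panel of a figure.
DEFAULT_COLORS = {PARENT1: "#3B75AF", PARENT2: "#C03D3E", UNKNOWN: "#B0B0B0"}

#: Beyond this many individuals a composite painting is still rendered,
#: but readability is not guaranteed and a warning is logged.
READABILITY_LIMIT = 200


@dataclass
class PaintSpec:
    """Figure configuration shared by all plot functions."""

    color_map: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    individuals: Optional[list[str]] = None
    chrom_lengths: Optional[dict[str, int]] = None
    dpi: int = 150

    def color(self, label: str) -> str:
        return self.color_map.get(label, DEFAULT_COLORS[label])


def _validate_labels(frame: pd.DataFrame) -> None:
    bad = frame[~frame["label"].isin(LABELS)]
    if not bad.empty:
        rows = ", ".join(
            f"{r.individual}:{r.chrom}:{r.start}-{r.end}={r.label!r}"
            if "start" in frame.columns else f"{r.individual}:{r.chrom}={r.label!r}"
            for r in bad.head(10).itertuples(index=False)
        )
        raise ValueError(f"unknown ancestry label(s) in table: {rows}")


def _ordered(values: Iterable[str], preferred: Optional[list[str]]) -> list[str]:
    seen = list(dict.fromkeys(values))
    if preferred:
        missing = [v for v in preferred if v not in seen]
        if missing:
            raise ValueError(f"requested individuals absent from table: {missing}")
        return list(preferred)
    return seen


def _save(fig, out: Path, dpi: int) -> list[Path]:
    out = Path(out)
    base = out.with_suffix("") if out.suffix in {".png", ".pdf"} else out
    base.parent.mkdir(parents=True, exist_ok=True)
    png, pdf = base.with_suffix(".png"), base.with_suffix(".pdf")
    fig.savefig(png, dpi=dpi)
    # a null CreationDate keeps repeated renders byte-identical
    fig.savefig(pdf, metadata={"CreationDate": None})
    plt.close(fig)
    return [png, pdf]


def build_painting(cluster_table: pd.DataFrame, spec: Optional[PaintSpec] = None):
    """Assemble the composite painted-chromosome figure.

    One horizontal track per (individual, chromosome); rows are
    individuals, columns are chromosomes, with a shared legend. Segment
    x-extents are the cluster [start, end] intervals, so bar widths are
    proportional to cluster spans.
    """
    if spec is None:
        spec = PaintSpec()
    if cluster_table.empty:
        raise ValueError("cluster table is empty; nothing to paint")
    _validate_labels(cluster_table)
    individuals = _ordered(cluster_table["individual"], spec.individuals)
    chroms = sorted(dict.fromkeys(cluster_table["chrom"]))
    if len(individuals) > READABILITY_LIMIT:
        logger.warning(
            "%d individuals exceed the readability guideline of %d; "
            "rendering anyway", len(individuals), READABILITY_LIMIT,
        )

    xmax = {}
    for chrom in chroms:
        if spec.chrom_lengths and chrom in spec.chrom_lengths:
            xmax[chrom] = spec.chrom_lengths[chrom]
        else:
            xmax[chrom] = int(cluster_table.loc[cluster_table["chrom"] == chrom, "end"].max())

    n_rows, n_cols = len(individuals), len(chroms)
    fig, axes = plt.subplots(
        n_rows, n_cols,
        figsize=(min(3.0 * n_cols + 1.5, 30), min(0.7 * n_rows + 1.2, 40)),
        squeeze=False,
    )
    grouped = cluster_table.groupby(["individual", "chrom"], sort=False)
    for i, individual in enumerate(individuals):
        for j, chrom in enumerate(chroms):
            ax = axes[i][j]
            try:
                sub = grouped.get_group((individual, chrom))
            except KeyError:
                sub = cluster_table.iloc[0:0]
            for row in sub.itertuples(index=False):
                ax.barh(
                    y=0.5, width=row.end - row.start + 1, left=row.start,
                    height=0.8, color=spec.color(row.label), edgecolor="none",
                )
            ax.set_xlim(1, xmax[chrom])
            ax.set_ylim(0, 1)
            ax.set_yticks([])
            if i == 0:
                ax.set_title(str(chrom), fontsize=9)
            if j == 0:
                ax.set_ylabel(str(individual), rotation=0, ha="right",
                              va="center", fontsize=8)
            if i == n_rows - 1:
                ax.tick_params(axis="x", labelsize=6)
            else:
                ax.set_xticks([])
            for side in ("top", "right", "left"):
                ax.spines[side].set_visible(False)
    handles = [Patch(color=spec.color(label), label=label) for label in LABELS]
    fig.legend(handles=handles, loc="lower center", ncol=3, frameon=False, fontsize=8)
    fig.subplots_adjust(bottom=0.18, hspace=0.4)
    return fig


def paint_chromosomes(
    cluster_table: pd.DataFrame, spec: Optional[PaintSpec] = None,
    out: Path = Path("painting"),
) -> list[Path]:
    """Render the composite painting to ``<out>.png`` and ``<out>.pdf``."""
    if spec is None:
        spec = PaintSpec()
    fig = build_painting(cluster_table, spec)
    return _save(fig, out, spec.dpi)


def build_contribution_plot(
    pct_table: pd.DataFrame, spec: Optional[PaintSpec] = None,
    value_label: str = "Genome%",
):
    """Stacked barplot of per-label percentages.

    ``pct_table`` is tidy with columns label and pct, plus chrom and
    (optionally) individual; one subplot per chromosome, one stacked bar
    per individual, stacking in Parent1 / Parent2 / Unknown order.
    """
    if spec is None:
        spec = PaintSpec()
    if pct_table.empty:
        raise ValueError("percentage table is empty; nothing to plot")
    _validate_labels(
        pct_table if "individual" in pct_table.columns
        else pct_table.assign(individual="all")
    )
    if (pct_table["pct"] < 0).any():
        bad = pct_table[pct_table["pct"] < 0]
        raise ValueError(f"negative percentages in table:\n{bad}")
    table = pct_table.copy()
    if "individual" not in table.columns:
        table["individual"] = "all"
    individuals = _ordered(table["individual"], spec.individuals)
    chroms = sorted(dict.fromkeys(table["chrom"]))

    fig, axes = plt.subplots(
        1, len(chroms),
        figsize=(min(0.55 * len(individuals) * len(chroms) + 2.5, 30), 3.4),
        squeeze=False, sharey=True,
    )
    pivot = table.pivot_table(
        index=["chrom", "individual"], columns="label", values="pct",
        aggfunc="sum", fill_value=0.0,
    )
    for j, chrom in enumerate(chroms):
        ax = axes[0][j]
        bottoms = [0.0] * len(individuals)
        xs = list(range(len(individuals)))
        for label in LABELS:
            heights = [
                float(pivot.at[(chrom, ind), label])
                if (chrom, ind) in pivot.index and label in pivot.columns else 0.0
                for ind in individuals
            ]
            ax.bar(xs, heights, bottom=bottoms, width=0.75,
                   color=spec.color(label), label=label)
            bottoms = [b + h for b, h in zip(bottoms, heights)]
        ax.set_title(str(chrom), fontsize=9)
        ax.set_xticks(xs)
        ax.set_xticklabels(individuals, rotation=90, fontsize=7)
        ax.set_ylim(0, 100)
        if j == 0:
            ax.set_ylabel(value_label)
    handles = [Patch(color=spec.color(label), label=label) for label in LABELS]
    fig.legend(handles=handles, loc="upper right", ncol=1, frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_contributions(
    pct_table: pd.DataFrame, spec: Optional[PaintSpec] = None,
    out: Path = Path("contributions"), value_label: str = "Genome%",
) -> list[Path]:
    """Render the stacked contribution barplot to ``<out>.png``/``.pdf``."""
    if spec is None:
        spec = PaintSpec()
    fig = build_contribution_plot(pct_table, spec, value_label=value_label)
    return _save(fig, out, spec.dpi)
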