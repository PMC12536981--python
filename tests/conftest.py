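from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from pedpaint.clustering import ClusterParams
from pedpaint.pipeline import run_base
from pedpaint.simdata import CrossConfig, simulate_cross

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def write_vcf(path: Path, records: list[str], sample: str = "s1",
              meta: list[str] | None = None) -> Path:
    """Write a minimal single-sample VCF from raw data lines."""
    lines = ["##fileformat=VCFv4.2"] + (meta or [])
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    path.write_text("\n".join(lines + records) + "\n")
    return path


@pytest.fixture(scope="session")
def small_cross(tmp_path_factory):
    """A small simulated cross plus its full base-pipeline run.

    Scaled-down study conditions (3 chromosomes of 200 kb instead of 5 Mb)
    so the whole suite stays fast; density and crossover counts match the
    generator defaults.
    """
    root = tmp_path_factory.mktemp("small_cross")
    cfg = CrossConfig(
        n_chroms=3, chrom_len=200_000, snp_density=1.0, n_offspring=4,
        crossovers_per_chrom=2, seed=11,
    )
    sim = simulate_cross(cfg, root / "sim")
    result = run_base(
        list(sim.offspring_vcfs.values()), sim.parent1_vcf, sim.parent2_vcf,
        root / "base", ClusterParams(),
    )
    return sim, result
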