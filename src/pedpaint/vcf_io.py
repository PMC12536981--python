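"""Reading, validating and splitting VCF files.

Plain-text VCF v4.x, optionally gzip-compressed. Only the fields the
ancestry pipeline consumes are modelled: CHROM, POS, REF, ALT and the GT
value of the single sample. INFO/FILTER-based quality filtering and BCF
are out of scope; callers are expected to pre-filter.

Coordinates are the VCF's native 1-based positions and stay 1-based,
closed, throughout the pipeline.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGTN")
_GT_SEP = re.compile(r"[/|]")
_SAFE_NAME = re.compile(r"[^A-Za-z0-9._-]")


class VcfFormatError(ValueError):
    """A VCF file violates the format this pipeline expects."""


@dataclass(frozen=True)
class VariantRecord:
    """One parsed VCF data line for a single individual.

    ``gt`` is the raw genotype string (e.g. ``"0/0"``, ``"1"``, ``"0|1"``).
    Files without a GT field are treated as parental consensus calls:
    every record is homozygous for the first ALT, encoded as ``gt="1"``.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    gt: str


@dataclass(frozen=True)
class SnpCall:
    """A resolved homozygous (or haploid) single-nucleotide call."""

    chrom: str
    pos: int
    allele: str


@dataclass
class ReadStats:
    """Per-file filtering counters, logged after reading."""

    records: int = 0
    het_dropped: int = 0
    missing_dropped: int = 0
    indel_dropped: int = 0
    kept: int = 0

    def as_dict(self) -> dict:
        return {
            "records": self.records,
            "het_dropped": self.het_dropped,
            "missing_dropped": self.missing_dropped,
            "indel_dropped": self.indel_dropped,
            "kept": self.kept,
        }


def _open_text(path: Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_vcf(vcf: Path) -> Iterator[VariantRecord]:
    """Yield :class:`VariantRecord` objects in file order.

    Header lines (``#``-prefixed) are skipped. Malformed data lines raise
    :class:`VcfFormatError` naming the offending line number.
    """
    path = Path(vcf)
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfFormatError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated "
                    f"fields, found {len(fields)}"
                )
            chrom, pos_str, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                pos = int(pos_str)
            except ValueError:
                raise VcfFormatError(
                    f"{path}: line {lineno}: non-numeric POS {pos_str!r}"
                ) from None
            if pos < 1:
                raise VcfFormatError(f"{path}: line {lineno}: POS must be >= 1, got {pos}")
            if not ref:
                raise VcfFormatError(f"{path}: line {lineno}: empty REF")
            alts: tuple[str, ...]
            if alt in (".", ""):
                alts = ()
            else:
                alts = tuple(a.upper() for a in alt.split(","))
            gt = _extract_gt(fields)
            yield VariantRecord(chrom=chrom, pos=pos, ref=ref.upper(), alts=alts, gt=gt)


def _extract_gt(fields: list[str]) -> str:
    # Parental consensus VCFs often carry no genotype column at all; each
    # record then simply asserts "this strain carries this ALT allele".
    if len(fields) < 10:
        return "1"
    fmt_keys = fields[8].split(":")
    if "GT" not in fmt_keys:
        return "1"
    return fields[9].split(":")[fmt_keys.index("GT")]


def resolve_homozygous(rec: VariantRecord) -> Optional[SnpCall]:
    """Resolve a record to its single allele, or ``None`` if uninformative.

    Haploid (``"0"``, ``"1"``, ...) and homozygous diploid (``"0/0"``,
    ``"1|1"``, ``"2/2"``, ...) genotypes resolve; heterozygous, missing and
    multi-nucleotide (indel) sites do not. ``/`` and ``|`` separators are
    treated identically — phase is irrelevant once heterozygotes are dropped.

    Raises :class:`VcfFormatError` if an allele index exceeds REF+ALT.
    """
    parts = _GT_SEP.split(rec.gt.strip())
    if any(p in ("", ".") for p in parts):
        return None  # missing call
    try:
        indices = [int(p) for p in parts]
    except ValueError:
        raise VcfFormatError(
            f"unparseable genotype {rec.gt!r} at {rec.chrom}:{rec.pos}"
        ) from None
    if len(set(indices)) != 1:
        return None  # heterozygous
    idx = indices[0]
    pool = (rec.ref,) + rec.alts
    if idx < 0 or idx >= len(pool):
        raise VcfFormatError(
            f"genotype index {idx} out of range for {len(pool)} allele(s) "
            f"at {rec.chrom}:{rec.pos}"
        )
    allele = pool[idx]
    if len(rec.ref) != 1 or len(allele) != 1:
        return None  # indel / multi-nucleotide site
    if allele not in _NUCLEOTIDES:
        return None
    return SnpCall(chrom=rec.chrom, pos=rec.pos, allele=allele)


def _classify(rec: VariantRecord, stats: ReadStats) -> Optional[SnpCall]:
    parts = _GT_SEP.split(rec.gt.strip())
    if any(p in ("", ".") for p in parts):
        stats.missing_dropped += 1
        return None
    indices = [int(p) for p in parts] if all(
        p.lstrip("-").isdigit() for p in parts
    ) else None
    if indices is not None and len(set(indices)) != 1:
        stats.het_dropped += 1
        return None
    call = resolve_homozygous(rec)
    if call is None:
        stats.indel_dropped += 1
        return None
    stats.kept += 1
    return call


def read_snp_calls(vcf: Path, stats: Optional[ReadStats] = None) -> list[SnpCall]:
    """Read a single-sample VCF and return its homozygous SNP calls,
    sorted by (chrom, pos).

    Duplicate (chrom, pos) records within one file are a hard error —
    the pipeline is deterministic and will not silently pick a winner.
    """
    path = Path(vcf)
    if stats is None:
        stats = ReadStats()
    seen: set[tuple[str, int]] = set()
    calls: list[SnpCall] = []
    for rec in read_vcf(path):
        stats.records += 1
        key = (rec.chrom, rec.pos)
        if key in seen:
            raise VcfFormatError(f"{path}: duplicate record at {rec.chrom}:{rec.pos}")
        seen.add(key)
        call = _classify(rec, stats)
        if call is not None:
            calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.pos))
    logger.info(
        "%s: %d records, %d kept, %d het dropped, %d missing, %d indel/multi-nt",
        path.name, stats.records, stats.kept, stats.het_dropped,
        stats.missing_dropped, stats.indel_dropped,
    )
    return calls


def split_vcf(combined_vcf: Path, out_dir: Path) -> list[Path]:
    """Split a multi-sample VCF into one single-sample VCF per sample column.

    Header lines are preserved; the #CHROM line and every data line are cut
    down to the first 9 columns plus the one sample column. Sample and
    record order are preserved. Output names are the sample IDs sanitized
    to filesystem-safe characters.
    """
    combined_vcf = Path(combined_vcf)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    meta_lines: list[str] = []
    header_cols: Optional[list[str]] = None
    with _open_text(combined_vcf) as handle:
        lines = handle.read().splitlines()

    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("##"):
            meta_lines.append(line)
        elif line.startswith("#CHROM"):
            header_cols = line.split("\t")
            body_start = i + 1
            break
        elif line.startswith("#"):
            meta_lines.append(line)
        else:
            break
    if header_cols is None:
        raise VcfFormatError(f"{combined_vcf}: missing #CHROM header line")
    if len(header_cols) < 10:
        raise VcfFormatError(f"{combined_vcf}: no sample columns in #CHROM line")

    samples = header_cols[9:]
    dups = sorted({s for s in samples if samples.count(s) > 1})
    if dups:
        raise VcfFormatError(
            f"{combined_vcf}: duplicate sample IDs: {', '.join(dups)}"
        )

    safe_names = [_SAFE_NAME.sub("_", s) for s in samples]
    # Sanitization may collide even when raw IDs do not; disambiguate by index.
    if len(set(safe_names)) != len(safe_names):
        safe_names = [f"{name}_{i}" for i, name in enumerate(safe_names)]

    n_fixed = 9
    out_paths = [out_dir / f"{name}.vcf" for name in safe_names]
    handles = [open(p, "w") for p in out_paths]
    try:
        for k, handle in enumerate(handles):
            for meta in meta_lines:
                handle.write(meta + "\n")
            handle.write("\t".join(header_cols[:n_fixed] + [samples[k]]) + "\n")
        for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_fixed + len(samples):
                raise VcfFormatError(
                    f"{combined_vcf}: line {lineno}: expected "
                    f"{n_fixed + len(samples)} columns, found {len(fields)}"
                )
            fixed = fields[:n_fixed]
            for k, handle in enumerate(handles):
                handle.write("\t".join(fixed + [fields[n_fixed + k]]) + "\n")
    finally:
        for handle in handles:
            handle.close()
    logger.info("split %s into %d single-sample VCFs", combined_vcf.name, len(out_paths))
    return out_paths
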