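"""Readers, writers and domain records for every external format the pipeline touches.

One coordinate convention is enforced internally: point mutations are 1-based
inclusive (MAF/VCF style) and genomic intervals are 0-based half-open (BED
style).  Conversion between the two happens only at this I/O boundary; a
1-based position ``p`` overlaps an interval ``[s, e)`` iff ``s < p <= e``.

Sequence access expects a mapping from chromosome name to an upper-case
string-like sequence supporting slicing — a plain ``dict`` of strings or a
:class:`pyfaidx.Fasta` opened via :func:`load_genome` both qualify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
SV_TYPES = ("DEL", "DUP", "INV", "TRA")
GENOTYPES = ("REF_HOM", "HET", "ALT_HOM", "missing")
SUBTYPES = ("type1", "type2", "unclassified")


class FormatError(ValueError):
    """Raised for malformed input rows; carries the offending line number."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None
    gene: str | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single A/C/G/T bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must lie in [0, 1], got {self.vaf}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open, 0-based interval, optionally carrying a value and a name."""

    chrom: str
    start: int
    end: int
    value: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_position(self, pos: int) -> bool:
        """Whether the 1-based position ``pos`` falls inside the interval."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class SVRecord:
    """A typed structural-variant call with its supporting evidence."""

    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    pe_support: int
    sr_support: int
    mapq: int
    qual_flag: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.qual_flag not in ("PASS", "LowQual"):
            raise ValueError(f"unknown quality flag {self.qual_flag!r}")
        if self.sv_type == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValueError("translocation breakpoints must be on different chromosomes")
        else:
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{self.sv_type} breakpoints must share a chromosome")
            if not self.pos1 < self.pos2:
                raise ValueError(f"{self.sv_type} requires pos1 < pos2")
        if min(self.pe_support, self.sr_support, self.mapq) < 0:
            raise ValueError("support and mapping-quality fields must be non-negative")

    def interval(self) -> GenomicInterval:
        """Span of an intrachromosomal event as a half-open interval."""
        if self.sv_type == "TRA":
            raise ValueError("translocations have no single-chromosome span")
        return GenomicInterval(self.chrom1, self.pos1 - 1, self.pos2)


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient genotype, staging, vital status and follow-up fields."""

    sample_id: str
    genotype: str
    subtype: str
    m_stage: str
    n_stage: str
    tumor_status: str | None = None
    days_followup: int = 0
    vital_status: str = "alive"
    days_to_death: int | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.vital_status not in ("alive", "dead"):
            raise ValueError(f"unknown vital status {self.vital_status!r}")
        if (self.days_to_death is not None) != (self.vital_status == "dead"):
            raise ValueError("days_to_death must be present iff vital_status == 'dead'")


# ---------------------------------------------------------------------------
# interval machinery
# ---------------------------------------------------------------------------


class IntervalSet:
    """Chromosome-indexed interval collection answering point/range queries.

    Input intervals may overlap; they are preserved as given.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):  # noqa: D107
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(sorted(self._intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)))

    def contains_position(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position lies inside any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.at(pos - 1))

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All stored intervals overlapping the half-open query ``[start, end)``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.overlap(start, end)),
                      key=lambda iv: (iv.start, iv.end))

    def covered_length(self) -> int:
        """Total number of bases covered, counting overlapped bases once."""
        total = 0
        for tree in self._trees.values():
            merged = tree.copy()
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total


# ---------------------------------------------------------------------------
# chromosome-name normalization
# ---------------------------------------------------------------------------


def normalize_chrom(name: str, use_prefix: bool = True) -> str:
    """Strip or add a ``chr`` prefix so joined files agree on naming."""
    bare = name[3:] if name.lower().startswith("chr") else name
    return f"chr{bare}" if use_prefix else bare


def check_chrom_compatibility(names_a: Iterable[str], names_b: Iterable[str]) -> None:
    """Error (never silently empty-join) when two inputs share no chromosome."""
    a, b = set(names_a), set(names_b)
    if a and b and not a & b:
        raise ValueError(
            f"no chromosome shared between inputs ({sorted(a)[:3]}... vs {sorted(b)[:3]}...); "
            "check 'chr' prefix conventions"
        )


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

_MAF_REQUIRED = ("sample_id", "chrom", "pos", "ref", "alt")


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in VALID_BASES and alt in VALID_BASES and ref != alt


def read_mutation_table(path: str | Path, dialect: str = "maf_like") -> list[MutationRecord]:
    """Read somatic SNVs from a MAF-like TSV or a minimal VCF.

    Indels/MNVs are skipped with a logged count; multi-allelic VCF rows are
    split into one record per alternate allele.
    """
    if dialect == "maf_like":
        return _read_maf_like(Path(path))
    if dialect == "vcf":
        return _read_vcf(Path(path))
    raise ValueError(f"unknown dialect {dialect!r} (expected 'maf_like' or 'vcf')")


def _read_maf_like(path: Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records: list[MutationRecord] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if not _is_snv(ref, alt):
            n_skipped += 1
            continue
        try:
            vaf = getattr(row, "vaf", None)
            vaf = float(vaf) if vaf is not None and not pd.isna(vaf) else None
            gene = getattr(row, "gene", None)
            gene = None if gene is None or pd.isna(gene) else str(gene)
            cons = getattr(row, "consequence", None)
            cons = None if cons is None or pd.isna(cons) else str(cons)
            records.append(
                MutationRecord(
                    sample_id=str(row.sample_id), chrom=str(row.chrom), pos=int(row.pos),
                    ref=ref, alt=alt, vaf=vaf, gene=gene, consequence=cons,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: malformed row at line {i}: {exc}") from exc
    if n_skipped:
        log.info("%s: skipped %d non-SNV row(s)", path, n_skipped)
    return records


def _read_vcf(path: Path) -> list[MutationRecord]:
    import pysam

    records: list[MutationRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) > 1:
            raise FormatError(f"{path}: multi-sample VCF not supported; split by sample first")
        sample_id = samples[0] if samples else Path(path).stem
        for rec in vcf:
            if rec.alts is None:
                n_skipped += 1
                continue
            for alt in rec.alts:
                ref, alt = str(rec.ref).upper(), str(alt).upper()
                if not _is_snv(ref, alt):
                    n_skipped += 1
                    continue
                vaf = None
                if samples:
                    fmt = rec.samples[samples[0]]
                    if "AF" in fmt and fmt["AF"] is not None:
                        raw = fmt["AF"]
                        vaf = float(raw[0] if isinstance(raw, tuple) else raw)
                records.append(
                    MutationRecord(sample_id=sample_id, chrom=rec.chrom, pos=rec.pos,
                                   ref=ref, alt=alt, vaf=vaf)
                )
    if n_skipped:
        log.info("%s: skipped %d non-SNV allele(s)", path, n_skipped)
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write records as a MAF-like TSV (round-trips with ``read_mutation_table``)."""
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in records],
            "chrom": [m.chrom for m in records],
            "pos": [m.pos for m in records],
            "ref": [m.ref for m in records],
            "alt": [m.alt for m in records],
            "vaf": [m.vaf for m in records],
            "gene": [m.gene for m in records],
            "consequence": [m.consequence for m in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval tracks (BED / bedGraph)
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read BED3/BED4 or bedGraph intervals, sorted by (chrom, start)."""
    if format not in ("bed", "bedgraph"):
        raise ValueError(f"unknown interval format {format!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
            value = None
            name = None
            if format == "bedgraph":
                if len(fields) < 4:
                    raise FormatError(f"{path}: line {lineno}: bedGraph needs a value column")
                value = float(fields[3])
            elif len(fields) >= 4:
                name = fields[3]
            intervals.append(GenomicInterval(chrom, start, end, value=value, name=name))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path,
                    format: str = "bed") -> None:
    """Write intervals as BED (name in column 4 when set) or bedGraph."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            if format == "bedgraph":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.value}\n")
            elif iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# reference sequence
# ---------------------------------------------------------------------------


def load_genome(path: str | Path):
    """Open an (indexed) FASTA for random access; slices return plain strings."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# signature catalogue
# ---------------------------------------------------------------------------


def read_signature_catalogue(path: str | Path):
    """Read a 96 x K signature probability table keyed by context-change labels.

    Rows are canonicalized to alphabetical label order (A[C>A]A ... T[T>G]T)
    and each column renormalized to sum to one.
    """
    from .signatures import SignatureCatalogue

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureCatalogue.from_frame(df)


def write_signature_catalogue(catalogue, path: str | Path) -> None:
    catalogue.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# clinical, SV and methylation tables
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ("sample_id", "genotype", "subtype", "m_stage", "n_stage",
                     "tumor_status", "days_followup", "vital_status", "days_to_death")


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CLINICAL_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required clinical column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            tumor = getattr(row, "tumor_status", None)
            tumor = None if tumor is None or pd.isna(tumor) else str(tumor)
            dtd = getattr(row, "days_to_death", None)
            dtd = None if dtd is None or pd.isna(dtd) else int(float(dtd))
            records.append(
                ClinicalRecord(
                    sample_id=str(row.sample_id), genotype=str(row.genotype),
                    subtype=str(row.subtype), m_stage=str(row.m_stage),
                    n_stage=str(row.n_stage), tumor_status=tumor,
                    days_followup=int(float(getattr(row, "days_followup", 0) or 0)),
                    vital_status=str(getattr(row, "vital_status", "alive")),
                    days_to_death=dtd,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: malformed clinical row at line {i}: {exc}") from exc
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _CLINICAL_COLUMNS} for r in records])
    df.to_csv(path, sep="\t", index=False)


_SV_COLUMNS = ("sample_id", "sv_type", "chrom1", "pos1", "chrom2", "pos2",
               "pe_support", "sr_support", "mapq", "qual_flag")


def read_sv_table(path: str | Path) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required SV column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SVRecord(sv_type=row.sv_type, chrom1=row.chrom1, pos1=int(row.pos1),
                         chrom2=row.chrom2, pos2=int(row.pos2),
                         pe_support=int(row.pe_support), sr_support=int(row.sr_support),
                         mapq=int(row.mapq), qual_flag=row.qual_flag,
                         sample_id=row.sample_id)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: malformed SV row at line {i}: {exc}") from exc
    return records


def write_sv_table(records: Sequence[SVRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _SV_COLUMNS} for r in records])
    df.to_csv(path, sep="\t", index=False)


def read_cn_segments(path: str | Path) -> list[GenomicInterval]:
    """SEG-like TSV (chrom, start, end, log2_ratio) as value-carrying intervals."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end", "log2_ratio"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing CN segment column {col!r}")
    return [GenomicInterval(str(r.chrom), int(r.start), int(r.end), value=float(r.log2_ratio))
            for r in df.itertuples(index=False)]


def read_methylation_matrix(path: str | Path) -> pd.DataFrame:
    """Sites x samples beta-value matrix; betas must lie in [0, 1]."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    finite = values[~pd.isna(values)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise FormatError(f"{path}: beta values must lie in [0, 1]")
    return df


def read_cluster_assignments(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping sample_id to a methylation-cluster label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample_id, cluster)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
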