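"""Quality and population filtering of structural-variant call sets.

Raw caller output is filtered in two passes: a quality pass dropping calls
flagged LowQual, re-derived as paired-end AND split-read support below 3, or
mapping quality below 20; and a germline pass dropping calls that reciprocally
overlap a population (e.g. 1000 Genomes phase 3) record of the same type by at
least 0.8 (translocations are matched by breakpoint proximity instead).
Samples are then classed genome-stable (< ``low`` events) or genome-unstable
(> ``high`` events) by their post-filter event count; counts in between are
reported as intermediate.  A separate helper prefilters SNVs for subclonal
tree inference by copy-number ratio and allele fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomicInterval, IntervalSet, MutationRecord, SVRecord

log = logging.getLogger(__name__)


def quality_filter(
    svs: Iterable[SVRecord],
    min_support: int = 3,
    min_mapq: int = 20,
    flag_only: bool = False,
) -> list[SVRecord]:
    """Drop low-quality calls.

    A call is removed when it is flagged ``LowQual``, or (unless ``flag_only``)
    when the rule is re-derived from the evidence fields: both paired-end and
    split-read support below ``min_support`` (either evidence type suffices to
    keep), or mapping quality below ``min_mapq``.
    """
    retained = []
    for sv in svs:
        if sv.qual_flag == "LowQual":
            continue
        if not flag_only:
            if sv.pe_support < min_support and sv.sr_support < min_support:
                continue
            if sv.mapq < min_mapq:
                continue
        retained.append(sv)
    return retained


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/|a|, overlap/|b|); 0 when disjoint or on different chromosomes."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("zero-length interval has no defined reciprocal overlap")
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def population_filter(
    svs: Sequence[SVRecord],
    population_set: Sequence[SVRecord],
    threshold: float = 0.8,
    tra_breakpoint_distance: int = 1000,
) -> list[SVRecord]:
    """Drop calls matching a population record of the SAME type.

    Intrachromosomal events match by reciprocal overlap >= ``threshold``;
    translocations match when both breakpoints lie within
    ``tra_breakpoint_distance`` bp of a population translocation's breakpoints
    on the same (unordered) chromosome pair.
    """
    by_type: dict[str, IntervalSet] = {}
    tra_pop: list[SVRecord] = []
    for p in population_set:
        if p.sv_type == "TRA":
            tra_pop.append(p)
        else:
            by_type.setdefault(p.sv_type, IntervalSet()).add(p.interval())

    retained = []
    for sv in svs:
        if sv.sv_type == "TRA":
            if any(_tra_match(sv, p, tra_breakpoint_distance) for p in tra_pop):
                continue
        else:
            iv = sv.interval()
            pop = by_type.get(sv.sv_type)
            hits = pop.overlapping(iv.chrom, iv.start, iv.end) if pop else []
            if any(reciprocal_overlap(iv, hit) >= threshold for hit in hits):
                continue
        retained.append(sv)
    return retained


def _tra_match(a: SVRecord, b: SVRecord, max_dist: int) -> bool:
    if {a.chrom1, a.chrom2} != {b.chrom1, b.chrom2}:
        return False
    b_pos = {b.chrom1: b.pos1, b.chrom2: b.pos2}
    return (abs(a.pos1 - b_pos[a.chrom1]) <= max_dist
            and abs(a.pos2 - b_pos[a.chrom2]) <= max_dist)


@dataclass(frozen=True)
class StabilityCall:
    """Genome-stability class of one sample, determined by its SV event count."""

    sample_id: str
    n_events: int
    category: str  # stable | unstable | intermediate


def classify_stability(
    svs_by_sample: Mapping[str, Sequence[SVRecord]],
    low: int = 10,
    high: int = 40,
) -> list[StabilityCall]:
    """Class samples by post-filter SV count: < low stable, > high unstable."""
    calls = []
    for sample_id in sorted(svs_by_sample):
        n = len(svs_by_sample[sample_id])
        if n < low:
            category = "stable"
        elif n > high:
            category = "unstable"
        else:
            category = "intermediate"
        calls.append(StabilityCall(sample_id, n, category))
    return calls


def tree_input_filter(
    snvs: Sequence[MutationRecord],
    cn_segments: Sequence[GenomicInterval],
    max_abs_log2: float = 0.3,
    max_vaf: float = 0.6,
) -> tuple[list[MutationRecord], dict[str, int]]:
    """Prefilter SNVs for subclonal tree inference.

    Drops SNVs inside any copy-number segment with |log2 ratio| > ``max_abs_log2``
    and SNVs with allele fraction above ``max_vaf`` (likely affected by copy
    loss).  Returns the retained records and a drop-reason tally.
    """
    missing = [m for m in snvs if m.vaf is None]
    if missing:
        ids = [f"{m.sample_id}:{m.chrom}:{m.pos}" for m in missing[:5]]
        raise ValueError(f"{len(missing)} SNV(s) lack a VAF, e.g. {ids}")
    cn_altered = IntervalSet(
        seg for seg in cn_segments
        if seg.value is not None and abs(seg.value) > max_abs_log2
    )
    retained = []
    reasons = {"cn_altered": 0, "high_vaf": 0, "retained": 0}
    for m in snvs:
        if cn_altered.contains_position(m.chrom, m.pos):
            reasons["cn_altered"] += 1
        elif m.vaf > max_vaf:
            reasons["high_vaf"] += 1
        else:
            reasons["retained"] += 1
            retained.append(m)
    return retained, reasons
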