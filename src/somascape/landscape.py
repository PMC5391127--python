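"""Mutation-landscape statistics: open chromatin, replication timing, recurrence.

Open-chromatin burden is the per-sample count and fraction of mutations whose
position falls inside a DNase I hypersensitive site (DHS) track.  Replication
timing per mutation is the median, across cell-type tracks, of the
length-weighted mean of a step signal over a +/- ``half_window`` bp window;
mutations in supplied exclusion regions (exome +/- flank, assembly gaps,
blacklist) are dropped.  "Early-replicating" mutations are those whose timing
value stands strictly above a cohort-pooled percentile.  Group comparisons use
the one-sided Wilcoxon rank-sum test (exact for small cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, IntervalSet, MutationRecord

log = logging.getLogger(__name__)

#: consequence classes that qualify as disruptive regardless of impact score
TRUNCATING_CONSEQUENCES = frozenset({
    "nonsense", "stop_gained", "frameshift", "frame_shift_del", "frame_shift_ins",
    "splice", "splice_site", "splice_acceptor", "splice_donor", "nonstop",
})
MISSENSE_CONSEQUENCES = frozenset({"missense", "missense_mutation"})


@dataclass(frozen=True)
class SampleLandscape:
    """Per-sample mutation-landscape summary."""

    sample_id: str
    n_total: int
    n_dhs: int
    frac_dhs: float
    frac_early: float = float("nan")
    remodeler_mutant: bool = False


def dhs_stats(
    mutations_by_sample: Mapping[str, Sequence[MutationRecord]],
    dhs: IntervalSet | Iterable[GenomicInterval],
) -> pd.DataFrame:
    """Count per sample how many mutations fall inside the DHS track."""
    dhs_set = dhs if isinstance(dhs, IntervalSet) else IntervalSet(dhs)
    rows = []
    for sample_id in sorted(mutations_by_sample):
        muts = mutations_by_sample[sample_id]
        n_total = len(muts)
        n_dhs = sum(dhs_set.contains_position(m.chrom, m.pos) for m in muts)
        if n_total == 0:
            log.warning("%s: no mutations; DHS fraction undefined", sample_id)
            frac = float("nan")
        else:
            frac = n_dhs / n_total
        rows.append({"sample_id": sample_id, "n_total": n_total,
                     "n_dhs": n_dhs, "frac_dhs": frac})
    return pd.DataFrame(rows).set_index("sample_id")


class StepTrack:
    """A stepwise-constant signal over sorted, non-overlapping intervals."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            if iv.value is None:
                raise ValueError("replication-timing intervals must carry a value")
            per_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in per_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: track intervals overlap")
            values = np.array([iv.value for iv in ivs], dtype=float)
            self._by_chrom[chrom] = (starts, ends, values)

    def window_mean(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        """Length-weighted mean over ``[start, end)`` and the covered fraction.

        Uncovered bases are ignored (not zero-filled).
        """
        if chrom not in self._by_chrom or end <= start:
            return float("nan"), 0.0
        starts, ends, values = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return float("nan"), 0.0
        seg_start = np.maximum(starts[lo:hi], start)
        seg_end = np.minimum(ends[lo:hi], end)
        lengths = np.maximum(seg_end - seg_start, 0)
        covered = int(lengths.sum())
        if covered == 0:
            return float("nan"), 0.0
        mean = float((values[lo:hi] * lengths).sum() / covered)
        return mean, covered / (end - start)


@dataclass(frozen=True)
class ReplicationProfile:
    """Step tracks of smoothed replication-timing signal, one per cell type."""

    tracks: Mapping[str, StepTrack]

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.tracks))

    @classmethod
    def from_intervals(cls, per_cell_type: Mapping[str, Sequence[GenomicInterval]]
                       ) -> "ReplicationProfile":
        return cls({name: StepTrack(ivs) for name, ivs in per_cell_type.items()})


def mutation_replication_time(
    m: MutationRecord,
    profile: ReplicationProfile,
    half_window: int = 10_000,
    exclusions: IntervalSet | None = None,
    min_coverage: float = 0.5,
) -> float | None:
    """Median across cell types of the windowed mean timing signal, or ``None``.

    Returns ``None`` (excluded) when the mutation overlaps the exclusion track
    or when no cell-type track covers at least ``min_coverage`` of the window.
    """
    if exclusions is not None and exclusions.contains_position(m.chrom, m.pos):
        return None
    start = max(0, m.pos - 1 - half_window)
    end = m.pos + half_window
    means = []
    for name in profile.cell_types:
        mean, coverage = profile.tracks[name].window_mean(m.chrom, start, end)
        if coverage >= min_coverage and not np.isnan(mean):
            means.append(mean)
    if not means:
        log.debug("%s:%d: no covering replication track; excluded", m.chrom, m.pos)
        return None
    return float(np.median(means))


def early_fraction(
    times_by_sample: Mapping[str, Sequence[float]],
    percentile: float = 90.0,
) -> tuple[pd.Series, float]:
    """Per-sample fraction of mutations strictly above the pooled percentile.

    The threshold is the linear-interpolation empirical quantile of ALL pooled
    (non-excluded) mutation times; ties at the threshold fall below.
    """
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in times_by_sample.values()
                             if len(v)]) if times_by_sample else np.array([])
    if pooled.size == 0:
        raise ValueError("no non-excluded mutation times pooled over the cohort")
    threshold = float(np.percentile(pooled, percentile))
    fracs = {}
    for sample_id, values in times_by_sample.items():
        arr = np.asarray(values, dtype=float)
        fracs[sample_id] = float(np.mean(arr > threshold)) if arr.size else float("nan")
    return pd.Series(fracs).sort_index(), threshold


def compare_groups(
    values: Sequence[float],
    group_flags: Sequence[bool],
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test of flagged vs unflagged samples.

    ``alternative='greater'`` tests whether flagged samples have larger values.
    Exact null distribution for combined n <= 20 without ties, normal
    approximation with tie correction otherwise.  Returns (statistic, p).
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(group_flags, dtype=bool)
    x = values[flags]
    y = values[~flags]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n = x.size + y.size
    has_ties = np.unique(values).size < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def region_recurrence(
    mutations_by_sample: Mapping[str, Sequence[MutationRecord]],
    regions: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """How many cohort samples carry >= 1 mutation in each named region."""
    n_cohort = len(mutations_by_sample)
    rows = []
    for i, region in enumerate(regions):
        name = region.name or f"region_{i + 1}"
        hit = sum(
            any(m.chrom == region.chrom and region.contains_position(m.pos) for m in muts)
            for muts in mutations_by_sample.values()
        )
        rows.append({"region": name, "chrom": region.chrom, "start": region.start,
                     "end": region.end, "n_samples_hit": hit,
                     "fraction": hit / n_cohort if n_cohort else float("nan")})
    return pd.DataFrame(rows).set_index("region")


def flag_remodeler_mutants(
    mutations_by_sample: Mapping[str, Sequence[MutationRecord]],
    gene_list: Iterable[str],
    polyphen: Mapping[tuple[str, str, int], float] | None = None,
    polyphen_min: float = 0.9,
    strict: bool = False,
) -> dict[str, bool]:
    """Flag samples carrying a disruptive mutation in a chromatin-remodeler gene.

    Truncating classes (nonsense, frameshift, splice) qualify regardless of
    score; missense requires an impact score >= ``polyphen_min`` looked up by
    ``(sample_id, chrom, pos)``.  A missense without a score counts with a
    warning, or is an error when ``strict``.
    """
    genes = {g.upper() for g in gene_list}
    flags: dict[str, bool] = {}
    for sample_id in sorted(mutations_by_sample):
        flagged = False
        for m in mutations_by_sample[sample_id]:
            if m.gene is None or m.gene.upper() not in genes or m.consequence is None:
                continue
            cons = m.consequence.lower()
            if cons in TRUNCATING_CONSEQUENCES:
                flagged = True
                break
            if cons in MISSENSE_CONSEQUENCES:
                score = None
                if polyphen is not None:
                    score = polyphen.get((m.sample_id, m.chrom, m.pos))
                if score is None:
                    msg = f"{sample_id} {m.gene} {m.chrom}:{m.pos}: missense without impact score"
                    if strict:
                        raise ValueError(msg)
                    log.warning("%s; counted as disruptive", msg)
                    flagged = True
                    break
                if score >= polyphen_min:
                    flagged = True
                    break
        flags[sample_id] = flagged
    return flags
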