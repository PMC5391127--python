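"""Per-sample 96-context mutation spectra, genome-frequency normalization and PCA.

Every single-base substitution is assigned to one of 96 classes: six
pyrimidine-centered changes (C>A, C>G, C>T, T>A, T>C, T>G) times the 16
combinations of 5' and 3' flanking bases.  Substitutions observed on the
purine strand are reverse-complemented before classification, so each class
label always carries a C or T in the middle.  Raw class counts can be
normalized by the trinucleotide frequencies of the (mappable) genome, turning
counts into per-context mutation rates that are comparable across contexts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, IntervalSet, MutationRecord

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = (("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"))

#: canonical alphabetical label order, A[C>A]A first and T[T>G]T last
CONTEXT_LABELS: tuple[str, ...] = tuple(sorted(
    f"{left}[{ref}>{alt}]{right}"
    for ref, alt in SUBSTITUTIONS
    for left in "ACGT"
    for right in "ACGT"
))

#: the 32 pyrimidine-centered reference trinucleotides, alphabetical
TRINUCLEOTIDES_32: tuple[str, ...] = tuple(sorted(
    f"{left}{center}{right}" for center in PYRIMIDINES for left in "ACGT" for right in "ACGT"
))

_LABEL_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}
_TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES_32)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def label_of(left: str, ref: str, alt: str, right: str) -> str:
    """Canonical 96-class label; purine-centered input is strand-collapsed."""
    if ref not in PYRIMIDINES:
        left, ref, alt, right = (COMPLEMENT[right], COMPLEMENT[ref],
                                 COMPLEMENT[alt], COMPLEMENT[left])
    return f"{left}[{ref}>{alt}]{right}"


def trinucleotide_of(label: str) -> str:
    """Reference trinucleotide (e.g. ``ACG``) underlying a 96-class label."""
    return label[0] + label[2] + label[6]


class RefMismatchError(ValueError):
    """The record's reference base disagrees with the genome sequence."""


class ContigEdgeError(ValueError):
    """The mutation sits at a contig edge where no flanking context exists."""


def classify_context(genome: Mapping[str, str], m: MutationRecord) -> str:
    """Assign a mutation to its canonical pyrimidine-centered 96-class label."""
    seq = genome[m.chrom]
    if m.pos < 2 or m.pos > len(seq) - 1:
        raise ContigEdgeError(f"{m.chrom}:{m.pos} lacks flanking context")
    trinuc = str(seq[m.pos - 2:m.pos + 1]).upper()
    if trinuc[1] != m.ref:
        raise RefMismatchError(
            f"{m.sample_id} {m.chrom}:{m.pos}: genome has {trinuc[1]}, record says {m.ref}"
        )
    if "N" in trinuc:
        raise ContigEdgeError(f"{m.chrom}:{m.pos}: ambiguous base in context {trinuc}")
    return label_of(trinuc[0], trinuc[1], m.alt, trinuc[2])


@dataclass(frozen=True)
class ContextFrequencyTable:
    """Counts of each of the 32 pyrimidine-centered trinucleotides in the genome."""

    freq: pd.Series  # indexed by TRINUCLEOTIDES_32, all entries > 0

    def __post_init__(self) -> None:
        if list(self.freq.index) != list(TRINUCLEOTIDES_32):
            raise ValueError("frequency table must be indexed by the 32 canonical trinucleotides")
        if (self.freq <= 0).any():
            zero = list(self.freq.index[self.freq <= 0])
            raise ValueError(f"zero-frequency context(s) make normalization undefined: {zero}")

    def __getitem__(self, trinuc: str) -> int:
        return int(self.freq[trinuc])


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def count_trinucleotides(
    genome: Mapping[str, str],
    mappability_mask: Iterable[GenomicInterval] | None = None,
) -> pd.Series:
    """Raw pyrimidine-collapsed trinucleotide window counts (zeros allowed).

    Every overlapping 3-mer window whose center lies inside the mask is
    counted once; windows containing an ambiguous base are skipped.
    """
    mask_set = IntervalSet(mappability_mask) if mappability_mask is not None else None
    counts = np.zeros(32, dtype=np.int64)
    # center code c with left l, right r: pyrimidine centers (C=1, T=3) count
    # directly; purine centers count as their reverse complement.
    code_to_bin = np.full((4, 4, 4), -1, dtype=np.int64)
    for left in "ACGT":
        for center in "ACGT":
            for right in "ACGT":
                tri = left + center + right
                canonical = tri if center in PYRIMIDINES else reverse_complement(tri)
                code_to_bin[_BASE_CODE[left], _BASE_CODE[center], _BASE_CODE[right]] = \
                    _TRINUC_INDEX[canonical]
    for chrom, seq in genome.items():
        seq = str(seq[:]).upper() if not isinstance(seq, str) else seq.upper()
        if len(seq) < 3:
            continue
        codes = _encode(seq)
        left, center, right = codes[:-2], codes[1:-1], codes[2:]
        valid = (left >= 0) & (center >= 0) & (right >= 0)
        if mask_set is not None:
            centers_1based = np.arange(2, len(seq))  # center of window i is base i+1 (1-based i+2)
            in_mask = np.fromiter(
                (mask_set.contains_position(chrom, int(p)) for p in centers_1based),
                count=len(centers_1based), dtype=bool,
            )
            valid &= in_mask
        idx = code_to_bin[left[valid], center[valid], right[valid]]
        counts += np.bincount(idx, minlength=32)
    return pd.Series(counts, index=list(TRINUCLEOTIDES_32))


def count_context_frequencies(
    genome: Mapping[str, str],
    mappability_mask: Iterable[GenomicInterval] | None = None,
) -> ContextFrequencyTable:
    """Genome trinucleotide frequencies for rate normalization.

    Errors when any of the 32 bins is empty (normalization undefined there),
    which rules out degenerate or fully masked genomes.
    """
    return ContextFrequencyTable(count_trinucleotides(genome, mappability_mask))


@dataclass(frozen=True)
class Spectrum96:
    """One sample's 96-class mutation counts and genome-normalized rates."""

    sample_id: str
    counts: pd.Series  # indexed by CONTEXT_LABELS, non-negative integers
    rates: pd.Series   # counts / genome frequency of the reference trinucleotide

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> pd.Series:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


def build_spectra(
    mutations: Sequence[MutationRecord],
    genome: Mapping[str, str],
    freq: ContextFrequencyTable,
    sample_ids: Sequence[str] | None = None,
) -> list[Spectrum96]:
    """Tally per-sample spectra; edge/ambiguous records are excluded and logged.

    ``sample_ids`` forces output (possibly all-zero) spectra for those samples
    even when they contributed no usable mutation.
    """
    per_sample: dict[str, np.ndarray] = {s: np.zeros(96, dtype=np.int64)
                                         for s in (sample_ids or ())}
    n_excluded = 0
    for m in mutations:
        try:
            label = classify_context(genome, m)
        except ContigEdgeError:
            n_excluded += 1
            continue
        arr = per_sample.setdefault(m.sample_id, np.zeros(96, dtype=np.int64))
        arr[_LABEL_INDEX[label]] += 1
    if n_excluded:
        log.info("excluded %d mutation(s) without usable flanking context", n_excluded)
    denominators = np.array([freq[trinucleotide_of(label)] for label in CONTEXT_LABELS],
                            dtype=float)
    spectra = []
    for sample_id in sorted(per_sample):
        counts = pd.Series(per_sample[sample_id], index=list(CONTEXT_LABELS))
        rates = pd.Series(per_sample[sample_id] / denominators, index=list(CONTEXT_LABELS))
        spectra.append(Spectrum96(sample_id, counts, rates))
    return spectra


def spectra_to_frame(spectra: Sequence[Spectrum96]) -> pd.DataFrame:
    """One row per sample: 96 ``count:`` columns then 96 ``rate:`` columns."""
    rows = {}
    for s in spectra:
        row = {f"count:{l}": int(s.counts[l]) for l in CONTEXT_LABELS}
        row.update({f"rate:{l}": float(s.rates[l]) for l in CONTEXT_LABELS})
        rows[s.sample_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def frame_to_spectra(df: pd.DataFrame) -> list[Spectrum96]:
    spectra = []
    for sample_id, row in df.iterrows():
        counts = pd.Series([int(row[f"count:{l}"]) for l in CONTEXT_LABELS],
                           index=list(CONTEXT_LABELS))
        rates = pd.Series([float(row[f"rate:{l}"]) for l in CONTEXT_LABELS],
                          index=list(CONTEXT_LABELS))
        spectra.append(Spectrum96(str(sample_id), counts, rates))
    return spectra


@dataclass(frozen=True)
class SpectraPCA:
    """PCA of per-sample spectra: samples are observations, the 96 bins variables."""

    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # 96 bins x components
    explained_variance_ratio: pd.Series


def spectra_pca(spectra: Sequence[Spectrum96], use: str = "rates") -> SpectraPCA:
    """Principal components of the cohort's spectra.

    Variables (the 96 bins) are centered but not unit-scaled, so high-rate
    contexts are allowed to dominate the leading component.  The sign of each
    component is fixed so that its largest-magnitude loading is positive.
    """
    if len(spectra) < 3:
        raise ValueError(f"PCA needs at least 3 samples, got {len(spectra)}")
    if use == "rates":
        X = np.vstack([s.rates.to_numpy(dtype=float) for s in spectra])
    elif use == "proportions":
        X = np.vstack([s.proportions.to_numpy(dtype=float) for s in spectra])
    else:
        raise ValueError(f"unknown PCA input {use!r} (expected 'rates' or 'proportions')")

    from sklearn.decomposition import PCA

    n_components = min(len(spectra), 96)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # 96 x C
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    sample_ids = [s.sample_id for s in spectra]
    evr = pca.explained_variance_ratio_.copy()
    # with n-1 <= 96 the retained components carry all the variance; report
    # fractions over all components so they sum to one
    return SpectraPCA(
        scores=pd.DataFrame(scores, index=sample_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=list(CONTEXT_LABELS), columns=comp_names),
        explained_variance_ratio=pd.Series(evr, index=comp_names),
    )
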