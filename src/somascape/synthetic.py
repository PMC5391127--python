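"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a whole-genome renal-tumor
cohort without any external download: a random reference sequence with an
open-chromatin (DHS) block track and smooth replication-timing tracks; somatic
SNVs drawn per sample from a mixture of catalogue signatures and placed at
genome positions matching their trinucleotide context (with configurable
depletion inside DHS and an optional APOBEC TCW boost); and a clinical cohort
with carrier-dependent survival hazard, a two-cluster methylation beta matrix
with a designated hypermethylated site subset, and a structural-variant table
containing designed stable/unstable samples plus low-quality and
germline-overlap decoys.

Determinism: one global integer seed fans out to independent substreams keyed
by operation and sample index, so adding a sample never perturbs the draws of
existing samples.  Every simulation returns a ground-truth manifest alongside
the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ClinicalRecord, GenomicInterval, MutationRecord, SVRecord
from .signatures import SignatureCatalogue
from .spectrum import (CONTEXT_LABELS, COMPLEMENT, PYRIMIDINES, TRINUCLEOTIDES_32,
                       reverse_complement, trinucleotide_of)

#: the four TCW bins of the 96-class spectrum (T[C>T|G]A and T[C>T|G]T)
TCW_LABELS = ("T[C>G]A", "T[C>G]T", "T[C>T]A", "T[C>T]T")

_STREAMS = {"genome": 0, "mutations": 1, "survival": 2, "methylation": 3, "svs": 4,
            "catalogue": 5}


def _rng(seed: int, stream: str, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream], *key))
    )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated cohort design.

    35 whole-genome samples (9 of them chromatin-remodeler mutant), ~900
    mutations each, 12% of the genome in DHS blocks where wild-type samples
    mutate at 0.6x the background rate; a 96-patient survival cohort with 7
    risk-allele carriers at hazard ratio 3; a two-cluster methylation matrix
    with a +0.3 beta shift at the designated hypermethylated sites; 29
    genome-stable (< 10 SVs) and 6 genome-unstable (> 40 SVs) samples.
    """

    seed: int = 0
    # genome
    genome_length: int = 200_000
    chrom_name: str = "chr1"
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)  # A,C,G,T
    dhs_fraction: float = 0.12
    dhs_block_size: int = 1_000
    n_replication_tracks: int = 3
    replication_bin_size: int = 1_000
    # mutations
    n_samples: int = 35
    mutations_per_sample: int = 900
    exposures_true: np.ndarray | None = None   # (n_samples, K), rows sum to 1
    dhs_rate_ratio: float = 0.6
    remodeler_samples: tuple[int, ...] = tuple(range(9))
    apobec_boost: float = 1.0
    apobec_samples: tuple[int, ...] = ()
    # survival cohort
    n_patients: int = 96
    n_carriers: int = 7
    carrier_hazard_ratio: float = 3.0
    baseline_median_days: float = 1_200.0
    censor_horizon_days: float = 2_000.0
    # methylation
    n_sites: int = 100
    n_true_hyper: int = 10
    cluster_beta_shift: float = 0.3
    beta_concentration: float = 50.0
    # structural variants
    n_stable_samples: int = 29
    n_unstable_samples: int = 6
    n_lowqual_decoys: int = 2
    n_germline_decoys: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.dhs_fraction < 1.0:
            raise ValueError(f"dhs_fraction must lie in (0, 1), got {self.dhs_fraction}")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10 kb")
        for name in ("dhs_rate_ratio", "apobec_boost", "carrier_hazard_ratio",
                     "baseline_median_days", "censor_horizon_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.exposures_true is not None:
            arr = np.asarray(self.exposures_true, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != self.n_samples:
                raise ValueError("exposures_true must be an (n_samples, K) matrix")
            if (arr < 0).any() or np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("exposures_true rows must be non-negative and sum to 1")
            self.exposures_true = arr


def sample_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_samples)]


# ---------------------------------------------------------------------------
# reference genome and tracks
# ---------------------------------------------------------------------------


@dataclass
class GenomeBundle:
    """A simulated reference sequence with its DHS and replication tracks."""

    sequences: dict[str, str]
    dhs: list[GenomicInterval]
    replication_tracks: dict[str, list[GenomicInterval]]
    _context_index: dict | None = field(default=None, repr=False)
    _dhs_mask: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def dhs_mask(self, chrom: str) -> np.ndarray:
        """Boolean per-base (0-based) DHS membership for one chromosome."""
        if self._dhs_mask is None:
            self._dhs_mask = {c: np.zeros(len(s), dtype=bool) for c, s in self.sequences.items()}
            for iv in self.dhs:
                self._dhs_mask[iv.chrom][iv.start:iv.end] = True
        return self._dhs_mask[chrom]

    def context_index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per 32-context: (chrom indices, 1-based positions, purine-strand flags)."""
        if self._context_index is None:
            chroms = list(self.sequences)
            per_context: dict[str, list[list]] = {t: [[], [], []] for t in TRINUCLEOTIDES_32}
            for ci, chrom in enumerate(chroms):
                seq = self.sequences[chrom]
                for i in range(1, len(seq) - 1):
                    tri = seq[i - 1:i + 2]
                    if "N" in tri:
                        continue
                    if tri[1] in PYRIMIDINES:
                        canonical, minus = tri, False
                    else:
                        canonical, minus = reverse_complement(tri), True
                    bucket = per_context[canonical]
                    bucket[0].append(ci)
                    bucket[1].append(i + 1)  # 1-based
                    bucket[2].append(minus)
            self._context_index = {
                t: (np.array(v[0], dtype=np.int32), np.array(v[1], dtype=np.int64),
                    np.array(v[2], dtype=bool))
                for t, v in per_context.items()
            }
            self._index_chroms = chroms
        return self._context_index


def simulate_genome(config: SimulationConfig) -> GenomeBundle:
    """Random i.i.d. reference sequence plus DHS blocks and timing tracks.

    DHS blocks of ``dhs_block_size`` bp are placed on a non-overlapping grid to
    cover ``dhs_fraction`` of the genome (up to block rounding).  Replication
    tracks are phase-shifted sinusoids binned at ``replication_bin_size`` bp,
    standing in for a panel of cell types.
    """
    rng = _rng(config.seed, "genome")
    L = config.genome_length
    seq = "".join(rng.choice(list("ACGT"), size=L, p=config.base_composition))
    chrom = config.chrom_name

    n_slots = L // config.dhs_block_size
    n_blocks = int(round(config.dhs_fraction * L / config.dhs_block_size))
    n_blocks = max(1, min(n_blocks, n_slots))
    slots = np.sort(rng.choice(n_slots, size=n_blocks, replace=False))
    dhs = [GenomicInterval(chrom, int(s) * config.dhs_block_size,
                           (int(s) + 1) * config.dhs_block_size) for s in slots]

    tracks: dict[str, list[GenomicInterval]] = {}
    period = L / 2.0
    for t in range(config.n_replication_tracks):
        phase = t / config.n_replication_tracks
        ivs = []
        for start in range(0, L, config.replication_bin_size):
            end = min(start + config.replication_bin_size, L)
            x = (start + end) / 2.0
            value = 50.0 + 40.0 * np.sin(2.0 * np.pi * (x / period + phase))
            ivs.append(GenomicInterval(chrom, start, end, value=float(value)))
        tracks[f"cell{t + 1}"] = ivs
    return GenomeBundle(sequences={chrom: seq}, dhs=dhs, replication_tracks=tracks)


# ---------------------------------------------------------------------------
# somatic mutations
# ---------------------------------------------------------------------------


def simulate_mutations(
    config: SimulationConfig,
    genome: GenomeBundle,
    catalogue: SignatureCatalogue,
) -> tuple[list[MutationRecord], dict]:
    """Draw per-sample SNVs from the true signature mixture and place them.

    Each mutation is drawn by sampling one of the 96 context-change bins from
    the sample's mixture spectrum (signature probabilities weighted by the true
    exposures), then placed uniformly among genome positions carrying the
    matching pyrimidine-collapsed context.  Placement inside DHS is
    down-weighted by ``dhs_rate_ratio`` for non-remodeler samples; samples in
    ``apobec_samples`` have their TCW-bin probabilities multiplied by
    ``apobec_boost`` and renormalized.
    """
    if config.exposures_true is None:
        raise ValueError("config.exposures_true must be set to simulate mutations")
    exposures = np.asarray(config.exposures_true, dtype=float)
    if exposures.shape[1] != catalogue.n_signatures:
        raise ValueError("exposures_true column count must match the catalogue")

    index = genome.context_index()
    chroms = list(genome.sequences)
    tcw_idx = [CONTEXT_LABELS.index(l) for l in TCW_LABELS]
    ids = sample_ids(config)
    remodeler = set(config.remodeler_samples)
    apobec = set(config.apobec_samples)

    # placement weights for DHS-depleted samples depend only on the context,
    # so compute them once and share across samples
    depleted_weights: dict[str, np.ndarray] = {}

    def _weights_for(context: str) -> np.ndarray:
        if context not in depleted_weights:
            chrom_idx, positions, _ = index[context]
            w = np.ones(positions.size)
            for ci, chrom in enumerate(chroms):
                mask = genome.dhs_mask(chrom)
                sel = chrom_idx == ci
                w[sel] = np.where(mask[positions[sel] - 1], config.dhs_rate_ratio, 1.0)
            depleted_weights[context] = w / w.sum()
        return depleted_weights[context]

    records: list[MutationRecord] = []
    for i, sid in enumerate(ids):
        rng = _rng(config.seed, "mutations", i)
        p = catalogue.matrix @ exposures[i]
        p = p / p.sum()
        if i in apobec and config.apobec_boost != 1.0:
            p = p.copy()
            p[tcw_idx] *= config.apobec_boost
            p /= p.sum()
        bin_counts = rng.multinomial(config.mutations_per_sample, p)
        ratio = 1.0 if i in remodeler else config.dhs_rate_ratio
        for b in np.nonzero(bin_counts)[0]:
            label = CONTEXT_LABELS[b]
            context = trinucleotide_of(label)
            chrom_idx, positions, minus = index[context]
            if positions.size == 0:
                raise ValueError(f"context {context} absent from the simulated genome")
            weights = _weights_for(context) if ratio != 1.0 else None
            picks = rng.choice(positions.size, size=int(bin_counts[b]), replace=True, p=weights)
            ref_pyr, alt_pyr = label[2], label[4]
            for k in picks:
                if minus[k]:
                    ref, alt = COMPLEMENT[ref_pyr], COMPLEMENT[alt_pyr]
                else:
                    ref, alt = ref_pyr, alt_pyr
                records.append(MutationRecord(sample_id=sid, chrom=chroms[chrom_idx[k]],
                                              pos=int(positions[k]), ref=ref, alt=alt))
    manifest = {
        "sample_ids": ids,
        "exposures_true": exposures.tolist(),
        "signature_names": list(catalogue.names),
        "remodeler_samples": sorted(remodeler),
        "apobec_samples": sorted(apobec),
        "apobec_boost": config.apobec_boost,
        "dhs_rate_ratio": config.dhs_rate_ratio,
        "mutations_per_sample": config.mutations_per_sample,
    }
    return records, manifest


# ---------------------------------------------------------------------------
# signature catalogue
# ---------------------------------------------------------------------------


def simulate_signature_catalogue(
    n_signatures: int = 30,
    seed: int = 0,
    concentration: float = 0.2,
) -> SignatureCatalogue:
    """A random column-stochastic 96 x K catalogue with peaky, distinct columns.

    Columns are Dirichlet draws with a small concentration so each signature
    loads on a handful of contexts, mimicking the sparsity of curated
    catalogues.
    """
    rng = _rng(seed, "catalogue")
    matrix = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    matrix = np.maximum(matrix, 1e-12)
    matrix /= matrix.sum(axis=0, keepdims=True)
    names = tuple(f"Signature_{k + 1}" for k in range(n_signatures))
    return SignatureCatalogue(matrix=matrix, names=names)


def context_matched_catalogue(genome: GenomeBundle) -> SignatureCatalogue:
    """A one-signature catalogue whose bin probabilities mirror the genome.

    Each 96-class probability is proportional to the genomic frequency of the
    class's reference trinucleotide (alternate alleles uniform), so mutations
    drawn from it land uniformly over eligible sites.  This is the natural
    null for motif-enrichment analyses: the mutated-motif fraction then matches
    the context-available fraction in expectation (enrichment fold ~ 1).
    """
    index = genome.context_index()
    probs = np.empty(96)
    for i, label in enumerate(CONTEXT_LABELS):
        tri = trinucleotide_of(label)
        probs[i] = index[tri][1].size / 3.0
    probs /= probs.sum()
    return SignatureCatalogue(matrix=probs[:, None], names=("context_null",))


def cohort_exposures(
    n_samples: int,
    n_signatures: int,
    active: Sequence[int],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Exposure matrix with the same sparse mixture in every sample."""
    w = np.zeros(n_signatures)
    if weights is None:
        weights = np.full(len(active), 1.0 / len(active))
    w[list(active)] = np.asarray(weights, dtype=float)
    w /= w.sum()
    return np.tile(w, (n_samples, 1))


# ---------------------------------------------------------------------------
# clinical cohort, methylation, SVs
# ---------------------------------------------------------------------------


def simulate_survival(config: SimulationConfig, replicate: int = 0
                      ) -> tuple[list[ClinicalRecord], list[str]]:
    """Exponential survival with carrier-multiplied hazard, administrative censoring.

    Exactly ``n_carriers`` patients are heterozygous carriers; their hazard is
    ``carrier_hazard_ratio`` times baseline.  Deaths before the censoring
    horizon are recorded as cancer-specific ("With Tumor"); everyone else is
    censored at the horizon.
    """
    rng = _rng(config.seed, "survival", replicate)
    n = config.n_patients
    carriers = set(rng.choice(n, size=config.n_carriers, replace=False).tolist())
    base_hazard = np.log(2.0) / config.baseline_median_days
    records = []
    carrier_ids = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        genotype = "HET" if i in carriers else "REF_HOM"
        if genotype == "HET":
            carrier_ids.append(pid)
        hazard = base_hazard * (config.carrier_hazard_ratio if i in carriers else 1.0)
        t = rng.exponential(1.0 / hazard)
        if t < config.censor_horizon_days:
            records.append(ClinicalRecord(
                sample_id=pid, genotype=genotype, subtype="type2", m_stage="MX",
                n_stage="NX", tumor_status="With Tumor", days_followup=int(t),
                vital_status="dead", days_to_death=int(t)))
        else:
            records.append(ClinicalRecord(
                sample_id=pid, genotype=genotype, subtype="type2", m_stage="MX",
                n_stage="NX", tumor_status=None,
                days_followup=int(config.censor_horizon_days), vital_status="alive"))
    return records, carrier_ids


def simulate_methylation(config: SimulationConfig
                         ) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Two-cluster beta matrix with a designated hypermethylated site subset.

    Per-site baseline means are uniform in [0.2, 0.5]; cluster-1 samples at the
    first ``n_true_hyper`` sites have their mean shifted up by
    ``cluster_beta_shift``.  Betas are Beta-distributed at a common
    concentration.  Returns (matrix, cluster labels, true hyper site names).
    """
    rng = _rng(config.seed, "methylation")
    n_sites, shift, nu = config.n_sites, config.cluster_beta_shift, config.beta_concentration
    n1 = config.n_patients // 2
    samples = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    clusters = {s: ("cluster1" if i < n1 else "cluster2") for i, s in enumerate(samples)}
    sites = [f"cg{j + 1:06d}" for j in range(n_sites)]
    true_hyper = sites[:config.n_true_hyper]

    base_mean = rng.uniform(0.2, 0.5, size=n_sites)
    betas = np.empty((n_sites, config.n_patients))
    for j in range(n_sites):
        for i, s in enumerate(samples):
            mean = base_mean[j]
            if clusters[s] == "cluster1" and j < config.n_true_hyper:
                mean = min(mean + shift, 0.95)
            betas[j, i] = rng.beta(mean * nu, (1.0 - mean) * nu)
    df = pd.DataFrame(betas, index=sites, columns=samples)
    df.index.name = "site"
    return df, clusters, true_hyper


def _random_sv(rng: np.random.Generator, sample_id: str, sv_type: str | None = None,
               qual_flag: str = "PASS", pe: int | None = None, sr: int | None = None,
               mapq: int | None = None, base: int = 1) -> SVRecord:
    # decoys use a base offset placing them in a coordinate band disjoint from
    # ordinary calls, so accidental reciprocal overlaps with the population set
    # cannot blur the designed truth labels
    if sv_type is None:
        sv_type = str(rng.choice(["DEL", "DUP", "INV", "TRA"], p=[0.4, 0.15, 0.25, 0.2]))
    pe = int(rng.integers(3, 30)) if pe is None else pe
    sr = int(rng.integers(3, 30)) if sr is None else sr
    mapq = int(rng.integers(20, 61)) if mapq is None else mapq
    if sv_type == "TRA":
        return SVRecord(sv_type, "chr1", base + int(rng.integers(0, 8_000_000)), "chr2",
                        base + int(rng.integers(0, 8_000_000)), pe, sr, mapq, qual_flag,
                        sample_id)
    start = base + int(rng.integers(0, 8_000_000))
    length = int(rng.integers(500, 200_000))
    chrom = str(rng.choice(["chr1", "chr2"]))
    return SVRecord(sv_type, chrom, start, chrom, start + length, pe, sr, mapq,
                    qual_flag, sample_id)


def simulate_sv_tables(config: SimulationConfig
                       ) -> tuple[list[SVRecord], list[SVRecord], list[bool], dict[str, str]]:
    """SV calls with designed stable/unstable samples and filtering decoys.

    Returns ``(calls, population_set, keep_truth, stability_truth)`` where
    ``keep_truth[i]`` says whether ``calls[i]`` survives correct quality and
    germline filtering, and ``stability_truth`` maps sample to its designed
    post-filter stability class.  Decoys per sample: LowQual/weak-evidence
    calls and calls reciprocally matching a population record of the same type;
    one type-mismatched population overlap (a kept call) exercises the
    type-stratified rule.
    """
    rng = _rng(config.seed, "svs")
    calls: list[SVRecord] = []
    keep: list[bool] = []
    population: list[SVRecord] = []
    stability: dict[str, str] = {}

    n_total = config.n_stable_samples + config.n_unstable_samples
    for i in range(n_total):
        sid = f"S{i + 1:02d}"
        unstable = i >= config.n_stable_samples
        # stable draws capped at 8 so the extra type-mismatch probe (below,
        # assigned to S01) can never lift a stable sample to the 10-event bound
        n_true = int(rng.integers(41, 89)) if unstable else int(rng.integers(0, 9))
        stability[sid] = "unstable" if unstable else "stable"
        for _ in range(n_true):
            calls.append(_random_sv(rng, sid))
            keep.append(True)
        # low-quality decoys: explicit flag, weak evidence, poor mapping
        for d in range(config.n_lowqual_decoys):
            mode = d % 3
            if mode == 0:
                calls.append(_random_sv(rng, sid, qual_flag="LowQual"))
            elif mode == 1:
                calls.append(_random_sv(rng, sid, pe=2, sr=2))
            else:
                calls.append(_random_sv(rng, sid, mapq=int(rng.integers(0, 20))))
            keep.append(False)
        # germline decoys: exact reciprocal match in the population set,
        # placed in the reserved decoy coordinate band
        for _ in range(config.n_germline_decoys):
            sv = _random_sv(rng, sid, sv_type="DEL", base=20_000_001)
            calls.append(sv)
            keep.append(False)
            population.append(SVRecord("DEL", sv.chrom1, sv.pos1, sv.chrom2, sv.pos2,
                                       10, 10, 60, "PASS", "population"))
    # one retained call whose span matches a population record of ANOTHER type
    probe = _random_sv(rng, "S01", sv_type="DEL", base=40_000_001)
    calls.append(probe)
    keep.append(True)
    population.append(SVRecord("DUP", probe.chrom1, probe.pos1, probe.chrom2, probe.pos2,
                               10, 10, 60, "PASS", "population"))
    return calls, population, keep, stability


@dataclass
class CohortSimulation:
    """Everything ``simulate_cohort`` produces, with its ground-truth manifest."""

    clinical: list[ClinicalRecord]
    carrier_ids: list[str]
    betas: pd.DataFrame
    clusters: dict[str, str]
    true_hyper_sites: list[str]
    sv_calls: list[SVRecord]
    sv_population: list[SVRecord]
    sv_keep_truth: list[bool]
    stability_truth: dict[str, str]
    manifest: dict


def simulate_cohort(config: SimulationConfig) -> CohortSimulation:
    """Clinical records, methylation matrix and SV tables with ground truth."""
    clinical, carrier_ids = simulate_survival(config)
    betas, clusters, true_hyper = simulate_methylation(config)
    sv_calls, sv_pop, sv_keep, stability = simulate_sv_tables(config)
    manifest = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "carrier_ids": carrier_ids,
        "carrier_hazard_ratio": config.carrier_hazard_ratio,
        "cluster_beta_shift": config.cluster_beta_shift,
        "true_hyper_sites": true_hyper,
        "stability_truth": stability,
        "n_sv_calls": len(sv_calls),
        "n_sv_truth": int(sum(sv_keep)),
    }
    return CohortSimulation(clinical, carrier_ids, betas, clusters, true_hyper,
                            sv_calls, sv_pop, sv_keep, stability, manifest)


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    """Write a ground-truth manifest as JSON next to the simulated data."""
    with open(path, "w") as fh:
        json.dump(dict(manifest), fh, indent=2, sort_keys=True)
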