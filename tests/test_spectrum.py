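"""Context classification, genome-frequency normalization and spectra PCA."""

import numpy as np
import pandas as pd
import pytest

from somascape import spectrum as sp
from somascape import synthetic
from somascape.io_formats import GenomicInterval, MutationRecord
from somascape.spectrum import (CONTEXT_LABELS, TRINUCLEOTIDES_32, ContigEdgeError,
                                RefMismatchError, Spectrum96, reverse_complement)


def test_canonical_label_order_is_alphabetical():
    assert CONTEXT_LABELS[0] == "A[C>A]A"
    assert CONTEXT_LABELS[-1] == "T[T>G]T"
    assert list(CONTEXT_LABELS) == sorted(CONTEXT_LABELS)
    assert len(CONTEXT_LABELS) == 96 and len(set(CONTEXT_LABELS)) == 96


class TestClassifyContext:
    def test_pyrimidine_center_read_off(self):
        genome = {"chr1": "TTACGTT"}
        m = MutationRecord("s", "chr1", 4, "C", "T")
        assert sp.classify_context(genome, m) == "A[C>T]G"

    def test_purine_center_strand_collapse(self):
        genome = {"chr1": "TTCGTTT"}
        m = MutationRecord("s", "chr1", 4, "G", "A")
        assert sp.classify_context(genome, m) == "A[C>T]G"

    def test_all_192_raw_pairs_collapse_to_twin_label(self):
        """Each raw (context, change) pair and its reverse complement share a label.

        Brute-force enumeration over all 64 trinucleotides x 3 alternate bases.
        """
        for left in "ACGT":
            for center in "ACGT":
                for right in "ACGT":
                    tri = left + center + right
                    for alt in "ACGT":
                        if alt == center:
                            continue
                        fwd_genome = {"c": tri}
                        fwd = sp.classify_context(
                            fwd_genome, MutationRecord("s", "c", 2, center, alt))
                        rc_tri = reverse_complement(tri)
                        rc_alt = reverse_complement(alt)
                        rev = sp.classify_context(
                            {"c": rc_tri}, MutationRecord("s", "c", 2, rc_tri[1], rc_alt))
                        assert fwd == rev
                        assert fwd in CONTEXT_LABELS
                        assert fwd[2] in "CT"

    def test_ref_mismatch_raises(self):
        with pytest.raises(RefMismatchError, match="chr1:2"):
            sp.classify_context({"chr1": "AAA"}, MutationRecord("s", "chr1", 2, "C", "T"))

    def test_contig_edge_raises(self):
        with pytest.raises(ContigEdgeError):
            sp.classify_context({"chr1": "CCC"}, MutationRecord("s", "chr1", 1, "C", "T"))
        with pytest.raises(ContigEdgeError):
            sp.classify_context({"chr1": "CCC"}, MutationRecord("s", "chr1", 3, "C", "T"))


class TestContextFrequencies:
    def test_hand_enumeration_on_4mer(self):
        # "ACGT": window ACG has C center; window CGT has G center -> collapses to ACG
        counts = sp.count_trinucleotides({"chr1": "ACGT"})
        assert counts["ACG"] == 2
        assert counts.sum() == 2

    def test_degenerate_genome_rejected(self):
        # poly-A collapses every window to TTT only; other bins stay empty
        with pytest.raises(ValueError, match="zero-frequency"):
            sp.count_context_frequencies({"chr1": "A" * 100})

    def test_fully_masked_genome_rejected(self, sim_bundle):
        _, genome, *_ = sim_bundle
        chrom, seq = next(iter(genome.sequences.items()))
        with pytest.raises(ValueError):
            # mask covering nothing of the genome (empty coverage elsewhere)
            sp.count_context_frequencies({chrom: seq},
                                         [GenomicInterval("other_chrom", 0, 10)])

    def test_mask_restricts_counted_windows(self):
        genome = {"chr1": "ACGTACGTACGT"}
        full = sp.count_trinucleotides(genome)
        masked = sp.count_trinucleotides(genome, [GenomicInterval("chr1", 0, 4)])
        assert masked.sum() < full.sum()
        # mask centers are 1-based positions 2..4 -> windows ACG, CGT, GTA
        assert masked.sum() == 3

    def test_counts_cover_all_windows(self, sim_bundle):
        _, genome, *_ = sim_bundle
        seq = next(iter(genome.sequences.values()))
        counts = sp.count_trinucleotides({"chr1": seq})
        assert counts.sum() == len(seq) - 2

    def test_strand_collapse_symmetry(self, toy_genome_50bp):
        seq = toy_genome_50bp["chr1"]
        fwd = sp.count_trinucleotides({"c": seq})
        rev = sp.count_trinucleotides({"c": reverse_complement(seq)})
        assert fwd.equals(rev)


def _uniform_freq(value: int = 100) -> sp.ContextFrequencyTable:
    return sp.ContextFrequencyTable(pd.Series(value, index=list(TRINUCLEOTIDES_32)))


class TestBuildSpectra:
    def test_single_mutation_rate(self):
        genome = {"chr1": "TACGT"}
        freq = _uniform_freq(100)
        (s,) = sp.build_spectra([MutationRecord("s1", "chr1", 3, "C", "T")], genome, freq)
        assert s.counts["A[C>T]G"] == 1
        assert s.counts.sum() == 1
        assert s.rates["A[C>T]G"] == pytest.approx(0.01)

    def test_empty_mutation_set_gives_zero_spectrum(self):
        spectra = sp.build_spectra([], {"chr1": "ACGT"}, _uniform_freq(),
                                   sample_ids=["s1"])
        assert len(spectra) == 1 and spectra[0].counts.sum() == 0

    def test_counts_conserve_classified_mutations(self, sim_bundle):
        cfg, genome, catalogue, mutations, _ = sim_bundle
        freq = sp.count_context_frequencies(genome.sequences)
        spectra = sp.build_spectra(mutations, genome.sequences, freq)
        total = sum(s.n_mutations for s in spectra)
        assert total == len(mutations)  # simulated mutations never sit on edges

    def test_single_signature_sample_matches_generating_column(self, small_catalogue):
        """Cosine similarity of a one-signature sample's spectrum to the column > 0.95."""
        cfg = synthetic.SimulationConfig(seed=3, genome_length=60_000, n_samples=1,
                                         mutations_per_sample=10_000,
                                         remodeler_samples=(0,))
        genome = synthetic.simulate_genome(cfg)
        cfg.exposures_true = synthetic.cohort_exposures(1, 6, [2], [1.0])
        mutations, _ = synthetic.simulate_mutations(cfg, genome, small_catalogue)
        freq = sp.count_context_frequencies(genome.sequences)
        (s,) = sp.build_spectra(mutations, genome.sequences, freq)
        observed = s.proportions.to_numpy()
        expected = small_catalogue.matrix[:, 2]
        cos = observed @ expected / (np.linalg.norm(observed) * np.linalg.norm(expected))
        assert cos > 0.95

    def test_strand_symmetry_of_spectra(self, toy_genome_50bp):
        seq = toy_genome_50bp["chr1"]
        n = len(seq)
        muts, rc_muts = [], []
        for pos in (10, 20, 30):
            ref = seq[pos - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            muts.append(MutationRecord("s1", "chr1", pos, ref, alt))
            rc_muts.append(MutationRecord("s1", "chr1", n - pos + 1,
                                          reverse_complement(ref), reverse_complement(alt)))
        freq = _uniform_freq()
        (fwd,) = sp.build_spectra(muts, {"chr1": seq}, freq)
        (rev,) = sp.build_spectra(rc_muts, {"chr1": reverse_complement(seq)}, freq)
        assert fwd.counts.equals(rev.counts)

    def test_frame_round_trip(self, sim_bundle):
        cfg, genome, catalogue, mutations, _ = sim_bundle
        freq = sp.count_context_frequencies(genome.sequences)
        spectra = sp.build_spectra(mutations, genome.sequences, freq)
        again = sp.frame_to_spectra(sp.spectra_to_frame(spectra))
        for a, b in zip(spectra, again):
            assert a.sample_id == b.sample_id
            assert a.counts.equals(b.counts)
            assert np.allclose(a.rates, b.rates)


def _spectrum_from_counts(sample_id: str, counts: np.ndarray) -> Spectrum96:
    c = pd.Series(counts.astype(np.int64), index=list(CONTEXT_LABELS))
    return Spectrum96(sample_id, c, c / 100.0)


class TestSpectraPCA:
    def test_needs_three_samples(self):
        s = _spectrum_from_counts("a", np.ones(96))
        with pytest.raises(ValueError, match="3 samples"):
            sp.spectra_pca([s, s])

    def test_distinct_sample_separated_and_variance_sums_to_one(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 50, size=96)
        distinct = base.copy()
        distinct[:10] += 200
        spectra = [_spectrum_from_counts("dup1", base),
                   _spectrum_from_counts("dup2", base),
                   _spectrum_from_counts("odd", distinct)]
        res = sp.spectra_pca(spectra, use="rates")
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        pc1 = res.scores["PC1"]
        assert abs(pc1["odd"] - pc1["dup1"]) > 10 * abs(pc1["dup1"] - pc1["dup2"])

    def test_cpg_variation_dominates_pc1_loadings(self):
        """Inter-sample variation confined to the N[C>T]G bins drives PC1 there."""
        rng = np.random.default_rng(5)
        cpg_bins = [i for i, l in enumerate(CONTEXT_LABELS)
                    if l[2] == "C" and l[4] == "T" and l[6] == "G"]
        assert len(cpg_bins) == 4  # A/C/G/T left flank, 3' G
        spectra = []
        for i in range(12):
            counts = np.full(96, 30.0) + rng.normal(0, 1, 96).clip(-3, 3)
            counts[cpg_bins] += rng.uniform(0, 150)  # sample-varying CpG load
            spectra.append(_spectrum_from_counts(f"s{i}", counts.clip(0)))
        res = sp.spectra_pca(spectra, use="rates")
        top4 = res.loadings["PC1"].abs().nlargest(4).index
        assert set(top4) == {CONTEXT_LABELS[i] for i in cpg_bins}

    def test_scores_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        spectra = [_spectrum_from_counts(f"s{i}", rng.integers(0, 80, 96)) for i in range(6)]
        res1 = sp.spectra_pca(spectra)
        res2 = sp.spectra_pca(spectra[::-1])
        pd.testing.assert_frame_equal(res1.scores.sort_index(),
                                      res2.scores.sort_index(), atol=1e-8, rtol=0)
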