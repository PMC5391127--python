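"""MAF arithmetic, cancer-specific survival, association and methylation calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somascape import cohort as ch
from somascape import synthetic
from somascape.cohort import IndeterminateDeathError, SurvivalObservation
from somascape.io_formats import ClinicalRecord


class TestMinorAlleleFrequency:
    def test_fourteen_hets_of_277(self):
        genotypes = ["HET"] * 14 + ["REF_HOM"] * 263
        maf = ch.minor_allele_frequency(genotypes)
        assert round(100 * maf, 2) == 2.53

    def test_seven_hets_of_96(self):
        genotypes = ["HET"] * 7 + ["REF_HOM"] * 89
        assert round(100 * ch.minor_allele_frequency(genotypes), 2) == 3.65

    def test_all_reference(self):
        assert ch.minor_allele_frequency(["REF_HOM"] * 10) == 0.0

    def test_homozygous_alt_counts_twice(self):
        assert ch.minor_allele_frequency(["ALT_HOM", "REF_HOM"]) == 0.5

    def test_missing_excluded_from_denominator(self):
        assert ch.minor_allele_frequency(["HET", "missing", "REF_HOM"]) == 0.25

    def test_no_genotyped_samples_is_error(self):
        with pytest.raises(ValueError):
            ch.minor_allele_frequency(["missing"])

    def test_order_invariance_and_duplication(self):
        g = ["HET"] * 3 + ["REF_HOM"] * 7
        assert ch.minor_allele_frequency(g) == ch.minor_allele_frequency(g[::-1])
        assert ch.minor_allele_frequency(g * 2) == ch.minor_allele_frequency(g)


def _clin(vital="dead", tumor=None, m="M0", n="NX", dtd=100):
    return ClinicalRecord("p", "HET", "type2", m, n, tumor_status=tumor,
                          days_followup=dtd if dtd is not None else 0,
                          vital_status=vital,
                          days_to_death=dtd if vital == "dead" else None)


class TestCancerSpecificDeath:
    def test_with_tumor_is_event(self):
        assert ch.classify_cancer_specific_death(_clin(tumor="With Tumor"))

    def test_tumor_free_is_not(self):
        assert not ch.classify_cancer_specific_death(_clin(tumor="Tumor Free"))

    def test_alive_is_not(self):
        assert not ch.classify_cancer_specific_death(_clin(vital="alive", dtd=None))

    def test_no_criteria_met_late_death(self):
        assert not ch.classify_cancer_specific_death(_clin(m="M0", n="NX", dtd=1000))

    def test_lymph_node_involvement_n2(self):
        assert ch.classify_cancer_specific_death(_clin(n="N2", dtd=1000))

    def test_metastasis_m1(self):
        assert ch.classify_cancer_specific_death(_clin(m="M1", dtd=1000))

    def test_death_within_two_years(self):
        assert ch.classify_cancer_specific_death(_clin(dtd=730))
        assert not ch.classify_cancer_specific_death(_clin(dtd=731))

    def test_indeterminate_without_days(self):
        record = ClinicalRecord("p", "HET", "type2", "M0", "NX", vital_status="dead",
                                days_to_death=100)
        # forge a record lacking the death date by bypassing validation
        object.__setattr__(record, "days_to_death", None)
        with pytest.raises(IndeterminateDeathError):
            ch.classify_cancer_specific_death(record)


def independent_logrank(times, events, flags):
    """Textbook O(n) log-rank statistic, written independently of lifelines."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    flags = np.asarray(flags, bool)
    observed = expected = variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & flags).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & flags).sum()
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (observed - expected) ** 2 / variance


class TestSurvival:
    def test_identical_groups_statistic_near_zero(self):
        obs = [SurvivalObservation(f"a{i}", t, True, "a") for i, t in enumerate([1, 2, 3])]
        obs += [SurvivalObservation(f"b{i}", t, True, "b") for i, t in enumerate([1, 2, 3])]
        res = ch.km_and_tests(obs)
        assert res.logrank_p > 0.9
        assert res.peto_p > 0.9

    def test_toy_logrank_matches_permutation_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        flags = [False, False, False, True, True, True]
        obs = [SurvivalObservation(f"p{i}", t, True, "g2" if f else "g1")
               for i, (t, f) in enumerate(zip(times, flags))]
        res = ch.km_and_tests(obs)
        expected_stat = independent_logrank(times, [True] * 6, flags)
        assert res.logrank_statistic == pytest.approx(expected_stat, rel=1e-6)
        # permutation oracle: the observed statistic over all 20 label splits
        stats_all = []
        for combo in itertools.combinations(range(6), 3):
            f = [i in combo for i in range(6)]
            stats_all.append(independent_logrank(times, [True] * 6, f))
        perm_p = np.mean(np.asarray(stats_all) >= expected_stat - 1e-12)
        assert perm_p == pytest.approx(2 / 20)  # the two complete separations

    def test_km_curves_start_at_one_and_decrease(self):
        obs = [SurvivalObservation(f"p{i}", t, e, "g1" if i < 4 else "g2")
               for i, (t, e) in enumerate([(5, True), (8, False), (12, True), (20, True),
                                           (3, True), (9, True), (15, False), (18, True)])]
        res = ch.km_and_tests(obs)
        for curve in res.curves.values():
            s = curve["survival"]
            assert s.iloc[0] == 1.0
            assert (s.diff().dropna() <= 1e-12).all()

    def test_no_events_anywhere_is_error(self):
        obs = [SurvivalObservation("a", 5, False, "a"), SurvivalObservation("b", 6, False, "b")]
        with pytest.raises(ValueError, match="events"):
            ch.km_and_tests(obs)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="two groups"):
            ch.km_and_tests([SurvivalObservation("a", 5, True, "a")])

    def test_clinical_to_survival_times(self):
        records = [
            _clin(tumor="With Tumor", dtd=400),
            ClinicalRecord("p2", "REF_HOM", "type2", "M0", "NX", days_followup=900),
        ]
        obs = ch.clinical_to_survival(records)
        assert (obs[0].time, obs[0].event) == (400.0, True)
        assert (obs[1].time, obs[1].event) == (900.0, False)

    def test_carrier_effect_detected_on_seeded_cohort(self):
        cfg = synthetic.SimulationConfig(seed=13, carrier_hazard_ratio=5.0,
                                         n_patients=200, n_carriers=30)
        records, carriers = synthetic.simulate_survival(cfg)
        obs = ch.clinical_to_survival(records, group_by="genotype")
        res = ch.km_and_tests(obs)
        assert res.logrank_p < 0.05
        assert res.peto_p < 0.05


class TestCategoricalAssociation:
    def test_flat_table(self):
        odds, p, corrected = ch.categorical_association([[10, 10], [10, 10]])
        assert odds == 1.0 and p == 1.0 and not corrected

    def test_or_sixteen_matches_enumeration_oracle(self):
        odds, p, _ = ch.categorical_association([[8, 2], [2, 8]])
        assert odds == pytest.approx(16.0)
        # two-sided Fisher by exhaustive hypergeometric enumeration at fixed margins
        probs = [stats.hypergeom.pmf(a, 20, 10, 10) for a in range(0, 11)]
        p_obs = stats.hypergeom.pmf(8, 20, 10, 10)
        expected = sum(q for q in probs if q <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_zero_cell_haldane_correction(self):
        odds, p, corrected = ch.categorical_association([[5, 0], [2, 8]])
        assert corrected and np.isfinite(odds) and odds > 1

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            ch.categorical_association([[0, 0], [0, 0]])


class TestDifferentialMethylation:
    def _clusters(self, n1, n2):
        samples = [f"P{i:03d}" for i in range(n1 + n2)]
        return samples, {s: ("c1" if i < n1 else "c2") for i, s in enumerate(samples)}

    def test_identical_distribution_not_called(self):
        rng = np.random.default_rng(0)
        samples, clusters = self._clusters(10, 10)
        beta = pd.DataFrame(rng.beta(3, 7, size=(20, 20)), columns=samples,
                            index=[f"cg{i}" for i in range(20)])
        calls = ch.differential_methylation(beta, clusters, "c1", "c2")
        assert not calls["hypermethylated"].any()

    def test_seeded_true_sites_recovered(self):
        """The designated shifted sites dominate the recovered hypermethylated set."""
        cfg = synthetic.SimulationConfig(seed=21, n_patients=60, n_sites=100,
                                         n_true_hyper=10, cluster_beta_shift=0.3)
        beta, clusters, true_sites = synthetic.simulate_methylation(cfg)
        calls = ch.differential_methylation(beta, clusters, "cluster1", "cluster2")
        called = set(calls.index[calls["hypermethylated"]])
        assert called == set(true_sites)

    def test_large_p_small_delta_not_called(self):
        rng = np.random.default_rng(3)
        samples, clusters = self._clusters(30, 30)
        base = rng.beta(10, 20, size=(1, 60))
        beta = pd.DataFrame(np.clip(base + np.where(
            [[clusters[s] == "c1" for s in samples]], 0.1, 0.0), 0, 1),
            columns=samples, index=["cg1"])
        calls = ch.differential_methylation(beta, clusters, "c1", "c2")
        # significant shift but below the 0.2 effect floor -> not called
        assert calls.loc["cg1", "p_adjusted"] < 0.05
        assert not calls.loc["cg1", "hypermethylated"]

    def test_missing_values_and_excluded_chromosomes_dropped(self):
        rng = np.random.default_rng(4)
        samples, clusters = self._clusters(5, 5)
        beta = pd.DataFrame(rng.beta(2, 5, size=(3, 10)), columns=samples,
                            index=["cg1", "cg2", "cg3"])
        beta.iloc[0, 0] = np.nan
        calls = ch.differential_methylation(
            beta, clusters, "c1", "c2", exclude_chroms=["chrX"],
            site_chroms={"cg2": "chrX", "cg3": "chr5"})
        assert list(calls.index) == ["cg3"]

    def test_absent_cluster_is_error(self):
        samples, clusters = self._clusters(5, 5)
        beta = pd.DataFrame(np.full((2, 10), 0.5), columns=samples, index=["a", "b"])
        with pytest.raises(ValueError, match="clusters"):
            ch.differential_methylation(beta, clusters, "c1", "nonexistent")
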