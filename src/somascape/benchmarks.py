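"""End-to-end study-condition runs with known ground truth.

Each function here wires the synthetic generators through the analysis modules
at the package's standard problem sizes and reports recovery/calibration
metrics.  The worked examples reproduce printed cohort arithmetic (allele
frequencies, regional recurrence) from their integer inputs; the simulation
studies measure parameter recovery, detection and test calibration under the
generators' default conditions.  Both the acceptance tests and the acceptance
script drive these entry points.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np

from . import apobec as apobec_mod
from . import cohort as cohort_mod
from . import landscape as landscape_mod
from . import signatures as sig_mod
from . import spectrum as spectrum_mod
from . import sv_filter as sv_mod
from . import synthetic
from .io_formats import GenomicInterval, IntervalSet, MutationRecord
from .synthetic import SimulationConfig


def _group(mutations):
    grouped: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        grouped.setdefault(m.sample_id, []).append(m)
    return grouped


# ---------------------------------------------------------------------------
# worked examples on printed cohort numbers
# ---------------------------------------------------------------------------


def maf_worked_examples() -> dict[str, float]:
    """Risk-allele frequencies of the genotyped cohorts (percent).

    277 patients with 14 heterozygous carriers overall; 96 type-II patients
    with 7 carriers.
    """
    overall = cohort_mod.minor_allele_frequency(["HET"] * 14 + ["REF_HOM"] * 263)
    type2 = cohort_mod.minor_allele_frequency(["HET"] * 7 + ["REF_HOM"] * 89)
    return {"maf_overall_pct": round(100 * overall, 2),
            "maf_type2_pct": round(100 * type2, 2)}


def recurrence_worked_example() -> dict[str, float]:
    """Regional recurrence: 6 of 35 samples hitting one 6.5-kb hotspot (percent)."""
    region = GenomicInterval("chr1", 10_000, 16_500, name="hotspot")
    muts = {}
    for i in range(35):
        sid = f"S{i + 1:02d}"
        pos = 10_500 + i if i < 6 else 50_000 + i  # first six inside the region
        muts[sid] = [MutationRecord(sid, "chr1", pos, "C", "T")]
    table = landscape_mod.region_recurrence(muts, [region])
    return {"hotspot_recurrence_pct": round(100 * float(table.loc["hotspot", "fraction"]), 1)}


# ---------------------------------------------------------------------------
# signature refitting
# ---------------------------------------------------------------------------


def signature_recovery_study(
    seed: int,
    n_samples: int = 20,
    mutations_per_sample: int = 10_000,
    n_signatures: int = 30,
    active: tuple[int, ...] = (2, 7, 15),
    weights: tuple[float, ...] = (0.5, 0.3, 0.2),
    floor: float = 0.05,
) -> dict[str, float]:
    """Exposure recovery from a 3-active-signature cohort against a 30-column catalogue.

    Returns the mean absolute error of recovered proportions over the active
    signatures and the fraction of samples retaining no inactive signature
    after the contribution floor.
    """
    catalogue = synthetic.simulate_signature_catalogue(n_signatures, seed=seed)
    cfg = SimulationConfig(seed=seed, genome_length=120_000, n_samples=n_samples,
                           mutations_per_sample=mutations_per_sample,
                           dhs_rate_ratio=1.0, remodeler_samples=())
    genome = synthetic.simulate_genome(cfg)
    cfg.exposures_true = synthetic.cohort_exposures(n_samples, n_signatures, active, weights)
    mutations, _ = synthetic.simulate_mutations(cfg, genome, catalogue)
    freq = spectrum_mod.count_context_frequencies(genome.sequences)
    spectra = spectrum_mod.build_spectra(mutations, genome.sequences, freq)

    true_props = dict(zip(active, np.asarray(weights) / np.sum(weights)))
    abs_errors = []
    clean_support = 0
    for s in spectra:
        fit = sig_mod.select_lambda(s.counts.to_numpy(float), catalogue,
                                    rng_seed=seed, sample_id=s.sample_id)
        fit = sig_mod.filter_exposures(fit, floor=floor)
        props = fit.proportions
        for j, p_true in true_props.items():
            abs_errors.append(abs(float(props.iloc[j]) - p_true))
        retained_idx = {list(catalogue.names).index(n) for n in fit.retained}
        if retained_idx <= set(active):
            clean_support += 1
    return {
        "signature_recovery_mae": float(np.mean(abs_errors)),
        "signature_clean_support_fraction": clean_support / len(spectra),
        "n_samples": len(spectra),
    }


def lasso_oracle_study(seed: int, n_instances: int = 200) -> dict[str, float]:
    """Coordinate-descent objective vs an independent bound-constrained solver.

    Random K <= 6 instances; reports the largest objective excess of the
    coordinate-descent solution over the oracle (negative = descent was better).
    """
    from scipy import optimize

    rng = np.random.default_rng(seed)
    worst_gap = -np.inf
    for _ in range(n_instances):
        k = int(rng.integers(2, 7))
        S = rng.dirichlet(np.full(96, 0.3), size=k).T
        w_true = rng.uniform(0, 50, size=k) * (rng.random(k) < 0.6)
        m = S @ w_true + rng.uniform(0, 0.5, size=96)
        lam = float(rng.uniform(0.0, 5.0))

        w_cd = sig_mod.fit_exposures(m, S, lam)
        obj_cd = sig_mod.lasso_objective(S, m, w_cd, lam)

        def fun(w, S=S, m=m, lam=lam):
            r = S @ w - m
            return r @ r + lam * w.sum()

        def grad(w, S=S, m=m, lam=lam):
            return 2.0 * S.T @ (S @ w - m) + lam

        res = optimize.minimize(fun, np.zeros(k), jac=grad, method="L-BFGS-B",
                                bounds=[(0, None)] * k,
                                options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
        obj_oracle = sig_mod.lasso_objective(S, m, res.x, lam)
        worst_gap = max(worst_gap, obj_cd - obj_oracle)
    return {"lasso_worst_objective_gap": float(worst_gap), "n_instances": n_instances}


# ---------------------------------------------------------------------------
# APOBEC enrichment
# ---------------------------------------------------------------------------


def apobec_calibration_study(
    seed: int,
    n_null_samples: int = 100,
    n_detection_samples: int = 31,
    boost: float = 5.0,
    mutations_per_sample: int = 500,
) -> dict[str, float]:
    """Null calibration and single-sample detection of the TCW enrichment scan.

    Null: mutation bins drawn in proportion to genomic context availability
    (fold ~ 1 by construction); reports the BH-significant fraction.
    Detection: one boosted sample among nulls; reports whether exactly that
    sample is called enriched.
    """
    base = SimulationConfig(seed=seed, genome_length=100_000,
                            n_samples=n_null_samples,
                            mutations_per_sample=mutations_per_sample,
                            dhs_rate_ratio=1.0, remodeler_samples=())
    genome = synthetic.simulate_genome(base)
    null_catalogue = synthetic.context_matched_catalogue(genome)
    base.exposures_true = np.ones((n_null_samples, 1))
    null_muts, _ = synthetic.simulate_mutations(base, genome, null_catalogue)
    null_results = apobec_mod.enrichment_scan(genome.sequences, _group(null_muts))
    null_fraction = float(np.mean([r.enriched for r in null_results]))

    det_cfg = SimulationConfig(seed=seed + 1, genome_length=100_000,
                               n_samples=n_detection_samples,
                               mutations_per_sample=mutations_per_sample,
                               dhs_rate_ratio=1.0, remodeler_samples=(),
                               apobec_boost=boost, apobec_samples=(0,))
    det_cfg.exposures_true = np.ones((n_detection_samples, 1))
    det_muts, manifest = synthetic.simulate_mutations(det_cfg, genome, null_catalogue)
    det_results = apobec_mod.enrichment_scan(genome.sequences, _group(det_muts))
    enriched = {r.sample_id for r in det_results if r.enriched}
    target = {manifest["sample_ids"][i] for i in manifest["apobec_samples"]}
    boosted_fold = next(r.enrichment_fold for r in det_results
                        if r.sample_id in target)
    return {
        "apobec_null_significant_fraction": null_fraction,
        "apobec_detection_exact": float(enriched == target),
        "apobec_boosted_fold": float(boosted_fold),
        "n_null_samples": n_null_samples,
    }


# ---------------------------------------------------------------------------
# landscape group comparison
# ---------------------------------------------------------------------------


def landscape_power_study(seed: int, n_replicates: int = 100,
                          alpha: float = 0.05) -> dict[str, float]:
    """Power of the one-sided rank-sum DHS-fraction comparison at default conditions.

    Each replicate redraws the cohort's mutations on a fixed genome (9
    remodeler-mutant samples placing mutations uniformly, 26 wild-type samples
    depleted inside DHS) and tests whether mutant DHS fractions are larger.
    Also reports the realized wild-type -> mutant shift in median DHS counts.
    """
    base = SimulationConfig(seed=seed, genome_length=100_000)
    genome = synthetic.simulate_genome(base)
    catalogue = synthetic.context_matched_catalogue(genome)
    dhs = IntervalSet(genome.dhs)
    remodeler = set(base.remodeler_samples)

    rejections = 0
    median_shifts = []
    for rep in range(n_replicates):
        cfg = dc_replace(base, seed=seed + 1000 + rep)
        cfg.exposures_true = np.ones((cfg.n_samples, 1))
        muts, manifest = synthetic.simulate_mutations(cfg, genome, catalogue)
        stats_df = landscape_mod.dhs_stats(_group(muts), dhs)
        ids = manifest["sample_ids"]
        flags = [ids.index(s) in remodeler for s in stats_df.index]
        _, p = landscape_mod.compare_groups(stats_df["frac_dhs"].to_numpy(), flags,
                                            alternative="greater")
        if p < alpha:
            rejections += 1
        counts = stats_df["n_dhs"]
        mut_median = counts[np.asarray(flags)].median()
        wt_median = counts[~np.asarray(flags)].median()
        median_shifts.append(mut_median / wt_median if wt_median > 0 else np.nan)
    return {
        "dhs_ranksum_power": rejections / n_replicates,
        "dhs_median_count_ratio": float(np.nanmean(median_shifts)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# survival testing
# ---------------------------------------------------------------------------


def survival_power_study(seed: int, n_replicates: int = 200,
                         alpha: float = 0.05) -> dict[str, float]:
    """Power at hazard ratio 3 (n=96, 7 carriers) and type-I error at ratio 1."""
    def rejection_rates(hazard_ratio: float, seed_offset: int) -> tuple[float, float]:
        cfg = SimulationConfig(seed=seed + seed_offset,
                               carrier_hazard_ratio=hazard_ratio)
        lr = pp = 0
        for rep in range(n_replicates):
            records, _ = synthetic.simulate_survival(cfg, replicate=rep)
            obs = cohort_mod.clinical_to_survival(records, group_by="genotype")
            res = cohort_mod.km_and_tests(obs)
            lr += res.logrank_p < alpha
            pp += res.peto_p < alpha
        return lr / n_replicates, pp / n_replicates

    power_lr, power_pp = rejection_rates(3.0, 0)
    t1_lr, t1_pp = rejection_rates(1.0, 50_000)
    return {
        "survival_logrank_power": power_lr,
        "survival_peto_power": power_pp,
        "survival_logrank_type1": t1_lr,
        "survival_peto_type1": t1_pp,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# SV filtering
# ---------------------------------------------------------------------------


def sv_filter_study(seed: int) -> dict[str, float]:
    """Exact recovery of the designed SV truth set and stability classes."""
    cfg = SimulationConfig(seed=seed)
    calls, population, keep_truth, stability_truth = synthetic.simulate_sv_tables(cfg)
    retained = sv_mod.population_filter(sv_mod.quality_filter(calls), population)
    expected = [sv for sv, keep in zip(calls, keep_truth) if keep]

    by_sample: dict[str, list] = {s: [] for s in stability_truth}
    for sv in retained:
        by_sample[sv.sample_id].append(sv)
    stability_calls = sv_mod.classify_stability(by_sample)
    stability_exact = all(c.category == stability_truth[c.sample_id] for c in stability_calls)
    return {
        "sv_truth_set_exact": float(retained == expected),
        "sv_stability_exact": float(stability_exact),
        "sv_n_calls": len(calls),
        "sv_n_retained": len(retained),
    }
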