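"""Cohort-level statistics: allele frequency, survival, association, methylation.

Cancer-specific survival (CSS) treats a death as an event only when it is
attributable to the tumor: the patient died "With Tumor", or — when tumor
status is unrecorded — had distant metastasis (M1), lymph-node involvement
(>= N1) or died within two years of diagnosis.  Group survival differences are
tested with the standard log-rank statistic and with the Peto & Peto
modification of the Gehan-Wilcoxon test, which down-weights late follow-up
using the pooled survival estimate.  Differential methylation between two
sample clusters combines a per-site two-sided rank-sum test (BH-corrected)
with an absolute effect-size filter on the mean beta difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ClinicalRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele frequency
# ---------------------------------------------------------------------------


def minor_allele_frequency(genotypes: Iterable[str]) -> float:
    """Minor-allele frequency from genotype calls; missing calls are excluded.

    MAF = (HET + 2 * ALT_HOM) / (2 * n_genotyped).
    """
    n_genotyped = 0
    minor = 0
    for g in genotypes:
        if g == "missing":
            continue
        if g not in ("REF_HOM", "HET", "ALT_HOM"):
            raise ValueError(f"unknown genotype {g!r}")
        n_genotyped += 1
        minor += {"REF_HOM": 0, "HET": 1, "ALT_HOM": 2}[g]
    if n_genotyped == 0:
        raise ValueError("no genotyped samples")
    return minor / (2 * n_genotyped)


# ---------------------------------------------------------------------------
# cancer-specific survival
# ---------------------------------------------------------------------------


class IndeterminateDeathError(ValueError):
    """Death cause cannot be classified from the available fields."""


def _n_stage_at_least_1(n_stage: str) -> bool:
    digits = "".join(ch for ch in n_stage if ch.isdigit())
    return bool(digits) and int(digits) >= 1


def classify_cancer_specific_death(record: ClinicalRecord,
                                   two_year_days: int = 730) -> bool:
    """Whether a patient's death counts as cancer-specific."""
    if record.vital_status == "alive":
        return False
    if record.tumor_status is not None:
        return record.tumor_status.strip().lower() == "with tumor"
    if record.m_stage.strip().upper() == "M1":
        return True
    if _n_stage_at_least_1(record.n_stage):
        return True
    if record.days_to_death is None:
        raise IndeterminateDeathError(
            f"{record.sample_id}: dead without tumor status or days_to_death; "
            "two-year rule cannot be applied"
        )
    return record.days_to_death <= two_year_days


@dataclass(frozen=True)
class SurvivalObservation:
    """One subject's follow-up time, event indicator and group label."""

    sample_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.sample_id}: negative follow-up time")


def clinical_to_survival(
    records: Sequence[ClinicalRecord],
    group_by: str = "genotype",
) -> list[SurvivalObservation]:
    """Build CSS observations: events are cancer-specific deaths.

    Follow-up time is days_to_death for the deceased and days_followup for the
    censored (non-cancer deaths are censored at death).
    """
    obs = []
    for r in records:
        event = classify_cancer_specific_death(r)
        time = r.days_to_death if r.vital_status == "dead" else r.days_followup
        obs.append(SurvivalObservation(r.sample_id, float(time), event, getattr(r, group_by)))
    return obs


@dataclass(frozen=True)
class SurvivalComparison:
    """Kaplan-Meier curves plus log-rank and Peto-Peto test results."""

    curves: dict[str, pd.DataFrame]     # per group: time, survival, censor marks
    logrank_statistic: float
    logrank_p: float
    peto_statistic: float
    peto_p: float


def km_and_tests(observations: Sequence[SurvivalObservation]) -> SurvivalComparison:
    """Kaplan-Meier estimates per group with log-rank and Peto-Peto tests.

    The log-rank test uses unit weights; the Peto-Peto modification of the
    Gehan-Wilcoxon test weights each event time by the left-continuous pooled
    survival estimate.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = sorted({o.group for o in observations})
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    if not any(o.event for o in observations):
        raise ValueError("no events in any group; tests undefined")

    times = np.array([o.time for o in observations], dtype=float)
    events = np.array([o.event for o in observations], dtype=bool)
    labels = np.array([o.group for o in observations])

    curves = {}
    for g in groups:
        sel = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=g)
        df = kmf.survival_function_.rename(columns={g: "survival"})
        df["at_risk"] = kmf.event_table["at_risk"].reindex(df.index)
        censor_times = sorted(times[sel & ~events])
        df.attrs["censor_times"] = censor_times
        curves[g] = df

    lr = multivariate_logrank_test(times, labels, events)
    pp = multivariate_logrank_test(times, labels, events, weightings="peto")
    return SurvivalComparison(
        curves=curves,
        logrank_statistic=float(lr.test_statistic), logrank_p=float(lr.p_value),
        peto_statistic=float(pp.test_statistic), peto_p=float(pp.p_value),
    )


# ---------------------------------------------------------------------------
# categorical association
# ---------------------------------------------------------------------------


def categorical_association(table: Sequence[Sequence[int]]) -> tuple[float, float, bool]:
    """Odds ratio and two-tailed Fisher exact p for a 2x2 count table.

    The Haldane 0.5 continuity correction is applied to the odds ratio only
    when a zero cell would make it undefined; the returned flag reports whether
    the correction was used.  The p-value always uses the uncorrected counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of non-negative integer counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    a, b, c, d = t.ravel()
    corrected = False
    if (b == 0 or c == 0 or a == 0 or d == 0):
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a2 * d2) / (b2 * c2)
        corrected = True
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return float(odds), float(p), corrected


# ---------------------------------------------------------------------------
# differential methylation
# ---------------------------------------------------------------------------


def differential_methylation(
    beta: pd.DataFrame,
    clusters: Mapping[str, str],
    cluster_a: str,
    cluster_b: str,
    alpha: float = 0.05,
    delta: float = 0.2,
    exclude_chroms: Iterable[str] = (),
    site_chroms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Call sites hypermethylated in cluster A relative to cluster B.

    Sites with any missing value, or located on an excluded chromosome, are
    dropped first.  Each remaining site gets a two-sided Wilcoxon rank-sum
    p-value comparing beta values between the two clusters, BH-adjusted across
    retained sites.  A site is called hypermethylated iff adjusted p < alpha
    AND mean(beta_A) - mean(beta_B) >= delta.
    """
    samples_a = [s for s in beta.columns if clusters.get(s) == cluster_a]
    samples_b = [s for s in beta.columns if clusters.get(s) == cluster_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"both clusters need >= 2 samples (got {len(samples_a)} in {cluster_a!r}, "
            f"{len(samples_b)} in {cluster_b!r})"
        )
    excluded = set(exclude_chroms)
    keep = beta.notna().all(axis=1)
    if excluded and site_chroms is not None:
        on_excluded = beta.index.map(lambda s: site_chroms.get(s) in excluded)
        keep &= ~np.asarray(on_excluded, dtype=bool)
    mat = beta.loc[keep]
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d site(s) with missing values or on excluded chromosomes", n_dropped)
    if mat.empty:
        raise ValueError("no sites left after filtering")

    a = mat[samples_a].to_numpy(dtype=float)
    b = mat[samples_b].to_numpy(dtype=float)
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    delta_mean = a.mean(axis=1) - b.mean(axis=1)
    out = pd.DataFrame({
        "mean_a": a.mean(axis=1),
        "mean_b": b.mean(axis=1),
        "delta_mean": delta_mean,
        "p_value": pvals,
        "p_adjusted": p_adj,
        "hypermethylated": (p_adj < alpha) & (delta_mean >= delta),
    }, index=mat.index)
    out.index.name = "site"
    return out
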