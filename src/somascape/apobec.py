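"""APOBEC TCW-motif enrichment per sample.

APOBEC cytidine deaminases preferentially mutate cytosines in a T-C-W motif
(W = A or T), producing C>T and C>G changes; on the opposite strand the motif
reads W-G-A with G>A and G>C changes.  For every qualifying cytosine mutation
(C>{T,G} or G>{A,C}) a +/- ``window`` bp reference sequence around it is
collected, and the enrichment fold compares the motif fraction among mutations
with the motif fraction available in those windows:

    fold = (mut_tcw * ctx_c) / (mut_c * ctx_tcw)

where ``mut_tcw`` counts qualifying mutations inside the motif, ``mut_c`` all
qualifying cytosine/guanine mutations, ``ctx_tcw`` the TCW/WGA occurrences in
the windows and ``ctx_c`` the C/G bases in the windows.  Significance is a
one-sided Fisher exact test on the corresponding 2 x 2 table, corrected across
samples by Benjamini-Hochberg; a sample is called enriched when the adjusted
p-value clears ``alpha`` and the fold exceeds one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MutationRecord
from .spectrum import RefMismatchError

log = logging.getLogger(__name__)

TCW_MOTIFS = ("TCA", "TCT")       # forward-strand target
WGA_MOTIFS = ("TGA", "AGA")       # reverse-strand mirror


def classify_apobec_mutation(genome: Mapping[str, str], m: MutationRecord) -> str:
    """Classify one mutation as ``tcw``, ``c_other`` or ``not_qualifying``."""
    seq = genome[m.chrom]
    ref_base = str(seq[m.pos - 1:m.pos]).upper()
    if ref_base != m.ref:
        raise RefMismatchError(
            f"{m.sample_id} {m.chrom}:{m.pos}: genome has {ref_base}, record says {m.ref}"
        )
    if m.ref == "C" and m.alt in ("T", "G"):
        trinuc = str(seq[m.pos - 2:m.pos + 1]).upper() if m.pos >= 2 else ""
        return "tcw" if trinuc in TCW_MOTIFS else "c_other"
    if m.ref == "G" and m.alt in ("A", "C"):
        trinuc = str(seq[m.pos - 2:m.pos + 1]).upper() if m.pos >= 2 else ""
        return "tcw" if trinuc in WGA_MOTIFS else "c_other"
    return "not_qualifying"


def _count_motifs(seq: str) -> int:
    n = 0
    for i in range(len(seq) - 2):
        tri = seq[i:i + 3]
        if tri in TCW_MOTIFS or tri in WGA_MOTIFS:
            n += 1
    return n


def collect_context(
    genome: Mapping[str, str],
    mutations: Sequence[MutationRecord],
    window: int = 20,
) -> tuple[int, int]:
    """Motif and C/G availability in the windows around qualifying mutations.

    Each qualifying (tcw or c_other) mutation contributes its own +/-``window``
    bp reference sequence, clipped at contig edges; overlapping windows are
    counted with multiplicity.  Returns ``(ctx_tcw, ctx_c)``.
    """
    ctx_tcw = 0
    ctx_c = 0
    for m in mutations:
        if classify_apobec_mutation(genome, m) == "not_qualifying":
            continue
        seq = genome[m.chrom]
        start = max(0, m.pos - 1 - window)
        end = min(len(seq), m.pos + window)
        win = str(seq[start:end]).upper()
        ctx_tcw += _count_motifs(win)
        ctx_c += win.count("C") + win.count("G")
    return ctx_tcw, ctx_c


@dataclass(frozen=True)
class ApobecResult:
    """Per-sample TCW enrichment counts, fold and significance."""

    sample_id: str
    mut_tcw: int
    mut_c: int
    ctx_tcw: int
    ctx_c: int
    enrichment_fold: float
    p_value: float
    p_adjusted: float = float("nan")
    enriched: bool = False
    testable: bool = True


def enrichment_test(sample_id: str, mut_tcw: int, mut_c: int,
                    ctx_tcw: int, ctx_c: int) -> ApobecResult:
    """Fold and one-sided Fisher p for one sample's counts (unadjusted)."""
    if mut_c == 0:
        log.warning("%s: no qualifying cytosine mutations; not testable", sample_id)
        return ApobecResult(sample_id, mut_tcw, mut_c, ctx_tcw, ctx_c,
                            float("nan"), float("nan"), testable=False)
    if ctx_tcw == 0:
        fold = math.inf if mut_tcw > 0 else float("nan")
        if mut_tcw > 0:
            log.warning("%s: motif absent from context windows; fold reported as +inf", sample_id)
        return ApobecResult(sample_id, mut_tcw, mut_c, ctx_tcw, ctx_c,
                            fold, float("nan"), testable=False)
    fold = (mut_tcw * ctx_c) / (mut_c * ctx_tcw)
    table = [[mut_tcw, mut_c - mut_tcw], [ctx_tcw, ctx_c - ctx_tcw]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return ApobecResult(sample_id, mut_tcw, mut_c, ctx_tcw, ctx_c, fold, float(p))


def enrichment_scan(
    genome: Mapping[str, str],
    mutations_by_sample: Mapping[str, Sequence[MutationRecord]],
    window: int = 20,
    alpha: float = 0.05,
) -> list[ApobecResult]:
    """Run the full per-sample enrichment analysis with BH correction.

    The Benjamini-Hochberg family is the set of testable samples in this
    invocation.  ``enriched`` additionally requires fold > 1 (one-sided claim).
    """
    raw: list[ApobecResult] = []
    for sample_id in sorted(mutations_by_sample):
        muts = mutations_by_sample[sample_id]
        mut_tcw = mut_c = 0
        for m in muts:
            cls = classify_apobec_mutation(genome, m)
            if cls == "tcw":
                mut_tcw += 1
                mut_c += 1
            elif cls == "c_other":
                mut_c += 1
        ctx_tcw, ctx_c = collect_context(genome, muts, window=window)
        raw.append(enrichment_test(sample_id, mut_tcw, mut_c, ctx_tcw, ctx_c))

    testable = [r for r in raw if r.testable]
    if testable:
        _, p_adj, _, _ = multipletests([r.p_value for r in testable], method="fdr_bh")
        adjusted = dict(zip((r.sample_id for r in testable), p_adj))
    else:
        adjusted = {}
    results = []
    for r in raw:
        if r.sample_id in adjusted:
            p_adj = float(adjusted[r.sample_id])
            enriched = bool(p_adj < alpha and r.enrichment_fold > 1.0)
            results.append(ApobecResult(r.sample_id, r.mut_tcw, r.mut_c, r.ctx_tcw,
                                        r.ctx_c, r.enrichment_fold, r.p_value,
                                        p_adj, enriched))
        else:
            results.append(r)
    return results


def results_to_frame(results: Sequence[ApobecResult]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "sample_id": r.sample_id, "mut_tcw": r.mut_tcw, "mut_c": r.mut_c,
        "ctx_tcw": r.ctx_tcw, "ctx_c": r.ctx_c, "enrichment_fold": r.enrichment_fold,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted, "enriched": r.enriched,
    } for r in results])
    return df.set_index("sample_id")
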