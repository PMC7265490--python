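"""Authentic-tail calling by background subtraction.

Ligation artifacts put spurious "tails" on reads in every library.  When a
treatment library exposes miRNA 3' ends (e.g. an Argonaute PAZ-pocket
mutant IP) while a control library keeps them protected (wild-type IP),
tail classes genuinely added in vivo are enriched in the treatment whereas
ligation noise appears at similar frequency in both.  We therefore compare
per-(nucleotide, k) class frequencies between the two libraries with a
pseudocounted log2 ratio and call classes exceeding an enrichment and a
minimum-frequency threshold.  Normalization is within-miRNA: each class
frequency is over that miRNA's reads, so library-size differences cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .stats import NUCLEOTIDES, TailProfile, tail_nt_counts


@dataclass(frozen=True)
class EnrichmentResult:
    mirna_id: str
    nt: str
    k: int
    freq_treat: float
    freq_ctrl: float
    enrichment: float  # log2(freq_treat / freq_ctrl), pseudocounted
    called: bool


def enrich_tails(
    profile_treat: TailProfile,
    profile_ctrl: TailProfile,
    pseudocount: float = 0.5,
    threshold_log2: float = 1.0,
    min_freq: float = 1e-3,
    exact_tails: bool = False,
) -> list[EnrichmentResult]:
    """Per-(nt, k) tail-class enrichment of treatment over control.

    freq = (count + pseudocount) / (total + pseudocount); enrichment is the
    log2 frequency ratio; a class is called authentic when enrichment >=
    ``threshold_log2`` and freq_treat >= ``min_freq``.  Classes for every
    nucleotide are always emitted (k from 1 to the larger library's
    maximum, minimum 1) so depletion is visible.  With ``exact_tails`` the
    classes are full tail strings instead of (nt, k) composition classes.
    """
    import math

    if profile_treat.mirna_id != profile_ctrl.mirna_id:
        raise ValueError(
            f"mirna_id mismatch: {profile_treat.mirna_id} vs {profile_ctrl.mirna_id}"
        )
    tot_t = profile_treat.total_count
    tot_c = profile_ctrl.total_count
    if tot_t == 0 or tot_c == 0:
        raise ValueError("both profiles must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    def freq(count: int, total: int) -> float:
        return (count + pseudocount) / (total + pseudocount)

    results: list[EnrichmentResult] = []
    if exact_tails:
        tails = sorted(
            {t for (_, t), _ in profile_treat.class_counts.items() if t}
            | {t for (_, t), _ in profile_ctrl.class_counts.items() if t}
        )
        for tail in tails:
            ct = sum(
                c for (_, t), c in profile_treat.class_counts.items() if t == tail
            )
            cc = sum(
                c for (_, t), c in profile_ctrl.class_counts.items() if t == tail
            )
            ft, fc = freq(ct, tot_t), freq(cc, tot_c)
            enr = math.log2(ft / fc)
            results.append(
                EnrichmentResult(
                    profile_treat.mirna_id, tail, len(tail), ft, fc, enr,
                    enr >= threshold_log2 and ft >= min_freq,
                )
            )
        return results

    for nt in NUCLEOTIDES:
        treat_k = tail_nt_counts(profile_treat, nt)
        ctrl_k = tail_nt_counts(profile_ctrl, nt)
        kmax = max([1, *treat_k.keys(), *ctrl_k.keys()])
        for k in range(1, kmax + 1):
            ft = freq(treat_k.get(k, 0), tot_t)
            fc = freq(ctrl_k.get(k, 0), tot_c)
            enr = math.log2(ft / fc)
            results.append(
                EnrichmentResult(
                    profile_treat.mirna_id, nt, k, ft, fc, enr,
                    enr >= threshold_log2 and ft >= min_freq,
                )
            )
    return results


def called_nucleotides(results: Iterable[EnrichmentResult]) -> set[str]:
    """Nucleotides with at least one called (authentic) tail class."""
    return {r.nt for r in results if r.called}


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "nt": r.nt,
                "k": r.k,
                "freq_treat": r.freq_treat,
                "freq_ctrl": r.freq_ctrl,
                "log2_enrichment": r.enrichment,
                "called": r.called,
            }
            for r in results
        ],
        columns=[
            "mirna_id", "nt", "k", "freq_treat", "freq_ctrl",
            "log2_enrichment", "called",
        ],
    )
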