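"""Per-miRNA tail statistics.

All fractions are reported on the percent scale and computed on raw read
counts within a profile; cross-sample normalization (counts per million)
only ever appears as an expression column in reports.  The "oligo"
restriction — at least ``min_oligo`` occurrences of the nucleotide in the
tail — defaults to 2 for weighted means and the U-score (mono-addition is
a distinct biology) and to 1 for cumulative curves.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import IsomiRAnnotation

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "U")


@dataclass
class TailProfile:
    """Aggregate of one miRNA in one condition over (templ3, tail) classes."""

    mirna_id: str
    condition: str = ""
    class_counts: dict[tuple[int, str], int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.class_counts.values())

    def validate(self) -> None:
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("negative class count")


def build_profiles(
    annotations: Iterable[IsomiRAnnotation],
    condition: str = "",
    max_offset5: int = 2,
) -> dict[str, TailProfile]:
    """Aggregate annotations into per-miRNA profiles.

    Reads with ``|offset5| > max_offset5`` are excluded from 3' statistics:
    large 5' shifts indicate a distinct species rather than a 3' isomiR.
    """
    profiles: dict[str, TailProfile] = {}
    for a in annotations:
        if abs(a.offset5) > max_offset5:
            continue
        prof = profiles.setdefault(a.mirna_id, TailProfile(a.mirna_id, condition))
        key = (a.templ3, a.tail)
        prof.class_counts[key] = prof.class_counts.get(key, 0) + a.count
    return profiles


def _require_nonempty(profile: TailProfile) -> int:
    total = profile.total_count
    if total == 0:
        raise ValueError(f"{profile.mirna_id}: empty profile")
    return total


def canonical_class(profile: TailProfile) -> tuple[int, str]:
    """The canonical read class: most abundant fully-templated (tail == '') class.

    Ties break toward templ3 == 0, then the smaller |templ3|.
    """
    templated = [
        (key, cnt) for key, cnt in profile.class_counts.items() if key[1] == ""
    ]
    if not templated:
        raise ValueError(f"{profile.mirna_id}: no templated reads")
    return max(
        templated, key=lambda kv: (kv[1], kv[0][0] == 0, -abs(kv[0][0]), kv[0][0])
    )[0]


def canonical_fraction(profile: TailProfile) -> float:
    """Percent of reads in the canonical class; 100 - this is the isomiR %."""
    total = _require_nonempty(profile)
    key = canonical_class(profile)
    return 100.0 * profile.class_counts[key] / total


def modification_fractions(profile: TailProfile) -> dict[str, float]:
    """Percentages of trim-only / tail-only / trim+tail / unmodified reads.

    Trim means templ3 < 0; tail means a non-empty non-templated tail.
    Templated extension without a tail (templ3 > 0, tail == "") is counted
    as unmodified here and reported in its own column of the metrics TSV.
    """
    total = _require_nonempty(profile)
    buckets = {"trim_only": 0, "tail_only": 0, "trim_and_tail": 0, "unmodified": 0}
    for (templ3, tail), cnt in profile.class_counts.items():
        trimmed = templ3 < 0
        tailed = tail != ""
        if trimmed and tailed:
            buckets["trim_and_tail"] += cnt
        elif trimmed:
            buckets["trim_only"] += cnt
        elif tailed:
            buckets["tail_only"] += cnt
        else:
            buckets["unmodified"] += cnt
    return {k: 100.0 * v / total for k, v in buckets.items()}


def templated_extension_fraction(profile: TailProfile) -> float:
    total = _require_nonempty(profile)
    ext = sum(
        cnt for (templ3, tail), cnt in profile.class_counts.items() if templ3 > 0 and tail == ""
    )
    return 100.0 * ext / total


def tail_nt_counts(profile: TailProfile, nt: str) -> dict[int, int]:
    """Read counts keyed by k = occurrences of ``nt`` anywhere in the tail.

    Occurrences, not run length: tail "UAU" has k=2 for U.  Reads with
    k == 0 are excluded.
    """
    if nt not in NUCLEOTIDES:
        raise ValueError(f"nt must be one of {NUCLEOTIDES}")
    out: dict[int, int] = defaultdict(int)
    for (_, tail), cnt in profile.class_counts.items():
        k = tail.count(nt)
        if k >= 1:
            out[k] += cnt
    return dict(out)


def cumulative_tail_curve(
    profile: TailProfile, nt: str, min_oligo: int = 1
) -> list[tuple[int, float]]:
    """Cumulative oligo-tail distribution from longest to shortest tails.

    For reads with at least ``min_oligo`` occurrences of ``nt`` in the
    tail, the value at k is the percent of those reads carrying >= k
    occurrences; the curve starts at 100 at ``min_oligo`` and is
    non-increasing.
    """
    by_k = tail_nt_counts(profile, nt)
    qualifying = {k: c for k, c in by_k.items() if k >= min_oligo}
    if not qualifying:
        warnings.warn(f"{profile.mirna_id}: no reads with >= {min_oligo} {nt} in tail")
        return []
    denom = sum(qualifying.values())
    kmax = max(qualifying)
    curve = []
    for k in range(min_oligo, kmax + 1):
        at_least_k = sum(c for kk, c in qualifying.items() if kk >= k)
        curve.append((k, 100.0 * at_least_k / denom))
    return curve


def weighted_mean_tail(profile: TailProfile, nt: str, min_oligo: int = 2) -> float:
    """Weighted average number of oligo-``nt`` tail nucleotides per read.

    Sum of count * k over all reads divided by the profile total, where
    k is the occurrence count of ``nt`` in the tail and reads with
    k < ``min_oligo`` contribute 0.  The denominator is all reads of the
    miRNA (see ``tailed_only`` in callers for the alternative).
    """
    total = _require_nonempty(profile)
    weighted = sum(
        cnt * tail.count(nt)
        for (_, tail), cnt in profile.class_counts.items()
        if tail.count(nt) >= min_oligo
    )
    return weighted / total


def u_score(
    profile_test: TailProfile, profile_ctrl: TailProfile, min_oligo: int = 2
) -> float:
    """Change in the weighted average oligo-U count between two conditions.

    Positive values mean the test condition carries more oligo-U than the
    control (e.g. an exonuclease knockout versus wild type).
    """
    if profile_test.mirna_id != profile_ctrl.mirna_id:
        raise ValueError(
            f"mirna_id mismatch: {profile_test.mirna_id} vs {profile_ctrl.mirna_id}"
        )
    return weighted_mean_tail(profile_test, "U", min_oligo) - weighted_mean_tail(
        profile_ctrl, "U", min_oligo
    )


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], paired: bool
) -> tuple[float, float]:
    """Two-sided comparison of a per-miRNA metric between two groups.

    Paired: Wilcoxon signed-rank (exact null for n <= 25 without ties or
    zeros, normal approximation with corrections otherwise).  Unpaired:
    Welch's t.  Returns (statistic, p_value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal-length vectors")
    if min(len(a), len(b)) < 5:
        raise ValueError("insufficient data: need at least 5 values per group")
    if paired:
        diffs = a - b
        if np.all(diffs == 0):
            return 0.0, 1.0
        nonzero = diffs[diffs != 0]
        has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
        method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
        res = sps.wilcoxon(
            a, b, zero_method="wilcox", alternative="two-sided", method=method
        )
        return float(res.statistic), float(res.pvalue)
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def metrics_table(
    profiles: Mapping[str, TailProfile],
    min_oligo: int = 2,
    min_reads: int = 50,
) -> pd.DataFrame:
    """One row per miRNA with every per-profile metric.

    miRNAs with fewer than ``min_reads`` reads are marked low_coverage and
    should be excluded from cross-miRNA comparisons.
    """
    rows = []
    for mid, prof in sorted(profiles.items()):
        total = prof.total_count
        if total == 0:
            continue
        frac = modification_fractions(prof)
        row = {
            "mirna_id": mid,
            "condition": prof.condition,
            "n_reads": total,
            "canonical_pct": canonical_fraction(prof),
            "isomir_pct": 100.0 - canonical_fraction(prof),
            "templated_ext_pct": templated_extension_fraction(prof),
            **{f"{k}_pct": v for k, v in frac.items()},
            "low_coverage": total < min_reads,
        }
        for nt in NUCLEOTIDES:
            row[f"wmean_{nt}"] = weighted_mean_tail(prof, nt, min_oligo)
        rows.append(row)
    return pd.DataFrame(rows)


def curves_table(
    profiles: Mapping[str, TailProfile], min_oligo: int = 1
) -> pd.DataFrame:
    """Cumulative-curve TSV: one row per (mirna, nt, k)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mid, prof in sorted(profiles.items()):
            for nt in NUCLEOTIDES:
                for k, pct in cumulative_tail_curve(prof, nt, min_oligo):
                    rows.append(
                        {"mirna_id": mid, "nt": nt, "k": k, "cum_percent": pct}
                    )
    return pd.DataFrame(rows, columns=["mirna_id", "nt", "k", "cum_percent"])
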