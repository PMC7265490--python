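"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or direct
recounting, deliberately sharing no code path with the implementation it
checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata

from mirtail.refs import MiRNARef
from mirtail.tdmd import PAIRABLE, STACK_TABLE, EnergyParams

WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


def brute_force_decomposition(read: str, ref: MiRNARef):
    """All (templ3, tail) splits reproducing the read; maximal templated span wins.

    Returns (offset5, templ3, tail) or None when no decomposition exists
    (motif absent/duplicated, 5' prefix mismatch, or read upstream of the
    canonical 5' end).
    """
    pos = read.find(ref.motif)
    if pos < 0 or read.find(ref.motif, pos + 1) >= 0:
        return None
    offset5 = ref.motif_offset - pos
    if offset5 < 0:
        return None
    L = len(ref.mature_seq)
    best = None
    for templ3 in range(-(L - offset5 - 1), len(ref.flank3) + 1):
        body = (
            ref.mature_seq[offset5 : L + min(templ3, 0)]
            + ref.flank3[: max(templ3, 0)]
        )
        if read.startswith(body):
            tail = read[len(body) :]
            if best is None or templ3 > best[1]:
                best = (offset5, templ3, tail)
    return best


def brute_force_mfe(a: str, b: str, params: EnergyParams) -> float | None:
    """Exhaustive enumeration of every admissible intermolecular pairing."""
    n, m = len(a), len(b)
    best = None
    for k in range(1, min(n, m) + 1):
        for I in combinations(range(n), k):
            for J_incr in combinations(range(m), k):
                J = tuple(reversed(J_incr))  # j decreasing as i increases
                if any((a[i], b[j]) not in PAIRABLE for i, j in zip(I, J)):
                    continue
                e = params.initiation
                for t in range(k - 1):
                    ga = I[t + 1] - I[t] - 1
                    gb = J[t] - J[t + 1] - 1
                    if ga == 0 and gb == 0:
                        e += STACK_TABLE[(a[I[t]], b[J[t]], a[I[t + 1]], b[J[t + 1]])]
                    else:
                        e += params.loop_energy(ga, gb)
                if best is None or e < best:
                    best = e
    return best if best is not None and best <= 0 else None


def exact_wilcoxon_two_sided(values_a, values_b) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    diffs = [a - b for a, b in zip(values_a, values_b) if a != b]
    n = len(diffs)
    if n == 0:
        return 1.0
    ranks = rankdata([abs(d) for d in diffs])
    w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s) for signs in product((0, 1), repeat=n)
    ]
    total = len(w_all)
    p_ge = sum(1 for w in w_all if w >= w_obs - 1e-12) / total
    p_le = sum(1 for w in w_all if w <= w_obs + 1e-12) / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def naive_seed_scan(mirna_seq: str, transcript_seq: str, seed_type: str):
    """Sliding-window seed scan checking Watson-Crick pairing per position."""
    m, t = mirna_seq, transcript_seq
    hits = []
    for s in range(len(t) - 6):
        window = t[s : s + 7]
        if seed_type == "7mer-m8":
            # window pairs miRNA nts 8..2 antiparallel: window[x] vs m[7 - x]
            ok = all((window[x], m[7 - x]) in WC for x in range(7))
        elif seed_type == "7mer-A1":
            ok = window[6] == "A" and all(
                (window[x], m[6 - x]) in WC for x in range(6)
            )
        else:
            raise ValueError(seed_type)
        if ok:
            hits.append(s)
    return hits


def recount_cumulative_curve(profile, nt: str, min_oligo: int = 1):
    """Expand a profile into individual reads and recount the curve."""
    ks = []
    for (_, tail), cnt in profile.class_counts.items():
        k = tail.count(nt)
        if k >= min_oligo:
            ks.extend([k] * cnt)
    if not ks:
        return []
    ks = np.asarray(ks)
    return [
        (k, 100.0 * float((ks >= k).sum()) / len(ks))
        for k in range(min_oligo, int(ks.max()) + 1)
    ]
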