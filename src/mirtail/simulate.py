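"""Synthetic small-RNA libraries with known ground truth.

The generator emulates AGO-IP small-RNA libraries: each miRNA contributes
a canonical majority, 3'-trimmed isoforms, and non-templated tails whose
composition is biased toward U and A; a small fraction of reads carries a
random ligation-noise "tail"; sequencing substitutions are applied per
base.  Condition presets differ only in the canonical fraction, the tail
continuation probability and the tail composition — they are illustrative
settings for a protected wild-type IP, 3'-pocket mutant IPs, and
uridylyl-transferase / exonuclease knockouts, not fits to any dataset.

To keep planted truth consistent with the greedy templated-first
annotation rule, the first tail nucleotide is drawn from the tail
composition renormalized to exclude the next templated base (the base
trimming removed, or the first flank base).  Without this, a tail whose
first base happens to match the genome would be annotated as templated and
truth-agreement tests would be meaningless.  Likewise the modified branch
resamples until the read is actually modified, so the planted canonical
fraction is the expected canonical read fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .refs import MiRNARef, MotifConfig, build_motif
from .tdmd import Transcript, seed_site_string

NTS = ("A", "C", "G", "U")
DEFAULT_ADAPTER = "AGAUCGGAAGAGCACACGUCU"  # standard small-RNA 3' adapter (RNA form)
FASTQ_QUAL = "F"  # Sanger Q37


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of one library condition.

    n_reads : library size.
    abundance_mu, abundance_sigma : per-miRNA expression weights are
        log-normal(mu, sigma) draws, normalized to probabilities.
    p_canonical : probability a read is the exact mature sequence.
    p_trim : success probability of the truncated-geometric trim length
        (P(t) proportional to (1-p_trim)^t for t = 0..max_trim).
    q : tail continuation probability; tail length is geometric with mean
        q/(1-q), capped at max_tail.
    pi : tail emission probabilities over (A, C, G, U).
    noise_rate : fraction of reads whose tail is replaced by a random
        ligation-noise fragment (length uniform 1..15, uniform bases).
    seq_error : per-base substitution probability.
    """

    n_reads: int = 10_000
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    p_canonical: float = 0.6
    p_trim: float = 0.5
    max_trim: int = 6
    q: float = 0.4
    max_tail: int = 20
    pi: tuple[float, float, float, float] = (0.30, 0.05, 0.05, 0.60)  # A,C,G,U
    noise_rate: float = 0.01
    seq_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_canonical, self.p_trim, self.q, self.noise_rate, self.seq_error)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.pi) - 1.0) > 1e-9 or any(p < 0 for p in self.pi):
            raise ValueError("pi must be a probability vector over A,C,G,U")


# Illustrative condition presets: a protected wild-type IP, two Argonaute
# 3'-pocket mutants (progressively exposed 3' ends -> more trimming and
# longer, U-richer tails), a TUT7 knockout (less tailing, more trimming)
# and a DIS3L2 knockout (oligo-U intermediates accumulate).
CONDITION_PRESETS: dict[str, dict] = {
    "WT": dict(p_canonical=0.75, q=0.25, pi=(0.35, 0.10, 0.10, 0.45)),
    "F2L3": dict(p_canonical=0.50, q=0.35, pi=(0.30, 0.05, 0.05, 0.60)),
    "dPAZ": dict(p_canonical=0.25, q=0.60, pi=(0.20, 0.03, 0.02, 0.75)),
    "TUT7KO": dict(p_canonical=0.60, q=0.15, pi=(0.45, 0.10, 0.10, 0.35)),
    "DIS3L2KO": dict(p_canonical=0.45, q=0.65, pi=(0.15, 0.03, 0.02, 0.80)),
}


def preset_params(condition: str, base: SimParams = SimParams(), **overrides) -> SimParams:
    if condition not in CONDITION_PRESETS:
        raise ValueError(f"unknown condition {condition!r}; presets: {sorted(CONDITION_PRESETS)}")
    return replace(base, **{**CONDITION_PRESETS[condition], **overrides})


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NTS, size=length))


def simulate_references(
    n: int,
    len_range: tuple[int, int] = (20, 24),
    flank_len: int = 10,
    seed: int = 0,
    config: MotifConfig = MotifConfig(),
) -> list[MiRNARef]:
    """Random references with unique, non-colliding motifs (rejection-sampled)."""
    if n < 1:
        raise ValueError("n >= 1 required")
    rng = np.random.default_rng(seed)
    refs: list[MiRNARef] = []
    seen_motifs: set[str] = set()
    attempts = 0
    while len(refs) < n:
        attempts += 1
        if attempts > 10 * n:
            raise RuntimeError(
                f"could not draw {n} references with unique motifs in {10 * n} attempts"
            )
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        mature = _random_rna(rng, length)
        flank = _random_rna(rng, flank_len)
        try:
            motif, offset = build_motif(mature, config)
        except ValueError:
            continue
        # reject motif collisions and motifs occurring inside another
        # reference's mature+flank (would make reads cross-match)
        if motif in seen_motifs:
            continue
        if any(motif in (r.mature_seq + r.flank3) for r in refs) or any(
            r.motif in (mature + flank) for r in refs
        ):
            continue
        seen_motifs.add(motif)
        refs.append(
            MiRNARef(
                mirna_id=f"sim-mir-{len(refs) + 1}",
                arm="5p" if len(refs) % 2 == 0 else "3p",
                mature_seq=mature,
                flank3=flank,
                motif=motif,
                motif_offset=offset,
            )
        )
    return refs


def _cat(rng: np.random.Generator, cum: np.ndarray) -> int:
    """Categorical draw from a cumulative-probability vector."""
    return min(int(np.searchsorted(cum, rng.random(), side="right")), len(cum) - 1)


def _sample_nt(rng: np.random.Generator, cum: np.ndarray) -> str:
    return NTS[_cat(rng, cum)]


def _draw_tail(
    rng: np.random.Generator,
    params: SimParams,
    next_templated: str,
) -> str:
    """Tail of geometric length; first base never equals the next templated base."""
    length = 0
    while length < params.max_tail and rng.random() < params.q:
        length += 1
    if length == 0:
        return ""
    pi = np.asarray(params.pi, dtype=float)
    first_pi = pi.copy()
    first_pi[NTS.index(next_templated)] = 0.0
    if first_pi.sum() == 0:  # degenerate composition: no legal first base
        return ""
    cum_first = np.cumsum(first_pi / first_pi.sum())
    cum_pi = np.cumsum(pi)
    bases = [_sample_nt(rng, cum_first)]
    for _ in range(length - 1):
        bases.append(_sample_nt(rng, cum_pi))
    return "".join(bases)


def _apply_seq_error(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for i in rng.choice(len(seq), size=n_err, replace=False):
        c = chars[i]
        chars[i] = [n for n in NTS if n != c][int(rng.integers(3))]
    return "".join(chars)


def simulate_library(
    refs: Sequence[MiRNARef],
    params: SimParams,
    condition_label: str = "",
    adapter: str = DEFAULT_ADAPTER,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate one library: FASTQ records plus a per-read ground-truth table.

    Returns (records, truth): records are (read_id, raw_sequence) with the
    adapter appended; truth has one row per read with the planted
    (mirna_id, templ3, tail, is_noise).  Identical params (including
    params.seed) reproduce identical output.
    """
    if not refs:
        raise ValueError("no references")
    rng = np.random.default_rng(params.seed)
    weights = rng.lognormal(params.abundance_mu, params.abundance_sigma, size=len(refs))
    weights /= weights.sum()
    trim_probs = np.array(
        [(1 - params.p_trim) ** t for t in range(params.max_trim + 1)]
    )
    trim_probs /= trim_probs.sum()
    cum_weights = np.cumsum(weights)
    cum_trim = np.cumsum(trim_probs)

    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for i in range(params.n_reads):
        ref = refs[_cat(rng, cum_weights)]
        L = len(ref.mature_seq)
        if rng.random() < params.p_canonical:
            trim, tail = 0, ""
        else:
            while True:  # resample until genuinely modified
                trim = _cat(rng, cum_trim)
                next_templated = ref.flank3[0] if trim == 0 else ref.mature_seq[L - trim]
                tail = _draw_tail(rng, params, next_templated)
                if trim > 0 or tail != "":
                    break
        is_noise = False
        if rng.random() < params.noise_rate:
            is_noise = True
            tail = _random_rna(rng, int(rng.integers(1, 16)))
        body = ref.mature_seq[: L - trim] if trim else ref.mature_seq
        insert = _apply_seq_error(rng, body + tail, params.seq_error)
        records.append((f"{condition_label or 'read'}_{i}", insert + adapter))
        truth_rows.append(
            {
                "read_id": f"{condition_label or 'read'}_{i}",
                "mirna_id": ref.mirna_id,
                "templ3": -trim,
                "tail": tail,
                "is_noise": is_noise,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Plain FASTQ with constant Sanger quality (Q37)."""
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{FASTQ_QUAL * len(seq)}\n")


def simulate_tdmd_transcriptome(
    mirna: MiRNARef,
    n_decoys: int = 100,
    seed: int = 0,
    trigger_abundance: float = 500.0,
    decoy_len: int = 80,
) -> tuple[list[Transcript], dict]:
    """A transcriptome with one planted trigger among seed-only decoys.

    The trigger embeds the full reverse complement of the miRNA (seed site
    plus extensive 3'-supplementary pairing) and has high abundance; each
    decoy carries exactly one seed site in otherwise random sequence with
    log-normal abundance.  Returns (transcripts, truth) where truth records
    the planted trigger id and its seed-site start.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys >= 1")
    rng = np.random.default_rng(seed)
    site = seed_site_string(mirna.mature_seq, "7mer-m8")
    L = len(mirna.mature_seq)

    def count_sites(seq: str) -> int:
        n, start = 0, seq.find(site)
        while start >= 0:
            n += 1
            start = seq.find(site, start + 1)
        return n

    # trigger: random flanks around the full reverse complement; the seed
    # site sits at offset (L - 8) within revcomp(mature)
    while True:
        up = _random_rna(rng, 20)
        down = _random_rna(rng, 20)
        tseq = up + revcomp(mirna.mature_seq) + down
        if count_sites(tseq) == 1:
            break
    trigger = Transcript("trigger", tseq, trigger_abundance)
    site_start = tseq.find(site)

    decoys: list[Transcript] = []
    while len(decoys) < n_decoys:
        pos = int(rng.integers(35, decoy_len - 7))
        seq = _random_rna(rng, decoy_len)
        seq = seq[:pos] + site + seq[pos + 7 :]
        if count_sites(seq) != 1:
            continue
        cpm = float(rng.lognormal(2.0, 1.0))
        decoys.append(Transcript(f"decoy_{len(decoys) + 1}", seq, cpm))

    truth = {"trigger_id": "trigger", "site_start": site_start}
    return [trigger, *decoys], truth


def write_transcripts(
    transcripts: Sequence[Transcript], fasta_path: str | Path, abundance_path: str | Path
) -> None:
    with open(fasta_path, "w") as fh:
        for tr in transcripts:
            fh.write(f">{tr.transcript_id}\n{tr.seq}\n")
    pd.DataFrame(
        [{"transcript_id": t.transcript_id, "cpm": t.abundance} for t in transcripts]
    ).to_csv(abundance_path, sep="\t", index=False)
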