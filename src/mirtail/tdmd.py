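"""Screen for candidate TDMD (target-directed miRNA degradation) triggers.

A TDMD trigger is a transcript that base-pairs with a miRNA seed and,
unusually, continues pairing extensively with the miRNA 3' region; such
targets dislodge the miRNA 3' end from the Argonaute PAZ pocket and expose
it to tailing/trimming machinery.  The screen is:

1. scan transcripts for perfect 7-mer seed matches (Watson-Crick only);
2. score each site's hybridization with the full miRNA by a duplex
   minimum-free-energy dynamic program over a window spanning the site
   plus upstream flank (3'-supplementary pairing lies 5' of the site on
   the transcript);
3. rank candidates by MFE against transcript abundance.

The energy model is a reduced nearest-neighbor model: an embedded
Turner-style stack table (Watson-Crick and G:U wobble pairs), a single
duplex initiation constant, and affine bulge/internal-loop penalties.
There are no dangles, terminal-AU penalties or loop-asymmetry terms, so
absolute energies differ from full-featured folding programs; rankings,
not absolute values, are the screen's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._seq import revcomp, validate_rna

SEED_TYPES = ("7mer-m8", "7mer-A1")

# Base pairs admissible in a duplex: Watson-Crick + G:U wobble.
PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

# Nearest-neighbor stack free energies at 37 C, kcal/mol.  Key
# (a, b, c, d) is the stack 5'-a c-3' / 3'-b d-5' (pair a:b followed by
# pair c:d).  Watson-Crick values follow the standard Turner set; G:U
# wobble stacks are approximate.  The table is completed below by the
# physical symmetry E(a,b,c,d) == E(d,c,b,a); unlisted wobble combinations
# get a weak default.
_STACK_PRIMARY: dict[tuple[str, str, str, str], float] = {
    ("A", "U", "A", "U"): -0.93,
    ("A", "U", "U", "A"): -1.10,
    ("U", "A", "A", "U"): -1.33,
    ("C", "G", "A", "U"): -2.11,
    ("C", "G", "U", "A"): -2.08,
    ("G", "C", "A", "U"): -2.35,
    ("G", "C", "U", "A"): -2.24,
    ("C", "G", "G", "C"): -2.36,
    ("G", "C", "C", "G"): -3.42,
    ("G", "C", "G", "C"): -3.26,
    # wobble-containing stacks
    ("A", "U", "G", "U"): -0.55,
    ("A", "U", "U", "G"): -1.36,
    ("C", "G", "G", "U"): -1.41,
    ("C", "G", "U", "G"): -2.11,
    ("G", "C", "G", "U"): -1.53,
    ("G", "C", "U", "G"): -2.51,
    ("G", "U", "A", "U"): -1.27,
    ("G", "U", "G", "U"): 0.47,
    ("G", "U", "U", "G"): 1.29,
    ("U", "G", "G", "U"): 0.30,
    ("U", "G", "A", "U"): -1.00,
}


def _complete_stack_table() -> dict[tuple[str, str, str, str], float]:
    table = dict(_STACK_PRIMARY)
    for (a, b, c, d), e in _STACK_PRIMARY.items():
        sym = (d, c, b, a)
        if sym in table and abs(table[sym] - e) > 1e-9:
            raise AssertionError(f"stack table asymmetric at {sym}")
        table[sym] = e
    for p1 in PAIRABLE:
        for p2 in PAIRABLE:
            key = (p1[0], p1[1], p2[0], p2[1])
            if key not in table:
                table[key] = -0.5  # unparameterized wobble combination
                table[(key[3], key[2], key[1], key[0])] = -0.5
    return table


STACK_TABLE = _complete_stack_table()


@dataclass(frozen=True)
class EnergyParams:
    """Constants of the reduced duplex energy model (kcal/mol)."""

    initiation: float = 4.1
    bulge_open: float = 3.8
    bulge_per_nt: float = 0.3
    internal_open: float = 1.7
    internal_per_nt: float = 0.4
    max_len: int = 60

    def loop_energy(self, gap_a: int, gap_b: int) -> float:
        """Penalty for the unpaired region between two consecutive pairs."""
        if gap_a == 0 and gap_b == 0:
            raise ValueError("not a loop")
        size = gap_a + gap_b
        if gap_a == 0 or gap_b == 0:
            return self.bulge_open + self.bulge_per_nt * size
        return self.internal_open + self.internal_per_nt * size


DEFAULT_ENERGY = EnergyParams()


def duplex_mfe(
    seq_a: str, seq_b: str, params: EnergyParams = DEFAULT_ENERGY
) -> float | None:
    """Minimum free energy of an intermolecular RNA:RNA duplex, or None.

    Both sequences are 5'->3'; pairing is antiparallel (position i of A
    with position j of B, i increasing while j decreases), non-crossing,
    intermolecular only.  Energy of a structure = initiation + stack terms
    for adjacent pairs + affine loop penalties for bulges/internal loops.
    Returns None when no structure achieves energy <= 0 ("no duplex").
    """
    import numpy as np

    a = validate_rna(seq_a, context="duplex strand A")
    b = validate_rna(seq_b, context="duplex strand B")
    if not a or not b:
        raise ValueError("empty sequence")
    if len(a) > params.max_len or len(b) > params.max_len:
        raise ValueError(f"sequence longer than max_len={params.max_len}")
    n, m = len(a), len(b)
    pairs = [(i, j) for i in range(n) for j in range(m) if (a[i], b[j]) in PAIRABLE]
    if not pairs:
        return None
    # Loop cost by gap sizes (gap_a on strand A, gap_b on strand B); the
    # (0, 0) entry is a stack, handled separately.
    ga = np.arange(n)[:, None]
    gb = np.arange(m)[None, :]
    size = ga + gb
    loop_cost = np.where(
        (ga == 0) | (gb == 0),
        params.bulge_open + params.bulge_per_nt * size,
        params.internal_open + params.internal_per_nt * size,
    ).astype(float)
    loop_cost[0, 0] = np.inf
    # E[i, j] = lowest energy (incl. initiation) of a structure whose
    # 3'-most pair on A is (i, j).  Pairs are visited in increasing i, so
    # every admissible predecessor (i' < i, j' > j) is final.
    E = np.full((n, m), np.inf)
    for i, j in pairs:
        e = params.initiation
        if i > 0 and j < m - 1:
            # predecessors i' in [0, i), j' in (j, m); row i'-th gap is
            # i - i' - 1, column j'-th gap is j' - j - 1
            block = E[:i, j + 1 :] + loop_cost[i - 1 :: -1, : m - j - 1]
            e = min(e, float(block.min()))
            stacked = E[i - 1, j + 1] + STACK_TABLE.get(
                (a[i - 1], b[j + 1], a[i], b[j]), np.inf
            )
            e = min(e, float(stacked))
        E[i, j] = e
    mfe = float(min(E[i, j] for i, j in pairs))
    return mfe if mfe <= 0 else None


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    seq: str
    abundance: float = 0.0  # counts per million; 0 when absent from the table

    def __post_init__(self) -> None:
        validate_rna(self.seq, context=self.transcript_id)
        if self.abundance < 0:
            raise ValueError(f"{self.transcript_id}: negative abundance")


@dataclass(frozen=True)
class DuplexHit:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based, half-open seed-site coordinates
    site_end: int
    seed_type: str
    mfe: float
    abundance: float
    low_expression: bool = False


def seed_site_string(mirna_seq: str, seed_type: str) -> str:
    """The 7-nt transcript sequence a perfect seed site must show.

    7mer-m8: reverse complement of miRNA nucleotides 2-8 (1-based).
    7mer-A1: reverse complement of nucleotides 2-7 followed by an A in the
    transcript opposite miRNA position 1.
    """
    m = validate_rna(mirna_seq, context="miRNA")
    if seed_type == "7mer-m8":
        return revcomp(m[1:8])
    if seed_type == "7mer-A1":
        return revcomp(m[1:7]) + "A"
    raise ValueError(f"unknown seed type {seed_type!r}")


def find_seed_sites(
    mirna_seq: str,
    transcript_seq: str,
    seed_types: Iterable[str] = ("7mer-m8",),
) -> list[tuple[int, str]]:
    """All (start, seed_type) seed matches in a transcript, overlaps allowed.

    Matching is exact Watson-Crick within the seed (no G:U).  When a
    position qualifies as both 7mer-m8 and 7mer-A1 it is reported once per
    requested type.
    """
    t = validate_rna(transcript_seq, context="transcript")
    hits: list[tuple[int, str]] = []
    for seed_type in seed_types:
        if seed_type not in SEED_TYPES:
            raise ValueError(f"unknown seed type {seed_type!r}")
        site = seed_site_string(mirna_seq, seed_type)
        start = t.find(site)
        while start >= 0:
            hits.append((start, seed_type))
            start = t.find(site, start + 1)
    hits.sort()
    return hits


def score_site(
    mirna_id: str,
    mirna_seq: str,
    transcript: Transcript,
    site_start: int,
    seed_type: str,
    upstream: int = 30,
    downstream: int = 5,
    params: EnergyParams = DEFAULT_ENERGY,
    min_cpm: float = 1.0,
) -> DuplexHit | None:
    """MFE-score one seed site; None when no duplex forms (never for a true
    seed match, which always pairs).

    The scored window spans ``upstream`` nt 5' of the site (where
    3'-supplementary pairing with the miRNA 3' region would lie), the 7-nt
    site, and ``downstream`` nt 3' of it.
    """
    site_end = site_start + 7
    w_lo = max(0, site_start - upstream)
    w_hi = min(len(transcript.seq), site_end + downstream)
    window = transcript.seq[w_lo:w_hi]
    mfe = duplex_mfe(mirna_seq, window, params)
    if mfe is None:
        return None
    return DuplexHit(
        mirna_id=mirna_id,
        transcript_id=transcript.transcript_id,
        site_start=site_start,
        site_end=site_end,
        seed_type=seed_type,
        mfe=mfe,
        abundance=transcript.abundance,
        low_expression=transcript.abundance < min_cpm,
    )


def screen_transcripts(
    mirna_id: str,
    mirna_seq: str,
    transcripts: Sequence[Transcript],
    seed_types: Iterable[str] = ("7mer-m8",),
    upstream: int = 30,
    downstream: int = 5,
    params: EnergyParams = DEFAULT_ENERGY,
    min_cpm: float = 1.0,
) -> list[DuplexHit]:
    """Seed-scan + MFE-score every transcript; returns ranked hits."""
    hits: list[DuplexHit] = []
    for tr in transcripts:
        if len(tr.seq) < 7:
            continue
        for start, seed_type in find_seed_sites(mirna_seq, tr.seq, seed_types):
            hit = score_site(
                mirna_id, mirna_seq, tr, start, seed_type,
                upstream, downstream, params, min_cpm,
            )
            if hit is not None:
                hits.append(hit)
    return rank_triggers(hits)


def rank_triggers(hits: Sequence[DuplexHit]) -> list[DuplexHit]:
    """Most-stable-first ranking: ascending MFE, ties by descending
    abundance, then transcript_id, then site position."""
    return sorted(
        hits, key=lambda h: (h.mfe, -h.abundance, h.transcript_id, h.site_start)
    )


def hits_table(hits: Sequence[DuplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "mirna_id": h.mirna_id,
                "transcript_id": h.transcript_id,
                "site_start": h.site_start,
                "site_end": h.site_end,
                "seed_type": h.seed_type,
                "mfe_kcal_mol": h.mfe,
                "abundance_cpm": h.abundance,
                "low_expression": h.low_expression,
            }
            for i, h in enumerate(hits)
        ],
        columns=[
            "rank", "mirna_id", "transcript_id", "site_start", "site_end",
            "seed_type", "mfe_kcal_mol", "abundance_cpm", "low_expression",
        ],
    )


def scatter_table(hits: Sequence[DuplexHit]) -> pd.DataFrame:
    """The (MFE, abundance) pairs underlying the trigger scatter plot."""
    return pd.DataFrame(
        [
            {
                "transcript_id": h.transcript_id,
                "mfe_kcal_mol": h.mfe,
                "abundance_cpm": h.abundance,
            }
            for h in hits
        ],
        columns=["transcript_id", "mfe_kcal_mol", "abundance_cpm"],
    )


def load_transcripts(
    fasta_path, abundance_path=None
) -> list[Transcript]:
    """Transcript FASTA + optional abundance TSV (transcript_id, cpm)."""
    from Bio import SeqIO

    abundance: dict[str, float] = {}
    if abundance_path is not None:
        df = pd.read_csv(abundance_path, sep="\t")
        for col in ("transcript_id", "cpm"):
            if col not in df.columns:
                raise ValueError(f"{abundance_path}: missing column '{col}'")
        abundance = dict(zip(df["transcript_id"], df["cpm"].astype(float)))
    return [
        Transcript(rec.id, str(rec.seq), abundance.get(rec.id, 0.0))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
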