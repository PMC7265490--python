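"""miRNA reference loading and central-motif construction.

Reads are later assigned to miRNAs by exact containment of a short
"central motif" — a substring taken from the middle of the mature
sequence, deliberately kept away from both ends so that 5' offsets and
3' trimming/tailing never disturb the match.  Mismatches are tolerated
only outside the motif; inside it matching is exact, which makes read
assignment deterministic without an aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from ._seq import normalize_rna, validate_rna

logger = logging.getLogger(__name__)

ARMS = ("5p", "3p", "unknown")


@dataclass(frozen=True)
class MotifConfig:
    """Parameters of central-motif construction.

    motif_len : length of the exact-match motif (13 nt by default; at 13 nt
        a random hit occurs about once per 4^13 ~ 6.7e7 nt).
    head_guard : motif never overlaps the first `head_guard` nucleotides,
        leaving room for 5' isomiR variation.
    tail_guard : motif never overlaps the last `tail_guard` nucleotides, so
        typical 3' trimming (1-4 nt) cannot break assignment.
    """

    motif_len: int = 13
    head_guard: int = 2
    tail_guard: int = 5

    def __post_init__(self) -> None:
        if self.motif_len < 1 or self.head_guard < 0 or self.tail_guard < 0:
            raise ValueError("motif_len >= 1 and guards >= 0 required")


@dataclass(frozen=True)
class MiRNARef:
    """One mature miRNA reference.

    mature_seq and flank3 are RNA, 5'->3'; flank3 is the genomic sequence
    immediately downstream of the mature 3' end.  motif is the substring
    mature_seq[motif_offset : motif_offset + len(motif)] used for read
    assignment.  ambiguous marks references whose motif collides with
    another reference's motif.
    """

    mirna_id: str
    arm: str
    mature_seq: str
    flank3: str
    motif: str
    motif_offset: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"{self.mirna_id}: arm must be one of {ARMS}")
        if not 16 <= len(self.mature_seq) <= 28:
            raise ValueError(
                f"{self.mirna_id}: mature_seq length {len(self.mature_seq)} "
                "outside [16, 28]"
            )
        validate_rna(self.mature_seq, context=f"{self.mirna_id} mature_seq")
        validate_rna(self.flank3, context=f"{self.mirna_id} flank3")
        if len(self.flank3) < 8:
            raise ValueError(f"{self.mirna_id}: flank3 shorter than 8 nt")
        if (
            self.motif
            != self.mature_seq[self.motif_offset : self.motif_offset + len(self.motif)]
        ):
            raise ValueError(f"{self.mirna_id}: motif is not at motif_offset")


def build_motif(mature_seq: str, config: MotifConfig = MotifConfig()) -> tuple[str, int]:
    """Derive the central motif of a mature sequence.

    The motif has length ``config.motif_len`` and is centered inside the
    window [head_guard, len - tail_guard); a centering tie is broken toward
    the 5' side.  Returns (motif, motif_offset).
    """
    mature_seq = normalize_rna(mature_seq)
    n = len(mature_seq)
    needed = config.motif_len + config.head_guard + config.tail_guard
    if n < needed:
        raise ValueError(
            f"mature sequence of {n} nt too short for motif_len="
            f"{config.motif_len} with guards ({config.head_guard},"
            f"{config.tail_guard}); lower motif_len"
        )
    lo = config.head_guard
    hi = n - config.tail_guard  # half-open window available for the motif
    slack = (hi - lo) - config.motif_len
    offset = lo + slack // 2  # floor division biases ties toward 5'
    return mature_seq[offset : offset + config.motif_len], offset


def _make_ref(
    mirna_id: str, arm: str, mature_seq: str, flank3: str, config: MotifConfig
) -> MiRNARef:
    raw_mature, raw_flank = mature_seq, flank3
    mature_seq = validate_rna(mature_seq, context=f"{mirna_id} mature_seq")
    flank3 = validate_rna(flank3, context=f"{mirna_id} flank3")
    if "T" in raw_mature.upper() or "T" in raw_flank.upper():
        logger.info("%s: DNA alphabet detected, converted T->U", mirna_id)
    motif, offset = build_motif(mature_seq, config)
    return MiRNARef(
        mirna_id=mirna_id,
        arm=arm if arm in ARMS else "unknown",
        mature_seq=mature_seq,
        flank3=flank3,
        motif=motif,
        motif_offset=offset,
    )


def _flag_collisions(refs: list[MiRNARef]) -> list[MiRNARef]:
    from collections import Counter

    motif_counts = Counter(r.motif for r in refs)
    out = []
    for r in refs:
        if motif_counts[r.motif] > 1:
            logger.warning("%s: motif collides with another reference", r.mirna_id)
            out.append(
                MiRNARef(
                    mirna_id=r.mirna_id,
                    arm=r.arm,
                    mature_seq=r.mature_seq,
                    flank3=r.flank3,
                    motif=r.motif,
                    motif_offset=r.motif_offset,
                    ambiguous=True,
                )
            )
        else:
            out.append(r)
    return out


def load_references(
    ref_path: str | Path, config: MotifConfig = MotifConfig()
) -> list[MiRNARef]:
    """Load references from TSV (mirna_id, arm, mature_seq, flank3).

    Every record is validated; a duplicate mirna_id is an error; references
    sharing an identical motif are both flagged ``ambiguous`` (reads hitting
    such a motif cannot be assigned uniquely).
    """
    ref_path = Path(ref_path)
    if not ref_path.exists():
        raise FileNotFoundError(ref_path)
    df = pd.read_csv(ref_path, sep="\t", dtype=str)
    required = {"mirna_id", "arm", "mature_seq", "flank3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{ref_path}: missing columns {sorted(missing)}")
    dup = df["mirna_id"][df["mirna_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate mirna_id: {sorted(dup.unique())}")
    refs = [
        _make_ref(row.mirna_id, row.arm, row.mature_seq, row.flank3, config)
        for row in df.itertuples(index=False)
    ]
    return _flag_collisions(refs)


def load_references_fasta(
    mature_fasta: str | Path,
    flank_fasta: str | Path,
    config: MotifConfig = MotifConfig(),
) -> list[MiRNARef]:
    """Load references from a mature FASTA + flank FASTA keyed by identical headers.

    The arm is taken from a trailing ``-5p``/``-3p`` in the header when
    present, else ``unknown``.
    """
    matures = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(mature_fasta), "fasta")}
    flanks = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(flank_fasta), "fasta")}
    missing = set(matures) - set(flanks)
    if missing:
        raise ValueError(f"flank FASTA missing entries: {sorted(missing)}")
    refs = []
    for mid, seq in matures.items():
        arm = "5p" if mid.endswith("-5p") else "3p" if mid.endswith("-3p") else "unknown"
        refs.append(_make_ref(mid, arm, seq, flanks[mid], config))
    return _flag_collisions(refs)


def write_references(refs: Iterable[MiRNARef], path: str | Path) -> None:
    """Write references as the canonical TSV."""
    df = pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "arm": r.arm,
                "mature_seq": r.mature_seq,
                "flank3": r.flank3,
            }
            for r in refs
        ]
    )
    df.to_csv(path, sep="\t", index=False)
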