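"""Adapter stripping, read collapsing, miRNA assignment and 3'-end decomposition.

Each assigned read is decomposed losslessly into

    mature_seq[offset5 : L + min(templ3, 0)]  +  flank3[: max(templ3, 0)]  +  tail

where ``templ3`` < 0 means the 3' end was trimmed by ``-templ3`` templated
nucleotides, ``templ3`` > 0 means a templated extension into the genomic 3'
flank, and ``tail`` is the non-templated suffix.  The decomposition is
greedy-templated: walking 3'-ward from the motif, every nucleotide that
matches the template (mature sequence, then flank) is classified templated;
the tail starts at the first mismatch.  This maximizes the templated span,
so a genuine added nucleotide that happens to match the genome is counted
as templated — the price of a deterministic, oracle-checkable rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import normalize_rna, validate_rna
from .refs import MiRNARef

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    """A collapsed read: unique sequence with its multiplicity."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        validate_rna(self.seq, context="read")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class IsomiRAnnotation:
    """Per-read 3'-end decomposition (coordinates 0-based, tails 5'->3')."""

    mirna_id: str
    offset5: int
    templ3: int
    tail: str
    count: int
    is_canonical: bool


@dataclass
class ReadFates:
    """Read-count bookkeeping; the categories partition the input.

    annotated + ambiguous + unassigned + refused + dropped == total input.
    ``refused`` covers reads whose motif hit cannot be turned into a valid
    decomposition (motif present twice, 5' region mismatching the mature
    sequence, or a 5' start upstream of the canonical end).
    """

    annotated: int = 0
    ambiguous: int = 0
    unassigned: int = 0
    refused: int = 0
    dropped: int = 0

    @property
    def total(self) -> int:
        return self.annotated + self.ambiguous + self.unassigned + self.refused + self.dropped

    def as_dict(self) -> dict[str, int]:
        return {
            "annotated": self.annotated,
            "ambiguous": self.ambiguous,
            "unassigned": self.unassigned,
            "refused": self.refused,
            "dropped": self.dropped,
            "total": self.total,
        }


def strip_adapter(
    raw_seq: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    min_insert: int = 15,
    max_insert: int = 35,
) -> str | None:
    """Remove the 3' sequencing adapter; return the insert or None to drop.

    The adapter may occur internally (full-length match) or as a suffix of
    the read (partial match of at least ``min_overlap`` nt).  The leftmost
    position whose mismatch fraction is <= ``max_mismatch_rate`` wins.
    Reads longer than ``max_insert`` with no adapter hit are treated as
    unligated and dropped; inserts shorter than ``min_insert`` are dropped.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    read = normalize_rna(raw_seq)
    adapter = normalize_rna(adapter)
    n = len(read)
    match_pos = None
    for pos in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - pos)
        mism = sum(
            1 for a, b in zip(read[pos : pos + overlap], adapter[:overlap]) if a != b
        )
        if mism <= max_mismatch_rate * overlap:
            match_pos = pos
            break
    if match_pos is None:
        if n > max_insert:
            return None  # unligated
        insert = read
    else:
        insert = read[:match_pos]
    if len(insert) < min_insert:
        return None
    return insert


def collapse(reads: Iterable[str]) -> list[ReadRecord]:
    """Collapse identical sequences into (seq, count) records."""
    counts = Counter(normalize_rna(r) for r in reads)
    return [ReadRecord(seq=s, count=c) for s, c in sorted(counts.items())]


def assign_read(record: ReadRecord, refs: Sequence[MiRNARef]) -> str | None:
    """Assign a read to the unique reference whose motif it contains.

    Returns None when zero or >= 2 motifs match, or when the only match is
    a reference flagged ambiguous at load time.
    """
    hits = [r for r in refs if r.motif in record.seq]
    if len(hits) != 1 or hits[0].ambiguous:
        return None
    return hits[0].mirna_id


def annotate_3prime(record: ReadRecord, ref: MiRNARef) -> IsomiRAnnotation | None:
    """Decompose an assigned read's 3' end; None when annotation is refused.

    Refusal cases: motif occurring more than once in the read; read start
    upstream of the canonical 5' end (offset5 < 0 cannot be reconstructed
    from mature_seq alone); a mismatch between the read's 5' region and the
    mature sequence (the decomposition would not be lossless).
    """
    read = record.seq
    pos = read.find(ref.motif)
    if pos < 0:
        raise ValueError(f"motif of {ref.mirna_id} not found in read")
    if read.find(ref.motif, pos + 1) >= 0:
        return None  # motif twice: ambiguous placement
    offset5 = ref.motif_offset - pos
    if offset5 < 0:
        return None
    if read[:pos] != ref.mature_seq[offset5 : ref.motif_offset]:
        return None
    template = ref.mature_seq + ref.flank3
    L = len(ref.mature_seq)
    r = pos + len(ref.motif)
    t = ref.motif_offset + len(ref.motif)
    while r < len(read) and t < len(template) and read[r] == template[t]:
        r += 1
        t += 1
    tail = read[r:]
    templ3 = t - L
    is_canonical = offset5 == 0 and templ3 == 0 and tail == ""
    return IsomiRAnnotation(
        mirna_id=ref.mirna_id,
        offset5=offset5,
        templ3=templ3,
        tail=tail,
        count=record.count,
        is_canonical=is_canonical,
    )


def annotate_library(
    records: Iterable[ReadRecord], refs: Sequence[MiRNARef]
) -> tuple[list[IsomiRAnnotation], ReadFates]:
    """Assign and decompose a collapsed library; returns annotations + fates."""
    by_id = {r.mirna_id: r for r in refs}
    fates = ReadFates()
    annotations: list[IsomiRAnnotation] = []
    for rec in records:
        n_hits = sum(1 for r in refs if r.motif in rec.seq)
        if n_hits == 0:
            fates.unassigned += rec.count
            continue
        if n_hits > 1:
            fates.ambiguous += rec.count
            continue
        mid = assign_read(rec, refs)
        if mid is None:  # single hit on an ambiguous-flagged reference
            fates.ambiguous += rec.count
            continue
        ann = annotate_3prime(rec, by_id[mid])
        if ann is None:
            fates.refused += rec.count
        else:
            fates.annotated += ann.count
            annotations.append(ann)
    return annotations, fates


def process_fastq(
    reads_path: str | Path,
    refs: Sequence[MiRNARef],
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    min_insert: int = 15,
    max_insert: int = 35,
) -> tuple[list[IsomiRAnnotation], ReadFates]:
    """Full per-read pipeline: strip adapters, collapse, assign, decompose.

    Accepts FASTQ (``.fastq``/``.fq``) or collapsed FASTA whose headers end
    in ``_xCOUNT``.
    """
    inserts: list[str] = []
    dropped = 0
    for seq, count in _read_sequences(reads_path):
        insert = strip_adapter(
            seq, adapter, min_overlap, max_mismatch_rate, min_insert, max_insert
        )
        if insert is None:
            dropped += count
        else:
            inserts.extend([insert] * count)
    annotations, fates = annotate_library(collapse(inserts), refs)
    fates.dropped += dropped
    return annotations, fates


def _read_sequences(path: str | Path) -> Iterator[tuple[str, int]]:
    path = Path(path)
    if path.suffix in (".fastq", ".fq"):
        for rec in SeqIO.parse(str(path), "fastq"):
            yield str(rec.seq), 1
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            count = 1
            if "_x" in rec.id:
                try:
                    count = int(rec.id.rsplit("_x", 1)[1])
                except ValueError:
                    pass
            yield str(rec.seq), count


def annotations_to_frame(annotations: Iterable[IsomiRAnnotation]) -> pd.DataFrame:
    """Annotations as the interchange TSV schema."""
    return pd.DataFrame(
        [
            {
                "mirna_id": a.mirna_id,
                "offset5": a.offset5,
                "templ3": a.templ3,
                "tail": a.tail,
                "count": a.count,
                "is_canonical": a.is_canonical,
            }
            for a in annotations
        ],
        columns=["mirna_id", "offset5", "templ3", "tail", "count", "is_canonical"],
    )


def write_annotations(
    annotations: Iterable[IsomiRAnnotation], path: str | Path
) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[IsomiRAnnotation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"tail": str})
    required = ["mirna_id", "offset5", "templ3", "tail", "count"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    out = []
    for row in df.itertuples(index=False):
        tail = row.tail
        out.append(
            IsomiRAnnotation(
                mirna_id=row.mirna_id,
                offset5=int(row.offset5),
                templ3=int(row.templ3),
                tail=tail,
                count=int(row.count),
                is_canonical=(int(row.offset5) == 0 and int(row.templ3) == 0 and tail == ""),
            )
        )
    return out
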