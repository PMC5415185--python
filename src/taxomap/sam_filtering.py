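"""Alignment record parsing and per-read / per-fragment acceptance rules.

Candidate records are selected with the samtools flag masks (``-F 256 -f 2``
for paired data, ``-F 260`` for single-end), then filtered on two per-read
thresholds: a minimum aligner-reported alignment score (MAS, AS tag) and a
minimum fraction of the read aligned in CIGAR match/mismatch state relative
to the full read length (FMM).  In paired mode a fragment survives only if
both mates pass — one failing mate removes the pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_IN_PAIR = 0x40
FLAG_SECOND_IN_PAIR = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# ops contributing to the FMM numerator ('=' and 'X' are explicit match /
# mismatch states and count as 'M')
_MATCH_OPS = frozenset("M=X")
# ops consuming read bases (full read length for records without hard clips)
_QUERY_OPS = frozenset("MIS=X")
# ops consuming reference positions
_REF_OPS = frozenset("MDN=X")


class RecordSkipped(Exception):
    """A SAM record unusable by the method (missing tags, no CIGAR, ...).

    ``reason`` is a short token used in the run diagnostics tally.
    """

    def __init__(self, reason: str, detail: str = "") -> None:
        super().__init__(detail or reason)
        self.reason = reason


@dataclass(frozen=True)
class AlignmentRecord:
    """One parsed alignment line.

    ``read_length`` is the full read length including soft- and hard-clipped
    bases; ``align_score`` and ``edit_distance`` follow AS / NM tag semantics.
    ``mate_index`` is 1 or 2 for paired reads, 0 for single-end.
    """

    query_name: str
    flags: int
    ref_name: str
    ref_db: str
    pos: int  # 1-based leftmost mapped position
    cigar: str
    align_score: int
    edit_distance: int
    read_length: int
    mate_index: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError(f"read_length must be positive, got {self.read_length}")
        if self.edit_distance < 0:
            raise ValueError(f"edit_distance must be >= 0, got {self.edit_distance}")


@dataclass(frozen=True)
class FilterConfig:
    """Per-read acceptance thresholds; both comparisons are inclusive minima."""

    mas: int = 30
    fmm: float = 0.8
    paired: bool = True


def cigar_ops(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, length) tuples; hard error if malformed."""
    if not cigar or cigar == "*":
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    return ops


def keep_candidate(record: AlignmentRecord, paired: bool, drop_supplementary: bool = True) -> bool:
    """Flag-mask candidate selection.

    Paired mode keeps records with the secondary bit unset and the
    properly-paired bit set (``-F 256 -f 2``); single-end mode keeps records
    that are neither secondary nor unmapped (``-F 260``).  Supplementary
    alignments (0x800, shorter split hits) are dropped as well by default;
    pass ``drop_supplementary=False`` for the bare mask semantics.
    """
    flags = record.flags
    if drop_supplementary and flags & FLAG_SUPPLEMENTARY:
        return False
    if paired:
        return not flags & FLAG_SECONDARY and bool(flags & FLAG_PROPER_PAIR)
    return not flags & (FLAG_SECONDARY | FLAG_UNMAPPED)


def matched_fraction(record: AlignmentRecord) -> float:
    """Fraction of the full read length in CIGAR match/mismatch state."""
    matched = sum(n for op, n in cigar_ops(record.cigar) if op in _MATCH_OPS)
    return matched / record.read_length


def pass_read_filter(record: AlignmentRecord, cfg: FilterConfig) -> bool:
    """True iff the record meets both the MAS and FMM minima (inclusive)."""
    return record.align_score >= cfg.mas and matched_fraction(record) >= cfg.fmm


def filter_fragment(records: Sequence[AlignmentRecord], cfg: FilterConfig) -> bool:
    """Fragment-level acceptance: every mate must pass the read filter.

    Paired mode expects exactly the two mates of one fragment aligned to one
    reference; any other multiplicity rejects the fragment (the caller tallies
    it as improper rather than raising).
    """
    if cfg.paired:
        if len(records) != 2:
            return False
        mates = {r.mate_index for r in records}
        if mates != {1, 2}:
            return False
    elif len(records) != 1:
        return False
    return all(pass_read_filter(r, cfg) for r in records)


def aligned_blocks(record: AlignmentRecord) -> list[tuple[int, int]]:
    """Reference intervals (0-based, half-open) covered by M/=/X operations.

    Deletions and skips advance the reference cursor without producing a
    block, matching pileup semantics where a deleted position receives no
    base from this read.
    """
    blocks: list[tuple[int, int]] = []
    cursor = record.pos - 1
    for op, n in cigar_ops(record.cigar):
        if op in _MATCH_OPS:
            blocks.append((cursor, cursor + n))
            cursor += n
        elif op in _REF_OPS:  # D or N
            cursor += n
    return blocks


def record_from_alignment(aln, db: str) -> AlignmentRecord:
    """Build an :class:`AlignmentRecord` from a pysam ``AlignedSegment``.

    Raises :class:`RecordSkipped` for records the method cannot score:
    missing AS/NM tags, absent CIGAR, or an unrecoverable read length
    (hard-clipped record with no sequence stored).
    """
    if aln.cigarstring is None:
        raise RecordSkipped("no_cigar", f"{aln.query_name}: no CIGAR")
    try:
        score = aln.get_tag("AS")
        nm = aln.get_tag("NM")
    except KeyError:
        raise RecordSkipped("missing_tags", f"{aln.query_name}: AS/NM tag absent") from None
    # infer_read_length sums query-consuming ops plus hard clips, i.e. the
    # full original read length the FMM denominator needs
    read_length = aln.infer_read_length()
    if not read_length:
        raise RecordSkipped("no_read_length", f"{aln.query_name}: read length unrecoverable")
    flags = aln.flag
    if flags & FLAG_PAIRED:
        mate_index = 1 if flags & FLAG_FIRST_IN_PAIR else 2
    else:
        mate_index = 0
    return AlignmentRecord(
        query_name=aln.query_name,
        flags=flags,
        ref_name=aln.reference_name or "*",
        ref_db=db,
        pos=aln.reference_start + 1,
        cigar=aln.cigarstring,
        align_score=int(score),
        edit_distance=int(nm),
        read_length=int(read_length),
        mate_index=mate_index,
    )
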