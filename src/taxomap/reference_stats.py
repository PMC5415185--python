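"""Per-reference read-count statistics.

For every reference with at least one assigned fragment a 14-column record is
computed: the two abundance measures, reference size, counts of mapped reads
(mates counted individually, so a pair contributes 2), uniquely mapped reads,
nucleotides placed on the reference, distinct covered positions, depth,
coverage and summed edit distance.

The size-normalized abundance is
``S_Abundance = 100 * ReadCount / Size`` for single-end data and
``100 * ReadCount / (2 * Size)`` for paired-end data — the factor 2 converts
mate counts back to fragment equivalents.  ``R_Abundance`` expresses the
mapped read count as a percentage of the sample's cleaned reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .hit_resolution import Assignment
from .sam_filtering import AlignmentRecord, aligned_blocks
from .taxonomy import TaxonomyPath, TaxonomyStore


@dataclass(frozen=True)
class SampleContext:
    """Sample-wide denominators: cleaned-read count (set to 100%) and mode."""

    total_clean_reads: int
    paired: bool = True

    def __post_init__(self) -> None:
        if self.total_clean_reads <= 0:
            raise ValueError("total_clean_reads must be positive")


@dataclass(frozen=True)
class StatRow:
    """One per-reference statistics record (strain level; seq_count is 1)."""

    database: str
    ref_seq: str
    s_abundance: float
    r_abundance: float
    size_bp: int
    seq_count: int
    nucleotides: int
    covered_positions: int
    coverage: float
    depth: float
    read_count: int
    read_count_uniq: int
    mismatches: int
    description: str = ""
    taxonomy: Optional[TaxonomyPath] = None

    def __post_init__(self) -> None:
        if self.covered_positions > self.size_bp:
            raise ValueError("covered_positions cannot exceed reference size")
        if self.read_count_uniq > self.read_count:
            raise ValueError("read_count_uniq cannot exceed read_count")


def s_abundance(read_count: int, size_bp: int, paired: bool) -> float:
    """Size-normalized abundance, scaled by 100; paired counts are halved."""
    if size_bp <= 0:
        raise ValueError(f"reference size must be positive, got {size_bp}")
    denom = 2 * size_bp if paired else size_bp
    return 100.0 * read_count / denom

def r_abundance(read_count: int, ctx: SampleContext) -> float:
    """Mapped reads as a percentage of the sample's cleaned reads."""
    return 100.0 * read_count / ctx.total_clean_reads


def pileup_stats(
    records: Iterable[AlignmentRecord], size_bp: int
) -> tuple[int, int]:
    """Covered positions and nucleotide count for one reference.

    ``nucleotides`` is the total number of read bases placed on the reference
    (CIGAR M/=/X lengths over all mates); ``covered_positions`` the number of
    distinct reference positions under at least one such base.  Insertions
    exist only in the read and contribute to neither; deletions/skips advance
    the reference without adding coverage.
    """
    blocks: list[tuple[int, int]] = []
    nucleotides = 0
    for rec in records:
        for start, end in aligned_blocks(rec):
            if end > size_bp:
                raise ValueError(
                    f"alignment of {rec.query_name!r} extends to {end} on "
                    f"{rec.ref_name!r} of size {size_bp}"
                )
            blocks.append((start, end))
            nucleotides += end - start
    blocks.sort()
    covered = 0
    cur_start, cur_end = -1, -1
    for start, end in blocks:
        if start > cur_end:
            covered += cur_end - cur_start
            cur_start, cur_end = start, end
        elif end > cur_end:
            cur_end = end
    covered += cur_end - cur_start
    return max(covered, 0), nucleotides


def build_stat_rows(
    assigned: Sequence[tuple[Assignment, Sequence[AlignmentRecord]]],
    taxonomy: TaxonomyStore,
    ctx: SampleContext,
    ref_sizes: Mapping[str, int],
    descriptions: Optional[Mapping[str, str]] = None,
) -> list[StatRow]:
    """Aggregate assignments into one row per (database, reference).

    Each element pairs a fragment's assignment with the alignment records
    (both mates in paired mode) that realized it.  ReadCount counts mates,
    ReadCount uniq counts mates of fragments whose assignment was unique,
    Mismatches sums the NM edit distance of every counted record.
    """
    groups: dict[tuple[str, str], list[tuple[Assignment, Sequence[AlignmentRecord]]]] = {}
    for assignment, records in assigned:
        groups.setdefault((assignment.db, assignment.ref_name), []).append(
            (assignment, records)
        )

    rows: list[StatRow] = []
    for (db, ref_name), members in sorted(groups.items()):
        if ref_name not in ref_sizes:
            raise KeyError(f"reference {ref_name!r} has no known size")
        size = ref_sizes[ref_name]
        all_records = [rec for _, records in members for rec in records]
        read_count = len(all_records)
        read_count_uniq = sum(
            len(records) for a, records in members if a.unique
        )
        mismatches = sum(rec.edit_distance for rec in all_records)
        covered, nucleotides = pileup_stats(all_records, size)
        path = taxonomy.lookup(ref_name)
        desc = (descriptions or {}).get(ref_name) or path.name("strain") or ref_name
        rows.append(
            StatRow(
                database=db,
                ref_seq=ref_name,
                s_abundance=s_abundance(read_count, size, ctx.paired),
                r_abundance=r_abundance(read_count, ctx),
                size_bp=size,
                seq_count=1,
                nucleotides=nucleotides,
                covered_positions=covered,
                coverage=covered / size,
                depth=nucleotides / size,
                read_count=read_count,
                read_count_uniq=read_count_uniq,
                mismatches=mismatches,
                description=desc,
                taxonomy=path,
            )
        )
    rows.sort(key=lambda r: (-r.s_abundance, r.ref_seq))
    return rows
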