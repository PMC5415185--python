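"""End-to-end orchestration: SAM files in, statistics tables out.

For each database the alignment file is streamed once: candidate records are
selected by flag mask, unusable records tallied, and surviving mate groups
turned into fragment hits.  Bestmode hits from all bestmode databases are
then resolved to one assignment per fragment; each fullmode database is
resolved independently.  Per-reference statistics follow, then clade
collapsing and the four-criterion post-processing at every requested level.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pysam

from .hit_resolution import (
    Assignment,
    DatabaseSpec,
    FragmentHit,
    resolve_bestmode,
    resolve_fullmode,
)
from .postprocess import CriteriaConfig, Verdict, partition
from .reference_stats import SampleContext, StatRow, build_stat_rows
from .sam_filtering import (
    AlignmentRecord,
    FilterConfig,
    RecordSkipped,
    filter_fragment,
    keep_candidate,
    record_from_alignment,
)
from .taxonomy import CLADE_LEVELS, CladeRow, TaxonomyStore, collapse_clade

log = logging.getLogger(__name__)


@dataclass
class DatabaseInput:
    spec: DatabaseSpec
    sam_path: Path


@dataclass
class RunConfig:
    databases: Sequence[DatabaseInput]
    taxonomy: TaxonomyStore
    context: SampleContext
    filter_config: FilterConfig
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    levels: Sequence[str] = ("strain", "species", "genus")
    ref_sizes: Optional[Mapping[str, int]] = None  # fallback: SAM @SQ headers
    descriptions: Optional[Mapping[str, str]] = None


@dataclass
class PipelineResult:
    strain_rows: dict[str, list[StatRow]]  # per database
    clade_partitions: dict[str, dict[str, tuple[list[CladeRow], list[Verdict]]]]
    summary: dict


def _scan_database(
    db: DatabaseInput, cfg: FilterConfig, sizes: dict[str, int], tally: Counter
) -> tuple[list[FragmentHit], dict[tuple[str, str], list[AlignmentRecord]]]:
    """Stream one SAM/BAM file into per-fragment hits and their records."""
    groups: dict[tuple[str, str], list[AlignmentRecord]] = defaultdict(list)
    with pysam.AlignmentFile(str(db.sam_path), check_sq=False) as sam:
        for name, length in zip(sam.references, sam.lengths):
            sizes.setdefault(name, length)
        for aln in sam.fetch(until_eof=True):
            tally["records_total"] += 1
            try:
                rec = record_from_alignment(aln, db.spec.name)
            except RecordSkipped as skip:
                if aln.flag & 0x4:
                    tally["records_unmapped"] += 1
                else:
                    tally[f"records_skipped_{skip.reason}"] += 1
                continue
            if not keep_candidate(rec, cfg.paired):
                tally["records_noncandidate"] += 1
                continue
            tally["records_candidate"] += 1
            groups[(rec.query_name, rec.ref_name)].append(rec)

    hits: list[FragmentHit] = []
    records: dict[tuple[str, str], list[AlignmentRecord]] = {}
    order = 0
    for (fragment_id, ref_name), recs in groups.items():
        expected = 2 if cfg.paired else 1
        if len(recs) != expected or (
            cfg.paired and {r.mate_index for r in recs} != {1, 2}
        ):
            tally["fragments_improper"] += 1
            continue
        if not filter_fragment(recs, cfg):
            tally["fragments_failed_filter"] += 1
            continue
        tally["fragments_passed_filter"] += 1
        scores = tuple(r.align_score for r in recs)
        hits.append(
            FragmentHit(fragment_id, db.spec.name, ref_name, sum(scores), scores, order)
        )
        records[(fragment_id, ref_name)] = recs
        order += 1
    return hits, records


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    for level in cfg.levels:
        if level not in CLADE_LEVELS:
            raise ValueError(f"unknown clade level {level!r}")
    sizes: dict[str, int] = dict(cfg.ref_sizes or {})
    tally: Counter = Counter()
    filt = cfg.filter_config

    per_db_hits: dict[str, list[FragmentHit]] = {}
    per_db_records: dict[str, dict[tuple[str, str], list[AlignmentRecord]]] = {}
    for db in cfg.databases:
        hits, records = _scan_database(db, filt, sizes, tally)
        per_db_hits[db.spec.name] = hits
        per_db_records[db.spec.name] = records

    bestmode_specs = [d.spec for d in cfg.databases if d.spec.mode == "bestmode"]
    fullmode_specs = [d.spec for d in cfg.databases if d.spec.mode == "fullmode"]

    # bestmode: pool hits per fragment across all bestmode databases
    pooled: dict[str, list[FragmentHit]] = defaultdict(list)
    for spec in bestmode_specs:
        for hit in per_db_hits[spec.name]:
            pooled[hit.fragment_id].append(hit)
    assignments: dict[str, list[tuple[Assignment, list[AlignmentRecord]]]] = defaultdict(list)
    for fragment_id, hits in pooled.items():
        assignment = resolve_bestmode(hits, bestmode_specs)
        recs = per_db_records[assignment.db][(fragment_id, assignment.ref_name)]
        assignments[assignment.db].append((assignment, recs))
        tally["bestmode_assignments"] += 1
        tally["bestmode_mates_assigned"] += len(recs)

    # fullmode: resolve each database on its own
    for spec in fullmode_specs:
        by_fragment: dict[str, list[FragmentHit]] = defaultdict(list)
        for hit in per_db_hits[spec.name]:
            by_fragment[hit.fragment_id].append(hit)
        for fragment_id, hits in by_fragment.items():
            assignment = resolve_fullmode(hits)
            recs = per_db_records[spec.name][(fragment_id, assignment.ref_name)]
            assignments[spec.name].append((assignment, recs))
            tally["fullmode_assignments"] += 1

    strain_rows: dict[str, list[StatRow]] = {}
    for db in cfg.databases:
        name = db.spec.name
        strain_rows[name] = build_stat_rows(
            assignments.get(name, []), cfg.taxonomy, cfg.context, sizes,
            cfg.descriptions,
        )

    clade_partitions: dict[str, dict[str, tuple[list[CladeRow], list[Verdict]]]] = {}
    for db in cfg.databases:
        name = db.spec.name
        clade_partitions[name] = {}
        for level in cfg.levels:
            clade_rows = collapse_clade(strain_rows[name], level)
            accepted, rejected = partition(clade_rows, level, cfg.criteria)
            clade_partitions[name][level] = (accepted, rejected)

    mates_assigned = tally["bestmode_mates_assigned"]
    if mates_assigned > cfg.context.total_clean_reads:
        log.warning(
            "assigned mates (%d) exceed the declared cleaned-read count (%d)",
            mates_assigned, cfg.context.total_clean_reads,
        )
    summary = dict(tally)
    summary["total_clean_reads"] = cfg.context.total_clean_reads
    summary["databases"] = [d.spec.name for d in cfg.databases]
    return PipelineResult(strain_rows, clade_partitions, summary)


def load_ref_sizes(path: str | Path) -> dict[str, int]:
    """Reference sizes from a 2-column TSV (name, length) or a FASTA file."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        sizes: dict[str, int] = {}
        name = None
        length = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if name is not None:
                        sizes[name] = length
                    name = line[1:].split()[0]
                    length = 0
                else:
                    length += len(line.strip())
            if name is not None:
                sizes[name] = length
        return sizes
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            if lineno == 1 and not parts[1].isdigit():
                continue  # header row
            sizes[parts[0]] = int(parts[1])
    return sizes
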