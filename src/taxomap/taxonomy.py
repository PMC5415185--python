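"""Reference-to-taxonomy mapping and clade-level aggregation.

Every reference sequence is keyed by its exact FASTA header token and carries
a taxonomy path over eight ranks, from strain up to superkingdom.  Per-reference
statistics rows are rolled up to any of those ranks by summing all numeric
identifiers over references sharing the rank's taxid (falling back to the
rank's name string, and finally to an "unclassified" bucket, so that no read
is ever dropped from the aggregate).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

log = logging.getLogger(__name__)

#: The eight taxonomic ranks attached to every reference, lowest first.
CLADE_LEVELS: tuple[str, ...] = (
    "strain",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TaxonomyPath:
    """Taxid and clade name for each of the eight ranks.

    ``taxids[i]`` / ``names[i]`` correspond to ``CLADE_LEVELS[i]``; either may
    be ``None`` when the rank is not annotated.  The strain name equals the
    reference header the path was keyed by.
    """

    taxids: tuple[Optional[int], ...]
    names: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.taxids) != len(CLADE_LEVELS) or len(self.names) != len(CLADE_LEVELS):
            raise ValueError("a taxonomy path has exactly 8 clade slots")
        for t in self.taxids:
            if t is not None and (not isinstance(t, int) or t <= 0):
                raise ValueError(f"taxid must be a positive integer, got {t!r}")

    def taxid(self, level: str) -> Optional[int]:
        return self.taxids[_level_index(level)]

    def name(self, level: str) -> Optional[str]:
        return self.names[_level_index(level)]

    @classmethod
    def unclassified(cls, ref_name: str) -> "TaxonomyPath":
        """Fallback path for a reference missing from the store."""
        taxids: list[Optional[int]] = [None] * len(CLADE_LEVELS)
        names: list[Optional[str]] = [None] * len(CLADE_LEVELS)
        names[0] = ref_name
        return cls(tuple(taxids), tuple(names))


def _level_index(level: str) -> int:
    try:
        return CLADE_LEVELS.index(level)
    except ValueError:
        raise ValueError(
            f"unknown clade level {level!r}; expected one of {', '.join(CLADE_LEVELS)}"
        ) from None


class TaxonomyStore:
    """Immutable-by-convention mapping ``ref_name -> TaxonomyPath``.

    Missing keys degrade to an unclassified path (logged once per key) so that
    downstream read conservation holds even with an incomplete taxonomy.
    """

    def __init__(self, paths: Optional[dict[str, TaxonomyPath]] = None) -> None:
        self._paths: dict[str, TaxonomyPath] = dict(paths or {})
        self._warned: set[str] = set()

    def __len__(self) -> int:
        return len(self._paths)

    def __contains__(self, ref_name: str) -> bool:
        return ref_name in self._paths

    def add(self, ref_name: str, path: TaxonomyPath) -> None:
        if ref_name in self._paths:
            raise ValueError(f"duplicate reference name in taxonomy: {ref_name!r}")
        self._paths[ref_name] = path

    def lookup(self, ref_name: str) -> TaxonomyPath:
        path = self._paths.get(ref_name)
        if path is None:
            if ref_name not in self._warned:
                log.warning("reference %r has no taxonomy entry; reported as unclassified", ref_name)
                self._warned.add(ref_name)
            return TaxonomyPath.unclassified(ref_name)
        return path


def load_taxonomy_tsv(path: str | Path) -> TaxonomyStore:
    """Read a taxonomy table: ``ref_name`` then (taxid, name) per rank.

    The file is UTF-8, tab-separated, with a header row; empty cells mean the
    rank is not annotated.  Duplicate reference names and malformed taxids are
    hard errors naming the offending key / line.
    """
    store = TaxonomyStore()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return store
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            ref_name = row[0]
            cells = row[1:]
            # pad to 16 taxonomy cells
            cells = list(cells) + [""] * (2 * len(CLADE_LEVELS) - len(cells))
            taxids: list[Optional[int]] = []
            names: list[Optional[str]] = []
            for i, level in enumerate(CLADE_LEVELS):
                raw_taxid = cells[2 * i].strip()
                raw_name = cells[2 * i + 1].strip()
                if raw_taxid:
                    try:
                        taxid = int(raw_taxid)
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: malformed taxid {raw_taxid!r} for rank {level}"
                        ) from None
                    if taxid <= 0:
                        raise ValueError(
                            f"{path}:{lineno}: taxid must be positive, got {taxid} for rank {level}"
                        )
                    taxids.append(taxid)
                else:
                    taxids.append(None)
                names.append(raw_name or None)
            if names[0] is None:
                names[0] = ref_name
            if ref_name in store:
                raise ValueError(f"{path}:{lineno}: duplicate reference name {ref_name!r}")
            store.add(ref_name, TaxonomyPath(tuple(taxids), tuple(names)))
    return store


def write_taxonomy_tsv(store_rows: Iterable[tuple[str, TaxonomyPath]], path: str | Path) -> None:
    """Write rows in the same dialect :func:`load_taxonomy_tsv` reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        cols = ["ref_name"]
        for level in CLADE_LEVELS:
            cols += [f"{level}_taxid", f"{level}_name"]
        fh.write("\t".join(cols) + "\n")
        for ref_name, p in store_rows:
            cells = [ref_name]
            for t, n in zip(p.taxids, p.names):
                cells.append("" if t is None else str(t))
                cells.append("" if n is None else n)
            fh.write("\t".join(cells) + "\n")


@dataclass(frozen=True)
class CladeRow:
    """Aggregate of per-reference statistics at one taxonomic rank.

    Ratio columns (``coverage``, ``depth``) are plain sums of the member rows,
    mirroring the per-reference report convention where every identifier is
    summed; an aggregated coverage can therefore exceed 1.  The recomputed
    ratios ``derived_coverage`` = sum(covered)/sum(size) and ``derived_depth``
    = sum(nucleotides)/sum(size) are emitted alongside for sanity checks.
    """

    database: str
    level: str
    taxid: Optional[int]
    name: str
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
    derived_coverage: float
    derived_depth: float


#: numeric StatRow/CladeRow attributes summed during clade collapsing
_SUMMED_FIELDS = (
    "s_abundance",
    "r_abundance",
    "size_bp",
    "seq_count",
    "nucleotides",
    "covered_positions",
    "coverage",
    "depth",
    "read_count",
    "read_count_uniq",
    "mismatches",
)


def collapse_clade(rows: Sequence, level: str) -> list[CladeRow]:
    """Merge statistics rows sharing the given rank's taxid into clade rows.

    ``rows`` are per-reference statistics records each carrying a ``taxonomy``
    path (see :mod:`taxomap.reference_stats`) or previously collapsed
    :class:`CladeRow` objects paired with paths.  Rows with no taxid at the
    rank are grouped by the rank's name string; rows with neither fall into a
    single "unclassified" group.  Output is sorted by descending size-normalized
    abundance, ties broken by clade name.
    """
    _level_index(level)  # validates the token
    groups: dict[tuple, list] = {}
    order: list[tuple] = []
    for row in rows:
        path: TaxonomyPath = row.taxonomy
        if path is None:
            raise ValueError(f"row {row!r} carries no taxonomy path")
        taxid = path.taxid(level)
        name = path.name(level)
        if taxid is not None:
            key = (row.database, "taxid", taxid)
        elif name is not None:
            key = (row.database, "name", name)
        else:
            key = (row.database, "name", UNCLASSIFIED)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(row)

    out: list[CladeRow] = []
    for key in order:
        # canonical member order keeps float sums independent of input order
        members = sorted(
            groups[key], key=lambda m: getattr(m, "ref_seq", None) or m.name
        )
        sums = {f: sum(getattr(m, f) for m in members) for f in _SUMMED_FIELDS}
        first_path: TaxonomyPath = members[0].taxonomy
        taxid = first_path.taxid(level)
        name = first_path.name(level)
        if name is None:
            name = UNCLASSIFIED if taxid is None else str(taxid)
        size = sums["size_bp"]
        out.append(
            CladeRow(
                database=members[0].database,
                level=level,
                taxid=taxid,
                name=name,
                derived_coverage=(sums["covered_positions"] / size) if size else 0.0,
                derived_depth=(sums["nucleotides"] / size) if size else 0.0,
                **sums,
            )
        )
    out.sort(key=lambda r: (-r.s_abundance, r.name))
    return out


# ---------------------------------------------------------------------------
# NCBI taxdump conversion utility (offline helper, not a runtime dependency)

def _read_dmp(path: str | Path) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield line.split("\t|\t")


def taxdump_to_tsv(
    nodes_dmp: str | Path,
    names_dmp: str | Path,
    refs: Sequence[tuple[str, int]],
    out_path: str | Path,
) -> int:
    """Convert NCBI taxdump files into the flat taxonomy TSV.

    ``refs`` pairs each reference sequence name with its anchor taxid (usually
    the strain-level node).  For each reference the lineage is walked upward
    through ``nodes.dmp`` and the eight standard ranks are filled from
    scientific names in ``names.dmp``; the strain slot always records the
    anchor node so the path stays keyed to the reference.  Returns the number
    of rows written.
    """
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    for fields in _read_dmp(nodes_dmp):
        taxid = int(fields[0])
        parent[taxid] = int(fields[1])
        rank[taxid] = fields[2].strip()
    sci_name: dict[int, str] = {}
    for fields in _read_dmp(names_dmp):
        if len(fields) >= 4 and fields[3].strip() == "scientific name":
            sci_name[int(fields[0])] = fields[1].strip()

    rows: list[tuple[str, TaxonomyPath]] = []
    for ref_name, anchor in refs:
        taxids: list[Optional[int]] = [None] * len(CLADE_LEVELS)
        names: list[Optional[str]] = [None] * len(CLADE_LEVELS)
        taxids[0] = anchor
        names[0] = ref_name
        node = anchor
        seen: set[int] = set()
        while node in parent and node not in seen:
            seen.add(node)
            r = rank.get(node)
            if r in CLADE_LEVELS and r != "strain":
                i = _level_index(r)
                if taxids[i] is None:
                    taxids[i] = node
                    names[i] = sci_name.get(node)
            if node == parent[node]:  # root points at itself
                break
            node = parent[node]
        rows.append((ref_name, TaxonomyPath(tuple(taxids), tuple(names))))
    write_taxonomy_tsv(rows, out_path)
    return len(rows)
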