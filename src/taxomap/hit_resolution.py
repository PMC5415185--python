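"""Best-hit resolution across databases using summed alignment scores.

For paired reads each candidate reference carries the sum of the two mates'
alignment scores (SAS); single-end reads use the one score.  In *bestmode*
a fragment is assigned to exactly one reference — the highest SAS across all
bestmode databases, ties broken by user-specified database priority and then
by file order.  In *fullmode* the best hit within one database is emitted
regardless of better hits elsewhere (intended for gene databases that are
subsets of genome databases).  A fragment is *unique* when its chosen SAS
strictly exceeds every alternative reference's SAS in the resolution scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class FragmentHit:
    """One fragment's candidate assignment to one reference in one database.

    ``order_index`` is the position of the hit in the database's alignment
    file and makes within-database tie-breaking deterministic.
    """

    fragment_id: str
    db: str
    ref_name: str
    sas: int
    mate_scores: tuple[int, ...]
    order_index: int = 0

    def __post_init__(self) -> None:
        if self.mate_scores and sum(self.mate_scores) != self.sas:
            raise ValueError("sas must equal the sum of mate_scores")


@dataclass(frozen=True)
class DatabaseSpec:
    name: str
    mode: str  # "bestmode" | "fullmode"
    priority: int  # 1 = highest (first database specified by the user)

    def __post_init__(self) -> None:
        if self.mode not in ("bestmode", "fullmode"):
            raise ValueError(f"mode must be bestmode or fullmode, got {self.mode!r}")


@dataclass(frozen=True)
class Assignment:
    fragment_id: str
    db: str
    ref_name: str
    sas: int
    unique: bool = False


def _priority_map(specs: Sequence[DatabaseSpec]) -> dict[str, int]:
    prios = [s.priority for s in specs]
    if len(set(prios)) != len(prios):
        raise ValueError("database priorities must be unique")
    return {s.name: s.priority for s in specs}


def _best(hits: Sequence[FragmentHit], priority: dict[str, int]) -> FragmentHit:
    # max SAS; ties to the highest-priority database; within one database to
    # the earliest record in the alignment file
    return min(hits, key=lambda h: (-h.sas, priority.get(h.db, 1 << 30), h.order_index))


def mark_unique(fragment_hits: Sequence[FragmentHit], chosen: Assignment) -> bool:
    """True iff no *other* reference in scope reaches the chosen SAS."""
    return all(
        h.sas < chosen.sas
        for h in fragment_hits
        if (h.db, h.ref_name) != (chosen.db, chosen.ref_name)
    )


def resolve_bestmode(
    hits: Sequence[FragmentHit], specs: Sequence[DatabaseSpec]
) -> Assignment:
    """Assign one fragment to its single best reference across bestmode databases."""
    if not hits:
        raise ValueError("resolve_bestmode requires at least one hit")
    priority = _priority_map(specs)
    best = _best(hits, priority)
    chosen = Assignment(best.fragment_id, best.db, best.ref_name, best.sas)
    return Assignment(
        chosen.fragment_id, chosen.db, chosen.ref_name, chosen.sas,
        unique=mark_unique(hits, chosen),
    )


def resolve_fullmode(hits: Sequence[FragmentHit]) -> Assignment:
    """Best hit within one fullmode database, independent of other databases."""
    if not hits:
        raise ValueError("resolve_fullmode requires at least one hit")
    dbs = {h.db for h in hits}
    if len(dbs) != 1:
        raise ValueError(f"fullmode resolution is per-database; got hits from {sorted(dbs)}")
    best = _best(hits, {next(iter(dbs)): 1})
    chosen = Assignment(best.fragment_id, best.db, best.ref_name, best.sas)
    return Assignment(
        chosen.fragment_id, chosen.db, chosen.ref_name, chosen.sas,
        unique=mark_unique(hits, chosen),
    )
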