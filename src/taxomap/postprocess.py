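"""Four-criterion post-processing of taxonomy annotations.

A candidate clade is accepted when it satisfies:

  I.   ReadCount >= 10 (an inclusive minimum),
  II.  mismatch ratio  Mismatches / Nucleotides  < 0.01,
  III. S_Abundance > 0.01,
  IV.  unique read fraction  ReadCount uniq / ReadCount  > 0.005.

At strain level all four criteria apply.  At species level criterion IV is
only used in a pre-cycle that selects confidently present species; the lowest
S_Abundance among those becomes a data-driven abundance threshold T, and a
second pass accepts species meeting I, II and S_Abundance >= T with IV
dropped (so a true species whose reads are shared with a close relative is
not lost to the uniqueness requirement).  At genus level and above only
criteria I–III are used.  Rejected rows are reported with the exact set of
criteria they violated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

CRITERIA = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class CriteriaConfig:
    min_read_count: int = 10
    max_mismatch_ratio: float = 0.01
    min_s_abundance: float = 0.01
    min_unique_fraction: float = 0.005
    #: species pre-cycle selects on all four criteria; set False for the
    #: alternative reading where the pre-cycle screens on IV alone
    precycle_all_criteria: bool = True

    def __post_init__(self) -> None:
        if min(self.min_read_count, self.max_mismatch_ratio,
               self.min_s_abundance, self.min_unique_fraction) < 0:
            raise ValueError("criteria thresholds must be nonnegative")


@dataclass(frozen=True)
class Verdict:
    row: object  # StatRow or CladeRow
    accepted: bool
    failed_criteria: frozenset[str]

    def __post_init__(self) -> None:
        if self.accepted != (not self.failed_criteria):
            raise ValueError("accepted must mean no failed criteria")


def mismatch_ratio(row) -> float:
    """Mismatches per aligned nucleotide; 0 for an empty but clean row."""
    if row.nucleotides == 0:
        return 0.0 if row.mismatches == 0 else float("inf")
    return row.mismatches / row.nucleotides


def _failures(row, cfg: CriteriaConfig, use: Sequence[str]) -> frozenset[str]:
    failed = set()
    if "I" in use and row.read_count < cfg.min_read_count:
        failed.add("I")
    if "II" in use and not mismatch_ratio(row) < cfg.max_mismatch_ratio:
        failed.add("II")
    if "III" in use and not row.s_abundance > cfg.min_s_abundance:
        failed.add("III")
    if "IV" in use:
        frac = row.read_count_uniq / row.read_count if row.read_count else 0.0
        if not frac > cfg.min_unique_fraction:
            failed.add("IV")
    return frozenset(failed)


def evaluate_strain(row, cfg: CriteriaConfig) -> Verdict:
    """All four criteria at strain level."""
    failed = _failures(row, cfg, CRITERIA)
    return Verdict(row, not failed, failed)


def evaluate_species(rows: Sequence, cfg: CriteriaConfig) -> list[Verdict]:
    """Two-pass species evaluation with a data-driven abundance threshold.

    Pass 1 selects rows passing the full criteria set (or IV alone when
    ``cfg.precycle_all_criteria`` is False) and takes T as the minimum
    S_Abundance among them, falling back to ``cfg.min_s_abundance`` when
    nothing is selected.  Pass 2 accepts rows passing I, II and
    S_Abundance >= T; criterion IV is not applied.
    """
    pre = CRITERIA if cfg.precycle_all_criteria else ("IV",)
    selected = [r for r in rows if not _failures(r, cfg, pre)]
    if selected:
        threshold = min(r.s_abundance for r in selected)
    else:
        threshold = cfg.min_s_abundance
    verdicts: list[Verdict] = []
    for row in rows:
        failed = set(_failures(row, cfg, ("I", "II")))
        if row.s_abundance < threshold:
            failed.add("III")
        failed = frozenset(failed)
        verdicts.append(Verdict(row, not failed, failed))
    return verdicts


def evaluate_genus_or_higher(row, cfg: CriteriaConfig) -> Verdict:
    """Criteria I, II and III only; uniqueness is not informative this high."""
    failed = _failures(row, cfg, ("I", "II", "III"))
    return Verdict(row, not failed, failed)


def partition(
    rows: Sequence, level: str, cfg: CriteriaConfig
) -> tuple[list, list[Verdict]]:
    """Split rows at one clade level into accepted rows and rejected verdicts.

    The union of both sides is the input; nothing is silently dropped.
    """
    if level == "strain":
        verdicts = [evaluate_strain(r, cfg) for r in rows]
    elif level == "species":
        verdicts = evaluate_species(rows, cfg)
    else:
        verdicts = [evaluate_genus_or_higher(r, cfg) for r in rows]
    accepted = [v.row for v in verdicts if v.accepted]
    rejected = [v for v in verdicts if not v.accepted]
    return accepted, rejected
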