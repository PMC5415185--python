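"""Tab-separated writers and readers for the statistics tables.

The per-database strain table carries 14 statistics columns followed by 16
taxonomy columns (taxid and name for each of the 8 clades).  Clade-level
tables are written in accepted/rejected pairs; rejected rows name the
criteria they violated.  Real numbers are printed with 6 significant digits;
rows are ordered by descending size-normalized abundance with a name
tie-break, so re-running on identical input is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

from .postprocess import Verdict
from .reference_stats import StatRow
from .taxonomy import CLADE_LEVELS, CladeRow, TaxonomyPath

STAT_COLUMNS = (
    "Database",
    "Ref. seq",
    "S_Abundance",
    "R_Abundance",
    "Size",
    "Seq_count",
    "Nucleotides",
    "Covered positions",
    "Coverage",
    "Depth",
    "ReadCount",
    "ReadCount uniq",
    "Mismatches",
    "Description",
)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _tax_header() -> list[str]:
    cols = []
    for level in CLADE_LEVELS:
        cols += [f"{level}_taxid", f"{level}_name"]
    return cols


def _tax_cells(path: Optional[TaxonomyPath]) -> list[str]:
    if path is None:
        return [""] * (2 * len(CLADE_LEVELS))
    cells = []
    for taxid, name in zip(path.taxids, path.names):
        cells.append("" if taxid is None else str(taxid))
        cells.append("" if name is None else name)
    return cells


def write_strain_table(rows: Sequence[StatRow], path: str | Path) -> None:
    """Per-reference table: 14 statistics + 16 taxonomy columns."""
    rows = sorted(rows, key=lambda r: (-r.s_abundance, r.ref_seq))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(list(STAT_COLUMNS) + _tax_header()) + "\n")
        for r in rows:
            cells = [
                r.database,
                r.ref_seq,
                _fmt(r.s_abundance),
                _fmt(r.r_abundance),
                str(r.size_bp),
                str(r.seq_count),
                str(r.nucleotides),
                str(r.covered_positions),
                _fmt(r.coverage),
                _fmt(r.depth),
                str(r.read_count),
                str(r.read_count_uniq),
                str(r.mismatches),
                r.description,
            ] + _tax_cells(r.taxonomy)
            fh.write("\t".join(cells) + "\n")


def read_strain_table(path: str | Path) -> list[StatRow]:
    """Re-parse a strain table written by :func:`write_strain_table`."""
    rows: list[StatRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(STAT_COLUMNS)] != list(STAT_COLUMNS):
            raise ValueError(f"{path}: not a strain statistics table")
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            tax_cells = cells[len(STAT_COLUMNS):]
            taxids: list[Optional[int]] = []
            names: list[Optional[str]] = []
            for i in range(len(CLADE_LEVELS)):
                raw_t = tax_cells[2 * i] if 2 * i < len(tax_cells) else ""
                raw_n = tax_cells[2 * i + 1] if 2 * i + 1 < len(tax_cells) else ""
                taxids.append(int(raw_t) if raw_t else None)
                names.append(raw_n or None)
            if names[0] is None:
                names[0] = cells[1]
            rows.append(
                StatRow(
                    database=cells[0],
                    ref_seq=cells[1],
                    s_abundance=float(cells[2]),
                    r_abundance=float(cells[3]),
                    size_bp=int(cells[4]),
                    seq_count=int(cells[5]),
                    nucleotides=int(cells[6]),
                    covered_positions=int(cells[7]),
                    coverage=float(cells[8]),
                    depth=float(cells[9]),
                    read_count=int(cells[10]),
                    read_count_uniq=int(cells[11]),
                    mismatches=int(cells[12]),
                    description=cells[13],
                    taxonomy=TaxonomyPath(tuple(taxids), tuple(names)),
                )
            )
    return rows


CLADE_COLUMNS = (
    "Database",
    "Clade",
    "Taxid",
    "S_Abundance",
    "R_Abundance",
    "Size",
    "Seq_count",
    "Nucleotides",
    "Covered positions",
    "Coverage",
    "Depth",
    "ReadCount",
    "ReadCount uniq",
    "Mismatches",
    "Coverage (recomputed)",
    "Depth (recomputed)",
)


def _clade_cells(r: CladeRow) -> list[str]:
    return [
        r.database,
        r.name,
        "" if r.taxid is None else str(r.taxid),
        _fmt(r.s_abundance),
        _fmt(r.r_abundance),
        str(r.size_bp),
        str(r.seq_count),
        str(r.nucleotides),
        str(r.covered_positions),
        _fmt(r.coverage),
        _fmt(r.depth),
        str(r.read_count),
        str(r.read_count_uniq),
        str(r.mismatches),
        _fmt(r.derived_coverage),
        _fmt(r.derived_depth),
    ]


def write_clade_tables(
    accepted: Sequence[CladeRow],
    rejected: Sequence[Verdict],
    accepted_path: str | Path,
    rejected_path: str | Path,
) -> None:
    """Accepted and rejected clade tables; rejected rows list failed criteria."""
    with open(accepted_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(CLADE_COLUMNS) + "\n")
        for r in sorted(accepted, key=lambda x: (-x.s_abundance, x.name)):
            fh.write("\t".join(_clade_cells(r)) + "\n")
    with open(rejected_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(CLADE_COLUMNS + ("Failed criteria",)) + "\n")
        for v in sorted(rejected, key=lambda x: (-x.row.s_abundance, x.row.name)):
            cells = _clade_cells(v.row) + [",".join(sorted(v.failed_criteria))]
            fh.write("\t".join(cells) + "\n")


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_xlsx(
    strain_rows: dict[str, Sequence[StatRow]],
    clade_partitions: dict[str, dict[str, tuple[Sequence[CladeRow], Sequence[Verdict]]]],
    path: str | Path,
) -> None:
    """Optional spreadsheet export: one sheet per database/level, accepted and
    rejected side by side (mirrors the TSV outputs)."""
    from openpyxl import Workbook  # optional dependency

    wb = Workbook()
    wb.remove(wb.active)
    for db, rows in strain_rows.items():
        ws = wb.create_sheet(f"{db}_strain"[:31])
        ws.append(list(STAT_COLUMNS) + _tax_header())
        for r in sorted(rows, key=lambda x: (-x.s_abundance, x.ref_seq)):
            ws.append([
                r.database, r.ref_seq, r.s_abundance, r.r_abundance, r.size_bp,
                r.seq_count, r.nucleotides, r.covered_positions, r.coverage,
                r.depth, r.read_count, r.read_count_uniq, r.mismatches,
                r.description,
            ] + _tax_cells(r.taxonomy))
    for db, per_level in clade_partitions.items():
        for level, (accepted, rejected) in per_level.items():
            ws = wb.create_sheet(f"{db}_{level}_pass"[:31])
            ws.append(list(CLADE_COLUMNS))
            for r in sorted(accepted, key=lambda x: (-x.s_abundance, x.name)):
                ws.append(_clade_cells(r))
            ws = wb.create_sheet(f"{db}_{level}_fail"[:31])
            ws.append(list(CLADE_COLUMNS) + ["Failed criteria"])
            for v in sorted(rejected, key=lambda x: (-x.row.s_abundance, x.row.name)):
                ws.append(_clade_cells(v.row) + [",".join(sorted(v.failed_criteria))])
    wb.save(str(path))
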