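"""Composition of the published mock bacterial benchmark communities.

Two widely used mock datasets for benchmarking metagenomic classifiers: an
*in vitro* sequenced mixture of 12 strains (11 species, 8 genera) and an *in
silico* simulated mixture of 13 strains (12 species, 9 genera) that adds
Nocardioides sp. JS614.  Only the composition is recorded here; it serves as
a worked example for clade collapsing — the strain rows must merge into
exactly the published species and genus counts.

Taxids are deterministic synthetic identifiers (one per distinct name), not
NCBI taxids: clade collapsing only requires that strains of the same species
share an identifier.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MockStrain:
    genus: str
    species: str
    strain: str
    in_vitro: bool
    in_silico: bool


MOCK_COMMUNITY: tuple[MockStrain, ...] = (
    MockStrain("Bacillus", "Bacillus amyloliquefaciens", "DSM7", True, True),
    MockStrain("Bacillus", "Bacillus cereus", "ATCC 14579", True, True),
    MockStrain("Burkholderia", "Burkholderia cenocepacia", "J2315", True, True),
    MockStrain("Escherichia", "Escherichia coli", "K-12", True, True),
    MockStrain("Frankia", "Frankia sp.", "CcI3", True, True),
    MockStrain("Micrococcus", "Micrococcus luteus", "NCTC 2665", True, True),
    MockStrain("Pseudomonas", "Pseudomonas aeruginosa", "PAO1", True, True),
    MockStrain("Pseudomonas", "Pseudomonas aeruginosa", "UCBPP-PA14", True, True),
    MockStrain("Pseudomonas", "Pseudomonas fluorescens", "Pf-5", True, True),
    MockStrain("Pseudomonas", "Pseudomonas putida", "KT2440", True, True),
    MockStrain("Rhodobacter", "Rhodobacter capsulatus", "SB 1003", True, True),
    MockStrain("Streptomyces", "Streptomyces coelicolor", "A3(2)", True, True),
    MockStrain("Nocardioides", "Nocardioides sp.", "JS614", False, True),
)


def mock_community_paths(dataset: str = "in_vitro"):
    """Taxonomy paths for the selected dataset ('in_vitro' or 'in_silico').

    Returns ``[(ref_name, TaxonomyPath), ...]`` with synthetic taxids assigned
    per distinct species and genus name.
    """
    from ..taxonomy import TaxonomyPath

    if dataset == "in_vitro":
        members = [m for m in MOCK_COMMUNITY if m.in_vitro]
    elif dataset == "in_silico":
        members = [m for m in MOCK_COMMUNITY if m.in_silico]
    else:
        raise ValueError(f"unknown dataset {dataset!r}")

    species_ids: dict[str, int] = {}
    genus_ids: dict[str, int] = {}
    out = []
    for m in members:
        sp_id = species_ids.setdefault(m.species, 10000 + len(species_ids))
        g_id = genus_ids.setdefault(m.genus, 20000 + len(genus_ids))
        ref_name = f"{m.species.replace(' ', '_')}_{m.strain.replace(' ', '_')}"
        path = TaxonomyPath(
            (None, sp_id, g_id, None, None, None, None, 2),
            (ref_name, m.species, m.genus, None, None, None, None, "Bacteria"),
        )
        out.append((ref_name, path))
    return out
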