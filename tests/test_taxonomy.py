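"""Taxonomy store contracts and clade-level aggregation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxomap.reference_stats import StatRow
from taxomap.taxonomy import (
    TaxonomyPath,
    TaxonomyStore,
    collapse_clade,
    load_taxonomy_tsv,
    taxdump_to_tsv,
    write_taxonomy_tsv,
)


def make_path(strain, species=None, genus=None, sp_id=None, g_id=None):
    taxids = [None] * 8
    names = [None] * 8
    names[0] = strain
    if species:
        names[1], taxids[1] = species, sp_id
    if genus:
        names[2], taxids[2] = genus, g_id
    return TaxonomyPath(tuple(taxids), tuple(names))


def make_row(ref, path, **over):
    fields = dict(
        database="db", ref_seq=ref, s_abundance=1.0, r_abundance=0.5,
        size_bp=1000, seq_count=1, nucleotides=500, covered_positions=400,
        coverage=0.4, depth=0.5, read_count=10, read_count_uniq=5,
        mismatches=2, description=ref, taxonomy=path,
    )
    fields.update(over)
    return StatRow(**fields)


class TestStore:
    def test_tsv_round_trip_preserves_rows(self, tmp_path):
        rows = [
            ("refA", make_path("refA", "sp1", "g1", 11, 21)),
            ("refB", make_path("refB", "sp1", "g1", 11, 21)),
            ("refC", make_path("refC")),
        ]
        path = tmp_path / "tax.tsv"
        write_taxonomy_tsv(rows, path)
        store = load_taxonomy_tsv(path)
        assert len(store) == 3
        for name, expected in rows:
            assert store.lookup(name) == expected

    def test_duplicate_reference_is_an_error_naming_the_line(self, tmp_path):
        path = tmp_path / "tax.tsv"
        lines = ["ref_name\tstrain_taxid\tstrain_name", "a\t\ta", "b\t\tb", "c\t\tc", "a\t\ta"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match=r":5.*'a'"):
            load_taxonomy_tsv(path)

    def test_malformed_taxid_is_an_error_with_line_number(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("ref_name\tstrain_taxid\tstrain_name\nx\tnot_a_number\tx\n")
        with pytest.raises(ValueError, match=":2"):
            load_taxonomy_tsv(path)

    def test_absent_strain_taxid_with_present_species_taxid(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(
            "ref_name\tstrain_taxid\tstrain_name\tspecies_taxid\tspecies_name\n"
            "r1\t\tr1\t42\tSpecies one\n"
        )
        p = load_taxonomy_tsv(path).lookup("r1")
        assert p.taxid("strain") is None
        assert p.taxid("species") == 42
        assert p.name("species") == "Species one"

    def test_unknown_key_degrades_to_unclassified(self):
        store = TaxonomyStore()
        p = store.lookup("refX")
        assert p.name("strain") == "refX"
        assert all(t is None for t in p.taxids)
        assert store.lookup("refX") == p  # repeat lookups identical


class TestCollapse:
    def test_singleton_group_equals_input_row(self):
        row = make_row("r1", make_path("r1", "sp", "g", 1, 2))
        [clade] = collapse_clade([row], "species")
        for f in ("s_abundance", "read_count", "nucleotides", "mismatches",
                  "covered_positions", "size_bp", "seq_count", "coverage", "depth"):
            assert getattr(clade, f) == getattr(row, f)
        assert clade.taxid == 1 and clade.name == "sp"

    def test_strains_merge_by_species_taxid(self):
        rows = [
            make_row("r1", make_path("r1", "sp", "g", 1, 2), read_count=10),
            make_row("r2", make_path("r2", "sp", "g", 1, 2), read_count=30),
            make_row("r3", make_path("r3", "other", "g", 9, 2), read_count=5),
        ]
        species = collapse_clade(rows, "species")
        assert len(species) == 2
        merged = next(c for c in species if c.taxid == 1)
        assert merged.read_count == 40 and merged.seq_count == 2
        assert len(collapse_clade(rows, "genus")) == 1

    def test_rows_without_taxid_group_by_name_then_unclassified(self):
        rows = [
            make_row("r1", make_path("r1", species="sp")),
            make_row("r2", make_path("r2", species="sp")),
            make_row("r3", make_path("r3")),  # nothing at species level
        ]
        groups = collapse_clade(rows, "species")
        names = {c.name for c in groups}
        assert names == {"sp", "unclassified"}

    def test_unknown_level_token_rejected(self):
        with pytest.raises(ValueError, match="superfamily"):
            collapse_clade([], "superfamily")

    def test_derived_ratios_recomputed_from_sums(self):
        rows = [
            make_row("r1", make_path("r1", "sp", sp_id=1), size_bp=1000,
                     covered_positions=500, coverage=0.5, nucleotides=800, depth=0.8),
            make_row("r2", make_path("r2", "sp", sp_id=1), size_bp=3000,
                     covered_positions=300, coverage=0.1, nucleotides=600, depth=0.2),
        ]
        [clade] = collapse_clade(rows, "species")
        # as-printed ratio columns are plain sums; derived ones are re-ratioed
        assert clade.coverage == pytest.approx(0.6)
        assert clade.derived_coverage == pytest.approx(800 / 4000)
        assert clade.derived_depth == pytest.approx(1400 / 4000)

    @given(st.lists(
        st.tuples(st.integers(0, 5), st.integers(1, 500)),
        min_size=1, max_size=30,
    ))
    @settings(max_examples=60, deadline=None)
    def test_conservation_and_monotonic_group_counts(self, raw):
        rows = []
        for i, (sp, rc) in enumerate(raw):
            g = sp % 3  # nested ranks: each species sits under one genus
            path = make_path(f"r{i}", f"sp{sp}", f"g{g}", 100 + sp, 200 + g)
            rows.append(make_row(f"r{i}", path, read_count=rc,
                                 read_count_uniq=min(rc, 1), s_abundance=rc / 10))
        prev_groups = len(rows)
        for level in ("species", "genus", "superkingdom"):
            clades = collapse_clade(rows, level)
            for f in ("read_count", "nucleotides", "mismatches", "s_abundance"):
                assert sum(getattr(c, f) for c in clades) == pytest.approx(
                    sum(getattr(r, f) for r in rows)
                )
            assert len(clades) <= prev_groups
            prev_groups = len(clades)
            # order independence
            assert collapse_clade(list(reversed(rows)), level) == clades


def test_taxdump_conversion_walks_the_lineage(tmp_path):
    nodes = tmp_path / "nodes.dmp"
    names = tmp_path / "names.dmp"
    # minimal taxdump: root(1) <- phylum(10) <- genus(20) <- species(30) <- strain(40)
    nodes.write_text(
        "1\t|\t1\t|\tno rank\t|\n"
        "10\t|\t1\t|\tphylum\t|\n"
        "20\t|\t10\t|\tgenus\t|\n"
        "30\t|\t20\t|\tspecies\t|\n"
        "40\t|\t30\t|\tstrain\t|\n"
    )
    names.write_text(
        "1\t|\troot\t|\t\t|\tscientific name\t|\n"
        "10\t|\tTestphyla\t|\t\t|\tscientific name\t|\n"
        "20\t|\tTestgenus\t|\t\t|\tscientific name\t|\n"
        "30\t|\tTestgenus species\t|\t\t|\tscientific name\t|\n"
    )
    out = tmp_path / "tax.tsv"
    assert taxdump_to_tsv(nodes, names, [("refZ", 40)], out) == 1
    p = load_taxonomy_tsv(out).lookup("refZ")
    assert p.taxid("strain") == 40 and p.name("strain") == "refZ"
    assert p.taxid("species") == 30 and p.name("species") == "Testgenus species"
    assert p.taxid("genus") == 20
    assert p.taxid("phylum") == 10
    assert p.taxid("family") is None
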