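"""The four acceptance criteria, the species two-pass, and partition laws."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxomap.postprocess import (
    CriteriaConfig,
    evaluate_genus_or_higher,
    evaluate_species,
    evaluate_strain,
    mismatch_ratio,
    partition,
)
from taxomap.taxonomy import CladeRow

CFG = CriteriaConfig()


def clade(name="c", rc=100, uniq=50, mism=3, nucl=10_000, s_ab=0.1, level="strain"):
    return CladeRow(
        database="db", level=level, taxid=None, name=name,
        s_abundance=s_ab, r_abundance=1.0, size_bp=10_000, seq_count=1,
        nucleotides=nucl, covered_positions=min(nucl, 10_000),
        coverage=0.5, depth=1.0, read_count=rc, read_count_uniq=uniq,
        mismatches=mism, derived_coverage=0.5, derived_depth=1.0,
    )


class TestMismatchRatio:
    @pytest.mark.parametrize("mism,nucl,expected", [
        (3, 1000, 0.003), (0, 1000, 0.0), (15, 1000, 0.015), (0, 0, 0.0),
    ])
    def test_ratio(self, mism, nucl, expected):
        assert mismatch_ratio(clade(mism=mism, nucl=nucl)) == pytest.approx(expected)

    def test_mismatches_without_nucleotides_fail_criterion_two(self):
        v = evaluate_strain(clade(mism=5, nucl=0), CFG)
        assert "II" in v.failed_criteria


class TestStrainLevel:
    def test_all_criteria_pass(self):
        assert evaluate_strain(clade(), CFG).accepted

    @pytest.mark.parametrize("kwargs,criterion", [
        (dict(rc=9, uniq=9), "I"),
        (dict(mism=150), "II"),          # ratio 0.015
        (dict(s_ab=0.009), "III"),
        (dict(rc=1000, uniq=4), "IV"),   # fraction 0.004
    ])
    def test_each_criterion_flags_its_own_violation(self, kwargs, criterion):
        v = evaluate_strain(clade(**kwargs), CFG)
        assert not v.accepted
        assert v.failed_criteria == frozenset({criterion})

    def test_boundary_strictness(self):
        # I is inclusive (>= 10); II, III, IV are strict
        assert evaluate_strain(clade(rc=10, uniq=10), CFG).accepted
        assert "II" in evaluate_strain(clade(mism=100, nucl=10_000), CFG).failed_criteria
        assert "III" in evaluate_strain(clade(s_ab=0.01), CFG).failed_criteria
        assert "IV" in evaluate_strain(clade(rc=1000, uniq=5), CFG).failed_criteria
        assert evaluate_strain(clade(rc=1000, uniq=6), CFG).accepted


class TestSpeciesTwoPass:
    def test_fully_passing_rows_all_accepted(self):
        rows = [clade("a", s_ab=0.5), clade("b", s_ab=0.2)]
        verdicts = evaluate_species(rows, CFG)
        assert all(v.accepted for v in verdicts)

    def test_low_uniqueness_species_rescued_above_threshold(self):
        """A species failing only IV is accepted in pass 2 when its abundance
        reaches the pre-cycle floor."""
        confident = clade("sure", s_ab=0.2)
        shared = clade("shared", s_ab=0.5, rc=1000, uniq=0)  # fails IV only
        verdicts = {v.row.name: v for v in evaluate_species([confident, shared], CFG)}
        assert verdicts["sure"].accepted
        assert verdicts["shared"].accepted

    def test_low_abundance_row_falls_below_the_data_driven_floor(self):
        confident = clade("sure", s_ab=0.5)
        weak = clade("weak", s_ab=0.05)  # passes I-IV but sits below T = 0.5
        verdicts = {v.row.name: v for v in evaluate_species([confident, weak], CFG)}
        # the pre-cycle keeps 'weak' too (it passes all four), so T = 0.05
        assert verdicts["weak"].accepted
        shared_weak = clade("shared", s_ab=0.05, rc=1000, uniq=0)
        verdicts = {
            v.row.name: v
            for v in evaluate_species([confident, shared_weak], CFG)
        }
        assert not verdicts["shared"].accepted
        assert verdicts["shared"].failed_criteria == frozenset({"III"})

    def test_empty_input(self):
        assert evaluate_species([], CFG) == []

    def test_no_selected_species_falls_back_to_configured_floor(self):
        # nothing passes the pre-cycle; T reverts to min_s_abundance
        rows = [clade("x", rc=9, uniq=9, s_ab=0.5)]
        [v] = evaluate_species(rows, CFG)
        assert v.failed_criteria == frozenset({"I"})

    def test_alternative_precycle_reading_is_exposed(self):
        cfg = CriteriaConfig(precycle_all_criteria=False)
        # under the IV-only pre-cycle a low-abundance high-uniqueness row
        # drags the floor down
        rows = [clade("hi", s_ab=0.5), clade("lo", s_ab=0.001)]
        verdicts = {v.row.name: v for v in evaluate_species(rows, cfg)}
        assert verdicts["lo"].accepted


class TestGenusAndHigher:
    def test_only_first_three_criteria_apply(self):
        row = clade(rc=10, mism=90, nucl=10_000, s_ab=0.011, uniq=0, level="genus")
        v = evaluate_genus_or_higher(row, CFG)
        assert v.accepted  # IV-equivalent failure is ignored

    def test_strict_abundance_boundary(self):
        v = evaluate_genus_or_higher(clade(s_ab=0.01, level="genus"), CFG)
        assert v.failed_criteria == frozenset({"III"})


@given(st.lists(
    st.tuples(st.integers(0, 40), st.integers(0, 100), st.integers(0, 200),
              st.floats(0.0, 1.0)),
    max_size=25,
), st.sampled_from(["strain", "species", "genus", "family"]))
@settings(max_examples=120, deadline=None)
def test_partition_is_complete_and_disjoint(raw, level):
    rows = [
        clade(f"c{i}", rc=rc, uniq=min(uniq, rc), mism=mism, s_ab=s_ab, level=level)
        for i, (rc, uniq, mism, s_ab) in enumerate(raw)
    ]
    accepted, rejected = partition(rows, level, CFG)
    assert len(accepted) + len(rejected) == len(rows)
    assert {id(r) for r in accepted}.isdisjoint({id(v.row) for v in rejected})
    assert {id(r) for r in accepted} | {id(v.row) for v in rejected} == {id(r) for r in rows}
    for v in rejected:
        assert v.failed_criteria


@given(st.lists(
    st.tuples(st.integers(0, 40), st.integers(0, 40), st.integers(0, 200),
              st.floats(0.0, 1.0)),
    max_size=20,
))
@settings(max_examples=100, deadline=None)
def test_tightening_thresholds_never_grows_the_accepted_set(raw):
    rows = [
        clade(f"c{i}", rc=rc, uniq=min(uniq, rc), mism=mism, s_ab=s_ab)
        for i, (rc, uniq, mism, s_ab) in enumerate(raw)
    ]
    loose = CriteriaConfig()
    tight = CriteriaConfig(min_read_count=15, max_mismatch_ratio=0.005,
                           min_s_abundance=0.05, min_unique_fraction=0.01)
    acc_loose, _ = partition(rows, "strain", loose)
    acc_tight, _ = partition(rows, "strain", tight)
    assert {id(r) for r in acc_tight} <= {id(r) for r in acc_loose}
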