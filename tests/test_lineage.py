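import numpy as np
import pandas as pd
import pytest

import mutlineage as ml
from mutlineage.lineage import (AssignmentErrorFlag, ColonyRecord,
                                LineageTable, Role, SegregantCounts,
                                assign_segregant_groups, classify_segregation,
                                detect_assignment_errors, filter_to_shared,
                                full_error_count, mismatch_counts,
                                shared_callable_genome, tally_segregation)


def _colony(cid, division, position, variants, callable_map):
    return ColonyRecord(cid, Role(division, position), set(variants),
                        callable_map)


@pytest.fixture()
def toy_lineage(toy_chromset):
    """Four hand-built sublineages with one variant per segregant group of
    division 1, plus a singleton destined for the noise filter."""
    full = {"chrA": [(0, 100)], "chrB": [(0, 300)]}
    da = ("chrA", 10, "C", "T")       # D1 + GD1.2
    db = ("chrA", 20, "C", "G")       # GD1.1 + GGD1.1
    ma = ("chrB", 30, "C", "A")       # all of sublineage 2
    mb = ("chrB", 40, "C", "T")       # everything in sublineages >= 3
    noise = ("chrB", 250, "C", "G")   # single colony only
    records = []
    for n in range(1, 5):
        for pos in ("D", "GD1", "GD2", "GGD"):
            cid = f"{pos}{n}"
            variants = set()
            if n == 1 and pos in ("D", "GD2"):
                variants.add(da)
            if n == 1 and pos in ("GD1", "GGD"):
                variants.add(db)
            if n == 2:
                variants.add(ma)
            if n >= 3:
                variants.add(mb)
            if n == 4 and pos == "GGD":
                variants.add(noise)
            records.append(_colony(cid, n, pos, variants, full))
    return LineageTable(records, toy_chromset), (da, db, ma, mb, noise)


def test_shared_callable_basics(toy_chromset):
    full = {"chrA": [(0, 100)]}
    a = _colony("a", 1, "D", [], {"chrA": [(0, 100)]})
    b = _colony("b", 1, "GD1", [], {"chrA": [(50, 150)]})
    c = _colony("c", 1, "GD2", [], {"chrA": [(0, 100)]})
    d = _colony("d", 1, "GGD", [], full)
    lineage = LineageTable([a, b, c, d], toy_chromset)
    shared, lengths = shared_callable_genome(lineage, members=["a", "b"])
    assert shared == {"chrA": [(50, 100)]}
    assert lengths == {"chrA": 50}
    # identical sets are idempotent
    shared2, _ = shared_callable_genome(lineage, members=["a", "c"])
    assert shared2 == {"chrA": [(0, 100)]}
    with pytest.raises(ValueError, match="empty"):
        shared_callable_genome(lineage, members=[])
    with pytest.raises(ValueError, match="unknown"):
        shared_callable_genome(lineage, members=["nope"])


def test_disjoint_callable_empty(toy_chromset):
    recs = [
        _colony("a", 1, "D", [], {"chrA": [(0, 50)]}),
        _colony("b", 1, "GD1", [], {"chrA": [(50, 100)]}),
        _colony("c", 1, "GD2", [], {"chrA": [(0, 50)]}),
        _colony("d", 1, "GGD", [], {"chrA": [(0, 50)]}),
    ]
    lineage = LineageTable(recs, toy_chromset)
    shared, _ = shared_callable_genome(lineage, members=["a", "b"])
    assert shared == {}


def test_filter_drops_singletons_and_out_of_shared(toy_lineage):
    lineage, (da, db, ma, mb, noise) = toy_lineage
    flt = filter_to_shared(lineage)
    remaining = set()
    for rec in flt.colonies():
        remaining |= rec.variants
    assert noise not in remaining          # observed in one colony only
    assert {da, db, ma, mb} <= remaining   # >= 2 colonies each


def test_filter_respects_shared_genome(toy_chromset):
    # a variant shared by two colonies but outside one colony's callable
    v = ("chrA", 75, "C", "T")
    recs = [
        _colony("a", 1, "D", [v], {"chrA": [(0, 100)]}),
        _colony("b", 1, "GD1", [v], {"chrA": [(0, 100)]}),
        _colony("c", 1, "GD2", [], {"chrA": [(0, 50)]}),
        _colony("d", 1, "GGD", [], {"chrA": [(0, 100)]}),
    ]
    flt = filter_to_shared(LineageTable(recs, toy_chromset))
    for rec in flt.colonies():
        assert v not in rec.variants


def test_toy_assignment_patterns(toy_lineage):
    lineage, (da, db, ma, mb, _) = toy_lineage
    flt = filter_to_shared(lineage)
    sc = assign_segregant_groups(flt, 1)
    assert sc.scorable
    assert (sc.da, sc.db, sc.ma, sc.mb) == (1, 1, 1, 1)
    assert sc.assignments == {da: "Da", db: "Db", ma: "Ma", mb: "Mb"}
    assert sc.unassigned == set()
    # per-chromosome table row sums match the scalar counts
    assert sc.per_chromosome.to_numpy().sum() == 4
    assert sc.per_chromosome.loc["chrA", "Da"] == 1


def test_unscorable_division_reported_not_zero(toy_lineage):
    lineage, _ = toy_lineage
    sc = assign_segregant_groups(filter_to_shared(lineage), 2)
    assert not sc.scorable           # needs sublineages up to 5
    assert sc.per_chromosome is None


def test_count_arithmetic():
    sc = SegregantCounts(division=1, scorable=True, da=10, db=20, ma=30, mb=40)
    assert full_error_count(sc) == 100
    assert mismatch_counts(sc) == (30, 70)
    zero = SegregantCounts(division=1, scorable=True)
    assert full_error_count(zero) == 0
    assert mismatch_counts(zero) == (0, 0)


def test_round_trip_labels_exact(small_lineage, small_called):
    """Noise-free synthetic pedigree: every scorable division's assignments
    equal the generator's ground-truth labels, with nothing unassigned."""
    _, truth = small_lineage
    counts, _ = small_called
    truth_map = truth.variant_truth()
    scored = 0
    for sc in counts:
        if not sc.scorable:
            continue
        assert sc.unassigned == set()
        for variant, group in sc.assignments.items():
            assert truth_map[variant] == (group, sc.division)
            scored += 1
        expected = truth.expected_counts(sc.division)
        assert (sc.da, sc.db, sc.ma, sc.mb) == tuple(expected.values())
    assert scored > 500


def test_round_trip_dm_matches_truth(small_lineage, small_called):
    _, truth = small_lineage
    counts, _ = small_called
    for sc in counts:
        if sc.scorable:
            exp = truth.expected_counts(sc.division)
            assert sc.dm == exp["Da"] + exp["Db"]
            assert sc.mm == exp["Ma"] + exp["Mb"]


def test_conservation_with_unassigned(small_lineage, small_called):
    """|Da|+|Db|+|Ma|+|Mb|+|unassigned| covers every variant implicating a
    scorable division (on clean data the residue is empty)."""
    _, truth = small_lineage
    counts, _ = small_called
    n_labeled = sum(len(sc.assignments) + len(sc.unassigned)
                    for sc in counts if sc.scorable)
    n_truth = sum(1 for (_, d) in truth.variant_truth().values()
                  if 1 <= d <= truth.n_divisions - 3)
    assert n_labeled == n_truth


def test_clean_lineage_no_flags(small_lineage):
    lineage, _ = small_lineage
    assert detect_assignment_errors(lineage) == []


def test_censoring_monotonicity(small_lineage):
    lineage, _ = small_lineage
    base = len(detect_assignment_errors(lineage))
    for error_type in ("Dn1_for_GDn1", "GDn1_GDn2_swap", "GGDn1_GGDn2_swap"):
        bad = ml.inject_assignment_error(lineage, 4, error_type)
        assert len(detect_assignment_errors(bad)) >= base


def test_censored_divisions_not_scored(small_lineage):
    lineage, _ = small_lineage
    bad = ml.inject_assignment_error(lineage, 4, "Dn1_for_GDn1")
    counts, flags = ml.call_lineage(bad)
    assert flags
    censored = set()
    for f in flags:
        censored.update(f.suggested_censor)
    for sc in counts:
        if sc.division in censored:
            assert not sc.scorable


def test_classify_segregation_classes(toy_chromset):
    table = pd.DataFrame(
        {"Da": [5, 3, 0], "Db": [0, 3, 0], "Ma": [0, 0, 0], "Mb": [0, 0, 0]},
        index=["chr1", "chr2", "chr3"],
    )
    sc = SegregantCounts(division=1, scorable=True, per_chromosome=table)
    tally = classify_segregation(sc, "Da/Db")
    assert (tally.none, tally.partial, tally.all) == (0, 1, 1)
    assert tally.fractions == [1.0, 0.5]     # zero-total chromosome excluded
    with pytest.raises(ValueError):
        classify_segregation(sc, "Dm/Mm")


def test_tally_accumulates(small_called):
    counts, _ = small_called
    t_da = tally_segregation(counts, "Da/Db")
    t_ma = tally_segregation(counts, "Ma/Mb")
    combined = t_da + t_ma
    assert combined.total == t_da.total + t_ma.total
    assert combined.total > 0
    assert len(combined.fractions) == combined.total


def test_lineage_table_validation(toy_chromset):
    full = {"chrA": [(0, 100)]}
    with pytest.raises(ValueError, match="consecutively"):
        LineageTable([_colony(f"a{p}", 2, p, [], full)
                      for p in ("D", "GD1", "GD2", "GGD")], toy_chromset)
    with pytest.raises(ValueError, match="missing"):
        LineageTable([_colony("a", 1, "D", [], full)], toy_chromset)
    with pytest.raises(ValueError, match="unknown chromosome"):
        LineageTable(
            [_colony(f"x{p}", 1, p, [("chrZ", 1, "C", "T")], full)
             for p in ("D", "GD1", "GD2", "GGD")], toy_chromset)


def test_flag_fields(small_lineage):
    lineage, _ = small_lineage
    bad = ml.inject_assignment_error(lineage, 4, "Dn1_for_GDn1")
    flags = detect_assignment_errors(bad)
    assert all(isinstance(f, AssignmentErrorFlag) for f in flags)
    sig = {f.signature for f in flags}
    assert "ma_zero_recurring_db" in sig
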