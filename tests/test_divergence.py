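"""Column classification, relative-rate test, domains and deletions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plkevol.divergence import (DomainMap, RelativeRateModel,
                                ThreeTaxonAlignment, classify_columns,
                                domain_counts, find_deletions,
                                tajima_1d_test)
from plkevol.simulate import ThreeTaxonConfig, simulate_three_taxon_proteins

AA = "ACDEFGHIKLMNPQRSTVWY"


def parsimony_oracle(a: str, b: str, o: str) -> str:
    """Exhaustive small-parsimony over all 20 ancestral states at the
    internal node of the unrooted 3-taxon tree; returns the column state
    implied by the minimum-change assignments (ambiguous when the optimal
    assignments disagree on branch placement)."""
    if "-" in (a, b, o):
        return "gapped"
    best = min(sum(s != x for x in (a, b, o)) for s in AA)
    placements = set()
    for s in AA:
        cost = sum(s != x for x in (a, b, o))
        if cost == best:
            placements.add((s != a, s != b, s != o))
    if best == 0:
        return "identical"
    if len(placements) > 1:
        return "ambiguous"
    ca, cb, co = placements.pop()
    if (ca, cb, co) == (True, False, False):
        return "subst_A"
    if (ca, cb, co) == (False, True, False):
        return "subst_B"
    if (ca, cb, co) == (False, False, True):
        return "subst_O"
    return "ambiguous"


class TestClassifyColumns:
    @pytest.mark.parametrize(
        "col, expected",
        [(("V", "L", "L"), "subst_A"),
         (("K", "K", "K"), "identical"),
         (("L", "V", "L"), "subst_B"),
         (("L", "L", "V"), "subst_O"),
         (("K", "R", "E"), "ambiguous"),
         (("K", "-", "K"), "gapped")],
    )
    def test_single_columns(self, col, expected):
        aln = classify_columns(ThreeTaxonAlignment(*col))
        assert aln.column_states == [expected]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ThreeTaxonAlignment("MK", "MKL", "MKL")

    def test_illegal_characters_name_position(self):
        with pytest.raises(ValueError, match="position"):
            ThreeTaxonAlignment("M1", "MK", "MK")

    @given(st.tuples(st.sampled_from(AA + "-"), st.sampled_from(AA + "-"),
                     st.sampled_from(AA + "-")))
    @settings(max_examples=500, derandomize=True)
    def test_agrees_with_parsimony_oracle(self, col):
        a, b, o = col
        aln = classify_columns(ThreeTaxonAlignment(a, b, o))
        assert aln.column_states[0] == parsimony_oracle(a, b, o)

    def test_states_partition_alignment(self):
        aln = simulate_three_taxon_proteins(
            ThreeTaxonConfig(length=200, m1=20, m2=5, m_out=10, seed=3)
        )
        classify_columns(aln)
        assert len(aln.column_states) == len(aln)

    def test_recovers_planted_counts_exactly(self):
        aln = simulate_three_taxon_proteins(
            ThreeTaxonConfig(length=567, m1=80, m2=3, seed=1)
        )
        states = classify_columns(aln).column_states
        assert states.count("subst_A") == 80
        assert states.count("subst_B") == 3
        assert aln.n_alignable == 567


class TestTajimaTest:
    def test_headline_counts(self):
        # 80 vs 3 lineage substitutions: the canonical strongly unequal case
        res = tajima_1d_test(80, 3)
        assert round(res.chi2, 2) == 71.43
        assert res.df == 1
        assert res.p < 0.00001

    def test_equal_counts_null(self):
        res = tajima_1d_test(5, 5)
        assert res.chi2 == 0.0 and res.p == 1.0
        res0 = tajima_1d_test(0, 0)
        assert res0.chi2 == 0.0 and res0.p == 1.0

    def test_hand_value(self):
        assert tajima_1d_test(7, 2).chi2 == pytest.approx(25 / 9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tajima_1d_test(-1, 2)

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=200, derandomize=True)
    def test_swap_symmetry(self, m1, m2):
        r12, r21 = tajima_1d_test(m1, m2), tajima_1d_test(m2, m1)
        assert r12.chi2 == pytest.approx(r21.chi2)
        assert (r12.m1, r12.m2) == (r21.m2, r21.m1)


class TestDomainCounts:
    def test_whole_alignment_domain_equals_global(self):
        aln = simulate_three_taxon_proteins(
            ThreeTaxonConfig(length=120, m1=12, m2=4, seed=7)
        )
        classify_columns(aln)
        dm = DomainMap({"all": [(0, 120)]})
        table = domain_counts(aln, dm)
        assert (table.loc["all", ["m1", "m2"]]
                == table.loc["whole", ["m1", "m2"]]).all()

    def test_disjoint_domains_are_additive(self):
        aln = simulate_three_taxon_proteins(
            ThreeTaxonConfig(length=120, m1=12, m2=4, seed=7)
        )
        classify_columns(aln)
        dm = DomainMap({"left": [(0, 50)], "right": [(50, 120)]})
        t = domain_counts(aln, dm)
        assert t.loc["left", "m1"] + t.loc["right", "m1"] == t.loc["whole", "m1"]
        assert t.loc["left", "m2"] + t.loc["right", "m2"] == t.loc["whole", "m2"]

    def test_substitutions_confined_to_one_domain(self):
        # all A-lineage changes inside the "linker" columns
        a = "MKLV" + "WWWW" + "PQRS"
        b = "MKLV" + "AAAA" + "PQRS"
        o = "MKLV" + "AAAA" + "PQRS"
        aln = classify_columns(ThreeTaxonAlignment(a, b, o))
        dm = DomainMap({"kinase": [(0, 4)], "linker": [(4, 8)],
                        "PBD": [(8, 12)]})
        t = domain_counts(aln, dm)
        assert t.loc["kinase", "m1"] == 0
        assert t.loc["linker", "m1"] == 4
        assert t.loc["linker", "m1"] == t.loc["whole", "m1"]

    def test_out_of_range_map_rejected(self):
        aln = ThreeTaxonAlignment("MK", "MK", "MK")
        with pytest.raises(ValueError, match="exceeds"):
            domain_counts(classify_columns(aln), DomainMap({"x": [(0, 5)]}))

    def test_structural_constraints(self):
        with pytest.raises(ValueError, match="within PBD"):
            DomainMap({"PBD": [(10, 20)], "PB1": [(0, 5)]})
        with pytest.raises(ValueError, match="overlaps"):
            DomainMap({"kinase": [(0, 10)], "linker": [(5, 15)]})


class TestDeletions:
    def test_single_lineage_deletion(self):
        aln = ThreeTaxonAlignment("MK--V", "MKLQV", "MKLQV")
        dels = find_deletions(aln)
        assert len(dels) == 1
        assert (dels[0].lineage, dels[0].start, dels[0].length) == ("A", 2, 2)

    def test_no_gaps_no_deletions(self):
        assert find_deletions(ThreeTaxonAlignment("MKV", "MKV", "MKV")) == []

    def test_shared_deletion_on_internal_branch(self):
        aln = ThreeTaxonAlignment("MK-V", "MK-V", "MKLV")
        dels = find_deletions(aln)
        assert [d.lineage for d in dels] == ["shared"]

    def test_outgroup_gap_not_reported(self):
        aln = ThreeTaxonAlignment("MKLV", "MKLV", "MK-V")
        assert find_deletions(aln) == []


class TestRelativeRateModel:
    def test_full_fit_summary(self):
        aln = simulate_three_taxon_proteins(
            ThreeTaxonConfig(length=567, m1=80, m2=3, seed=1)
        )
        res = RelativeRateModel(aln).fit()
        assert res.overall.m1 == 80 and res.overall.m2 == 3
        assert round(res.overall.chi2, 2) == 71.43
        assert round(100 * res.divergence_fraction) == 14
        assert "71.43" in res.summary()

    def test_swapping_ingroups_swaps_counts(self):
        aln = simulate_three_taxon_proteins(
            ThreeTaxonConfig(length=200, m1=20, m2=5, seed=2)
        )
        swapped = ThreeTaxonAlignment(aln.seq_B, aln.seq_A, aln.seq_O)
        r1 = RelativeRateModel(aln).fit().overall
        r2 = RelativeRateModel(swapped).fit().overall
        assert (r1.m1, r1.m2) == (r2.m2, r2.m1)
        assert r1.chi2 == pytest.approx(r2.chi2)
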