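"""MK site classification, table assembly and the exact test."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plkevol.mk import (CODON_TABLE, MKModel, MKTable, SpeciesAlignment,
                        build_mk_table, classify_codon_sites,
                        fisher_exact_2x2, g_test_2x2, mk_exact_test)
from plkevol.simulate import MKConfig, simulate_mk_alignments


def fisher_oracle(a, b, c, d) -> float:
    """Brute-force hypergeometric enumeration with fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = [math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
           for k in range(lo, hi + 1)]
    p_obs = pmf[a - lo]
    return min(sum(p for p in pmf if p <= p_obs * (1 + 1e-7)), 1.0)


def pathway_oracle(c_from, c_to):
    """(syn, nonsyn) totals averaged over all stop-free minimal pathways."""
    diff = [i for i in range(3) if c_from[i] != c_to[i]]
    syn = non = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur, steps, ok = c_from, [], True
        for pos in order:
            nxt = cur[:pos] + c_to[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*" and nxt != c_to:
                ok = False
                break
            steps.append(CODON_TABLE[cur] == CODON_TABLE[nxt])
            cur = nxt
        if ok:
            n_paths += 1
            syn += sum(steps)
            non += len(steps) - sum(steps)
    return syn / n_paths, non / n_paths


class TestClassifyCodonSites:
    def test_fixed_synonymous_single_codon(self):
        sp1 = SpeciesAlignment("sp1", ["AAA", "AAA"])
        sp2 = SpeciesAlignment("sp2", ["AAG", "AAG"])
        records = classify_codon_sites(sp1, sp2)
        assert len(records) == 1
        r = records[0]
        assert r.kind == "fixed" and r.syn == 1.0 and r.nonsyn == 0.0

    def test_polymorphic_nonsynonymous(self):
        sp1 = SpeciesAlignment("sp1", ["AAA", "AAA", "AGA"])
        sp2 = SpeciesAlignment("sp2", ["AAA"])
        records = classify_codon_sites(sp1, sp2)
        assert len(records) == 1
        r = records[0]
        assert r.kind == "polymorphic_sp1"
        assert (r.syn, r.nonsyn) == (0.0, 1.0)  # Lys -> Arg

    def test_triple_fixed_difference_pathway_fractions(self):
        # TTT vs GGG: 3 fixed records, fractional effects from 6 pathways
        sp1 = SpeciesAlignment("sp1", ["TTT", "TTT"])
        sp2 = SpeciesAlignment("sp2", ["GGG"])
        records = classify_codon_sites(sp1, sp2)
        assert len(records) == 3
        syn, non = pathway_oracle("TTT", "GGG")
        assert sum(r.syn for r in records) == pytest.approx(syn)
        assert sum(r.nonsyn for r in records) == pytest.approx(non)
        assert (syn, non) == (0.5, 2.5)  # frozen from the oracle

    def test_polymorphic_in_one_species_not_fixed(self):
        # sp1 segregates A/G at pos 3; sp2 monomorphic G: no fixed record
        sp1 = SpeciesAlignment("sp1", ["AAA", "AAG"])
        sp2 = SpeciesAlignment("sp2", ["AAG"])
        kinds = {r.kind for r in classify_codon_sites(sp1, sp2)}
        assert kinds == {"polymorphic_sp1"}

    def test_gap_and_n_columns_excluded(self):
        sp1 = SpeciesAlignment("sp1", ["AA-AAA", "AAAAAA"])
        sp2 = SpeciesAlignment("sp2", ["AANGGN"])
        records = classify_codon_sites(sp1, sp2)
        # first codon gapped in sp1 and N in sp2, second has N in sp2
        assert records == []

    def test_stop_codon_column_warned_and_excluded(self):
        sp1 = SpeciesAlignment("sp1", ["TAAAAA"])
        sp2 = SpeciesAlignment("sp2", ["TAAAAG"])
        with pytest.warns(RuntimeWarning, match="stop"):
            records = classify_codon_sites(sp1, sp2)
        assert all(r.codon != 0 for r in records)

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            SpeciesAlignment("sp1", ["AAAA"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            classify_codon_sites(SpeciesAlignment("a", ["AAA"]),
                                 SpeciesAlignment("b", ["AAAAAA"]))

    def test_monomorphic_identical_codon_is_inert(self):
        sp1a = SpeciesAlignment("sp1", ["AAA", "AGA"])
        sp2a = SpeciesAlignment("sp2", ["AAA"])
        sp1b = SpeciesAlignment("sp1", ["AAAGGT", "AGAGGT"])
        sp2b = SpeciesAlignment("sp2", ["AAAGGT"])
        t_a = build_mk_table(classify_codon_sites(sp1a, sp2a))
        t_b = build_mk_table(classify_codon_sites(sp1b, sp2b))
        assert (t_a.Dn, t_a.Ds, t_a.Pn, t_a.Ps) == (t_b.Dn, t_b.Ds, t_b.Pn,
                                                    t_b.Ps)


class TestBuildTable:
    def test_single_fixed_synonymous(self):
        sp1 = SpeciesAlignment("sp1", ["AAA", "AAA"])
        sp2 = SpeciesAlignment("sp2", ["AAG"])
        t = build_mk_table(classify_codon_sites(sp1, sp2))
        assert (t.Dn, t.Ds, t.Pn, t.Ps) == (0, 1, 0, 0)

    def test_ni_alpha_arithmetic(self):
        t = MKTable(Dn=40, Ds=20, Pn=10, Ps=20)
        assert t.NI == pytest.approx(0.25)
        assert t.alpha == pytest.approx(0.75)

    def test_zero_denominator_flags_ni(self):
        t = MKTable(Dn=5, Ds=0, Pn=1, Ps=2)
        assert math.isnan(t.NI) and math.isnan(t.alpha)

    def test_empty_records_zero_table(self):
        t = build_mk_table([])
        assert (t.Dn, t.Ds, t.Pn, t.Ps) == (0, 0, 0, 0)
        assert math.isnan(t.NI)

    def test_fractional_rounding_policies(self):
        sp1 = SpeciesAlignment("sp1", ["TTT", "TTT"])
        sp2 = SpeciesAlignment("sp2", ["GGG"])
        records = classify_codon_sites(sp1, sp2)
        assert build_mk_table(records, rounding="round").Dn == 3  # 2.5 -> 3
        assert build_mk_table(records, rounding="floor").Dn == 2
        keep = build_mk_table(records, rounding="keep")
        assert keep.Dn == pytest.approx(2.5)
        with pytest.raises(ValueError, match="rounding"):
            mk_exact_test(keep)
        assert 0.0 <= keep.p_value <= 1.0  # G-test path


class TestExactTest:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_diagonal_table_oracle_value(self):
        # frozen from the enumeration oracle: margins (5,5),(5,5)
        assert fisher_exact_2x2(0, 5, 5, 0) == pytest.approx(
            0.007936507936507936, abs=1e-12
        )

    def test_headline_style_table(self):
        assert fisher_exact_2x2(40, 20, 10, 20) == pytest.approx(
            fisher_oracle(40, 20, 10, 20), abs=1e-12
        )

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25))
    @settings(max_examples=300, derandomize=True)
    def test_matches_enumeration_and_transpose_invariant(self, a, b, c, d):
        p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
        assert p == pytest.approx(fisher_exact_2x2(a, c, b, d), abs=1e-12)

    def test_matches_scipy_on_sampled_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact([[a, b], [c, d]])[1], rel=1e-9
            )

    def test_rejects_fractional_cells(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(1.5, 1, 1, 1)


class TestMKModel:
    def test_recovers_planted_counts_exactly(self):
        sp1, sp2 = simulate_mk_alignments(
            MKConfig(Pn=10, Ps=20, Dn=40, Ds=20, seed=7)
        )
        res = MKModel(sp1, sp2, focal="sp1").fit()
        t = res.table
        assert (t.Dn, t.Ds, t.Pn, t.Ps) == (40, 20, 10, 20)
        assert t.NI == pytest.approx(0.25)

    def test_focal_species_switch(self):
        sp1, sp2 = simulate_mk_alignments(
            MKConfig(Pn=3, Ps=5, Dn=2, Ds=2, seed=9)
        )
        res = MKModel(sp1, sp2, focal="sp2").fit()
        # all planted polymorphism is within sp1; sp2 focal sees none
        assert (res.table.Pn, res.table.Ps) == (0, 0)
        assert (res.table_other_focal.Pn, res.table_other_focal.Ps) == (3, 5)

    def test_multi_hit_produces_fractional_counts(self):
        sp1, sp2 = simulate_mk_alignments(
            MKConfig(Pn=0, Ps=0, Dn=0, Ds=0, multi_hit=1, n_codons=10, seed=2)
        )
        res = MKModel(sp1, sp2).fit(rounding="keep")
        syn, non = pathway_oracle("TTT", "GGG")
        assert res.table.Dn == pytest.approx(non)
        assert res.table.Ds == pytest.approx(syn)
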