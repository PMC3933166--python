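"""Alignment, identity, consensus, profiles, codon usage, divergence."""

import numpy as np
import pytest

from spidroin.alignment import AlignmentError, MultipleAlignment, align, pairwise_align
from spidroin.homogeneity import (GAP_MISMATCH, PAIRWISE_DELETION,
                                  UndefinedIdentityError, codon_usage, composition,
                                  consensus, identity_matrix, pairwise_identity,
                                  positional_codon_table, positional_profile,
                                  region_divergence)
from spidroin.seqio import Interval, SeqRecord
from spidroin.synthetic_data import SimParams, evolve_loci, simulate_gene

from conftest import random_nt


def nw_oracle(a, b, match=1, mismatch=-1, gap=-2):
    F = [[j * gap for j in range(len(b) + 1)]]
    for i in range(1, len(a) + 1):
        F.append([i * gap] + [0] * len(b))
        for j in range(1, len(b) + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            F[i][j] = max(F[i - 1][j - 1] + sub, F[i - 1][j] + gap, F[i][j - 1] + gap)
    return F[-1][-1]


class TestAlign:
    def test_identical_sequences_align_gapless(self):
        aln = align([SeqRecord(id="a", residues="ACGTACGT"),
                     SeqRecord(id="b", residues="ACGTACGT")])
        assert aln.rows == ["ACGTACGT", "ACGTACGT"]

    def test_one_gap_alignment_matches_dp_oracle_score(self):
        _, _, score = pairwise_align("ACGTACGT", "ACGACGT")
        assert score == nw_oracle("ACGTACGT", "ACGACGT") == 5.0

    def test_random_pairs_match_dp_oracle(self, rng):
        for _ in range(100):
            a = random_nt(rng, int(rng.integers(1, 11)))
            b = random_nt(rng, int(rng.integers(1, 11)))
            assert pairwise_align(a, b)[2] == nw_oracle(a, b)

    def test_codon_mode_gaps_on_codon_boundaries(self):
        aln = align([SeqRecord(id="a", residues="ATGGCT"),
                     SeqRecord(id="b", residues="ATGGATGCT")], codon=True)
        row = aln.row("a")
        assert row.replace("-", "") == "ATGGCT"
        assert aln.n_cols == 9
        gap_start = row.index("-")
        assert gap_start % 3 == 0 and row[gap_start:gap_start + 3] == "---"

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(AlignmentError, match="mixed"):
            align([SeqRecord(id="a", residues="ACGT", alphabet="nt"),
                   SeqRecord(id="b", residues="MASW", alphabet="aa")])

    def test_multi_sequence_alignment_is_consistent(self, rng):
        base = random_nt(rng, 60)
        variants = [base, base[:20] + base[23:], base[:40] + "TTT" + base[40:]]
        aln = align([SeqRecord(id=f"s{i}", residues=v) for i, v in enumerate(variants)])
        for i, v in enumerate(variants):
            assert aln.row(f"s{i}").replace("-", "") == v


class TestPairwiseIdentity:
    @pytest.mark.parametrize("a,b,policy,expected", [
        ("ACGT", "ACGT", PAIRWISE_DELETION, 100.0),
        ("ACGT", "ACGA", PAIRWISE_DELETION, 75.0),
        ("AC-T", "ACGT", PAIRWISE_DELETION, 100.0),
        ("AC-T", "ACGT", GAP_MISMATCH, 75.0),
        ("ACNT", "ACNT", PAIRWISE_DELETION, 75.0),  # N never matches, even N-N
    ])
    def test_policies(self, a, b, policy, expected):
        assert pairwise_identity(a, b, policy) == expected

    def test_all_gap_overlap_is_undefined(self):
        with pytest.raises(UndefinedIdentityError):
            pairwise_identity("A--", "-GG")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACG", "AC")


class TestIdentityMatrix:
    def test_identical_rows(self):
        aln = MultipleAlignment(ids=list("abc"), rows=["ACGT"] * 3)
        m = identity_matrix(aln)
        assert m.mean_offdiag() == 100.0
        assert np.allclose(np.diag(m.values), 100.0)

    def test_row_reordering_invariance(self, rng):
        rows = [random_nt(rng, 40) for _ in range(4)]
        ids = list("abcd")
        m1 = identity_matrix(MultipleAlignment(ids=ids, rows=rows))
        perm = [2, 0, 3, 1]
        m2 = identity_matrix(MultipleAlignment(ids=[ids[i] for i in perm],
                                               rows=[rows[i] for i in perm]))
        assert m1.mean_offdiag() == pytest.approx(m2.mean_offdiag())
        for x in ids:
            assert m1.per_row_mean(x) == pytest.approx(m2.per_row_mean(x))


class TestConsensus:
    def test_identical_rows_return_that_sequence(self):
        aln = MultipleAlignment(ids=list("ab"), rows=["ACGT", "ACGT"])
        assert consensus(aln).record.residues == "ACGT"

    def test_majority_column(self):
        rows = ["G"] * 11 + ["A"] * 9
        aln = MultipleAlignment(ids=[f"r{i}" for i in range(20)], rows=rows)
        assert consensus(aln).record.residues == "G"

    def test_tie_flagged_and_broken_alphabetically(self):
        aln = MultipleAlignment(ids=list("ab"), rows=["ACGT", "ACGA"])
        res = consensus(aln)
        assert res.record.residues == "ACGA"  # T vs A tie -> A
        assert res.tie_columns == [3]

    def test_gap_majority_column_dropped(self):
        aln = MultipleAlignment(ids=list("abc"), rows=["AC-T", "AC-T", "ACGT"])
        res = consensus(aln)
        assert res.record.residues == "ACT"
        assert res.dropped_columns == [2]

    def test_consensus_is_columnwise_optimal(self, rng):
        """Majority choice matches >= any row at every kept column."""
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(7)]
        aln = MultipleAlignment(ids=[f"r{i}" for i in range(7)], rows=rows)
        cons = consensus(aln).record.residues
        for j, c in enumerate(cons):
            col = [r[j] for r in rows]
            assert col.count(c) == max(col.count(x) for x in set(col))


class TestPositionalProfile:
    def test_identical_sequences_give_unit_profile(self):
        seqs = [SeqRecord(id=i, residues="MASGA", alphabet="aa") for i in "abc"]
        prof = positional_profile(seqs, "a", domains=[(Interval(0, 5), "all")])
        assert np.all(prof.fractions == 1.0)
        assert prof.region_mean("all") == 100.0

    def test_conserved_block_in_mutated_background(self, rng):
        base = random_nt(rng, 200)
        block = Interval(80, 120)
        others = []
        for k in range(5):
            s = list(base)
            for pos in range(200):
                if block.start <= pos < block.end:
                    continue
                if rng.random() < 0.2:
                    s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1 + rng.integers(0, 3)) % 4]
            others.append(SeqRecord(id=f"m{k}", residues="".join(s)))
        seqs = [SeqRecord(id="ref", residues=base)] + others
        prof = positional_profile(seqs, "ref",
                                  domains=[(block, "block"),
                                           (Interval(0, 80), "background")])
        assert prof.region_mean("block") == 100.0
        assert abs(prof.region_mean("background") - 80.0) < 6.0  # binomial error

    def test_domain_outside_alignment_rejected(self):
        seqs = [SeqRecord(id=i, residues="MASGA", alphabet="aa") for i in "ab"]
        with pytest.raises(ValueError):
            positional_profile(seqs, "a", domains=[(Interval(0, 9), "too_long")])


class TestCompositionAndCodonUsage:
    def test_toy_composition(self):
        comp = composition(SeqRecord(id="p", residues="AAAG", alphabet="aa"))
        assert comp == {"A": 75.0, "G": 25.0}

    def test_composition_normalizes(self, rng):
        residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
        comp = composition(SeqRecord(id="p", residues=residues, alphabet="aa"))
        assert sum(comp.values()) == pytest.approx(100.0, abs=1e-6)

    def test_alanine_codon_fractions_and_gcw(self):
        table = codon_usage(SeqRecord(id="c", residues="GCAGCTGCCGCG"))
        assert table.per_aa["A"] == pytest.approx(
            {"GCA": 0.25, "GCT": 0.25, "GCC": 0.25, "GCG": 0.25})
        assert table.gcw_fraction() == pytest.approx(0.50)

    def test_gcw_undefined_without_alanine(self):
        assert codon_usage(SeqRecord(id="c", residues="ATGTTTTAA")).gcw_fraction() is None

    def test_codon_fractions_normalize_per_amino_acid(self, small_sim):
        gene, _ = small_sim
        table = codon_usage(gene)
        for aa, codons in table.per_aa.items():
            assert sum(codons.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(table.composition.values()) == pytest.approx(100.0, abs=1e-6)

    def test_internal_stop_warns(self):
        with pytest.warns(UserWarning, match="internal stop"):
            codon_usage(SeqRecord(id="c", residues="ATGTAAGCT"))


class TestPositionalCodonTable:
    def test_uniform_and_variable_columns(self):
        aln = MultipleAlignment(ids=list("ab"), rows=["ATGGCT", "ATGGCA"])
        pct = positional_codon_table(aln)
        assert list(pct.table[0]) == ["ATG", "ATG"]
        assert pct.uniform.tolist() == [True, False]
        assert list(pct.codon_at(4)) == ["GCT", "GCA"]

    def test_frame_breaking_gap_rejected(self):
        aln = MultipleAlignment(ids=list("ab"), rows=["ATG-CT", "ATGGCA"])
        with pytest.raises(AlignmentError, match="frame-breaking"):
            positional_codon_table(aln)


class TestRegionDivergence:
    def test_identical_region_has_zero_distance(self):
        groups = {"r": MultipleAlignment(ids=list("ab"), rows=["ACGT", "ACGT"])}
        assert region_divergence(groups)["r"] == 0.0

    def test_homogenized_repeats_less_divergent_than_terminals(self):
        """Terminals mutate 5x faster and never undergo conversion, so the
        repeat region must be the least divergent in nearly every run."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            p = SimParams(seed=seed + 100, repeat_len_nt=300, n_repeats=6,
                          n_term_len=300, c_term_len=300, n_loci=2, ploidy=2,
                          mutation_rate=2e-4, terminal_rate_multiplier=5.0,
                          conversion_rate=2.0, n_generations=150)
            gene, truth = simulate_gene(p)
            evolve_loci(gene, truth)
            groups = {}
            for region, iv in (("N", truth.model.n_term), ("C", truth.model.c_term),
                               ("repeat", truth.model.repeats[2])):
                rows = [a.residues[iv.start:iv.end] for a in truth.alleles]
                groups[region] = MultipleAlignment(
                    ids=[a.id for a in truth.alleles], rows=rows)
            d = region_divergence(groups)
            wins += d["repeat"] < d["N"] and d["repeat"] < d["C"]
        assert wins >= 9
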