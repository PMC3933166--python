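"""Singleton masking, unsupported-clone discard, clustering, locus counting."""

import pytest

from spidroin.alignment import MultipleAlignment
from spidroin.seqio import SeqRecord
from spidroin.synthetic_data import SimParams, evolve_loci, simulate_clones, simulate_gene
from spidroin.variant_diagnosis import (CloneSet, DiagnosisError, cluster_variants,
                                        diagnose, discard_unsupported,
                                        mask_singletons, min_loci)


def _aln(rows, ids=None):
    ids = ids or [f"c{i}" for i in range(len(rows))]
    return MultipleAlignment(ids=ids, rows=rows, alphabet="nt")


class TestMaskSingletons:
    def test_private_snp_masked_to_majority(self):
        rows = ["ACGT", "ACGT", "ACGT", "ACGT", "ACGG"]
        masked, report = mask_singletons(_aln(rows))
        assert masked.rows == ["ACGT"] * 5
        assert len(report) == 1
        assert (report.cells[0].clone_id, report.cells[0].column,
                report.cells[0].original) == ("c4", 3, "G")

    def test_shared_snp_protected(self):
        rows = ["ACGT", "ACGT", "ACGT", "ACGG", "ACGG"]
        masked, report = mask_singletons(_aln(rows))
        assert masked.rows == rows
        assert len(report) == 0

    def test_two_clone_set_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="2-clone"):
            masked, report = mask_singletons(_aln(["ACGT", "ACGA"]))
        assert report.skipped and masked.rows == ["ACGT", "ACGA"]

    def test_masking_never_touches_shared_residues(self, rng):
        """Property: any residue carried by >= 2 clones survives masking."""
        for _ in range(25):
            n, L = int(rng.integers(3, 8)), 30
            rows = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
                    for _ in range(n)]
            masked, _ = mask_singletons(_aln(rows))
            for j in range(L):
                col = [r[j] for r in rows]
                for i, r in enumerate(masked.rows):
                    if col.count(col[i]) >= 2:
                        assert r[j] == col[i]

    def test_zero_error_clones_produce_empty_report(self):
        p = SimParams(seed=2, repeat_len_nt=90, n_repeats=3, n_term_len=150,
                      c_term_len=150, n_loci=2, ploidy=2, mutation_rate=5e-4,
                      conversion_rate=0.0, n_generations=40, pcr_error_rate=0.0,
                      clones_per_template=5)
        gene, truth = simulate_gene(p)
        evolve_loci(gene, truth)
        cs = simulate_clones(truth.templates["N"], truth, "N")
        _, report = mask_singletons(_aln([c.residues for c in cs.clones],
                                         ids=[c.id for c in cs.clones]))
        assert len(report) == 0


class TestDiscardUnsupported:
    def test_two_identical_pairs_all_retained(self):
        retained, discards = discard_unsupported(_aln(["ACGT", "ACGT", "AGGT", "AGGT"]))
        assert retained.n_rows == 4 and discards == []

    def test_chimera_discarded(self):
        """A recombinant combining the SNPs of two templates has a unique
        polymorphism pattern and must be discarded."""
        t1, t2 = "AAACGTACGT", "AAACCTACAT"  # differ at columns 4 and 8
        chimera = t1[:6] + t2[6:]            # t1's col 4 with t2's col 8
        retained, discards = discard_unsupported(
            _aln([t1, t1, t2, t2, chimera], ids=["a", "b", "c", "d", "chi"]))
        assert discards == ["chi"]
        assert retained.n_rows == 4
        # oracle: enumerate patterns at polymorphic columns
        patterns = {r[4] + r[8] for r in [t1, t2]}
        assert chimera[4] + chimera[8] not in patterns

    def test_lone_unique_clone_discarded(self):
        retained, discards = discard_unsupported(_aln(["ACGT", "ACGT", "ATTT"]))
        assert retained.n_rows == 2 and discards == ["c2"]

    def test_all_unique_clones_all_discarded(self):
        with pytest.warns(UserWarning, match="all clones discarded"):
            retained, discards = discard_unsupported(_aln(["AAAA", "CCCC", "GGGG"]))
        assert retained.n_rows == 0 and len(discards) == 3


class TestClusterVariants:
    def test_two_pairs_two_variants(self):
        a = "A" * 20
        b = "A" * 10 + "G" * 10  # 50% identity to a
        calls = cluster_variants(_aln([a, a, b, b]))
        assert len(calls) == 2
        assert sorted(c.consensus.residues for c in calls) == sorted([a, b])
        for c in calls:
            assert len(c.supporting_clones) == 2
            assert c.within_identity_pct == 100.0

    def test_singleton_cluster_emits_no_variant(self):
        a, b = "A" * 20, "A" * 10 + "G" * 10
        calls = cluster_variants(_aln([a, a, b]))
        assert len(calls) == 1
        assert calls[0].consensus.residues == a

    def test_threshold_validation(self):
        with pytest.raises(DiagnosisError):
            cluster_variants(_aln(["AA", "AA"]), threshold_pct=40.0)


class TestMinLoci:
    @pytest.mark.parametrize("n,expected", [(7, 4), (2, 1), (6, 3), (0, 0), (1, 1)])
    def test_diploid_ceiling(self, n, expected):
        assert min_loci(n, ploidy=2) == expected

    def test_ploidy_validation(self):
        with pytest.raises(DiagnosisError):
            min_loci(3, ploidy=0)


class TestDiagnose:
    def test_identical_clones_one_variant(self):
        cs = CloneSet(individual="i1", species="sp", region="C",
                      clones=[SeqRecord(id=f"c{i}", residues="ACGTACGT")
                              for i in range(4)])
        res = diagnose(cs)
        assert len(res.variants) == 1 and res.min_loci == 1

    def test_all_singleton_clones_yield_no_variants(self):
        cs = CloneSet(individual="i1", species="sp", region="C",
                      clones=[SeqRecord(id="c0", residues="A" * 12),
                              SeqRecord(id="c1", residues="C" * 12),
                              SeqRecord(id="c2", residues="G" * 12)])
        with pytest.warns(UserWarning):
            res = diagnose(cs)
        assert res.variants == [] and res.min_loci == 0

    def test_clone_order_permutation_invariance(self, rng):
        p = SimParams(seed=17, repeat_len_nt=90, n_repeats=3, n_term_len=330,
                      c_term_len=330, n_loci=3, ploidy=2, mutation_rate=2e-4,
                      terminal_rate_multiplier=5.0, conversion_rate=0.0,
                      n_generations=40, pcr_error_rate=5e-4, clones_per_template=6)
        gene, truth = simulate_gene(p)
        evolve_loci(gene, truth)
        cs = simulate_clones(truth.templates["C"], truth, "C")
        res1 = diagnose(cs)
        order = rng.permutation(len(cs.clones))
        shuffled = CloneSet(individual=cs.individual, species=cs.species,
                            region=cs.region, clones=[cs.clones[i] for i in order])
        res2 = diagnose(shuffled)
        assert sorted(v.consensus.residues for v in res1.variants) == \
               sorted(v.consensus.residues for v in res2.variants)
        assert res1.min_loci == res2.min_loci

    def test_multilocus_individual_implies_at_least_four_loci(self):
        """An individual with >= 7 distinct terminal-region templates must
        be diagnosed as carrying at least 4 gene copies."""
        p = SimParams(seed=23, repeat_len_nt=90, n_repeats=3, n_term_len=330,
                      c_term_len=330, n_loci=4, ploidy=2, mutation_rate=5e-4,
                      terminal_rate_multiplier=5.0, conversion_rate=0.0,
                      n_generations=40, pcr_error_rate=5e-4, clones_per_template=6)
        gene, truth = simulate_gene(p)
        evolve_loci(gene, truth)
        assert len(truth.templates["C"]) >= 7
        cs = simulate_clones(truth.templates["C"], truth, "C")
        res = diagnose(cs)
        assert res.min_loci >= 4
        assert res.min_loci <= p.n_loci

    def test_length_variant_amplicons_are_aligned_first(self):
        base = "ATGGCTTCAGGTATTGCAACC" * 3
        # second template: 6-nt deletion plus substitutions pushing the
        # identical-sites fraction below the clustering threshold
        other = list(base[:30] + base[36:])
        for pos in (2, 11, 20, 29, 38, 47, 52):
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        other = "".join(other)
        clones = ([SeqRecord(id=f"a{i}", residues=base) for i in range(3)]
                  + [SeqRecord(id=f"b{i}", residues=other) for i in range(3)])
        res = diagnose(CloneSet(individual="i", species="s", region="C", clones=clones))
        assert {v.consensus.residues for v in res.variants} == {base, other}

    def test_indel_only_variants_merge_under_identical_sites_metric(self):
        """Gapped columns are excluded from the identical-sites count
        (pairwise deletion), so templates differing only by an indel fall
        in one cluster and yield a single consensus variant."""
        base = "ATGGCTTCAGGTATTGCAACC" * 3
        indel = base[:30] + base[36:]
        clones = ([SeqRecord(id=f"a{i}", residues=base) for i in range(3)]
                  + [SeqRecord(id=f"b{i}", residues=indel) for i in range(3)])
        res = diagnose(CloneSet(individual="i", species="s", region="C", clones=clones))
        assert len(res.variants) == 1
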