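"""Period detection and repeat-array segmentation against generator truth."""

import numpy as np
import pytest

from spidroin.repeat_array import (GeneModel, NoTandemStructureError,
                                   SegmentationError, detect_period,
                                   extract_regions, segment_repeats)
from spidroin.seqio import Interval, SeqRecord
from spidroin.synthetic_data import SimParams, evolve_loci, simulate_gene

from conftest import random_nt


def autocorrelation_oracle(seq: str, min_p: int, max_p: int, tol: float = 0.01) -> int:
    """Independent period scan: smallest codon-multiple shift within *tol*
    of the best self-match fraction."""
    best = {}
    for p in range(min_p, max_p + 1, 3):
        matches = sum(1 for i in range(len(seq) - p) if seq[i] == seq[i + p])
        best[p] = matches / (len(seq) - p)
    top = max(best.values())
    return min(p for p, s in best.items() if s >= top - tol)


class TestDetectPeriod:
    def test_exact_tandem(self, rng):
        unit = random_nt(rng, 150)
        rec = SeqRecord(id="t", residues=unit * 12)
        assert detect_period(rec).period_nt == 150

    def test_mutated_tandem_matches_oracle(self, rng):
        unit = random_nt(rng, 300)
        copies = []
        for _ in range(15):
            u = list(unit)
            for pos in rng.choice(300, size=3, replace=False):  # 1% per copy
                u[pos] = "ACGT"[(("ACGT".index(u[pos])) + 1 + rng.integers(0, 3)) % 4]
            copies.append("".join(u))
        seq = "".join(copies)
        det = detect_period(SeqRecord(id="m", residues=seq), min_period=30, max_period=900)
        assert det.period_nt == 300
        assert det.period_nt == autocorrelation_oracle(seq, 30, 900)

    def test_random_sequence_has_no_tandem_structure(self, rng):
        rec = SeqRecord(id="r", residues=random_nt(rng, 600))
        with pytest.raises(NoTandemStructureError):
            detect_period(rec)

    def test_period_is_codon_multiple_and_validated(self, small_sim):
        gene, _ = small_sim
        det = detect_period(gene)
        assert det.period_nt % 3 == 0
        with pytest.raises(ValueError):
            detect_period(gene, min_period=100)  # not a codon multiple


class TestSegmentRepeats:
    def test_recovers_generator_boundaries(self):
        for seed in range(5):
            p = SimParams(seed=seed, repeat_len_nt=300, n_repeats=8, n_term_len=120,
                          c_term_len=90, n_loci=1, ploidy=1, mutation_rate=1e-4,
                          conversion_rate=0.0, n_generations=100)
            gene, truth = simulate_gene(p)
            evolve_loci(gene, truth)
            evolved = truth.alleles[0]
            det = detect_period(evolved)
            assert det.period_nt == 300
            model = segment_repeats(evolved, det.period_nt)
            assert [(r.start, r.end) for r in model.repeats] == \
                   [(r.start, r.end) for r in truth.model.repeats]

    def test_truncated_final_repeat_boundary(self):
        p = SimParams(seed=3, repeat_len_nt=300, n_repeats=8, n_term_len=120,
                      c_term_len=90, last_repeat_len_nt=240, n_loci=1, ploidy=1,
                      mutation_rate=1e-4, conversion_rate=0.0, n_generations=50)
        gene, truth = simulate_gene(p)
        model = segment_repeats(gene, 300)
        assert model.n_repeats == 8
        assert len(model.repeats[-1]) == 240
        assert (model.repeats[-1].start, model.repeats[-1].end) == \
               (truth.model.repeats[-1].start, truth.model.repeats[-1].end)

    def test_exact_units_with_empty_terminals(self, rng):
        unit = random_nt(rng, 90)
        model = segment_repeats(SeqRecord(id="t", residues=unit * 3), 90)
        assert model.n_term is None and model.c_term is None
        assert model.n_repeats == 3

    def test_idempotent_on_repeat_region(self, small_sim):
        gene, truth = small_sim
        evolved = truth.alleles[0]
        model = segment_repeats(evolved, truth.params.repeat_len_nt)
        core = evolved.residues[model.repeats[0].start:model.repeats[-1].end]
        again = segment_repeats(SeqRecord(id="core", residues=core),
                                truth.params.repeat_len_nt)
        assert again.n_term is None and again.c_term is None
        assert again.n_repeats == model.n_repeats
        assert [len(r) for r in again.repeats] == [len(r) for r in model.repeats]

    def test_errors(self, rng):
        rec = SeqRecord(id="t", residues=random_nt(rng, 300))
        with pytest.raises(SegmentationError):
            segment_repeats(rec, 100)  # period not a codon multiple
        with pytest.raises(SegmentationError):
            segment_repeats(SeqRecord(id="s", residues=random_nt(rng, 120)), 90)

    def test_period_recovery_over_seeded_replicates(self):
        """Unit ~600 nt, 10–25 copies, per-copy divergence <= 2%:
        period and boundary recovery must be exact."""
        master = np.random.default_rng(42)
        for _ in range(20):
            n_rep = int(master.integers(10, 26))
            p = SimParams(seed=int(master.integers(0, 2**31 - 1)), repeat_len_nt=600,
                          n_repeats=n_rep, n_term_len=300, c_term_len=210,
                          n_loci=1, ploidy=1, mutation_rate=1e-4,
                          terminal_rate_multiplier=1.0, conversion_rate=0.0,
                          n_generations=100)  # E[per-copy divergence] = 1%
            gene, truth = simulate_gene(p)
            evolve_loci(gene, truth)
            evolved = truth.alleles[0]
            det = detect_period(evolved, min_period=30, max_period=1500)
            assert det.period_nt == 600
            model = segment_repeats(evolved, 600)
            assert [(r.start, r.end) for r in model.repeats] == \
                   [(r.start, r.end) for r in truth.model.repeats]


class TestGeneModel:
    def test_invariants_enforced(self):
        with pytest.raises(SegmentationError):
            GeneModel(orf=Interval(0, 600), period_nt=300,
                      repeats=[Interval(0, 300), Interval(310, 600)])  # gap

    def test_json_round_trip(self, small_sim):
        _, truth = small_sim
        back = GeneModel.from_json(truth.model.to_json())
        assert [(r.start, r.end) for r in back.repeats] == \
               [(r.start, r.end) for r in truth.model.repeats]
        assert back.period_nt == truth.model.period_nt


class TestExtractRegions:
    def test_regions_tile_the_orf(self, small_sim):
        gene, truth = small_sim
        regions = extract_regions(truth.model, gene)
        cat = (regions.n_term.residues + "".join(r.residues for r in regions.repeats)
               + regions.c_term.residues)
        assert cat == gene.residues
        assert [r.id for r in regions.repeats] == \
               [f"{gene.id}_R{k}" for k in range(1, truth.model.n_repeats + 1)]

    def test_empty_terminal_is_flagged_as_none(self, rng):
        unit = random_nt(rng, 90)
        rec = SeqRecord(id="t", residues=unit * 3)
        model = segment_repeats(rec, 90)
        regions = extract_regions(model, rec)
        assert regions.n_term is None and regions.c_term is None

    def test_out_of_bounds_rejected(self, small_sim):
        gene, truth = small_sim
        short = SeqRecord(id="s", residues=gene.residues[:-30])
        with pytest.raises(ValueError):
            extract_regions(truth.model, short)
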