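"""Synthetic spidroin-like genes, multi-locus genomes, and PCR clone sets.

The generator emulates the data regime of an aciniform silk gene study:
a single long ORF whose short unique N-/C-terminal coding regions flank
an array of near-identical ~600-nt repeat units; several diverged gene
copies (loci) per diploid genome, evolved by point mutation plus
intragenic gene conversion (whole-unit copy-paste between repeats of one
sequence, the mechanism behind concerted evolution); and clone sets of
PCR amplicons carrying independent polymerase errors at a fixed per-base
rate.  Every stage records its ground truth so downstream modules can be
scored for parameter recovery.

All randomness flows through numpy Generators seeded from
``SimParams.seed``; identical parameters give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .repeat_array import GeneModel
from .seqio import Interval, SeqRecord, STANDARD_TABLE

_BASES = "ACGT"
_SENSE_CODONS = sorted(c for c, aa in STANDARD_TABLE.items() if aa != "*")
_SAG_CODONS = frozenset(c for c, aa in STANDARD_TABLE.items() if aa in "SAG")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Generator knobs.  Lengths in nt (multiples of 3); rates per base.

    Defaults describe the study regime: 20 repeats of 612 nt flanked by
    510/330-nt terminals, diploid individuals with several loci,
    terminals mutating faster than the conversion-homogenized repeats,
    and amplicon clones with polymerase error around 5×10⁻⁴ per base.
    """

    seed: int = 0
    repeat_len_nt: int = 612
    n_repeats: int = 20
    n_term_len: int = 510
    c_term_len: int = 330
    last_repeat_len_nt: int | None = None  # e.g. 558 for a truncated final unit
    n_loci: int = 4
    ploidy: int = 2
    mutation_rate: float = 1e-4        # per base per generation (repeat region)
    terminal_rate_multiplier: float = 5.0
    conversion_rate: float = 1.0       # unit-conversion events per sequence per generation
    convert_edge_units: bool = True    # include first/last units as conversion partners
    n_generations: int = 200
    synonymous_bias: float = 0.0       # fraction of coding mutations forced synonymous
    sag_skew: float = 5.0              # codon-weight multiplier for Ser/Ala/Gly in repeats
    pcr_error_rate: float = 5e-4       # per base per clone
    clones_per_template: int = 6

    def __post_init__(self) -> None:
        for name in ("repeat_len_nt", "n_term_len", "c_term_len"):
            v = getattr(self, name)
            if v <= 0 or v % 3:
                raise SimulationError(f"{name} must be a positive multiple of 3, got {v}")
        if self.last_repeat_len_nt is not None and (
                self.last_repeat_len_nt <= 0 or self.last_repeat_len_nt % 3
                or self.last_repeat_len_nt > self.repeat_len_nt):
            raise SimulationError("last_repeat_len_nt must be a positive multiple of 3 "
                                  "no longer than repeat_len_nt")
        for name in ("mutation_rate", "synonymous_bias", "pcr_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_repeats < 1 or self.n_loci < 1 or self.ploidy < 1:
            raise SimulationError("n_repeats, n_loci and ploidy must be >= 1")


@dataclass
class SimTruth:
    """Ground truth accumulated across the simulation stages."""

    params: SimParams
    ancestral: SeqRecord
    model: GeneModel
    alleles: list[SeqRecord] = field(default_factory=list)
    templates: dict[str, list[SeqRecord]] = field(default_factory=dict)
    template_carriers: dict[str, list[str]] = field(default_factory=dict)
    clone_template: dict[str, str] = field(default_factory=dict)
    clone_errors: dict[str, list[int]] = field(default_factory=dict)


def _rng(p: SimParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([p.seed, stage])


def _random_codons(rng: np.random.Generator, n: int, skew: float | None = None) -> str:
    codons = _SENSE_CODONS
    if skew:
        w = np.array([skew if c in _SAG_CODONS else 1.0 for c in codons])
        w = w / w.sum()
        idx = rng.choice(len(codons), size=n, p=w)
    else:
        idx = rng.integers(0, len(codons), size=n)
    return "".join(codons[i] for i in idx)


def _distinct_codon(rng: np.random.Generator, avoid: str) -> str:
    """A sense codon sharing at most one position with *avoid*."""
    while True:
        c = _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
        if sum(a == b for a, b in zip(c, avoid)) <= 1:
            return c


def simulate_gene(p: SimParams) -> tuple[SeqRecord, SimTruth]:
    """Build an ancestral gene: ATG + N-terminal + repeat array + C-terminal + stop.

    The repeat array is one random unit (codon composition skewed toward
    serine/alanine/glycine) tandem-duplicated ``n_repeats`` times, the
    final copy optionally truncated to ``last_repeat_len_nt``.  The ORF
    spans the whole sequence; repeats start out 100% identical.

    The terminals are unique, non-repetitive sequence: the two terminal
    codons on each side of the array are constrained not to mimic the
    codon that would continue the repeat consensus, so the true array
    boundaries are identifiable from the sequence alone (without this
    the ground truth of boundary-recovery checks would be ill-posed).
    """
    rng = _rng(p, 0)
    n_term = "ATG" + _random_codons(rng, p.n_term_len // 3 - 1)
    unit = _random_codons(rng, p.repeat_len_nt // 3, skew=p.sag_skew)
    last_len = p.last_repeat_len_nt or p.repeat_len_nt
    # junction identifiability: resample flank codons that look like the
    # continuation of the array (<=1 shared position with the repeat codon
    # that would sit there)
    u2 = unit + unit
    fixed_head = []
    for k in (2, 1):  # n_term codons at -2, -1 vs the unit's wrap codons
        if p.n_term_len >= 3 * (k + 1):  # never touch the ATG
            avoid = u2[p.repeat_len_nt - 3 * k:p.repeat_len_nt - 3 * k + 3]
            n_term = n_term[:len(n_term) - 3 * k] \
                + _distinct_codon(rng, avoid) + n_term[len(n_term) - 3 * (k - 1):]
    c_term = _random_codons(rng, p.c_term_len // 3 - 1) + "TAA"
    for k in (0, 1):  # c_term codons 0, 1 vs the codons continuing the unit
        if p.c_term_len >= 3 * (k + 2):  # never touch the stop
            avoid = u2[last_len + 3 * k:last_len + 3 * k + 3]
            c_term = c_term[:3 * k] + _distinct_codon(rng, avoid) + c_term[3 * k + 3:]
    repeats = unit * (p.n_repeats - 1) + unit[:last_len]
    seq = n_term + repeats + c_term
    rep_start = p.n_term_len
    intervals = []
    for k in range(p.n_repeats):
        s = rep_start + k * p.repeat_len_nt
        e = s + (last_len if k == p.n_repeats - 1 else p.repeat_len_nt)
        intervals.append(Interval(s, e))
    model = GeneModel(orf=Interval(0, len(seq)), repeats=intervals,
                      period_nt=p.repeat_len_nt,
                      n_term=Interval(0, rep_start),
                      c_term=Interval(intervals[-1].end, len(seq)))
    gene = SeqRecord(id="sim_gene", residues=seq, alphabet="nt",
                     description="synthetic spidroin-like gene")
    return gene, SimTruth(params=p, ancestral=gene, model=model)


def _synonymous_alternatives(codon: str) -> list[tuple[int, str]]:
    """All (position, base) single-base changes preserving the amino acid."""
    aa = STANDARD_TABLE.get(codon)
    if aa is None or aa == "*":
        return []
    return [(pos, b) for pos in range(3) for b in _BASES
            if b != codon[pos]
            and STANDARD_TABLE[codon[:pos] + b + codon[pos + 1:]] == aa]


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator,
            synonymous_bias: float) -> None:
    """Point-mutate *seq* (uint8 codes 0–3) in place at *positions*.

    With probability ``synonymous_bias`` a mutation is redirected to a
    random synonymous single-base change of the codon it landed in
    (codons with no synonymous change, ATG and TGG, mutate freely).
    """
    for pos in positions:
        pos = int(pos)
        if synonymous_bias and rng.random() < synonymous_bias:
            c0 = 3 * (pos // 3)
            codon = "".join(_BASES[b] for b in seq[c0:c0 + 3])
            alts = _synonymous_alternatives(codon)
            if alts:
                off, base = alts[int(rng.integers(0, len(alts)))]
                seq[c0 + off] = _BASES.index(base)
                continue
        seq[pos] = (seq[pos] + 1 + rng.integers(0, 3)) % 4


def evolve_loci(gene: SeqRecord, truth: SimTruth, p: SimParams | None = None) -> SimTruth:
    """Evolve one diploid genome: ``n_loci × ploidy`` independent allele copies.

    Each generation every allele receives binomial point mutations (the
    terminal regions at ``terminal_rate_multiplier`` times the repeat
    rate) followed by Poisson-distributed gene-conversion events, each
    overwriting one repeat unit with a copy of another unit of the same
    allele.  Terminals never undergo conversion — they have no repeat
    partner.  Fills ``truth.alleles`` and the per-region template tables.
    """
    p = p or truth.params
    rng = _rng(p, 1)
    model = truth.model
    base = np.frombuffer(gene.residues.encode(), dtype=np.uint8)
    code = np.zeros(base.size, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        code[base == ord(b)] = i
    L = code.size
    rep_start, rep_end = model.repeats[0].start, model.repeats[-1].end
    term_len = L - (rep_end - rep_start)
    rep_len = rep_end - rep_start
    units = model.repeats
    conv_pool = list(range(len(units)))
    if not p.convert_edge_units and len(units) > 2:
        conv_pool = conv_pool[1:-1]

    term_positions = np.concatenate([np.arange(0, rep_start), np.arange(rep_end, L)])
    term_rate = min(1.0, p.mutation_rate * p.terminal_rate_multiplier)

    alleles = []
    for locus in range(p.n_loci):
        for allele in range(p.ploidy):
            s = code.copy()
            for _ in range(p.n_generations):
                n_rep = rng.binomial(rep_len, p.mutation_rate)
                if n_rep:
                    pos = rep_start + rng.choice(rep_len, size=n_rep, replace=False)
                    _mutate(s, pos, rng, p.synonymous_bias)
                n_term = rng.binomial(term_len, term_rate)
                if n_term:
                    pos = rng.choice(term_positions, size=n_term, replace=False)
                    _mutate(s, pos, rng, p.synonymous_bias)
                if p.conversion_rate > 0 and len(conv_pool) > 1:
                    for _ in range(rng.poisson(p.conversion_rate)):
                        d, a = rng.choice(len(conv_pool), size=2, replace=False)
                        du, au = units[conv_pool[int(d)]], units[conv_pool[int(a)]]
                        m = min(len(du), len(au))
                        s[au.start:au.start + m] = s[du.start:du.start + m]
            residues = "".join(_BASES[b] for b in s)
            alleles.append(SeqRecord(id=f"L{locus + 1}a{allele + 1}", residues=residues,
                                     alphabet="nt"))
    truth.alleles = alleles
    truth.templates = {}
    truth.template_carriers = {}
    for region in ("N", "C", "repeat"):
        _collect_templates(truth, region)
    return truth


def _region_interval(model: GeneModel, region: str) -> Interval:
    if region == "N":
        if model.n_term is None:
            raise SimulationError("gene model has no N-terminal region")
        return model.n_term
    if region == "C":
        if model.c_term is None:
            raise SimulationError("gene model has no C-terminal region")
        return model.c_term
    if region == "repeat":
        # a single interior unit stands in for the repeat-region amplicon
        return model.repeats[len(model.repeats) // 2]
    raise SimulationError(f"unknown region {region!r}")


def _collect_templates(truth: SimTruth, region: str) -> None:
    iv = _region_interval(truth.model, region)
    seen: dict[str, str] = {}
    templates: list[SeqRecord] = []
    carriers: dict[str, list[str]] = {}
    for allele in truth.alleles:
        sub = allele.residues[iv.start:iv.end]
        if sub not in seen:
            tid = f"{region}_T{len(templates) + 1}"
            seen[sub] = tid
            templates.append(SeqRecord(id=tid, residues=sub, alphabet="nt"))
            carriers[tid] = []
        carriers[seen[sub]].append(allele.id)
    truth.templates[region] = templates
    truth.template_carriers.update(carriers)


def simulate_clones(templates: list[SeqRecord], truth: SimTruth, region: str,
                    p: SimParams | None = None, individual: str = "ind1",
                    species: str = "sim_species"):
    """PCR-clone each template with independent per-base polymerase errors.

    Returns a :class:`~spidroin.variant_diagnosis.CloneSet`; error
    positions and the clone→template map are recorded in *truth*.
    """
    from .variant_diagnosis import CloneSet

    p = p or truth.params
    rng = _rng(p, 2)
    clones = []
    for t in templates:
        arr = np.frombuffer(t.residues.encode(), dtype=np.uint8)
        code = np.zeros(arr.size, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            code[arr == ord(b)] = i
        for k in range(p.clones_per_template):
            s = code.copy()
            n_err = rng.binomial(s.size, p.pcr_error_rate)
            pos = (rng.choice(s.size, size=n_err, replace=False) if n_err
                   else np.array([], dtype=int))
            for q in pos:
                s[q] = (s[q] + 1 + rng.integers(0, 3)) % 4
            cid = f"{t.id}_c{k + 1}"
            clones.append(SeqRecord(id=cid, residues="".join(_BASES[b] for b in s),
                                    alphabet="nt"))
            truth.clone_template[cid] = t.id
            truth.clone_errors[cid] = sorted(int(q) for q in pos)
    return CloneSet(individual=individual, species=species, region=region, clones=clones)


def simulate_species(p: SimParams, n_species: int = 2,
                     species_seeds: list[int] | None = None) -> list[SimTruth]:
    """Independent genomes evolved from one common ancestral gene.

    Each species runs :func:`evolve_loci` with its own random stream, so
    between-species divergence accumulates on both branches while
    conversion keeps homogenizing repeats within each genome.
    """
    gene, truth0 = simulate_gene(p)
    seeds = species_seeds or [p.seed + 1000 + i for i in range(n_species)]
    out = []
    for sp, seed in enumerate(seeds[:n_species]):
        sp_params = replace(p, seed=seed)
        t = SimTruth(params=sp_params, ancestral=gene, model=truth0.model)
        evolve_loci(gene, t, sp_params)
        out.append(t)
    return out
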