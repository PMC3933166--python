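"""Clone-based variant diagnosis for multi-locus gene families.

PCR amplicons cloned from one individual mix true allelic/locus variants
with polymerase errors.  The pipeline: (1) mask singleton SNPs — a
residue carried by exactly one clone at a column is attributed to Taq
error and replaced by the column majority; (2) discard clones whose
post-masking polymorphism pattern is not shared with at least one other
clone (e.g. PCR chimeras); (3) single-linkage cluster the survivors at a
percent-identical-sites threshold (default >95%); (4) emit each
cluster of two or more clones as a variant (majority-rule consensus);
(5) the minimum locus count of a diploid is ceil(variants / 2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .alignment import MultipleAlignment, align
from .homogeneity import (PAIRWISE_DELETION, UndefinedIdentityError, consensus,
                          pairwise_identity)
from .seqio import SeqRecord

GAP = "-"


class DiagnosisError(ValueError):
    pass


@dataclass
class CloneSet:
    """Amplicon clone sequences from one individual and gene region."""

    individual: str
    species: str
    region: str  # {"N", "C", "repeat"}
    clones: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.clones:
            raise DiagnosisError("clone set must contain at least one clone")
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise DiagnosisError("duplicate clone ids in clone set")


@dataclass
class MaskedCell:
    clone_id: str
    column: int
    original: str
    replacement: str


@dataclass
class MaskReport:
    cells: list[MaskedCell] = field(default_factory=list)
    skipped: bool = False  # True for 2-clone sets, where the rule is undefined

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class VariantCall:
    """A consensus sequence supported by at least two clones."""

    variant_id: str
    region: str
    species: str
    consensus: SeqRecord
    supporting_clones: list[str]
    within_identity_pct: float

    def __post_init__(self) -> None:
        if len(self.supporting_clones) < 2:
            raise DiagnosisError("a variant needs >= 2 supporting clones")


def mask_singletons(clone_aln: MultipleAlignment) -> tuple[MultipleAlignment, MaskReport]:
    """Replace singleton residues by the column majority.

    A cell is masked only when every other clone in its column carries
    one single shared state (so a residue seen in two or more clones is
    never touched).  For 2-clone alignments every difference is a
    reciprocal singleton; masking is skipped with a warning.
    """
    if clone_aln.n_rows < 2:
        raise DiagnosisError("masking needs >= 2 aligned clones")
    if clone_aln.n_rows == 2:
        warnings.warn("2-clone set: singleton masking is undefined and was skipped")
        return clone_aln, MaskReport(skipped=True)
    rows = [list(r) for r in clone_aln.rows]
    report = MaskReport()
    for j in range(clone_aln.n_cols):
        col = [r[j] for r in rows]
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        if len(counts) != 2:
            continue
        (s1, n1), (s2, n2) = sorted(counts.items(), key=lambda kv: kv[1])
        if n1 != 1:
            continue
        i = col.index(s1)
        rows[i][j] = s2
        report.cells.append(MaskedCell(clone_id=clone_aln.ids[i], column=j,
                                       original=s1, replacement=s2))
    masked = MultipleAlignment(ids=list(clone_aln.ids),
                               rows=["".join(r) for r in rows],
                               alphabet=clone_aln.alphabet)
    return masked, report


def discard_unsupported(masked: MultipleAlignment) -> tuple[MultipleAlignment, list[str]]:
    """Keep clones whose polymorphism pattern occurs in >= 2 clones.

    The pattern is the residue vector over the columns that remain
    polymorphic after masking; a clone with a unique pattern (e.g. a PCR
    chimera combining SNPs of two templates) is discarded.
    """
    poly = [j for j in range(masked.n_cols)
            if len(set(masked.column(j))) > 1]
    patterns = [tuple(r[j] for j in poly) for r in masked.rows]
    counts: dict[tuple, int] = {}
    for p in patterns:
        counts[p] = counts.get(p, 0) + 1
    keep = [i for i, p in enumerate(patterns) if counts[p] >= 2]
    discards = [masked.ids[i] for i, p in enumerate(patterns) if counts[p] < 2]
    if not keep:
        warnings.warn("all clones discarded as unsupported")
        return MultipleAlignment(ids=[], rows=[], alphabet=masked.alphabet), discards
    return MultipleAlignment(ids=[masked.ids[i] for i in keep],
                             rows=[masked.rows[i] for i in keep],
                             alphabet=masked.alphabet), discards


def _single_linkage(n: int, sim: "list[list[float]]", threshold: float) -> list[list[int]]:
    """Single-linkage clusters: edges where similarity > threshold."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sim[i][j] > threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def cluster_variants(retained: MultipleAlignment, threshold_pct: float = 95.0,
                     region: str = "", species: str = "",
                     policy: str = PAIRWISE_DELETION) -> list[VariantCall]:
    """Single-linkage clustering at > *threshold_pct* identical sites.

    Clusters of a single clone are dropped; each surviving cluster emits
    a majority-rule consensus :class:`VariantCall`.  Variant ids are
    V1, V2... ordered by first supporting clone.
    """
    if not (50.0 < threshold_pct <= 100.0):
        raise DiagnosisError(f"threshold must be in (50, 100], got {threshold_pct}")
    n = retained.n_rows
    if n < 2:
        return []
    sim = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            try:
                sim[i][j] = sim[j][i] = pairwise_identity(
                    retained.rows[i], retained.rows[j], policy)
            except UndefinedIdentityError:
                sim[i][j] = sim[j][i] = 0.0
    calls = []
    k = 0
    for group in _single_linkage(n, sim, threshold_pct):
        if len(group) < 2:
            continue
        k += 1
        sub = MultipleAlignment(ids=[retained.ids[i] for i in group],
                                rows=[retained.rows[i] for i in group],
                                alphabet=retained.alphabet)
        cons = consensus(sub, id=f"V{k}").record
        within = [sim[i][j] for a, i in enumerate(group) for j in group[a + 1:]]
        calls.append(VariantCall(
            variant_id=f"V{k}", region=region, species=species, consensus=cons,
            supporting_clones=[retained.ids[i] for i in group],
            within_identity_pct=float(sum(within) / len(within)),
        ))
    return calls


def min_loci(n_variants: int, ploidy: int = 2) -> int:
    """Smallest gene-copy number consistent with the variant count.

    A diploid locus contributes at most two distinct alleles, so the
    minimum locus count is ceil(variants / ploidy).
    """
    if ploidy < 1:
        raise DiagnosisError(f"ploidy must be >= 1, got {ploidy}")
    if n_variants < 0:
        raise DiagnosisError("variant count cannot be negative")
    return math.ceil(n_variants / ploidy)


@dataclass
class DiagnosisResult:
    clone_set: CloneSet
    variants: list[VariantCall]
    mask_report: MaskReport
    discarded_clones: list[str]
    min_loci: int

    def summary(self) -> dict:
        return {
            "individual": self.clone_set.individual,
            "species": self.clone_set.species,
            "region": self.clone_set.region,
            "n_clones": len(self.clone_set.clones),
            "n_masked_cells": len(self.mask_report),
            "n_discarded": len(self.discarded_clones),
            "n_variants": len(self.variants),
            "min_loci": self.min_loci,
            "within_identity_pct": {v.variant_id: v.within_identity_pct
                                    for v in self.variants},
        }


def diagnose(clone_set: CloneSet, threshold_pct: float = 95.0, ploidy: int = 2,
             discard_first: bool = False) -> DiagnosisResult:
    """Full diagnosis: align, mask, discard, cluster, count minimum loci.

    ``discard_first`` flips the mask/discard order for sensitivity
    analysis (the default order masks polymerase errors first).
    """
    if len(clone_set.clones) == 1:
        warnings.warn("single-clone set: no variant can be supported")
        return DiagnosisResult(clone_set=clone_set, variants=[],
                               mask_report=MaskReport(skipped=True),
                               discarded_clones=[], min_loci=0)
    lengths = {len(c) for c in clone_set.clones}
    if len(lengths) == 1:
        aln = MultipleAlignment(ids=[c.id for c in clone_set.clones],
                                rows=[c.residues for c in clone_set.clones],
                                alphabet=clone_set.clones[0].alphabet)
    else:  # length-variant amplicons: align first
        aln = align(clone_set.clones)
    if discard_first:
        aln, discards = discard_unsupported(aln)
        if aln.n_rows >= 2:
            aln, report = mask_singletons(aln)
        else:
            report = MaskReport(skipped=True)
    else:
        aln, report = mask_singletons(aln)
        aln, discards = discard_unsupported(aln)
    variants = cluster_variants(aln, threshold_pct, region=clone_set.region,
                                species=clone_set.species) if aln.n_rows >= 2 else []
    if not variants:
        warnings.warn(f"no supported variants in clone set "
                      f"{clone_set.individual}/{clone_set.region}")
    return DiagnosisResult(clone_set=clone_set, variants=variants, mask_report=report,
                           discarded_clones=discards,
                           min_loci=min_loci(len(variants), ploidy))
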