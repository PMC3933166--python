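"""Repeat homogenization and positional conservation statistics.

Quantifies how alike the iterated repeat units of a spidroin gene are:
pairwise identity matrices, majority-rule consensus sequences,
per-column conservation profiles against domain annotations, amino-acid
composition, codon-usage tables with positional codon analysis, and
region-wise divergence summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignmentError, MultipleAlignment, align  # noqa: F401  (re-export)
from .seqio import Interval, SeqRecord, SequenceError, STANDARD_TABLE, translate

GAP = "-"
#: identity denominators: skip columns where either row is gapped
PAIRWISE_DELETION = "pairwise_deletion"
#: count a gap against a residue as a mismatch (both-gap columns skipped)
GAP_MISMATCH = "gap_mismatch"


class UndefinedIdentityError(ValueError):
    """No counted columns between two rows (all-gap overlap)."""


def pairwise_identity(a_row: str, b_row: str, policy: str = PAIRWISE_DELETION) -> float:
    """Percent identical sites between two equal-length gapped rows.

    ``pairwise_deletion`` (default) counts only columns where neither row
    has a gap; ``gap_mismatch`` counts gap-vs-residue columns as
    mismatches.  Columns where both rows are gapped are never counted.
    ``N`` never matches anything, including another ``N``.
    """
    if len(a_row) != len(b_row):
        raise ValueError(f"row lengths differ: {len(a_row)} vs {len(b_row)}")
    if policy not in (PAIRWISE_DELETION, GAP_MISMATCH):
        raise ValueError(f"unknown gap policy {policy!r}")
    a = np.frombuffer(a_row.encode(), dtype="S1")
    b = np.frombuffer(b_row.encode(), dtype="S1")
    gap_a, gap_b = a == b"-", b == b"-"
    if policy == PAIRWISE_DELETION:
        counted = ~gap_a & ~gap_b
    else:
        counted = ~(gap_a & gap_b)
    n = int(counted.sum())
    if n == 0:
        raise UndefinedIdentityError("no counted columns between rows")
    match = (a == b) & counted & ~gap_a & (a != b"N")
    return 100.0 * int(match.sum()) / n


@dataclass
class IdentityMatrix:
    """Square symmetric matrix of percent identities with unit diagonal."""

    ids: list[str]
    values: np.ndarray  # (n, n) float, percent

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        self.values = v

    def mean_offdiag(self) -> float:
        n = len(self.ids)
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())

    def per_row_mean(self, id: str) -> float:
        i = self.ids.index(id)
        others = [j for j in range(len(self.ids)) if j != i]
        return float(self.values[i, others].mean())

    def to_distance(self) -> np.ndarray:
        """p-distance matrix (1 − identity/100) with exact zero diagonal."""
        d = 1.0 - self.values / 100.0
        np.fill_diagonal(d, 0.0)
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def identity_matrix(aln: MultipleAlignment, policy: str = PAIRWISE_DELETION) -> IdentityMatrix:
    if aln.n_rows < 2:
        raise AlignmentError("identity matrix needs >= 2 rows")
    n = aln.n_rows
    m = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        m[i, j] = m[j, i] = pairwise_identity(aln.rows[i], aln.rows[j], policy)
    return IdentityMatrix(ids=list(aln.ids), values=m)


@dataclass
class ConsensusResult:
    record: SeqRecord
    tie_columns: list[int]      # alignment columns where the majority was tied
    dropped_columns: list[int]  # gap-majority columns omitted from the consensus


def consensus(aln: MultipleAlignment, id: str = "consensus") -> ConsensusResult:
    """Majority-rule consensus of an alignment.

    The gap counts as a residue; columns where the gap is the single most
    frequent state are dropped.  Residue ties break to the alphabetically
    first residue and are flagged; a residue tied with the gap wins.
    """
    if aln.n_rows < 2:
        raise AlignmentError("consensus needs >= 2 rows")
    out, ties, dropped = [], [], []
    for j in range(aln.n_cols):
        col = aln.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.values())
        winners = sorted(ch for ch, c in counts.items() if c == best)
        residues = [w for w in winners if w != GAP]
        if not residues:  # gap is the unique majority
            dropped.append(j)
            continue
        if len(winners) > 1 and len(residues) == len(winners):
            ties.append(j)
        out.append(residues[0])
    rec = SeqRecord(id=id, residues="".join(out), alphabet=aln.alphabet)
    return ConsensusResult(record=rec, tie_columns=ties, dropped_columns=dropped)


@dataclass
class PositionalProfile:
    """Per-column agreement with a reference row, plus domain annotation.

    ``fractions[j]`` is the fraction of non-reference rows whose residue
    at column *j* equals the reference residue (0–1).
    """

    reference_id: str
    fractions: np.ndarray
    domains: list[tuple[Interval, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size and (f.min() < 0 or f.max() > 1):
            raise ValueError("profile fractions must lie in [0, 1]")
        for iv, label in self.domains:
            if iv.end > f.size:
                raise ValueError(f"domain {label!r} {iv} outside alignment of {f.size} columns")
        self.fractions = f

    def region_mean(self, label: str) -> float:
        """Mean per-column identity over a labeled region, as a percent."""
        for iv, lab in self.domains:
            if lab == label:
                return 100.0 * float(self.fractions[iv.start:iv.end].mean())
        raise KeyError(f"no domain labeled {label!r}")

    def to_frame(self) -> pd.DataFrame:
        labels = [""] * self.fractions.size
        for iv, lab in self.domains:
            for j in range(iv.start, iv.end):
                labels[j] = lab
        return pd.DataFrame({"column": np.arange(self.fractions.size),
                             "fraction_identical": self.fractions,
                             "domain": labels})


def positional_profile(consensus_set: list[SeqRecord], reference_id: str,
                       domains: list[tuple[Interval, str]] | None = None,
                       aln: MultipleAlignment | None = None) -> PositionalProfile:
    """Column-wise identity of each sequence to a reference sequence.

    Unaligned input records are aligned first.  The fraction at each
    column is computed over non-reference rows; a row matches only when
    its residue equals the reference residue exactly (gaps never match).
    """
    if aln is None:
        ids = [s.id for s in consensus_set]
        if reference_id not in ids:
            raise KeyError(f"reference {reference_id!r} not among sequences")
        if len({len(s.residues) for s in consensus_set}) == 1:
            aln = MultipleAlignment(ids=ids, rows=[s.residues for s in consensus_set],
                                    alphabet=consensus_set[0].alphabet)
        else:
            aln = align(consensus_set)
    ref = aln.row(reference_id)
    others = [r for i, r in zip(aln.ids, aln.rows) if i != reference_id]
    if not others:
        raise AlignmentError("positional profile needs at least one non-reference row")
    fr = np.zeros(aln.n_cols)
    for j in range(aln.n_cols):
        rc = ref[j]
        fr[j] = sum(1 for r in others if r[j] == rc and rc != GAP) / len(others)
    return PositionalProfile(reference_id=reference_id, fractions=fr,
                             domains=list(domains or []))


def read_domains(path: str | Path) -> list[tuple[Interval, str]]:
    """Read a BED-like TSV of domain annotations.

    Columns: name (ignored), start, end (0-based half-open alignment
    columns), label.  Lines starting with ``#`` are comments.
    """
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"malformed domain line: {line!r}")
        out.append((Interval(int(parts[1]), int(parts[2])), parts[3]))
    return out


def composition(protein: SeqRecord) -> dict[str, float]:
    """Percent of each amino acid, stop codons excluded; sums to 100."""
    if protein.alphabet != "aa":
        raise SequenceError("composition requires a protein record")
    residues = [c for c in protein.residues if c != "*"]
    if not residues:
        raise SequenceError("protein contains only stops")
    n = len(residues)
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    return {aa: 100.0 * c / n for aa, c in sorted(counts.items())}


@dataclass
class CodonUsageTable:
    """Per-amino-acid codon fractions plus overall composition percents."""

    per_aa: dict[str, dict[str, float]]
    composition: dict[str, float]

    def gcw_fraction(self) -> float | None:
        """Fraction of alanine codons ending A or T: (GCA+GCT)/(all GCN).

        Returns ``None`` (undefined) when the sequence encodes no alanine.
        """
        ala = self.per_aa.get("A")
        if not ala:
            return None
        return ala.get("GCA", 0.0) + ala.get("GCT", 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(aa, codon, frac) for aa, codons in sorted(self.per_aa.items())
                for codon, frac in sorted(codons.items())]
        return pd.DataFrame(rows, columns=["amino_acid", "codon", "fraction"])


def codon_usage(cds: SeqRecord) -> CodonUsageTable:
    """Codon-usage table of an in-frame coding sequence.

    Internal stop codons raise a warning but are counted (under ``*``).
    Codons containing N are skipped.
    """
    if cds.alphabet != "nt":
        raise SequenceError("codon_usage requires a nucleotide record")
    if len(cds.residues) % 3:
        raise SequenceError(f"record {cds.id!r}: length not a multiple of 3")
    counts: dict[str, dict[str, int]] = {}
    n_codons = len(cds.residues) // 3
    for k in range(n_codons):
        codon = cds.residues[3 * k:3 * k + 3]
        aa = STANDARD_TABLE.get(codon)
        if aa is None:  # contains N
            continue
        if aa == "*" and k < n_codons - 1:
            warnings.warn(f"internal stop codon at codon {k + 1} of {cds.id!r}")
        counts.setdefault(aa, {})[codon] = counts.get(aa, {}).get(codon, 0) + 1
    per_aa = {aa: {c: n / sum(cs.values()) for c, n in cs.items()}
              for aa, cs in counts.items()}
    comp = composition(translate(cds))
    return CodonUsageTable(per_aa=per_aa, composition=comp)


@dataclass
class PositionalCodonTable:
    """Codon used by each row at each codon column of a repeat alignment."""

    table: pd.DataFrame       # rows = repeat ids, columns = codon index (0-based)
    uniform: np.ndarray       # per codon column: all rows share one (non-gap) codon

    def codon_at(self, nt_start_1based: int) -> pd.Series:
        """Codons at the column whose 1-based first nt position is given."""
        return self.table[(nt_start_1based - 1) // 3]


def positional_codon_table(repeat_aln_nt: MultipleAlignment) -> PositionalCodonTable:
    """Tabulate codon usage per alignment codon column across repeat units.

    Requires a codon-aligned nucleotide alignment (every gap a whole
    ``---`` triplet on a codon boundary); raises on frame-breaking gaps.
    """
    if repeat_aln_nt.n_cols % 3:
        raise AlignmentError("alignment length not a multiple of 3")
    n_codon_cols = repeat_aln_nt.n_cols // 3
    data = {}
    for j in range(n_codon_cols):
        col = []
        for rid, row in zip(repeat_aln_nt.ids, repeat_aln_nt.rows):
            codon = row[3 * j:3 * j + 3]
            if "-" in codon and codon != "---":
                raise AlignmentError(
                    f"frame-breaking gap in {rid!r} at nt columns {3 * j + 1}-{3 * j + 3}")
            col.append(codon)
        data[j] = col
    table = pd.DataFrame(data, index=list(repeat_aln_nt.ids))
    uniform = np.array([(table[j] != "---").all() and table[j].nunique() == 1
                        for j in range(n_codon_cols)])
    return PositionalCodonTable(table=table, uniform=uniform)


def region_divergence(groups: dict[str, MultipleAlignment],
                      policy: str = PAIRWISE_DELETION) -> dict[str, float]:
    """Mean pairwise p-distance within each region's alignment.

    Returns ``{region: mean p-distance}``; the caller can rank regions
    (the homogenized repeat region is expected to be the least divergent).
    """
    out = {}
    for label, aln in groups.items():
        if aln.n_rows < 2:
            raise AlignmentError(f"region {label!r}: need >= 2 sequences")
        dists = [1.0 - pairwise_identity(a, b, policy) / 100.0
                 for a, b in combinations(aln.rows, 2)]
        out[label] = float(np.mean(dists))
    return out
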