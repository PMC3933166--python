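"""Global pairwise and progressive multiple alignment.

Pairwise alignment is Needleman–Wunsch with affine gaps (via
Bio.Align.PairwiseAligner).  Multiple alignment uses a center-star
progressive scheme: every sequence is aligned to a center sequence and
the pairwise alignments are merged on the center's coordinates.  For the
near-identical sequence sets this package targets (intragenic repeat
units, amplicon clones, congeneric consensus repeats) this is accurate
and fully deterministic.  Coding nucleotide sequences can be aligned in
protein space and back-threaded to codons, so gaps land only on codon
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SeqRecord, SequenceError, translate

#: default nucleotide scoring (match, mismatch, gap open, gap extend)
NT_SCORING = dict(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-2.0)


class AlignmentError(ValueError):
    pass


@dataclass
class MultipleAlignment:
    """Rows of equal length over residues plus the gap character ``-``."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate row ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment rows: lengths {sorted(lengths)}")
        self._drop_all_gap_columns()

    def _drop_all_gap_columns(self) -> None:
        if not self.rows:
            return
        keep = [j for j in range(len(self.rows[0]))
                if any(r[j] != "-" for r in self.rows)]
        if len(keep) != len(self.rows[0]):
            self.rows = ["".join(r[j] for j in keep) for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, id: str) -> str:
        try:
            return self.rows[self.ids.index(id)]
        except ValueError:
            raise KeyError(f"no row with id {id!r}") from None

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def to_records(self, degap: bool = False) -> list[SeqRecord]:
        out = []
        for i, r in zip(self.ids, self.rows):
            s = r.replace("-", "") if degap else r
            out.append(SeqRecord(id=i, residues=s, alphabet=self.alphabet)
                       if degap else _GappedRecord(i, s, self.alphabet))
        return out


class _GappedRecord:
    """Minimal record carrier for gapped rows (bypasses alphabet checks)."""

    def __init__(self, id: str, residues: str, alphabet: str) -> None:
        self.id, self.residues, self.alphabet, self.description = id, residues, alphabet, ""

    def __len__(self) -> int:
        return len(self.residues)


def _make_aligner(alphabet: str, scoring: dict | None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "aa" and scoring is None:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
    else:
        sc = dict(NT_SCORING)
        if scoring:
            sc.update(scoring)
        aligner.match_score = sc["match"]
        aligner.mismatch_score = sc["mismatch"]
        aligner.open_gap_score = sc["gap_open"]
        aligner.extend_gap_score = sc["gap_extend"]
    return aligner


def pairwise_align(a: str, b: str, alphabet: str = "nt",
                   scoring: dict | None = None) -> tuple[str, str, float]:
    """Globally align two ungapped sequences; return (row_a, row_b, score).

    Nucleotide scoring defaults to match +1 / mismatch −1 / gap −2;
    protein scoring defaults to BLOSUM62 with affine gaps (−10/−1).
    """
    aligner = _make_aligner(alphabet, scoring)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def _center_index(seqs: list[str]) -> int:
    """Pick the center row: longest sequence, ties to the first."""
    return max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))


def _merge_on_center(center: str, pairs: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise (center, other) alignments into one MSA.

    ``pairs[k]`` is the gapped (center_row, other_row) for sequence k.
    Returns rows ordered [center, others...] on the merged coordinates.
    """
    n = len(center)
    # per sequence: insertion strings before each center position (and at end)
    ins_len = [0] * (n + 1)
    parsed = []  # per seq: (inserts: list[str] of len n+1, aligned: list[str] of len n)
    for gc, gs in pairs:
        inserts = [""] * (n + 1)
        aligned = []
        pos = 0
        buf = []
        for cc, sc in zip(gc, gs):
            if cc == "-":
                buf.append(sc)
            else:
                inserts[pos] = "".join(buf)
                buf = []
                aligned.append(sc)
                pos += 1
        inserts[n] = "".join(buf)
        parsed.append((inserts, aligned))
        for i in range(n + 1):
            ins_len[i] = max(ins_len[i], len(inserts[i]))

    def build(inserts: list[str], aligned: list[str]) -> str:
        out = []
        for i in range(n):
            out.append(inserts[i].ljust(ins_len[i], "-") if ins_len[i] else "")
            out.append(aligned[i])
        out.append(inserts[n].ljust(ins_len[n], "-") if ins_len[n] else "")
        return "".join(out)

    center_row = build([""] * (n + 1), list(center))
    rows = [center_row] + [build(ins, al) for ins, al in parsed]
    return rows


def align(seqs: list[SeqRecord], codon: bool = False,
          scoring: dict | None = None) -> MultipleAlignment:
    """Progressive (center-star) global multiple alignment.

    With ``codon=True`` the nucleotide sequences (length a multiple of 3,
    frame 0) are aligned in protein space and the amino-acid gaps are
    back-threaded as codon triplets, so the nucleotide alignment never
    breaks the reading frame.
    """
    if len(seqs) < 2:
        raise AlignmentError("need at least 2 sequences to align")
    alphabets = {s.alphabet for s in seqs}
    if len(alphabets) > 1:
        raise AlignmentError(f"mixed alphabets: {sorted(alphabets)}")
    alphabet = alphabets.pop()

    if codon:
        if alphabet != "nt":
            raise AlignmentError("codon mode requires nucleotide sequences")
        for s in seqs:
            if len(s) % 3:
                raise AlignmentError(f"record {s.id!r}: length not a multiple of 3")
        prot = [translate(s) for s in seqs]
        aa_aln = align(prot, codon=False, scoring=scoring)
        rows = []
        for rec, aa_row in zip(seqs, aa_aln.rows):
            nt_iter = iter(range(0, len(rec.residues), 3))
            chunks = []
            for ch in aa_row:
                if ch == "-":
                    chunks.append("---")
                else:
                    i = next(nt_iter)
                    chunks.append(rec.residues[i:i + 3])
            rows.append("".join(chunks))
        return MultipleAlignment(ids=[s.id for s in seqs], rows=rows, alphabet="nt")

    plain = [s.residues for s in seqs]
    if len(plain) == 2:
        ra, rb, _ = pairwise_align(plain[0], plain[1], alphabet, scoring)
        return MultipleAlignment(ids=[s.id for s in seqs], rows=[ra, rb], alphabet=alphabet)

    ci = _center_index(plain)
    center = plain[ci]
    others = [i for i in range(len(plain)) if i != ci]
    pairs = [pairwise_align(center, plain[i], alphabet, scoring)[:2] for i in others]
    rows = _merge_on_center(center, pairs)
    order = [ci] + others
    # restore input row order
    id_rows = sorted(zip(order, rows))
    return MultipleAlignment(ids=[seqs[i].id for i, _ in id_rows],
                             rows=[r for _, r in id_rows], alphabet=alphabet)


def read_aligned_fasta(path, alphabet: str = "nt") -> MultipleAlignment:
    from pathlib import Path

    ids, rows = [], []
    with open(Path(path)) as fh:
        cur = None
        buf: list[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if cur is not None:
                    ids.append(cur)
                    rows.append("".join(buf).upper())
                cur = line[1:].split()[0]
                buf = []
            elif line:
                buf.append(line)
        if cur is not None:
            ids.append(cur)
            rows.append("".join(buf).upper())
    if not ids:
        raise SequenceError(f"no FASTA records found in {path}")
    return MultipleAlignment(ids=ids, rows=rows, alphabet=alphabet)


def write_aligned_fasta(aln: MultipleAlignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, r in zip(aln.ids, aln.rows):
            fh.write(f">{i}\n")
            for j in range(0, len(r), width):
                fh.write(r[j:j + width] + "\n")
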