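"""Sequence records, FASTA input/output, ORF finding and translation.

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates appear only in serialized reports and CLI output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGTN")
# 20 standard residues + ambiguity codes, X for unknown, * for stop.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZXU*")

STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = frozenset(c for c, aa in STANDARD_TABLE.items() if aa == "*")


class SequenceError(ValueError):
    """Malformed sequence input (bad alphabet, duplicate ids, empty file)."""


class OrfNotFoundError(ValueError):
    """No open reading frame satisfying the minimum length was found."""


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval, 0-based, with strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SeqRecord:
    """A named nucleotide or protein sequence.

    Residues are stored uppercase.  ``alphabet`` is ``"nt"`` (A/C/G/T/N)
    or ``"aa"`` (IUPAC amino-acid letters, X, ``*``).
    """

    id: str
    residues: str
    alphabet: str = "nt"
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        legal = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        if self.alphabet not in ("nt", "aa"):
            raise SequenceError(f"record {self.id!r}: unknown alphabet {self.alphabet!r}")
        bad = set(self.residues) - legal
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal {self.alphabet} character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, iv: Interval, id: str | None = None) -> "SeqRecord":
        if iv.end > len(self.residues):
            raise ValueError(f"interval {iv} out of bounds for {self.id!r} (len {len(self)})")
        sub = self.residues[iv.start:iv.end]
        if iv.strand == "-":
            sub = revcomp(sub)
        return SeqRecord(id=id or self.id, residues=sub, alphabet=self.alphabet)


def revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def reverse_complement(rec: SeqRecord) -> SeqRecord:
    if rec.alphabet != "nt":
        raise SequenceError("reverse_complement requires a nucleotide record")
    return SeqRecord(id=rec.id, residues=revcomp(rec.residues), alphabet="nt",
                     description=rec.description)


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Residues are uppercased; record order is preserved.  Raises
    :class:`SequenceError` on an empty file, duplicate ids, or characters
    illegal under *alphabet*, naming the offending record.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise SequenceError(f"duplicate record id {bio.id!r} in {path}")
        seen.add(bio.id)
        desc = bio.description[len(bio.id):].strip() if bio.description.startswith(bio.id) else bio.description
        records.append(SeqRecord(id=bio.id, residues=str(bio.seq), alphabet=alphabet,
                                 description=desc))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def translate(nt: SeqRecord | str, frame: int = 0) -> SeqRecord:
    """Translate a nucleotide record with the standard genetic code.

    The trailing partial codon is dropped; stops render ``*``; any codon
    containing a non-ACGT character (e.g. N) renders ``X``.
    """
    if isinstance(nt, str):
        nt = SeqRecord(id="seq", residues=nt, alphabet="nt")
    if nt.alphabet != "nt":
        raise SequenceError("translate requires a nucleotide record")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = nt.residues[frame:]
    if len(s) < 3:
        raise SequenceError(f"record {nt.id!r}: fewer than 3 nt after frame offset")
    aa = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i:i + 3]
        aa.append(STANDARD_TABLE.get(codon, "X"))
    return SeqRecord(id=nt.id, residues="".join(aa), alphabet="aa", description=nt.description)


def _orfs_in_frame(seq: str, frame: int) -> list[tuple[int, int]]:
    """ATG-initiated, stop-terminated ORFs in one frame of the + representation.

    Returned intervals include the stop codon.  Within each inter-stop
    stretch only the 5'-most ATG opens an ORF (longest-ORF convention).
    """
    orfs = []
    start = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            if start is not None:
                orfs.append((start, i + 3))
                start = None
        elif codon == "ATG" and start is None:
            start = i
    return orfs


def find_longest_orf(nt: SeqRecord, both_strands: bool = False, min_len: int = 30) -> Interval:
    """Locate the longest ATG-initiated, stop-terminated ORF.

    The reported interval length includes the stop codon.  Ties break
    toward the + strand, then the 5'-most start.  Raises
    :class:`OrfNotFoundError` when no ORF reaches *min_len* nucleotides.
    """
    if nt.alphabet != "nt":
        raise SequenceError("find_longest_orf requires a nucleotide record")
    candidates: list[Interval] = []
    strands = [("+", nt.residues)]
    if both_strands:
        strands.append(("-", revcomp(nt.residues)))
    L = len(nt.residues)
    for strand, seq in strands:
        for frame in (0, 1, 2):
            for s, e in _orfs_in_frame(seq, frame):
                if strand == "-":
                    s, e = L - e, L - s
                candidates.append(Interval(s, e, strand))
    candidates = [iv for iv in candidates if len(iv) >= min_len]
    if not candidates:
        raise OrfNotFoundError(f"no ORF of >= {min_len} nt in record {nt.id!r}")
    # longest; ties: + strand first, then smallest start
    return sorted(candidates, key=lambda iv: (-len(iv), iv.strand, iv.start))[0]
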