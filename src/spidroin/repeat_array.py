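"""Tandem-repeat period detection and gene-architecture segmentation.

A spidroin ORF is modeled as a short non-repetitive N-terminal coding
region, an array of near-identical repeat units (the last unit possibly
truncated), and a short C-terminal coding region.  The period is found
by self-similarity: the codon-multiple shift maximizing the identity
between the sequence and itself shifted.  Segmentation scans every
codon-aligned phase of that period, keeps the longest contiguous run of
units that agree with the unit consensus, and assigns the flanks to the
terminals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import Interval, SeqRecord

_BASE_CODE = {ord(b): i for i, b in enumerate("ACGTN")}


class NoTandemStructureError(ValueError):
    """Best self-similarity score fell below the configured floor."""


class SegmentationError(ValueError):
    pass


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.int8)
    for byte, code in _BASE_CODE.items():
        out[arr == byte] = code
    return out


@dataclass
class PeriodDetection:
    period_nt: int
    score: float
    runner_up: tuple[int, float] | None  # best period outside ±1 codon of the winner


def detect_period(orf_nt: SeqRecord, min_period: int = 30, max_period: int | None = None,
                  score_floor: float = 0.60, tolerance: float = 0.01) -> PeriodDetection:
    """Find the tandem-repeat period of an in-frame ORF.

    Scores every codon-multiple shift ``p`` by the mean identity between
    the sequence and itself shifted by ``p`` (over their overlap).  Since
    every multiple of the true period scores equally well, the reported
    period is the smallest ``p`` whose score is within *tolerance* of
    the maximum.  Raises :class:`NoTandemStructureError` when the best
    score is below *score_floor*.
    """
    if min_period < 3 or min_period % 3:
        raise ValueError("min_period must be >= 3 and a multiple of 3")
    seq = _encode(orf_nt.residues)
    L = seq.size
    if max_period is None:
        max_period = L // 2
    max_period = min(max_period, L - 3)
    if max_period < min_period:
        raise ValueError("sequence too short for the requested period range")
    periods = np.arange(min_period, max_period + 1, 3)
    scores = np.array([float((seq[:-p] == seq[p:]).mean()) for p in periods])
    best = float(scores.max())
    if best < score_floor:
        raise NoTandemStructureError(
            f"best self-similarity {best:.3f} below floor {score_floor} "
            f"for record {orf_nt.id!r}")
    winner_idx = int(np.argmax(scores >= best - tolerance))
    period = int(periods[winner_idx])
    ru = None
    far = np.abs(periods - period) > 3
    if far.any():
        j = int(np.argmax(np.where(far, scores, -np.inf)))
        ru = (int(periods[j]), float(scores[j]))
    return PeriodDetection(period_nt=period, score=float(scores[winner_idx]), runner_up=ru)


@dataclass
class GeneModel:
    """Partition of an ORF into N-terminal, repeat units, C-terminal.

    All intervals are 0-based half-open on the ORF sequence.  ``n_term``
    or ``c_term`` is ``None`` when the corresponding terminal is empty.
    Every repeat except possibly the last has length ``period_nt``.
    """

    orf: Interval
    repeats: list[Interval]
    period_nt: int
    n_term: Interval | None = None
    c_term: Interval | None = None

    def __post_init__(self) -> None:
        if not self.repeats:
            raise SegmentationError("gene model needs at least one repeat unit")
        start = self.n_term.end if self.n_term else self.orf.start
        if self.n_term and self.n_term.start != self.orf.start:
            raise SegmentationError("n_term must start at the ORF start")
        prev_end = start
        for k, r in enumerate(self.repeats):
            if r.start != prev_end:
                raise SegmentationError(f"repeat {k + 1} not contiguous")
            if k < len(self.repeats) - 1 and len(r) != self.period_nt:
                raise SegmentationError(f"repeat {k + 1} length {len(r)} != period {self.period_nt}")
            prev_end = r.end
        end = self.c_term.start if self.c_term else self.orf.end
        if prev_end != end or (self.c_term and self.c_term.end != self.orf.end):
            raise SegmentationError("regions do not tile the ORF")

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize with 1-based inclusive coordinates for readability."""
        def one_based(iv: Interval | None):
            return None if iv is None else {"start": iv.start + 1, "end": iv.end}
        doc = {
            "coordinate_system": "1-based inclusive",
            "orf": one_based(self.orf),
            "period_nt": self.period_nt,
            "n_term": one_based(self.n_term),
            "repeats": [one_based(r) for r in self.repeats],
            "c_term": one_based(self.c_term),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "GeneModel":
        doc = json.loads(text)

        def iv(d):
            return None if d is None else Interval(d["start"] - 1, d["end"])
        return cls(orf=iv(doc["orf"]), repeats=[iv(r) for r in doc["repeats"]],
                   period_nt=doc["period_nt"], n_term=iv(doc["n_term"]),
                   c_term=iv(doc["c_term"]))


def _column_consensus(M: np.ndarray) -> np.ndarray:
    counts = np.stack([(M == v).sum(axis=0) for v in range(5)])
    return counts.argmax(axis=0)


def _block_identities(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cons = _column_consensus(M)
    return (M == cons[None, :]).mean(axis=1), cons


def _scan_boundary(seq: np.ndarray, anchor: int, cons: np.ndarray, forward: bool,
                   t: float, slack: float) -> int:
    """Extend an array boundary from *anchor* (a unit boundary of the
    rotated consensus) codon-aligned, as far as the sequence keeps
    matching the consensus.

    Each window chooses the prefix length maximizing matched positions
    minus ``t`` per position; among lengths within *slack* of that
    maximum the longest wins, so a single mutated codon at the true
    boundary does not shorten the array.  Full-period windows continue
    the scan; a shorter window (or no gain) closes the array.
    """
    p = cons.size
    pos = anchor
    while True:
        if forward:
            window = seq[pos:pos + p]
        else:
            window = seq[max(0, pos - p):pos]
        m = window.size - window.size % 3
        if m < 3:
            break
        if forward:
            eq = window[:m] == cons[:m]
        else:
            eq = window[-m:][::-1] == cons[::-1][:m]
        cum = np.cumsum(eq)
        lengths = np.arange(3, m + 1, 3)
        gains = cum[lengths - 1] - t * lengths
        gmax = float(gains.max())
        if gmax <= 0:
            break
        L = int(lengths[np.nonzero(gains >= gmax - slack)[0][-1]])
        pos = pos + L if forward else pos - L
        if L < p:
            break
    return pos


def segment_repeats(orf_nt: SeqRecord, period_nt: int,
                    terminal_threshold: float = 0.5,
                    boundary_threshold: float = 0.75,
                    boundary_slack: float = 1.0) -> GeneModel:
    """Segment an in-frame ORF into terminals and repeat units.

    For a near-perfect tandem array the unit decomposition is rotation
    ambiguous, so segmentation proceeds in two steps.  First, every
    codon-aligned phase of the period is scanned: full-length blocks
    agreeing with the block consensus (identity >= *terminal_threshold*)
    form candidate repeat runs and the phase maximizing summed in-run
    identity wins (ties: longer run, then smaller phase).  Second, the
    exact array span is recovered by change-point scans from the run's
    outermost unit boundaries (see :func:`_scan_boundary`, with the
    stricter *boundary_threshold*), and the units are tiled from the
    refined start: full periods followed by a possibly truncated final
    unit, matching the head-to-tail growth of these arrays.  Flanks
    outside the span become the N-/C-terminal regions.
    """
    if period_nt % 3:
        raise SegmentationError(f"period {period_nt} is not a multiple of 3")
    seq = _encode(orf_nt.residues)
    L = seq.size
    if L < 2 * period_nt:
        raise SegmentationError("sequence shorter than two repeat units")

    best = None  # (score, run_len, -phase, k0, k1, cons)
    for phase in range(0, period_nt, 3):
        nb = (L - phase) // period_nt
        if nb < 2:
            continue
        M = seq[phase:phase + nb * period_nt].reshape(nb, period_nt)
        ident, cons = _block_identities(M)
        ok = ident >= terminal_threshold
        # maximal-score contiguous run of qualifying blocks
        k = 0
        while k < nb:
            if not ok[k]:
                k += 1
                continue
            k0 = k
            while k < nb and ok[k]:
                k += 1
            run_score = float(ident[k0:k].sum())
            cand = (run_score, k - k0, -phase, k0, k - 1)
            if best is None or cand > best[:5]:
                run_M = M[k0:k]
                best = cand + (_column_consensus(run_M),)
    if best is None or best[1] < 2:
        raise SegmentationError("fewer than 2 repeat units detected")
    _, _, neg_phase, k0, k1, cons = best
    phase = -neg_phase

    # the run's outer blocks can straddle the terminal junctions, so refine
    # the span from interior unit boundaries outward, then tile from the start
    rep_start = _scan_boundary(seq, phase + (k0 + 1) * period_nt, cons,
                               forward=False, t=boundary_threshold,
                               slack=boundary_slack)
    rep_end = _scan_boundary(seq, phase + k1 * period_nt, cons,
                             forward=True, t=boundary_threshold,
                             slack=boundary_slack)
    if rep_end - rep_start < period_nt + 3:
        raise SegmentationError("fewer than 2 repeat units detected")
    n_full, trunc = divmod(rep_end - rep_start, period_nt)
    repeats = [Interval(rep_start + i * period_nt, rep_start + (i + 1) * period_nt)
               for i in range(n_full)]
    if trunc:
        repeats.append(Interval(rep_end - trunc, rep_end))
    if len(repeats) < 2:
        raise SegmentationError("fewer than 2 repeat units detected")
    n_term = Interval(0, rep_start) if rep_start > 0 else None
    c_term = Interval(rep_end, L) if rep_end < L else None
    return GeneModel(orf=Interval(0, L), repeats=repeats, period_nt=period_nt,
                     n_term=n_term, c_term=c_term)


@dataclass
class Regions:
    """Extracted region sequences; an empty terminal is ``None`` (flagged)."""

    n_term: SeqRecord | None
    repeats: list[SeqRecord]
    c_term: SeqRecord | None

    def all_records(self) -> list[SeqRecord]:
        out = [r for r in (self.n_term,) if r] + list(self.repeats)
        if self.c_term:
            out.append(self.c_term)
        return out


def extract_regions(model: GeneModel, orf: SeqRecord) -> Regions:
    """Slice the ORF into region records; repeats are named R1..Rn 5'→3'."""
    if model.orf.end > len(orf.residues):
        raise ValueError("gene model extends past the ORF sequence")
    n_term = orf.slice(model.n_term, id=f"{orf.id}_Nterm") if model.n_term else None
    c_term = orf.slice(model.c_term, id=f"{orf.id}_Cterm") if model.c_term else None
    reps = [orf.slice(iv, id=f"{orf.id}_R{k + 1}") for k, iv in enumerate(model.repeats)]
    return Regions(n_term=n_term, repeats=reps, c_term=c_term)
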