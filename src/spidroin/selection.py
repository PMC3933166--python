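"""Pairwise and region-averaged dN/dS by Nei–Gojobori (NG86) counting.

Synonymous and nonsynonymous *sites* per codon are counted by
enumerating all nine single-base changes (changes creating a stop codon
count as nonsynonymous, so the site fractions of every codon sum to 3).
Substitutions between codons differing at several positions are averaged
over all shortest mutational pathways, excluding pathways that pass
through a stop codon (unless every pathway does, in which case all are
used).  The proportions pS and pN are Jukes–Cantor corrected; raw
proportions are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

from .alignment import MultipleAlignment
from .seqio import STANDARD_TABLE

_BASES = "ACGT"

NEUTRAL_TOLERANCE = 0.05


class DnDsError(ValueError):
    pass


def _syn_site_fractions() -> dict[str, float]:
    """Synonymous site count (0–3) for every sense codon."""
    out = {}
    for codon, aa in STANDARD_TABLE.items():
        if aa == "*":
            continue
        syn = 0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if STANDARD_TABLE[alt] == aa:  # stop targets are never synonymous
                    syn += 1
        out[codon] = syn / 3.0
    return out


_SYN_SITES = _syn_site_fractions()


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) substitution counts between codons.

    Averages over all orderings of the differing positions; orderings
    that visit a stop codon are dropped when any stop-free ordering
    exists.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if STANDARD_TABLE[nxt] == "*":
                through_stop = True
            if STANDARD_TABLE[cur] != "*" and STANDARD_TABLE[nxt] != "*" \
                    and STANDARD_TABLE[cur] == STANDARD_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if through_stop else valid).append((sd, nd))
    paths = valid or fallback
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsEstimate:
    """NG86 estimate for one sequence pair (or a region average)."""

    pair_id: str
    dN: float | None
    dS: float | None
    pN: float
    pS: float
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    method: str = "NG86+JC"

    @property
    def ratio(self) -> float | None:
        """dN/dS; ``None`` when undefined (no synonymous divergence, or a
        saturated correction).  Zero nonsynonymous divergence against any
        synonymous divergence is exactly 0 even if the JC correction of
        pS is saturated."""
        if self.pN == 0.0 and self.pS > 0.0:
            return 0.0
        if self.dN is None or self.dS is None or self.dS == 0.0:
            return None
        return self.dN / self.dS


def pairwise_dnds(a_cds: str, b_cds: str, pair_id: str = "pair") -> DnDsEstimate:
    """NG86 dN/dS between two codon-aligned coding sequences.

    Codons containing a gap or N in either sequence, and stop codons,
    are excluded pairwise.
    """
    if len(a_cds) != len(b_cds):
        raise DnDsError("sequences must be codon-aligned to equal length")
    if len(a_cds) % 3:
        raise DnDsError("aligned length is not a multiple of 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a_cds), 3):
        c1, c2 = a_cds[i:i + 3], b_cds[i:i + 3]
        if c1 not in _SYN_SITES or c2 not in _SYN_SITES:
            continue  # gap/N/stop codon: excluded
        S += (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2.0
        N += 3.0 - (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0.0 or N == 0.0:
        raise DnDsError(f"no comparable codons in pair {pair_id!r}")
    pS, pN = Sd / S, Nd / N
    return DnDsEstimate(pair_id=pair_id, dN=_jukes_cantor(pN), dS=_jukes_cantor(pS),
                        pN=pN, pS=pS, S_sites=S, N_sites=N, Sd=Sd, Nd=Nd)


@dataclass
class RegionDnDs:
    """Region-level summary over all sequence pairs of an alignment."""

    region: str
    mean_dN: float
    mean_dS: float
    ratio_of_means: float | None   # mean dN / mean dS (robust to dS=0 pairs)
    mean_of_ratios: float | None   # mean of per-pair defined ratios
    n_pairs: int
    pairs: list[DnDsEstimate]


def region_dnds(aln: MultipleAlignment, region: str = "region") -> RegionDnDs:
    """Average NG86 estimates over all pairs of a codon alignment.

    The headline summary is the ratio of mean dN to mean dS; the mean of
    the per-pair ratios (where defined) is reported alongside.
    """
    if aln.n_rows < 2:
        raise DnDsError("region dN/dS needs >= 2 sequences")
    ests = []
    for (ia, ra), (ib, rb) in combinations(zip(aln.ids, aln.rows), 2):
        ests.append(pairwise_dnds(ra, rb, pair_id=f"{ia}|{ib}"))
    defined = [e for e in ests if e.dN is not None and e.dS is not None]
    if not defined:
        raise DnDsError(f"all pairs undefined (saturated) in region {region!r}")
    mean_dN = sum(e.dN for e in defined) / len(defined)
    mean_dS = sum(e.dS for e in defined) / len(defined)
    rom = (mean_dN / mean_dS) if mean_dS > 0 else None
    ratios = [e.ratio for e in defined if e.ratio is not None]
    mor = sum(ratios) / len(ratios) if ratios else None
    return RegionDnDs(region=region, mean_dN=mean_dN, mean_dS=mean_dS,
                      ratio_of_means=rom, mean_of_ratios=mor,
                      n_pairs=len(ests), pairs=ests)


def classify(ratio: float | DnDsEstimate | None,
             tolerance: float = NEUTRAL_TOLERANCE) -> str:
    """Interpret a dN/dS ratio: purifying (<1), neutral (≈1), positive (>1)."""
    if isinstance(ratio, DnDsEstimate):
        ratio = ratio.ratio
    if ratio is None:
        return "undefined"
    if abs(ratio - 1.0) <= tolerance:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"
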