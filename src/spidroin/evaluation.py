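"""Dual-route validation: independent oracles and parameter-recovery experiments.

Each check pits a package implementation against an independent
computation route: exhaustive dynamic programming for the aligner,
path-length enumeration on randomly generated additive trees for
neighbor joining, full mutational-pathway enumeration for the
Nei–Gojobori counts, and simulator ground truth for variant diagnosis,
singleton masking, and the homogenizing effect of gene conversion.
The oracles deliberately share no code with the implementations they
check (the genetic-code table is shared data, not an algorithm).
"""

from __future__ import annotations

from dataclasses import replace
from itertools import product

import numpy as np
from scipy import stats

from .alignment import MultipleAlignment, pairwise_align
from .homogeneity import pairwise_identity
from .seqio import STANDARD_TABLE
from .selection import pairwise_dnds
from .synthetic_data import SimParams, evolve_loci, simulate_clones, simulate_gene
from .trees import bipartitions, nj_tree
from .variant_diagnosis import diagnose, mask_singletons

_BASES = "ACGT"


# --------------------------------------------------------------------------
# aligner vs. exhaustive DP oracle
# --------------------------------------------------------------------------

def nw_score_oracle(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                    gap: float = -2.0) -> float:
    """Textbook Needleman–Wunsch score, linear gap penalty."""
    n, m = len(a), len(b)
    F = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = i * gap
    for j in range(1, m + 1):
        F[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            F[i][j] = max(F[i - 1][j - 1] + sub, F[i - 1][j] + gap, F[i][j - 1] + gap)
    return F[n][m]


def aligner_oracle_agreement(n_cases: int = 1000, seed: int = 0,
                             max_len: int = 10) -> dict:
    """Fraction of random short pairs where the aligner score equals the
    DP oracle score (match +1 / mismatch −1 / gap −2)."""
    rng = np.random.default_rng([seed, 10])
    agree = 0
    max_diff = 0.0
    for _ in range(n_cases):
        la, lb = rng.integers(1, max_len + 1, size=2)
        a = "".join(_BASES[i] for i in rng.integers(0, 4, size=la))
        b = "".join(_BASES[i] for i in rng.integers(0, 4, size=lb))
        _, _, score = pairwise_align(a, b, "nt")
        expected = nw_score_oracle(a, b)
        diff = abs(score - expected)
        max_diff = max(max_diff, diff)
        agree += diff < 1e-9
    return {"n": n_cases, "agreement_rate": agree / n_cases, "max_abs_diff": max_diff}


# --------------------------------------------------------------------------
# neighbor joining vs. random additive trees
# --------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary topology with uniform branch lengths.

    Returns (leaf names, distance matrix, set of non-trivial
    bipartitions) computed by direct path-length enumeration on an
    edge-list representation, independent of any tree library.
    """
    # nodes 0..n-1 are leaves; grow by joining two live roots under a new node
    nodes = list(range(n_leaves))
    next_id = n_leaves
    edges: list[tuple[int, int, float]] = []
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        edges.append((next_id, a, float(rng.uniform(0.05, 1.0))))
        edges.append((next_id, b, float(rng.uniform(0.05, 1.0))))
        nodes = [x for x in nodes if x not in (a, b)] + [next_id]
        next_id += 1
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    names = [f"t{i}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    D = (D + D.T) / 2.0  # per-source traversals agree only to float round-off
    np.fill_diagonal(D, 0.0)

    # bipartitions: cutting each internal edge splits the leaves
    bips: set[frozenset[str]] = set()
    for u, v, _ in edges:
        side = set()
        stack, seen = [v], {u, v}
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.add(names[x])
            for y, _w in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        comp = set(names) - side
        if len(side) >= 2 and len(comp) >= 2:
            small = side if (len(side), sorted(side)) <= (len(comp), sorted(comp)) else comp
            bips.add(frozenset(small))
    return names, D, bips


def nj_additive_recovery(n_trees: int = 100, seed: int = 0,
                         max_leaves: int = 10) -> dict:
    """Rate at which NJ exactly recovers random additive trees
    (topology via bipartitions, branch lengths via induced distances)."""
    from skbio import DistanceMatrix

    rng = np.random.default_rng([seed, 11])
    exact = 0
    for _ in range(n_trees):
        n = int(rng.integers(4, max_leaves + 1))
        names, D, true_bips = random_additive_tree(rng, n)
        tree = nj_tree(DistanceMatrix(D, ids=names))
        topo_ok = bipartitions(tree) == true_bips
        induced = tree.tip_tip_distances(endpoints=names)
        len_ok = np.allclose(np.asarray(induced.data), D, atol=1e-8)
        exact += topo_ok and len_ok
    return {"n": n_trees, "recovery_rate": exact / n_trees}


# --------------------------------------------------------------------------
# Nei–Gojobori vs. exhaustive enumeration oracle
# --------------------------------------------------------------------------

def _oracle_codon_sites(codon: str) -> float:
    syn = 0
    aa = STANDARD_TABLE[codon]
    for pos, b in product(range(3), _BASES):
        if b == codon[pos]:
            continue
        if STANDARD_TABLE[codon[:pos] + b + codon[pos + 1:]] == aa:
            syn += 1
    return syn / 3.0


def _oracle_pathways(c1: str, c2: str):
    """All shortest mutational pathways with per-step classification."""
    from itertools import permutations

    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in permutations(diff):
        cur, sd, nd, stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if STANDARD_TABLE[nxt] == "*":
                stop = True
            if "*" not in (STANDARD_TABLE[cur], STANDARD_TABLE[nxt]) \
                    and STANDARD_TABLE[cur] == STANDARD_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, stop))
    clean = [(s, n) for s, n, stop in results if not stop]
    use = clean or [(s, n) for s, n, _ in results]
    return (sum(s for s, _ in use) / len(use), sum(n for _, n in use) / len(use))


def ng86_oracle(seq1: str, seq2: str):
    """Independent NG86 estimate (raw proportions and JC distances)."""
    import math

    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if STANDARD_TABLE.get(c1, "*") == "*" or STANDARD_TABLE.get(c2, "*") == "*":
            continue
        s = (_oracle_codon_sites(c1) + _oracle_codon_sites(c2)) / 2.0
        S += s
        N += 3.0 - s
        sd, nd = _oracle_pathways(c1, c2)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return {"pS": pS, "pN": pN, "dS": jc(pS), "dN": jc(pN)}


#: a diverse sense-codon panel: all amino-acid classes, stop-adjacent codons
CODON_PANEL = ["TTT", "TTA", "CTG", "ATG", "ATA", "GTT", "TCA", "TCG", "AGT",
               "CCA", "ACC", "GCT", "GCC", "TAT", "CAA", "AAA", "GAT", "TGT",
               "TGG", "GGA"]


def ng86_oracle_comparison(panel: list[str] | None = None) -> dict:
    """Compare implementation vs. oracle on two-codon sequence pairs built
    from every ordered codon pair of the panel."""
    panel = panel or CODON_PANEL
    k = len(panel)
    max_diff = 0.0
    n = 0
    for idx, (a, b) in enumerate(product(panel, panel)):
        c, d = panel[idx % k], panel[(idx // 3) % k]
        s1, s2 = a + c, b + d
        est = pairwise_dnds(s1, s2)
        orc = ng86_oracle(s1, s2)
        for key in ("pS", "pN"):
            max_diff = max(max_diff, abs(getattr(est, key) - orc[key]))
        for key in ("dS", "dN"):
            mine, theirs = getattr(est, key), orc[key]
            if (mine is None) != (theirs is None):
                max_diff = max(max_diff, float("inf"))
            elif mine is not None:
                max_diff = max(max_diff, abs(mine - theirs))
        n += 1
    return {"n": n, "max_abs_diff": max_diff}


# --------------------------------------------------------------------------
# simulator-truth experiments
# --------------------------------------------------------------------------

def variant_recovery_experiment(n_sims: int = 50, seed: int = 0) -> dict:
    """Precision/recall of diagnosed variants against true templates.

    Parameter box per simulation: 2–5 loci (diploid), 4–10 clones per
    template, polymerase error 10⁻⁴–10⁻³ per base, and enough
    generations that templates diverge ~6–10% (safely below the 95%
    clustering threshold, so every template is its own variant).
    """
    rng = np.random.default_rng([seed, 12])
    tp = fp = fn = 0
    bound_ok = 0
    for k in range(n_sims):
        # rejection-sample genomes until every template pair sits below the
        # clustering threshold: the claim concerns templates the threshold
        # can distinguish (merging near-identical templates is by design)
        for _ in range(50):
            p = SimParams(
                seed=int(rng.integers(0, 2**31 - 1)),
                repeat_len_nt=90, n_repeats=4, n_term_len=330, c_term_len=330,
                n_loci=int(rng.integers(2, 6)), ploidy=2,
                mutation_rate=2e-4, terminal_rate_multiplier=5.0,
                conversion_rate=1.0, n_generations=int(rng.integers(30, 51)),
                pcr_error_rate=float(10 ** rng.uniform(-4, -3)),
                clones_per_template=int(rng.integers(4, 11)),
            )
            gene, truth = simulate_gene(p)
            evolve_loci(gene, truth)
            tmpl = truth.templates["C"]
            if all(pairwise_identity(a.residues, b.residues) < 95.0
                   for i, a in enumerate(tmpl) for b in tmpl[i + 1:]):
                break
        cs = simulate_clones(truth.templates["C"], truth, "C")
        result = diagnose(cs)
        true_seqs = {t.residues for t in truth.templates["C"]}
        called = {v.consensus.residues for v in result.variants}
        tp += len(called & true_seqs)
        fp += len(called - true_seqs)
        fn += len(true_seqs - called)
        bound_ok += result.min_loci <= p.n_loci
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"n": n_sims, "precision": precision, "recall": recall,
            "min_loci_bound_rate": bound_ok / n_sims}


def _within_repeat_identity(seq: str, model) -> float:
    units = [seq[iv.start:iv.end] for iv in model.repeats]
    full = [u for u in units if len(u) == model.period_nt]
    vals = [pairwise_identity(full[i], full[j])
            for i in range(len(full)) for j in range(i + 1, len(full))]
    return float(np.mean(vals))


def conversion_monotonicity(n_seeds: int = 30, conversion_rate: float = 5.0,
                            n_generations: int = 200,
                            mutation_rate: float = 1e-4) -> dict:
    """Gene conversion must raise within-gene repeat identity.

    Runs matched pairs (conversion off/on, same seed) and sign-tests the
    per-seed identity difference.
    """
    wins = ties = 0
    diffs = []
    for seed in range(n_seeds):
        base = SimParams(seed=seed, repeat_len_nt=612, n_repeats=10,
                         n_term_len=120, c_term_len=120, n_loci=1, ploidy=1,
                         mutation_rate=mutation_rate, terminal_rate_multiplier=1.0,
                         n_generations=n_generations, conversion_rate=0.0)
        gene, truth0 = simulate_gene(base)
        evolve_loci(gene, truth0)
        ident0 = _within_repeat_identity(truth0.alleles[0].residues, truth0.model)
        conv = replace(base, conversion_rate=conversion_rate)
        gene2, truth1 = simulate_gene(conv)
        evolve_loci(gene2, truth1)
        ident1 = _within_repeat_identity(truth1.alleles[0].residues, truth1.model)
        diffs.append(ident1 - ident0)
        if ident1 > ident0:
            wins += 1
        elif ident1 == ident0:
            ties += 1
    n_informative = n_seeds - ties
    p_value = float(stats.binomtest(wins, n_informative, 0.5,
                                    alternative="greater").pvalue) if n_informative else 1.0
    return {"n": n_seeds, "wins": wins, "ties": ties,
            "mean_identity_gain_pct": float(np.mean(diffs)), "sign_test_p": p_value}


def masking_soundness(n_sets: int = 100, seed: int = 0) -> dict:
    """Every masked cell must be an injected polymerase error; no residue
    shared by two or more clones is ever masked."""
    rng = np.random.default_rng([seed, 13])
    violations = 0
    n_masked = 0
    for _ in range(n_sets):
        p = SimParams(seed=int(rng.integers(0, 2**31 - 1)),
                      repeat_len_nt=90, n_repeats=3, n_term_len=300, c_term_len=300,
                      n_loci=2, ploidy=2, mutation_rate=5e-4,
                      terminal_rate_multiplier=2.0, conversion_rate=0.0,
                      n_generations=40, pcr_error_rate=1e-3,
                      clones_per_template=int(rng.integers(3, 8)))
        gene, truth = simulate_gene(p)
        evolve_loci(gene, truth)
        cs = simulate_clones(truth.templates["N"], truth, "N")
        aln = MultipleAlignment(ids=[c.id for c in cs.clones],
                                rows=[c.residues for c in cs.clones], alphabet="nt")
        _, report = mask_singletons(aln)
        n_masked += len(report)
        for cell in report.cells:
            if cell.column not in truth.clone_errors[cell.clone_id]:
                violations += 1
    return {"n": n_sets, "n_masked_cells": n_masked, "violations": violations}
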