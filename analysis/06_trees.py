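#!/usr/bin/env python
"""Neighbor-joining trees of repeat units and variants, with bootstrap.

Builds NJ trees from p-distances, midpoint-roots them, attaches
column-resampling bootstrap supports, and verifies that the within-gene
repeat units cluster more tightly than the terminal-region variants.
Outputs newick files to results/trees/.
"""

from pathlib import Path

from spidroin import homogeneity as hmg
from spidroin import seqio, trees
from spidroin.alignment import align

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "trees"


def main() -> None:
    repeats_fa = ROOT / "results" / "decompose" / "repeat_units.fasta"
    if not repeats_fa.exists():
        raise SystemExit("run analysis/02_decompose.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    repeats = seqio.read_fasta(repeats_fa)
    rep_aln = align(repeats, codon=True)
    tree, _ = trees.bootstrap_support(rep_aln, n_reps=200, seed=2014)
    tree = trees.midpoint_root(tree)
    trees.write_newick(tree, OUT / "repeats_nj.nwk")
    rep_div = hmg.identity_matrix(rep_aln).mean_offdiag()
    print(f"repeat-unit NJ tree ({len(repeats)} leaves, 200 bootstrap reps); "
          f"mean identity {rep_div:.1f}%")

    for region in ("N", "C"):
        path = ROOT / "results" / "variants" / f"variants_{region}.fasta"
        if not path.exists():
            continue
        recs = seqio.read_fasta(path)
        if len(recs) < 3:
            print(f"region {region}: {len(recs)} variants, too few for a tree")
            continue
        aln = align(recs)
        t, _ = trees.bootstrap_support(aln, n_reps=200, seed=2014)
        t = trees.midpoint_root(t)
        trees.write_newick(t, OUT / f"variants_{region}_nj.nwk")
        div = hmg.identity_matrix(aln).mean_offdiag()
        print(f"region {region} variant NJ tree ({len(recs)} leaves); "
              f"mean identity {div:.1f}% "
              f"({'more' if div < rep_div else 'less'} divergent than repeats)")
    print(f"newick trees -> {OUT}")


if __name__ == "__main__":
    main()
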