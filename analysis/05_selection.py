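#!/usr/bin/env python
"""Region-averaged dN/dS across the diagnosed variants.

Codon-aligns the variant consensuses of each region, estimates pairwise
Nei-Gojobori dN/dS, and classifies the selection regime.  Repeat-unit
divergence (within the gene) is summarized the same way for contrast.
Outputs results/selection/dnds.tsv.
"""

from pathlib import Path

from spidroin import selection, seqio
from spidroin.alignment import align

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "selection"


def main() -> None:
    variants_dir = ROOT / "results" / "variants"
    repeats_fa = ROOT / "results" / "decompose" / "repeat_units.fasta"
    if not variants_dir.exists() or not repeats_fa.exists():
        raise SystemExit("run analysis/02 and analysis/04 first")
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    sources = [("N", variants_dir / "variants_N.fasta"),
               ("C", variants_dir / "variants_C.fasta"),
               ("repeat", repeats_fa)]
    for region, path in sources:
        if not path.exists():
            continue
        recs = seqio.read_fasta(path)
        if len(recs) < 2:
            continue
        aln = align(recs, codon=all(len(r) % 3 == 0 for r in recs))
        est = selection.region_dnds(aln, region=region)
        regime = selection.classify(est.ratio_of_means)
        ratio = "NA" if est.ratio_of_means is None else f"{est.ratio_of_means:.3f}"
        rows.append("\t".join([region, f"{est.mean_dN:.4f}", f"{est.mean_dS:.4f}",
                               ratio, regime, str(est.n_pairs)]))
        print(f"{region}: mean dN {est.mean_dN:.4f}, mean dS {est.mean_dS:.4f}, "
              f"dN/dS {ratio} -> {regime} ({est.n_pairs} pairs)")
    header = "# region\tmean_dN\tmean_dS\tdnds_ratio_of_means\tregime\tn_pairs"
    (OUT / "dnds.tsv").write_text("\n".join([header] + rows) + "\n")
    print(f"estimates -> {OUT / 'dnds.tsv'}")


if __name__ == "__main__":
    main()
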