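#!/usr/bin/env python
"""Decompose the gene into its architecture: ORF, repeat period, units.

Input preference: the deposited complete gene (data/reference/
KJ206620.fasta, if fetched) else the synthetic gene from step 01.
Writes the gene model JSON and the repeat-unit FASTA to results/decompose/.
"""

from pathlib import Path

from spidroin import repeat_array, seqio

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "decompose"


def input_fasta() -> Path:
    real = ROOT / "data" / "reference" / "KJ206620.fasta"
    if real.exists():
        return real
    sim = ROOT / "results" / "sim" / "gene.fasta"
    if not sim.exists():
        raise SystemExit("no input gene: run analysis/01_simulate.py first "
                         "(or fetch the reference data)")
    return sim


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    path = input_fasta()
    gene = seqio.read_fasta(path)[0]
    orf_iv = seqio.find_longest_orf(gene)
    orf = gene.slice(orf_iv, id=f"{gene.id}_ORF")
    protein = seqio.translate(orf)
    det = repeat_array.detect_period(orf, min_period=90, max_period=2100)
    model = repeat_array.segment_repeats(orf, det.period_nt)
    model.to_json(OUT / "gene_model.json")
    regions = repeat_array.extract_regions(model, orf)
    seqio.write_fasta(regions.repeats, OUT / "repeat_units.fasta")
    seqio.write_fasta([orf], OUT / "orf.fasta")
    print(f"input: {path.name}")
    print(f"ORF: {len(orf_iv)} nt -> {len(protein.residues.rstrip('*'))} aa")
    print(f"repeat period {det.period_nt} nt (self-similarity {det.score:.3f}); "
          f"{model.n_repeats} units, first {len(model.repeats[0]) // 3} aa, "
          f"last {len(model.repeats[-1]) // 3} aa")
    print(f"gene model and repeat units -> {OUT}")


if __name__ == "__main__":
    main()
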