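#!/usr/bin/env python
"""Generate the study-scale synthetic dataset all later steps analyze.

Builds a spidroin-like gene (20 x 612-nt repeats, truncated 558-nt final
unit, 510/330-nt terminals), evolves a diploid genome with four loci
under point mutation + intragenic gene conversion, and simulates a PCR
clone survey of the terminal regions.  Everything, including the ground
truth, lands in results/sim/.
"""

import json
from dataclasses import asdict
from pathlib import Path

from spidroin.seqio import write_fasta
from spidroin.synthetic_data import SimParams, evolve_loci, simulate_clones, simulate_gene

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 2014

#: the diploid survey individual: 4 loci, terminals diverging 5x faster
#: than the conversion-homogenized repeats
PARAMS = SimParams(seed=SEED, repeat_len_nt=612, n_repeats=20, n_term_len=510,
                   c_term_len=330, last_repeat_len_nt=558, n_loci=4, ploidy=2,
                   mutation_rate=2e-4, terminal_rate_multiplier=5.0,
                   conversion_rate=2.0, n_generations=80, synonymous_bias=0.7,
                   pcr_error_rate=5e-4, clones_per_template=6)

#: the sequenced reference haplotype: one locus homogenized by conversion
#: long enough for repeat identity to settle near the real-data regime
REF_PARAMS = SimParams(seed=SEED, repeat_len_nt=612, n_repeats=20, n_term_len=510,
                       c_term_len=330, last_repeat_len_nt=558, n_loci=1, ploidy=1,
                       mutation_rate=1e-4, terminal_rate_multiplier=5.0,
                       conversion_rate=2.0, n_generations=200, synonymous_bias=0.9)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref_gene, ref_truth = simulate_gene(REF_PARAMS)
    evolve_loci(ref_gene, ref_truth)
    reference = ref_truth.alleles[0]
    reference.id, reference.description = "sim_gene", "evolved reference haplotype"
    write_fasta([reference], OUT / "gene.fasta")
    write_fasta([ref_gene], OUT / "ancestor.fasta")

    gene, truth = simulate_gene(PARAMS)  # same seed/lengths: same ancestor
    evolve_loci(gene, truth)
    write_fasta(truth.alleles, OUT / "alleles.fasta")
    clones, meta = [], []
    for region in ("N", "C"):
        cs = simulate_clones(truth.templates[region], truth, region)
        clones.extend(cs.clones)
        meta.extend("\t".join([c.id, cs.individual, cs.species, region])
                    for c in cs.clones)
    write_fasta(clones, OUT / "clones.fasta")
    (OUT / "clones_meta.tsv").write_text("\n".join(meta) + "\n")
    truth_doc = {
        "params": asdict(PARAMS),
        "model": json.loads(truth.model.to_json()),
        "templates": {r: [t.id for t in ts] for r, ts in truth.templates.items()},
        "template_carriers": truth.template_carriers,
        "clone_template": truth.clone_template,
        "clone_errors": truth.clone_errors,
    }
    (OUT / "truth.json").write_text(json.dumps(truth_doc, indent=2) + "\n")
    n_templates = {r: len(ts) for r, ts in truth.templates.items()}
    print(f"simulated gene of {len(gene)} nt with {PARAMS.n_repeats} repeat units, "
          f"{PARAMS.n_loci} loci x {PARAMS.ploidy} alleles")
    print(f"distinct region templates: {n_templates}")
    print(f"clone survey: {len(clones)} amplicons -> {OUT}")


if __name__ == "__main__":
    main()
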