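#!/usr/bin/env python
"""Diagnose terminal-region variants from the clone survey.

Masks singleton SNPs as polymerase error, discards unsupported clones,
clusters at >95% identical sites, and infers the minimum gene-copy
number per diploid individual.  With simulator truth available the calls
are scored against the true templates.  Outputs to results/variants/.
"""

import json
from pathlib import Path

from spidroin import seqio
from spidroin.pipeline import _read_clone_sets
from spidroin.variant_diagnosis import diagnose

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "variants"


def main() -> None:
    if not (SIM / "clones.fasta").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((SIM / "truth.json").read_text())
    clone_sets = _read_clone_sets(str(SIM / "clones.fasta"),
                                  str(SIM / "clones_meta.tsv"))
    summaries = []
    for cs in clone_sets:
        res = diagnose(cs, threshold_pct=95.0)
        summaries.append(res.summary())
        recs = [seqio.SeqRecord(id=f"{cs.region}|{v.variant_id}",
                                residues=v.consensus.residues, alphabet="nt")
                for v in res.variants]
        seqio.write_fasta(recs, OUT / f"variants_{cs.region}.fasta")
        n_true = len(truth["templates"][cs.region])
        n_masked = len(res.mask_report)
        print(f"region {cs.region}: {len(cs.clones)} clones, {n_masked} cells "
              f"masked as polymerase error, {len(res.discarded_clones)} clones "
              f"discarded, {len(res.variants)} variants "
              f"(true templates: {n_true}) -> minimum {res.min_loci} loci")
    (OUT / "diagnosis.json").write_text(json.dumps(summaries, indent=2) + "\n")
    print(f"variant calls and report -> {OUT}")


if __name__ == "__main__":
    main()
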