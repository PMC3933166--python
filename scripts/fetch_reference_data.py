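#!/usr/bin/env python
"""Download the public GenBank records behind the published-sequence checks.

Requires network access to NCBI E-utilities; run once on a connected
machine, then the reference-data tests under tests/test_acceptance.py can
replay the published analyses offline.

Writes to data/reference/:
    KJ206620.fasta      complete Argiope argentata AcSp1 gene
    KJ206570-KJ206619/  the 50 deposited terminal/repeat variant records
                        (one multi-FASTA, variants_raw.fasta)

The per-region variant FASTAs (variants_nterm/repeat/cterm.fasta) and the
four-species consensus-repeat file (consensus_repeats_aa.fasta) must be
curated from the raw records and the published supplementary tables,
since the region assignment of each accession is not encoded in the
sequence records themselves.
"""

from __future__ import annotations

import sys
import time
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
OUT = Path(__file__).resolve().parents[1] / "data" / "reference"


def efetch(ids: str) -> str:
    url = f"{EUTILS}?db=nuccore&id={ids}&rettype=fasta&retmode=text"
    with urllib.request.urlopen(url, timeout=60) as fh:
        return fh.read().decode()


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    print("fetching KJ206620 (complete gene) ...", file=sys.stderr)
    (OUT / "KJ206620.fasta").write_text(efetch("KJ206620"))
    time.sleep(0.5)
    print("fetching KJ206570-KJ206619 (variants) ...", file=sys.stderr)
    ids = ",".join(f"KJ2065{n}" if n >= 70 else f"KJ2066{n:02d}"
                   for n in list(range(70, 100))) \
        + "," + ",".join(f"KJ2066{n:02d}" for n in range(0, 20))
    (OUT / "variants_raw.fasta").write_text(efetch(ids))
    print(f"wrote reference data under {OUT}", file=sys.stderr)


if __name__ == "__main__":
    main()
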