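#!/usr/bin/env python
"""Fetch the PP171485 ORF from NCBI and verify its protein statistics.

Requires network access (NCBI efetch).  Downloads the nucleotide FASTA,
translates it with the standard genetic code, and prints the ORF length,
protein length, and average molecular mass — which should come out at
1137 bp, 378 aa and 42.8 kDa.

    python scripts/fetch_pp171485.py [--out pp171485.fasta]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

from haloquant.seqstats import average_molecular_mass, orf_protein_length, translate

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id=PP171485&rettype=fasta&retmode=text"
)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=None, help="Save the FASTA here.")
    args = parser.parse_args()

    try:
        with urllib.request.urlopen(EFETCH, timeout=30) as resp:
            text = resp.read().decode()
    except OSError as exc:
        print(f"error: could not reach NCBI ({exc}); network access is required",
              file=sys.stderr)
        return 1
    lines = text.strip().splitlines()
    if not lines or not lines[0].startswith(">"):
        print("error: unexpected efetch response", file=sys.stderr)
        return 1
    seq = "".join(lines[1:])
    if args.out is not None:
        args.out.write_text(text)

    protein = translate(seq)
    mass = average_molecular_mass(protein)
    print(f"ORF length      : {len(seq)} bp")
    print(f"Protein length  : {protein.length_aa} aa "
          f"(arithmetic check: {orf_protein_length(len(seq))})")
    print(f"Average mass    : {mass:.1f} Da = {mass / 1000:.1f} kDa")
    ok = len(seq) == 1137 and protein.length_aa == 378 and round(mass / 1000, 1) == 42.8
    print("PASS" if ok else "MISMATCH")
    return 0 if ok else 2


if __name__ == "__main__":
    sys.exit(main())
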