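#!/usr/bin/env python
"""Fetch the deposited Chilean bull-kelp COI/rbcL sequences from GenBank.

Optional helper for the real-data analysis tier; requires network access and
is never used by the test suite.  Downloads the accessions deposited for the
Chilean dataset (FJ550093-FJ550095, FJ550097, FJ550099, FJ550119 and
HM103936-HM104173) as a single FASTA file.  Sequences still need trimming to
a common aligned fragment (629 bp COI / 886 bp rbcL) before analysis.

Usage:
    python scripts/fetch_genbank.py --email you@example.org --out chile.fasta
"""

from __future__ import annotations

import argparse

from Bio import Entrez, SeqIO

ACCESSIONS = (
    ["FJ550093", "FJ550094", "FJ550095", "FJ550097", "FJ550099", "FJ550119"]
    + [f"HM{n}" for n in range(103936, 104174)]
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI requires a contact email")
    parser.add_argument("--out", required=True)
    args = parser.parse_args()

    Entrez.email = args.email
    with Entrez.efetch(
        db="nucleotide", id=",".join(ACCESSIONS), rettype="fasta", retmode="text"
    ) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    SeqIO.write(records, args.out, "fasta")
    print(f"wrote {len(records)} records to {args.out}")


if __name__ == "__main__":
    main()
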