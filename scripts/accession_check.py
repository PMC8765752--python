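#!/usr/bin/env python
"""K2P distance between two complete mitogenomes, via mafft alignment.

Give either two local FASTA files or two GenBank accessions (fetched
over the network with Biopython's Entrez, which requires internet
access and an e-mail address per NCBI policy). The two sequences are
globally aligned with mafft and Kimura's two-parameter distance is
computed over ungapped, unambiguous columns.

Examples:
    python scripts/accession_check.py host.fasta donor.fasta
    python scripts/accession_check.py MW662607 MW662591 --email you@lab.org
"""

from __future__ import annotations

import argparse
import sys
import tempfile
from pathlib import Path

from clamtc.phylo import k2p_between_fasta


def _fetch(accession: str, email: str, tmp: Path) -> Path:
    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(db="nuccore", id=accession, rettype="fasta",
                       retmode="text") as handle:
        out = tmp / f"{accession}.fasta"
        out.write_text(handle.read())
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("a", help="FASTA path or GenBank accession")
    ap.add_argument("b", help="FASTA path or GenBank accession")
    ap.add_argument("--email", default=None,
                    help="contact e-mail, required when fetching accessions")
    args = ap.parse_args()

    with tempfile.TemporaryDirectory() as tmpdir:
        tmp = Path(tmpdir)
        paths = []
        for token in (args.a, args.b):
            if Path(token).exists():
                paths.append(Path(token))
            else:
                if not args.email:
                    sys.exit(f"{token!r} is not a file; pass --email to fetch "
                             "it from GenBank")
                paths.append(_fetch(token, args.email, tmp))
        d = k2p_between_fasta(paths[0], paths[1])
    print(f"K2P distance: {d:.4f} ({100 * d:.2f}%)")


if __name__ == "__main__":
    main()
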