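#!/usr/bin/env python
"""Fetch the eleven study genomes (LC386195-LC386205) into
data/study_genomes.fasta.

Needs network access to NCBI E-utilities; the package and its test suite
never require the download — only the two acceptance checks that compare
against the deposited records do.  Run once from the repository root:

    python scripts/fetch_study_genomes.py
"""

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = [f"LC386{195 + k}" for k in range(11)]

URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={ids}&rettype=fasta&retmode=text"
)


def main() -> int:
    out = Path(__file__).resolve().parents[1] / "data" / "study_genomes.fasta"
    out.parent.mkdir(exist_ok=True)
    url = URL.format(ids=",".join(ACCESSIONS))
    print(f"fetching {len(ACCESSIONS)} records from NCBI ...", file=sys.stderr)
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            text = resp.read().decode()
    except OSError as e:
        print(f"fetch failed ({e}); network access to NCBI is required",
              file=sys.stderr)
        return 1
    n = text.count(">")
    if n != len(ACCESSIONS):
        print(f"expected {len(ACCESSIONS)} records, got {n}; not writing",
              file=sys.stderr)
        return 1
    out.write_text(text)
    print(f"wrote {out}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
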