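"""Download the 11 hillstream-loach mitogenome GenBank records from NCBI.

Usage:
    python scripts/fetch_accessions.py [--outdir data/accessions]

Requires network access; the library itself never downloads anything.
The files enable the accession regression test in tests/test_acceptance.py.
"""

from __future__ import annotations

import argparse
import time
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "OR350601",    # P. fasciatus jiulongjiangensis
    "OR353705",    # P. myersi
    "MN123556.1",  # P. fangi
    "MZ853163.1",  # P. cheni
    "MZ853164.1",  # P. laticeps
    "MZ853166.1",  # P. lianjiangensis
    "NC_046437.1", # P. changtingensis changtingensis
    "NC_046438.1", # P. changtingensis tungpeiensis
    "NC_046441.1", # P. fasciatus fasciatus
    "NC_046445.1", # P. meihuashanensis
    "NC_046446.1", # P. peristictus
]

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text"
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="data/accessions")
    args = parser.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        stem = acc.split(".")[0]
        target = outdir / f"{stem}.gb"
        if target.exists():
            print(f"{target} already present")
            continue
        url = EFETCH.format(acc=acc)
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(url, timeout=60) as response:
            target.write_bytes(response.read())
        time.sleep(0.4)  # NCBI rate courtesy
    print(f"done; files in {outdir}")


if __name__ == "__main__":
    main()
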