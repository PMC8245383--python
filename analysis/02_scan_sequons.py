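"""Scan every protein for N-glycosylation sequons and tabulate the yield.

NxS/NxT are the canonical classes; NxC and NxV are also scanned here so
the downstream enrichment step can contrast them.
"""

import argparse
from pathlib import Path

from cmglyco import io as cio
from cmglyco.sequon import scan_proteome


def main(fasta: str = "results/simulated/proteins.fasta",
         outdir: str = "results/sequons") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = cio.read_fasta(fasta)
    sites = scan_proteome(records, ["NxS", "NxT", "NxC", "NxV"])
    cio.write_tsv(sites, out / "sequon_sites.tsv")

    by_class = sites.motif_class.value_counts()
    n_with_site = sites.protein_id.nunique()
    print(f"{len(records)} proteins scanned, {len(sites)} sequon sites")
    print(f"per class: {by_class.to_dict()}")
    print(f"{n_with_site} proteins carry at least one site")
    print(f"site table -> {out / 'sequon_sites.tsv'}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fasta", default="results/simulated/proteins.fasta")
    parser.add_argument("--outdir", default="results/sequons")
    args = parser.parse_args()
    main(args.fasta, args.outdir)
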