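"""Test sequon-motif enrichment in surface vs intracellular protein sets.

Surface = SPC score 3-4; intracellular = SPC score 0. For each motif class
the observed site count is compared to a per-sequence residue-shuffling
null. The scientific contrast: canonical NxS/T sequons should behave
differently from the proposed NxC/NxV variants between the two sets.
"""

import argparse
from pathlib import Path

import pandas as pd

from cmglyco import io as cio
from cmglyco.enrichment import NullConfig, compare_sets, results_to_frame
from cmglyco.surface import SpcTable


def main(fasta: str = "results/simulated/proteins.fasta",
         spc_path: str = "results/simulated/spc.tsv",
         outdir: str = "results/enrichment",
         n_permutations: int = 1000,
         seed: int = 1) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = [r for r in cio.read_fasta(fasta) if r.role == "canonical"]
    spc = SpcTable.from_tsv(spc_path)
    surface = [r for r in records if (spc.get(r.gene_symbol) or 0) >= 3]
    intra = [r for r in records if spc.get(r.gene_symbol) == 0]
    results = compare_sets(
        surface, intra, ["NxS", "NxT", "NxC", "NxV"],
        NullConfig(n_permutations=n_permutations, seed=seed),
    )
    frame = results_to_frame(results)
    cio.write_tsv(frame, out / "enrichment.tsv", {"seed": seed})

    print(f"surface set: {len(surface)} proteins; "
          f"intracellular set: {len(intra)} proteins")
    with pd.option_context("display.width", 120):
        print(frame.to_string(index=False))
    print("(the generator plants NxS/T sequons into every protein, so those "
          "classes exceed the shuffle null in both sets; NxC/NxV are never "
          "planted and hover at or below 1. No surface-specific bias is "
          "simulated, so the two sets behave alike.)")
    print(f"table -> {out / 'enrichment.tsv'}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fasta", default="results/simulated/proteins.fasta")
    parser.add_argument("--spc", default="results/simulated/spc.tsv")
    parser.add_argument("--outdir", default="results/enrichment")
    parser.add_argument("--n-permutations", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    main(args.fasta, args.spc, args.outdir, args.n_permutations, args.seed)
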