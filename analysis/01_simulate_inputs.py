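"""Generate the synthetic study inputs every later analysis step consumes.

Emulates the full experimental design: a canonical proteome with splice
isoforms (and coordinate-derived sequon-change ground truth), RNA-seq
counts for differentiation days 15/30/45/60 in triplicate with planted
fold changes, sparse PSM tables with late-onset surface proteins, and SPC
surface-prediction scores.
"""

import argparse
from pathlib import Path

import pandas as pd

from cmglyco import io as cio
from cmglyco.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_isoforms,
    simulate_proteome,
    simulate_psm,
    simulate_spc,
)


def main(seed: int = 1, outdir: str = "results/simulated") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=seed, n_proteins=300, isoforms_per_canonical=2)
    meta = {"seed": seed}

    proteome = simulate_proteome(config)
    isoforms, truth = simulate_isoforms(proteome, config)
    cio.write_fasta(proteome + isoforms, out / "proteins.fasta")
    cio.write_tsv(truth, out / "truth_sequon_changes.tsv", meta)

    genes = [r.gene_symbol for r in proteome]
    matrix, count_truth = simulate_counts(config, genes)
    with open(out / "counts.tsv", "w") as fh:
        fh.write(f"# seed: {seed}\n")
        matrix.counts.to_csv(fh, sep="\t")
    cio.write_tsv(matrix.metadata, out / "samples.tsv", meta)
    cio.write_tsv(count_truth, out / "truth_fold_changes.tsv", meta)

    psm, psm_truth = simulate_psm(genes, config)
    long = psm.stack().rename("psm_count").reset_index()
    long.columns = ["protein", "day", "psm_count"]
    cio.write_tsv(long, out / "psm.tsv", meta)
    cio.write_tsv(psm_truth, out / "truth_psm.tsv", meta)

    spc = simulate_spc(genes, config)
    cio.write_tsv(
        pd.DataFrame({"gene_symbol": genes,
                      "spc_score": [spc.get(g) for g in genes]}),
        out / "spc.tsv", meta,
    )

    print(f"proteome: {len(proteome)} canonicals, {len(isoforms)} isoforms")
    print(f"truth labels: {truth.status.value_counts().to_dict()}")
    print(f"counts: {matrix.counts.shape[0]} genes x {matrix.counts.shape[1]} samples")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results/simulated")
    args = parser.parse_args()
    main(args.seed, args.outdir)
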