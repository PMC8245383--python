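"""Surface-prediction (SPC) annotation and filtering.

The surface prediction consensus (SPC) score is an integer 0-4 combining
several cell-surface localization predictors; 3-4 is a high-confidence
surface prediction. Score 0 is *not* evidence of intracellular localization
(GPI-anchored and extracellular-matrix proteins also score 0), so missing
genes are marked missing rather than silently scored 0. Topology annotations
(transmembrane-domain counts, signal peptides) are consumed from an external
predictor's output, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

MISSING = pd.NA
VALID_SCORES = frozenset({0, 1, 2, 3, 4})


class SpcTable:
    """Mapping gene_symbol -> SPC score (integer 0-4).

    Lookups are exact-match first, then case-insensitive, to tolerate
    mixed-source symbol casing.
    """

    def __init__(self, scores: Mapping[str, int]):
        self._exact = {}
        self._folded = {}
        for gene, score in scores.items():
            score = int(score)
            if score not in VALID_SCORES:
                raise ValueError(f"SPC score for {gene!r} outside 0-4: {score}")
            self._exact[gene] = score
            self._folded.setdefault(gene.upper(), score)

    def __len__(self) -> int:
        return len(self._exact)

    def get(self, gene: str) -> Optional[int]:
        if gene in self._exact:
            return self._exact[gene]
        return self._folded.get(gene.upper())

    @classmethod
    def from_tsv(cls, path) -> "SpcTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"gene_symbol", "spc_score"} <= set(df.columns):
            raise ValueError(
                f"SPC table needs columns gene_symbol, spc_score; got {list(df.columns)}"
            )
        return cls(dict(zip(df.gene_symbol, df.spc_score)))


@dataclass(frozen=True)
class TopologyAnnotation:
    """Consumed topology facts for one protein (from an external predictor)."""

    protein_id: str
    n_tm_domains: int
    has_signal_peptide: bool
    source: str = ""

    def __post_init__(self) -> None:
        if self.n_tm_domains < 0:
            raise ValueError("n_tm_domains must be >= 0")


def read_topology_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"protein_id", "n_tm_domains", "has_signal_peptide"}
    if not need <= set(df.columns):
        raise ValueError(f"topology table needs columns {sorted(need)}")
    if (df.n_tm_domains < 0).any():
        raise ValueError("negative transmembrane-domain count")
    return df


def annotate_spc(
    genes: Iterable[str], table: SpcTable, missing_policy: str = "mark"
) -> pd.DataFrame:
    """Attach SPC scores to genes.

    missing_policy: "mark" records missing genes with a NA score;
    "drop" omits them; "error" raises on the first unknown gene.
    """
    if missing_policy not in ("mark", "drop", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    rows = []
    for gene in genes:
        score = table.get(gene)
        if score is None:
            if missing_policy == "error":
                raise KeyError(f"gene {gene!r} absent from SPC table")
            if missing_policy == "drop":
                continue
            rows.append((gene, MISSING))
        else:
            rows.append((gene, score))
    return pd.DataFrame(rows, columns=["gene_symbol", "spc_score"]).astype(
        {"spc_score": "Int64"}
    )


def high_confidence_filter(annotated: pd.DataFrame, threshold: int = 3) -> pd.DataFrame:
    """Retain genes with SPC score >= threshold (default 3-4 = high confidence).

    Genes with a missing score are always excluded: absence of a prediction
    is not a surface prediction.
    """
    mask = annotated["spc_score"].notna() & (annotated["spc_score"] >= threshold)
    return annotated[mask].reset_index(drop=True)
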