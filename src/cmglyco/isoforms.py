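"""Canonical-vs-isoform sequon comparison.

Alternative splicing rearranges coding sequence, so an N-glycosylation
sequon present in a canonical protein may be *retained* at the same
coordinate in a predicted isoform, *shifted* to a different coordinate,
*lost* altogether, or a sequon may be *gained* that the canonical sequence
lacks. Correspondence between canonical and isoform coordinates is
established by global pairwise alignment (BLOSUM62, affine gaps), since
splice-event coordinates are not recoverable from protein sequences alone.

Classification operates on the Asn coordinate only: a canonical sequon is
retained when its Asn aligns to the same absolute isoform coordinate and a
valid sequon exists there, shifted when a valid sequon exists at a different
aligned coordinate, and lost when the Asn falls in a gap or the aligned
position no longer completes a sequon. Isoform sequons not matched by any
canonical sequon are gained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord, RecordError
from .sequon import SequonSite

GAP = None  # sentinel for an unaligned (gap) coordinate


@dataclass(frozen=True)
class ScoringConfig:
    """Global-alignment scoring: substitution matrix and affine gap costs."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


def _make_aligner(config: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    # First gap residue costs open, each further residue costs extend.
    aligner.open_gap_score = -float(config.gap_open)
    aligner.extend_gap_score = -float(config.gap_extend)
    return aligner


@dataclass
class AlignmentMap:
    """Column-wise coordinate correspondence from a global alignment.

    ``columns`` lists ``(canonical_pos, isoform_pos)`` pairs in alignment
    order; a ``None`` entry marks a gap in that track. Positions are 1-based.
    """

    canonical_id: str
    isoform_id: str
    columns: List[Tuple[Optional[int], Optional[int]]]
    score: float
    canonical_length: int = 0
    isoform_length: int = 0
    _forward: Dict[int, Optional[int]] = field(default_factory=dict, repr=False)
    _reverse: Dict[int, Optional[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for c, i in self.columns:
            if c is GAP and i is GAP:
                raise ValueError("alignment column with gaps in both tracks")
            if c is not GAP:
                self._forward[c] = i
            if i is not GAP:
                self._reverse[i] = c
        if not self.canonical_length:
            self.canonical_length = len(self._forward)
        if not self.isoform_length:
            self.isoform_length = len(self._reverse)
        if len(self._forward) != self.canonical_length:
            raise ValueError("alignment does not cover the canonical sequence")
        if len(self._reverse) != self.isoform_length:
            raise ValueError("alignment does not cover the isoform sequence")

    def map_position(self, canonical_pos: int) -> Optional[int]:
        """Isoform coordinate aligned to ``canonical_pos``, or GAP (None)."""
        if not 1 <= canonical_pos <= self.canonical_length:
            raise IndexError(
                f"canonical position {canonical_pos} outside 1..{self.canonical_length}"
            )
        return self._forward[canonical_pos]

    def map_back(self, isoform_pos: int) -> Optional[int]:
        """Canonical coordinate aligned to ``isoform_pos``, or GAP (None)."""
        if not 1 <= isoform_pos <= self.isoform_length:
            raise IndexError(
                f"isoform position {isoform_pos} outside 1..{self.isoform_length}"
            )
        return self._reverse[isoform_pos]


def align_pair(
    canonical: ProteinRecord,
    isoform: ProteinRecord,
    scoring: ScoringConfig = ScoringConfig(),
) -> AlignmentMap:
    """Globally align an isoform to its canonical parent.

    The highest-scoring alignment is used; among co-optimal tracebacks the
    aligner's first enumeration is taken, which is deterministic for fixed
    inputs and scoring.
    """
    if not canonical.sequence or not isoform.sequence:
        raise RecordError("cannot align empty sequences")
    if isoform.parent_id is not None and isoform.parent_id != canonical.id:
        raise RecordError(
            f"isoform {isoform.id!r} is not a child of canonical {canonical.id!r}"
        )
    aligner = _make_aligner(scoring)
    aln = aligner.align(canonical.sequence, isoform.sequence)[0]
    # indices: 2 x ncols array of 0-based coordinates, -1 at gaps
    idx = aln.indices
    columns: List[Tuple[Optional[int], Optional[int]]] = [
        (
            int(idx[0, k]) + 1 if idx[0, k] >= 0 else GAP,
            int(idx[1, k]) + 1 if idx[1, k] >= 0 else GAP,
        )
        for k in range(idx.shape[1])
    ]
    return AlignmentMap(
        canonical_id=canonical.id,
        isoform_id=isoform.id,
        columns=columns,
        score=float(aln.score),
        canonical_length=len(canonical.sequence),
        isoform_length=len(isoform.sequence),
    )


@dataclass(frozen=True)
class SequonChange:
    """Classification of one sequon in a canonical-isoform pair."""

    canonical_id: str
    isoform_id: str
    status: str  # retained | shifted | lost | gained
    canonical_site: Optional[SequonSite] = None
    isoform_site: Optional[SequonSite] = None

    def __post_init__(self) -> None:
        if self.status in ("retained", "shifted"):
            assert self.canonical_site is not None and self.isoform_site is not None
        elif self.status == "lost":
            assert self.canonical_site is not None and self.isoform_site is None
        elif self.status == "gained":
            assert self.canonical_site is None and self.isoform_site is not None
        else:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "retained":
            assert self.canonical_site.position == self.isoform_site.position
        if self.status == "shifted":
            assert self.canonical_site.position != self.isoform_site.position


def classify_pair(
    canonical: ProteinRecord,
    isoform: ProteinRecord,
    canonical_sites: Sequence[SequonSite],
    isoform_sites: Sequence[SequonSite],
    amap: AlignmentMap,
) -> List[SequonChange]:
    """Classify every sequon of both sequences as retained/shifted/lost/gained.

    Each sequon of either sequence appears in exactly one
    :class:`SequonChange`; per pair, retained + shifted + lost equals the
    canonical sequon count and gained never exceeds the isoform count.
    """
    if (
        amap.canonical_length != len(canonical.sequence)
        or amap.isoform_length != len(isoform.sequence)
    ):
        raise ValueError("alignment map does not cover both sequences")
    iso_by_pos = {s.position: s for s in isoform_sites}
    changes: List[SequonChange] = []
    matched_iso = set()
    for site in sorted(canonical_sites, key=lambda s: s.position):
        q = amap.map_position(site.position)
        partner = iso_by_pos.get(q) if q is not GAP else None
        if partner is not None:
            status = "retained" if q == site.position else "shifted"
            changes.append(
                SequonChange(
                    canonical.id, isoform.id, status,
                    canonical_site=site, isoform_site=partner,
                )
            )
            matched_iso.add(q)
        else:
            changes.append(
                SequonChange(canonical.id, isoform.id, "lost", canonical_site=site)
            )
    for site in sorted(isoform_sites, key=lambda s: s.position):
        if site.position in matched_iso:
            continue
        changes.append(
            SequonChange(canonical.id, isoform.id, "gained", isoform_site=site)
        )
    return changes


def changes_to_frame(changes: Sequence[SequonChange]) -> pd.DataFrame:
    """Flatten SequonChange objects into a tidy table."""
    rows = []
    for ch in changes:
        rows.append(
            {
                "canonical_id": ch.canonical_id,
                "isoform_id": ch.isoform_id,
                "status": ch.status,
                "canonical_pos": ch.canonical_site.position if ch.canonical_site else pd.NA,
                "isoform_pos": ch.isoform_site.position if ch.isoform_site else pd.NA,
                "canonical_triplet": ch.canonical_site.triplet if ch.canonical_site else "",
                "isoform_triplet": ch.isoform_site.triplet if ch.isoform_site else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "canonical_id", "isoform_id", "status",
            "canonical_pos", "isoform_pos",
            "canonical_triplet", "isoform_triplet",
        ],
    )


@dataclass
class ChangeSummary:
    """Per-pair and global tallies of sequon changes.

    ``total_differing_sites`` counts shifted+lost+gained per
    canonical-isoform pair (a site affected in two isoforms counts twice);
    ``n_unique_differing_sites`` deduplicates canonical sites by
    (canonical_id, position) and gained sites by (isoform_id, position).
    Protein-level counts deduplicate by canonical id across isoforms.
    """

    per_pair: pd.DataFrame
    n_retained: int
    n_shifted: int
    n_lost: int
    n_gained: int
    total_differing_sites: int
    n_unique_differing_sites: int
    n_proteins_with_any_difference: int
    n_proteins_with_lost: int
    n_proteins_with_gained: int
    fraction_shifted: float
    fraction_lost: float
    fraction_gained: float

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_retained", "n_shifted", "n_lost", "n_gained",
                "total_differing_sites", "n_unique_differing_sites",
                "n_proteins_with_any_difference",
                "n_proteins_with_lost", "n_proteins_with_gained",
                "fraction_shifted", "fraction_lost", "fraction_gained",
            )
        }
        return d


def summarize(
    changes: Sequence[SequonChange],
    gene_map: Optional[Mapping[str, str]] = None,
) -> ChangeSummary:
    """Aggregate classified changes into per-pair and global tallies."""
    df = changes_to_frame(changes)
    if df.empty:
        per_pair = pd.DataFrame(
            columns=[
                "canonical_id", "isoform_id",
                "n_retained", "n_shifted", "n_lost", "n_gained",
            ]
        )
        return ChangeSummary(per_pair, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0)
    counts = (
        df.groupby(["canonical_id", "isoform_id", "status"])
        .size()
        .unstack("status", fill_value=0)
        .reindex(columns=["retained", "shifted", "lost", "gained"], fill_value=0)
        .rename(columns=lambda s: f"n_{s}")
        .reset_index()
    )
    if gene_map is not None:
        counts.insert(
            1, "gene_symbol", counts["canonical_id"].map(dict(gene_map))
        )
    n_ret = int((df.status == "retained").sum())
    n_shift = int((df.status == "shifted").sum())
    n_lost = int((df.status == "lost").sum())
    n_gain = int((df.status == "gained").sum())
    total_diff = n_shift + n_lost + n_gain
    diff = df[df.status != "retained"]
    can_side = diff[diff.status.isin(["shifted", "lost"])]
    uniq = len(
        can_side[["canonical_id", "canonical_pos"]].drop_duplicates()
    ) + len(
        diff[diff.status == "gained"][["isoform_id", "isoform_pos"]].drop_duplicates()
    )
    prot_any = diff["canonical_id"].nunique()
    prot_lost = diff.loc[diff.status == "lost", "canonical_id"].nunique()
    prot_gain = diff.loc[diff.status == "gained", "canonical_id"].nunique()
    if total_diff:
        fs, fl, fg = (n_shift / total_diff, n_lost / total_diff, n_gain / total_diff)
    else:
        fs = fl = fg = 0.0
    return ChangeSummary(
        per_pair=counts,
        n_retained=n_ret, n_shifted=n_shift, n_lost=n_lost, n_gained=n_gain,
        total_differing_sites=total_diff,
        n_unique_differing_sites=uniq,
        n_proteins_with_any_difference=prot_any,
        n_proteins_with_lost=prot_lost,
        n_proteins_with_gained=prot_gain,
        fraction_shifted=fs, fraction_lost=fl, fraction_gained=fg,
    )
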