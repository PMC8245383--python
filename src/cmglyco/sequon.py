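"""N-glycosylation sequon scanning.

The canonical N-glycosylation consensus is the tripeptide N-x-S/T where x is
any residue except proline; Asn-x-Cys is part of the quoted consensus and
Asn-x-Val has been proposed as a further non-canonical variant. Each motif
class is named by its third residue: ``NxS``, ``NxT``, ``NxC``, ``NxV``.
``NxS`` and ``NxT`` are the default classes; ``NxC``/``NxV`` are optional
because their presence alone is weak evidence of surface N-glycosylation.

Coordinates are 1-based and index the Asn residue. An unknown residue 'X' at
any of the three sequon positions disqualifies the site: a site cannot be
asserted from unknown residues. Proline is only excluded at the x position;
the consensus states no constraint at +2 beyond the class letter itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import pandas as pd

from .records import ProteinRecord, RecordError

#: Motif class -> required third residue.
MOTIF_THIRD: Dict[str, str] = {"NxS": "S", "NxT": "T", "NxC": "C", "NxV": "V"}

#: Classes the published isoform analysis used ("only NxS and NxT").
DEFAULT_CLASSES = frozenset({"NxS", "NxT"})

#: All supported classes, including the proposed non-canonical variants.
ALL_CLASSES = frozenset(MOTIF_THIRD)

FLANK = 5  # residues kept on either side of the Asn in the report


@dataclass(frozen=True)
class SequonSite:
    """One predicted N-glycosylation sequon.

    ``position`` is the 1-based coordinate of the Asn; ``triplet`` is the
    N-x-? window and ``flank`` a +/-5 residue context clipped at the termini.
    """

    protein_id: str
    position: int
    motif_class: str
    triplet: str
    flank: str

    def __post_init__(self) -> None:
        assert self.triplet[0] == "N" and self.triplet[1] != "P"
        assert self.triplet[2] == MOTIF_THIRD[self.motif_class]


def _check_classes(motif_classes: Iterable[str]) -> Set[str]:
    classes = set(motif_classes)
    if not classes:
        raise ValueError("motif_classes must be non-empty")
    unknown = classes - ALL_CLASSES
    if unknown:
        raise ValueError(f"unknown motif classes: {sorted(unknown)}")
    return classes


def find_sequons(
    record: ProteinRecord, motif_classes: Iterable[str] = DEFAULT_CLASSES
) -> List[SequonSite]:
    """Return all sequon sites of the requested classes, sorted by position.

    Overlapping sequons (e.g. ``NNSS`` -> sites at 1 and 2) are each
    reported. Sites whose triplet contains 'X' are never reported.
    """
    classes = _check_classes(motif_classes)
    if not record.sequence:
        raise RecordError(f"record {record.id!r}: empty sequence")
    thirds = {MOTIF_THIRD[c]: c for c in classes}
    seq = record.sequence
    sites: List[SequonSite] = []
    for i in range(len(seq) - 2):
        if seq[i] != "N":
            continue
        x, third = seq[i + 1], seq[i + 2]
        if x == "P" or x == "X":
            continue
        cls = thirds.get(third)
        if cls is None:
            continue
        pos = i + 1  # 1-based Asn coordinate
        flank = seq[max(0, i - FLANK) : i + 3 + FLANK]
        sites.append(
            SequonSite(
                protein_id=record.id,
                position=pos,
                motif_class=cls,
                triplet=seq[i : i + 3],
                flank=flank,
            )
        )
    return sites


def scan_proteome(
    records: Sequence[ProteinRecord],
    motif_classes: Iterable[str] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Scan every record and return one row per sequon site.

    The table is ordered by (protein_id, position) and has columns
    ``protein_id, position, motif_class, triplet, flank``.
    """
    classes = _check_classes(motif_classes)
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise RecordError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
    rows = [
        (s.protein_id, s.position, s.motif_class, s.triplet, s.flank)
        for rec in records
        for s in find_sequons(rec, classes)
    ]
    df = pd.DataFrame(
        rows, columns=["protein_id", "position", "motif_class", "triplet", "flank"]
    )
    return df.sort_values(["protein_id", "position"], kind="stable").reset_index(
        drop=True
    )
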