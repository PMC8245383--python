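"""Protein sequence records for the glycoproteogenomics pipeline.

A :class:`ProteinRecord` carries one amino-acid sequence together with its
role in a canonical/isoform pair. Splice isoforms predicted from RNA-seq are
linked back to their canonical parent through ``parent_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

#: The 20 standard amino acids; 'X' (unknown residue) is tolerated in input.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(STANDARD_AA + "X")


class RecordError(ValueError):
    """Raised for malformed or inconsistent protein records."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with canonical/isoform role.

    Parameters
    ----------
    id : str
        Unique record identifier.
    sequence : str
        Uppercase amino-acid sequence (20 standard letters; 'X' tolerated).
    role : str
        Either ``"canonical"`` or ``"isoform"``.
    parent_id : str, optional
        Identifier of the canonical record; required when ``role="isoform"``.
    gene_symbol : str, optional
        Gene symbol used for SPC and expression lookups.
    event_note : str, optional
        Free-text descriptor of the splice event that produced an isoform.
    """

    id: str
    sequence: str
    role: str = "canonical"
    parent_id: Optional[str] = None
    gene_symbol: Optional[str] = None
    event_note: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("record id must be non-empty")
        if not self.sequence:
            raise RecordError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - ALPHABET
        if bad:
            raise RecordError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )
        if self.role not in ("canonical", "isoform"):
            raise RecordError(f"record {self.id!r}: unknown role {self.role!r}")
        if self.role == "isoform" and not self.parent_id:
            raise RecordError(
                f"record {self.id!r}: role=isoform requires parent_id"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def validate_parentage(records: Iterable[ProteinRecord]) -> None:
    """Check that every isoform's ``parent_id`` names a canonical record.

    Raises
    ------
    RecordError
        On duplicate ids or dangling/invalid parent references.
    """
    records = list(records)
    by_id = {}
    for rec in records:
        if rec.id in by_id:
            raise RecordError(f"duplicate record id {rec.id!r}")
        by_id[rec.id] = rec
    for rec in records:
        if rec.role == "isoform":
            parent = by_id.get(rec.parent_id)
            if parent is None:
                raise RecordError(
                    f"isoform {rec.id!r}: parent {rec.parent_id!r} not found"
                )
            if parent.role != "canonical":
                raise RecordError(
                    f"isoform {rec.id!r}: parent {rec.parent_id!r} is not canonical"
                )
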