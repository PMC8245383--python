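"""Readers and writers for the pipeline's on-disk formats.

FASTA is the interchange format for protein sequences; record metadata
travels in the description line as ``key=value`` tokens (``role=``,
``parent=``, ``gene=``, ``event=``). All tables are TSV; the deposited
splice-isoform supplementary table can be read from XLSX or TSV with a
user-supplied column map, since its schema is not standardized. Tabular
outputs carry ``#``-prefixed header lines embedding the run seed and
config hash; all coordinates in outputs are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CountMatrix
from .records import ProteinRecord, RecordError, validate_parentage

logger = logging.getLogger(__name__)


def _parse_metadata(description: str) -> Dict[str, str]:
    meta = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def read_fasta(path) -> List[ProteinRecord]:
    """Load protein records, parsing role/parent/gene metadata from headers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[ProteinRecord] = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        seq = str(seq_rec.seq).upper()
        if "*" in seq:
            warnings.warn(
                f"record {seq_rec.id!r}: stripping stop character(s) '*'",
                stacklevel=2,
            )
            seq = seq.replace("*", "")
        if not seq:
            raise RecordError(f"record {seq_rec.id!r}: header without sequence")
        meta = _parse_metadata(seq_rec.description)
        records.append(
            ProteinRecord(
                id=seq_rec.id,
                sequence=seq,
                role=meta.get("role", "canonical"),
                parent_id=meta.get("parent"),
                gene_symbol=meta.get("gene"),
                event_note=meta.get("event"),
            )
        )
    if not records:
        warnings.warn(f"no records in {path}", stacklevel=2)
    validate_parentage(records)
    return records


def write_fasta(records, path) -> None:
    seq_records = []
    for rec in records:
        tokens = [f"role={rec.role}"]
        if rec.parent_id:
            tokens.append(f"parent={rec.parent_id}")
        if rec.gene_symbol:
            tokens.append(f"gene={rec.gene_symbol}")
        if rec.event_note:
            tokens.append(f"event={rec.event_note}")
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.id, description=" ".join(tokens))
        )
    SeqIO.write(seq_records, str(path), "fasta")


def read_isoform_table(
    path, column_map: Mapping[str, str]
) -> Tuple[List[Tuple[ProteinRecord, ProteinRecord]], int]:
    """Read canonical/isoform sequence pairs from an XLSX or TSV table.

    ``column_map`` names the file's columns for keys ``canonical_id``,
    ``canonical_seq``, ``isoform_id``, ``isoform_seq`` (optional ``gene``).
    Returns the record pairs and the number of rows skipped for empty
    sequences.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    need = ["canonical_id", "canonical_seq", "isoform_id", "isoform_seq"]
    missing = [k for k in need if column_map.get(k) not in df.columns]
    if missing:
        raise ValueError(
            f"column_map keys {missing} not resolvable; "
            f"available columns: {list(df.columns)}"
        )
    pairs = []
    n_skipped = 0
    for _, row in df.iterrows():
        can_seq = row[column_map["canonical_seq"]]
        iso_seq = row[column_map["isoform_seq"]]
        if not isinstance(can_seq, str) or not can_seq.strip() or \
           not isinstance(iso_seq, str) or not iso_seq.strip():
            n_skipped += 1
            continue
        gene = row[column_map["gene"]] if "gene" in column_map else None
        can = ProteinRecord(
            id=str(row[column_map["canonical_id"]]),
            sequence=can_seq.strip().upper().replace("*", ""),
            role="canonical",
            gene_symbol=gene,
        )
        iso = ProteinRecord(
            id=str(row[column_map["isoform_id"]]),
            sequence=iso_seq.strip().upper().replace("*", ""),
            role="isoform",
            parent_id=can.id,
            gene_symbol=gene,
        )
        pairs.append((can, iso))
    if n_skipped:
        logger.info("skipped %d rows with empty sequences", n_skipped)
    return pairs, n_skipped


def read_gene_list(path) -> List[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Counts TSV (gene rows x sample columns) + sample metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    return CountMatrix(counts=counts, metadata=meta)


def read_psm(path) -> pd.DataFrame:
    """Long PSM TSV (protein, day, psm_count) -> protein x day matrix."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"protein", "day", "psm_count"}
    if not need <= set(df.columns):
        raise ValueError(f"PSM table needs columns {sorted(need)}")
    return df.pivot_table(
        index="protein", columns="day", values="psm_count", fill_value=0
    ).astype(int)


def write_tsv(
    df: pd.DataFrame, path, header_meta: Optional[Mapping[str, object]] = None
) -> None:
    """Write a TSV with '#'-prefixed metadata lines (seed, config hash...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)
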