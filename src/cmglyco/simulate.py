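"""Synthetic data with known ground truth for every pipeline stage.

Generates canonical proteomes, splice isoforms with coordinate-derived
sequon-change labels (an alignment-free oracle for the classifier),
negative-binomial RNA-seq count matrices with planted fold changes across
differentiation days, sparse PSM tables with late-onset detection, and SPC
score assignments. All generators are pure functions of (config, seed):
the same configuration reproduces byte-identical outputs.

Splice events model the taxonomy of mRNA rearrangements at the protein
level: internal deletions (exon skipping), internal insertions (retained
sequence), terminal truncations (alternative starts/ends; frameshifts are
modeled only this way), and segment substitutions (mutually exclusive
exons). Ground-truth sequon labels come from the known event coordinates,
never from alignment, so they can arbitrate the alignment-based classifier.
A label is flagged *ambiguous* when the sequon triplet lies within three
residues of an event boundary, where co-optimal gap placements could map
the site differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .records import STANDARD_AA, ProteinRecord
from .sequon import find_sequons
from .surface import SpcTable

EVENT_TYPES = (
    "internal_deletion",
    "internal_insertion",
    "terminal_truncation",
    "segment_substitution",
)

# residues allowed at the sequon x position when planting
_X_CHOICES = STANDARD_AA.replace("P", "")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with field-realistic defaults.

    Day labels and replicate counts follow the study design this package
    analyses (differentiation days 15/30/45/60, triplicate RNA-seq).
    """

    seed: int = 0
    # proteome
    n_proteins: int = 200
    length_mean: float = 400.0
    length_sd: float = 120.0
    length_min: int = 50
    composition: Optional[Dict[str, float]] = None  # default uniform over 20
    sequon_plant_rate: float = 0.005  # planted sequons per residue
    # isoforms
    isoforms_per_canonical: int = 1
    event_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "internal_deletion": 0.4,
            "internal_insertion": 0.2,
            "terminal_truncation": 0.2,
            "segment_substitution": 0.2,
        }
    )
    event_size_min: int = 6
    event_size_max: int = 45
    # expression
    days: Tuple[int, ...] = (15, 30, 45, 60)
    replicates_per_day: int = 3
    nb_mean: float = 200.0
    nb_mean_sigma: float = 1.0  # lognormal spread of per-gene baselines
    nb_dispersion: float = 0.1
    planted_fraction: float = 0.1
    planted_fold: float = 16.0
    # PSM
    psm_mean: float = 8.0
    psm_detection: float = 0.8
    late_onset_fraction: float = 0.25
    # SPC
    spc_probs: Tuple[float, ...] = (0.55, 0.10, 0.10, 0.15, 0.10)

    def __post_init__(self) -> None:
        p = sum(self.event_probs.values())
        if not np.isclose(p, 1.0):
            raise ValueError(f"event probabilities sum to {p}, not 1")
        unknown = set(self.event_probs) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types {sorted(unknown)}")
        if not np.isclose(sum(self.spc_probs), 1.0) or len(self.spc_probs) != 5:
            raise ValueError("spc_probs must be 5 probabilities summing to 1")
        if self.composition is not None:
            tot = sum(self.composition.values())
            if not np.isclose(tot, 1.0, atol=1e-6):
                raise ValueError(f"composition sums to {tot}, not 1")

    def rng(self, stream: int) -> np.random.Generator:
        # independent, reproducible stream per generator
        return np.random.default_rng([int(self.seed), stream])


def _composition_arrays(config: SimulationConfig) -> Tuple[np.ndarray, np.ndarray]:
    if config.composition is None:
        letters = np.array(list(STANDARD_AA))
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        letters = np.array(list(config.composition))
        probs = np.array([config.composition[a] for a in letters], dtype=float)
    return letters, probs


def _random_sequence(
    rng: np.random.Generator, length: int, letters: np.ndarray, probs: np.ndarray
) -> str:
    return "".join(rng.choice(letters, size=length, p=probs))


def _plant_sequons(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0 or len(seq) < 3:
        return seq
    n_plant = rng.binomial(len(seq) - 2, rate)
    if n_plant == 0:
        return seq
    chars = list(seq)
    taken: List[int] = []
    starts = rng.permutation(len(seq) - 2)
    for i in starts:
        if len(taken) == n_plant:
            break
        if all(abs(i - t) >= 3 for t in taken):
            chars[i] = "N"
            chars[i + 1] = _X_CHOICES[rng.integers(len(_X_CHOICES))]
            chars[i + 2] = "ST"[rng.integers(2)]
            taken.append(i)
    return "".join(chars)


def simulate_proteome(config: SimulationConfig) -> List[ProteinRecord]:
    """Draw canonical protein sequences from the configured composition."""
    rng = config.rng(1)
    letters, probs = _composition_arrays(config)
    records = []
    for i in range(config.n_proteins):
        L = max(
            config.length_min,
            int(round(rng.normal(config.length_mean, config.length_sd))),
        )
        seq = _random_sequence(rng, L, letters, probs)
        seq = _plant_sequons(rng, seq, config.sequon_plant_rate)
        pid = f"PROT{i:05d}"
        records.append(
            ProteinRecord(id=pid, sequence=seq, role="canonical", gene_symbol=pid)
        )
    return records


# ---------------------------------------------------------------------------
# isoform events and the coordinate-derived truth labels


def _apply_event(
    rng: np.random.Generator,
    seq: str,
    event_type: str,
    letters: np.ndarray,
    probs: np.ndarray,
    size_min: int,
    size_max: int,
) -> Tuple[str, Dict]:
    """Apply one splice event; return (isoform sequence, event description).

    The description carries enough coordinates to derive the true
    canonical->isoform position map without alignment.
    """
    L = len(seq)
    for _ in range(100):
        k = int(rng.integers(size_min, size_max + 1))
        if event_type == "terminal_truncation":
            if k < L - 3:
                break
        elif k < L - 4:
            break
    else:  # event larger than sequence: fall back to smallest size
        k = max(1, min(size_min, L - 5))
    if event_type == "internal_deletion":
        a = int(rng.integers(2, L - k))  # 1-based start, keeps both termini
        iso = seq[: a - 1] + seq[a + k - 1 :]
        desc = {"type": event_type, "start": a, "size": k}
    elif event_type == "internal_insertion":
        a = int(rng.integers(1, L))  # insert after canonical position a
        ins = _random_sequence(rng, k, letters, probs)
        iso = seq[:a] + ins + seq[a:]
        desc = {"type": event_type, "after": a, "size": k}
    elif event_type == "terminal_truncation":
        side = "C" if rng.random() < 0.5 else "N"
        if side == "C":
            iso = seq[: L - k]
        else:
            iso = seq[k:]
        desc = {"type": event_type, "side": side, "size": k}
    elif event_type == "segment_substitution":
        a = int(rng.integers(2, L - k))
        sub = _random_sequence(rng, k, letters, probs)
        iso = seq[: a - 1] + sub + seq[a + k - 1 :]
        desc = {"type": event_type, "start": a, "size": k}
    else:
        raise ValueError(f"unknown event type {event_type!r}")
    return iso, desc


def _true_map(desc: Dict, canonical_length: int):
    """True canonical->isoform position map plus event boundaries.

    Returns ``(f, can_bounds, iso_bounds)`` where ``f(p)`` maps a 1-based
    canonical position to its isoform position (None in a gap) and the
    bound lists give the gap-junction coordinates on each track, around
    which co-optimal alignments may slide.
    """
    t = desc["type"]
    if t == "internal_deletion":
        a, k = desc["start"], desc["size"]

        def f(p):
            if p < a:
                return p
            if p <= a + k - 1:
                return None
            return p - k

        can_bounds = [a, a + k]
        iso_bounds = [a]
    elif t == "internal_insertion":
        a, k = desc["after"], desc["size"]

        def f(p):
            return p if p <= a else p + k

        can_bounds = [a, a + 1]
        iso_bounds = [a + 1, a + k + 1]
    elif t == "terminal_truncation":
        k = desc["size"]
        if desc["side"] == "C":

            def f(p):
                return p if p <= canonical_length - k else None

            can_bounds = [canonical_length - k]
            iso_bounds = [canonical_length - k]
        else:

            def f(p):
                return None if p <= k else p - k

            can_bounds = [k + 1]
            iso_bounds = [1]
    elif t == "segment_substitution":
        a, k = desc["start"], desc["size"]

        def f(p):
            return p

        # the true map is the identity, but inside the substituted window
        # (random vs random residues) a gapped realignment can score as well
        # as the mismatch path, so sites there are not coordinate-faithful
        can_bounds = iso_bounds = list(range(a, a + k))
    else:
        raise ValueError(t)
    return f, can_bounds, iso_bounds


def _truth_labels(
    canonical: ProteinRecord,
    isoform: ProteinRecord,
    desc: Dict,
    motif_classes,
) -> List[Dict]:
    """Label every sequon of the pair from the event coordinates."""
    fmap, can_bounds, iso_bounds = _true_map(desc, len(canonical.sequence))
    can_sites = find_sequons(canonical, motif_classes)
    iso_sites = {s.position: s for s in find_sequons(isoform, motif_classes)}

    def near(p: int, bounds) -> bool:
        # triplet [p, p+2] within 3 residues of a gap junction
        return any(p - 3 <= b <= p + 5 for b in bounds)

    rows = []
    matched = set()
    for site in can_sites:
        q = fmap(site.position)
        if q is not None and q in iso_sites:
            status = "retained" if q == site.position else "shifted"
            matched.add(q)
            amb = near(site.position, can_bounds) or near(q, iso_bounds)
        else:
            status, q = "lost", None
            amb = near(site.position, can_bounds)
        rows.append(
            {
                "canonical_id": canonical.id,
                "isoform_id": isoform.id,
                "status": status,
                "canonical_pos": site.position,
                "isoform_pos": q,
                "event_type": desc["type"],
                "ambiguous": amb,
            }
        )
    for q, site in sorted(iso_sites.items()):
        if q in matched:
            continue
        rows.append(
            {
                "canonical_id": canonical.id,
                "isoform_id": isoform.id,
                "status": "gained",
                "canonical_pos": None,
                "isoform_pos": q,
                "event_type": desc["type"],
                "ambiguous": near(q, iso_bounds),
            }
        )
    return rows


def simulate_isoforms(
    proteome: Sequence[ProteinRecord],
    config: SimulationConfig,
    motif_classes=("NxS", "NxT"),
    event_type: Optional[str] = None,
) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """Derive isoforms (one splice event each) plus coordinate-derived labels.

    ``event_type`` forces a single event class (used for per-event
    benchmarking); by default events are drawn from ``config.event_probs``.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rng = config.rng(2)
    letters, probs = _composition_arrays(config)
    types = list(config.event_probs)
    tprobs = np.array([config.event_probs[t] for t in types])
    isoforms: List[ProteinRecord] = []
    truth_rows: List[Dict] = []
    for rec in proteome:
        for j in range(config.isoforms_per_canonical):
            etype = event_type or types[rng.choice(len(types), p=tprobs)]
            iso_seq, desc = _apply_event(
                rng, rec.sequence, etype, letters, probs,
                config.event_size_min, config.event_size_max,
            )
            iso = ProteinRecord(
                id=f"{rec.id}.iso{j + 1}",
                sequence=iso_seq,
                role="isoform",
                parent_id=rec.id,
                gene_symbol=rec.gene_symbol,
                event_note=f"{desc['type']}:{desc.get('size')}",
            )
            isoforms.append(iso)
            truth_rows.extend(_truth_labels(rec, iso, desc, motif_classes))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "canonical_id", "isoform_id", "status",
            "canonical_pos", "isoform_pos", "event_type", "ambiguous",
        ],
    )
    return isoforms, truth


# ---------------------------------------------------------------------------
# expression, PSM, SPC


def simulate_counts(
    config: SimulationConfig, genes: Sequence[str]
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts per gene/day/replicate with planted changes.

    Planted genes multiply their baseline mean by ``planted_fold`` (up) or
    its reciprocal (down) on every day after the first (reference) day. The
    truth table records each gene's baseline mean, planted flag and signed
    fold.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("NB dispersion must be > 0")
    rng = config.rng(3)
    genes = list(genes)
    G = len(genes)
    base = config.nb_mean * rng.lognormal(0.0, config.nb_mean_sigma, size=G)
    planted = rng.random(G) < config.planted_fraction
    up = rng.random(G) < 0.5
    fold = np.where(planted, np.where(up, config.planted_fold, 1.0 / config.planted_fold), 1.0)
    ref_day = config.days[0]
    n_nb = 1.0 / config.nb_dispersion
    columns, samples, meta = {}, [], []
    for day in config.days:
        mean = base * np.where(day == ref_day, 1.0, fold)
        for r in range(1, config.replicates_per_day + 1):
            name = f"d{day}_r{r}"
            p = n_nb / (n_nb + mean)
            columns[name] = rng.negative_binomial(n_nb, p, size=G)
            meta.append({"sample": name, "day": day, "replicate": r})
    counts = pd.DataFrame(columns, index=genes)
    matrix = CountMatrix(counts=counts, metadata=pd.DataFrame(meta))
    truth = pd.DataFrame(
        {"gene": genes, "baseline_mean": base, "planted": planted, "fold": fold}
    )
    return matrix, truth


def simulate_psm(
    proteins: Sequence[str], config: SimulationConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Spectral counts per protein/day with optional late detection onset.

    A ``late_onset_fraction`` of proteins is undetectable before a random
    onset day (emulating surface proteins that appear only late in
    differentiation); afterwards each day is detected with probability
    ``psm_detection`` and detected counts are 1 + Poisson(psm_mean - 1).
    """
    rng = config.rng(4)
    proteins = list(proteins)
    days = list(config.days)
    late = rng.random(len(proteins)) < config.late_onset_fraction
    onset_idx = np.where(late, rng.integers(1, len(days), size=len(proteins)), 0)
    table = np.zeros((len(proteins), len(days)), dtype=np.int64)
    for i in range(len(proteins)):
        for j in range(len(days)):
            if j < onset_idx[i]:
                continue
            if rng.random() < config.psm_detection:
                table[i, j] = 1 + rng.poisson(max(config.psm_mean - 1, 0))
    psm = pd.DataFrame(table, index=proteins, columns=days)
    truth = pd.DataFrame(
        {
            "protein": proteins,
            "late_onset": late,
            "onset_day": [days[k] for k in onset_idx],
        }
    )
    return psm, truth


def simulate_spc(genes: Sequence[str], config: SimulationConfig) -> SpcTable:
    """Assign SPC scores 0-4 from the configured score distribution."""
    rng = config.rng(5)
    scores = rng.choice(5, size=len(genes), p=np.asarray(config.spc_probs))
    return SpcTable(dict(zip(genes, (int(s) for s in scores))))
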