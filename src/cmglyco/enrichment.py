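"""Sequon-motif enrichment against a composition-preserving null.

Tests whether a motif class (NxS/NxT, or the proposed NxC/NxV variants)
occurs more or less often than expected in a protein set. Two nulls are
provided and labeled explicitly:

* **permutation** — every sequence's residues are shuffled uniformly, so each
  protein keeps its own length and amino-acid composition; the expected count
  is the mean over permutations and the p-value is a two-sided empirical one
  with add-one correction (never exactly zero).
* **analytic** — an i.i.d. closed form: for a sequence of length L drawn from
  residue frequencies f, the expected number of N-x-Z sites (x not proline,
  not unknown) is (L-2) * f_N * (1 - f_P - f_X) * f_Z.

The biological contrast of interest is surface (SPC >= 3) versus
intracellular (SPC 0, optionally minus a GPI/ECM exclusion list) protein
sets: canonical NxS/T sequons run above expectation on surface proteins
while NxC/NxV do not, so the latter alone are weak surface evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import ProteinRecord
from .sequon import MOTIF_THIRD, find_sequons

_N, _P, _X = (ord(c) for c in "NPX")


@dataclass(frozen=True)
class NullConfig:
    """Settings for the permutation null."""

    n_permutations: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class EnrichmentResult:
    motif_class: str
    set_label: str
    observed_count: int
    expected_count: float
    ratio: Optional[float]  # None when expected_count == 0
    p_value: float
    n_permutations: int
    seed: int


def _as_arrays(records: Sequence[ProteinRecord]) -> List[np.ndarray]:
    return [
        np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        for rec in records
    ]


def _count_array(arr: np.ndarray, third: int) -> int:
    if arr.size < 3:
        return 0
    a, b, c = arr[:-2], arr[1:-1], arr[2:]
    return int(((a == _N) & (b != _P) & (b != _X) & (c == third)).sum())


def observed_count(records: Sequence[ProteinRecord], motif_class: str) -> int:
    """Total sequon sites of one class across a protein set."""
    return sum(len(find_sequons(rec, {motif_class})) for rec in records)


def analytic_expected(
    composition: Mapping[str, float],
    lengths: Iterable[int],
    motif_class: str,
) -> float:
    """Closed-form expected site count under an i.i.d. residue model."""
    freqs = dict(composition)
    total = sum(freqs.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"residue frequencies sum to {total}, not 1")
    third = MOTIF_THIRD[motif_class]
    f_n = freqs.get("N", 0.0)
    f_x_ok = 1.0 - freqs.get("P", 0.0) - freqs.get("X", 0.0)
    f_third = freqs.get(third, 0.0)
    per_pos = f_n * f_x_ok * f_third
    return float(sum(max(L - 2, 0) for L in lengths) * per_pos)


def permutation_expected(
    records: Sequence[ProteinRecord],
    motif_class: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Expected count and two-sided empirical p under per-sequence shuffling.

    Returns ``(expected_count, p_value)`` where expected is the mean site
    count over permutations and p uses the add-one correction
    ``(1 + #{|c_b - mean| >= |observed - mean|}) / (B + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    third = ord(MOTIF_THIRD[motif_class])
    arrays = _as_arrays(records)
    observed = sum(_count_array(a, third) for a in arrays)
    perm_counts = np.empty(n_permutations, dtype=np.int64)
    for b in range(n_permutations):
        perm_counts[b] = sum(
            _count_array(rng.permutation(a), third) for a in arrays
        )
    expected = float(perm_counts.mean())
    dev = abs(observed - expected)
    n_extreme = int((np.abs(perm_counts - expected) >= dev - 1e-12).sum())
    p = (1 + n_extreme) / (n_permutations + 1)
    return expected, float(p)


def compare_sets(
    surface_records: Sequence[ProteinRecord],
    intracellular_records: Sequence[ProteinRecord],
    motif_classes: Iterable[str] = ("NxS", "NxT", "NxC", "NxV"),
    null_config: NullConfig = NullConfig(),
) -> List[EnrichmentResult]:
    """One EnrichmentResult per (motif class, protein set).

    NxS/NxT are evaluated alongside NxC/NxV so the surface-vs-intracellular
    contrast (opposite enrichment direction) can be read off one table.
    """
    sets = {"surface": list(surface_records), "intracellular": list(intracellular_records)}
    for label, recs in sets.items():
        if not recs:
            raise ValueError(f"{label} protein set is empty")
    results: List[EnrichmentResult] = []
    for label, recs in sets.items():
        for cls in motif_classes:
            obs = observed_count(recs, cls)
            exp, p = permutation_expected(
                recs, cls, null_config.n_permutations, null_config.seed
            )
            ratio = obs / exp if exp > 0 else None
            results.append(
                EnrichmentResult(
                    motif_class=cls,
                    set_label=label,
                    observed_count=obs,
                    expected_count=exp,
                    ratio=ratio,
                    p_value=p,
                    n_permutations=null_config.n_permutations,
                    seed=null_config.seed,
                )
            )
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_class": r.motif_class,
                "set_label": r.set_label,
                "observed": r.observed_count,
                "expected": r.expected_count,
                "ratio": r.ratio if r.ratio is not None else pd.NA,
                "p_value": r.p_value,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
            }
            for r in results
        ]
    )
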