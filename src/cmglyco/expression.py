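"""Transcript/glycopeptide abundance integration across differentiation.

RNA-seq counts (genes x samples, with day and replicate labels for
differentiation days such as 15/30/45/60) are tested day-vs-day for
differential abundance and visualized as volcano tables restricted to
surface-predicted (SPC >= 3) genes or glyco-enzyme (CAZy) genes.
Glycopeptide evidence (peptide-spectrum-match counts per protein and
timepoint) is combined with transcripts as max-normalized profiles so
trends can be compared across modalities.

Differential testing is deliberately simple and transparent: a two-sided
Welch t-test on log2(count + pseudocount) across replicates, with the fold
change computed on group means. The published significance call is
threshold-level — raw p < 0.05 together with |log2 fold change| > 4 versus
the day-15 reference — so no external differential-expression package is
invoked; a Benjamini-Hochberg adjusted column is emitted alongside for
users who want it. Library-size (CPM) normalization is available via
``VolcanoConfig.cpm`` but off by default, because the fold-change gate is
defined on the count scale and CPM rescales fold changes whenever library
composition shifts between days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class VolcanoConfig:
    """Thresholds of the volcano significance call."""

    p_threshold: float = 0.05
    fc_threshold: float = 4.0  # |log2FC| must exceed this
    reference_day: int = 15
    count_pseudocount: float = 1.0
    min_count_threshold: float = 10.0  # total-count expression floor
    # fold-change thresholds are defined on the count scale, so library-size
    # (CPM) normalization is opt-in; enabling it rescales fold changes when
    # library compositions differ between days
    cpm: bool = False

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class CountMatrix:
    """Gene x sample count matrix with per-sample day/replicate metadata."""

    counts: pd.DataFrame  # genes x samples, nonnegative
    metadata: pd.DataFrame  # columns: sample, day, replicate

    def __post_init__(self) -> None:
        need = {"sample", "day", "replicate"}
        if not need <= set(self.metadata.columns):
            raise ValueError(f"metadata needs columns {sorted(need)}")
        if set(self.counts.columns) != set(self.metadata["sample"]):
            raise ValueError("count columns and metadata samples disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.metadata = self.metadata.set_index("sample").loc[
            list(self.counts.columns)
        ].reset_index()

    @property
    def days(self) -> List[int]:
        return sorted(self.metadata["day"].unique())

    def samples_for_day(self, day: int) -> List[str]:
        sel = self.metadata.loc[self.metadata["day"] == day, "sample"]
        return list(sel)


def average_replicates(matrix: CountMatrix) -> pd.DataFrame:
    """Arithmetic mean of counts per gene per day (genes x days)."""
    out = {}
    for day in matrix.days:
        samples = matrix.samples_for_day(day)
        if not samples:
            raise ValueError(f"day {day} has no samples")
        out[day] = matrix.counts[samples].mean(axis=1)
    return pd.DataFrame(out)


def normalize_to_max(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Scale a per-timepoint profile to [0, 1] by its maximum.

    Returns ``(profile, detected)``; an all-zero profile stays all-zero with
    ``detected=False``.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("profile values must be nonnegative")
    m = arr.max() if arr.size else 0.0
    if m == 0:
        return np.zeros_like(arr), False
    return arr / m, True


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    lib = lib.replace(0, 1)  # an empty library stays all-zero
    return counts.div(lib, axis=1) * 1e6


def differential(
    matrix: CountMatrix,
    day: int,
    reference_day: int,
    config: VolcanoConfig = VolcanoConfig(),
) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch-t p-value for day vs reference.

    Genes whose total raw count over all samples falls below
    ``config.min_count_threshold`` are excluded before testing. With fewer
    than two replicates in either group, or zero variance in both, the
    p-value is reported missing and the gene is never called significant.
    """
    for d in (day, reference_day):
        if d not in matrix.days:
            raise ValueError(f"day {d} not present in the matrix")
    keep = matrix.counts.sum(axis=1) >= config.min_count_threshold
    counts = matrix.counts[keep]
    values = _cpm(counts) if config.cpm else counts
    c = config.count_pseudocount
    g1 = values[matrix.samples_for_day(day)]
    g0 = values[matrix.samples_for_day(reference_day)]
    log2fc = np.log2(g1.mean(axis=1) + c) - np.log2(g0.mean(axis=1) + c)
    if g1.shape[1] >= 2 and g0.shape[1] >= 2:
        l1 = np.log2(g1 + c)
        l0 = np.log2(g0 + c)
        _, pvals = stats.ttest_ind(l1, l0, axis=1, equal_var=False)
        pvals = np.asarray(pvals, dtype=float)
        # identical zero-variance groups: report missing, not 1
        same = (l1.var(axis=1, ddof=1) == 0) & (l0.var(axis=1, ddof=1) == 0)
        pvals[np.asarray(same)] = np.nan
    else:
        pvals = np.full(len(counts), np.nan)
    df = pd.DataFrame(
        {
            "gene": counts.index,
            "day": day,
            "reference_day": reference_day,
            "log2fc": log2fc.to_numpy(),
            "p_value": pvals,
        }
    )
    ok = df["p_value"].notna()
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["significant"] = (
        ok
        & (df["p_value"] < config.p_threshold)
        & (df["log2fc"].abs() > config.fc_threshold)
    )
    return df.reset_index(drop=True)


def volcano_table(
    diffs: pd.DataFrame,
    gene_subset: str = "all",
    spc_high: Optional[Iterable[str]] = None,
    cazy_list: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Restrict a differential table to a labeled gene subset.

    ``gene_subset`` is one of ``all``, ``spc_high`` (surface-predicted genes,
    SPC 3-4) or ``cazy`` (glycosyltransferase/glycosidase genes). Significant
    rows carry the gene symbol in a ``label`` column; output is sorted by
    p-value.
    """
    if gene_subset == "all":
        sub = diffs
    elif gene_subset == "spc_high":
        if spc_high is None:
            raise ValueError("spc_high subset requested but no SPC gene set given")
        sub = diffs[diffs["gene"].isin(set(spc_high))]
    elif gene_subset == "cazy":
        if cazy_list is None:
            raise ValueError("cazy subset requested but no enzyme gene list given")
        sub = diffs[diffs["gene"].isin(set(cazy_list))]
    else:
        raise ValueError(f"unknown gene_subset {gene_subset!r}")
    sub = sub.copy()
    sub["label"] = np.where(sub["significant"], sub["gene"], "")
    return sub.sort_values("p_value", na_position="last").reset_index(drop=True)


@dataclass
class EvidenceProfile:
    """Max-normalized transcript and PSM profiles for one protein."""

    protein: str
    days: List[int]
    transcript: np.ndarray  # in [0,1]
    psm: np.ndarray  # in [0,1]
    transcript_detected: bool
    psm_detected: bool


def build_profiles(
    rna_per_day: pd.DataFrame,
    psm: pd.DataFrame,
    gene_of_protein: Optional[Dict[str, str]] = None,
) -> List[EvidenceProfile]:
    """Max-normalize replicate-averaged RNA and PSM counts per protein.

    ``rna_per_day`` is genes x days (already replicate-averaged); ``psm`` is
    proteins x days of spectral counts. Only shared days are profiled.
    """
    days = sorted(set(rna_per_day.columns) & set(psm.columns))
    profiles = []
    for protein in psm.index:
        gene = gene_of_protein.get(protein, protein) if gene_of_protein else protein
        if gene not in rna_per_day.index:
            continue
        t, t_det = normalize_to_max(rna_per_day.loc[gene, days].to_numpy())
        p, p_det = normalize_to_max(psm.loc[protein, days].to_numpy())
        profiles.append(EvidenceProfile(protein, list(days), t, p, t_det, p_det))
    return profiles


def evidence_concordance(
    profiles: Sequence[EvidenceProfile], detection_floor: float = 0.0
) -> pd.DataFrame:
    """Per-protein trend agreement between transcript and PSM profiles.

    Reports the Spearman correlation over shared timepoints and its sign,
    plus a ``discordant`` flag when one modality is undetected while the
    other exceeds ``detection_floor`` at some timepoint — the pattern of
    proteins seen robustly by only one technique.
    """
    rows = []
    for pr in profiles:
        n = len(pr.days)
        rho = np.nan
        if n >= 3 and pr.transcript_detected and pr.psm_detected:
            rho = stats.spearmanr(pr.transcript, pr.psm).statistic
        one_sided = (
            (not pr.transcript_detected and pr.psm.max(initial=0) > detection_floor)
            or (not pr.psm_detected and pr.transcript.max(initial=0) > detection_floor)
        )
        rows.append(
            {
                "protein": pr.protein,
                "n_timepoints": n,
                "spearman_rho": rho,
                "trend_sign": int(np.sign(rho)) if not math.isnan(rho) else 0,
                "discordant": bool(one_sided),
            }
        )
    return pd.DataFrame(rows)
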