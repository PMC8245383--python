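import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cmglyco.expression import (
    CountMatrix,
    EvidenceProfile,
    VolcanoConfig,
    average_replicates,
    build_profiles,
    differential,
    evidence_concordance,
    normalize_to_max,
    volcano_table,
)


def make_matrix(data, days, reps):
    """data: gene -> list of counts ordered (day-major, replicate-minor)."""
    samples = [f"d{d}_r{r}" for d in days for r in range(1, reps + 1)]
    counts = pd.DataFrame(data, index=samples).T
    meta = pd.DataFrame(
        {
            "sample": samples,
            "day": [d for d in days for _ in range(reps)],
            "replicate": [r for _ in days for r in range(1, reps + 1)],
        }
    )
    return CountMatrix(counts=counts, metadata=meta)


class TestAverageReplicates:
    def test_simple_mean(self):
        m = make_matrix({"g1": [10, 14, 2, 4]}, days=[30, 45], reps=2)
        per_day = average_replicates(m)
        assert per_day.loc["g1", 30] == 12
        assert per_day.loc["g1", 45] == 3

    def test_single_replicate_identity(self):
        m = make_matrix({"g1": [7, 9]}, days=[15, 30], reps=1)
        per_day = average_replicates(m)
        assert per_day.loc["g1", 15] == 7

    def test_matches_bruteforce_group_mean(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 1000, size=(50, 6))
        m = make_matrix(
            {f"g{i}": raw[i] for i in range(50)}, days=[15, 30], reps=3
        )
        per_day = average_replicates(m)
        np.testing.assert_allclose(per_day[15], raw[:, :3].mean(axis=1))
        np.testing.assert_allclose(per_day[30], raw[:, 3:].mean(axis=1))


class TestNormalizeToMax:
    def test_basic(self):
        profile, detected = normalize_to_max([100, 200, 400])
        np.testing.assert_allclose(profile, [0.25, 0.5, 1.0])
        assert detected

    def test_all_zero_is_undetected(self):
        profile, detected = normalize_to_max([0, 0, 0])
        np.testing.assert_array_equal(profile, [0, 0, 0])
        assert not detected

    def test_single_value(self):
        profile, detected = normalize_to_max([7])
        assert profile[0] == 1.0 and detected

    def test_idempotent_and_scale_invariant(self):
        values = np.array([3.0, 9.0, 6.0])
        once, _ = normalize_to_max(values)
        twice, _ = normalize_to_max(once)
        np.testing.assert_allclose(once, twice)
        scaled, _ = normalize_to_max(values * 37.5)
        np.testing.assert_allclose(once, scaled)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_max([1, -2])


class TestDifferential:
    def test_log2fc_closed_form(self):
        m = make_matrix({"g1": [1, 1, 31, 31]}, days=[15, 30], reps=2)
        d = differential(m, 30, 15, VolcanoConfig(cpm=False, min_count_threshold=0))
        assert d.loc[0, "log2fc"] == pytest.approx(4.0)

    def test_identical_groups_zero_variance(self):
        m = make_matrix({"g1": [5, 5, 5, 5]}, days=[15, 30], reps=2)
        d = differential(m, 30, 15, VolcanoConfig(cpm=False, min_count_threshold=0))
        assert d.loc[0, "log2fc"] == 0.0
        assert pd.isna(d.loc[0, "p_value"])
        assert not d.loc[0, "significant"]

    def test_same_day_comparison_is_null(self):
        rng = np.random.default_rng(1)
        m = make_matrix(
            {f"g{i}": rng.integers(10, 500, size=4) for i in range(20)},
            days=[15, 30], reps=2,
        )
        d = differential(m, 15, 15, VolcanoConfig(cpm=False))
        assert (d["log2fc"] == 0).all()

    def test_single_replicate_gives_missing_p(self):
        m = make_matrix({"g1": [1, 31]}, days=[15, 30], reps=1)
        d = differential(m, 30, 15, VolcanoConfig(cpm=False, min_count_threshold=0))
        assert pd.isna(d.loc[0, "p_value"])
        assert not d.loc[0, "significant"]

    def test_expression_floor_excludes_low_genes(self):
        m = make_matrix(
            {"low": [1, 1, 1, 1], "high": [100, 100, 100, 100]},
            days=[15, 30], reps=2,
        )
        d = differential(m, 30, 15, VolcanoConfig(cpm=False, min_count_threshold=10))
        assert list(d["gene"]) == ["high"]

    def test_welch_p_matches_direct_computation(self):
        m = make_matrix({"g1": [12, 30, 21, 200, 310, 150]}, days=[15, 30], reps=3)
        d = differential(m, 30, 15, VolcanoConfig(cpm=False, min_count_threshold=0))
        a = np.log2(np.array([200, 310, 150]) + 1)
        b = np.log2(np.array([12, 30, 21]) + 1)
        expected = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert d.loc[0, "p_value"] == pytest.approx(expected)

    def test_missing_day_rejected(self):
        m = make_matrix({"g1": [1, 2]}, days=[15, 30], reps=1)
        with pytest.raises(ValueError):
            differential(m, 60, 15, VolcanoConfig(cpm=False))


class TestVolcanoTable:
    def diffs(self):
        df = pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "log2fc": [4.5, 5.0, 3.9],
                "p_value": [0.01, 0.2, 0.01],
            }
        )
        config = VolcanoConfig()
        df["significant"] = (df.p_value < config.p_threshold) & (
            df.log2fc.abs() > config.fc_threshold
        )
        return df

    def test_joint_thresholds_label_only_a(self):
        table = volcano_table(self.diffs(), "all")
        labeled = set(table.loc[table.label != "", "gene"])
        assert labeled == {"A"}

    def test_subset_restriction(self):
        table = volcano_table(self.diffs(), "cazy", cazy_list=["A", "Z1", "Z2"])
        assert list(table.gene) == ["A"]
        empty = volcano_table(self.diffs(), "spc_high", spc_high=[])
        assert len(empty) == 0

    def test_sorted_by_p_value(self):
        table = volcano_table(self.diffs(), "all")
        assert list(table.p_value) == sorted(table.p_value)

    def test_unknown_subset_rejected(self):
        with pytest.raises(ValueError):
            volcano_table(self.diffs(), "bogus")
        with pytest.raises(ValueError):
            volcano_table(self.diffs(), "cazy")  # list not supplied


class TestEvidenceConcordance:
    def profile(self, transcript, psm, days=(15, 30, 45)):
        t, t_det = normalize_to_max(transcript)
        p, p_det = normalize_to_max(psm)
        return EvidenceProfile("P", list(days), t, p, t_det, p_det)

    def test_monotone_agreement_positive(self):
        out = evidence_concordance([self.profile([0.2, 0.5, 1.0], [0.1, 0.6, 1.0])])
        assert out.loc[0, "trend_sign"] == 1
        assert not out.loc[0, "discordant"]

    def test_protein_only_detection_is_discordant(self):
        out = evidence_concordance([self.profile([0, 0, 0], [0, 0.4, 1.0])])
        assert out.loc[0, "discordant"]

    def test_too_few_timepoints_missing_rho(self):
        out = evidence_concordance([self.profile([1, 2], [2, 1], days=(15, 30))])
        assert np.isnan(out.loc[0, "spearman_rho"])

    def test_independent_profiles_average_to_zero(self):
        rng = np.random.default_rng(4)
        profiles = [
            self.profile(rng.random(4), rng.random(4), days=(15, 30, 45, 60))
            for _ in range(1000)
        ]
        out = evidence_concordance(profiles)
        assert abs(out["spearman_rho"].mean()) < 0.1

    def test_build_profiles_max_is_one(self):
        rna = pd.DataFrame(
            {15: [10.0, 5.0], 30: [20.0, 1.0]}, index=["G1", "G2"]
        )
        psm = pd.DataFrame({15: [0, 3], 30: [4, 1]}, index=["G1", "G2"])
        profiles = build_profiles(rna, psm)
        for pr in profiles:
            assert pr.transcript.max() == pytest.approx(1.0)
            if pr.psm_detected:
                assert pr.psm.max() == pytest.approx(1.0)
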