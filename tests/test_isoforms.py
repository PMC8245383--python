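import pytest
from Bio.Align import substitution_matrices

from cmglyco.isoforms import (
    GAP,
    AlignmentMap,
    align_pair,
    classify_pair,
    summarize,
)
from cmglyco.records import ProteinRecord, RecordError
from cmglyco.sequon import find_sequons


def can(seq, id="c"):
    return ProteinRecord(id=id, sequence=seq, role="canonical")


def iso(seq, parent="c", id=None):
    return ProteinRecord(
        id=id or f"{parent}.iso", sequence=seq, role="isoform", parent_id=parent
    )


def classify(c_seq, i_seq):
    c, i = can(c_seq), iso(i_seq)
    amap = align_pair(c, i)
    return classify_pair(c, i, find_sequons(c), find_sequons(i), amap)


class TestAlignPair:
    def test_identity_alignment(self):
        seq = "MANGSTWYKL"
        amap = align_pair(can(seq), iso(seq))
        blosum = substitution_matrices.load("BLOSUM62")
        assert amap.score == sum(blosum[a, a] for a in seq)
        assert amap.columns == [(k, k) for k in range(1, len(seq) + 1)]

    def test_internal_deletion_mapping(self):
        # isoform lacks two residues of the A-run; any co-optimal gap
        # placement leaves canonical position 5 mapped to isoform 3
        amap = align_pair(can("MAAANGSAA"), iso("MANGSAA"))
        assert amap.map_position(5) == 3
        gapped = [p for p in range(1, 10) if amap.map_position(p) is GAP]
        assert len(gapped) == 2 and all(2 <= p <= 4 for p in gapped)

    def test_map_position_bounds(self):
        amap = align_pair(can("MANGSAAA"), iso("MANGSAAA"))
        assert amap.map_position(7) == 7
        with pytest.raises(IndexError):
            amap.map_position(0)
        with pytest.raises(IndexError):
            amap.map_position(9)

    def test_empty_sequence_rejected(self):
        with pytest.raises((RecordError, ValueError)):
            ProteinRecord(id="x", sequence="", role="isoform", parent_id="c")

    def test_wrong_parent_rejected(self):
        other = ProteinRecord(
            id="i2", sequence="MA", role="isoform", parent_id="other"
        )
        with pytest.raises(RecordError):
            align_pair(can("MA"), other)


class TestAlignmentMapInvariants:
    def test_no_double_gap_column(self):
        with pytest.raises(ValueError):
            AlignmentMap("c", "i", [(1, 1), (None, None)], 0.0, 2, 1)

    def test_must_cover_both_sequences(self):
        with pytest.raises(ValueError):
            AlignmentMap("c", "i", [(1, 1)], 0.0, canonical_length=2,
                         isoform_length=1)


class TestClassifyPair:
    def test_identity_isoform_all_retained(self):
        changes = classify("MANGSAAA", "MANGSAAA")
        assert [(c.status, c.canonical_site.position) for c in changes] == [
            ("retained", 3)
        ]

    def test_deletion_upstream_shifts_site(self):
        (change,) = classify("MAAANGSAA", "MANGSAA")
        assert change.status == "shifted"
        assert change.canonical_site.position == 5
        assert change.isoform_site.position == 3

    def test_deleted_asn_is_lost(self):
        (change,) = classify("MANGSAAA", "MAGSAAA")
        assert change.status == "lost"
        assert change.canonical_site.position == 3
        assert change.isoform_site is None

    def test_new_sequon_is_gained(self):
        (change,) = classify("MAAAAA", "MANTSA")
        assert change.status == "gained"
        assert change.canonical_site is None
        assert change.isoform_site.position == 3

    def test_broken_sequon_at_aligned_asn_is_lost(self):
        # the Asn survives but +1 became proline: the site no longer exists
        (change,) = classify("MANGSAAA", "MANPSAAA")
        assert change.status == "lost"

    def test_conservation_identity(self, random_records):
        from cmglyco.simulate import SimulationConfig, simulate_isoforms

        config = SimulationConfig(seed=5, n_proteins=30)
        proteome = random_records[:30]
        isoforms, _ = simulate_isoforms(proteome, config)
        by_id = {r.id: r for r in proteome}
        for isof in isoforms:
            parent = by_id[isof.parent_id]
            amap = align_pair(parent, isof)
            c_sites = find_sequons(parent)
            i_sites = find_sequons(isof)
            changes = classify_pair(parent, isof, c_sites, i_sites, amap)
            by_status = {s: sum(c.status == s for c in changes)
                         for s in ("retained", "shifted", "lost", "gained")}
            assert (
                by_status["retained"] + by_status["shifted"] + by_status["lost"]
                == len(c_sites)
            )
            assert by_status["gained"] <= len(i_sites)
            assert len(changes) == len(c_sites) + by_status["gained"]

    def test_swap_exchanges_lost_and_gained(self):
        from cmglyco.simulate import SimulationConfig, simulate_isoforms

        config = SimulationConfig(seed=21, n_proteins=40)
        from cmglyco.simulate import simulate_proteome

        proteome = simulate_proteome(config)
        isoforms, truth = simulate_isoforms(proteome, config)
        by_id = {r.id: r for r in proteome}
        ambiguous_pairs = set(
            truth.loc[truth.ambiguous, "isoform_id"]
        )
        for isof in isoforms:
            if isof.id in ambiguous_pairs:
                continue
            parent = by_id[isof.parent_id]
            fwd = classify(parent.sequence, isof.sequence)
            rev = classify(isof.sequence, parent.sequence)

            def tally(changes):
                return {
                    s: sum(c.status == s for c in changes)
                    for s in ("retained", "shifted", "lost", "gained")
                }

            f, r = tally(fwd), tally(rev)
            assert f["lost"] == r["gained"] and f["gained"] == r["lost"]
            assert f["shifted"] == r["shifted"]
            assert f["retained"] == r["retained"]


class TestSummarize:
    def build_four_example_changes(self):
        changes = []
        changes += classify("MANGSAAA", "MANGSAAA")  # retained
        c2 = can("MAAANGSAA", id="c2")
        i2 = iso("MANGSAA", parent="c2")
        changes += classify_pair(
            c2, i2, find_sequons(c2), find_sequons(i2), align_pair(c2, i2)
        )  # shifted
        c3 = can("MANGSAAA", id="c3")
        i3 = iso("MAGSAAA", parent="c3")
        changes += classify_pair(
            c3, i3, find_sequons(c3), find_sequons(i3), align_pair(c3, i3)
        )  # lost
        c4 = can("MAAAAA", id="c4")
        i4 = iso("MANTSA", parent="c4")
        changes += classify_pair(
            c4, i4, find_sequons(c4), find_sequons(i4), align_pair(c4, i4)
        )  # gained
        return changes

    def test_four_example_pairs(self):
        summary = summarize(self.build_four_example_changes())
        assert summary.n_retained == 1
        assert summary.n_shifted == 1
        assert summary.n_lost == 1
        assert summary.n_gained == 1
        assert summary.total_differing_sites == 3
        assert summary.fraction_shifted == pytest.approx(1 / 3)
        assert summary.fraction_lost == pytest.approx(1 / 3)
        assert summary.fraction_gained == pytest.approx(1 / 3)
        assert summary.n_proteins_with_lost == 1
        assert summary.n_proteins_with_gained == 1

    def test_empty_changes(self):
        summary = summarize([])
        assert summary.total_differing_sites == 0
        assert summary.fraction_shifted == 0.0
        assert len(summary.per_pair) == 0

    def test_protein_dedup_across_isoforms(self):
        # two isoforms of one canonical each lose the same site:
        # site-by-pair tally counts 2, the protein tally counts 1
        c = can("MANGSAAA")
        changes = []
        for j in (1, 2):
            i_j = iso("MAGSAAA", parent="c", id=f"c.iso{j}")
            changes += classify_pair(
                c, i_j, find_sequons(c), find_sequons(i_j), align_pair(c, i_j)
            )
        summary = summarize(changes)
        assert summary.n_lost == 2
        assert summary.n_proteins_with_lost == 1
        assert summary.n_unique_differing_sites == 1
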