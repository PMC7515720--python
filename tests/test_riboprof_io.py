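"""A-site mapping, count aggregation, normalization and gene filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from near.riboprof_io import (
    ASITE_OFFSETS,
    DISCARD,
    FootprintRecord,
    GeneRejected,
    RawProfile,
    aggregate_counts,
    asite_offset,
    filter_gene,
    map_asite,
    normalize,
    read_counts_tsv,
)

# the full (length, frame) -> offset table for 27-33 nt monosome footprints
EXPECTED_OFFSETS = {
    (27, 0): 15, (27, 1): 15, (27, 2): 18,
    (28, 0): 15, (28, 1): 15, (28, 2): 18,
    (29, 0): 15, (29, 1): None, (29, 2): 18,
    (30, 0): 15, (30, 1): 18, (30, 2): 18,
    (31, 0): 15, (31, 1): 18, (31, 2): 18,
    (32, 0): None, (32, 1): 18, (32, 2): 18,
    (33, 0): 18, (33, 1): 18, (33, 2): 18,
}


class TestAsiteMapping:
    def test_offset_table_all_21_cells(self):
        assert ASITE_OFFSETS == EXPECTED_OFFSETS
        for (length, frame), offset in EXPECTED_OFFSETS.items():
            assert asite_offset(length, frame) == offset

    @pytest.mark.parametrize(
        "length,frame,offset",
        [(28, 0, 15), (30, 1, 18), (27, 2, 18), (33, 0, 18)],
    )
    def test_known_offsets(self, length, frame, offset):
        pos5 = 30 + frame
        rec = FootprintRecord("g", pos5, length)
        assert map_asite(rec) == (pos5 + offset) // 3 + 1

    @pytest.mark.parametrize("length,frame", [(32, 0), (29, 1)])
    def test_ambiguous_cells_discarded(self, length, frame):
        rec = FootprintRecord("g", 30 + frame, length)
        assert map_asite(rec) is DISCARD

    def test_frame_derived_from_position(self):
        assert FootprintRecord("g", 31, 28).frame == 1
        with pytest.raises(ValueError):
            FootprintRecord("g", 10, 28, frame=5)

    @given(
        pos5=st.integers(min_value=0, max_value=300),
        length=st.integers(min_value=27, max_value=33),
    )
    @settings(max_examples=60, deadline=None)
    def test_pure_lookup_is_deterministic(self, pos5, length):
        rec = FootprintRecord("g", pos5, length)
        assert map_asite(rec) == map_asite(rec)
        out = map_asite(rec)
        if out is not DISCARD:
            # A-site lies downstream of the 5' end, within the fragment
            assert out >= pos5 // 3 + 1


class TestAggregation:
    def test_empty_records_give_zero_profile(self):
        profiles, reasons = aggregate_counts([], {"g1": 20})
        assert profiles["g1"].total == 0
        assert all(v == 0 for v in reasons.values())

    def test_three_records_one_codon(self):
        # pos5=0, length 28, frame 0 -> offset 15 -> codon 6
        recs = [FootprintRecord("g1", 0, 28)] * 3
        profiles, _ = aggregate_counts(recs, {"g1": 20})
        assert profiles["g1"].counts[6 - 2] == 3
        assert profiles["g1"].total == 3

    def test_hand_filtered_mixed_records(self):
        recs = [
            FootprintRecord("g1", 0, 28),    # offset 15 -> codon 6
            FootprintRecord("g1", 3, 28),    # offset 15 -> codon 7
            FootprintRecord("g1", 1, 30),    # frame 1, offset 18 -> codon 7
            FootprintRecord("g1", 1, 29),    # frame 1, X -> discard
            FootprintRecord("g1", 0, 32),    # frame 0, X -> discard
            FootprintRecord("g1", 0, 35),    # out of range
            FootprintRecord("g2", 0, 28),    # unknown gene
            FootprintRecord("g1", 50, 28),   # offset 15 -> codon 22 > L
        ]
        profiles, reasons = aggregate_counts(recs, {"g1": 12})
        expected = np.zeros(11, dtype=int)
        expected[6 - 2] = 1
        expected[7 - 2] = 2
        np.testing.assert_array_equal(profiles["g1"].counts, expected)
        assert reasons["ambiguous_offset"] == 2
        assert reasons["length_out_of_range"] == 1
        assert reasons["unknown_gene"] == 1
        assert reasons["outside_cds"] == 1


class TestNormalization:
    def test_uniform_counts_preserve_uniformity(self):
        raw = RawProfile("g", np.full(10, 7), 11)
        prof = normalize(raw, 0.05)
        np.testing.assert_allclose(prof.r, 0.05)
        assert prof.r_mean == pytest.approx(0.05)

    def test_direct_arithmetic(self):
        raw = RawProfile("g", np.array([1, 2, 3, 4]), 5)
        prof = normalize(raw, 0.05)
        np.testing.assert_allclose(prof.r, [0.02, 0.04, 0.06, 0.08])
        assert prof.N == pytest.approx(0.2)

    def test_density_above_one_rejected(self):
        counts = np.array([90, 2, 2, 2, 2, 2])
        raw = RawProfile("g", counts, 7)
        with pytest.raises(GeneRejected, match="density>1"):
            normalize(raw, 0.3)

    def test_no_reads_rejected(self):
        with pytest.raises(GeneRejected, match="no reads"):
            normalize(RawProfile("g", np.zeros(5, int), 6), 0.05)

    @given(
        counts=st.lists(st.integers(0, 500), min_size=4, max_size=40).filter(
            lambda c: sum(c) > 0
        ),
        density=st.floats(0.001, 0.02),
    )
    @settings(max_examples=50, deadline=None)
    def test_mean_density_closure(self, counts, density):
        raw = RawProfile("g", np.array(counts), len(counts) + 1)
        try:
            prof = normalize(raw, density)
        except GeneRejected:
            return  # a legitimately rejected spiky profile
        assert prof.r_mean == pytest.approx(density, abs=1e-9)
        assert prof.r.sum() == pytest.approx(prof.N, abs=1e-9)


class TestCoverageFilter:
    def test_boundary_inclusive(self):
        L = 11
        raw = RawProfile("g", np.full(L - 1, 10), L)
        assert filter_gene(raw, 10).passed

    def test_no_reads(self):
        res = filter_gene(RawProfile("g", np.zeros(10, int), 11))
        assert not res.passed and res.reason == "no reads"

    def test_low_coverage(self):
        counts = np.zeros(100, dtype=int)
        counts[:50] = 10  # total 500 over 100 codons -> mean 5
        res = filter_gene(RawProfile("g", counts, 101), 10)
        assert not res.passed and res.reason == "low coverage"
        assert res.mean_reads == pytest.approx(5.0)

    def test_zero_count_codons_reported(self):
        counts = np.full(10, 20)
        counts[3] = 0
        res = filter_gene(RawProfile("g", counts, 11))
        assert res.passed
        np.testing.assert_array_equal(res.zero_count_codons, [5])


def test_counts_tsv_roundtrip(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {
            "gene_id": ["a"] * 3 + ["b"] * 2,
            "codon": [2, 3, 5, 2, 4],
            "count": [1, 2, 3, 4, 5],
        }
    )
    path = tmp_path / "counts.tsv"
    df.to_csv(path, sep="\t", index=False)
    profiles = read_counts_tsv(path)
    np.testing.assert_array_equal(profiles["a"].counts, [1, 2, 0, 3])
    np.testing.assert_array_equal(profiles["b"].counts, [4, 0, 5])
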