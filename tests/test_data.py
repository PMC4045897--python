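"""Container invariants, file round-trips, pooling and frequency reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from closedcmr import (
    CaptureData,
    CaptureFormatError,
    FrequencyData,
    capture_frequencies,
    pool_occasions,
    read_capture_data,
    restrict_to_period,
    write_capture_data,
)


class TestCaptureDataInvariants:
    def test_rejects_all_zero_history(self):
        with pytest.raises(ValueError, match="all-zero"):
            CaptureData(["a", "b"], ["1", "2"],
                        np.array([[1, 0], [0, 0]]))

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            CaptureData(["a"], ["1", "2"], np.array([[1, 2]]))

    def test_rejects_non_contiguous_period(self):
        with pytest.raises(ValueError, match="contiguous"):
            CaptureData(["a"], ["1", "2", "3"], np.array([[1, 1, 1]]),
                        primary_of={"1": "P1", "2": "P2", "3": "P1"})

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            CaptureData([], ["1"], np.zeros((0, 1)))


class TestIO:
    def test_csv_round_trip_identity(self, toy, tmp_path):
        path = tmp_path / "toy.csv"
        write_capture_data(toy, path, format="csv")
        back = read_capture_data(path, format="csv",
                                 design=path.with_suffix(".csv.yaml"))
        assert back.individuals == toy.individuals
        assert back.occasions == toy.occasions
        assert np.array_equal(back.matrix, toy.matrix)

    def test_csv_round_trip_preserves_design(self, three_periods, tmp_path):
        path = tmp_path / "d.csv"
        write_capture_data(three_periods, path, format="csv")
        back = read_capture_data(path, format="csv",
                                 design=path.with_suffix(".csv.yaml"))
        assert back.primary_of == three_periods.primary_of
        assert back.birth_period == three_periods.birth_period

    def test_inp_round_trip(self, toy, tmp_path):
        path = tmp_path / "toy.inp"
        write_capture_data(toy, path, format="inp")
        text = path.read_text()
        assert "111 1;" in text
        back = read_capture_data(path, format="inp")
        assert sorted(back.history_strings()) == sorted(toy.history_strings())

    def test_inp_single_record(self, tmp_path):
        p = tmp_path / "one.inp"
        p.write_text("/* a comment */\n111 1;\n")
        data = read_capture_data(p, format="inp")
        assert data.n_individuals == 1
        assert data.history_strings() == ["111"]

    def test_inp_frequency_expansion(self, tmp_path):
        p = tmp_path / "f.inp"
        p.write_text("110 3;\n011 2;\n")
        data = read_capture_data(p, format="inp")
        assert data.n_individuals == 5
        assert data.history_strings().count("110") == 3

    def test_inp_rejects_ragged_histories(self, tmp_path):
        p = tmp_path / "bad.inp"
        p.write_text("110 1;\n01 1;\n")
        with pytest.raises(CaptureFormatError, match="line 2"):
            read_capture_data(p, format="inp")

    def test_csv_rejects_non_binary_symbol(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,1,2\na,1,0\nb,1,7\n")
        with pytest.raises(CaptureFormatError, match="non-binary"):
            read_capture_data(p, format="csv")


class TestPooling:
    def test_pool_two_occasions_by_hand(self, toy):
        pooled = pool_occasions(toy, [["2", "3"]])
        assert pooled.occasions == ["1", "2+3"]
        b = pooled.individuals.index("B")
        assert pooled.matrix[b].tolist() == [1, 1]
        # distinct individuals detected in the pooled block: A, B, C, E
        assert pooled.occasion_captures().tolist() == [3, 4]

    def test_singleton_groups_identity(self, toy):
        pooled = pool_occasions(toy, [["1"], ["2"], ["3"]])
        assert np.array_equal(pooled.matrix, toy.matrix)

    def test_pool_everything_single_column(self, toy):
        pooled = pool_occasions(toy, [["1", "2", "3"]])
        assert pooled.n_occasions == 1
        assert pooled.matrix.sum() == 5  # every individual caught >= once
        assert capture_frequencies(pooled).S == 5

    def test_rejects_non_contiguous_group(self, toy):
        with pytest.raises(ValueError, match="contiguous"):
            pool_occasions(toy, [["1", "3"]])

    def test_rejects_cross_period_group(self, three_periods):
        with pytest.raises(ValueError, match="crosses"):
            pool_occasions(three_periods, [["a2", "b1"]])

    def test_pooling_never_increases_n_never_changes_S(self, toy):
        before = capture_frequencies(toy)
        after = capture_frequencies(pool_occasions(toy, [["2", "3"]]))
        assert after.n <= before.n
        assert after.S == before.S


class TestFrequencies:
    def test_toy_counts_by_hand(self, toy_freq):
        assert toy_freq.S == 5
        assert toy_freq.f.tolist() == [2, 2, 1]
        assert toy_freq.n == 9
        assert toy_freq.n_j.tolist() == [3, 3, 3]

    def test_all_ones_matrix(self, all_caught):
        fq = capture_frequencies(all_caught)
        assert fq.f.tolist() == [0, 0, 10]

    def test_frequency_identities(self, toy_freq):
        k = np.arange(1, len(toy_freq.f) + 1)
        assert toy_freq.f.sum() == toy_freq.S
        assert (k * toy_freq.f).sum() == toy_freq.n_j.sum()

    def test_inconsistent_n_j_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            FrequencyData(f=[2, 1], t=2, n_j=[1, 1])


class TestRestrict:
    def test_drops_individuals_absent_from_period(self, three_periods):
        p1 = restrict_to_period(three_periods, "P1")
        assert "Z" not in p1.individuals
        assert p1.individuals == ["X", "Y", "W"]
        assert p1.occasions == ["a1", "a2"]

    def test_restrict_then_frequencies_matches_block(self, three_periods):
        p2 = restrict_to_period(three_periods, "P2")
        fq = capture_frequencies(p2)
        # only W was caught in P2, once
        assert fq.S == 1 and fq.n == 1

    def test_unknown_period(self, three_periods):
        with pytest.raises(ValueError, match="unknown"):
            restrict_to_period(three_periods, "P9")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(2, 30), st.integers(2, 6), st.integers(0, 10_000))
def test_frequency_identities_hold_on_random_matrices(n_ind, n_occ, seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(0, 2, size=(n_ind, n_occ))
    m[m.sum(axis=1) == 0, 0] = 1  # ensure every animal caught once
    data = CaptureData([f"i{k}" for k in range(n_ind)],
                       [str(j) for j in range(n_occ)], m)
    fq = capture_frequencies(data)
    k = np.arange(1, len(fq.f) + 1)
    assert fq.f.sum() == fq.S == n_ind
    assert (k * fq.f).sum() == fq.n == fq.n_j.sum()
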