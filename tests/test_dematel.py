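import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from danpkit.dematel import (
    DegeneratePanelError,
    ExpertMatrix,
    PanelError,
    aggregate,
    consensus_gap,
    dimension_totals,
    influence_indices,
    normalize,
    read_panel_long,
    read_panel_wide,
    total_influence,
    write_panel_long,
    write_panel_wide,
)

from conftest import random_expert_values


def _expert(expert_id, values):
    return ExpertMatrix(expert_id=expert_id, values=np.asarray(values))


class TestExpertMatrix:
    def test_out_of_scale_entry_names_expert(self):
        with pytest.raises(PanelError, match="e7"):
            _expert("e7", [[0, 5], [1, 0]])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(PanelError, match="diagonal"):
            _expert("e1", [[1, 2], [3, 0]])

    def test_non_square_rejected(self):
        with pytest.raises(PanelError, match="square"):
            _expert("e1", np.zeros((2, 3), dtype=int))


class TestAggregate:
    def test_hand_mean_of_two_experts(self):
        panel = [_expert("a", [[0, 4], [2, 0]]), _expert("b", [[0, 2], [0, 0]])]
        A = aggregate(panel).A
        np.testing.assert_array_equal(A, [[0, 3], [1, 0]])

    def test_identical_experts_idempotent(self):
        values = [[0, 3], [1, 0]]
        panel = [_expert(str(k), values) for k in range(5)]
        np.testing.assert_array_equal(aggregate(panel).A, values)

    def test_matches_entrywise_loop_oracle(self):
        rng = np.random.default_rng(7)
        panel = [_expert(str(k), random_expert_values(rng, 18)) for k in range(33)]
        A = aggregate(panel).A
        # independent double-loop mean
        expected = np.empty((18, 18))
        for i in range(18):
            for j in range(18):
                expected[i, j] = sum(e.values[i, j] for e in panel) / len(panel)
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_empty_panel_rejected(self):
        with pytest.raises(PanelError, match="empty"):
            aggregate([])

    def test_shape_mismatch_names_expert(self):
        panel = [
            _expert("ok", np.zeros((3, 3), dtype=int) + np.diag([0, 0, 0])),
            _expert("bad", np.zeros((2, 2), dtype=int)),
        ]
        with pytest.raises(PanelError, match="bad"):
            aggregate(panel)

    @settings(deadline=None, max_examples=25)
    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, pyrandom):
        rng = np.random.default_rng(pyrandom.randrange(2**31))
        panel = [_expert(str(k), random_expert_values(rng, 5)) for k in range(6)]
        shuffled = list(panel)
        pyrandom.shuffle(shuffled)
        np.testing.assert_allclose(aggregate(panel).A, aggregate(shuffled).A, atol=1e-12)


class TestNormalize:
    def test_column_sum_dominates(self):
        norm = normalize(np.array([[0.0, 2.0], [4.0, 0.0]]))
        assert norm.delta == 4
        np.testing.assert_allclose(norm.D, [[0, 0.5], [1, 0]])

    def test_row_sum_dominates(self):
        A = np.array([[0.0, 10.0], [2.0, 0.0]])  # row sums (10, 2), col sums (2, 10)
        assert normalize(A).delta == 10

    def test_all_line_sums_at_most_one(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(0, 4, size=(17, 17))
        np.fill_diagonal(A, 0)
        D = normalize(A).D
        assert D.sum(axis=1).max() <= 1 + 1e-12
        assert D.sum(axis=0).max() <= 1 + 1e-12
        # the arg-max line hits 1 exactly
        assert np.isclose(max(D.sum(axis=1).max(), D.sum(axis=0).max()), 1.0)

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(DegeneratePanelError):
            normalize(np.zeros((3, 3)))


class TestTotalInfluence:
    def test_nilpotent_matrix_is_its_own_total(self):
        D = np.array([[0.0, 0.5], [0.0, 0.0]])
        np.testing.assert_allclose(total_influence(D), D)

    def test_zero_matrix(self):
        np.testing.assert_allclose(total_influence(np.zeros((3, 3))), np.zeros((3, 3)))

    def test_matches_neumann_series_oracle(self):
        rng = np.random.default_rng(3)
        # heterogeneous factor strengths keep the spectral radius of D low
        # enough for 60 series terms to resolve T to 1e-8
        A = rng.uniform(0.2, 1.0, size=18)[:, None] * rng.uniform(0, 4, size=(18, 18))
        np.fill_diagonal(A, 0)
        D = normalize(A).D
        T = total_influence(D)
        partial = np.zeros_like(D)
        power = np.eye(18)
        for _ in range(60):
            power = power @ D
            partial += power
        assert np.abs(T - partial).max() < 1e-8

    def test_entrywise_at_least_direct(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 4, size=(10, 10))
        np.fill_diagonal(A, 0)
        D = normalize(A).D
        assert np.all(total_influence(D) >= D - 1e-15)

    def test_singular_normalization_rejected(self):
        # row-stochastic D has spectral radius exactly 1 -> (I - D) singular
        D = np.full((3, 3), 1.0 / 3.0)
        with pytest.raises(DegeneratePanelError):
            total_influence(D)


class TestDimensionTotals:
    def test_all_ones_collapse_to_ones(self, small_system):
        T_D = dimension_totals(np.ones((4, 4)), small_system)
        np.testing.assert_allclose(T_D, np.ones((2, 2)))

    def test_block_constant_matrix(self, small_system):
        a, b, c, d = 0.1, 0.2, 0.3, 0.4
        T = np.block([[np.full((2, 2), a), np.full((2, 2), b)],
                      [np.full((2, 2), c), np.full((2, 2), d)]])
        np.testing.assert_allclose(dimension_totals(T, small_system), [[a, b], [c, d]])

    def test_matches_double_loop_block_mean_oracle(self, system):
        rng = np.random.default_rng(9)
        T = rng.uniform(size=(system.n, system.n))
        T_D = dimension_totals(T, system)
        slices = system.block_slices()
        for o in range(3):
            for p in range(3):
                total, count = 0.0, 0
                for i in range(slices[o].start, slices[o].stop):
                    for j in range(slices[p].start, slices[p].stop):
                        total += T[i, j]
                        count += 1
                assert T_D[o, p] == pytest.approx(total / count, abs=1e-12)


class TestInfluenceIndices:
    def test_grand_sum_conservation(self):
        rng = np.random.default_rng(13)
        T = rng.uniform(size=(17, 17))
        table = influence_indices(T, [f"f{i}" for i in range(17)])
        assert table["give"].sum() == pytest.approx(T.sum(), abs=1e-10)
        assert table["receive"].sum() == pytest.approx(T.sum(), abs=1e-10)
        np.testing.assert_allclose(table["center"], table["give"] + table["receive"])
        np.testing.assert_allclose(table["net"], table["give"] - table["receive"])

    def test_center_net_recombine_to_twice_give_and_receive(self):
        rng = np.random.default_rng(21)
        T = rng.uniform(size=(8, 8))
        table = influence_indices(T, list("abcdefgh"))
        np.testing.assert_allclose(table["center"] + table["net"], 2 * table["give"])
        np.testing.assert_allclose(table["center"] - table["net"], 2 * table["receive"])

    def test_symmetric_matrix_has_no_cause_group(self):
        rng = np.random.default_rng(17)
        T = rng.uniform(size=(6, 6))
        T = (T + T.T) / 2
        table = influence_indices(T, list("abcdef"))
        assert (table["group"] == "effect").all()
        np.testing.assert_allclose(table["net"], 0, atol=1e-12)

    def test_cause_requires_strictly_positive_net(self):
        T = np.array([[0.0, 2.0], [1.0, 0.0]])
        table = influence_indices(T, ["a", "b"])
        assert list(table["group"]) == ["cause", "effect"]


class TestScalingInvariance:
    def test_constant_panel_rescale_leaves_d_and_t_unchanged(self):
        rng = np.random.default_rng(23)
        A = rng.uniform(0.5, 3.5, size=(9, 9))
        np.fill_diagonal(A, 0)
        D1 = normalize(A)
        D2 = normalize(2.5 * A)
        assert D2.delta == pytest.approx(2.5 * D1.delta)
        np.testing.assert_allclose(D1.D, D2.D, atol=1e-14)
        np.testing.assert_allclose(total_influence(D1), total_influence(D2), atol=1e-12)


class TestConsensusGap:
    def test_identical_experts_have_zero_gap(self):
        panel = [_expert(str(k), [[0, 3], [2, 0]]) for k in range(2)]
        report = consensus_gap(panel)
        assert report.gap == 0
        assert report.confidence == 1

    def test_last_expert_at_running_mean_leaves_gap_zero(self):
        base = [[0, 2], [4, 0]]
        other = [[0, 4], [2, 0]]
        mean = [[0, 3], [3, 0]]
        panel = [_expert("a", base), _expert("b", other), _expert("c", mean)]
        assert consensus_gap(panel).gap == pytest.approx(0, abs=1e-15)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(29)
        panel = [_expert(str(k), random_expert_values(rng, 18)) for k in range(33)]
        report = consensus_gap(panel)
        n, v = 18, len(panel)
        full = np.mean([e.values for e in panel], axis=0)
        head = np.mean([e.values for e in panel[:-1]], axis=0)
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i != j and full[i, j] > 0:
                    total += abs(full[i, j] - head[i, j]) / full[i, j]
        assert report.gap == pytest.approx(total / (n * (n - 1)), abs=1e-12)
        assert report.confidence == pytest.approx(1 - report.gap)

    def test_single_expert_rejected(self):
        with pytest.raises(PanelError):
            consensus_gap([_expert("solo", [[0, 1], [1, 0]])])

    def test_depends_on_which_expert_is_last(self):
        rng = np.random.default_rng(31)
        panel = [_expert(str(k), random_expert_values(rng, 6)) for k in range(5)]
        reordered = [panel[-1]] + panel[1:-1] + [panel[0]]
        assert consensus_gap(panel).gap != consensus_gap(reordered).gap


class TestPanelIO:
    def _random_panel(self, system, size=4, seed=37):
        rng = np.random.default_rng(seed)
        return [_expert(f"expert{k:02d}", random_expert_values(rng, system.n)) for k in range(size)]

    def test_wide_round_trip(self, system, tmp_path):
        panel = self._random_panel(system)
        paths = write_panel_wide(panel, system, tmp_path)
        loaded = read_panel_wide(paths, system)
        assert [e.expert_id for e in loaded] == [e.expert_id for e in panel]
        for a, b in zip(panel, loaded):
            np.testing.assert_array_equal(a.values, b.values)

    def test_long_round_trip(self, system, tmp_path):
        panel = self._random_panel(system, seed=41)
        path = write_panel_long(panel, system, tmp_path / "panel.csv")
        loaded = read_panel_long(path, system)
        for a, b in zip(panel, loaded):
            np.testing.assert_array_equal(a.values, b.values)

    def test_wide_rejects_code_mismatch(self, system, small_system, tmp_path):
        panel = self._random_panel(small_system)
        paths = write_panel_wide(panel, small_system, tmp_path)
        with pytest.raises(PanelError, match="codes"):
            read_panel_wide(paths, system)

    def test_long_rejects_incomplete_matrix(self, small_system, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "expert_id,source,target,score\n"
            "e1,D11,D12,3\n"  # all other pairs missing
        )
        with pytest.raises(PanelError, match="incomplete"):
            read_panel_long(path, small_system)
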