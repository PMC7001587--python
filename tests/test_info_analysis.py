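"""Binned single-cell information: worked example, oracle equivalence,
and the analytic bounds that hold for every computed entry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sharedrep.info_analysis import (
    ActivationMatrix,
    AnalysisError,
    BinnedResponseTable,
    assign_bins,
    bin_responses,
    info_matrix,
    make_bin_edges,
    max_information,
    rank_order_curve,
    shuffled_info_null,
    single_cell_information,
)
from sharedrep.synthetic_data import (
    PlantedActivationSpec,
    closed_form_information,
    plant_activations,
    selective_unit,
)

from conftest import TABLE1_BITS, brute_force_information


class TestWorkedExample:
    @pytest.mark.parametrize("category,expected", list(TABLE1_BITS.items()))
    def test_printed_information_values(self, table1, category, expected):
        """The 4-category, 3-bin count table reproduces the printed
        per-category information to the printed precision."""
        assert single_cell_information(table1, category) == pytest.approx(
            expected, abs=1e-3)

    def test_marginal_totals(self, table1):
        assert np.allclose(table1.p_r() * 400, [209, 85, 106])

    def test_preferred_category_is_A(self, table1):
        infos = {s: single_cell_information(table1, s) for s in "ABCD"}
        assert max(infos, key=infos.get) == "A"


class TestBinning:
    def test_worked_example_edges_put_033_in_middle_bin(self):
        # the example's printed bins: [0, 0.33), [0.33, 0.67), [0.67, 1]
        assert assign_bins(np.array([0.33]), [0.0, 0.33, 0.67, 1.0])[0] == 1

    def test_upper_edge_closed(self):
        assert assign_bins(np.array([1.0]), make_bin_edges(3))[0] == 2

    def test_left_closed_right_open(self):
        edges = make_bin_edges(10)
        vals = np.array([0.0, 0.1, 0.1 - 1e-12, 0.999, 1.0])
        assert assign_bins(vals, edges).tolist() == [0, 1, 0, 9, 9]

    def test_out_of_range_clipped_with_warning(self):
        acts = ActivationMatrix(np.array([[1.5], [-0.2]]), np.array([0, 1]),
                                np.array(["both", "both"]))
        with pytest.warns(UserWarning):
            table = bin_responses(acts, 0, n_bins=3)
        assert table.counts.sum() == 2

    def test_table_reconstruction_from_samples(self):
        """Sampling bin centers with known multiplicities reproduces an
        exact count table."""
        rng = np.random.default_rng(0)
        counts = np.array([[3, 17, 80], [68, 31, 1]])
        centers = [0.15, 0.5, 0.9]
        vals, labels = [], []
        for s in range(2):
            for b in range(3):
                vals.extend([centers[b]] * counts[s, b])
                labels.extend([s] * counts[s, b])
        order = rng.permutation(len(vals))
        acts = ActivationMatrix(np.array(vals)[order, None],
                                np.array(labels)[order],
                                np.full(len(vals), "both"))
        table = bin_responses(acts, 0, bin_edges=[0.0, 0.33, 0.67, 1.0])
        assert np.array_equal(table.counts, counts)

    def test_too_few_bins_rejected(self):
        with pytest.raises(AnalysisError):
            make_bin_edges(1)


class TestSingleCellInformation:
    def test_identical_rows_give_zero(self):
        table = BinnedResponseTable(counts=np.tile([10, 20, 30], (4, 1)),
                                    bin_edges=make_bin_edges(3))
        for s in range(4):
            assert single_cell_information(table, s) == pytest.approx(0.0, abs=1e-12)

    def test_empty_category_row_rejected(self):
        table = BinnedResponseTable(counts=np.array([[5, 5], [0, 0]]),
                                    bin_edges=make_bin_edges(2))
        with pytest.raises(AnalysisError):
            single_cell_information(table, 1)

    def test_missing_category_rejected(self, table1):
        with pytest.raises(AnalysisError):
            single_cell_information(table1, "Z")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        """Direct summation over the materialized joint table agrees to
        1e-9 on randomized count tables."""
        rng = np.random.default_rng(seed)
        n_cat = int(rng.integers(2, 8))
        n_bins = int(rng.integers(2, 12))
        counts = rng.integers(0, 50, (n_cat, n_bins)).astype(float)
        counts[:, 0] += 1  # no empty category rows
        table = BinnedResponseTable(counts=counts,
                                    bin_edges=make_bin_edges(n_bins))
        for s in range(n_cat):
            assert single_cell_information(table, s) == pytest.approx(
                brute_force_information(counts, s), abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_with_equal_priors(self, seed):
        """0 <= I(s, R) <= log2(nCat) whenever classes are equally
        presented."""
        rng = np.random.default_rng(seed)
        n_cat = int(rng.integers(2, 11))
        n_bins = int(rng.integers(2, 12))
        # equal row totals = equal priors
        counts = rng.multinomial(60, np.ones(n_bins) / n_bins, size=n_cat).astype(float)
        table = BinnedResponseTable(counts=counts, bin_edges=make_bin_edges(n_bins))
        bound = max_information(n_cat)
        for s in range(n_cat):
            info = single_cell_information(table, s)
            assert -1e-12 <= info <= bound + 1e-9


class TestInfoMatrix:
    def test_shape(self):
        rng = np.random.default_rng(3)
        acts = ActivationMatrix(rng.random((300, 64)),
                                np.repeat(np.arange(10), 30),
                                np.full(300, "both"))
        table = info_matrix(acts, n_bins=10)
        assert table.info.shape == (64, 10)

    def test_constant_unit_is_all_zero(self):
        acts = ActivationMatrix(np.full((40, 2), 0.5),
                                np.repeat(np.arange(4), 10),
                                np.full(40, "both"))
        assert np.allclose(info_matrix(acts, n_bins=5).info, 0.0)

    def test_planted_unit_matches_closed_form(self):
        """Deterministic planted responses (full bin occupancy per the
        plan) give exactly the closed-form information."""
        spec = PlantedActivationSpec(
            units=(selective_unit(10, 10, visual_digits=[0]),), n_bins=10)
        acts = plant_activations(spec, n_per_class=2000, seed=5)
        table = info_matrix(acts.filtered("visual_only"), n_bins=10)
        expected = closed_form_information(spec.units[0].dist_visual)
        assert np.allclose(table.info[0], expected, atol=0.05)
        # the planted digit carries maximal information
        assert table.info[0].argmax() == 0

    def test_condition_filter_selects_rows(self):
        resp = np.concatenate([np.zeros((20, 1)), np.ones((20, 1))])
        labels = np.tile(np.repeat([0, 1], 10), 2)
        conds = np.array(["visual_only"] * 20 + ["audio_only"] * 20)
        acts = ActivationMatrix(resp, labels, conds)
        # within each condition the unit is constant -> zero info
        assert np.allclose(info_matrix(acts, 5, "visual_only").info, 0.0)
        # pooled, the unit still carries no digit information
        assert np.allclose(info_matrix(acts, 5, "all").info, 0.0)

    def test_empty_filter_rejected(self):
        acts = ActivationMatrix(np.zeros((4, 1)), np.zeros(4, dtype=int),
                                np.full(4, "both"))
        with pytest.raises(AnalysisError):
            info_matrix(acts, 5, "visual_only")

    def test_monotone_remapping_invariance(self):
        """Any strictly monotone activation remap preserving bin
        assignment leaves the information unchanged."""
        rng = np.random.default_rng(11)
        resp = rng.random((400, 8))
        labels = np.repeat(np.arange(10), 40)
        conds = np.full(400, "both")
        base = info_matrix(ActivationMatrix(resp, labels, conds), 10).info
        edges = make_bin_edges(10)
        idx = assign_bins(resp, edges)
        # remap every response to a shifted point inside its own bin
        remapped = edges[idx] + 0.25 * (edges[idx + 1] - edges[idx])
        again = info_matrix(ActivationMatrix(remapped, labels, conds), 10).info
        assert np.allclose(base, again, atol=1e-12)


class TestMaxInformation:
    @pytest.mark.parametrize("n_cat,expected", [
        (10, np.log2(10)), (4, 2.0), (1, 0.0),
    ])
    def test_values(self, n_cat, expected):
        assert max_information(n_cat) == pytest.approx(expected, abs=1e-12)

    def test_invalid(self):
        with pytest.raises(AnalysisError):
            max_information(0)


class TestRankOrderCurve:
    def test_descending_per_unit_maxima(self):
        info = np.zeros((5, 10))
        info[2, 7] = np.log2(10)
        from sharedrep.info_analysis import InfoTable
        curve = rank_order_curve(InfoTable(info=info, n_bins=10))
        assert curve[0] == pytest.approx(np.log2(10))
        assert np.allclose(curve[1:], 0.0)
        assert np.all(np.diff(curve) <= 0)


class TestShuffleNull:
    def test_planted_selectivity_exceeds_null(self):
        """Planted selective units carry information above the 95th
        percentile of the label-shuffle null; the null itself sits near
        the finite-sampling floor, far below the planted value."""
        spec = PlantedActivationSpec(
            units=tuple(selective_unit(10, 10, visual_digits=[d]) for d in range(4)),
            n_bins=10)
        acts = plant_activations(spec, n_per_class=100, seed=9).filtered("visual_only")
        observed = info_matrix(acts, 10).max_per_unit()
        null = shuffled_info_null(acts, n_bins=10, n_shuffles=20, seed=3)
        q95 = np.quantile(null, 0.95, axis=0)
        assert np.all(observed > q95)
        assert null.mean() < 0.5 * observed.mean()
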