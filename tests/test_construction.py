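import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connectoctrl as cc
from connectoctrl.construction import STUDY_FRACTIONS

from conftest import make_matrix, symmetric_weights


def matrix_from_upper(values, n, **kw):
    """Place `values` on the upper triangle of an n x n symmetric matrix."""
    w = np.zeros((n, n))
    w[np.triu_indices(n, k=1)] = values
    return make_matrix(w + w.T, **kw)


def fc_from_correlation(r, **kw):
    """Store a correlation matrix the way the pipeline expects FC: Fisher z."""
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    np.fill_diagonal(z, 0.0)
    return make_matrix(z, modality="FC", **kw)


class TestPercentageThreshold:
    def test_hand_counted_cutoff_on_ten_weights(self):
        # weights 1..10 on K5, remove 30% -> cutoff 3, seven edges survive
        m = matrix_from_upper(np.arange(1.0, 11.0), 5)
        g = cc.percentage_threshold(m, cc.ThresholdSpec(fraction=0.30))
        assert g.provenance["cutoff"] == 3.0
        assert g.n_edges == 7

    def test_zero_fraction_keeps_every_nonzero_edge(self):
        rng = np.random.default_rng(0)
        m = make_matrix(symmetric_weights(rng, 8, density=0.5))
        g = cc.percentage_threshold(m, cc.ThresholdSpec(fraction=0.0))
        assert g.n_edges == np.count_nonzero(np.triu(m.values, 1))

    def test_ties_at_cutoff_are_all_removed(self):
        m = matrix_from_upper(np.full(10, 2.0), 5)
        g = cc.percentage_threshold(m, cc.ThresholdSpec(fraction=0.10))
        assert g.n_edges == 0  # every weight equals the cutoff

    def test_shared_control_cutoff_shrinks_weakened_patient_graph(self):
        rng = np.random.default_rng(1)
        control = make_matrix(symmetric_weights(rng, 12, density=0.8),
                              group="control")
        patient = make_matrix(0.5 * control.values, group="IDHwt")
        spec = cc.ThresholdSpec(fraction=0.30, reference=control)
        g_control = cc.percentage_threshold(control, spec)
        g_patient = cc.percentage_threshold(patient, spec)
        assert g_patient.n_edges < g_control.n_edges

    def test_all_zero_matrix_yields_empty_graph(self):
        m = make_matrix(np.zeros((4, 4)))
        g = cc.percentage_threshold(m, cc.ThresholdSpec(fraction=0.30))
        assert g.n_edges == 0

    def test_magnitude_thresholding_keeps_strong_negative_fc(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = -0.9
        r[1, 2] = r[2, 1] = 0.2
        m = fc_from_correlation(r)
        g = cc.percentage_threshold(m, cc.ThresholdSpec(fraction=0.4))
        assert (1, 2) in g.edges()  # the strong anticorrelation survives

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10**6),
           pair=st.tuples(st.floats(0, 0.9), st.floats(0, 0.9)))
    def test_edge_sets_nest_as_fraction_grows(self, seed, pair):
        lo, hi = sorted(pair)
        rng = np.random.default_rng(seed)
        m = make_matrix(symmetric_weights(rng, 10, density=0.6))
        g_lo = cc.percentage_threshold(m, cc.ThresholdSpec(fraction=lo))
        g_hi = cc.percentage_threshold(m, cc.ThresholdSpec(fraction=hi))
        assert set(g_hi.edges()) <= set(g_lo.edges())

    def test_reference_with_different_labels_rejected(self):
        m = make_matrix(np.zeros((3, 3)))
        ref = make_matrix(np.zeros((3, 3)),
                          labels=cc.RoiLabelSet((7, 8, 9)))
        with pytest.raises(ValueError):
            cc.percentage_threshold(m, cc.ThresholdSpec(fraction=0.1, reference=ref))


class TestAdaptiveThreshold:
    def test_two_edge_path_keeps_the_weak_bridge(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.1
        m = make_matrix(w)
        g, cutoff = cc.adaptive_threshold(m)
        assert g.n_edges == 2  # removing the 0.1 edge would disconnect
        assert 0.1 - 1e-4 <= cutoff < 0.1

    def test_equal_weight_complete_graph_stays_complete(self):
        c = 0.7
        m = matrix_from_upper(np.full(6, c), 4)
        g, cutoff = cc.adaptive_threshold(m)
        assert g.n_edges == 6
        assert c - 1e-4 <= cutoff < c

    def test_weakest_bridge_edge_always_survives(self):
        # two K3 blocks joined by a single weakest edge
        w = np.zeros((6, 6))
        for i, j in itertools.combinations(range(3), 2):
            w[i, j] = w[j, i] = 1.0
            w[i + 3, j + 3] = w[j + 3, i + 3] = 1.0
        w[2, 3] = w[3, 2] = 0.05
        g, _ = cc.adaptive_threshold(make_matrix(w))
        assert (3, 4) in g.edges()  # labels are 1-based: bridge is 3-4

    def test_output_connected_and_two_tolerance_more_disconnects(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            m = make_matrix(symmetric_weights(rng, 10, density=0.9) + 0.01)
            g, cutoff = cc.adaptive_threshold(m)
            assert nx.is_connected(g.to_networkx())
            harder = (np.abs(m.values) > cutoff + 2e-4).astype(int)
            np.fill_diagonal(harder, 0)
            assert not nx.is_connected(nx.from_numpy_array(harder))

    def test_disconnected_input_is_an_error(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0  # nodes 3, 4 isolated
        with pytest.raises(cc.DisconnectedGraphError):
            cc.adaptive_threshold(make_matrix(w))


class TestPartialCorrelation:
    def test_identity_correlation_gives_empty_graph(self):
        m = fc_from_correlation(np.eye(4))
        g = cc.partial_correlation_graph(m, cc.ThresholdSpec(soft_threshold=0.0))
        assert g.n_edges == 0

    def test_gaussian_chain_recovers_two_edges_only(self):
        # x - y - z chain precision; the marginal x-z correlation is nonzero
        # but the partial correlation vanishes
        prec = np.array([[1.0, -0.5, 0.0], [-0.5, 1.5, -0.5], [0.0, -0.5, 1.0]])
        cov = np.linalg.inv(prec)
        d = np.sqrt(np.diag(cov))
        r = cov / np.outer(d, d)
        assert abs(r[0, 2]) > 0.1  # marginally correlated
        m = fc_from_correlation(r)
        g = cc.partial_correlation_graph(m, cc.ThresholdSpec(soft_threshold=0.05))
        assert g.edges() == [(1, 2), (2, 3)]

    def test_soft_threshold_one_empties_any_graph(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(200, 5))
        r = np.corrcoef(x, rowvar=False)
        m = fc_from_correlation(r)
        g = cc.partial_correlation_graph(m, cc.ThresholdSpec(soft_threshold=1.0))
        assert g.n_edges == 0

    def test_support_recovery_from_sparse_precision(self):
        # strong-signal support recovery at n <= 8
        rng = np.random.default_rng(8)
        n = 8
        g_true = nx.random_labeled_tree(n, seed=4)
        prec = np.eye(n) * 2.0
        for i, j in g_true.edges:
            prec[i, j] = prec[j, i] = -0.6
        cov = np.linalg.inv(prec)
        d = np.sqrt(np.diag(cov))
        r = cov / np.outer(d, d)
        m = fc_from_correlation(r)
        g = cc.partial_correlation_graph(m, cc.ThresholdSpec(soft_threshold=0.1))
        expected = sorted(tuple(sorted((i + 1, j + 1))) for i, j in g_true.edges)
        assert g.edges() == expected

    def test_non_positive_definite_named_in_error(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(r)[0] < 0
        m = fc_from_correlation(r)
        with pytest.raises(cc.NotPositiveDefiniteError, match="eigenvalue"):
            cc.partial_correlation_graph(m)

    def test_sc_input_rejected(self):
        m = make_matrix(np.zeros((3, 3)), modality="SC")
        with pytest.raises(ValueError):
            cc.partial_correlation_graph(m)


def _brute_force_max_spanning_tree_weight(w: np.ndarray) -> float:
    """Exhaustive maximum over all spanning trees (n <= 7)."""
    n = w.shape[0]
    edges = [(i, j) for i, j in itertools.combinations(range(n), 2) if w[i, j] > 0]
    best = -np.inf
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == n and nx.is_connected(g):
            best = max(best, sum(w[i, j] for i, j in subset))
    return best


class TestChowLiuTree:
    def test_26_node_connected_input_yields_25_edges(self, study_set):
        for group in cc.GROUPS:
            g = cc.chow_liu_tree(study_set[(group, "SC")])
            assert g.n_edges == 25
            assert nx.is_connected(g.to_networkx())

    def test_triangle_keeps_the_two_heaviest_edges(self):
        m = matrix_from_upper(np.array([3.0, 2.0, 1.0]), 3)  # w12=3 w13=2 w23=1
        g = cc.chow_liu_tree(m)
        assert g.edges() == [(1, 2), (1, 3)]

    def test_tree_input_is_returned_unchanged(self):
        w = np.zeros((5, 5))
        for i in range(4):
            w[i, i + 1] = w[i + 1, i] = float(i + 1)
        m = make_matrix(w)
        g = cc.chow_liu_tree(m)
        assert g.edges() == [(1, 2), (2, 3), (3, 4), (4, 5)]

    def test_matches_exhaustive_enumeration_up_to_seven_nodes(self):
        rng = np.random.default_rng(12)
        for n in range(3, 8):
            w = symmetric_weights(rng, n, density=0.8)
            m = make_matrix(w)
            if not nx.is_connected(nx.from_numpy_array((w > 0).astype(int))):
                continue
            g = cc.chow_liu_tree(m)
            total = sum(w[i - 1, j - 1] for i, j in g.edges())
            assert total == pytest.approx(
                _brute_force_max_spanning_tree_weight(w), abs=1e-10
            )

    def test_deterministic_tie_break_by_label_order(self):
        # all weights equal: Kruskal must pick edges in ascending label order
        m = matrix_from_upper(np.full(6, 1.0), 4)
        g = cc.chow_liu_tree(m)
        assert g.edges() == [(1, 2), (1, 3), (1, 4)]

    def test_disconnected_input_is_an_error(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(cc.DisconnectedGraphError):
            cc.chow_liu_tree(make_matrix(w))


class TestProvenance:
    def test_every_scheme_records_method_and_parameters(self, study_set):
        m = study_set[("control", "SC")]
        fc = study_set[("control", "FC")]
        g1 = cc.percentage_threshold(m, cc.ThresholdSpec(fraction=0.30))
        assert g1.provenance["method"] == "percentage"
        assert "cutoff" in g1.provenance
        g2, cutoff = cc.adaptive_threshold(m)
        assert g2.provenance == {"method": "adaptive", "cutoff": cutoff,
                                 "tolerance": 1e-4}
        g3 = cc.partial_correlation_graph(fc)
        assert g3.provenance["soft_threshold"] == 0.1
        g4 = cc.chow_liu_tree(m)
        assert g4.provenance["method"] == "chowliu"

    def test_study_fractions_are_canonical(self):
        assert STUDY_FRACTIONS == (0.025, 0.05, 0.10, 0.20, 0.30)
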