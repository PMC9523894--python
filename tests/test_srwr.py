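"""Signed random walk: normalization, fixed point, prediction, LOOCV."""

import numpy as np
import pytest

from micropharm import (
    SignedEdge,
    SignedNetwork,
    SRWRParams,
    annotate_all,
    loocv,
    macro_f1,
    predict_label,
    semi_row_normalize,
    srwr,
)
from oracles import classical_rwr, random_signed_digraph, signed_walk_linear_solution


def net_from_weights(weights):
    """Build a SignedNetwork from {(u, v): weight}."""
    net = SignedNetwork()
    nodes = sorted({n for pair in weights for n in pair})
    net.graph.add_nodes_from(nodes)
    for (u, v), w in weights.items():
        pos, neg = (w, 0.0) if w > 0 else (0.0, -w)
        net.add_edge(SignedEdge(u, v, neg, pos, w))
    return net


def net_from_matrix(w):
    net = SignedNetwork()
    n = w.shape[0]
    names = [f"n{i:02d}" for i in range(n)]
    net.graph.add_nodes_from(names)
    for i in range(n):
        for j in range(n):
            if w[i, j] != 0.0:
                weight = float(w[i, j])
                pos, neg = (weight, 0.0) if weight > 0 else (0.0, -weight)
                net.add_edge(SignedEdge(names[i], names[j], neg, pos, weight))
    return net


class TestSemiRowNormalize:
    def test_single_negative_edge(self):
        ops = semi_row_normalize(net_from_weights({("u", "v"): -0.5}))
        iu, iv = ops.index["u"], ops.index["v"]
        assert ops.t_minus[iu, iv] == 1.0
        assert ops.t_plus[iu, iv] == 0.0
        assert ops.dangling[iv] and not ops.dangling[iu]

    def test_mixed_row_splits_by_magnitude(self):
        ops = semi_row_normalize(
            net_from_weights({("u", "v"): 0.3, ("u", "w"): -0.1})
        )
        iu = ops.index["u"]
        assert ops.t_plus[iu, ops.index["v"]] == pytest.approx(0.75)
        assert ops.t_minus[iu, ops.index["w"]] == pytest.approx(0.25)

    def test_all_positive_network_has_zero_negative_part(self):
        ops = semi_row_normalize(
            net_from_weights({("a", "b"): 0.2, ("b", "c"): 0.9, ("c", "a"): 0.5})
        )
        assert not ops.t_minus.any()
        np.testing.assert_allclose(ops.t_plus.sum(axis=1), 1.0)

    def test_row_sums_are_one_for_non_dangling(self, rng):
        net = net_from_matrix(random_signed_digraph(rng, max_nodes=15))
        ops = semi_row_normalize(net)
        totals = ops.t_plus.sum(axis=1) + ops.t_minus.sum(axis=1)
        np.testing.assert_allclose(totals[~ops.dangling], 1.0, atol=1e-12)
        assert (totals[ops.dangling] == 0.0).all()


class TestSRWR:
    def test_two_node_mutual_positive_closed_form(self):
        net = net_from_weights({("a", "b"): 1.0, ("b", "a"): 1.0})
        ops = semi_row_normalize(net)
        scores = srwr(ops, "a", SRWRParams(c=0.15))
        c = 0.15
        p1 = c / (1.0 - (1.0 - c) ** 2)
        assert scores.p_of("a") == pytest.approx(p1, abs=1e-8)
        assert scores.p_of("b") == pytest.approx((1 - c) * p1, abs=1e-8)
        assert scores.p_of("a") == pytest.approx(0.540540540, abs=1e-6)
        assert not scores.m.any()
        assert scores.converged

    def test_matches_linear_system_oracle_on_random_digraphs(self, rng):
        params = SRWRParams(c=0.15, beta=0.5, gamma=0.5, tol=1e-12, max_iter=5000)
        worst = 0.0
        for _ in range(20):
            w = random_signed_digraph(rng, max_nodes=25)
            net = net_from_matrix(w)
            ops = semi_row_normalize(net)
            seed = ops.nodes[int(rng.integers(len(ops.nodes)))]
            scores = srwr(ops, seed, params)
            p_ref, m_ref = signed_walk_linear_solution(
                ops.t_plus,
                ops.t_minus,
                ops.dangling,
                ops.index[seed],
                params.c,
                params.beta,
                params.gamma,
            )
            worst = max(
                worst,
                np.max(np.abs(scores.p - p_ref)),
                np.max(np.abs(scores.m - m_ref)),
            )
            assert scores.p.sum() + scores.m.sum() == pytest.approx(1.0, abs=1e-8)
        assert worst < 1e-8

    def test_all_positive_reduces_to_classical_rwr(self, rng):
        for _ in range(5):
            w = np.abs(random_signed_digraph(rng, max_nodes=15))
            net = net_from_matrix(w)
            ops = semi_row_normalize(net)
            scores = srwr(ops, ops.nodes[0], SRWRParams(tol=1e-13, max_iter=5000))
            assert not scores.m.any()
            # weights enter by magnitude, so reconstruct the matrix in node order
            n = len(ops.nodes)
            dense = ops.t_plus  # already row-normalized, same object suffices
            ref = classical_rwr(dense, 0, 0.15)
            assert np.max(np.abs(scores.p - ref)) < 1e-10

    def test_scores_nonnegative_and_conserved(self, rng):
        for _ in range(5):
            net = net_from_matrix(random_signed_digraph(rng, max_nodes=20))
            ops = semi_row_normalize(net)
            scores = srwr(ops, ops.nodes[0], SRWRParams())
            assert (scores.p >= 0).all() and (scores.m >= 0).all()
            assert scores.p.sum() + scores.m.sum() == pytest.approx(1.0, abs=1e-8)

    def test_deterministic_bitwise(self, rng):
        net = net_from_matrix(random_signed_digraph(rng, max_nodes=12))
        ops = semi_row_normalize(net)
        first = srwr(ops, ops.nodes[1], SRWRParams())
        second = srwr(ops, ops.nodes[1], SRWRParams())
        assert (first.p == second.p).all() and (first.m == second.m).all()

    def test_unknown_seed_rejected(self):
        ops = semi_row_normalize(net_from_weights({("a", "b"): 1.0}))
        with pytest.raises(KeyError):
            srwr(ops, "zzz")

    def test_nonconvergence_reported_via_flag(self):
        net = net_from_weights({("a", "b"): 1.0, ("b", "a"): 1.0})
        scores = srwr(semi_row_normalize(net), "a", SRWRParams(tol=1e-15, max_iter=3))
        assert not scores.converged
        assert scores.iterations == 3


class TestPredictLabel:
    def test_single_negative_hop_marks_enemy(self):
        net = net_from_weights({("seed", "L"): -1.0})
        scores = srwr(semi_row_normalize(net), "seed")
        assert scores.m_of("L") > 0 and scores.p_of("L") == 0
        pred = predict_label(scores, {"L": 1})
        assert pred.s_neg > pred.s_pos
        assert pred.predicted == -1

    def test_enemy_of_enemy_scores_positive(self):
        # two negative hops route beta of the negative mass back to positive;
        # at beta = 0.5 the two channels tie exactly, above 0.5 the
        # friend-of-friend reading wins
        net = net_from_weights({("seed", "X"): -1.0, ("X", "L"): -1.0})
        balanced = srwr(semi_row_normalize(net), "seed", SRWRParams(beta=0.5))
        assert balanced.p_of("L") > 0
        assert balanced.p_of("L") == pytest.approx(balanced.m_of("L"), abs=1e-12)
        trusting = srwr(semi_row_normalize(net), "seed", SRWRParams(beta=0.8))
        pred = predict_label(trusting, {"L": 1})
        assert pred.s_pos > pred.s_neg
        assert pred.predicted == 1

    def test_tie_rule(self):
        net = net_from_weights({("a", "b"): 1.0})
        scores = srwr(semi_row_normalize(net), "b")  # b dangling: all mass stays at b
        assert predict_label(scores, {"a": 1}, tie_rule="to_negative").predicted == -1
        assert predict_label(scores, {"a": 1}, tie_rule="to_positive").predicted == 1
        with pytest.raises(ValueError):
            predict_label(scores, {"a": 1}, tie_rule="coin_flip")

    def test_empty_labels_rejected(self):
        net = net_from_weights({("a", "b"): 1.0})
        scores = srwr(semi_row_normalize(net), "a")
        with pytest.raises(ValueError):
            predict_label(scores, {})

    def test_label_antisymmetry(self, rng):
        net = net_from_matrix(random_signed_digraph(rng, max_nodes=15))
        ops = semi_row_normalize(net)
        labels = {ops.nodes[1]: 1, ops.nodes[2]: -1, ops.nodes[3]: 1}
        scores = srwr(ops, ops.nodes[0])
        pred = predict_label(scores, labels)
        flipped = predict_label(scores, {k: -v for k, v in labels.items()})
        assert flipped.s_pos == pred.s_neg and flipped.s_neg == pred.s_pos


class TestAnnotateAndLoocv:
    @staticmethod
    def _two_cliques(size=3):
        weights = {}
        pos_nodes = [f"p{i}" for i in range(size)]
        neg_nodes = [f"q{i}" for i in range(size)]
        for group in (pos_nodes, neg_nodes):
            for a in group:
                for b in group:
                    if a != b:
                        weights[(a, b)] = 1.0
        return net_from_weights(weights), pos_nodes, neg_nodes

    def test_disjoint_uniform_cliques_recovered_perfectly(self):
        net, pos_nodes, neg_nodes = self._two_cliques()
        labels = {**{n: 1 for n in pos_nodes}, **{n: -1 for n in neg_nodes}}
        summary = loocv(net, labels)
        assert summary.macro_f1 == 1.0
        assert summary.n_evaluated == 6

    def test_isolated_labels_all_fall_to_negative(self):
        net = net_from_weights({("x", "y"): 1.0})
        net.graph.add_nodes_from(["i1", "i2", "i3", "i4"])
        labels = {"i1": 1, "i2": 1, "i3": -1, "i4": -1}
        summary = loocv(net, labels)
        assert summary.recall_neg == 1.0
        assert summary.recall_pos == 0.0

    def test_loocv_validates_label_table(self):
        net, pos_nodes, neg_nodes = self._two_cliques()
        with pytest.raises(ValueError):
            loocv(net, {pos_nodes[0]: 1})
        with pytest.raises(ValueError):
            loocv(net, {n: 1 for n in pos_nodes})

    def test_annotate_all_covers_every_unlabeled_node(self):
        net, pos_nodes, neg_nodes = self._two_cliques(size=4)
        labels = {pos_nodes[0]: 1, neg_nodes[0]: -1}
        preds = annotate_all(net, labels)
        assert {p.microbe_id for p in preds} == set(pos_nodes[1:] + neg_nodes[1:])
        assert sum(p.predicted == 1 for p in preds) + sum(
            p.predicted == -1 for p in preds
        ) == len(preds)
        by_id = {p.microbe_id: p.predicted for p in preds}
        assert all(by_id[n] == 1 for n in pos_nodes[1:])
        assert all(by_id[n] == -1 for n in neg_nodes[1:])


@pytest.mark.parametrize(
    "args, expected, tol",
    [
        ((0.780, 1.000, 1.000, 0.875), 0.905, 5e-4),
        ((1.0, 1.0, 1.0, 1.0), 1.0, 0),
        ((0.5, 0.5, 0.5, 0.5), 0.5, 0),
        ((0.0, 0.0, 1.0, 1.0), 0.5, 0),
    ],
)
def test_macro_f1(args, expected, tol):
    assert macro_f1(*args) == pytest.approx(expected, abs=tol or 1e-12)


def test_macro_f1_rejects_out_of_range():
    with pytest.raises(ValueError):
        macro_f1(1.2, 0.5, 0.5, 0.5)
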