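"""Signed Random Walk with Restart (SRWR) over the interaction network.

A signed surfer starts at a seed node carrying a positive sign and unit
score, restarts to the seed with probability ``c`` at every step, and
otherwise moves along outgoing edges with probability proportional to the
magnitude of their weights (semi-row normalization).  Edge signs route the
surfer's sign:

* a positive surfer crossing a positive edge stays positive;
* a positive surfer crossing a negative edge becomes negative;
* a negative surfer crossing a negative edge becomes positive with the
  balance-attenuation probability ``beta`` (enemy of my enemy), otherwise
  stays negative;
* a negative surfer crossing a positive edge stays negative with
  probability ``gamma`` (friend of my enemy), otherwise turns positive.

The stationary positive and negative visiting scores ``p`` and ``m`` rank
every node as friend or enemy of the seed.  Summing ``p`` over known
commensals plus ``m`` over known pathogens (and vice versa) predicts the
seed's own health label; leave-one-out cross-validation over the curated
labels measures the accuracy of that rule.

Fixed-point iteration, with the defaults ``beta = gamma = 0.5`` and restart
``c = 0.15``::

    p <- (1-c) * [T+^T p + beta*T-^T m + (1-gamma)*T+^T m] + c*q
    m <- (1-c) * [T-^T p + gamma*T+^T m + (1-beta)*T-^T m]

where ``T+``/``T-`` hold the positive entries / magnitudes of negative
entries of the semi-row-normalized weight matrix and ``q`` is the seed
indicator.  Mass leaving a dangling node (zero out-weight) restarts to the
seed, so ``sum(p) + sum(m) = 1`` at convergence.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .network import SignedNetwork

__all__ = [
    "SRWRParams",
    "TransitionOperators",
    "SRWRScores",
    "LabelPrediction",
    "ConfusionSummary",
    "semi_row_normalize",
    "srwr",
    "predict_label",
    "annotate_all",
    "loocv",
    "macro_f1",
]


@dataclass(frozen=True)
class SRWRParams:
    """Walk parameters: restart ``c``, attenuations ``beta``/``gamma``, stopping rule."""

    c: float = 0.15
    beta: float = 0.5
    gamma: float = 0.5
    tol: float = 1e-9
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.c < 1.0):
            raise ValueError("restart probability c must lie in (0, 1)")
        for name in ("beta", "gamma"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


@dataclass(frozen=True)
class TransitionOperators:
    """Semi-row-normalized split of the signed weight matrix.

    ``t_plus[i, j]`` / ``t_minus[i, j]`` are the probabilities of stepping
    from node ``i`` to node ``j`` along a positive / negative edge; rows of
    non-dangling nodes sum to one across the two parts.
    """

    t_plus: np.ndarray
    t_minus: np.ndarray
    nodes: tuple[str, ...]
    dangling: np.ndarray
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            object.__setattr__(
                self, "index", {node: i for i, node in enumerate(self.nodes)}
            )


def semi_row_normalize(network: SignedNetwork, reverse: bool = False) -> TransitionOperators:
    """Split the signed weight matrix into nonnegative transition operators.

    Each row of ``W`` (entry ``u, v`` = weight of edge ``u -> v``) is divided
    by the sum of absolute values of its entries; positive entries populate
    ``t_plus``, magnitudes of negative entries populate ``t_minus``.  Rows
    with zero total out-weight are flagged dangling.  With ``reverse=True``
    the walk runs against edge direction (scores flow source-ward).
    """
    nodes = tuple(sorted(network.graph.nodes))
    if not nodes:
        raise ValueError("cannot normalize an empty network")
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, d in network.graph.edges(data=True):
        w[index[u], index[v]] = d["weight"]
    if reverse:
        w = w.T
    norms = np.abs(w).sum(axis=1)
    dangling = norms == 0.0
    safe = np.where(dangling, 1.0, norms)
    w = w / safe[:, None]
    return TransitionOperators(
        t_plus=np.clip(w, 0.0, None),
        t_minus=np.clip(-w, 0.0, None),
        nodes=nodes,
        dangling=dangling,
    )


@dataclass(frozen=True)
class SRWRScores:
    """Positive (``p``) and negative (``m``) stationary scores for one seed."""

    seed: str
    nodes: tuple[str, ...]
    p: np.ndarray
    m: np.ndarray
    iterations: int
    converged: bool

    def p_of(self, node: str) -> float:
        return float(self.p[self.nodes.index(node)])

    def m_of(self, node: str) -> float:
        return float(self.m[self.nodes.index(node)])


def srwr(operators: TransitionOperators, seed: str, params: SRWRParams | None = None) -> SRWRScores:
    """Iterate the signed walk from ``seed`` to its stationary score vectors.

    Non-convergence within ``max_iter`` sweeps is reported through the
    ``converged`` flag, not an exception.
    """
    params = params or SRWRParams()
    if seed not in operators.index:
        raise KeyError(f"seed {seed!r} not in node set")
    n = len(operators.nodes)
    q = np.zeros(n)
    q[operators.index[seed]] = 1.0

    tp_t = operators.t_plus.T
    tm_t = operators.t_minus.T
    dangling = operators.dangling.astype(float)
    c, beta, gamma = params.c, params.beta, params.gamma

    p = q.copy()
    m = np.zeros(n)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        lost = float(dangling @ (p + m))  # mass at dangling nodes restarts to the seed
        p_new = (1.0 - c) * (tp_t @ p + beta * (tm_t @ m) + (1.0 - gamma) * (tp_t @ m) + lost * q) + c * q
        m_new = (1.0 - c) * (tm_t @ p + gamma * (tp_t @ m) + (1.0 - beta) * (tm_t @ m))
        delta = max(np.max(np.abs(p_new - p)), np.max(np.abs(m_new - m)))
        p, m = p_new, m_new
        if delta < params.tol:
            converged = True
            break
    return SRWRScores(
        seed=seed, nodes=operators.nodes, p=p, m=m, iterations=iterations, converged=converged
    )


@dataclass(frozen=True)
class LabelPrediction:
    microbe_id: str
    s_pos: float
    s_neg: float
    predicted: int


def predict_label(
    scores: SRWRScores,
    labels: Mapping[str, int],
    tie_rule: str = "to_negative",
) -> LabelPrediction:
    """Vote the seed's label from its scores at annotated nodes.

    ``s_pos`` collects positive scores at commensals plus negative scores at
    pathogens (evidence the seed behaves like the commensals); ``s_neg`` is
    the mirror image.  Ties fall to the ``tie_rule`` side (default
    pathogenic, the conservative choice for downstream drug screening).
    """
    if not labels:
        raise ValueError("predict_label requires at least one labeled node")
    if tie_rule not in ("to_negative", "to_positive"):
        raise ValueError("tie_rule must be 'to_negative' or 'to_positive'")
    index = {node: i for i, node in enumerate(scores.nodes)}
    s_pos = 0.0
    s_neg = 0.0
    for microbe, label in labels.items():
        if microbe not in index:
            raise KeyError(f"labeled microbe {microbe!r} not in score vector")
        i = index[microbe]
        if label == 1:
            s_pos += scores.p[i]
            s_neg += scores.m[i]
        elif label == -1:
            s_pos += scores.m[i]
            s_neg += scores.p[i]
        else:
            raise ValueError(f"label for {microbe!r} must be +1 or -1")
    if s_pos > s_neg:
        predicted = 1
    elif s_pos < s_neg:
        predicted = -1
    else:
        predicted = -1 if tie_rule == "to_negative" else 1
    return LabelPrediction(scores.seed, float(s_pos), float(s_neg), predicted)


def annotate_all(
    network: SignedNetwork,
    labels: Mapping[str, int],
    params: SRWRParams | None = None,
    tie_rule: str = "to_negative",
    reverse: bool = False,
) -> list[LabelPrediction]:
    """Predict a +/-1 label for every unlabeled node of the network."""
    if not labels:
        raise ValueError("annotate_all requires a nonempty label table")
    operators = semi_row_normalize(network, reverse=reverse)
    unlabeled = [node for node in operators.nodes if node not in labels]
    if not unlabeled:
        raise ValueError("no unlabeled nodes to annotate")
    predictions = []
    for node in unlabeled:
        scores = srwr(operators, node, params)
        predictions.append(predict_label(scores, labels, tie_rule))
    return predictions


@dataclass(frozen=True)
class ConfusionSummary:
    """Two-class confusion counts and derived metrics from LOOCV."""

    tp_pos: int
    fp_pos: int
    fn_pos: int
    tp_neg: int
    fp_neg: int
    fn_neg: int
    precision_pos: float
    recall_pos: float
    f1_pos: float
    precision_neg: float
    recall_neg: float
    f1_neg: float
    macro_f1: float

    @property
    def n_evaluated(self) -> int:
        return self.tp_pos + self.fn_pos + self.tp_neg + self.fn_neg

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__} | {
            "n_evaluated": self.n_evaluated
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def _f1(precision: float, recall: float) -> float:
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_f1(
    precision_pos: float, recall_pos: float, precision_neg: float, recall_neg: float
) -> float:
    """Unweighted mean of the two per-class F1 scores."""
    for val in (precision_pos, recall_pos, precision_neg, recall_neg):
        if not (0.0 <= val <= 1.0):
            raise ValueError("precision/recall values must lie in [0, 1]")
    return 0.5 * (_f1(precision_pos, recall_pos) + _f1(precision_neg, recall_neg))


def loocv(
    network: SignedNetwork,
    labels: Mapping[str, int],
    params: SRWRParams | None = None,
    tie_rule: str = "to_negative",
    reverse: bool = False,
) -> ConfusionSummary:
    """Leave-one-out cross-validation of the label-propagation rule.

    Each labeled node in turn is hidden, used as the walk seed, and
    predicted against the remaining labels.
    """
    if len(labels) < 2:
        raise ValueError("loocv needs at least two labeled nodes")
    if len(set(labels.values())) < 2:
        raise ValueError("loocv needs both classes among the labels")
    operators = semi_row_normalize(network, reverse=reverse)
    counts = {(true, pred): 0 for true in (1, -1) for pred in (1, -1)}
    for microbe, true_label in labels.items():
        held_out = {k: v for k, v in labels.items() if k != microbe}
        scores = srwr(operators, microbe, params)
        pred = predict_label(scores, held_out, tie_rule)
        counts[(true_label, pred.predicted)] += 1

    tp_pos = counts[(1, 1)]
    fn_pos = counts[(1, -1)]
    fp_pos = counts[(-1, 1)]
    tp_neg = counts[(-1, -1)]
    fn_neg = counts[(-1, 1)]
    fp_neg = counts[(1, -1)]
    precision_pos = _safe_div(tp_pos, tp_pos + fp_pos)
    recall_pos = _safe_div(tp_pos, tp_pos + fn_pos)
    precision_neg = _safe_div(tp_neg, tp_neg + fp_neg)
    recall_neg = _safe_div(tp_neg, tp_neg + fn_neg)
    return ConfusionSummary(
        tp_pos=tp_pos,
        fp_pos=fp_pos,
        fn_pos=fn_pos,
        tp_neg=tp_neg,
        fp_neg=fp_neg,
        fn_neg=fn_neg,
        precision_pos=precision_pos,
        recall_pos=recall_pos,
        f1_pos=_f1(precision_pos, recall_pos),
        precision_neg=precision_neg,
        recall_neg=recall_neg,
        f1_neg=_f1(precision_neg, recall_neg),
        macro_f1=0.5 * (_f1(precision_pos, recall_pos) + _f1(precision_neg, recall_neg)),
    )
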