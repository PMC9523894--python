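"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (dense linear solves, exhaustive
enumeration, double loops) and shares no code with the implementation under
test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def signed_walk_linear_solution(t_plus, t_minus, dangling, seed_index, c, beta, gamma):
    """Solve the stationary signed-walk equations directly as a linear system."""
    n = t_plus.shape[0]
    q = np.zeros(n)
    q[seed_index] = 1.0
    d = dangling.astype(float)
    # stacked x = [p; m];  x = A x + b
    tp_t, tm_t = t_plus.T, t_minus.T
    a = np.zeros((2 * n, 2 * n))
    a[:n, :n] = (1 - c) * (tp_t + np.outer(q, d))
    a[:n, n:] = (1 - c) * (beta * tm_t + (1 - gamma) * tp_t + np.outer(q, d))
    a[n:, :n] = (1 - c) * tm_t
    a[n:, n:] = (1 - c) * (gamma * tp_t + (1 - beta) * tm_t)
    b = np.concatenate([c * q, np.zeros(n)])
    x = np.linalg.solve(np.eye(2 * n) - a, b)
    return x[:n], x[n:]


def classical_rwr(weights, seed_index, c):
    """Classical random walk with restart on a nonnegative weight matrix.

    Row-normalized transitions, dangling mass restarting to the seed,
    solved directly.
    """
    n = weights.shape[0]
    norms = weights.sum(axis=1)
    dangling = norms == 0.0
    t = weights / np.where(dangling, 1.0, norms)[:, None]
    q = np.zeros(n)
    q[seed_index] = 1.0
    a = (1 - c) * (t.T + np.outer(q, dangling.astype(float)))
    return np.linalg.solve(np.eye(n) - a, c * q)


def random_signed_digraph(rng, max_nodes=25):
    """A random mixed-sign weighted digraph as a (weights, n) pair."""
    n = int(rng.integers(2, max_nodes + 1))
    w = np.zeros((n, n))
    density = rng.uniform(0.1, 0.5)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < density:
                w[i, j] = rng.uniform(-1, 1)
    return w


def hypergeom_tail_by_enumeration(k, K, n, N):
    """P[X >= k] by enumerating every size-n draw from N items (exact rational)."""
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return Fraction(hits, total)


def hypergeom_tail_exact(k, K, n, N):
    """P[X >= k] from the exact combinatorial formula with rational arithmetic."""
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)), comb(N, n)
    )


def brute_force_selective(interactions, homology_map, pathogenic, commensal):
    """Double-loop reference for the untyped selective screen."""
    kept = set()
    for drug in set(interactions["drug_id"]):
        reached = set()
        for _, row in interactions[interactions["drug_id"] == drug].iterrows():
            reached |= set(homology_map.get(row["target_id"], ()))
        if (reached & pathogenic) and not (reached & commensal):
            kept.add(drug)
    return kept


def brute_force_typed(typed, required, excluded, pathogenic, commensal, drugs_only):
    """Double-loop reference for the four action-typed screens."""
    kept = set()
    for chem in set(typed["chemical_id"]):
        rows = typed[typed["chemical_id"] == chem]
        if drugs_only and not rows["is_drug"].any():
            continue
        has_required = False
        has_excluded = False
        for _, row in rows.iterrows():
            if row["action"] == required and row["microbe_id"] in pathogenic:
                has_required = True
            if row["action"] == excluded and row["microbe_id"] in commensal:
                has_excluded = True
        if has_required and not has_excluded:
            kept.add(chem)
    return kept
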