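"""Independent brute-force oracles used to verify the pipeline's statistics.

Everything here is written from first principles (explicit rank
computation, pair counting, combinatorial sums, exhaustive subgraph
enumeration) and shares no code path with the implementations it checks.
"""

import itertools
import math
from fractions import Fraction

import numpy as np


def mean_ranks(values):
    """Average ranks with mean assignment for ties, by explicit enumeration."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return np.array(ranks)


def pearson_oracle(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum()))


def spearman_oracle(x, y):
    """Rank both vectors (mean ties) then Pearson."""
    return pearson_oracle(mean_ranks(x), mean_ranks(y))


def cosine_oracle(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float((x * y).sum() / (np.linalg.norm(x) * np.linalg.norm(y)))


def auc_pair_counting(pos_scores, neg_scores):
    """AUC as the fraction of concordant (pos > neg) pairs, ties half."""
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos_scores) * len(neg_scores))


def hypergeom_tail_exact(k, N, K, n):
    """P(X >= k) for hypergeometric(N, K, n) by exact rational sums."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def to_networkx(mol):
    import networkx as nx

    g = nx.Graph()
    for i, el in enumerate(mol.atoms):
        g.add_node(i, el=el)
    for i, j, order in mol.bonds:
        g.add_edge(i, j, order=order)
    return g


def mcs_exhaustive(a, b):
    """Largest common connected induced subgraph by exhaustive enumeration.

    Enumerates connected vertex subsets of the smaller molecule from the
    largest size down and tests induced subgraph isomorphism into the
    larger one (element and bond-order labels must match).
    """
    import networkx as nx

    if a.n_atoms > b.n_atoms:
        a, b = b, a
    ga, gb = to_networkx(a), to_networkx(b)
    node_match = lambda u, v: u["el"] == v["el"]
    edge_match = lambda u, v: u["order"] == v["order"]
    for size in range(a.n_atoms, 0, -1):
        for subset in itertools.combinations(range(a.n_atoms), size):
            sub = ga.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gm = nx.algorithms.isomorphism.GraphMatcher(
                gb, sub, node_match=node_match, edge_match=edge_match
            )
            if gm.subgraph_is_isomorphic():
                return size
    return 0
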