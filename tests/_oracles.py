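"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by enumeration or direct
counting, sharing no code with the implementation they check.
"""

from itertools import permutations


def sequential_inclusion_probs(weights: dict[str, float], n_select: int) -> dict[str, float]:
    """Exact inclusion probability of each item under sequential weighted
    sampling without replacement, by enumerating all ordered draw
    sequences with renormalization.  Exponential in pool size; use only
    for tiny pools."""
    items = [k for k, w in weights.items() if w > 0]
    probs = {k: 0.0 for k in weights}
    for seq in permutations(items, n_select):
        p = 1.0
        remaining = dict((k, weights[k]) for k in items)
        for pick in seq:
            total = sum(remaining.values())
            p *= remaining[pick] / total
            del remaining[pick]
        for pick in seq:
            probs[pick] += p
    return probs


def mixing_matrix_assortativity(edges, labels):
    """Newman categorical assortativity by direct double counting over
    ordered edge endpoints (each undirected edge counted in both
    directions).  Returns None when the denominator vanishes."""
    cats = sorted(set(labels.values()))
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    counts = [[0] * k for _ in range(k)]
    total = 0
    for u, v in edges:
        for a, b in ((u, v), (v, u)):
            counts[index[labels[a]]][index[labels[b]]] += 1
            total += 1
    e = [[c / total for c in row] for row in counts]
    trace = sum(e[i][i] for i in range(k))
    a_marg = [sum(e[i][j] for j in range(k)) for i in range(k)]
    b_marg = [sum(e[i][j] for i in range(k)) for j in range(k)]
    ab = sum(a_marg[i] * b_marg[i] for i in range(k))
    if 1.0 - ab == 0.0:
        return None
    return (trace - ab) / (1.0 - ab)


def vertical_rule(pw: bool, f1: bool, f2: bool, o1: bool, o2: bool) -> bool:
    """Hand-coded transmission rule for 1 parental-worker, 2 founder and
    2 offspring samples: parental presence, presence in ALL founders, and
    presence in at least one offspring sample."""
    return pw and (f1 and f2) and (o1 or o2)
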