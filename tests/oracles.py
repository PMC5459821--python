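"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain-Python dynamic
programming, positional arithmetic and exhaustive enumeration, small enough
to be obviously correct.
"""

from __future__ import annotations

from itertools import permutations


def gotoh_local_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Affine-gap Smith-Waterman optimal score, plain O(nm) DP.

    Gap costs follow the open+extend convention of the package's aligner: a
    gap of length L scores gap_open + (L-1)*gap_extend.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    best = 0.0
    H = [0.0] * (m + 1)
    E = [neg] * (m + 1)  # gap in a (consuming b)
    for i in range(1, n + 1):
        diag = 0.0  # H[i-1][0]
        H_new = [0.0] * (m + 1)
        F_col = [neg] * (m + 1)  # gap in b (consuming a), along the row
        for j in range(1, m + 1):
            E[j] = max(H[j] + gap_open, E[j] + gap_extend)  # vertical: gap in b
            F_col[j] = max(H_new[j - 1] + gap_open, F_col[j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = max(0.0, diag + s, E[j], F_col[j])
            diag = H[j]
            H_new[j] = h
            if h > best:
                best = h
        H = H_new
    return best


def hamming_identity(a: str, b: str) -> float:
    """Positional identity for equal-length, substitution-only pairs."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def chimera_scan(query: str, parent_a: str, parent_b: str) -> tuple[float, float, int]:
    """Exhaustive crossover scan on an equal-length (no-indel) triple.

    Returns (best_model_identity_pct, best_single_parent_identity_pct,
    best_crossover).  Both parent orders are scanned; the crossover reported
    is the midpoint of the optimal plateau of the winning order.
    """
    L = len(query)
    assert len(parent_a) == len(parent_b) == L
    ia = [query[i] == parent_a[i] for i in range(L)]
    ib = [query[i] == parent_b[i] for i in range(L)]
    single = max(sum(ia), sum(ib)) * 100.0 / L
    best_m, best_ks = -1, [0]
    for left, right in ((ia, ib), (ib, ia)):
        pre_l = [0]
        pre_r = [0]
        for x, y in zip(left, right):
            pre_l.append(pre_l[-1] + x)
            pre_r.append(pre_r[-1] + y)
        counts = [pre_l[k] + (pre_r[L] - pre_r[k]) for k in range(1, L)]
        order_best = max(counts)
        if order_best > best_m:
            best_m = order_best
            best_ks = [k + 1 for k, c in enumerate(counts) if c == order_best]
    return best_m * 100.0 / L, single, best_ks[len(best_ks) // 2]


def upgma_first_merge(dist: list[list[float]]) -> tuple[int, int, float]:
    """Brute force over all first merges: the closest pair and half-distance."""
    n = len(dist)
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            if best is None or dist[i][j] < 2.0 * best[2]:
                best = (i, j, dist[i][j] / 2.0)
    return best


def nj_topology_4taxa(dist: list[list[float]]) -> frozenset[frozenset[int]]:
    """Four-point-condition topology of an additive 4x4 matrix.

    The correct unrooted topology pairs the two taxa whose pairing minimises
    the sum of the two within-pair distances.
    """
    d = dist
    sums = {
        frozenset([frozenset([0, 1]), frozenset([2, 3])]): d[0][1] + d[2][3],
        frozenset([frozenset([0, 2]), frozenset([1, 3])]): d[0][2] + d[1][3],
        frozenset([frozenset([0, 3]), frozenset([1, 2])]): d[0][3] + d[1][2],
    }
    return min(sums, key=sums.get)


def indval_enumeration(
    table: dict[str, dict[str, float]], groups: dict[str, str]
) -> dict[tuple[str, str], tuple[float, float]]:
    """Exhaustive-permutation IndVal: returns (indval, p) per (species, group).

    p = (1 + #{permuted max-group indval >= observed}) / (1 + n_permutations)
    over every ordering of the label vector.
    """
    samples = sorted(groups)
    labels = [groups[s] for s in samples]
    group_names = sorted(set(labels))

    def iv(species: str, lab: list[str]) -> dict[str, float]:
        out = {}
        for g in group_names:
            in_g = [table[species][s] for s, l in zip(samples, lab) if l == g]
            out_g = {
                g2: [table[species][s] for s, l in zip(samples, lab) if l == g2]
                for g2 in group_names
            }
            mean_g = sum(in_g) / len(in_g)
            total = sum(sum(v) / len(v) for v in out_g.values())
            a = mean_g / total if total > 0 else 0.0
            b = sum(1 for x in in_g if x > 0) / len(in_g)
            out[g] = a * b
        return out

    observed = {sp: iv(sp, labels) for sp in table}
    results = {}
    perms = list(permutations(labels))
    for sp in table:
        for g in group_names:
            obs = observed[sp][g]
            count = sum(1 for perm in perms if max(iv(sp, list(perm)).values()) >= obs)
            results[(sp, g)] = (obs, (1 + count) / (1 + len(perms)))
    return results
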