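"""Independent brute-force oracles used to validate the package's fast paths."""

from itertools import permutations

import numpy as np


def emd_permutation_oracle(cost: np.ndarray) -> float:
    """Exact EMD between two uniform equal-size bags: best assignment / n.

    For uniform weights 1/n on both sides the transportation optimum is
    attained at a permutation matrix, so enumerating all assignments is exact.
    """
    n = cost.shape[0]
    assert cost.shape == (n, n)
    best = min(sum(cost[i, p[i]] for i in range(n)) for p in permutations(range(n)))
    return best / n


def emd_grid_oracle(cost: np.ndarray, a: np.ndarray, b: np.ndarray, step: float = 0.05) -> float:
    """Exact EMD for marginals on a simplex grid, by enumerating grid plans.

    Vertices of the transportation polytope have entries that are partial
    sums/differences of the marginals, so when every marginal is a multiple
    of ``step`` the optimum lies on the grid and exhaustive enumeration of
    grid-feasible plans is exact.
    """
    m, n = cost.shape
    units_a = np.rint(np.asarray(a) / step).astype(int)
    units_b = np.rint(np.asarray(b) / step).astype(int)
    assert np.allclose(units_a * step, a) and np.allclose(units_b * step, b)
    best = [np.inf]

    plan = np.zeros((m, n), dtype=int)

    def fill(i: int, j: int, row_left: int, cols_left: np.ndarray, cost_so_far: float):
        if cost_so_far >= best[0]:
            return
        if j == n:
            if row_left != 0:
                return
            if i == m - 1:
                best[0] = cost_so_far
                return
            fill(i + 1, 0, units_a[i + 1], cols_left, cost_so_far)
            return
        max_units = min(row_left, cols_left[j])
        for u in range(max_units + 1):
            cols_left[j] -= u
            fill(i, j + 1, row_left - u, cols_left, cost_so_far + u * step * cost[i, j])
            cols_left[j] += u

    fill(0, 0, units_a[0], units_b.copy(), 0.0)
    return float(best[0])


def clusters_union_find_oracle(anns, threshold: float) -> set[frozenset[str]]:
    """All-pairs overlap matrix + union-find connected components."""
    n = len(anns)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            inter = len(anns[i].go_ids & anns[j].go_ids)
            ov = inter / min(len(anns[i].go_ids), len(anns[j].go_ids))
            if ov >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(anns[i].accession)
    return {frozenset(g) for g in groups.values()}


def fmax_exhaustive_oracle(predictions, truth) -> float:
    """Fmax by enumerating every distinct prediction score as a threshold."""
    truth = {acc: set(t) for acc, t in truth.items() if t}
    scores = sorted({s for scored in predictions.values() for s in scored.values()})
    best = 0.0
    for t in scores:
        precisions, recalls = [], []
        for acc, true_set in truth.items():
            pred = {g for g, s in predictions.get(acc, {}).items() if s >= t}
            if pred:
                precisions.append(len(pred & true_set) / len(pred))
            recalls.append(len(pred & true_set) / len(true_set))
        if not precisions:
            continue
        p, r = float(np.mean(precisions)), float(np.mean(recalls))
        if p + r > 0:
            best = max(best, 2 * p * r / (p + r))
    return best


def beam_enumeration_oracle(backend, input_ids, max_len: int, top_n: int):
    """Top-N sequences by exhaustive enumeration of the backend's tree.

    Enumerates every token sequence up to ``max_len``, scoring complete
    sequences (those that emit EOS) and length-capped incomplete ones by
    their product of token probabilities.
    """
    results = []

    def walk(prefix, logprob):
        if len(prefix) == max_len:
            results.append((prefix, logprob))
            return
        logprobs = backend.next_logprobs(input_ids, prefix)
        for tok, lp in enumerate(logprobs):
            if not np.isfinite(lp):
                continue
            if tok == backend.eos_id:
                results.append((prefix + [tok], logprob + lp))
            else:
                walk(prefix + [tok], logprob + lp)

    walk([], 0.0)
    results.sort(key=lambda r: r[1], reverse=True)
    return results[:top_n]
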