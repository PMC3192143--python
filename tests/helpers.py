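"""Independent oracle implementations used by the test suite.

These deliberately avoid the library's code paths: grouping by pairwise row
comparison, Hamming counting by explicit loops, greedy scoring by scanning
every remaining instance, minimal-subset search by subset enumeration, and
the stratified estimator re-derived directly from its definition.
"""

from __future__ import annotations

from itertools import combinations
from math import sqrt

import numpy as np

from vda.core import PredictionMatrix


def random_matrix(rng: np.random.Generator, n: int, m: int) -> PredictionMatrix:
    calls = rng.integers(0, 2, size=(n, m))
    return PredictionMatrix(
        instance_ids=tuple(f"i{k}" for k in range(n)),
        algorithm_ids=tuple(f"a{k}" for k in range(m)),
        calls=calls,
    )


def fingerprint_groups_oracle(pm: PredictionMatrix) -> list[tuple[tuple[int, ...], set[str]]]:
    """Group instances by O(n^2) pairwise row equality, no hashing."""
    n = pm.n_instances
    assigned = [False] * n
    groups = []
    for i in range(n):
        if assigned[i]:
            continue
        members = {pm.instance_ids[i]}
        assigned[i] = True
        for j in range(i + 1, n):
            if not assigned[j] and all(
                pm.calls[i, c] == pm.calls[j, c] for c in range(pm.n_algorithms)
            ):
                members.add(pm.instance_ids[j])
                assigned[j] = True
        groups.append((tuple(int(v) for v in pm.calls[i]), members))
    return sorted(groups)


def hamming_oracle(pm: PredictionMatrix, ai: str, aj: str, subset) -> int:
    ci = pm.algorithm_ids.index(ai)
    cj = pm.algorithm_ids.index(aj)
    count = 0
    for iid in subset:
        row = pm.calls[pm.instance_ids.index(iid)]
        if row[ci] != row[cj]:
            count += 1
    return count


def discordant_oracle(pm: PredictionMatrix) -> set[str]:
    out = set()
    for iid, row in zip(pm.instance_ids, pm.calls):
        if min(row) != max(row):
            out.add(iid)
    return out


def pair_list(m: int):
    return [(i, j) for i in range(m) for j in range(i + 1, m)]


def hamming_vector(pm: PredictionMatrix, selected: list[str]) -> list[int]:
    """Pairwise Hamming distances within a selected instance set."""
    pairs = pair_list(pm.n_algorithms)
    vec = [0] * len(pairs)
    for iid in selected:
        row = pm.calls[pm.instance_ids.index(iid)]
        for k, (i, j) in enumerate(pairs):
            vec[k] += int(row[i] != row[j])
    return vec


def greedy_best_key(pm: PredictionMatrix, selected: list[str], candidates) -> tuple:
    """Brute-force leximin maximum over every remaining discordant instance."""
    best = None
    for iid in candidates:
        key = tuple(sorted(hamming_vector(pm, selected + [iid])))
        if best is None or key > best:
            best = key
    return best


def min_subset_size_oracle(pm: PredictionMatrix, h: int) -> int | None:
    """Exhaustive enumeration: smallest subset of D with all pair distances >= h."""
    if h == 0:
        return 0
    d = sorted(discordant_oracle(pm), key=pm.instance_ids.index)
    for size in range(1, len(d) + 1):
        for combo in combinations(d, size):
            if min(hamming_vector(pm, list(combo))) >= h:
                return size
    return None


def stratified_auc_oracle(pm: PredictionMatrix, labels: dict[str, int]) -> dict[str, float]:
    """Direct re-implementation of the partition-reweighted estimator."""
    groups: dict[tuple[int, ...], list[str]] = {}
    for iid, row in zip(pm.instance_ids, pm.calls):
        groups.setdefault(tuple(int(v) for v in row), []).append(iid)
    p_hat = n_hat = 0.0
    tp_hat = {a: 0.0 for a in pm.algorithm_ids}
    tn_hat = {a: 0.0 for a in pm.algorithm_ids}
    for pattern, members in groups.items():
        validated = [iid for iid in members if iid in labels]
        if not validated:
            continue
        pv = sum(labels[iid] for iid in validated)
        nv = len(validated) - pv
        w = len(members)
        p_hat += w * pv / (pv + nv)
        n_hat += w * nv / (pv + nv)
        for c, a in enumerate(pm.algorithm_ids):
            if pattern[c] == 1:
                tp_hat[a] += w * pv / (pv + nv)
            else:
                tn_hat[a] += w * nv / (pv + nv)
    return {
        a: (tp_hat[a] / p_hat + tn_hat[a] / n_hat) / 2 for a in pm.algorithm_ids
    }


def kendall_tau_b_oracle(x: list[float], y: list[float]) -> float:
    """All-pairs concordance count with the tie correction."""
    n = len(x)
    concordant = discordant = 0
    ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom
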