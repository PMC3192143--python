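"""Validation-set selectors.

Three strategies order discordant instances for experimental validation:

* :func:`gvda_sort` — the greedy selector.  At each step it adds the instance
  that maximizes, in leximin order, the vector of pairwise Hamming distances
  inside the growing validation set: the minimum distance is raised first,
  then the next-smallest, and so on.  Ties are broken uniformly at random
  under an explicit seed.  Candidates are enumerated at fingerprint level,
  so each iteration is linear in the number of fingerprints and quadratic in
  the number of algorithms.
* :func:`evda_min_set` / :func:`evda_sort` — the exact selector: a
  depth-first search with memoization over per-fingerprint counts that
  returns a smallest subset whose pairwise Hamming distances all reach a
  target ``h``.  Exponential in the worst case, hence guarded by a state
  ceiling; intended for small panels or tight validation budgets.
* :func:`random_sort` — uniform random ordering, the baseline every
  comparison is made against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .core import (
    Fingerprint,
    PredictionMatrix,
    build_fingerprints,
    pair_indices,
    pattern_pair_deltas,
)

__all__ = [
    "SelectionPlan",
    "PlanStep",
    "gvda_sort",
    "evda_min_set",
    "evda_sort",
    "random_sort",
    "add_reference_algorithms",
    "NothingToDiscriminateError",
    "UnachievableDistanceError",
    "SearchBudgetExceededError",
]

logger = logging.getLogger(__name__)


class NothingToDiscriminateError(ValueError):
    """Raised when the discordant set is empty: no validation can separate the panel."""


class UnachievableDistanceError(ValueError):
    """Raised when the requested minimum Hamming distance cannot be reached."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"minimum Hamming distance {requested} is unachievable; "
            f"the maximum achievable value is {achievable}"
        )


class SearchBudgetExceededError(RuntimeError):
    """Raised when the exact search would visit too many states; use the greedy selector."""


@dataclass(frozen=True)
class PlanStep:
    """Audit record for one selection iteration."""

    iteration: int
    instance_id: str
    fingerprint: tuple[int, ...]
    hamming_after: tuple[int, ...]  # pairwise distances within the selected set

    @property
    def min_hamming_after(self) -> int:
        return min(self.hamming_after)


@dataclass(frozen=True)
class SelectionPlan:
    """Ordered validation set with a per-iteration min-Hamming audit trail."""

    method: str
    instance_ids: tuple[str, ...]
    steps: tuple[PlanStep, ...]
    algorithm_ids: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.instance_ids)) != len(self.instance_ids):
            raise ValueError("a selection plan must not repeat instances")

    def __len__(self) -> int:
        return len(self.instance_ids)

    def prefix(self, k: int) -> tuple[str, ...]:
        return self.instance_ids[:k]


def _discordant_fingerprints(fps: list[Fingerprint]) -> list[Fingerprint]:
    return [fp for fp in fps if fp.is_discordant]


def _leximin_key(vec: np.ndarray) -> tuple[int, ...]:
    return tuple(sorted(int(v) for v in vec))


def gvda_sort(
    pm: PredictionMatrix,
    budget: int | str = "all",
    seed: int = 0,
) -> SelectionPlan:
    """Greedy ordering of discordant instances by leximin Hamming gain.

    At iteration ``k`` the candidate fingerprints are scored by the
    ascending-sorted vector of pairwise Hamming distances the validation set
    would have after adding one of their instances; the lexicographically
    largest such vector wins.  Maximizing this leximin order raises the
    minimum pairwise distance whenever any candidate can, and otherwise
    improves the smallest distances first.  When several fingerprints tie,
    one is drawn uniformly at random; within a fingerprint the member is
    drawn uniformly among those not yet selected.

    Parameters
    ----------
    pm:
        The prediction panel.
    budget:
        Number of instances to order, or ``"all"`` for the whole discordant
        set.  A budget exceeding the discordant set is truncated with a
        warning.
    seed:
        Drives all tie-breaking; identical (matrix, seed) reruns yield
        byte-identical plans.
    """
    fps = _discordant_fingerprints(build_fingerprints(pm))
    n_discordant = sum(fp.multiplicity for fp in fps)
    if n_discordant == 0:
        raise NothingToDiscriminateError(
            "all algorithms agree on every instance; nothing to discriminate"
        )
    if budget == "all":
        n_select = n_discordant
    else:
        n_select = int(budget)
        if n_select < 1:
            raise ValueError("budget must be >= 1")
        if n_select > n_discordant:
            warnings.warn(
                f"budget {n_select} exceeds the discordant set size "
                f"{n_discordant}; returning a plan of length {n_discordant}",
                stacklevel=2,
            )
            n_select = n_discordant

    rng = np.random.default_rng(seed)
    pairs = pair_indices(pm.n_algorithms)
    deltas = np.stack([pattern_pair_deltas(fp.pattern, pairs) for fp in fps])
    remaining = np.array([fp.multiplicity for fp in fps], dtype=np.int64)
    # members not yet selected, kept in row order; random member drawn per pick
    pools = [list(fp.members) for fp in fps]

    hamming = np.zeros(len(pairs), dtype=np.int64)
    steps: list[PlanStep] = []
    chosen_ids: list[str] = []
    for k in range(n_select):
        candidates = np.flatnonzero(remaining > 0)
        keys = [_leximin_key(hamming + deltas[c]) for c in candidates]
        best = max(keys)
        tied = candidates[[i for i, key in enumerate(keys) if key == best]]
        f = int(rng.choice(tied))
        member = pools[f].pop(int(rng.integers(len(pools[f]))))
        remaining[f] -= 1
        hamming = hamming + deltas[f]
        chosen_ids.append(member)
        steps.append(
            PlanStep(
                iteration=k,
                instance_id=member,
                fingerprint=fps[f].pattern,
                hamming_after=tuple(int(v) for v in hamming),
            )
        )
        logger.debug(
            "gvda iteration %d: chose %s (fingerprint %s), min Hamming %d",
            k, member, fps[f].pattern_string(), int(hamming.min()),
        )
    return SelectionPlan(
        method="gvda",
        instance_ids=tuple(chosen_ids),
        steps=tuple(steps),
        algorithm_ids=pm.algorithm_ids,
        seed=seed,
    )


def _max_achievable_h(deltas: np.ndarray, mults: np.ndarray) -> int:
    """Largest h with a feasible subset: per pair, the total distance available on D."""
    if len(deltas) == 0:
        return 0
    totals = (deltas * mults[:, None]).sum(axis=0)
    return int(totals.min())


def evda_min_set(
    pm: PredictionMatrix,
    h: int | str = "auto",
    max_states: int = 2_000_000,
) -> set[str]:
    """Smallest validation subset whose pairwise Hamming distances all reach ``h``.

    The search works on fingerprint multiplicity vectors: instances within a
    fingerprint are exchangeable, so a state is the count taken from each
    discordant fingerprint.  A depth-first recursion over fingerprints
    memoizes the residual per-pair deficits and prunes branches that cannot
    beat the best subset found so far.

    ``h="auto"`` targets the minimum pairwise Hamming distance available on
    the discordant set — the largest value feasible for every pair.

    Raises
    ------
    UnachievableDistanceError
        If ``h`` exceeds what the discordant set can provide for some pair.
    SearchBudgetExceededError
        If more than ``max_states`` memoized states would be needed; large
        panels should fall back to the greedy selector.
    """
    fps = _discordant_fingerprints(build_fingerprints(pm))
    pairs = pair_indices(pm.n_algorithms)
    deltas = np.stack(
        [pattern_pair_deltas(fp.pattern, pairs) for fp in fps]
    ) if fps else np.zeros((0, len(pairs)), dtype=np.int64)
    mults = np.array([fp.multiplicity for fp in fps], dtype=np.int64)

    h_max = _max_achievable_h(deltas, mults)
    if h == "auto":
        target = h_max
    else:
        target = int(h)
        if target < 0:
            raise ValueError("h must be >= 0")
    if target == 0:
        return set()
    if target > h_max:
        raise UnachievableDistanceError(target, h_max)

    n_f = len(fps)
    # suffix_totals[f] = per-pair distance obtainable from fingerprints f..end
    suffix = np.zeros((n_f + 1, len(pairs)), dtype=np.int64)
    for f in range(n_f - 1, -1, -1):
        suffix[f] = suffix[f + 1] + deltas[f] * mults[f]

    INF = int(mults.sum()) + 1
    # memo[(f, deficit)] = minimal number of instances from fingerprints f..end
    # needed to cover the per-pair deficit (exchangeability makes counts the
    # only state that matters)
    memo: dict[tuple[int, tuple[int, ...]], int] = {}

    def solve(f: int, deficit: tuple[int, ...]) -> int:
        if not any(deficit):
            return 0
        if f == n_f:
            return INF
        if any(d > s for d, s in zip(deficit, suffix[f])):
            return INF  # remaining fingerprints cannot cover the deficit
        key = (f, deficit)
        hit = memo.get(key)
        if hit is not None:
            return hit
        if len(memo) > max_states:
            raise SearchBudgetExceededError(
                f"exact search exceeded {max_states} states; "
                "the problem is too large — use the greedy selector"
            )
        covers = deltas[f] > 0
        dvec = np.array(deficit, dtype=np.int64)
        useful_max = int(dvec[covers].max()) if covers.any() else 0
        c_hi = min(int(mults[f]), useful_max)
        best = INF
        for c in range(c_hi + 1):
            nxt = tuple(int(v) for v in np.maximum(dvec - c * deltas[f], 0))
            sub = solve(f + 1, nxt)
            if sub < INF and c + sub < best:
                best = c + sub
        memo[key] = best
        return best

    root = tuple([target] * len(pairs))
    total = solve(0, root)
    assert total < INF  # guaranteed by the achievability check above

    # reconstruct per-fingerprint counts by walking the memoized values
    chosen: set[str] = set()
    deficit = root
    remaining_needed = total
    for f in range(n_f):
        if not any(deficit):
            break
        dvec = np.array(deficit, dtype=np.int64)
        covers = deltas[f] > 0
        useful_max = int(dvec[covers].max()) if covers.any() else 0
        for c in range(min(int(mults[f]), useful_max) + 1):
            nxt = tuple(int(v) for v in np.maximum(dvec - c * deltas[f], 0))
            if c + solve(f + 1, nxt) == remaining_needed:
                # deterministic member choice: first members in matrix row order
                chosen.update(fps[f].members[:c])
                deficit = nxt
                remaining_needed -= c
                break
    return chosen


def evda_sort(
    pm: PredictionMatrix,
    h_max: int | str = "auto",
    max_states: int = 2_000_000,
) -> SelectionPlan:
    """Ordered plan from the exact selector.

    Concatenates minimal subsets for ``h = 1, 2, ..., h_max``, appending at
    each level only the instances not already placed.  Because members inside
    a fingerprint are taken deterministically in row order, each level's
    subset tends to extend the previous one; regardless, the prefix ending
    level ``h`` always satisfies min-Hamming >= ``h`` since supersets never
    lower a Hamming distance.
    """
    fps = _discordant_fingerprints(build_fingerprints(pm))
    pairs = pair_indices(pm.n_algorithms)
    if fps:
        deltas = np.stack([pattern_pair_deltas(fp.pattern, pairs) for fp in fps])
        mults = np.array([fp.multiplicity for fp in fps], dtype=np.int64)
    else:
        deltas = np.zeros((0, len(pairs)), dtype=np.int64)
        mults = np.zeros(0, dtype=np.int64)
    achievable = _max_achievable_h(deltas, mults)
    if h_max == "auto":
        levels = achievable
    else:
        levels = int(h_max)
        if levels > achievable:
            raise UnachievableDistanceError(levels, achievable)
    if levels < 1:
        raise NothingToDiscriminateError(
            "no achievable Hamming level: some algorithm pair never disagrees"
        )

    fp_of_instance = {iid: fp for fp in fps for iid in fp.members}
    ordered: list[str] = []
    placed: set[str] = set()
    steps: list[PlanStep] = []
    hamming = np.zeros(len(pairs), dtype=np.int64)
    delta_of = {fp.pattern: pattern_pair_deltas(fp.pattern, pairs) for fp in fps}
    for h in range(1, levels + 1):
        level_set = evda_min_set(pm, h, max_states=max_states)
        for iid in sorted(level_set, key=pm.instance_index):
            if iid in placed:
                continue
            placed.add(iid)
            fp = fp_of_instance[iid]
            hamming = hamming + delta_of[fp.pattern]
            ordered.append(iid)
            steps.append(
                PlanStep(
                    iteration=len(ordered) - 1,
                    instance_id=iid,
                    fingerprint=fp.pattern,
                    hamming_after=tuple(int(v) for v in hamming),
                )
            )
    return SelectionPlan(
        method="evda",
        instance_ids=tuple(ordered),
        steps=tuple(steps),
        algorithm_ids=pm.algorithm_ids,
        seed=None,
    )


def random_sort(
    pm: PredictionMatrix,
    pool: str = "D",
    seed: int = 0,
) -> SelectionPlan:
    """Uniform random ordering of a candidate pool — the baseline strategy.

    ``pool="D"`` permutes the discordant set (the default: concordant
    instances can never change a ranking, so this is the fair comparator for
    the discriminative selectors).  ``pool="Uprime"`` permutes every instance
    with at least one positive call, the agnostic-sampling variant.
    """
    if pool == "D":
        mask = pm.calls.min(axis=1) != pm.calls.max(axis=1)
    elif pool == "Uprime":
        mask = pm.calls.max(axis=1) == 1
    else:
        raise ValueError(f"unknown pool {pool!r}; expected 'D' or 'Uprime'")
    ids = [iid for iid, m in zip(pm.instance_ids, mask) if m]
    if not ids:
        raise NothingToDiscriminateError(f"pool {pool!r} is empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    pairs = pair_indices(pm.n_algorithms)
    hamming = np.zeros(len(pairs), dtype=np.int64)
    steps: list[PlanStep] = []
    chosen: list[str] = []
    for k, idx in enumerate(order):
        iid = ids[int(idx)]
        pattern = tuple(int(v) for v in pm.row(iid))
        hamming = hamming + pattern_pair_deltas(pattern, pairs)
        chosen.append(iid)
        steps.append(
            PlanStep(
                iteration=k,
                instance_id=iid,
                fingerprint=pattern,
                hamming_after=tuple(int(v) for v in hamming),
            )
        )
    return SelectionPlan(
        method=f"random[{pool}]",
        instance_ids=tuple(chosen),
        steps=tuple(steps),
        algorithm_ids=pm.algorithm_ids,
        seed=seed,
    )


def add_reference_algorithms(pm: PredictionMatrix) -> PredictionMatrix:
    """Append the degenerate AllTrue and AllFalse reference columns.

    Each scores balanced accuracy 0.5 under full validation, anchoring the
    estimate of every other algorithm; including them also turns every
    instance with a mixed relationship to the references into a discordant
    one, widening the selectable set.
    """
    for name in ("AllTrue", "AllFalse"):
        if name in pm.algorithm_ids:
            raise ValueError(f"algorithm id {name!r} already present")
    calls = np.concatenate(
        [
            pm.calls,
            np.ones((pm.n_instances, 1), dtype=np.uint8),
            np.zeros((pm.n_instances, 1), dtype=np.uint8),
        ],
        axis=1,
    )
    return PredictionMatrix(
        instance_ids=pm.instance_ids,
        algorithm_ids=pm.algorithm_ids + ("AllTrue", "AllFalse"),
        calls=calls,
    )
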