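"""Data model for binary prediction panels.

A panel of ``M`` black-box algorithms applied to a set of instances yields a
binary call matrix (1 = event predicted, 0 = no event).  Every downstream
primitive — fingerprint clustering, discordance, pairwise Hamming distances —
is defined on this matrix.  Instances sharing an identical row of calls form a
*fingerprint* cluster; those clusters are both the search units of the greedy
selector and the strata of the bias-corrected performance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PredictionMatrix",
    "Fingerprint",
    "build_fingerprints",
    "discordant_set",
    "hamming_distance",
]


class UnknownIdentifierError(KeyError):
    """Raised when an algorithm or instance id is not present in a matrix."""


@dataclass(frozen=True)
class PredictionMatrix:
    """Binary calls of ``M`` algorithms on a set of instances.

    Parameters
    ----------
    instance_ids:
        Opaque, pairwise-distinct row labels.  Instance ids may encode
        genomic intervals or time segments; no coordinate semantics are
        attached.
    algorithm_ids:
        Pairwise-distinct column labels, ``M >= 2``.
    calls:
        ``(n_instances, M)`` array of 0/1 entries.  Non-binary or missing
        values are rejected rather than coerced: a silently imputed call
        would corrupt every Hamming count computed from the matrix.

    Notes
    -----
    Rows whose calls are all zero are retained.  Conceptually they fall
    outside the detectable set (no algorithm called an event there), but a
    user who supplies them keeps them; such rows can never be discordant
    and therefore never enter a validation plan.
    """

    instance_ids: tuple[str, ...]
    algorithm_ids: tuple[str, ...]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        instance_ids = tuple(str(x) for x in self.instance_ids)
        algorithm_ids = tuple(str(x) for x in self.algorithm_ids)
        calls = np.asarray(self.calls)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if len(algorithm_ids) < 2:
            raise ValueError("at least two algorithms are required (M >= 2)")
        if calls.shape != (len(instance_ids), len(algorithm_ids)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(instance_ids)} instances x {len(algorithm_ids)} algorithms"
            )
        if len(set(instance_ids)) != len(instance_ids):
            raise ValueError("instance ids must be pairwise distinct")
        if len(set(algorithm_ids)) != len(algorithm_ids):
            raise ValueError("algorithm ids must be pairwise distinct")
        if calls.dtype.kind not in "iub" or not np.isin(calls, (0, 1)).all():
            bad = np.argwhere(~np.isin(calls, (0, 1)))
            r, c = (int(v) for v in bad[0]) if len(bad) else (0, 0)
            raise ValueError(
                f"calls must be exactly 0 or 1; offending entry at "
                f"instance {instance_ids[r]!r}, algorithm {algorithm_ids[c]!r}"
            )
        object.__setattr__(self, "instance_ids", instance_ids)
        object.__setattr__(self, "algorithm_ids", algorithm_ids)
        calls = calls.astype(np.uint8, copy=True)
        calls.setflags(write=False)
        object.__setattr__(self, "calls", calls)

    # -- basic shape -------------------------------------------------------
    @property
    def n_instances(self) -> int:
        return len(self.instance_ids)

    @property
    def n_algorithms(self) -> int:
        """M, the panel width."""
        return len(self.algorithm_ids)

    def algorithm_index(self, algorithm_id: str) -> int:
        try:
            return self.algorithm_ids.index(algorithm_id)
        except ValueError:
            raise UnknownIdentifierError(
                f"unknown algorithm id {algorithm_id!r}"
            ) from None

    def instance_index(self, instance_id: str) -> int:
        idx = self._instance_lookup().get(instance_id)
        if idx is None:
            raise UnknownIdentifierError(f"unknown instance id {instance_id!r}")
        return idx

    def _instance_lookup(self) -> dict[str, int]:
        cached = self.__dict__.get("_lookup")
        if cached is None:
            cached = {iid: k for k, iid in enumerate(self.instance_ids)}
            self.__dict__["_lookup"] = cached
        return cached

    def row(self, instance_id: str) -> np.ndarray:
        return self.calls[self.instance_index(instance_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredictionMatrix):
            return NotImplemented
        return (
            self.instance_ids == other.instance_ids
            and self.algorithm_ids == other.algorithm_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class Fingerprint:
    """A cluster of instances sharing one M-bit call pattern."""

    pattern: tuple[int, ...]
    members: tuple[str, ...]  # in original matrix row order

    @property
    def multiplicity(self) -> int:
        return len(self.members)

    @property
    def is_discordant(self) -> bool:
        """True when the pattern mixes 0s and 1s, i.e. two algorithms disagree."""
        return 0 < sum(self.pattern) < len(self.pattern)

    def pattern_string(self) -> str:
        return "".join(str(b) for b in self.pattern)


def build_fingerprints(pm: PredictionMatrix) -> list[Fingerprint]:
    """Partition the instances of ``pm`` by identical call rows.

    Returns fingerprints sorted lexicographically by pattern so that all
    downstream iteration (selection, scoring) is reproducible.  Member lists
    preserve the matrix row order.
    """
    groups: dict[tuple[int, ...], list[str]] = {}
    for iid, row in zip(pm.instance_ids, pm.calls):
        groups.setdefault(tuple(int(v) for v in row), []).append(iid)
    return [
        Fingerprint(pattern=pat, members=tuple(groups[pat]))
        for pat in sorted(groups)
    ]


def discordant_set(pm: PredictionMatrix) -> set[str]:
    """Instances on which at least two algorithms disagree (the set D).

    Only these instances can change a performance ranking: on a concordant
    instance every algorithm gains or loses the same count.
    """
    mask = pm.calls.min(axis=1) != pm.calls.max(axis=1)
    return {iid for iid, m in zip(pm.instance_ids, mask) if m}


def hamming_distance(
    pm: PredictionMatrix,
    algo_i: str,
    algo_j: str,
    subset: Iterable[str] | None = None,
) -> int:
    """Number of instances in ``subset`` where the two algorithms disagree.

    ``subset=None`` means all instances.  Symmetric in the algorithm pair.
    """
    ci = pm.algorithm_index(algo_i)
    cj = pm.algorithm_index(algo_j)
    if subset is None:
        rows = slice(None)
    else:
        rows = [pm.instance_index(iid) for iid in subset]
    return int(np.count_nonzero(pm.calls[rows, ci] != pm.calls[rows, cj]))


def pair_indices(m: int) -> list[tuple[int, int]]:
    """All unordered algorithm pairs (i < j), in row-major order."""
    return [(i, j) for i in range(m) for j in range(i + 1, m)]


def pattern_pair_deltas(pattern: Sequence[int], pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """Per-pair Hamming contribution of one instance with this pattern."""
    return np.array([abs(pattern[i] - pattern[j]) for i, j in pairs], dtype=np.int64)
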