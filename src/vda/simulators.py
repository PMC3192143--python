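"""Synthetic predictor classes for benchmarking selection strategies.

Two families of simulated black-box predictors make every selector and
estimator testable without external data:

* **RDFA** (random detector with fixed AUCROC): a binary column built so
  that its full-validation balanced accuracy equals a prescribed target ``a``
  *exactly*.  The (TP, TN) split realizing ``a`` is drawn uniformly from all
  feasible integer pairs, and the identity of the correct instances is
  uniform given the split, so two RDFA draws with the same target are
  independent detectors.
* **IDRE** (identical detectors with random errors): ``n`` copies of one
  RDFA realization, each corrupted by flipping the calls of a fixed random
  fraction ``p`` of instances.  All copies share a base but differ in their
  flip sets, emulating near-identical tools with independent noise.

All randomness flows from a single seed through ``numpy``'s SeedSequence
spawning, so panels are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PredictionMatrix
from .scoring import ValidationOutcomes

__all__ = [
    "TruthTable",
    "InfeasibleTargetError",
    "make_truth",
    "rdfa_generate",
    "idre_generate",
    "make_panel",
    "make_idre_panel",
]


@dataclass(frozen=True)
class TruthTable:
    """Ground-truth labels for a simulated panel."""

    instance_ids: tuple[str, ...]
    labels: np.ndarray  # 0/1 per instance

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.uint8)
        if labels.shape != (len(self.instance_ids),):
            raise ValueError("labels must align with instance_ids")
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "instance_ids", tuple(self.instance_ids))

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self.instance_ids) - self.n_positive

    def outcomes(self) -> ValidationOutcomes:
        """Full-validation view: every instance's label revealed."""
        return ValidationOutcomes(dict(zip(self.instance_ids, map(int, self.labels))))


class InfeasibleTargetError(ValueError):
    """The requested balanced accuracy has no exact (TP, TN) realization."""

    def __init__(self, target: float, nearest: tuple[float, float]):
        self.target = target
        self.nearest = nearest
        super().__init__(
            f"target AUCROC {target} is not exactly achievable on this grid; "
            f"nearest achievable values are {nearest[0]:.6g} and {nearest[1]:.6g}"
        )


def make_truth(
    n_instances: int,
    pos_fraction: float,
    seed: int | np.random.Generator = 0,
) -> TruthTable:
    """Random ground truth with ``round(pos_fraction * n)`` positives."""
    if n_instances < 2:
        raise ValueError("n_instances must be >= 2")
    if not 0 < pos_fraction < 1:
        raise ValueError("pos_fraction must lie strictly between 0 and 1")
    n_pos = round(pos_fraction * n_instances)
    if n_pos == 0 or n_pos == n_instances:
        raise ValueError(
            f"pos_fraction {pos_fraction} leaves no "
            f"{'positives' if n_pos == 0 else 'negatives'} at n={n_instances}"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_instances, dtype=np.uint8)
    labels[rng.choice(n_instances, size=n_pos, replace=False)] = 1
    ids = tuple(f"inst{k:05d}" for k in range(n_instances))
    return TruthTable(instance_ids=ids, labels=labels)


def _feasible_pairs(target: float, p: int, n: int, tol: float = 1e-9) -> list[tuple[int, int]]:
    """Integer (TP, TN) with TP/P + TN/N == 2*target, to within ``tol``."""
    pairs = []
    for tp in range(p + 1):
        # TN/N = 2a - TP/P
        tn_frac = 2 * target - tp / p
        tn = round(tn_frac * n)
        if 0 <= tn <= n and abs(tp / p + tn / n - 2 * target) <= tol:
            pairs.append((tp, tn))
    return pairs


def _nearest_achievable(target: float, p: int, n: int) -> tuple[float, float]:
    grid = sorted({(tp / p + tn / n) / 2 for tp in range(p + 1) for tn in range(n + 1)})
    arr = np.asarray(grid)
    below = arr[arr <= target]
    above = arr[arr >= target]
    lo = float(below[-1]) if below.size else float(arr[0])
    hi = float(above[0]) if above.size else float(arr[-1])
    return lo, hi


def snap_target(target: float, truth: TruthTable) -> float:
    """Nearest exactly-achievable balanced accuracy on the truth's (P, N) grid.

    Real-valued targets (e.g. drawn uniformly from (0, 1)) are almost never
    an exact ``(TP/P + TN/N)/2`` value; snapping to the nearest grid point
    keeps the detector class exact while moving the target by at most
    ``1/(4*min(P, N))``.
    """
    lo, hi = _nearest_achievable(target, truth.n_positive, truth.n_negative)
    return lo if target - lo <= hi - target else hi


def rdfa_generate(
    target: float,
    truth: TruthTable,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One binary prediction column scoring exactly ``target`` under full validation.

    A uniformly drawn feasible pair (TP, TN) fixes how many positives and
    negatives receive the correct call; which individual instances are
    correct is then uniform given the pair.  An infeasible target raises
    :class:`InfeasibleTargetError` reporting the nearest achievable values —
    exactness is the class's defining property, so no silent rounding.
    """
    if not 0 <= target <= 1:
        raise ValueError("target AUCROC must lie in [0, 1]")
    p, n = truth.n_positive, truth.n_negative
    if p == 0 or n == 0:
        raise ValueError("truth table must contain both classes")
    pairs = _feasible_pairs(target, p, n)
    if not pairs:
        raise InfeasibleTargetError(target, _nearest_achievable(target, p, n))
    rng = np.random.default_rng(seed)
    tp, tn = pairs[int(rng.integers(len(pairs)))]
    col = np.empty(len(truth.instance_ids), dtype=np.uint8)
    pos_idx = np.flatnonzero(truth.labels == 1)
    neg_idx = np.flatnonzero(truth.labels == 0)
    correct_pos = rng.choice(pos_idx, size=tp, replace=False)
    correct_neg = rng.choice(neg_idx, size=tn, replace=False)
    col[pos_idx] = 0  # missed positives by default
    col[neg_idx] = 1  # false alarms by default
    col[correct_pos] = 1
    col[correct_neg] = 0
    return col


def idre_generate(
    p_error: float,
    target: float,
    n_copies: int,
    truth: TruthTable,
    seed: int = 0,
) -> np.ndarray:
    """``n_copies`` noisy copies of one base detector, as a (n_instances, n_copies) array.

    Each copy flips the base RDFA(``target``) calls on ``round(p_error * n)``
    instances drawn without replacement — a fixed corrupted fraction, not
    per-instance Bernoulli noise — with an independent flip set per copy.
    """
    if not 0 <= p_error <= 1:
        raise ValueError("error probability must lie in [0, 1]")
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2 for pairwise studies")
    n_inst = len(truth.instance_ids)
    n_flip = round(p_error * n_inst)
    base_ss, *copy_ss = np.random.SeedSequence(seed).spawn(n_copies + 1)
    base = rdfa_generate(target, truth, np.random.default_rng(base_ss))
    cols = np.empty((n_inst, n_copies), dtype=np.uint8)
    for c, ss in enumerate(copy_ss):
        rng = np.random.default_rng(ss)
        col = base.copy()
        flips = rng.choice(n_inst, size=n_flip, replace=False)
        col[flips] ^= 1
        cols[:, c] = col
    return cols


def make_panel(
    targets: list[float],
    truth: TruthTable,
    seed: int = 0,
    name_prefix: str = "RDFA",
) -> PredictionMatrix:
    """Independent RDFA columns, one per target; column names carry the targets."""
    sss = np.random.SeedSequence(seed).spawn(len(targets))
    cols = [
        rdfa_generate(a, truth, np.random.default_rng(ss))
        for a, ss in zip(targets, sss)
    ]
    names = tuple(f"{name_prefix}_{k}_a{a:g}" for k, a in enumerate(targets))
    return PredictionMatrix(
        instance_ids=truth.instance_ids,
        algorithm_ids=names,
        calls=np.column_stack(cols),
    )


def make_idre_panel(
    p_error: float,
    target: float,
    n_copies: int,
    truth: TruthTable,
    seed: int = 0,
    confounders: list[float] | None = None,
) -> PredictionMatrix:
    """IDRE copies, optionally flanked by independent RDFA confounder columns."""
    seeder = np.random.default_rng(seed)
    idre_seed = int(seeder.integers(2**31))
    conf_seed = int(seeder.integers(2**31))
    idre = idre_generate(p_error, target, n_copies, truth, seed=idre_seed)
    names = [f"IDRE_{k}_p{p_error:g}_a{target:g}" for k in range(n_copies)]
    cols = [idre]
    if confounders:
        conf = make_panel(confounders, truth, seed=conf_seed, name_prefix="RDFAconf")
        cols.append(conf.calls)
        names.extend(conf.algorithm_ids)
    return PredictionMatrix(
        instance_ids=truth.instance_ids,
        algorithm_ids=tuple(names),
        calls=np.column_stack(cols),
    )
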