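"""Simulation studies comparing selection strategies.

Two reusable experiments quantify what a selection strategy buys:

* :func:`convergence_experiment` — how fast the Kendall rank correlation
  between estimated and true AUCROCs rises with the validation budget, on
  panels of independent fixed-accuracy detectors.  Balanced panels (equally
  spaced targets, well-balanced fingerprint partitions) and imbalanced
  panels (random targets, lopsided partitions) probe the two regimes in
  which greedy selection respectively matches and beats random sampling.
* :func:`idre_error_experiment` — the worst-case AUCROC estimation error
  across near-identical noisy detectors at a fixed budget, as a function of
  the noise level.  Discriminative selection deliberately over-samples
  disagreement, so it pays an error premium here; the experiment measures
  that premium.

Both experiments are deterministic given their seed and emit tidy
per-strategy summary curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import (
    UndefinedComponentError,
    auc_operative,
    auc_weighted,
    kendall_tau,
    rank_algorithms,
)
from .selection import add_reference_algorithms, gvda_sort, evda_sort, random_sort
from .simulators import TruthTable, make_idre_panel, make_panel, make_truth, snap_target

__all__ = [
    "ConvergenceCurve",
    "ErrorDistribution",
    "convergence_experiment",
    "idre_error_experiment",
    "summarize_ratio",
]


@dataclass(frozen=True)
class ConvergenceCurve:
    """Quantiles of Kendall tau as a function of validation budget."""

    strategy: str
    budgets: tuple[int, ...]
    median: tuple[float, ...]
    q25: tuple[float, ...]
    q75: tuple[float, ...]
    q05: tuple[float, ...]
    n_valid: tuple[int, ...]  # replicates with a defined tau at each budget

    def __post_init__(self) -> None:
        if list(self.budgets) != sorted(set(self.budgets)):
            raise ValueError("budgets must be strictly increasing")
        for q05, q25, med, q75 in zip(self.q05, self.q25, self.median, self.q75):
            vals = [v for v in (q05, q25, med, q75) if not np.isnan(v)]
            if vals != sorted(vals):
                raise ValueError("quantiles must be ordered q05 <= q25 <= median <= q75")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "budget": self.budgets,
                "median": self.median,
                "q25": self.q25,
                "q75": self.q75,
                "q05": self.q05,
                "n_reps": self.n_valid,
            }
        )


@dataclass(frozen=True)
class ErrorDistribution:
    """Quantiles of the max absolute AUCROC error across noisy copies, per noise level."""

    strategy: str
    p_grid: tuple[float, ...]
    median: tuple[float, ...]
    lo95: tuple[float, ...]
    hi95: tuple[float, ...]
    n_valid: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.p_grid) != sorted(set(self.p_grid)):
            raise ValueError("p grid must be strictly increasing")
        for lo, med, hi in zip(self.lo95, self.median, self.hi95):
            if not np.isnan(med) and not (lo <= med <= hi):
                raise ValueError("95% interval must contain its median")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "p": self.p_grid,
                "median": self.median,
                "lo95": self.lo95,
                "hi95": self.hi95,
                "n_reps": self.n_valid,
            }
        )


def _make_plan(strategy: str, pm, seed: int):
    if strategy == "gvda":
        return gvda_sort(pm, "all", seed=seed)
    if strategy == "evda":
        return evda_sort(pm)
    if strategy == "random":
        return random_sort(pm, pool="D", seed=seed)
    raise ValueError(f"unknown strategy {strategy!r}")


def _tau_at_budget(pm, truth: TruthTable, plan, budget: int, true_rank) -> float:
    prefix = plan.prefix(budget)
    if not prefix:
        return np.nan
    outcomes = truth.outcomes().restrict(prefix)
    try:
        estimates = auc_weighted(pm, outcomes)
    except UndefinedComponentError:
        return np.nan  # missing, not zero: the budget could not define both classes
    # rank only the algorithms under study (reference columns are anchors)
    estimates = [e for e in estimates if e.algorithm_id in true_rank]
    tau = kendall_tau(rank_algorithms(estimates), true_rank)
    return tau  # NaN when every estimate ties


def convergence_experiment(
    panel_mode: str,
    M: int,
    n_instances: int,
    budgets: list[int],
    reps: int,
    strategies: list[str],
    seed: int = 0,
    include_reference: bool = True,
) -> dict[str, ConvergenceCurve]:
    """Kendall-tau convergence of each strategy on simulated detector panels.

    Each replicate draws a ground truth with a positive fraction uniform on
    [0.1, 0.9], builds an M-detector panel — targets equally spaced at
    ``k/(M+1)`` in balanced mode, uniform on (0, 1) in imbalanced mode, both
    snapped to the truth's achievable grid — orders the discordant set with
    every strategy, and records, at each budget, the tie-corrected Kendall
    correlation between the stratified AUCROC estimates on the budget prefix
    and the true target values.  Budgets where an estimate is undefined
    count as missing.  ``include_reference`` appends the AllTrue/AllFalse
    anchor columns before selection; tau is always computed over the M
    detectors under study only.
    """
    if panel_mode not in ("balanced", "imbalanced"):
        raise ValueError(f"unknown panel mode {panel_mode!r}")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    budgets = sorted(budgets)
    taus = {s: np.full((reps, len(budgets)), np.nan) for s in strategies}
    seeder = np.random.default_rng(seed)
    for r in range(reps):
        rng = np.random.default_rng(int(seeder.integers(2**31)))
        pos_fraction = float(rng.uniform(0.1, 0.9))
        truth = make_truth(n_instances, pos_fraction, int(rng.integers(2**31)))
        if panel_mode == "balanced":
            raw = [k / (M + 1) for k in range(1, M + 1)]
        else:
            raw = [float(rng.uniform(0, 1)) for _ in range(M)]
        targets = [snap_target(a, truth) for a in raw]
        pm = make_panel(targets, truth, seed=int(rng.integers(2**31)))
        true_rank = {
            aid: rank
            for aid, rank in zip(
                pm.algorithm_ids,
                _descending_midranks(targets),
            )
        }
        if include_reference:
            pm = add_reference_algorithms(pm)
        for s in strategies:
            plan = _make_plan(s, pm, seed=int(rng.integers(2**31)))
            for b, budget in enumerate(budgets):
                taus[s][r, b] = _tau_at_budget(pm, truth, plan, budget, true_rank)
    return {s: _curve_from_taus(s, budgets, taus[s]) for s in strategies}


def _descending_midranks(values: list[float]) -> list[float]:
    from scipy.stats import rankdata

    return list(rankdata([-v for v in values], method="average"))


def _curve_from_taus(strategy: str, budgets: list[int], mat: np.ndarray) -> ConvergenceCurve:
    with np.errstate(all="ignore"):
        med = np.nanmedian(mat, axis=0)
        q25 = np.nanpercentile(mat, 25, axis=0)
        q75 = np.nanpercentile(mat, 75, axis=0)
        q05 = np.nanpercentile(mat, 5, axis=0)
    n_valid = (~np.isnan(mat)).sum(axis=0)
    return ConvergenceCurve(
        strategy=strategy,
        budgets=tuple(budgets),
        median=tuple(float(v) for v in med),
        q25=tuple(float(v) for v in q25),
        q75=tuple(float(v) for v in q75),
        q05=tuple(float(v) for v in q05),
        n_valid=tuple(int(v) for v in n_valid),
    )


def _true_copy_aucs(pm, truth: TruthTable, copy_ids: list[str]) -> dict[str, float]:
    """Full-validation balanced accuracy of each noisy copy (its true value)."""
    out = {}
    labels = truth.labels
    p, n = truth.n_positive, truth.n_negative
    for aid in copy_ids:
        col = pm.calls[:, pm.algorithm_index(aid)]
        tp = int(np.sum((col == 1) & (labels == 1)))
        tn = int(np.sum((col == 0) & (labels == 0)))
        out[aid] = auc_operative(tp, tn, p, n)
    return out


def idre_error_experiment(
    p_grid: list[float],
    a: float,
    n_copies: int,
    confounders: list[float] | None,
    budget: int,
    reps: int,
    strategies: list[str],
    seed: int = 0,
    n_instances: int = 200,
    pos_fraction: float = 0.5,
    include_reference: bool = True,
) -> dict[str, ErrorDistribution]:
    """Worst-case AUCROC error over noisy near-identical detectors, per noise level.

    Each replicate builds a panel of ``n_copies`` copies of one base
    detector with target accuracy ``a``, each corrupted at rate ``p``
    (optionally flanked by independent fixed-accuracy confounder columns),
    validates the first ``budget`` instances of each strategy's ordering,
    and records the maximum over copies of the absolute difference between
    the stratified estimate and the copy's true full-validation accuracy.

    The AllTrue/AllFalse anchor columns are appended by default: without
    them the big concordant partitions are never selectable, the estimator's
    partition coverage — not the copies' noise level — dominates the error,
    and the noise effect under study is masked.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    p_grid = sorted(p_grid)
    errs = {s: np.full((reps, len(p_grid)), np.nan) for s in strategies}
    seeder = np.random.default_rng(seed)
    for r in range(reps):
        rng = np.random.default_rng(int(seeder.integers(2**31)))
        truth = make_truth(n_instances, pos_fraction, int(rng.integers(2**31)))
        a_snap = snap_target(a, truth)
        conf = [snap_target(c, truth) for c in confounders] if confounders else None
        for pi, p_err in enumerate(p_grid):
            pm = make_idre_panel(
                p_err, a_snap, n_copies, truth,
                seed=int(rng.integers(2**31)), confounders=conf,
            )
            if include_reference:
                pm = add_reference_algorithms(pm)
            copy_ids = [aid for aid in pm.algorithm_ids if aid.startswith("IDRE_")]
            true_aucs = _true_copy_aucs(pm, truth, copy_ids)
            for s in strategies:
                plan = _make_plan(s, pm, seed=int(rng.integers(2**31)))
                prefix = plan.prefix(budget)
                outcomes = truth.outcomes().restrict(prefix)
                try:
                    estimates = auc_weighted(pm, outcomes)
                except UndefinedComponentError:
                    continue  # recorded as missing
                est = {e.algorithm_id: e.auc for e in estimates}
                errs[s][r, pi] = max(
                    abs(est[aid] - true_aucs[aid]) for aid in copy_ids
                )
    out = {}
    for s in strategies:
        mat = errs[s]
        with np.errstate(all="ignore"):
            med = np.nanmedian(mat, axis=0)
            lo = np.nanpercentile(mat, 2.5, axis=0)
            hi = np.nanpercentile(mat, 97.5, axis=0)
        out[s] = ErrorDistribution(
            strategy=s,
            p_grid=tuple(p_grid),
            median=tuple(float(v) for v in med),
            lo95=tuple(float(v) for v in lo),
            hi95=tuple(float(v) for v in hi),
            n_valid=tuple(int(v) for v in (~np.isnan(mat)).sum(axis=0)),
        )
    return out


def summarize_ratio(
    dist_a: ErrorDistribution,
    dist_b: ErrorDistribution,
) -> tuple[list[float], float]:
    """Element-wise ratio of median errors (a over b) and its mean over the grid.

    Grid points where the denominator is zero or either median is missing
    are reported as NaN and excluded from the mean.
    """
    if dist_a.p_grid != dist_b.p_grid:
        raise ValueError("error distributions must share the same p grid")
    ratios = []
    for ma, mb in zip(dist_a.median, dist_b.median):
        if np.isnan(ma) or np.isnan(mb) or mb == 0:
            ratios.append(float("nan"))
        else:
            ratios.append(ma / mb)
    finite = [r for r in ratios if not np.isnan(r)]
    mean = float(np.mean(finite)) if finite else float("nan")
    return ratios, mean
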