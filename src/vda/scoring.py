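"""Performance estimation for black-box binary predictors.

A black-box algorithm run with fixed parameters sits at a single operative
point of the ROC plane, so its AUCROC under trapezoidal interpolation equals
its balanced accuracy, ``(sensitivity + specificity) / 2``.  With complete
experimental validation that is :func:`auc_operative`.  When only a
non-randomly chosen subset of instances has been validated — the situation
every discriminative selection strategy creates — the raw counts are biased,
and :func:`auc_weighted` corrects for the bias by stratifying on fingerprint
partitions: within a partition every algorithm's call is constant, so the
validated class mix of the partition estimates its true mix, and partition
cardinalities reweight the counts back to the full instance set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import PredictionMatrix, build_fingerprints

__all__ = [
    "ValidationOutcomes",
    "PerformanceEstimate",
    "UndefinedComponentError",
    "auc_operative",
    "auc_weighted",
    "pair_delta",
    "pair_delta_discordant",
    "rank_algorithms",
    "kendall_tau",
]


class UndefinedComponentError(ValueError):
    """A sensitivity or specificity term has an empty denominator."""

    def __init__(self, component: str, detail: str = ""):
        self.component = component  # "sensitivity" or "specificity"
        msg = f"{component} is undefined: no validated "
        msg += "positives" if component == "sensitivity" else "negatives"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass(frozen=True)
class ValidationOutcomes:
    """Experimentally determined labels: instance id -> 1 (event) / 0 (no event)."""

    labels: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for iid, lab in self.labels.items():
            lab = int(lab)
            if lab not in (0, 1):
                raise ValueError(f"label for {iid!r} must be 0 or 1, got {lab}")
            clean[str(iid)] = lab
        object.__setattr__(self, "labels", clean)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, iid: str) -> bool:
        return iid in self.labels

    @property
    def n_positive(self) -> int:
        return sum(self.labels.values())

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def restrict(self, ids: Sequence[str]) -> "ValidationOutcomes":
        return ValidationOutcomes({i: self.labels[i] for i in ids if i in self.labels})


@dataclass(frozen=True)
class PerformanceEstimate:
    """Estimated operative-point AUCROC for one algorithm."""

    algorithm_id: str
    auc: float
    sensitivity: float
    specificity: float
    n_validated: int
    estimator: str  # "full" | "stratified"
    coverage: float = 1.0  # fraction of instances in partitions with >=1 validation


def auc_operative(tp: int, tn: int, p: int, n: int) -> float:
    """Balanced accuracy ``(TP/P + TN/N) / 2`` — the operative-point AUCROC."""
    if not (0 <= tp <= p):
        raise ValueError(f"need 0 <= TP <= P, got TP={tp}, P={p}")
    if not (0 <= tn <= n):
        raise ValueError(f"need 0 <= TN <= N, got TN={tn}, N={n}")
    if p == 0:
        raise UndefinedComponentError("sensitivity")
    if n == 0:
        raise UndefinedComponentError("specificity")
    return (tp / p + tn / n) / 2


def _check_outcome_ids(pm: PredictionMatrix, outcomes: ValidationOutcomes) -> None:
    unknown = set(outcomes.labels) - set(pm.instance_ids)
    if unknown:
        raise KeyError(
            f"validation outcomes refer to unknown instance ids: {sorted(unknown)[:5]}"
        )


def auc_weighted(
    pm: PredictionMatrix,
    outcomes: ValidationOutcomes,
) -> list[PerformanceEstimate]:
    """Stratified, bias-corrected AUCROC for every algorithm of the panel.

    Instances are stratified by fingerprint.  Within each partition ``w``
    holding at least one validated instance, the validated positive fraction
    estimates the partition's class mix, so the partition contributes
    ``|w| * Pv_w / (Pv_w + Nv_w)`` estimated positives (and analogously
    negatives, true positives and true negatives, each validated count scaled
    by ``|w| / (Pv_w + Nv_w)``).  Partitions without any validation are
    excluded; ``coverage`` reports the fraction of instances living in
    covered partitions so extrapolation risk is visible.

    Under complete validation every scale factor is 1 and the result reduces
    exactly to :func:`auc_operative` on the pooled counts.
    """
    _check_outcome_ids(pm, outcomes)
    if len(outcomes) == 0:
        raise ValueError("at least one validated instance is required")
    fps = build_fingerprints(pm)
    m = pm.n_algorithms
    p_hat = 0.0
    n_hat = 0.0
    tp_hat = np.zeros(m)
    tn_hat = np.zeros(m)
    covered_instances = 0
    for fp in fps:
        validated = [iid for iid in fp.members if iid in outcomes]
        if not validated:
            continue
        covered_instances += fp.multiplicity
        pv = sum(outcomes.labels[iid] for iid in validated)
        nv = len(validated) - pv
        scale = fp.multiplicity / (pv + nv)
        p_hat += scale * pv
        n_hat += scale * nv
        pattern = np.asarray(fp.pattern)
        # calls are constant within the partition: an algorithm calling 1
        # confirms every validated positive, an algorithm calling 0 every
        # validated negative
        tp_hat += scale * pv * pattern
        tn_hat += scale * nv * (1 - pattern)
    if p_hat == 0:
        raise UndefinedComponentError(
            "sensitivity", "no validated positives in any covered partition"
        )
    if n_hat == 0:
        raise UndefinedComponentError(
            "specificity", "no validated negatives in any covered partition"
        )
    full = len(outcomes) == pm.n_instances
    coverage = covered_instances / pm.n_instances
    out = []
    for a in range(m):
        sens = float(tp_hat[a] / p_hat)
        spec = float(tn_hat[a] / n_hat)
        out.append(
            PerformanceEstimate(
                algorithm_id=pm.algorithm_ids[a],
                auc=(sens + spec) / 2,
                sensitivity=sens,
                specificity=spec,
                n_validated=len(outcomes),
                estimator="full" if full else "stratified",
                coverage=coverage,
            )
        )
    return out


def pair_delta(est_i: PerformanceEstimate, est_j: PerformanceEstimate) -> float:
    """Absolute AUCROC difference between two estimates."""
    return abs(est_i.auc - est_j.auc)


def pair_delta_discordant(
    pm: PredictionMatrix,
    outcomes: ValidationOutcomes,
    algo_i: str,
    algo_j: str,
) -> float:
    """AUCROC difference computed from discordant instances only.

    On an instance where both algorithms make the same call, both gain (or
    both miss) the same count, so the difference in balanced accuracies is
    carried entirely by the instances where the calls are opposite:

        delta = | (TP_i^d - TP_j^d) / P + (TN_i^d - TN_j^d) / N | / 2

    with the ``d`` counts restricted to the pair's discordant instances and
    ``P``, ``N`` the overall validated class sizes.  Equals
    :func:`pair_delta` under full validation.
    """
    _check_outcome_ids(pm, outcomes)
    ci = pm.algorithm_index(algo_i)
    cj = pm.algorithm_index(algo_j)
    p = outcomes.n_positive
    n = outcomes.n_negative
    if p == 0:
        raise UndefinedComponentError("sensitivity")
    if n == 0:
        raise UndefinedComponentError("specificity")
    d_tp = 0
    d_tn = 0
    for iid, lab in outcomes.labels.items():
        row = pm.row(iid)
        vi, vj = int(row[ci]), int(row[cj])
        if vi == vj:
            continue
        if lab == 1:
            d_tp += (vi == 1) - (vj == 1)
        else:
            d_tn += (vi == 0) - (vj == 0)
    return abs(d_tp / p + d_tn / n) / 2


def rank_algorithms(estimates: Sequence[PerformanceEstimate]) -> dict[str, float]:
    """Descending ranks by AUCROC; exact ties share their midrank."""
    aucs = np.array([e.auc for e in estimates])
    ranks = stats.rankdata(-aucs, method="average")
    return {e.algorithm_id: float(r) for e, r in zip(estimates, ranks)}


def kendall_tau(
    rank_est: Mapping[str, float],
    rank_true: Mapping[str, float],
) -> float:
    """Tie-corrected Kendall rank correlation (tau-b) between two rankings.

    1 for identical strict rankings, -1 for a full reversal.  Estimated
    AUCROCs tie frequently at small validation counts, which is why the
    tie-corrected variant is used throughout.
    """
    if set(rank_est) != set(rank_true):
        raise ValueError("rankings must cover the same item set")
    if len(rank_est) < 2:
        raise ValueError("at least two items are required")
    items = sorted(rank_est)
    x = [rank_est[i] for i in items]
    y = [rank_true[i] for i in items]
    # ranks are descending; tau on ranks equals tau on the underlying scores
    tau = stats.kendalltau(x, y).statistic
    return float(tau)
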