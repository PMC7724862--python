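"""Ground-truth labeling, the n/p/s selection metrics, and the rank-based
statistical comparison of selection strategies.

A decoy is a true positive (near-native) when its lRMSD to the known native
is at most the per-target cutoff dist_thresh: 2 Å for easy targets
(min_dist < 1 Å), 2.5–3 Å for medium targets (1 ≤ min_dist < 2), and an
escalating cutoff for hard targets. Over a merged group of selected basins,
n is the recall-like captured share of all near-natives, p the precision-like
purity, and s the group size relative to |Ω|. Strategies are compared over
many targets with the Friedman rank test, followed by a step-down post-hoc
against the best-ranked strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .io_formats import Ensemble, ValidationError

DIFFICULTIES = ("easy", "medium", "hard")

#: default category cutoffs (Å); the medium value may be overridden to 2.5
CATEGORY_THRESH = {"easy": 2.0, "medium": 3.0, "hard": 3.0}


@dataclass
class TargetMeta:
    """Per-target ground-truth metadata: difficulty class, the near-native
    cutoff, and the count of true near-natives under it."""

    target_id: str
    min_dist: float
    difficulty: str
    dist_thresh: float
    n_near_native: int
    demoted: bool = False


def _category(min_dist: float) -> str:
    if min_dist < 1.0:
        return "easy"
    if min_dist < 2.0:
        return "medium"
    return "hard"


def classify_target(min_dist: float,
                    near_natives: Union[None, int, np.ndarray, Callable[[float], int]] = None,
                    scarcity_min: int = 10,
                    target_id: str = "",
                    medium_thresh: float = 3.0) -> TargetMeta:
    """Assign a difficulty class and near-native cutoff from min_dist.

    ``near_natives`` supplies the near-native count at a given cutoff: either
    the ensemble's rmsd_native array, a callable thresh->count, or a bare
    count at the category cutoff. A target with fewer than ``scarcity_min``
    near-natives at its category cutoff is demoted one difficulty level and
    re-thresholded (repeatedly if counts can be recomputed, once otherwise).
    """
    if min_dist < 0:
        raise ValidationError("min_dist must be non-negative")
    if medium_thresh not in (2.5, 3.0):
        raise ValidationError("medium_thresh must be 2.5 or 3.0")

    def count_at(thresh: float) -> Optional[int]:
        if near_natives is None:
            return None
        if callable(near_natives):
            return int(near_natives(thresh))
        if np.ndim(near_natives) > 0:
            return int(np.sum(np.asarray(near_natives, dtype=float) <= thresh))
        return None  # bare count: not recomputable

    def thresh_for(cat: str) -> float:
        return medium_thresh if cat == "medium" else CATEGORY_THRESH[cat]

    cat = _category(min_dist)
    thresh = thresh_for(cat)
    count = count_at(thresh)
    if count is None and near_natives is not None and np.ndim(near_natives) == 0:
        count = int(near_natives)
    demoted = False
    while count is not None and count < scarcity_min and cat != "hard":
        cat = DIFFICULTIES[DIFFICULTIES.index(cat) + 1]
        thresh = thresh_for(cat)
        demoted = True
        count = count_at(thresh)
        if count is None:  # bare count cannot be recomputed: demote once
            break
    return TargetMeta(target_id=target_id, min_dist=float(min_dist),
                      difficulty=cat, dist_thresh=float(thresh),
                      n_near_native=int(count) if count is not None else 0,
                      demoted=demoted)


def escalate_threshold(ensemble: Ensemble, selections: Sequence,
                       start: float = 3.0, step: float = 0.5) -> float:
    """Raise a hard target's cutoff along start, start+step, … until at least
    one strategy's selected groups contain a true near-native; capped at
    min_dist + 2.0 (the cap is returned if no ladder value succeeds).

    ``selections`` are SelectionResult-like objects; each contributes its
    largest merged group of decoy indices.
    """
    if ensemble.rmsd_native is None:
        raise ValidationError("escalation requires rmsd_native")
    cap = float(ensemble.min_dist) + 2.0
    pools = []
    for sel in selections:
        groups = getattr(sel, "groups", sel)
        if groups:
            largest = groups[max(groups)]
            if len(largest):
                pools.append(np.asarray(list(largest), dtype=int))
    best = min((float(ensemble.rmsd_native[p].min()) for p in pools), default=np.inf)
    t = float(start)
    while t <= cap + 1e-9:
        if best <= t:
            return t
        t += step
    return cap


@dataclass
class EvalMetrics:
    """n/p/s over the merged top-x group of one selection."""

    x: int
    tp: int
    group_size: int
    ensemble_size: int
    total_near_native: int
    p: float
    n: Optional[float]
    s: float
    truncated: bool = False  # x exceeded the available basins

    def to_dict(self) -> dict:
        return {"x": self.x, "tp": self.tp, "group_size": self.group_size,
                "p": self.p, "n": self.n, "s": self.s,
                "truncated": self.truncated}


def group_metrics(selection, labels: np.ndarray, ensemble: Ensemble,
                  x: int) -> EvalMetrics:
    """Evaluate the merged top-x group of a selection against true labels."""
    if not 1 <= x <= 3:
        raise ValidationError("x must be in 1..3")
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != ensemble.size:
        raise ValidationError("labels length does not match ensemble size")
    groups = selection.groups if hasattr(selection, "groups") else selection
    available = sorted(groups)
    truncated = x not in groups
    use_x = max((a for a in available if a <= x), default=None)
    members = np.asarray(sorted(groups[use_x]), dtype=int) if use_x is not None else \
        np.empty(0, dtype=int)
    tp = int(labels[members].sum())
    total = int(labels.sum())
    gsize = len(members)
    return EvalMetrics(
        x=x, tp=tp, group_size=gsize, ensemble_size=ensemble.size,
        total_near_native=total,
        p=tp / gsize if gsize else 0.0,
        n=tp / total if total > 0 else None,
        s=gsize / ensemble.size,
        truncated=truncated)


# ---------------------------------------------------------------------------
# Friedman test with step-down post-hoc


@dataclass
class StatsResult:
    methods: list[str]
    average_rank: dict[str, float]
    friedman_statistic: float
    friedman_p: float
    iman_davenport_f: float
    iman_davenport_p: float
    control: str
    comparisons: list[dict]
    alpha: float

    def to_dict(self) -> dict:
        return {
            "methods": self.methods, "average_rank": self.average_rank,
            "friedman_statistic": self.friedman_statistic,
            "friedman_p": self.friedman_p,
            "iman_davenport_f": self.iman_davenport_f,
            "iman_davenport_p": self.iman_davenport_p,
            "control": self.control, "comparisons": self.comparisons,
            "alpha": self.alpha,
        }


def posthoc_critical_ladder(k: int, alpha: float = 0.05) -> list[float]:
    """Step-down critical levels alpha/m, alpha/(m-1), …, alpha for the
    m = k-1 comparisons against the control, ordered by ascending p."""
    m = k - 1
    return [alpha / (m - i) for i in range(m)]


def _control_comparisons(methods: Sequence[str], avg_rank: np.ndarray, n_datasets: int,
                         alpha: float, procedure: str) -> tuple[str, list[dict]]:
    k = len(methods)
    control_idx = int(np.argmin(avg_rank))
    control = methods[control_idx]
    se = np.sqrt(k * (k + 1) / (6.0 * n_datasets))
    comps = []
    for i, m in enumerate(methods):
        if i == control_idx:
            continue
        z = (avg_rank[i] - avg_rank[control_idx]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        comps.append({"method": m, "z": float(z), "p": float(p)})
    comps.sort(key=lambda c: c["p"])
    ladder = posthoc_critical_ladder(k, alpha)
    if procedure == "ladder":
        for c, crit in zip(comps, ladder):
            c["critical"] = crit
            c["significant"] = bool(c["p"] < crit)
    elif procedure == "hommel":
        from statsmodels.stats.multitest import multipletests
        reject, adj, *_ = multipletests([c["p"] for c in comps], alpha=alpha,
                                        method="hommel")
        for c, crit, r, a in zip(comps, ladder, reject, adj):
            c["critical"] = crit
            c["p_adjusted"] = float(a)
            c["significant"] = bool(r)
    else:
        raise ValidationError(f"unknown post-hoc procedure {procedure!r}")
    return control, comps


def friedman_hommel(purity_matrix: np.ndarray,
                    methods: Optional[Sequence[str]] = None,
                    alpha: float = 0.05,
                    procedure: str = "ladder") -> StatsResult:
    """Friedman rank test over a (datasets × methods) purity matrix, with a
    step-down post-hoc against the best-ranked (control) method.

    Rank 1 is the highest purity in each row (mid-ranks on ties). The default
    post-hoc compares the i-th smallest unadjusted two-sided normal p against
    alpha/(m-i+1); ``procedure='hommel'`` applies the full Hommel step-up
    adjustment instead.
    """
    X = np.asarray(purity_matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("purity matrix must be 2-dimensional (datasets x methods)")
    if np.isnan(X).any():
        raise ValidationError("purity matrix has missing cells")
    N, k = X.shape
    if N < 2 or k < 2:
        raise ValidationError("need at least 2 datasets and 2 methods")
    if methods is None:
        methods = [f"method_{j}" for j in range(k)]
    if len(methods) != k:
        raise ValidationError("methods list length does not match matrix")
    ranks = np.apply_along_axis(lambda row: stats.rankdata(-row, method="average"),
                                1, X)
    avg_rank = ranks.mean(axis=0)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (N * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * N * (k + 1)
    chi2 = float(max(chi2, 0.0))
    p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    denom = N * (k - 1) - chi2
    if denom > 0:
        f_stat = (N - 1) * chi2 / denom
        f_p = float(stats.f.sf(f_stat, k - 1, (k - 1) * (N - 1)))
    else:
        f_stat, f_p = float("inf"), 0.0
    control, comps = _control_comparisons(list(methods), avg_rank, N, alpha, procedure)
    return StatsResult(
        methods=list(methods),
        average_rank={m: float(r) for m, r in zip(methods, avg_rank)},
        friedman_statistic=chi2, friedman_p=p,
        iman_davenport_f=float(f_stat), iman_davenport_p=f_p,
        control=control, comparisons=comps, alpha=alpha)
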