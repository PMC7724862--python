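"""Benchmark orchestration: leave-one-out training pools, repeated seeded
runs with averaging, the all-strategy comparison, and report assembly.

The training pool holds two targets per difficulty level. When the test
target itself sits in the pool, the first same-difficulty non-pool target
(by id) substitutes for it, so no run ever trains on its own test target.
The baselines are deterministic and run once; ML-Select is retrained over
repeated seeded runs (resampling both the phase-1 negative draw and the
booster seeds) and its metrics are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .baseline_ranking import BASELINE_STRATEGIES, rank_basins
from .evaluation import (EvalMetrics, StatsResult, TargetMeta, classify_target,
                         escalate_threshold, friedman_hommel, group_metrics)
from .io_formats import ConfigurationError, Ensemble, ValidationError
from .mlselect import (MLSelectConfig, SelectionResult, TargetData,
                       run_mlselect, selection_from_ranking)


def leave_one_out_pool(test_target_id: str, pool: Sequence[TargetMeta],
                       benchmark: Sequence[TargetMeta]) -> list[str]:
    """Return the 6 training target ids (2 per difficulty) for one test
    target, substituting the first same-difficulty non-pool target when the
    test target is itself a pool member."""
    by_difficulty: dict[str, list[TargetMeta]] = {}
    for m in pool:
        by_difficulty.setdefault(m.difficulty, []).append(m)
    if sorted(by_difficulty) != ["easy", "hard", "medium"] or \
            any(len(v) != 2 for v in by_difficulty.values()):
        raise ConfigurationError("pool must contain exactly 2 targets per difficulty")
    pool_ids = [m.target_id for m in pool]
    if test_target_id not in pool_ids:
        return list(pool_ids)
    member = next(m for m in pool if m.target_id == test_target_id)
    candidates = sorted(
        (m.target_id for m in benchmark
         if m.difficulty == member.difficulty and m.target_id not in pool_ids
         and m.target_id != test_target_id))
    if not candidates:
        raise ConfigurationError(
            f"no same-difficulty substitute for pool member {test_target_id!r}")
    return [candidates[0] if pid == test_target_id else pid for pid in pool_ids]


def repeat_and_average(run: Callable[[int], dict], runs: int = 50,
                       base_seed: int = 0) -> tuple[dict, list[dict]]:
    """Execute ``run(seed)`` with seeds base_seed..base_seed+runs-1 and
    average every numeric leaf of the returned nested dicts."""
    if runs < 1:
        raise ValidationError("runs must be >= 1")
    raw = []
    for i in range(runs):
        try:
            raw.append(run(base_seed + i))
        except Exception as exc:
            raise RuntimeError(f"run {i} (seed {base_seed + i}) failed") from exc

    def average(values):
        if isinstance(values[0], dict):
            return {k: average([v[k] for v in values]) for k in values[0]}
        if values[0] is None or any(v is None for v in values):
            return None
        if isinstance(values[0], bool):
            return float(np.mean([float(v) for v in values]))
        if isinstance(values[0], (int, float, np.integer, np.floating)):
            return float(np.mean(values))
        return values[0]

    return average(raw), raw


@dataclass
class BenchmarkReport:
    """Per-target × strategy × group mean metrics, the purity matrices, the
    Friedman/post-hoc results, and the raw per-run values."""

    strategies: list[str]
    target_ids: list[str]
    metas: dict[str, dict]
    metrics: dict[str, dict[str, dict[str, dict]]]  # target -> strategy -> "B1".. -> means
    purity_matrix: dict[str, list[list[float]]]     # "B1"/"B1-2"/"B1-3" -> targets x strategies
    stats: dict[str, Optional[dict]]
    raw_ml_runs: dict[str, list[dict]]
    config: dict

    def to_dict(self) -> dict:
        return {
            "strategies": self.strategies, "target_ids": self.target_ids,
            "metas": self.metas, "metrics": self.metrics,
            "purity_matrix": self.purity_matrix, "stats": self.stats,
            "raw_ml_runs": self.raw_ml_runs, "config": self.config,
        }


_GROUP_NAMES = {1: "B1", 2: "B1-2", 3: "B1-3"}


def _metrics_dict(selection, labels, ensemble) -> dict[str, dict]:
    return {_GROUP_NAMES[x]: group_metrics(selection, labels, ensemble, x).to_dict()
            for x in (1, 2, 3)}


def _finalize_meta(ensemble: Ensemble, decomp, rows) -> TargetMeta:
    """Classify a target and, for hard targets with no near-natives at the
    starting cutoff, escalate it using the deterministic baseline selections
    (ML is excluded to avoid training-label circularity)."""
    meta = classify_target(ensemble.min_dist, ensemble.rmsd_native,
                           target_id=ensemble.target_id)
    if meta.difficulty == "hard" and meta.n_near_native == 0:
        selections = [selection_from_ranking(rank_basins(s, rows), decomp,
                                             ensemble.target_id)
                      for s in BASELINE_STRATEGIES]
        thresh = escalate_threshold(ensemble, selections, start=meta.dist_thresh)
        meta.dist_thresh = float(thresh)
        meta.n_near_native = int(np.sum(ensemble.rmsd_native <= thresh))
    return meta


def run_benchmark(targets: Sequence[tuple[Ensemble, TargetMeta]],
                  strategies: Sequence[str] = ("S", "S+E", "PR", "PR+PC", "ML"),
                  config: MLSelectConfig = MLSelectConfig(),
                  runs: Optional[int] = None,
                  base_seed: int = 0,
                  pool_ids: Optional[Sequence[str]] = None) -> BenchmarkReport:
    """Evaluate every strategy on every labeled target and assemble the
    report, including the Friedman comparison when ≥ 2 strategies are run.

    ``pool_ids`` names the 6 designated ML training targets; by default the
    first two of each difficulty (benchmark order).
    """
    if len(strategies) < 1:
        raise ConfigurationError("need at least one strategy")
    runs = config.runs if runs is None else runs
    ensembles = [e for e, _ in targets]
    if any(e.rmsd_native is None for e in ensembles):
        raise ValidationError("benchmark targets must be labeled (rmsd_native)")

    # stage 1: decompose every target once, finalize thresholds and labels
    prepared: dict[str, TargetData] = {}
    metas: dict[str, TargetMeta] = {}
    for ens, _ in targets:
        td = TargetData.prepare(ens)
        meta = _finalize_meta(ens, td.decomp, td.rows)
        td = TargetData.prepare(ens, dist_thresh=meta.dist_thresh, decomp=td.decomp)
        prepared[ens.target_id] = td
        metas[ens.target_id] = meta
    target_ids = [e.target_id for e in ensembles]
    meta_list = [metas[t] for t in target_ids]

    if pool_ids is None:
        pool_ids = []
        for difficulty in ("easy", "medium", "hard"):
            members = [m.target_id for m in meta_list if m.difficulty == difficulty][:2]
            pool_ids.extend(members)
    pool = [metas[t] for t in pool_ids]

    metrics: dict[str, dict[str, dict]] = {t: {} for t in target_ids}
    raw_ml: dict[str, list[dict]] = {}
    for t in target_ids:
        td = prepared[t]
        labels = td.labels
        for strat in strategies:
            if strat == "ML":
                train_ids = leave_one_out_pool(t, pool, meta_list)
                train = [prepared[i] for i in train_ids]

                def one_run(seed: int, _train=train, _td=td, _labels=labels) -> dict:
                    from dataclasses import replace
                    sel = run_mlselect(_train, _td, replace(config, seed=seed))
                    return _metrics_dict(sel, _labels, _td.ensemble)

                mean, raw = repeat_and_average(one_run, runs=runs, base_seed=base_seed)
                metrics[t]["ML"] = mean
                raw_ml[t] = raw
            else:
                sel = selection_from_ranking(rank_basins(strat, td.rows),
                                             td.decomp, t, k_out=config.k_out)
                metrics[t][strat] = _metrics_dict(sel, labels, td.ensemble)

    purity_matrix = {}
    for x, gname in _GROUP_NAMES.items():
        purity_matrix[gname] = [
            [metrics[t][s][gname]["p"] for s in strategies] for t in target_ids]

    stats: dict[str, Optional[dict]] = {}
    for gname, mat in purity_matrix.items():
        if len(strategies) >= 2 and len(target_ids) >= 2:
            stats[gname] = friedman_hommel(np.asarray(mat), methods=list(strategies)).to_dict()
        else:
            stats[gname] = None

    return BenchmarkReport(
        strategies=list(strategies), target_ids=target_ids,
        metas={m.target_id: {
            "min_dist": m.min_dist, "difficulty": m.difficulty,
            "dist_thresh": m.dist_thresh, "n_near_native": m.n_near_native,
            "demoted": m.demoted} for m in meta_list},
        metrics=metrics, purity_matrix=purity_matrix, stats=stats,
        raw_ml_runs=raw_ml,
        config={"runs": runs, "base_seed": base_seed, "pool": list(pool_ids),
                "n_phase1": config.n_phase1, "k_out": config.k_out,
                "q": config.q, "boosting_rounds": config.boosting_rounds,
                "tau": config.tau, "booster": config.booster})
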