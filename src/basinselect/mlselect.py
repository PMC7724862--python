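"""ML-Select: two-phase gradient-boosted decoy selection over basins.

Phase 1 fits a boosted regression of basin purity on the Pareto-derived
ranks and the component count, then keeps the top n basins by predicted
purity. Phase 2 fits a boosted regression of per-decoy lRMSD-to-native on
the 20 scoring features, removes from each kept basin every decoy whose
predicted lRMSD exceeds dist_thresh·(1+τ), re-ranks the basins by the
fraction of members retained, and outputs the top k purified basins. Both
regressors use 15 rounds of boosting with linear base learners on
z-standardized inputs; training pools 2 easy + 2 medium + 2 hard labeled
targets disjoint from the test target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import xgboost as xgb

from .basin_features import (PHASE1_FEATURES, BasinFeatureRow, feature_matrix,
                             featurize_basins)
from .baseline_ranking import RankedSelection
from .io_formats import ConfigurationError, Ensemble, ValidationError
from .landscape import Basin, BasinDecomposition, build_nn_graph


@dataclass
class MLSelectConfig:
    """Tunable parameters of the two-phase procedure.

    n_phase1: basins passed from phase 1; k_out: basins output; q: per-target
    positive basins sampled for phase-1 training (2q rows per target);
    boosting_rounds: boosting iterations per regressor; tau: signed
    fractional shift of dist_thresh (|tau| ≤ 0.25); runs: repeated seeded
    trainings averaged by the protocol layer.
    """

    n_phase1: int = 10
    k_out: int = 3
    q: int = 10
    boosting_rounds: int = 15
    booster: str = "linear"
    tau: float = 0.0
    runs: int = 50
    seed: int = 0
    per_basin_refit: bool = False
    phase1_features: tuple[str, ...] = PHASE1_FEATURES

    def __post_init__(self) -> None:
        if not self.n_phase1 >= self.k_out >= 1:
            raise ConfigurationError("need n_phase1 >= k_out >= 1")
        if self.q < 1:
            raise ConfigurationError("q must be >= 1")
        if abs(self.tau) > 0.25 + 1e-12:
            raise ConfigurationError("|tau| must be <= 0.25")
        if self.booster not in ("linear", "tree"):
            raise ConfigurationError("booster must be 'linear' or 'tree'")


class Regressor:
    """Gradient-boosted regressor (squared error) over z-standardized inputs.

    Features with zero training variance are dropped. With the linear
    booster, single-threaded cyclic coordinate descent makes training
    bit-deterministic for a fixed seed.
    """

    def __init__(self, booster: xgb.Booster, feature_names: Sequence[str],
                 mean: np.ndarray, sd: np.ndarray, kept: np.ndarray):
        self.booster = booster
        self.feature_names = list(feature_names)
        self.mean = mean
        self.sd = sd
        self.kept = kept  # boolean mask over feature_names

    @classmethod
    def train(cls, X: np.ndarray, y: np.ndarray, feature_names: Sequence[str],
              rounds: int = 15, seed: int = 0, booster: str = "linear") -> "Regressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValidationError("training matrix must be non-empty and 2-D")
        if len(X) < 2:
            raise ValidationError("need at least 2 training rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        kept = sd > 0
        Z = (X[:, kept] - mean[kept]) / sd[kept]
        if Z.shape[1] == 0:  # all features constant: fall back to intercept-only
            Z = np.zeros((len(X), 1))
            kept = np.zeros(len(feature_names), dtype=bool)
        params = {
            "objective": "reg:squarederror",
            "seed": int(seed) % (2 ** 31),
            "nthread": 1,
        }
        if booster == "linear":
            params.update({"booster": "gblinear", "updater": "coord_descent",
                           "feature_selector": "cyclic"})
        else:
            params.update({"booster": "gbtree", "max_depth": 3, "eta": 0.3})
        dtrain = xgb.DMatrix(Z, label=y)
        bst = xgb.train(params, dtrain, num_boost_round=int(rounds))
        return cls(bst, feature_names, mean, sd, kept)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        if not self.kept.any():
            return np.zeros((len(X), 1))
        return (X[:, self.kept] - self.mean[self.kept]) / self.sd[self.kept]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.booster.predict(xgb.DMatrix(self._standardize(X)))

    def save(self, path) -> None:
        """Persist model + feature names + standardization stats as one JSON."""
        import json
        payload = {
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "kept": self.kept.astype(int).tolist(),
            "booster_raw": self.booster.save_raw("json").decode(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path) -> "Regressor":
        import json
        payload = json.loads(Path(path).read_text())
        bst = xgb.Booster()
        bst.load_model(bytearray(payload["booster_raw"].encode()))
        return cls(bst, payload["feature_names"],
                   np.asarray(payload["mean"], dtype=float),
                   np.asarray(payload["sd"], dtype=float),
                   np.asarray(payload["kept"], dtype=bool))


@dataclass
class TargetData:
    """Everything ML-Select needs about one target: the ensemble, its basin
    decomposition, per-decoy near-native labels (None when blind) and the
    per-basin feature rows."""

    ensemble: Ensemble
    decomp: BasinDecomposition
    rows: list[BasinFeatureRow]
    labels: Optional[np.ndarray] = None
    dist_thresh: Optional[float] = None

    @property
    def target_id(self) -> str:
        return self.ensemble.target_id

    @classmethod
    def prepare(cls, ensemble: Ensemble, dist_thresh: Optional[float] = None,
                epsilon0: float = 1.0, step: float = 0.5,
                k_cap: Optional[int] = None,
                decomp: Optional[BasinDecomposition] = None) -> "TargetData":
        """Build graph, basins, labels (when rmsd_native and dist_thresh are
        known) and feature rows for one target."""
        from .landscape import assign_basins
        if decomp is None:
            graph = build_nn_graph(ensemble, epsilon0=epsilon0, step=step, k_cap=k_cap)
            decomp = assign_basins(graph, ensemble.energies)
        labels = None
        if dist_thresh is not None and ensemble.rmsd_native is not None:
            labels = ensemble.rmsd_native <= dist_thresh
        rows = featurize_basins(decomp, ensemble, labels=labels)
        return cls(ensemble=ensemble, decomp=decomp, rows=rows, labels=labels,
                   dist_thresh=dist_thresh)


# ---------------------------------------------------------------------------
# phase 1


def make_phase1_training_set(targets: Sequence[TargetData], q: int = 10,
                             seed: int = 0) -> list[BasinFeatureRow]:
    """Per training target: the top q basins by true purity (ties: larger
    size, then basin_id) plus q more sampled uniformly without replacement
    from the remainder; all basins when a target has ≤ 2q."""
    rng = np.random.default_rng(seed)
    out: list[BasinFeatureRow] = []
    for t in targets:
        if any(r.purity_label is None for r in t.rows):
            raise ValidationError(f"target {t.target_id!r} is unlabeled")
        rows = sorted(t.rows, key=lambda r: (-r.purity_label, -r.size, r.basin_id))
        if len(rows) <= 2 * q:
            out.extend(rows)
            continue
        out.extend(rows[:q])
        rest = rows[q:]
        picks = rng.choice(len(rest), size=q, replace=False)
        out.extend(rest[i] for i in sorted(picks))
    return out


def train_phase1(rows: Sequence[BasinFeatureRow],
                 config: MLSelectConfig) -> Regressor:
    """Boosted regression of basin purity on the phase-1 feature set."""
    if not rows:
        raise ValidationError("no training rows")
    if any(r.purity_label is None for r in rows):
        raise ValidationError("phase-1 training rows must carry purity_label")
    X = feature_matrix(rows, config.phase1_features)
    y = np.array([r.purity_label for r in rows], dtype=float)
    return Regressor.train(X, y, config.phase1_features,
                           rounds=config.boosting_rounds, seed=config.seed,
                           booster=config.booster)


def phase1_select(model: Regressor, rows: Sequence[BasinFeatureRow],
                  n_phase1: int = 10) -> RankedSelection:
    """Top-n basins by predicted purity (ties: ascending basin_id)."""
    X = feature_matrix(rows, model.feature_names)
    pred = model.predict(X)
    order = sorted(range(len(rows)), key=lambda i: (-pred[i], rows[i].basin_id))
    top = order[:min(n_phase1, len(rows))]
    return RankedSelection(
        strategy="ML",
        ordered_basins=[rows[i].basin_id for i in top],
        scores={rows[i].basin_id: float(pred[i]) for i in range(len(rows))},
        ascending=False)


# ---------------------------------------------------------------------------
# phase 2


def make_phase2_training_set(targets: Sequence[TargetData]) -> tuple[np.ndarray, np.ndarray]:
    """Pool every decoy of every training target: (Σ|Ω|, 20) feature matrix
    in schema order plus the true-lRMSD target vector."""
    Xs, ys = [], []
    for t in targets:
        if t.ensemble.rmsd_native is None:
            raise ValidationError(f"target {t.target_id!r} lacks rmsd_native")
        Xs.append(t.ensemble.features)
        ys.append(t.ensemble.rmsd_native)
    return np.vstack(Xs), np.concatenate(ys)


def train_phase2(X: np.ndarray, y: np.ndarray, config: MLSelectConfig,
                 feature_names: Optional[Sequence[str]] = None) -> Regressor:
    """Boosted regression of per-decoy lRMSD on the 20 scoring features."""
    if feature_names is None:
        from .io_formats import DEFAULT_SCHEMA
        feature_names = DEFAULT_SCHEMA.names
    return Regressor.train(X, y, feature_names, rounds=config.boosting_rounds,
                           seed=config.seed + 1, booster=config.booster)


@dataclass
class PurifiedBasin:
    basin_id: int
    original_members: np.ndarray
    retained_members: np.ndarray
    predicted_rmsd: np.ndarray  # per original member

    @property
    def retained_fraction(self) -> float:
        return len(self.retained_members) / len(self.original_members)


def purify_basins(model: Union[Regressor, np.ndarray], ensemble: Ensemble,
                  selected: Sequence[Basin], dist_thresh: float,
                  tau: float = 0.0, k_out: int = 3) -> list[PurifiedBasin]:
    """Remove from each selected basin every decoy whose predicted lRMSD
    exceeds dist_thresh·(1+tau); rank basins by retained fraction (ties:
    larger retained set, then basin_id); drop emptied basins; return top k.

    ``model`` may be a trained :class:`Regressor` or a precomputed per-decoy
    prediction vector (used for oracle analyses).
    """
    if not selected:
        raise ValidationError("no basins to purify")
    if dist_thresh <= 0:
        raise ValidationError("dist_thresh must be positive")
    cutoff = dist_thresh * (1.0 + tau)
    if isinstance(model, Regressor):
        pred_all = model.predict(ensemble.features)
    else:
        pred_all = np.asarray(model, dtype=float)
        if pred_all.shape != (ensemble.size,):
            raise ValidationError("prediction vector length must equal |Ω|")
    purified = []
    for b in selected:
        members = np.asarray(b.members)
        pred = pred_all[members]
        retained = members[pred <= cutoff]
        purified.append(PurifiedBasin(
            basin_id=b.basin_id, original_members=members,
            retained_members=retained, predicted_rmsd=pred))
    purified = [p for p in purified if len(p.retained_members)]
    purified.sort(key=lambda p: (-p.retained_fraction, -len(p.retained_members),
                                 p.basin_id))
    return purified[:k_out]


# ---------------------------------------------------------------------------
# end-to-end


@dataclass
class SelectionResult:
    """A strategy's final output: ordered basins and the merged member groups
    B_1, B_1−2, B_1−3 (decoy indices)."""

    strategy: str
    target_id: str
    ordered_basins: list[int]
    groups: dict[int, list[int]]  # x -> sorted member indices of top-x merge
    purified: Optional[list[PurifiedBasin]] = None
    phase1_selection: Optional[RankedSelection] = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "target_id": self.target_id,
            "ordered_basins": [int(b) for b in self.ordered_basins],
            "groups": {str(x): [int(i) for i in mem]
                       for x, mem in sorted(self.groups.items())},
        }


def merge_top_groups(ordered_basins: Sequence[int],
                     members_of: dict[int, np.ndarray],
                     k_out: int = 3) -> dict[int, list[int]]:
    """Merged member groups for x = 1..min(k_out, available)."""
    groups: dict[int, list[int]] = {}
    acc: set[int] = set()
    for x, bid in enumerate(ordered_basins[:k_out], start=1):
        acc |= set(int(i) for i in members_of[bid])
        groups[x] = sorted(acc)
    return groups


def selection_from_ranking(ranked: RankedSelection, decomp: BasinDecomposition,
                           target_id: str, k_out: int = 3) -> SelectionResult:
    """Materialize a baseline ranking into merged top-x member groups."""
    members_of = {b.basin_id: b.members for b in decomp.basins}
    return SelectionResult(
        strategy=ranked.strategy, target_id=target_id,
        ordered_basins=list(ranked.ordered_basins[:k_out]),
        groups=merge_top_groups(ranked.ordered_basins, members_of, k_out))


def run_mlselect(train_targets: Sequence[TargetData], test_target: TargetData,
                 config: MLSelectConfig = MLSelectConfig(),
                 skip_phase2: bool = False) -> SelectionResult:
    """Train both phases on the labeled training targets and select/purify
    basins on the (disjoint) test target.

    With ``skip_phase2`` the top-k basins of the phase-1 ranking are output
    unpurified (the phase-1-only control).
    """
    train_ids = {t.target_id for t in train_targets}
    if test_target.target_id in train_ids:
        raise ValidationError(
            f"test target {test_target.target_id!r} overlaps the training pool")
    if test_target.dist_thresh is None:
        raise ValidationError("test target needs a dist_thresh for purification")
    rng = np.random.default_rng(config.seed)
    sample_seed = int(rng.integers(2 ** 31))
    booster_seed = int(rng.integers(2 ** 31))
    cfg = replace(config, seed=booster_seed)

    p1_rows = make_phase1_training_set(train_targets, q=config.q, seed=sample_seed)
    model1 = train_phase1(p1_rows, cfg)
    phase1 = phase1_select(model1, test_target.rows, config.n_phase1)
    basin_by_id = {b.basin_id: b for b in test_target.decomp.basins}

    if skip_phase2:
        top = phase1.ordered_basins[:config.k_out]
        return SelectionResult(
            strategy="ML-phase1", target_id=test_target.target_id,
            ordered_basins=list(top),
            groups=merge_top_groups(phase1.ordered_basins,
                                    {bid: basin_by_id[bid].members for bid in top},
                                    config.k_out),
            phase1_selection=phase1)

    X2, y2 = make_phase2_training_set(train_targets)
    selected = [basin_by_id[bid] for bid in phase1.ordered_basins]
    if config.per_basin_refit:
        # literal reading: one regressor per kept basin; identical data, so
        # refits differ only by booster seed
        purified = []
        for j, b in enumerate(selected):
            model2 = train_phase2(X2, y2, replace(cfg, seed=booster_seed + 1 + j))
            purified.extend(purify_basins(model2, test_target.ensemble, [b],
                                          test_target.dist_thresh, config.tau,
                                          k_out=1))
        purified.sort(key=lambda p: (-p.retained_fraction,
                                     -len(p.retained_members), p.basin_id))
        purified = purified[:config.k_out]
    else:
        model2 = train_phase2(X2, y2, cfg)
        purified = purify_basins(model2, test_target.ensemble, selected,
                                 test_target.dist_thresh, config.tau,
                                 config.k_out)
    ordered = [p.basin_id for p in purified]
    groups = merge_top_groups(ordered,
                              {p.basin_id: p.retained_members for p in purified},
                              config.k_out)
    return SelectionResult(strategy="ML", target_id=test_target.target_id,
                           ordered_basins=ordered, groups=groups,
                           purified=purified, phase1_selection=phase1)
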