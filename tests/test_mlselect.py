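import numpy as np
import pytest

from basinselect import (ConfigurationError, MLSelectConfig, Regressor,
                         TargetData, ValidationError, generate_ensemble,
                         make_phase1_training_set, make_phase2_training_set,
                         phase1_select, purify_basins, run_mlselect,
                         train_phase1, train_phase2, write_report)
from basinselect.basin_features import PHASE1_FEATURES, BasinFeatureRow
from basinselect.landscape import Basin
from basinselect.synthdata import SyntheticSpec
from conftest import random_ensemble


def _row(bid, purity=None, pr_rank=1.0, pc_rank=1.0, ncomp=1, size=1):
    return BasinFeatureRow(basin_id=bid, size=size, focal_energy=0.0, PR=0,
                           PC=0, pr_rank=pr_rank, pc_rank=pc_rank, pdist=0.0,
                           n_components=ncomp, purity_label=purity)


def _fake_target(target_id, n_basins, rng):
    rows = [_row(i, purity=float(rng.random()), pr_rank=float(i + 1),
                 size=int(rng.integers(1, 50))) for i in range(n_basins)]
    td = TargetData.__new__(TargetData)
    td.ensemble = type("E", (), {"target_id": target_id})()
    td.rows = rows
    td.decomp = None
    td.labels = None
    td.dist_thresh = 2.0
    return td


def test_config_validation():
    with pytest.raises(ConfigurationError):
        MLSelectConfig(n_phase1=2, k_out=3)
    with pytest.raises(ConfigurationError):
        MLSelectConfig(tau=0.5)
    with pytest.raises(ConfigurationError):
        MLSelectConfig(q=0)


def test_phase1_training_set_sizes(rng):
    targets = [_fake_target(f"t{i}", 25, rng) for i in range(6)]
    rows = make_phase1_training_set(targets, q=10, seed=0)
    assert len(rows) == 120  # 2q per target over 6 targets
    small = [_fake_target("small", 5, rng)]
    assert len(make_phase1_training_set(small, q=10, seed=0)) == 5


def test_phase1_negative_sampling_deterministic(rng):
    targets = [_fake_target(f"t{i}", 40, rng) for i in range(3)]
    a = make_phase1_training_set(targets, q=10, seed=42)
    b = make_phase1_training_set(targets, q=10, seed=42)
    assert [(r.target_id, r.basin_id) for r in a] == \
        [(r.target_id, r.basin_id) for r in b]
    c = make_phase1_training_set(targets, q=10, seed=43)
    assert [(r.target_id, r.basin_id) for r in a] != \
        [(r.target_id, r.basin_id) for r in c]


def test_phase1_positives_are_purest(rng):
    t = _fake_target("t", 30, rng)
    rows = make_phase1_training_set([t], q=5, seed=0)
    purities = sorted((r.purity_label for r in t.rows), reverse=True)
    assert sorted((r.purity_label for r in rows[:5]), reverse=True) == purities[:5]


def test_unlabeled_target_rejected(rng):
    t = _fake_target("t", 10, rng)
    t.rows[0].purity_label = None
    with pytest.raises(ValidationError):
        make_phase1_training_set([t], q=2, seed=0)


def test_train_constant_labels_predicts_constant():
    rng = np.random.default_rng(0)
    rows = [_row(i, purity=0.7, pr_rank=float(rng.integers(1, 9)),
                 pc_rank=float(rng.integers(1, 9))) for i in range(30)]
    model = train_phase1(rows, MLSelectConfig(seed=1))
    from basinselect.basin_features import feature_matrix
    pred = model.predict(feature_matrix(rows, PHASE1_FEATURES))
    assert np.all(np.abs(pred - 0.7) < 0.05)


def test_regressor_recovers_planted_linear_map():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(400, 20))
    w = rng.normal(size=20)
    y = X @ w + 2.0
    model = Regressor.train(X[:300], y[:300], [f"f{i}" for i in range(20)],
                            rounds=15, seed=0)
    pred = model.predict(X[300:])
    resid = y[300:] - pred
    r2 = 1 - resid.var() / y[300:].var()
    assert r2 >= 0.99


def test_regressor_deterministic_and_persistable(tmp_path):
    rng = np.random.default_rng(5)
    X = rng.normal(size=(50, 4))
    y = rng.normal(size=50)
    names = ["a", "b", "c", "d"]
    m1 = Regressor.train(X, y, names, seed=9)
    m2 = Regressor.train(X, y, names, seed=9)
    np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
    m1.save(tmp_path / "m.json")
    m3 = Regressor.load(tmp_path / "m.json")
    np.testing.assert_array_equal(m1.predict(X), m3.predict(X))


def test_constant_feature_dropped():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(40, 3))
    X[:, 1] = 7.0
    y = X[:, 0] * 2
    m = Regressor.train(X, y, ["a", "b", "c"], seed=0)
    assert m.kept.tolist() == [True, False, True]
    assert np.isfinite(m.predict(X)).all()


def test_phase1_select_ties_and_truncation():
    rows = [_row(0, pr_rank=2.0), _row(1, pr_rank=2.0), _row(2, pr_rank=2.0)]
    model = train_phase1([_row(i, purity=0.5, pr_rank=2.0) for i in range(4)],
                         MLSelectConfig(seed=0))
    sel = phase1_select(model, rows, n_phase1=10)
    assert sel.ordered_basins == [0, 1, 2]  # equal predictions: basin_id order
    sel2 = phase1_select(model, rows, n_phase1=2)
    assert len(sel2.ordered_basins) == 2


def test_phase1_top1_recovers_purest_basin_under_planted_signal():
    """When true purity is a monotone function of the phase-1 features, the
    top-ranked basin is the truly purest in ≥ 90% of seeds."""
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        def mk(tid):
            rows = []
            ranks = rng.permutation(15) + 1.0  # injective: one rank per basin
            for i in range(15):
                pr = float(ranks[i])
                purity = max(0.0, 1.0 - pr / 15 + rng.normal(scale=0.01))
                rows.append(_row(i, purity=purity, pr_rank=pr,
                                 pc_rank=pr, size=int(rng.integers(1, 30))))
            t = _fake_target(tid, 1, rng)
            t.rows = rows
            return t
        train = [mk(f"t{i}") for i in range(4)]
        test = mk("test")
        model = train_phase1(make_phase1_training_set(train, q=5, seed=seed),
                             MLSelectConfig(seed=seed))
        top = phase1_select(model, test.rows, n_phase1=1).ordered_basins[0]
        best = max(test.rows, key=lambda r: (r.purity_label, -r.basin_id)).basin_id
        hits += int(top == best)
    assert hits >= 45


def test_phase2_training_set_shape(rng):
    tds = [TargetData.prepare(random_ensemble(rng, n=30, rmsd=True),
                              dist_thresh=2.0) for _ in range(3)]
    X, y = make_phase2_training_set(tds)
    assert X.shape == (90, 20)
    assert y.shape == (90,)
    # column order equals the schema order
    np.testing.assert_array_equal(X[:30], tds[0].ensemble.features)


def test_phase2_missing_rmsd_rejected(rng):
    td = TargetData.prepare(random_ensemble(rng, n=10, rmsd=False))
    with pytest.raises(ValidationError):
        make_phase2_training_set([td])


def _basins_from(ensemble):
    td = TargetData.prepare(ensemble, dist_thresh=2.0)
    return td, td.decomp.basins


def test_purify_cutoff_arithmetic(rng):
    ens = random_ensemble(rng, n=20, rmsd=True)
    _, basins = _basins_from(ens)
    pred = np.full(ens.size, 2.3)
    kept = purify_basins(pred, ens, basins, dist_thresh=2.0, tau=0.20)
    assert all(p.retained_fraction == 1.0 for p in kept)     # 2.3 <= 2.4
    none = purify_basins(pred, ens, basins, dist_thresh=2.0, tau=0.0)
    assert none == []                                        # 2.3 > 2.0


def test_purify_oracle_predictor_yields_pure_groups(rng):
    ens = generate_ensemble(SyntheticSpec(target_id="t", size=500, seed=8))
    td = TargetData.prepare(ens, dist_thresh=2.0)
    kept = purify_basins(ens.rmsd_native, ens, td.decomp.basins,
                         dist_thresh=2.0, tau=0.0)
    labels = ens.rmsd_native <= 2.0
    for p in kept:
        assert labels[p.retained_members].all()
        assert set(p.retained_members) <= set(p.original_members)


def test_purify_anti_oracle_empties_everything(rng):
    ens = random_ensemble(rng, n=20, rmsd=True)
    _, basins = _basins_from(ens)
    kept = purify_basins(np.full(ens.size, 99.0), ens, basins, dist_thresh=2.0)
    assert kept == []


def _synthetic_pool(seed, n_targets=7, size=400):
    rng = np.random.default_rng(seed)
    out = []
    for i, difficulty in enumerate(["easy", "easy", "medium", "medium",
                                    "hard", "hard", "easy"][:n_targets]):
        spec = SyntheticSpec(target_id=f"t{i}", size=size, difficulty=difficulty,
                             min_dist={"easy": 0.6, "medium": 1.3, "hard": 2.3}[difficulty],
                             seed=int(rng.integers(2 ** 31)))
        ens = generate_ensemble(spec)
        out.append(TargetData.prepare(ens, dist_thresh=spec.resolved_dist_thresh()))
    return out


def test_run_mlselect_rejects_train_test_overlap():
    tds = _synthetic_pool(0)
    with pytest.raises(ValidationError):
        run_mlselect(tds[:6], tds[0])


def test_run_mlselect_k_out_one_only_b1():
    tds = _synthetic_pool(1)
    cfg = MLSelectConfig(k_out=1, seed=3)
    sel = run_mlselect(tds[:6], tds[6], cfg)
    assert set(sel.groups) <= {1}


def test_run_mlselect_groups_nested_and_subset_of_phase1():
    tds = _synthetic_pool(2)
    sel = run_mlselect(tds[:6], tds[6], MLSelectConfig(seed=4))
    xs = sorted(sel.groups)
    for a, b in zip(xs, xs[1:]):
        assert set(sel.groups[a]) <= set(sel.groups[b])
    phase1_members = set()
    by_id = {b.basin_id: b for b in tds[6].decomp.basins}
    for bid in sel.phase1_selection.ordered_basins:
        phase1_members |= set(by_id[bid].members.tolist())
    assert set(sel.groups[max(xs)]) <= phase1_members


def test_run_mlselect_seeded_determinism(tmp_path):
    tds = _synthetic_pool(3)
    out = []
    for rep in range(2):
        sel = run_mlselect(tds[:6], tds[6], MLSelectConfig(seed=11))
        path = tmp_path / f"r{rep}.json"
        write_report(sel.to_dict(), path)
        out.append(path.read_bytes())
    assert out[0] == out[1]


def test_per_basin_refit_matches_pooled_up_to_seed_noise():
    tds = _synthetic_pool(4)
    pooled = run_mlselect(tds[:6], tds[6], MLSelectConfig(seed=5))
    refit = run_mlselect(tds[:6], tds[6], MLSelectConfig(seed=5, per_basin_refit=True))
    assert set(refit.ordered_basins) <= set(
        pooled.phase1_selection.ordered_basins)
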