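"""The full two-phase ML-Select run on one held-out target.

Phase 1 trains a boosted purity regressor on basin features from 2 easy +
2 medium + 2 hard labeled targets and keeps the top-10 basins of the test
target; phase 2 trains a boosted lRMSD regressor on the 20 score features,
drops every kept decoy predicted beyond dist_thresh, and outputs the top-3
purified basins.
"""

from basinselect import (MLSelectConfig, SyntheticSpec, TargetData,
                         generate_ensemble, group_metrics, run_mlselect)

difficulties = ["easy", "easy", "medium", "medium", "hard", "hard"]
MIN_DIST = {"easy": 0.6, "medium": 1.3, "hard": 2.4}
train = []
for i, diff in enumerate(difficulties):
    spec = SyntheticSpec(target_id=f"train_{diff}{i}", size=2000,
                         difficulty=diff, min_dist=MIN_DIST[diff], seed=100 + i)
    ens = generate_ensemble(spec)
    train.append(TargetData.prepare(ens, dist_thresh=spec.resolved_dist_thresh()))

test_spec = SyntheticSpec(target_id="test_medium", size=2000,
                          difficulty="medium", min_dist=1.5, seed=999)
test_ens = generate_ensemble(test_spec)
test = TargetData.prepare(test_ens, dist_thresh=3.0)

sel = run_mlselect(train, test, MLSelectConfig(seed=7))
print(f"phase-1 kept basins: {sel.phase1_selection.ordered_basins}")
print(f"purified output basins: {sel.ordered_basins}")
for p in sel.purified:
    print(f"  basin {p.basin_id}: kept {len(p.retained_members)}/"
          f"{len(p.original_members)} decoys "
          f"(retained fraction {p.retained_fraction:.3f})")
for x in sorted(sel.groups):
    m = group_metrics(sel, test.labels, test_ens, x)
    print(f"B_1-{x}: purity p={m.p:.3f}, capture n={m.n:.3f}, "
          f"size s={m.s:.5f} ({m.group_size} decoys)")
# With informative features the retained sets are almost entirely true
# near-natives: purity near 1 at a group size a few hundredths of |Omega|.
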