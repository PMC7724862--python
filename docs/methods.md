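# Methods

This note documents the models and procedures implemented in `basinselect`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Landscape model and basin decomposition

A decoy ensemble Ω with energy f and pairwise distance d is treated as a
sampled fitness landscape. The ε-nearest-neighbor graph connects decoys
within ε of each other; because sparse sampling can disconnect the graph at
small cutoffs, ε starts at 1 Å and is raised in additive steps of 0.5 Å
until the graph is connected. Internally the smallest connecting ε is found
via the minimax-path property — a threshold graph is connected iff the
threshold is at least the largest edge of a minimum spanning tree — using a
dense Prim scan, which is O(n²) and far faster on full distance matrices
than generic sparse MST routines. An optional `k_cap` keeps only each
vertex's k nearest neighbors (an edge survives if either endpoint selects
it); connectivity is re-checked after capping. `k_cap` is off by default:
density control is a secondary mechanism and no principled default exists.

A vertex u is a local minimum iff f(u) ≤ f(v) for all neighbors v. The ≤
convention means plateaus of equal-energy neighbors yield several adjacent
single-minimum basins; this is deliberate and documented rather than
"fixed", since any merging rule would need an arbitrary tolerance. Every
non-minimum follows the neighbor maximizing [f(u)−f(v)]/d(u,v). Ties break
to the smallest vertex index for determinism. Zero-distance edges (duplicate
decoys) take ratio +∞ toward strictly lower energy and are skipped
otherwise, which preserves the termination argument: a non-minimum always
has a strictly lower neighbor, so f strictly decreases along every descent
step and paths are finite; the implementation asserts this per step.

Three distance semantics are supported: plain per-atom RMS on raw
coordinates (`euclidean`), RMSD after optimally superposing every structure
onto the first decoy of the ensemble (`common-frame-rmsd`, Kabsch), and a
precomputed matrix. Whether pairwise RMSD should be computed in a common
frame or pairwise-optimally is ambiguous in practice; both views are
available (common-frame as the default for ensemble work, pairwise-optimal
via `pairwise_distance` on two structures), and the entire pipeline
downstream of the distance matrix is agnostic to the choice.

## Basin features

Per basin: size, focal (minimum) energy, Pareto rank PR and Pareto count PC
under (maximize size, minimize focal energy), mid-rank transforms of both
(pr_rank ascending in PR, pc_rank descending in PC, average ranks on ties),
the mean pairwise member distance `pdist`, and the number of connected
components of the member graph at cutoff pdist + 1 Å. Singletons take
pdist = 0 and one component by definition. The default phase-1 feature set
is {pr_rank, pc_rank, n_components}; the raw PR/PC values stay on each row
and a config switch (`MLSelectConfig.phase1_features`) can widen the set.
Mid-ranks were chosen over ordinal positions because they are deterministic
under ties and scale-free across targets with different basin counts.

## Baseline strategies

S sorts by descending size. S+E is under-specified in the literature it
follows ("a combination of size and the energy"); it is implemented as the
equal-weight sum of the size mid-rank (descending) and focal-energy mid-rank
(ascending) — parameter-free and symmetric in the two criteria. PR sorts by
ascending Pareto rank; PR+PC additionally breaks ties by descending Pareto
count. All residual ties break by ascending basin id, so every ordering is a
pure function of the feature rows.

## ML-Select

Both phases use gradient-boosted regression with squared error, 15 boosting
rounds, and linear base learners (XGBoost `gblinear`). Linear base learners
need comparable feature scales, so inputs are z-standardized with training
means and standard deviations; zero-variance features are dropped. Training
uses single-threaded cyclic coordinate descent, making model fits
bit-deterministic for a fixed seed. A `booster="tree"` option exists for
experimentation but is not the default.

Phase-1 training draws, per labeled training target, the q = 10 purest
basins (ties: larger, then lower id) plus q sampled uniformly without
replacement from the rest — 2q rows per target, or all basins when a target
has ≤ 2q. The 50-fold repetition protocol resamples both the negative draw
and the booster seeds in every run, since neither source of randomness is
privileged. Phase 2 pools every decoy of the six training targets (Σ|Ω|
rows × 20 features, target = true lRMSD). The "n regression models for n
basins" formulation is implemented as one pooled phase-2 regressor applied
to every kept basin: the training data cannot depend on the test basin, so
per-basin refits could differ only by seed noise; `per_basin_refit=True`
reproduces the literal per-basin variant.

Purification removes a decoy when its *predicted* lRMSD exceeds
dist_thresh·(1+τ), τ ∈ {0, ±0.10, ±0.20, ±0.25}. Kept basins are re-ranked
by retained fraction (ties: larger retained set, then id) — the only purity
proxy computable without labels on a blind target — basins emptied by
purification are dropped, and the top k = 3 survivors are merged into
groups B₁, B₁₋₂, B₁₋₃. n = 10 basins pass phase 1 by default: large enough
that the native basin is rarely excluded at desk scale, small enough that
phase 2 stays focused; k = 3 matches the standard top-1/2/3 reporting
convention.

## Ground truth and evaluation

A decoy is near-native when its true lRMSD is at most dist_thresh: 2 Å for
easy targets (min_dist < 1 Å), 3 Å by default for medium targets
(1 ≤ min_dist < 2; 2.5 Å available as a per-target override), and for hard
targets (min_dist ≥ 2) a cutoff starting at 3 Å and escalated in 0.5 Å
steps until at least one strategy's selected groups contain a near-native,
capped at min_dist + 2 Å. The printed category rules leave [2, 3) Å
formally unassigned; hard ⇔ min_dist ≥ 2 reproduces the intended grouping.
A target with fewer than 10 near-natives at its category cutoff is demoted
one difficulty level and re-thresholded (the "very few near-natives" rule;
10 is the package's fixed scarcity constant). Inside the benchmark driver
the escalation uses only the four deterministic baselines, because ML
training labels for every target must exist before any ML model can be
trained.

Metrics over a merged group: purity p = TP/|group| (0 for an empty group),
capture n = TP/(all near-natives) (undefined when the ensemble has none),
relative size s = |group|/|Ω|. p·|group| and n·(total near-natives) recover
the integer TP count exactly; n and s are non-decreasing in the number of
merged basins, p is not.

Strategies are compared with the Friedman test on per-target mid-ranks
(rank 1 = highest purity): χ² = 12/(Nk(k+1))·ΣRⱼ² − 3N(k+1) with N targets
and k methods, p from χ²(k−1); the Iman–Davenport F transform is reported
alongside. The post-hoc compares each method against the best (lowest)
average rank: z = (R̄ᵢ−R̄c)/√(k(k+1)/(6N)), two-sided normal p, ordered
comparisons judged against the step-down critical ladder α/m, α/(m−1), …, α
(m = k−1). The full Hommel step-up adjustment is available behind
`procedure="hommel"`; the ladder is the default because it is the form the
comparison tables in this literature print.

## Synthetic-data generator

The pipeline consumes only pairwise distances, energies, and per-decoy
score features, so the generator reproduces the joint statistics of those
quantities rather than protein geometry. Structure space is 3-dimensional
Euclidean (one pseudo-atom per decoy; lRMSD to the native = distance to
the origin). Decoys come from a funnel mixture: with probability
`near_native_frac` (default 0.01 at desk scale; the real-data regime goes
down to 5·10⁻⁵) a decoy is drawn in the near-native shell with radius
uniform on [min_dist, dist_thresh); otherwise from one of four background
funnels centered 8–14 Å from the origin (sd 1.5 Å, geometrically decaying
weights), resampled out of the shell so the realized near-native count is
exactly binomial. One seed decoy is pinned at exactly min_dist, making the
difficulty category deterministic.

Energy = 1.0/Å · (distance to the nearest funnel center) + that funnel's
depth + N(0, 1). The native funnel depth is −15 versus −9…−5 for the
background funnels: deep enough that the native basin anchors the lowest
focal minimum in ≥ 90% of seeds (a sanity property the tests check), while
the noise keeps energy-only ranking imperfect — mirroring the observation
that energy bias alone does not find natives. Each of the 20 score features
is sⱼ·lRMSD + cⱼ + N(0, σⱼ) with σⱼ = |sⱼ|·sd(lRMSD)·√(1/ρ²−1), giving
Pearson correlation ρ with the true lRMSD (default 0.9; ρ = 0 yields
intercept-plus-noise features for the leakage control). The slopes and
intercepts are a fixed table shared by all targets, as real physics-based
scores share one functional form across proteins — this is what lets a
regressor trained on six targets transfer to a seventh.

What the generator does *not* emulate: torsional geometry, fragment-
assembly sampling artifacts, heavy-tailed score distributions, or
inter-feature correlations beyond their common lRMSD dependence. Passing
benchmarks on it therefore demonstrates that the pipeline's machinery is
correct and that the method's logic works when its statistical assumptions
hold; it does not certify performance on real Rosetta ensembles.

## Problem sizes and numerical choices

The desk benchmark uses 18 targets (5 easy / 6 medium / 7 hard) of 2,000
decoys each with 5 repeated ML trainings per target — sizes chosen so a
full all-strategy benchmark completes in tens of seconds on one CPU while
preserving every structural property of the full-scale setting (51k–68k
decoys, 50 repetitions), which the same code handles by changing two
numbers. Very small test fixtures (a few hundred decoys) raise
`near_native_frac` to 0.05 because 1% of 300 decoys trips the
scarcity-demotion rule and collapses every category to hard.

Determinism: all randomness flows from explicit integer seeds through
NumPy generators and XGBoost's seeded single-threaded updater; reports are
JSON with sorted keys, so a full benchmark is byte-reproducible.

Statistical test validation compares the Friedman p against a seeded
permutation null. The statistic is lattice-valued, so the continuous χ²
tail is compared against the permutation mid-p (the standard convention for
discrete nulls), with the Monte-Carlo standard error evaluated at the
hypothesized value (score form). At N = 18 the χ² approximation error is of
order 0.01 — the same order as three Monte-Carlo standard errors at 10⁴
shuffles — so these two conventions matter and are fixed here explicitly.

## Known limitations

- The full-scale 60k-decoy regime needs ~30 GB for a dense double-precision
  distance matrix; the landscape stage accepts precomputed (memory-mapped)
  matrices, but no out-of-core path is built in.
- Per-decoy quality scores are out of scope: the output is a group of
  decoys, not a ranking within it.
- S+E and the exact escalation protocol follow this package's documented
  conventions where the literature is silent; results for those baselines
  should be compared across implementations with that in mind.
- The local-minimum ≤ convention can fragment flat plateaus into many
  basins on quantized energies.
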