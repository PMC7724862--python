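"""Seeded generator of synthetic decoy ensembles with multi-funnel landscape
structure.

The pipeline consumes only pairwise distances, energies and per-decoy score
features, so the generator reproduces their joint statistics rather than
protein geometry: structure space is a low-dimensional Euclidean space (one
pseudo-atom per decoy), the native sits at the origin, and decoys are drawn
from a mixture of funnels. Near-natives appear with a small Bernoulli
probability inside the near-native shell; background decoys come from
funnels centered well away from the origin and are rejected from the shell,
so the realized near-native count is exactly binomial. Energy couples to the
landscape through the nearest funnel center (distance-within-funnel slope
plus funnel depth plus Gaussian noise) with the native funnel deepest, and
each of the 20 score features is an affine function of true lRMSD with noise
calibrated to a requested Pearson correlation ρ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .evaluation import TargetMeta, classify_target
from .io_formats import DEFAULT_SCHEMA, Ensemble, FeatureSchema, ValidationError

#: fixed affine map feature_j = slope_j * rmsd + intercept_j + noise, shared
#: across targets the way real physics-based scores share one functional form
_FEATURE_SLOPES = tuple(((-1.0) ** j) * (0.8 + 0.37 * j) for j in range(20))
_FEATURE_INTERCEPTS = tuple(10.0 * (j % 7) - 30.0 for j in range(20))

_DEFAULT_MIN_DIST = {"easy": 0.6, "medium": 1.3, "hard": 2.5}


def default_dist_thresh(difficulty: str, min_dist: float) -> float:
    """Near-native cutoff used at generation time: the category default, or
    for hard targets at least 1 Å beyond min_dist so the shell is non-empty."""
    if difficulty == "easy":
        return 2.0
    if difficulty == "medium":
        return 3.0
    return max(3.0, min_dist + 1.0)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic decoy ensemble.

    Defaults are the desk-scale study conditions: 2,000 decoys, 5 funnels,
    1% near-natives, feature–lRMSD correlation 0.9. ``preset='fullscale'``
    in :func:`generate_ensemble` callers may raise size to 51,000–68,000.
    """

    target_id: str = "synthetic"
    size: int = 2000
    dim: int = 3
    n_funnels: int = 5
    funnel_centers: Optional[np.ndarray] = None  # (n_funnels, dim); row 0 = native
    funnel_weights: Optional[np.ndarray] = None
    funnel_spread: float = 1.5       # Å, sd of each background funnel
    near_native_frac: float = 0.01
    min_dist: float = 0.6            # Å, engineered minimum lRMSD to native
    dist_thresh: Optional[float] = None
    energy_slope: float = 1.0        # a: energy per Å from nearest center
    funnel_depths: Optional[np.ndarray] = None  # b-term; row 0 = native depth
    energy_noise: float = 1.0        # σ_E
    feature_rho: float = 0.9         # ρ; 0 gives the uninformative control
    difficulty: str = "easy"
    seed: int = 0

    def resolved_dist_thresh(self) -> float:
        if self.dist_thresh is not None:
            return float(self.dist_thresh)
        return default_dist_thresh(self.difficulty, self.min_dist)


FULLSCALE_SIZE_RANGE = (51_000, 68_000)


def _default_centers(rng: np.random.Generator, n_funnels: int, dim: int) -> np.ndarray:
    centers = np.zeros((n_funnels, dim))
    for i in range(1, n_funnels):
        v = rng.normal(size=dim)
        v /= np.linalg.norm(v)
        centers[i] = v * rng.uniform(8.0, 14.0)
    return centers


def _default_depths(n_funnels: int) -> np.ndarray:
    depths = np.empty(n_funnels)
    depths[0] = -15.0
    if n_funnels > 1:
        depths[1:] = np.linspace(-9.0, -5.0, n_funnels - 1)
    return depths


def generate_ensemble(spec: SyntheticSpec) -> Ensemble:
    """Draw one ensemble (coords, energies, features, true lRMSD) from the
    spec; fully reproducible from ``spec.seed``."""
    if not 0.0 <= spec.near_native_frac <= 1.0:
        raise ValidationError("near_native_frac must be in [0, 1]")
    if spec.size < 2:
        raise ValidationError("size must be at least 2")
    if spec.n_funnels < 1:
        raise ValidationError("need at least one funnel")
    thresh = spec.resolved_dist_thresh()
    if spec.near_native_frac > 0 and not spec.min_dist < thresh:
        raise ValidationError("min_dist must be below dist_thresh when "
                              "near-natives are requested")
    rng = np.random.default_rng(spec.seed)
    centers = spec.funnel_centers
    if centers is None:
        centers = _default_centers(rng, spec.n_funnels, spec.dim)
    centers = np.asarray(centers, dtype=float)
    depths = spec.funnel_depths
    if depths is None:
        depths = _default_depths(spec.n_funnels)
    depths = np.asarray(depths, dtype=float)

    n = spec.size
    is_native = rng.random(n) < spec.near_native_frac
    if spec.near_native_frac > 0:
        is_native[0] = True  # seed decoy pins the realized min_dist
    pos = np.empty((n, spec.dim))

    # near-native shell: uniform radius in [min_dist, thresh), random direction
    idx_nat = np.flatnonzero(is_native)
    if len(idx_nat):
        dirs = rng.normal(size=(len(idx_nat), spec.dim))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = rng.uniform(spec.min_dist, thresh, size=len(idx_nat))
        radii[0] = spec.min_dist
        pos[idx_nat] = dirs * radii[:, None]

    # background: funnel mixture, resampled out of the near-native shell
    idx_bg = np.flatnonzero(~is_native)
    if len(idx_bg):
        if spec.n_funnels < 2:
            raise ValidationError("background decoys need at least 2 funnels")
        if spec.funnel_weights is not None:
            w = np.asarray(spec.funnel_weights, dtype=float)[1:]
        else:
            w = 0.8 ** np.arange(spec.n_funnels - 1)
        w = w / w.sum()
        funnel = rng.choice(np.arange(1, spec.n_funnels), size=len(idx_bg), p=w)
        draw = centers[funnel] + rng.normal(scale=spec.funnel_spread,
                                            size=(len(idx_bg), spec.dim))
        bad = np.linalg.norm(draw, axis=1) <= thresh
        while bad.any():
            k = int(bad.sum())
            draw[bad] = centers[funnel[bad]] + rng.normal(
                scale=spec.funnel_spread, size=(k, spec.dim))
            bad = np.linalg.norm(draw, axis=1) <= thresh
        pos[idx_bg] = draw

    rmsd = np.linalg.norm(pos, axis=1)
    d_to_centers = np.linalg.norm(pos[:, None, :] - centers[None, :, :], axis=2)
    nearest = np.argmin(d_to_centers, axis=1)
    energy = (spec.energy_slope * d_to_centers[np.arange(n), nearest]
              + depths[nearest] + rng.normal(scale=spec.energy_noise, size=n))

    schema = DEFAULT_SCHEMA
    sd_r = float(np.std(rmsd))
    features = np.empty((n, schema.total))
    for j in range(schema.total):
        s, c = _FEATURE_SLOPES[j], _FEATURE_INTERCEPTS[j]
        if spec.feature_rho > 0:
            sigma = abs(s) * sd_r * np.sqrt(1.0 / spec.feature_rho ** 2 - 1.0)
            features[:, j] = s * rmsd + c + rng.normal(scale=sigma, size=n)
        else:
            features[:, j] = c + rng.normal(scale=abs(s) * sd_r, size=n)

    return Ensemble(
        target_id=spec.target_id,
        decoy_ids=[f"{spec.target_id}_d{i:05d}" for i in range(n)],
        energies=energy,
        features=features,
        schema=schema,
        rmsd_native=rmsd,
        coords=pos[:, None, :],
        distance_spec="euclidean",
    )


def generate_benchmark(n_easy: int = 5, n_medium: int = 6, n_hard: int = 7,
                       base_seed: int = 0, size: int = 2000,
                       feature_rho: float = 0.9,
                       near_native_frac: float = 0.01,
                       ) -> list[tuple[Ensemble, TargetMeta]]:
    """A benchmark of labeled synthetic targets mirroring a 5/6/7
    easy/medium/hard design, with per-target seeds derived from base_seed.

    Engineered min_dist values walk each category's interval (easy < 1 Å,
    medium [1, 2), hard ≥ 2, extending past 3 so cutoff escalation is
    exercised). Metadata comes from :func:`classify_target` on the realized
    lRMSDs.
    """
    master = np.random.default_rng(base_seed)
    plans = []
    for i in range(n_easy):
        plans.append(("easy", 0.50 + 0.09 * (i % 5)))
    for i in range(n_medium):
        plans.append(("medium", 1.05 + 0.16 * (i % 6)))
    for i in range(n_hard):
        plans.append(("hard", 2.10 + 0.22 * (i % 7)))
    out = []
    for t, (difficulty, min_dist) in enumerate(plans):
        seed = int(master.integers(2 ** 31))
        spec = SyntheticSpec(
            target_id=f"{difficulty}{t:02d}", size=size, difficulty=difficulty,
            min_dist=min_dist, near_native_frac=near_native_frac,
            feature_rho=feature_rho, seed=seed)
        ens = generate_ensemble(spec)
        meta = classify_target(ens.min_dist, ens.rmsd_native,
                               target_id=ens.target_id)
        out.append((ens, meta))
    return out
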