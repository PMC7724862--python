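"""The four ranking-based basin-selection baselines.

S ranks by basin size alone; S+E by an equal-weight rank-sum of size and
focal energy; PR by ascending Pareto rank; PR+PC by Pareto rank with Pareto
count breaking ties. All residual ties fall back to ascending basin_id so
every ordering is deterministic and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import rankdata

from .basin_features import BasinFeatureRow
from .io_formats import ConfigurationError, ValidationError

STRATEGIES = ("S", "S+E", "PR", "PR+PC", "ML")
BASELINE_STRATEGIES = ("S", "S+E", "PR", "PR+PC")


@dataclass
class RankedSelection:
    """An ordered (best-first) list of basin ids plus the scalar each basin
    was scored with; lower-is-better or higher-is-better depends on the
    strategy and is recorded in ``ascending``."""

    strategy: str
    ordered_basins: list[int]
    scores: dict[int, float] = field(default_factory=dict)
    ascending: bool = True


def rank_basins(strategy: str, rows: Sequence[BasinFeatureRow]) -> RankedSelection:
    """Order basins best-first under one of the baseline strategies."""
    if not rows:
        raise ValidationError("no basins to rank")
    if strategy == "S":
        keyed = [((-r.size, r.basin_id), r.basin_id, float(r.size)) for r in rows]
        ascending = False
    elif strategy == "S+E":
        size_rank = rankdata([-r.size for r in rows], method="average")
        energy_rank = rankdata([r.focal_energy for r in rows], method="average")
        keyed = [((size_rank[i] + energy_rank[i], r.basin_id), r.basin_id,
                  float(size_rank[i] + energy_rank[i]))
                 for i, r in enumerate(rows)]
        ascending = True
    elif strategy == "PR":
        keyed = [((r.PR, r.basin_id), r.basin_id, float(r.PR)) for r in rows]
        ascending = True
    elif strategy == "PR+PC":
        keyed = [((r.PR, -r.PC, r.basin_id), r.basin_id, float(r.PR)) for r in rows]
        ascending = True
    else:
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    keyed.sort(key=lambda t: t[0])
    return RankedSelection(
        strategy=strategy,
        ordered_basins=[bid for _, bid, _ in keyed],
        scores={bid: s for _, bid, s in keyed},
        ascending=ascending)
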