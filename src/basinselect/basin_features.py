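"""Per-basin learning features: Pareto dominance statistics and a graph
feature describing the spatial organization of each basin's members.

Basins compete on two conflicting objectives — maximize size, minimize focal
energy. A dominates B iff A is at least as good on both objectives and
strictly better on one. The Pareto rank PR(A) counts the basins dominating A
(0 = nondominated) and the Pareto count PC(A) counts the basins A dominates.
The graph feature re-embeds each basin's members in their own
nearest-neighbor graph at cutoff pdist+1 Å, where pdist is the mean pairwise
member distance, and counts connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .io_formats import Ensemble, ValidationError
from .landscape import Basin, BasinDecomposition, distance_matrix

#: Default phase-1 model inputs: the two Pareto-derived ranks plus the
#: component count.  Raw PR/PC stay available on each row for wider sets.
PHASE1_FEATURES = ("pr_rank", "pc_rank", "n_components")


@dataclass
class BasinFeatureRow:
    """Learning features and optional purity label for one basin."""

    basin_id: int
    size: int
    focal_energy: float
    PR: int
    PC: int
    pr_rank: float
    pc_rank: float
    pdist: float
    n_components: int
    purity_label: Optional[float] = None
    target_id: Optional[str] = None


def pareto_rank_count(basins: Sequence[Basin]) -> tuple[np.ndarray, np.ndarray]:
    """PR and PC per basin under (maximize size, minimize focal energy).

    dom[i, j] is True iff basin i dominates basin j; PR is the column sum,
    PC the row sum.
    """
    sizes = np.array([b.size for b in basins], dtype=float)
    energies = np.array([b.focal_energy for b in basins], dtype=float)
    ge_size = sizes[:, None] >= sizes[None, :]
    le_energy = energies[:, None] <= energies[None, :]
    strict = (sizes[:, None] > sizes[None, :]) | (energies[:, None] < energies[None, :])
    dom = ge_size & le_energy & strict
    return dom.sum(axis=0).astype(int), dom.sum(axis=1).astype(int)


def basin_component_count(ensemble: Ensemble, basin: Basin) -> tuple[float, int]:
    """(pdist, n_components) for one basin.

    pdist is the mean distance over unordered member pairs (0 for a
    singleton); the member graph connects pairs within pdist+1 Å and its
    connected components are counted.
    """
    members = np.asarray(basin.members)
    if members.size == 0:
        raise ValidationError("basin has no members")
    if members.size == 1:
        return 0.0, 1
    D = distance_matrix(ensemble)[np.ix_(members, members)]
    iu = np.triu_indices(members.size, k=1)
    pd_mean = float(D[iu].mean())
    adj = D <= pd_mean + 1.0
    np.fill_diagonal(adj, False)
    ncomp, _ = connected_components(csr_matrix(adj), directed=False)
    return pd_mean, int(ncomp)


def featurize_basins(decomp: BasinDecomposition, ensemble: Ensemble,
                     labels: Optional[np.ndarray] = None) -> list[BasinFeatureRow]:
    """One :class:`BasinFeatureRow` per basin.

    pr_rank ranks ascending PR (rank 1 = nondominated) and pc_rank ranks
    descending PC (rank 1 = dominates most), both with mid-rank ties. With
    ``labels`` (per-decoy near-native flags) the true purity of each basin is
    attached as the training label.
    """
    if labels is not None:
        labels = np.asarray(labels, dtype=bool)
        if len(labels) != ensemble.size:
            raise ValidationError("labels length does not match ensemble size")
    PR, PC = pareto_rank_count(decomp.basins)
    pr_rank = rankdata(PR, method="average")
    pc_rank = rankdata(-PC, method="average")
    rows = []
    for i, b in enumerate(decomp.basins):
        pd_mean, ncomp = basin_component_count(ensemble, b)
        purity = None
        if labels is not None:
            purity = float(labels[b.members].sum() / b.size)
        rows.append(BasinFeatureRow(
            basin_id=b.basin_id, size=b.size, focal_energy=b.focal_energy,
            PR=int(PR[i]), PC=int(PC[i]), pr_rank=float(pr_rank[i]),
            pc_rank=float(pc_rank[i]), pdist=pd_mean, n_components=ncomp,
            purity_label=purity, target_id=ensemble.target_id))
    return rows


def rows_to_frame(rows: Sequence[BasinFeatureRow]) -> pd.DataFrame:
    """Tabular view of feature rows (for the `features` CLI and model IO)."""
    return pd.DataFrame([{
        "target_id": r.target_id, "basin_id": r.basin_id, "size": r.size,
        "focal_energy": r.focal_energy, "PR": r.PR, "PC": r.PC,
        "pr_rank": r.pr_rank, "pc_rank": r.pc_rank, "pdist": r.pdist,
        "n_components": r.n_components, "purity_label": r.purity_label,
    } for r in rows])


def feature_matrix(rows: Sequence[BasinFeatureRow],
                   feature_names: Sequence[str] = PHASE1_FEATURES) -> np.ndarray:
    return np.array([[getattr(r, name) for name in feature_names] for r in rows],
                    dtype=float)
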