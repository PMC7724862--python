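"""Generic energy-vs-lRMSD scatter plots of ensembles and selections."""

from __future__ import annotations

from typing import Optional, Sequence

from .io_formats import Ensemble, ValidationError

_GROUP_COLORS = ("maroon", "gold", "navy")


def plot_selection(ensemble: Ensemble, selection=None, ax=None,
                   max_groups: int = 3):
    """Scatter decoys by (lRMSD to native, energy); highlight the merged
    top-x groups of a selection in distinct colors. Returns the axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ensemble.rmsd_native is None:
        raise ValidationError("plotting requires rmsd_native")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ensemble.rmsd_native, ensemble.energies, s=4, c="0.8",
               label="ensemble", rasterized=True)
    if selection is not None:
        shown: set[int] = set()
        groups = selection.groups if hasattr(selection, "groups") else selection
        for x in sorted(groups)[:max_groups]:
            fresh = [i for i in groups[x] if i not in shown]
            shown.update(fresh)
            if fresh:
                ax.scatter(ensemble.rmsd_native[fresh], ensemble.energies[fresh],
                           s=10, c=_GROUP_COLORS[(x - 1) % len(_GROUP_COLORS)],
                           label=f"basin group {x}")
    ax.set_xlabel("lRMSD to native (Å)")
    ax.set_ylabel("energy")
    ax.set_title(ensemble.target_id)
    ax.legend(loc="best", fontsize=8)
    return ax
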