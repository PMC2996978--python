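"""Red-green heatmaps of gene sets with score-ordered columns."""

from __future__ import annotations

import numpy as np

from .dataio import ClinicalTable, ExpressionMatrix
from .survival import column_sum_score

__all__ = ["set_heatmap"]


def set_heatmap(
    m: ExpressionMatrix,
    probes,
    clinical: ClinicalTable | None = None,
    path=None,
    title: str = "",
):
    """Draw one gene set as a heatmap.

    Columns (samples) are ordered by the set's column-sum score, rows by
    the given probe order; values map onto a green (low) to red (high)
    continuum.  When clinical data are supplied, samples with an observed
    event are marked along the top edge.  Returns the matplotlib figure;
    saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    probes = list(probes)
    scores = column_sum_score(m, probes)
    order = np.lexsort((np.arange(m.n_samples), scores))
    index = {p: i for i, p in enumerate(m.probe_ids)}
    block = m.values[[index[p] for p in probes]][:, order]

    fig, ax = plt.subplots(
        figsize=(max(4, m.n_samples / 20), max(2, len(probes) / 4))
    )
    vmax = float(np.nanmax(np.abs(block - np.nanmean(block))))
    ax.imshow(
        block,
        aspect="auto",
        cmap="RdYlGn_r",
        vmin=np.nanmean(block) - vmax,
        vmax=np.nanmean(block) + vmax,
        interpolation="nearest",
    )
    ax.set_yticks(range(len(probes)))
    ax.set_yticklabels(probes, fontsize=5)
    ax.set_xticks([])
    ax.set_xlabel("samples (ordered by column sum)")
    if title:
        ax.set_title(title, fontsize=8)
    if clinical is not None:
        clin = clinical.align(m.sample_ids)
        events = np.asarray(clin.event)[order] == 1
        ax.scatter(
            np.flatnonzero(events),
            np.full(events.sum(), -0.8),
            marker="v",
            s=8,
            color="black",
            clip_on=False,
        )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
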