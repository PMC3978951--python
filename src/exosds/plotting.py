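"""Plots: the NMDS scatter and the SDS-versus-error reference curve."""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .curve import ReferenceCurve
from .nmds import Embedding


def plot_embedding(
    embedding: Embedding,
    populations: Optional[dict[str, str]] = None,
    test_samples: Sequence[str] = (),
    ax=None,
):
    """Scatter the 2-D embedding; reference samples as circles colored by
    population, test samples as triangles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    populations = populations or {}
    test_set = set(test_samples)
    pops = sorted({populations.get(l, "reference") for l in embedding.labels if l not in test_set})
    cmap = plt.get_cmap("tab10")
    colors = {pop: cmap(i % 10) for i, pop in enumerate(pops)}
    for pop in pops:
        idx = [
            i
            for i, l in enumerate(embedding.labels)
            if l not in test_set and populations.get(l, "reference") == pop
        ]
        ax.scatter(
            embedding.coords[idx, 0], embedding.coords[idx, 1],
            s=18, color=colors[pop], label=pop, alpha=0.8,
        )
    for label in test_samples:
        i = embedding.labels.index(label)
        ax.scatter(
            embedding.coords[i, 0], embedding.coords[i, 1],
            marker="^", s=70, edgecolor="black", zorder=3, label=label,
        )
    ax.set_xlabel(r"$\Phi_1$")
    ax.set_ylabel(r"$\Phi_2$")
    ax.legend(fontsize=8, loc="best")
    ax.set_title(f"non-metric MDS (stress-1 = {embedding.stress1:.3g})")
    return ax


def plot_curve(
    curve: ReferenceCurve,
    sds_values: Optional[dict[str, float]] = None,
    ax=None,
):
    """SDS against log10 error rate with the 5%/95% band; observed test
    SDS values are drawn as horizontal lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    log_p = np.log10(curve.grid)
    ax.fill_between(log_p, curve.sds_q05, curve.sds_q95, alpha=0.25, label="5%-95% band")
    ax.plot(log_p, curve.sds_median, marker="o", label="median SDS")
    for name, value in (sds_values or {}).items():
        ax.axhline(value, linestyle="--", linewidth=1)
        ax.annotate(name, xy=(log_p[0], value), fontsize=8, va="bottom")
    ax.set_xlabel(r"$\log_{10}$ genotyping error rate")
    ax.set_ylabel("standardized dissimilarity score")
    ax.legend(fontsize=8)
    return ax
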