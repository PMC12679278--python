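"""Thin plotting layer over exported GGE coordinates (optional).

Everything analytic lives in :mod:`metgge.gge`; these helpers only draw the
standard biplot views from a fitted model for quick visual inspection.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .gge import AECFrame, GGEModel, MegaEnvironmentResult


def plot_biplot(
    model: GGEModel,
    frame: AECFrame | None = None,
    result: MegaEnvironmentResult | None = None,
    path: str | Path | None = None,
):
    """Scatter of genotype and environment scores on the two retained axes."""
    geno, env = model.scores_2d()
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.scatter(geno[:, 0], geno[:, 1], s=12, color="tab:blue", label="genotypes")
    for label, (x, y) in zip(model.environment_labels, env):
        ax.annotate(label, (x, y), color="tab:red")
        ax.plot([0, x], [0, y], color="tab:red", lw=1)
    if frame is not None:
        span = float(np.abs(geno).max() + np.abs(env).max())
        ax.plot([-span * frame.abscissa[0], span * frame.abscissa[0]],
                [-span * frame.abscissa[1], span * frame.abscissa[1]],
                color="tab:green", lw=1, label="AEC abscissa")
    if result is not None:
        idx = {g: i for i, g in enumerate(model.genotype_labels)}
        hull = np.array([geno[idx[v]] for v in result.hull_vertices])
        closed = np.vstack([hull, hull[:1]])
        ax.plot(closed[:, 0], closed[:, 1], color="0.4", lw=1)
    pct = 100 * model.variance_explained
    ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
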