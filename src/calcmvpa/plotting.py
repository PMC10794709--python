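"""Plot helpers for the pipeline's main result objects."""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_psychometric(fit, data=None, ax=None):
    """Fitted psychometric curve with observed proportions per ratio."""
    ax = _axes(ax)
    x = np.linspace(np.log(0.45), np.log(2.2), 200)
    ax.plot(x, fit.predict(np.exp(x)), label=f"fit (JND={fit.jnd:.3f})")
    if data is not None:
        grouped = (data.assign(larger=(data["response"] == "larger"))
                       .groupby("probe_ratio")["larger"].mean())
        ax.plot(np.log(grouped.index.to_numpy(float)), grouped.to_numpy(),
                "o", label="observed")
    ax.axhline(0.5, color="gray", lw=0.5)
    ax.axvline(fit.pse, color="gray", lw=0.5, ls="--")
    ax.set_xlabel("log probe:result ratio")
    ax.set_ylabel('P(respond "larger")')
    ax.legend(frameon=False)
    return ax


def plot_generalization_matrix(matrix, ax=None):
    """Heatmap of a train-bin x test-bin decoding generalization matrix."""
    ax = _axes(ax)
    im = ax.imshow(matrix.scores, origin="lower", cmap="RdBu_r",
                   extent=(0.5, len(matrix.bins) + 0.5, 0.5, len(matrix.bins) + 0.5))
    ax.figure.colorbar(im, ax=ax, label="Fisher-z score")
    ax.set_xlabel(f"test bin ({matrix.test_attr})")
    ax.set_ylabel(f"train bin ({matrix.train_attr})")
    return ax


def plot_rsa_timecourse(effects, ax=None):
    """Bin-wise RDM-regression betas per predictor for one voxel set."""
    ax = _axes(ax)
    for j, name in enumerate(effects.predictor_names):
        ax.plot(effects.bins, effects.betas[:, j], marker="o", label=name)
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("FIR bin (2 s each)")
    ax.set_ylabel("beta")
    ax.legend(frameon=False)
    return ax
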