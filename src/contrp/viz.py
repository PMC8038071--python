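"""Visualization: Cont-RP raster images and 2-D t-SNE maps of representations."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE

from .errors import DataError
from .recurrence import ContRP, rp_to_image

#: low distances dark blue, high distances yellow
RP_CMAP = "viridis"
CLASS_COLORS = {1: "red", 0: "green"}  # stressed red, relaxed green


def render_rp_image(rp: ContRP, path: str | Path) -> None:
    """Write a Cont-RP as an M x M pixel raster with the viridis colormap."""
    img = rp_to_image(rp)
    plt.imsave(str(path), img, cmap=RP_CMAP, vmin=0.0, vmax=1.0, origin="lower")


def embed_2d(representations: np.ndarray, labels, seed: int = 0,
             out_path: str | Path | None = None) -> np.ndarray:
    """t-SNE of representation vectors down to 2-D, optionally with a scatter plot.

    Deterministic for a fixed seed; perplexity adapts to small batches.
    """
    reps = np.asarray(representations, dtype=float)
    if reps.ndim != 2 or reps.shape[0] < 3:
        raise DataError("need a 2-D batch of at least 3 representation vectors")
    n = reps.shape[0]
    perplexity = min(30.0, max(1.0, (n - 2) / 3))
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(reps)
    if out_path is not None:
        labels = np.asarray(labels)
        fig, ax = plt.subplots(figsize=(5, 5))
        for lab, color in CLASS_COLORS.items():
            sel = labels == lab
            name = "stressed" if lab == 1 else "relaxed"
            ax.scatter(coords[sel, 0], coords[sel, 1], s=12, c=color, label=name)
        ax.legend()
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return coords
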