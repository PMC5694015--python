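"""Optional kymograph-style heatmaps (cells x time) of a trajectory.

Matplotlib is imported lazily; everything else in the package works without
it.  Blue-to-red maps low-to-high expression.  PNGs are presentation output
and are excluded from the byte-reproducibility guarantees.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulate import TrajectoryRecord

__all__ = ["trajectory_heatmap"]


def trajectory_heatmap(record: TrajectoryRecord, path: str | Path,
                       species: tuple[str, ...] = ("B", "V")) -> Path:
    """Write a heatmap PNG with one panel per species (cells x time)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(species), figsize=(4 * len(species), 3),
                             squeeze=False)
    times = np.asarray(record.times)
    for ax, sp in zip(axes[0], species):
        img = np.stack([s.species(sp) for s in record.snapshots], axis=1)
        im = ax.imshow(img, aspect="auto", origin="lower", cmap="coolwarm",
                       extent=(times[0], times[-1], 0, img.shape[0]))
        ax.set_title(sp)
        ax.set_xlabel("time")
        ax.set_ylabel("cell")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
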