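"""Contour-plot export for PES maps with optional path overlays.

Matplotlib is imported lazily so the rest of the toolkit has no hard
plotting dependency.
"""

from __future__ import annotations

import numpy as np


def plot_pesmap(
    pesmap,
    out_path,
    paths: dict[str, np.ndarray] | None = None,
    levels: int = 20,
    mask_outliers: bool = True,
):
    """Write a filled contour plot of a PES map to ``out_path``.

    ``paths`` maps legend labels to (n, 2) arrays of CV-plane points (e.g.
    from :func:`mepkit.scan.project_structures`) drawn over the map.
    Flagged outlier points are masked from the contours and marked.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    v1, v2 = pesmap.axis1.values, pesmap.axis2.values
    e = np.ma.masked_invalid(pesmap.energies)
    if mask_outliers:
        e = np.ma.masked_where(pesmap.outlier, e)

    fig, ax = plt.subplots(figsize=(6.4, 4.8))
    cs = ax.contourf(v1, v2, e.T, levels=levels, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="energy (kcal/mol)")
    if mask_outliers and pesmap.outlier.any():
        oi, oj = np.nonzero(pesmap.outlier)
        ax.plot(v1[oi], v2[oj], "x", color="red", label="outliers")
    for label, pts in (paths or {}).items():
        pts = np.asarray(pts)
        ax.plot(pts[:, 0], pts[:, 1], "o-", ms=3, label=label)
    ax.set_xlabel(pesmap.axis1.name or "axis 1 (Å)")
    ax.set_ylabel(pesmap.axis2.name or "axis 2 (Å)")
    if (paths or (mask_outliers and pesmap.outlier.any())):
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
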