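"""Eigenspace figures: score scatter plots with KDE probability contours."""

from __future__ import annotations

import numpy as np

from .strainspace import KDECoverageRegion, ScoreSet

#: plotting-only contour coverages (no classification role)
DEFAULT_CONTOURS = (0.3, 0.6, 0.9)

_COHORT_COLORS = {"DS": "tab:blue", "AD": "tab:green", "ADNC": "tab:purple"}


def eigenspace_scatter(
    scores: ScoreSet,
    contours: tuple[float, ...] = DEFAULT_CONTOURS,
    regions: dict[str, KDECoverageRegion] | None = None,
    ax=None,
    grid_size: int = 150,
):
    """Scatter the first two retained components per cohort, overlaying KDE
    contours at the stated coverages and, optionally, fitted coverage regions
    (e.g. the 99.5% ADNC/AD boundaries).

    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xy = scores.coords[:, :2]
    for cohort, sub in scores.to_frame().groupby("cohort"):
        ax.scatter(
            sub[scores.columns[0]],
            sub[scores.columns[1]],
            s=6,
            alpha=0.6,
            label=str(cohort),
            color=_COHORT_COLORS.get(str(cohort)),
        )
    if len(xy) > 3 and np.ptp(xy, axis=0).min() > 0:
        pad = 0.1 * np.ptp(xy, axis=0)
        gx = np.linspace(xy[:, 0].min() - pad[0], xy[:, 0].max() + pad[0], grid_size)
        gy = np.linspace(xy[:, 1].min() - pad[1], xy[:, 1].max() + pad[1], grid_size)
        mesh = np.meshgrid(gx, gy)
        levels = []
        region_all = KDECoverageRegion(coverage=0.5).fit(xy)
        dens = region_all.score_samples(
            np.column_stack([m.ravel() for m in mesh])
        ).reshape(grid_size, grid_size)
        for cov in sorted(contours, reverse=True):
            k = int(np.ceil(cov * len(xy)))
            levels.append(float(np.sort(region_all.self_density_)[len(xy) - k]))
        ax.contour(mesh[0], mesh[1], dens, levels=sorted(levels),
                   colors="gray", linewidths=0.8)
    if regions:
        for name, region in regions.items():
            ref = region.reference_
            pad = 0.2 * np.ptp(ref, axis=0)
            gx = np.linspace(ref[:, 0].min() - pad[0], ref[:, 0].max() + pad[0],
                             grid_size)
            gy = np.linspace(ref[:, 1].min() - pad[1], ref[:, 1].max() + pad[1],
                             grid_size)
            mesh = np.meshgrid(gx, gy)
            dens = region.score_samples(
                np.column_stack([m.ravel() for m in mesh])
            ).reshape(grid_size, grid_size)
            ax.contourf(
                mesh[0], mesh[1], dens, levels=[region.threshold_, dens.max() + 1],
                colors=[_COHORT_COLORS.get(name, "gray")], alpha=0.15,
            )
    ax.set_xlabel(scores.columns[0].upper())
    ax.set_ylabel(scores.columns[1].upper())
    ax.legend(frameon=False, fontsize=8)
    return ax
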