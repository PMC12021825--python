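"""Patch-wise spatial maps of morphometric metrics.

Whole-section trends (e.g. sparse fiber packing in inner subregions,
denser packing toward the outer edge) are visualized by averaging each
metric over the patches of a :class:`~axonmorph.io.PatchGrid` and
standardizing the per-patch means to z-scores (mean 0, SD 1 over the
included patches). Patches with fewer than ``n_min`` instances are
masked: tiny-n means are noise, not signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

from .io import PatchGrid

__all__ = ["MetricMap", "zscore", "per_patch_mean", "render_heatmap"]


@dataclass
class MetricMap:
    """Per-patch mean and z-score grids for one metric.

    ``mean`` and ``z`` are (n_rows, n_cols) float grids with NaN at
    masked patches; ``n`` counts the instances contributing to each
    patch. Over unmasked patches the z grid has mean 0 and population
    SD 1.
    """

    metric: str
    mean: np.ndarray
    z: np.ndarray
    n: np.ndarray


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD).

    A zero-variance input yields all zeros with a warning rather than a
    division error. NaNs are ignored in the statistics and propagated.
    """
    values = np.asarray(values, dtype=float)
    mu = np.nanmean(values)
    sd = np.nanstd(values)  # population SD (ddof=0)
    if sd == 0 or np.isnan(sd):
        warnings.warn("zscore: zero variance; returning zeros", stacklevel=2)
        out = np.zeros_like(values)
        out[np.isnan(values)] = np.nan
        return out
    return (values - mu) / sd


def per_patch_mean(table: pd.DataFrame, grid: PatchGrid, metric: str,
                   n_min: int = 5) -> MetricMap:
    """Average a metric over patches and z-score the patch means.

    ``table`` must carry ``patch_row``/``patch_col`` columns (as written
    by :func:`axonmorph.morphometry.compute_metrics` with a grid) and the
    requested metric column. Instances with NaN metric values are
    ignored; patches with fewer than ``n_min`` contributing instances
    are masked (NaN) and excluded from the z-score normalization.
    """
    if metric not in table.columns:
        raise KeyError(f"unknown metric column {metric!r}")
    shape = (grid.n_rows, grid.n_cols)
    total = np.zeros(shape)
    n = np.zeros(shape, dtype=int)
    sub = table.loc[table[metric].notna(),
                    ["patch_row", "patch_col", metric]]
    for pr, pc, v in sub.itertuples(index=False):
        total[int(pr), int(pc)] += v
        n[int(pr), int(pc)] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    mean = np.where(n >= n_min, mean, np.nan)
    z = np.full(shape, np.nan)
    included = ~np.isnan(mean)
    if included.sum() >= 1:
        z[included] = zscore(mean[included])
    return MetricMap(metric=metric, mean=mean, z=z, n=n)


def render_heatmap(metric_map: MetricMap, path, vmax: float = 3.0) -> None:
    """Render the z-scored map as a PNG heatmap.

    Uses a fixed diverging scale (±``vmax`` SD) so maps of different
    metrics and sections are directly comparable.
    """
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(metric_map.z, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_title(f"{metric_map.metric} (z-score)")
    ax.set_xlabel("patch col")
    ax.set_ylabel("patch row")
    fig.colorbar(im, ax=ax, label="z")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
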