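"""End-to-end convenience: semantic mask -> per-instance metric table."""

from __future__ import annotations

import pandas as pd

from .instancing import InstancingParams, extract_instances
from .io import SemanticMask, make_patch_grid
from .morphometry import compute_metrics, density_map

__all__ = ["measure_mask"]


def measure_mask(mask: SemanticMask,
                 params: InstancingParams = InstancingParams(),
                 patch_px: int = 2048,
                 cc_mask=None, subregion_masks=None,
                 thickness_reducer: str = "mean"):
    """Run instancing + morphometry on one semantic mask.

    Returns
    -------
    metrics : pandas.DataFrame
        Per-instance metric table (see
        :data:`axonmorph.morphometry.METRIC_COLUMNS`).
    instances : list of AxonInstance
    qc : pandas.DataFrame
        Dropped/flagged objects with reasons.
    density : DensityMap
        Centroid counts and per-μm² densities over the patch grid.
    """
    instances, qc = extract_instances(mask, params, cc_mask, subregion_masks)
    grid = make_patch_grid(mask, patch_px)
    metrics = compute_metrics(instances, mask.pixel_size, grid,
                              thickness_reducer=thickness_reducer)
    dens = density_map(instances, grid)
    return metrics, instances, qc, dens
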