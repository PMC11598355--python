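"""Region-level quantification of a saliency map against a parcellation.

For each atlas region the table reports:

* ``saliency_score`` — proportion of the region's voxels with normalised
  saliency strictly above the threshold tau (default 0.1);
* ``mean_saliency`` — mean saliency over all the region's voxels
  (sub-threshold voxels included);
* ``norm_mean`` — the regional means min-max normalised **across regions**
  to [0, 1], so the region with the highest mean gets 1;
* ``weighted_score`` — saliency_score x norm_mean, the ranking statistic.

Background (label 0) is never scored.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ShapeError
from .saliency import SaliencyMap
from .volume import Atlas

log = logging.getLogger(__name__)

__all__ = ["region_scores", "weighted_scores", "top_k"]


def region_scores(smap, atlas: Atlas, tau: float = 0.1) -> pd.DataFrame:
    """Per-region voxel counts, saliency score (strict > tau), and mean
    saliency, with norm_mean and weighted_score filled in.

    The map must be normalised to [0, 1] on the atlas grid. Regions with no
    voxels on the grid are excluded with a warning.
    """
    values = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap)
    if values.shape != atlas.labels.shape:
        raise ShapeError(f"map {values.shape} vs atlas {atlas.labels.shape}")
    rows = []
    for rid in sorted(atlas.names):
        region = atlas.labels == rid
        n = int(region.sum())
        if n == 0:
            log.warning("region %d (%s) has no voxels; excluded",
                        rid, atlas.names[rid])
            continue
        vals = values[region]
        rows.append({
            "region_id": rid,
            "name": atlas.names[rid],
            "n_voxels": n,
            "saliency_score": float(np.mean(vals > tau)),
            "mean_saliency": float(vals.mean()),
        })
    return weighted_scores(pd.DataFrame(rows))


def weighted_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``norm_mean`` (across-regions min-max of mean_saliency) and
    ``weighted_score`` (saliency_score x norm_mean).

    With all regional means equal the normalisation is degenerate;
    norm_mean is then defined as 1 for every region (flagged in the log).
    """
    table = table.copy()
    means = table["mean_saliency"].to_numpy(dtype=float)
    lo, hi = means.min(), means.max()
    if hi == lo:
        log.warning("all regional means equal (%.4g): norm_mean degenerate, "
                    "set to 1 for all regions", lo)
        table["norm_mean"] = 1.0
    else:
        table["norm_mean"] = (means - lo) / (hi - lo)
    table["weighted_score"] = table["saliency_score"] * table["norm_mean"]
    return table


def top_k(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top regions by weighted score, descending; ties broken by saliency
    score, then region id (stable)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} scored regions")
    ordered = table.sort_values(
        by=["weighted_score", "saliency_score", "region_id"],
        ascending=[False, False, True], kind="stable")
    return ordered.head(k).reset_index(drop=True)
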