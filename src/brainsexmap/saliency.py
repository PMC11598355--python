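"""Gradient class-saliency maps and their aggregation into a sex differences
map.

A subject's saliency map is the voxelwise magnitude of the gradient of the
classifier's pre-sigmoid score with respect to the input volume, obtained in
a single backward pass, then min-max normalised to [0, 1] within the brain
mask (0 outside). Because the classifier has a single logit, targeting the
female class only flips the gradient's sign, so the magnitude map is
class-agnostic. Per-sex maps average the normalised maps of correctly
classified subjects of each sex; the composite "sex differences map"
averages over the TIV-balanced correctly-classified subset.

The gradient is taken on the pre-sigmoid score rather than the probability
to avoid sigmoid saturation shrinking gradients for confident predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, NumericError, ShapeError

log = logging.getLogger(__name__)

__all__ = [
    "SaliencyMap", "gradient_saliency", "gradient_saliency_batch",
    "average_maps", "sexwise_average", "spearman_maps", "minmax_normalize",
]


@dataclass
class SaliencyMap:
    """Voxelwise importance grid on the template grid.

    ``state`` is 'raw' (unnormalised gradient magnitudes) or 'minmax'
    (min 0 / max 1 within the mask, 0 outside).
    """

    values: np.ndarray
    state: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)


def minmax_normalize(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = values[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateInputError("constant saliency within the mask")
    out = np.zeros_like(values, dtype=np.float32)
    out[mask] = (vals - lo) / (hi - lo)
    return out


def gradient_saliency(model, vol, mask: np.ndarray) -> SaliencyMap:
    """|d score/d voxel| of one volume, min-max normalised within the mask.

    ``model`` must expose ``input_gradient`` (evaluation mode, dropout off);
    one backward pass per subject.
    """
    from .volume import Volume
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ShapeError(f"mask {mask.shape} vs volume {data.shape}")
    g = model.input_gradient(data[None])[0]
    if not np.all(np.isfinite(g)):
        bad = int(np.sum(~np.isfinite(g)))
        raise NumericError(f"{bad} non-finite gradient voxels")
    return SaliencyMap(minmax_normalize(np.abs(g), mask), state="minmax")


def gradient_saliency_batch(model, stack: np.ndarray, masks,
                            batch_size: int = 8) -> list[SaliencyMap]:
    """Per-subject saliency maps for a stack of volumes, computed in batched
    backward passes; semantics identical to :func:`gradient_saliency`."""
    out: list[SaliencyMap] = []
    for i in range(0, len(stack), batch_size):
        g = model.input_gradient(stack[i:i + batch_size])
        if not np.all(np.isfinite(g)):
            raise NumericError("non-finite gradient voxels in batch")
        for j in range(g.shape[0]):
            mask = np.asarray(masks[i + j], dtype=bool)
            out.append(SaliencyMap(minmax_normalize(np.abs(g[j]), mask),
                                   state="minmax"))
    return out


def average_maps(maps, mask: np.ndarray, renormalize: bool = True) -> SaliencyMap:
    """Voxelwise mean of normalised maps, optionally min-max re-normalised so
    downstream thresholds operate on [0, 1]."""
    maps = list(maps)
    if not maps:
        raise DegenerateInputError("no maps to average")
    stack = np.stack([m.values if isinstance(m, SaliencyMap) else np.asarray(m)
                      for m in maps])
    mean = stack.mean(axis=0)
    if renormalize:
        return SaliencyMap(minmax_normalize(mean, np.asarray(mask, dtype=bool)),
                           state="minmax")
    return SaliencyMap(mean.astype(np.float32), state="raw")


def sexwise_average(maps: dict[str, SaliencyMap], preds: pd.DataFrame,
                    mask: np.ndarray, renormalize: bool = True,
                    ) -> tuple[SaliencyMap | None, SaliencyMap | None]:
    """(female map, male map): averages over correctly classified subjects of
    each sex. A sex with no correct classifications yields None (logged)."""
    out = []
    for sex in ("F", "M"):
        ok = preds.loc[(preds["true"] == sex) & (preds["pred"] == sex),
                       "subject_id"]
        chosen = [maps[s] for s in ok if s in maps]
        if not chosen:
            log.warning("no correctly classified %s subjects with maps; "
                        "per-sex map absent", sex)
            out.append(None)
        else:
            out.append(average_maps(chosen, mask, renormalize=renormalize))
    return tuple(out)


def spearman_maps(map_a, map_b, mask: np.ndarray) -> float:
    """Spearman rank correlation over in-mask voxels (average-rank ties)."""
    a = map_a.values if isinstance(map_a, SaliencyMap) else np.asarray(map_a)
    b = map_b.values if isinstance(map_b, SaliencyMap) else np.asarray(map_b)
    mask = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ShapeError("maps and mask must share one grid")
    if not mask.any():
        raise DegenerateInputError("empty mask")
    av, bv = a[mask], b[mask]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise DegenerateInputError("constant map: rank correlation undefined")
    rho = stats.spearmanr(av, bv).statistic
    return float(rho)
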