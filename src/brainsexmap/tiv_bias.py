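"""Post-hoc total-intracranial-volume (TIV) bias audit.

TIV is the dominant confound for sex classification from brain images
(female TIV averages 10-15% below male). Rather than correcting for it
during training, the audit quantifies the trained model's reliance on it:

* **tertile performance** — rank-split the evaluated TIVs into three
  near-equal groups and report per-sex recall and balanced accuracy in each;
  a TIV-reliant model classifies females best at low TIV and males best at
  high TIV, with the smallest gap in the middle;
* **KDE overlap interval (R_tiv)** — the TIV range where both sexes' kernel
  density estimates stay above 20% of their own maximum, i.e. the zone where
  TIV is least informative about sex;
* **balanced correctly-classified subset** — equal numbers of correctly
  classified females and males drawn from R_tiv, the cohort the composite
  saliency map is averaged over.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import DegenerateInputError
from .evaluation import balanced_accuracy_from_recalls

log = logging.getLogger(__name__)

__all__ = [
    "tiv_tertiles", "tertile_performance", "OverlapInterval", "kde_overlap",
    "balanced_correct_subset", "TERTILE_NAMES",
]

TERTILE_NAMES = ("First", "Second", "Third")


def tiv_tertiles(tivs) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Rank-based split into three near-equal groups (sizes differ by at
    most 1, larger groups first; ties broken by stable input order).

    Returns ``(assignment, ranges)`` where ``assignment[i]`` is the tertile
    index (0 = lowest TIV) of sample ``i`` and ``ranges`` the (min, max) TIV
    per tertile.
    """
    tivs = np.asarray(tivs, dtype=float)
    if tivs.size < 3 or not np.all(np.isfinite(tivs)):
        raise DegenerateInputError("need >= 3 finite TIV values")
    order = np.argsort(tivs, kind="stable")
    assignment = np.empty(tivs.size, dtype=int)
    ranges = []
    for k, chunk in enumerate(np.array_split(order, 3)):
        assignment[chunk] = k
        ranges.append((float(tivs[chunk].min()), float(tivs[chunk].max())))
    return assignment, ranges


def tertile_performance(preds: pd.DataFrame, tivs) -> pd.DataFrame:
    """Per-tertile per-sex recall and balanced accuracy.

    ``tivs`` aligns with ``preds`` row order. A tertile missing one sex gets
    NaN for that recall and the balanced accuracy, with a note in ``flag``.
    """
    tivs = np.asarray(tivs, dtype=float)
    if len(tivs) != len(preds):
        raise ValueError("tivs must align with predictions")
    assignment, ranges = tiv_tertiles(tivs)
    rows = []
    for k in range(3):
        sel = preds.iloc[np.flatnonzero(assignment == k)]
        n_f = int((sel["true"] == "F").sum())
        n_m = int((sel["true"] == "M").sum())
        rf = float((sel.loc[sel["true"] == "F", "pred"] == "F").mean()) \
            if n_f else math.nan
        rm = float((sel.loc[sel["true"] == "M", "pred"] == "M").mean()) \
            if n_m else math.nan
        flag = "" if n_f and n_m else "missing sex in tertile"
        bal = balanced_accuracy_from_recalls(rf, rm) \
            if n_f and n_m else math.nan
        rows.append({"tertile": TERTILE_NAMES[k],
                     "tiv_lo": ranges[k][0], "tiv_hi": ranges[k][1],
                     "n": len(sel), "n_female": n_f, "n_male": n_m,
                     "recall_female": rf, "recall_male": rm,
                     "balanced_accuracy": bal, "flag": flag})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapInterval:
    """TIV range where both sexes' densities exceed the threshold fraction
    of their own maxima; ``empty`` when the thresholded supports miss."""

    lo: float
    hi: float
    density_threshold: float
    bandwidth_f: float
    bandwidth_m: float
    empty: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def contains(self, t) -> np.ndarray:
        if self.empty:
            return np.zeros(np.shape(t), dtype=bool)
        t = np.asarray(t, dtype=float)
        return (t >= self.lo) & (t <= self.hi)


def kde_overlap(tiv_female, tiv_male, threshold: float = 0.2,
                grid_points: int = 512) -> OverlapInterval:
    """Gaussian-KDE overlap interval of the two TIV distributions.

    Each sex's density is estimated with Scott's-rule bandwidth on a common
    dense grid spanning the pooled range padded by three bandwidths. The
    per-sex support is where that sex's density reaches ``threshold`` times
    its own maximum; the interval is the intersection of the supports' convex
    hulls (fragmented supports are logged). An empty intersection returns an
    explicit empty interval rather than raising.
    """
    f = np.asarray(tiv_female, dtype=float)
    m = np.asarray(tiv_male, dtype=float)
    if f.size < 5 or m.size < 5:
        raise DegenerateInputError("need >= 5 TIV samples per sex")
    kde_f, kde_m = gaussian_kde(f), gaussian_kde(m)
    h_f = float(np.sqrt(kde_f.covariance[0, 0]))
    h_m = float(np.sqrt(kde_m.covariance[0, 0]))
    pad = 3.0 * max(h_f, h_m)
    grid = np.linspace(min(f.min(), m.min()) - pad,
                       max(f.max(), m.max()) + pad, grid_points)
    supports = []
    for kde in (kde_f, kde_m):
        d = kde(grid)
        keep = d >= threshold * d.max()
        idx = np.flatnonzero(keep)
        if np.any(np.diff(idx) > 1):
            log.info("thresholded KDE support is fragmented; using its "
                     "convex hull")
        supports.append((grid[idx[0]], grid[idx[-1]]))
    lo = max(supports[0][0], supports[1][0])
    hi = min(supports[0][1], supports[1][1])
    if lo >= hi:
        log.info("no density overlap at threshold %.2f", threshold)
        return OverlapInterval(math.nan, math.nan, threshold, h_f, h_m,
                               empty=True)
    return OverlapInterval(float(lo), float(hi), threshold, h_f, h_m)


def balanced_correct_subset(preds: pd.DataFrame, tivs, interval: OverlapInterval,
                            rng: np.random.Generator) -> list[str]:
    """Correctly classified subjects inside the overlap interval, with the
    larger sex down-sampled (uniformly, seeded) to match the smaller.

    Returns subject ids (equal counts per sex, input order preserved);
    empty when either sex has no correct classifications in range.
    """
    if interval.empty:
        raise DegenerateInputError("overlap interval is empty")
    tivs = np.asarray(tivs, dtype=float)
    correct = (preds["pred"] == preds["true"]).to_numpy()
    in_range = interval.contains(tivs)
    keep = preds.loc[correct & in_range]
    ids_f = keep.loc[keep["true"] == "F", "subject_id"].to_list()
    ids_m = keep.loc[keep["true"] == "M", "subject_id"].to_list()
    if not ids_f or not ids_m:
        log.warning("a sex has no correctly classified samples in the "
                    "overlap range; empty subset")
        return []
    k = min(len(ids_f), len(ids_m))
    if len(ids_f) > k:
        ids_f = [ids_f[i] for i in sorted(rng.choice(len(ids_f), k, replace=False))]
    if len(ids_m) > k:
        ids_m = [ids_m[i] for i in sorted(rng.choice(len(ids_m), k, replace=False))]
    chosen = set(ids_f) | set(ids_m)
    return [s for s in preds["subject_id"] if s in chosen]
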