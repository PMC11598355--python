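"""Minimal preprocessing: rigid alignment, z-score normalisation, mask-based
TIV, and stratified cohort splitting.

Rigid (6-degree-of-freedom) registration rotates and translates a volume into
a common space without altering individual brain volumes, which is the
property the downstream TIV analysis relies on. The similarity metric is mean
squared intensity difference, minimised by a derivative-free Powell search
over a 3-level multi-resolution pyramid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import DegenerateInputError, RegistrationConvergenceError, ShapeError
from .volume import Volume

log = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "zscore_normalize",
    "resample",
    "rigid_register",
    "estimate_tiv",
    "stratified_split",
    "largest_remainder",
]


def _rot_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix R = Rz @ Ry @ Rx, angles in degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF transform: rotation (degrees, applied as Rz·Ry·Rx about the grid
    centre) followed by translation (mm)."""

    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def params(self) -> np.ndarray:
        return np.array(self.rotations + self.translations, dtype=float)

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        p = np.asarray(p, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]))

    def matrix(self) -> np.ndarray:
        return _rot_matrix(*self.rotations)

    def inverse(self) -> "RigidTransform":
        R = self.matrix()
        Rinv = R.T
        tinv = -Rinv @ np.asarray(self.translations)
        # recover Euler angles (ZYX convention) from the inverse rotation
        ry = np.arcsin(-Rinv[2, 0])
        if abs(np.cos(ry)) > 1e-8:
            rx = np.arctan2(Rinv[2, 1], Rinv[2, 2])
            rz = np.arctan2(Rinv[1, 0], Rinv[0, 0])
        else:                              # gimbal lock
            rx = np.arctan2(-Rinv[1, 2], Rinv[1, 1])
            rz = 0.0
        return RigidTransform(tuple(np.rad2deg([rx, ry, rz])), tuple(tinv))


def resample(vol: Volume, t: RigidTransform, order: int = 1) -> Volume:
    """Apply a rigid transform by trilinear interpolation, background fill 0.

    The identity transform on the same grid returns the input exactly.
    ``order=0`` gives nearest-neighbour resampling.
    """
    if not np.any(t.params):
        return vol.copy()
    S = np.diag(vol.voxel_mm)
    Sinv = np.diag([1.0 / v for v in vol.voxel_mm])
    Rinv = t.matrix().T
    A = Sinv @ Rinv @ S
    c = (np.array(vol.shape) - 1) / 2.0
    offset = c - A @ c - Sinv @ Rinv @ np.asarray(t.translations)
    out = ndimage.affine_transform(vol.data, A, offset=offset, order=order,
                                   mode="constant", cval=0.0, output=np.float32)
    return Volume(out, vol.voxel_mm, vol.origin)


def _shrink(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    data = ndimage.zoom(vol.data, 1.0 / factor, order=1)
    return Volume(data, tuple(v * factor for v in vol.voxel_mm), vol.origin)


def rigid_register(moving: Volume, fixed: Volume, *,
                   shrink_factors: tuple[int, ...] = (4, 2, 1),
                   maxiter: int = 60) -> RigidTransform:
    """Estimate the 6-DOF transform aligning ``moving`` onto ``fixed``.

    Powell minimisation of the mean squared intensity difference, coarse to
    fine; each level is warm-started from the previous one. Raises
    :class:`RegistrationConvergenceError` (carrying the best-so-far
    transform) if the final level hits the iteration cap without converging.
    """
    if moving.shape != fixed.shape:
        raise ShapeError(f"moving {moving.shape} vs fixed {fixed.shape}")
    params = np.zeros(6)
    res = None
    for f in shrink_factors:
        mov_l, fix_l = _shrink(moving, f), _shrink(fixed, f)
        fix_data = fix_l.data

        def cost(p):
            warped = resample(mov_l, RigidTransform.from_params(p))
            return float(np.mean((warped.data - fix_data) ** 2))

        res = optimize.minimize(cost, params, method="Powell",
                                options={"maxiter": maxiter,
                                         "xtol": 1e-3, "ftol": 1e-6})
        params = res.x
    t = RigidTransform.from_params(params)
    if res is not None and not res.success:
        raise RegistrationConvergenceError(
            f"Powell search did not converge at full resolution: {res.message}", t)
    return t


def zscore_normalize(vol: Volume, mask: np.ndarray) -> Volume:
    """Zero-mean unit-SD intensities within the brain mask, 0 outside.

    Uses the population SD. Idempotent: z-scoring a z-scored volume changes
    nothing (within float tolerance).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ShapeError(f"mask {mask.shape} vs volume {vol.shape}")
    if not mask.any():
        raise DegenerateInputError("empty mask")
    vals = vol.data[mask]
    sd = float(vals.std())
    if sd == 0.0:
        raise DegenerateInputError("zero intensity variance within the mask")
    out = np.zeros_like(vol.data)
    out[mask] = (vals - vals.mean()) / sd
    return Volume(out, vol.voxel_mm, vol.origin)


def estimate_tiv(mask: np.ndarray, voxel_mm) -> float:
    """Mask-based total intracranial volume: voxel count x voxel volume
    (mm^3) / 1,000, in ml."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise DegenerateInputError("empty mask")
    if np.isscalar(voxel_mm):
        voxel_mm = (voxel_mm,) * 3
    return n * float(np.prod(voxel_mm)) / 1000.0


def largest_remainder(n: int, fractions) -> np.ndarray:
    """Integer allocation of ``n`` by the largest-remainder method."""
    ideal = np.asarray(fractions, dtype=float) * n
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    # deterministic tie-break: larger remainder first, then lower index
    order = sorted(range(len(rem)), key=lambda i: (-rem[i], i))
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    return counts


def stratified_split(cohort: pd.DataFrame,
                     fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0,
                     keys: tuple[str, ...] = ("sex", "site", "field"),
                     ) -> pd.DataFrame:
    """Stratified train/val/test assignment over sex x site x field strata.

    Counts are allocated per stratum by largest remainder, then reconciled so
    the global totals equal the largest-remainder rounding of the whole
    cohort (e.g. 2,110 at 80/10/10 gives exactly 1,688/211/211). Deterministic
    for a fixed seed. Returns a frame with ``subject_id``, ``split``,
    ``stratum``.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if cohort.empty:
        return pd.DataFrame(columns=["subject_id", "split", "stratum"])
    splits = ("train", "val", "test")
    strat = cohort[list(keys)].astype(str).agg("|".join, axis=1)
    names = sorted(strat.unique())
    n = len(cohort)
    global_targets = largest_remainder(n, fractions)

    sizes = {s: int((strat == s).sum()) for s in names}
    small = [s for s in names if sizes[s] < len(splits)]
    if small:
        warnings.warn(f"strata smaller than the number of splits "
                      f"(best-effort assignment): {small}", stacklevel=2)
    counts = {s: largest_remainder(sizes[s], fractions) for s in names}
    ideal = {s: np.asarray(fractions) * sizes[s] for s in names}

    # Per-stratum rounding can drift from the global targets by a few
    # subjects; move single subjects between splits, choosing the stratum
    # whose move best restores its own proportions.
    totals = np.sum([counts[s] for s in names], axis=0)
    while not np.array_equal(totals, global_targets):
        src = int(np.argmax(totals - global_targets))
        dst = int(np.argmin(totals - global_targets))
        best = max(
            (s for s in names if counts[s][src] > 0),
            key=lambda s: (counts[s][src] - ideal[s][src])
            + (ideal[s][dst] - counts[s][dst]),
        )
        counts[best][src] -= 1
        counts[best][dst] += 1
        totals = np.sum([counts[s] for s in names], axis=0)

    rng = np.random.default_rng(seed)
    rows = []
    for s in names:
        ids = cohort.loc[strat == s, "subject_id"].to_numpy()
        rng.shuffle(ids)
        edges = np.concatenate([[0], np.cumsum(counts[s])])
        for k, name in enumerate(splits):
            for sid in ids[edges[k]:edges[k + 1]]:
                rows.append((sid, name, s))
    out = pd.DataFrame(rows, columns=["subject_id", "split", "stratum"])
    return out.set_index("subject_id").loc[cohort["subject_id"]].reset_index()
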