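"""Synthetic brain-phantom cohorts with a controllable sex signal.

The generator emulates the statistical structure a sex-classification study
of brain MRI rests on, on a desk-scale voxel grid:

* a near-balanced cohort with site (scanner vendor) and field-strength
  covariates drawn from configurable marginals,
* a total-intracranial-volume (TIV) confound: per-sex Normal TIV with the
  female mean a configurable fraction (default 12.5%) below the male mean,
* planted regional structural effects: an additive intensity shift inside
  chosen atlas regions, applied to one sex only, so region-level recovery has
  an exact ground truth,
* a toy parcellation of disjoint spherical regions standing in for an
  anatomical atlas.

Phantoms are brain-extracted by construction: a smooth ellipsoidal "brain"
with concentric tissue-like intensity bands plus Gaussian noise, background
exactly zero. The ellipsoid is scaled so the voxelised mask volume matches
the subject's sampled TIV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PlacementError, SizingError
from .volume import Atlas, Volume

log = logging.getLogger(__name__)

__all__ = [
    "PhantomConfig",
    "STUDY_DEMOGRAPHICS",
    "make_atlas",
    "make_phantom",
    "generate_cohort",
    "simulate_metadata",
]

# Pooled demographics of the four-dataset study cohort this generator
# emulates: 1,115 F / 995 M of 2,110; vendor mix GE/Philips/Siemens
# 11/8/81%; field strength 3T/1.5T 79/21%.
STUDY_DEMOGRAPHICS = {
    "n_subjects": 2110,
    "female_fraction": 1115 / 2110,
    "site_marginals": {"GE": 0.11, "Philips": 0.08, "Siemens": 0.81},
    "field_marginals": {3.0: 0.79, 1.5: 0.21},
}

# Ellipsoid semi-axis ratios (x, y, z): brains are longest front-to-back.
_AX_RATIOS = np.array([1.0, 1.25, 1.05])

# Tissue-like intensity bands by normalised ellipsoid radius:
# core "white matter", mid "gray matter", outer "CSF" rim.
_BANDS = ((0.60, 1.0), (0.85, 0.75), (1.0, 0.45))


@dataclass
class PhantomConfig:
    """Study conditions for one simulated cohort.

    Defaults are desk scale: a 48^3 grid at 3 mm voxels with TIVs rescaled
    proportionally (male mean 500 ml, SD 35 ml) so the female/male overlap in
    SD units matches what full-scale cohorts show. ``tiv_deficit_female``
    is the average fractional TIV deficit of females (literature range
    10-15%, default 12.5%).
    """

    n_subjects: int = 200
    female_fraction: float = STUDY_DEMOGRAPHICS["female_fraction"]
    tiv_mean_male: float = 500.0          # ml
    tiv_deficit_female: float = 0.125     # proportion
    tiv_sd: float = 35.0                  # ml, both sexes
    effect_regions: tuple[int, ...] = ()  # atlas labels carrying the shift
    effect_size: float = 0.15             # additive intensity (arbitrary units)
    effect_sex: str = "F"                 # sex receiving the shift
    noise_sd: float = 0.05                # intensity
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 3.0
    age_range: tuple[int, int] = (18, 90)
    site_marginals: dict = field(
        default_factory=lambda: dict(STUDY_DEMOGRAPHICS["site_marginals"]))
    field_marginals: dict = field(
        default_factory=lambda: dict(STUDY_DEMOGRAPHICS["field_marginals"]))
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.n_subjects < 0:
            errs.append(f"n_subjects must be >= 0, got {self.n_subjects}")
        if not 0.0 <= self.female_fraction <= 1.0:
            errs.append(f"female_fraction must be in [0, 1], got {self.female_fraction}")
        if not 0.0 <= self.tiv_deficit_female < 1.0:
            errs.append(f"tiv_deficit_female must be in [0, 1), got {self.tiv_deficit_female}")
        if min(self.grid_shape) < 16:
            errs.append(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if self.tiv_mean_male <= 0 or self.tiv_sd < 0 or self.noise_sd < 0:
            errs.append("tiv_mean_male must be > 0; tiv_sd and noise_sd must be >= 0")
        if self.effect_sex not in ("F", "M"):
            errs.append(f"effect_sex must be 'F' or 'M', got {self.effect_sex!r}")
        if errs:
            raise ValueError("; ".join(errs))

    @property
    def tiv_mean_female(self) -> float:
        return self.tiv_mean_male * (1.0 - self.tiv_deficit_female)

    def min_tiv(self) -> float:
        """Smallest TIV the truncated-Normal sampler can produce (ml)."""
        return self.tiv_mean_female - 3.0 * self.tiv_sd

    def max_tiv(self) -> float:
        return self.tiv_mean_male + 3.0 * self.tiv_sd


def _semiaxes_mm(tiv_ml: float) -> np.ndarray:
    """Semi-axes (mm) of an ellipsoid with the given volume and fixed ratios."""
    vol_mm3 = tiv_ml * 1000.0
    s = (vol_mm3 * 3.0 / (4.0 * np.pi * np.prod(_AX_RATIOS))) ** (1.0 / 3.0)
    return s * _AX_RATIOS


def _ellipsoid_rho(grid_shape, voxel_mm: float, semiaxes: np.ndarray) -> np.ndarray:
    """Normalised ellipsoid radius of every voxel centre (<=1 inside)."""
    coords = [(np.arange(n) - (n - 1) / 2.0) * voxel_mm for n in grid_shape]
    xs, ys, zs = np.meshgrid(*coords, indexing="ij")
    return np.sqrt((xs / semiaxes[0]) ** 2 + (ys / semiaxes[1]) ** 2
                   + (zs / semiaxes[2]) ** 2)


def make_atlas(grid_shape, n_regions: int, seed: int, *, voxel_mm: float = 3.0,
               envelope_tiv_ml: float = 300.0, region_radius_mm: float | None = None,
               max_tries: int = 5000) -> Atlas:
    """Toy parcellation: ``n_regions`` disjoint spherical blobs inside the
    brain envelope of the smallest plausible phantom.

    ``envelope_tiv_ml`` should be at or below the cohort's minimum TIV so that
    every region lies inside every subject's brain mask. Deterministic for a
    fixed seed; raises :class:`PlacementError` when the blobs cannot be placed
    without overlap.
    """
    if n_regions < 2:
        raise ValueError(f"n_regions must be >= 2, got {n_regions}")
    rng = np.random.default_rng(seed)
    semi = _semiaxes_mm(envelope_tiv_ml)
    if region_radius_mm is None:
        region_radius_mm = 0.18 * float(semi.min())
    r = float(region_radius_mm)

    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_regions:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_regions} disjoint regions of radius "
                f"{r:.1f} mm inside a {envelope_tiv_ml:.0f} ml envelope "
                f"after {max_tries} tries")
        tries += 1
        u = rng.uniform(-1.0, 1.0, size=3)
        # candidate centre in mm, relative to grid centre
        c = u * semi
        # sphere of radius r must stay inside the envelope: shrink the
        # allowed normalised radius by r over the smallest semi-axis
        if np.sqrt(np.sum((c / semi) ** 2)) + r / float(semi.min()) > 0.92:
            continue
        if any(np.linalg.norm(c - p) < 2.0 * r + voxel_mm for p in centers):
            continue
        centers.append(c)

    coords = [(np.arange(n) - (n - 1) / 2.0) * voxel_mm for n in grid_shape]
    xs, ys, zs = np.meshgrid(*coords, indexing="ij")
    labels = np.zeros(tuple(grid_shape), dtype=np.int16)
    for i, c in enumerate(centers, start=1):
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        labels[d2 <= r * r] = i
    names = {i: f"region_{i:02d}" for i in range(1, n_regions + 1)}
    atlas = Atlas(labels=labels, names=names, voxel_mm=(voxel_mm,) * 3)
    empty = [i for i in range(1, n_regions + 1) if not np.any(labels == i)]
    if empty:
        raise PlacementError(f"regions {empty} contain no voxels at "
                             f"{voxel_mm} mm resolution; increase region_radius_mm")
    return atlas


def make_phantom(sex: str, tiv_target: float, atlas: Atlas | None,
                 config: PhantomConfig, rng: np.random.Generator,
                 ) -> tuple[Volume, np.ndarray]:
    """One brain-extracted phantom scaled so its mask volume matches
    ``tiv_target`` (ml) within voxelisation error.

    Returns ``(volume, mask)``. The sex given in ``config.effect_sex``
    receives an additive ``effect_size`` shift inside ``effect_regions``.
    """
    if tiv_target <= 0:
        raise ValueError(f"tiv_target must be > 0, got {tiv_target}")
    grid = tuple(config.grid_shape)
    voxvol = config.voxel_mm ** 3
    half_extent = (np.array(grid) - 1) / 2.0 * config.voxel_mm

    semi0 = _semiaxes_mm(tiv_target)
    if np.any(semi0 >= half_extent - config.voxel_mm):
        raise SizingError(
            f"a {tiv_target:.0f} ml brain (semi-axes {np.round(semi0, 1)} mm) "
            f"does not fit a {grid} grid at {config.voxel_mm} mm voxels")

    # Voxelisation shifts the counted volume off the continuous one; bisect a
    # global scale so the counted mask volume matches the target. Scaling the
    # semi-axes by s divides the normalised radius by s, so one radius grid
    # serves every candidate scale.
    target_vox = tiv_target * 1000.0 / voxvol
    rho0 = _ellipsoid_rho(grid, config.voxel_mm, semi0)
    lo, hi = 0.9, min(1.1, float(np.min((half_extent - 0.5) / semi0)))
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if int(np.sum(rho0 <= mid)) < target_vox:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    rho = rho0 / scale
    mask = rho <= 1.0

    data = np.zeros(grid, dtype=np.float32)
    for upper, intensity in _BANDS:
        band = mask & (data == 0) & (rho <= upper) if upper < 1.0 else mask & (data == 0)
        data[band] = intensity
    data = ndimage.gaussian_filter(data, sigma=0.6).astype(np.float32)
    data[~mask] = 0.0

    if atlas is not None and config.effect_regions and sex == config.effect_sex:
        for region in config.effect_regions:
            data[atlas.region_mask(region) & mask] += config.effect_size

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=grid).astype(np.float32)
        data[mask] += noise[mask]

    vol = Volume(data=data, voxel_mm=(config.voxel_mm,) * 3)
    return vol, mask


def _categorical_counts(n: int, marginals: dict, rng: np.random.Generator) -> list:
    """Assign categories hitting the marginals exactly (largest remainder)."""
    keys = list(marginals)
    ideal = np.array([marginals[k] for k in keys], dtype=float) * n
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    out = [k for k, c in zip(keys, counts) for _ in range(c)]
    rng.shuffle(out)
    return out


def simulate_metadata(config: PhantomConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Cohort table only (no volumes): id, sex, age, site, field, sampled TIV.

    Sex and site/field are assigned by exact marginal counts then shuffled, so
    the configured fractions hold to rounding. TIV is Normal per sex,
    truncated at +/-3 SD, with the female mean ``(1 - deficit)`` times the
    male mean.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if n == 0:
        return pd.DataFrame(columns=["subject_id", "sex", "age", "site",
                                     "field", "tiv_ml", "path"])
    n_f = int(round(n * config.female_fraction))
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sexes)
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sites = _categorical_counts(n, config.site_marginals, rng)
    fields = _categorical_counts(n, config.field_marginals, rng)

    means = {"F": config.tiv_mean_female, "M": config.tiv_mean_male}
    tivs = np.empty(n)
    for i, s in enumerate(sexes):
        while True:
            t = rng.normal(means[s], config.tiv_sd)
            if abs(t - means[s]) <= 3.0 * config.tiv_sd:
                break
        tivs[i] = t

    return pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "sex": sexes,
        "age": ages,
        "site": sites,
        "field": fields,
        "tiv_ml": tivs,
        "path": [""] * n,
    })


def generate_cohort(config: PhantomConfig, atlas: Atlas | None,
                    out_dir: str | Path | None = None,
                    ) -> tuple[pd.DataFrame, dict[str, tuple[Volume, np.ndarray]]]:
    """Full cohort: metadata table plus per-subject phantom volumes.

    Returns ``(table, {subject_id: (volume, mask)})``. When ``out_dir`` is
    given, each phantom and its brain mask are also written as NIfTI and the
    table's ``path`` column points at the volume files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    table = simulate_metadata(config, rng)
    volumes: dict[str, tuple[Volume, np.ndarray]] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    paths = []
    for row in table.itertuples():
        vol, mask = make_phantom(row.sex, row.tiv_ml, atlas, config, rng)
        volumes[row.subject_id] = (vol, mask)
        if out_dir is not None:
            vpath = out_dir / "volumes" / f"{row.subject_id}.nii.gz"
            vol.to_nifti(vpath)
            Volume(mask.astype(np.float32), vol.voxel_mm).to_nifti(
                out_dir / "masks" / f"{row.subject_id}.nii.gz")
            # run-dir-relative so the cohort table is location-independent
            paths.append(str(vpath.relative_to(out_dir)))
        else:
            paths.append("")
    table = table.assign(path=paths)
    if out_dir is not None:
        table.to_csv(out_dir / "cohort.csv", index=False)
    log.info("generated cohort: n=%d (%d F / %d M)", len(table),
             int((table.sex == "F").sum()), int((table.sex == "M").sum()))
    return table, volumes
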