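"""Synthetic grey-matter cohorts with a known regional atrophy cascade.

Generates modulated-GM-style density maps for a two-group cohort (patients
spanning a disease-severity range, controls at severity 0) in which a set of
disjoint cuboid/spherical "regions" lose grey matter along a sigmoidal
trajectory of disease severity (CDR-plus-NACC-FTLD sum-of-boxes units), each
region with its own onset.  The true spatio-temporal cascade is therefore
known exactly, so every downstream stage — group GLM, pseudo-time Granger
mapping, event-based model — can be validated against ground truth.

The expected density of a voxel in region ``r`` for a subject at severity
``s`` is::

    B_r - A_r * logistic((s - s0_r) / w_r)
        + beta_age * (age - age_ref) + beta_sex * [sex == M] + site_offset

with ``logistic(u) = 1 / (1 + exp(-u))``.  Out-of-region voxels sit at a
constant background density.  Independent Gaussian voxel noise and optional
isotropic Gaussian smoothing are applied last.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ConfigurationError",
    "RegionSpec",
    "CohortConfig",
    "GroundTruthCascade",
    "default_regions",
    "logistic",
    "expected_region_density",
    "region_masks",
    "generate_cohort",
    "write_cohort",
    "staged_biomarker_cohort",
    "match_masks_to_truth",
    "sequence_tau",
]

#: FWHM of a Gaussian = _FWHM_PER_SIGMA * sigma
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class ConfigurationError(ValueError):
    """Invalid cohort configuration (overlapping regions, bad ranges, ...)."""


def logistic(u):
    """Standard logistic function 1 / (1 + exp(-u))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(u, dtype=float)))


@dataclass(frozen=True)
class RegionSpec:
    """One synthetic region and its atrophy trajectory.

    Exactly one of ``box`` (half-open index ranges ``((i0,i1),(j0,j1),(k0,k1))``)
    or ``sphere`` (``((ci,cj,ck), radius)`` in voxel units) must be given.

    Parameters
    ----------
    baseline : grey-matter density at severity -inf (unitless, ~0-1).
    amplitude : maximal density loss (>= 0).
    onset : severity at half-maximal loss, sum-of-boxes units.
    width : severity units controlling the steepness of the transition (> 0).
    """

    name: str
    baseline: float = 0.8
    amplitude: float = 0.35
    onset: float = 10.0
    width: float = 2.0
    box: tuple | None = None
    sphere: tuple | None = None

    def __post_init__(self):
        if (self.box is None) == (self.sphere is None):
            raise ConfigurationError(
                f"region {self.name!r}: exactly one of box/sphere required"
            )
        if self.amplitude < 0:
            raise ConfigurationError(f"region {self.name!r}: amplitude < 0")
        if self.width <= 0:
            raise ConfigurationError(f"region {self.name!r}: width <= 0")
        if not 0.0 <= self.baseline <= 1.0:
            raise ConfigurationError(f"region {self.name!r}: baseline outside [0, 1]")

    def voxel_mask(self, grid_shape) -> np.ndarray:
        """Boolean lattice mask of this region on a grid of ``grid_shape``."""
        mask = np.zeros(grid_shape, dtype=bool)
        if self.box is not None:
            (i0, i1), (j0, j1), (k0, k1) = self.box
            mask[i0:i1, j0:j1, k0:k1] = True
        else:
            center, radius = self.sphere
            grids = np.ogrid[[slice(0, n) for n in grid_shape]]
            d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
            mask[d2 <= radius**2] = True
        return mask


def default_regions() -> list[RegionSpec]:
    """Eight disjoint 5x5x5 blocks on the default 24^3 grid.

    Named and ordered after the canonical frontoinsular-origin cascade
    (anterior insula first, lingual gyrus last), with onsets spread evenly
    over the patient severity range so every transition is observable.
    """
    names_onsets = [
        ("insula_ant", 5.0),
        ("orbitofrontal", 6.5),
        ("putamen_nacc", 8.0),
        ("acc_pregenual", 9.5),
        ("dlpfc", 11.0),
        ("temporal_inf", 12.5),
        ("supramarginal", 14.0),
        ("lingual", 15.5),
    ]
    corners = list(itertools.product((4, 15), repeat=3))
    regions = []
    for (name, onset), corner in zip(names_onsets, corners):
        box = tuple((c, c + 5) for c in corner)
        regions.append(RegionSpec(name=name, onset=onset, width=5.0, box=box))
    return regions


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one cohort deterministically."""

    n_patients: int = 150
    n_controls: int = 80
    grid_shape: tuple = (24, 24, 24)
    voxel_size: float = 1.5  # mm, isotropic
    regions: tuple = field(default_factory=lambda: tuple(default_regions()))
    beta_age: float = -0.003  # density per year away from age_ref
    beta_sex: float = 0.01  # density offset for males
    site_offsets: tuple = (("philips", 0.0), ("ge", 0.01))
    tiv_scale: bool = False  # multiply maps by tiv / tiv_ref
    noise_sd: float = 0.03  # density units, iid per voxel
    severity_range: tuple = (2.0, 22.0)  # sum-of-boxes, patients
    smoothing_fwhm: float | None = None  # mm; None = no smoothing
    background: float = 0.5  # density of out-of-region voxels
    age_ref: float = 64.0
    age_sd: float = 7.5
    education_mean: float = 13.0
    education_sd: float = 2.5
    tiv_ref: float = 1450.0
    tiv_sd: float = 120.0
    rng_seed: int = 0

    def validate(self):
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = self.severity_range
        if not (0.0 <= lo <= hi <= 24.0):
            raise ConfigurationError(
                "severity_range must lie within [0, 24] (sum-of-boxes scale)"
            )
        # pairwise-disjoint region blocks
        total = np.zeros(self.grid_shape, dtype=int)
        for r in self.regions:
            total += r.voxel_mask(self.grid_shape)
        if (total > 1).any():
            raise ConfigurationError("region voxel blocks overlap")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        return aff

    def site_names(self):
        return [name for name, _ in self.site_offsets]


@dataclass(frozen=True)
class GroundTruthCascade:
    """The true atrophy-event order: region names by ascending onset."""

    order: tuple
    onsets: tuple  # (name, onset) pairs, same order as ``order``

    @classmethod
    def from_regions(cls, regions) -> "GroundTruthCascade":
        onsets = sorted((r.onset, r.name) for r in regions)
        vals = [o for o, _ in onsets]
        if len(set(vals)) != len(vals):
            raise ConfigurationError("tied region onsets: cascade order undefined")
        return cls(
            order=tuple(n for _, n in onsets),
            onsets=tuple((n, o) for o, n in onsets),
        )


def expected_region_density(region: RegionSpec, s, cov=None, cfg: CohortConfig | None = None):
    """Noise-free in-region density at severity ``s`` for covariates ``cov``.

    ``cov`` is a mapping with optional keys ``age``, ``sex`` ("M"/"F") and
    ``site``; absent keys contribute nothing.  Strictly decreasing in ``s``
    whenever ``amplitude > 0``.
    """
    cov = cov or {}
    cfg = cfg or CohortConfig()
    d = region.baseline - region.amplitude * logistic((s - region.onset) / region.width)
    if "age" in cov:
        d = d + cfg.beta_age * (cov["age"] - cfg.age_ref)
    if "sex" in cov:
        d = d + (cfg.beta_sex if cov["sex"] == "M" else 0.0)
    if "site" in cov:
        d = d + dict(cfg.site_offsets).get(cov["site"], 0.0)
    return d


def region_masks(cfg: CohortConfig) -> dict:
    """name -> boolean lattice mask for every configured region."""
    return {r.name: r.voxel_mask(cfg.grid_shape) for r in cfg.regions}


def generate_cohort(cfg: CohortConfig):
    """Generate one cohort.

    Returns
    -------
    records : pandas.DataFrame
        One row per subject: id, diagnosis, sex, age, education, tiv, site,
        sumbox.  Patients first, then controls.
    maps : ndarray, shape (n_subjects, *grid_shape)
        Grey-matter density maps aligned with ``records`` rows.
    truth : GroundTruthCascade

    Patients receive severities drawn uniformly from ``severity_range``;
    controls have severity 0.  Identical ``rng_seed`` gives bit-identical
    output.
    """
    cfg.validate()
    truth = GroundTruthCascade.from_regions(cfg.regions)
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_patients + cfg.n_controls

    sev = np.concatenate(
        [
            rng.uniform(*cfg.severity_range, size=cfg.n_patients),
            np.zeros(cfg.n_controls),
        ]
    )
    sexes = rng.choice(["M", "F"], size=n)
    ages = np.clip(rng.normal(cfg.age_ref, cfg.age_sd, size=n), 40.0, 90.0)
    edus = np.clip(rng.normal(cfg.education_mean, cfg.education_sd, size=n), 6.0, 22.0)
    tivs = rng.normal(cfg.tiv_ref, cfg.tiv_sd, size=n)
    sites = rng.choice(cfg.site_names(), size=n)

    ids = [f"sub-p{i+1:03d}" for i in range(cfg.n_patients)] + [
        f"sub-c{i+1:03d}" for i in range(cfg.n_controls)
    ]
    diag = ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls
    records = pd.DataFrame(
        {
            "id": ids,
            "diagnosis": diag,
            "sex": sexes,
            "age": np.round(ages, 2),
            "education": np.round(edus, 2),
            "tiv": np.round(tivs, 1),
            "site": sites,
            "sumbox": np.round(sev, 3),
        }
    )

    masks = region_masks(cfg)
    maps = np.empty((n,) + tuple(cfg.grid_shape), dtype=np.float64)
    smooth_sigma = None
    if cfg.smoothing_fwhm:
        smooth_sigma = cfg.smoothing_fwhm / (_FWHM_PER_SIGMA * cfg.voxel_size)
    for i in range(n):
        cov = {"age": records.at[i, "age"], "sex": records.at[i, "sex"],
               "site": records.at[i, "site"]}
        vol = np.full(cfg.grid_shape, cfg.background, dtype=np.float64)
        for r in cfg.regions:
            vol[masks[r.name]] = expected_region_density(
                r, records.at[i, "sumbox"], cov, cfg
            )
        if cfg.noise_sd > 0:
            vol += rng.normal(0.0, cfg.noise_sd, size=cfg.grid_shape)
        if cfg.tiv_scale:
            vol *= records.at[i, "tiv"] / cfg.tiv_ref
        if smooth_sigma:
            vol = gaussian_filter(vol, smooth_sigma)
        maps[i] = vol
    return records, maps, truth


def write_cohort(records, maps, out_dir, cfg: CohortConfig | None = None,
                 truth: GroundTruthCascade | None = None, affine=None):
    """Write one NIfTI-1 map per subject plus covariate TSV and ground truth.

    Layout: ``maps/<id>.nii``, ``participants.tsv``, ``ground_truth.json``
    and, when ``cfg`` is given, ``masks/<region>.nii`` atlas masks.
    Returns a manifest dict of the written paths.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    if len(records) != len(maps):
        raise ValueError("records and maps are not aligned")
    if affine is None:
        affine = cfg.affine if cfg is not None else np.diag([1.5, 1.5, 1.5, 1.0])
    (out_dir / "maps").mkdir(parents=True, exist_ok=True)
    manifest = {"maps": []}
    for i, sid in enumerate(records["id"]):
        path = out_dir / "maps" / f"{sid}.nii"
        nib.Nifti1Image(np.asarray(maps[i], dtype=np.float32), affine).to_filename(path)
        manifest["maps"].append(str(path))
    tsv = out_dir / "participants.tsv"
    records.to_csv(tsv, sep="\t", index=False)
    manifest["participants"] = str(tsv)
    if truth is not None:
        gt = out_dir / "ground_truth.json"
        gt.write_text(json.dumps(
            {"order": list(truth.order), "onsets": dict(truth.onsets)},
            indent=2, sort_keys=True))
        manifest["ground_truth"] = str(gt)
    if cfg is not None:
        (out_dir / "masks").mkdir(exist_ok=True)
        manifest["masks"] = {}
        for name, mask in region_masks(cfg).items():
            path = out_dir / "masks" / f"{name}.nii"
            nib.Nifti1Image(mask.astype(np.uint8), affine).to_filename(path)
            manifest["masks"][name] = str(path)
    return manifest


def staged_biomarker_cohort(rng, n_subjects: int = 200, n_events: int = 3,
                            mu_normal: float = 0.8, mu_abnormal: float = 0.5,
                            sd: float = 0.05):
    """Well-separated staged biomarkers with ground-truth order 0, 1, 2, ...

    Half the subjects are controls at stage 0; patients draw a uniform stage
    in 1..n_events, and event ``e`` is abnormal for subjects past stage
    ``e``.  Returns ``(X, patient_indicator)``; the maximum-likelihood event
    order of the generating process is the index order, which makes this the
    reference problem for validating sequence search against exhaustive
    enumeration.
    """
    n_pat = n_subjects // 2
    labels = np.array([False] * (n_subjects - n_pat) + [True] * n_pat)
    stages = np.concatenate([
        np.zeros(n_subjects - n_pat, dtype=int),
        rng.integers(1, n_events + 1, n_pat),
    ])
    X = np.empty((n_subjects, n_events))
    for e in range(n_events):
        X[:, e] = np.where(stages > e, mu_abnormal, mu_normal)
        X[:, e] += rng.normal(0.0, sd, n_subjects)
    return X, labels


# ---------------------------------------------------------------------------
# Ground-truth evaluation helpers (used to score recovery on synthetic runs)

def match_masks_to_truth(masks: dict, truth_masks: dict) -> dict:
    """Map each recovered mask to the ground-truth region it overlaps most.

    Returns ``{recovered_name: truth_name}``; masks with no overlap with any
    true region are omitted.  When several recovered masks hit the same true
    region, all are kept (callers decide how to handle splits).
    """
    out = {}
    for name, mask in masks.items():
        best, best_ov = None, 0
        for tname, tmask in truth_masks.items():
            ov = int(np.logical_and(mask, tmask).sum())
            if ov > best_ov:
                best, best_ov = tname, ov
        if best is not None:
            out[name] = best
    return out


def sequence_tau(recovered_order, truth_order):
    """Kendall's tau between a recovered event order and the true cascade.

    ``recovered_order`` is a sequence of ground-truth region names (possibly
    a subset); ranks are compared against their positions in ``truth_order``.
    """
    from scipy.stats import kendalltau

    common = [n for n in recovered_order if n in truth_order]
    if len(common) < 2:
        return np.nan
    truth_rank = {n: i for i, n in enumerate(truth_order)}
    tau, _ = kendalltau(range(len(common)), [truth_rank[n] for n in common])
    return float(tau)
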