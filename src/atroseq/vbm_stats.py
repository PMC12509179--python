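"""Voxel-wise group-comparison GLM and supporting machinery.

Mass-univariate ordinary least squares of grey-matter density on a group
indicator plus nuisance covariates (sex, age, education, TIV, site), with
Benjamini-Hochberg FDR and Bonferroni FWE correction, connected-component
cluster-extent thresholding, peak detection, and extraction of a seed
("epicentre") region as the intersection of the peak surviving cluster with
an atlas mask.

The contrast of interest is patient < control; the reported statistic is
positive where patients have *less* grey matter ("atrophy" direction).  The
analysis mask contains voxels whose across-subject mean density is at least
``mask_threshold`` (default 0.1, the usual absolute masking threshold for
modulated GM maps).  FWE control uses Bonferroni rather than random-field
theory: deterministic, desk-scale and conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CollinearDesignError",
    "SeedUndefinedError",
    "StatMap",
    "ClusterRecord",
    "SeedRegion",
    "covariate_design",
    "fit_group_glm",
    "fdr_correct",
    "fwe_correct",
    "extract_clusters",
    "define_seed",
    "GroupAtrophyGLM",
]

DEFAULT_COVARIATES = ("sex", "age", "education", "tiv", "site")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


class CollinearDesignError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


class SeedUndefinedError(ValueError):
    """No seed region can be defined (no surviving cluster / empty overlap)."""


@dataclass
class StatMap:
    """Voxel-wise statistic + p-value lattice with its analysis mask."""

    stat: np.ndarray  # 3D, 0 outside mask
    p: np.ndarray  # 3D, 1 outside mask
    mask: np.ndarray  # 3D bool
    df: int
    affine: np.ndarray | None = None

    def __post_init__(self):
        if not (self.stat.shape == self.p.shape == self.mask.shape):
            raise ValueError("stat, p and mask lattices must share a shape")


@dataclass
class ClusterRecord:
    """One supra-threshold connected component."""

    label: int
    size: int
    indices: np.ndarray  # (size, 3) int lattice coordinates
    peak_index: tuple
    peak_stat: float
    peak_mm: tuple | None = None

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.indices.T)] = True
        return m


@dataclass
class SeedRegion:
    """Named voxel mask with provenance of how it was derived."""

    name: str
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def covariate_design(records: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Numeric nuisance-covariate matrix (no intercept) and column names.

    ``sex`` becomes a male indicator, ``site`` becomes drop-first dummy
    columns (omitted entirely for single-site cohorts); other covariates are
    taken as numeric columns.
    """
    cols, names = [], []
    for c in covariates:
        if c == "sex":
            cols.append((records["sex"].to_numpy() == "M").astype(float))
            names.append("sex_M")
        elif c == "site":
            levels = sorted(pd.unique(records["site"]))
            for lv in levels[1:]:
                cols.append((records["site"].to_numpy() == lv).astype(float))
                names.append(f"site_{lv}")
        else:
            cols.append(records[c].to_numpy(dtype=float))
            names.append(c)
    if not cols:
        return np.empty((len(records), 0)), []
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names):
    """Flag columns adding no rank given the columns listed before them."""

    p = X.shape[1]
    if p == 0:
        return
    if np.linalg.matrix_rank(X) == p:
        return
    bad = []
    rank = 0
    for j in range(p):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            bad.append(names[j])
        rank = new_rank
    raise CollinearDesignError(
        f"design matrix is rank deficient; collinear columns: {bad}"
    )


def fit_group_glm(maps, records: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                  mask_threshold: float = 0.1, group_col: str = "diagnosis",
                  affine=None) -> StatMap:
    """Patient-vs-control OLS per in-mask voxel; positive stat = atrophy.

    ``maps`` is an (n_subjects, nx, ny, nz) array aligned with ``records``.
    Per voxel, density is regressed on [intercept, patient indicator,
    covariates]; the returned statistic is the negated t of the patient
    coefficient (so atrophy is positive) with two-sided p-values and
    residual df = n - rank(X).
    """
    maps = np.asarray(maps, dtype=np.float64)
    n = maps.shape[0]
    if n != len(records):
        raise ValueError("maps and records are not aligned")
    groups = records[group_col].to_numpy()
    if (groups == "patient").sum() < 2 or (groups == "control").sum() < 2:
        raise ValueError("need at least 2 subjects per group")

    Z, znames = covariate_design(records, covariates)
    X = np.column_stack([np.ones(n), (groups == "patient").astype(float), Z])
    names = ["intercept", "group_patient"] + list(znames)
    _check_full_rank(X, names)

    mask = maps.mean(axis=0) >= mask_threshold
    Y = maps.reshape(n, -1)[:, mask.ravel()]

    rank = np.linalg.matrix_rank(X)
    df = n - rank
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    c_var = XtX_inv[1, 1]
    se = np.sqrt(np.maximum(sigma2 * c_var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, -beta[1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)

    stat3 = np.zeros(mask.shape)
    p3 = np.ones(mask.shape)
    stat3[mask] = t
    p3[mask] = p
    return StatMap(stat=stat3, p=p3, mask=mask, df=df, affine=affine)


def fdr_correct(sm: StatMap, q: float = 0.005) -> np.ndarray:
    """Benjamini-Hochberg FDR over in-mask voxel p-values; boolean 3D mask."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if not sm.mask.any():
        raise ValueError("empty analysis mask")
    keep = np.zeros(sm.mask.shape, dtype=bool)
    keep[sm.mask] = multipletests(sm.p[sm.mask], alpha=q, method="fdr_bh")[0]
    return keep


def fwe_correct(sm: StatMap, alpha: float = 1e-5) -> np.ndarray:
    """Bonferroni FWE: keep voxels with p <= alpha / m, m = in-mask count."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = int(sm.mask.sum())
    if m == 0:
        raise ValueError("empty analysis mask")
    keep = np.zeros(sm.mask.shape, dtype=bool)
    keep[sm.mask] = sm.p[sm.mask] <= alpha / m
    return keep


def extract_clusters(mask: np.ndarray, stat: np.ndarray | None = None,
                     min_extent: int = 0, connectivity: int = 26,
                     affine=None) -> list[ClusterRecord]:
    """Connected components of a boolean lattice, extent-thresholded.

    Components smaller than ``min_extent`` are dropped.  Records are sorted
    by size descending, ties by peak statistic descending, then by
    lexicographically smallest peak index.  The peak of a cluster is its
    member voxel with maximal statistic (ties: smallest lexicographic index).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_lab = ndimage.label(mask, structure=structure)
    records = []
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_extent:
            continue
        # argwhere output is lexicographically sorted; first argmax keeps the
        # smallest index among tied peaks
        if stat is not None:
            vals = stat[tuple(idx.T)]
            peak_pos = int(np.argmax(vals))
            peak_stat = float(vals[peak_pos])
        else:
            peak_pos, peak_stat = 0, float("nan")
        peak_index = tuple(int(v) for v in idx[peak_pos])
        peak_mm = None
        if affine is not None:
            peak_mm = tuple(
                float(v) for v in (affine @ np.array(peak_index + (1,)))[:3]
            )
        records.append(ClusterRecord(label=lab, size=len(idx), indices=idx,
                                     peak_index=peak_index, peak_stat=peak_stat,
                                     peak_mm=peak_mm))
    records.sort(key=lambda r: (-r.size,
                                -(r.peak_stat if np.isfinite(r.peak_stat) else -np.inf),
                                r.peak_index))
    return records


def define_seed(sm: StatMap, fwe_mask: np.ndarray, atlas_mask: np.ndarray,
                min_extent: int = 500, connectivity: int = 26,
                name: str = "seed") -> SeedRegion:
    """Seed region = (peak FWE-surviving cluster) intersected with an atlas mask.

    The peak cluster is the one containing the global maximum statistic among
    surviving clusters of at least ``min_extent`` voxels.
    """
    if not atlas_mask.any():
        raise SeedUndefinedError("atlas mask is empty")
    clusters = extract_clusters(fwe_mask, stat=sm.stat, min_extent=min_extent,
                                connectivity=connectivity, affine=sm.affine)
    if not clusters:
        raise SeedUndefinedError(
            f"no FWE-surviving cluster of >= {min_extent} voxels"
        )
    peak_cluster = max(
        clusters, key=lambda r: (r.peak_stat, [-v for v in r.peak_index])
    )
    inter = peak_cluster.mask(sm.mask.shape) & atlas_mask.astype(bool)
    if not inter.any():
        raise SeedUndefinedError(
            "peak cluster does not overlap the atlas mask: seed undefined"
        )
    return SeedRegion(
        name=name,
        mask=inter,
        provenance={
            "cluster_label": peak_cluster.label,
            "cluster_size": peak_cluster.size,
            "peak_index": list(peak_cluster.peak_index),
            "peak_stat": peak_cluster.peak_stat,
            "min_extent": min_extent,
            "connectivity": connectivity,
        },
    )


class GroupAtrophyGLM(BaseEstimator):
    """Estimator wrapper around :func:`fit_group_glm`.

    Parameters mirror the function; after :meth:`fit` the fitted attributes
    ``stat_map_``, ``fdr_mask_`` and ``clusters_`` are available.
    """

    def __init__(self, covariates=DEFAULT_COVARIATES, mask_threshold=0.1,
                 q_fdr=0.005, min_extent=300, connectivity=26):
        self.covariates = covariates
        self.mask_threshold = mask_threshold
        self.q_fdr = q_fdr
        self.min_extent = min_extent
        self.connectivity = connectivity

    def fit(self, maps, records, affine=None):
        self.stat_map_ = fit_group_glm(
            maps, records, covariates=self.covariates,
            mask_threshold=self.mask_threshold, affine=affine)
        self.fdr_mask_ = fdr_correct(self.stat_map_, q=self.q_fdr)
        self.clusters_ = extract_clusters(
            self.fdr_mask_, stat=self.stat_map_.stat,
            min_extent=self.min_extent, connectivity=self.connectivity,
            affine=affine)
        return self
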