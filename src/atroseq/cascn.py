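"""Causal structural covariance network (CaSCN) mapping.

Cross-sectional grey-matter maps of patients are ordered by disease severity
(sum-of-boxes score) into a "pseudo-time series"; a lag-1 signed-path
Granger-causality model then asks, voxel by voxel, whether the seed region's
past grey matter adds predictive power for the voxel's present grey matter
beyond the voxel's own past:

    y_t = alpha + a * y_{t-1} + b * x_{t-1} + gamma' z_t + eps_t,   t = 2..T

where x is the mean seed density, y the target voxel density, and z_t the
contemporaneous covariates (sex, age, education, TIV, site dummies) plus the
per-step severity increment Delta s_t.  The signed-path coefficient ``b`` is
reported as a Wald statistic z = b / SE(b) with two-sided p-values from the
Student t reference; only voxels with b > 0 ("seed loss precedes target
loss") are eligible for FDR correction and cluster reporting.  Model order
is fixed at 1 by default; seed voxels are excluded from the reported map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .vbm_stats import (
    ClusterRecord,
    SeedRegion,
    _check_full_rank,
    covariate_design,
    extract_clusters,
)

__all__ = [
    "PseudoTimeSeries",
    "GCAPathResult",
    "GCAMap",
    "build_pseudo_timeseries",
    "gca_signed_path",
    "cascn_map",
    "extract_region_masks",
    "CausalCovarianceNetwork",
]

GCA_COVARIATES = ("sex", "age", "education", "tiv", "site")


@dataclass
class PseudoTimeSeries:
    """Patients ordered by ascending severity: the CaSCN "time" axis.

    ``order`` indexes into the records/maps arrays the series was built
    from; ``ds`` is the per-step severity increment with ds[0] = 0.
    """

    ids: list
    order: np.ndarray  # indices into the source records/maps
    x: np.ndarray  # mean seed density per step
    s: np.ndarray  # severity per step (non-decreasing)
    ds: np.ndarray  # severity increments, ds[0] = 0
    Z: pd.DataFrame  # per-step covariate rows (numeric design columns)
    seed: SeedRegion | None = None

    def __len__(self):
        return len(self.ids)


@dataclass
class GCAPathResult:
    """Signed-path fit for one (x, y) pair."""

    b: float  # signed path coefficient of x_{t-1}
    z: float  # Wald b / SE(b)
    p: float
    a: float  # autoregressive coefficient of y_{t-1}
    df: int


@dataclass
class GCAMap:
    """Voxel-wise signed-path coefficient map with z and p lattices."""

    b: np.ndarray
    z: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    df: int
    n_failed: int = 0
    meta: dict = field(default_factory=dict)


def build_pseudo_timeseries(records: pd.DataFrame, maps, seed: SeedRegion,
                            covariates=GCA_COVARIATES) -> PseudoTimeSeries:
    """Order patients by sum-of-boxes (ties by id) and extract the seed series.

    ``records``/``maps`` must be aligned; non-patient rows are ignored.  The
    sort is stable and deterministic: ascending ``sumbox``, ties broken by
    subject id, so permuting the input order leaves the output unchanged.
    """
    if not seed.mask.any():
        raise ValueError("empty seed region")
    maps = np.asarray(maps, dtype=np.float64)
    patients = records.reset_index(drop=True)
    is_pat = patients["diagnosis"].to_numpy() == "patient"
    pidx = np.flatnonzero(is_pat)
    if len(pidx) < 3:
        raise ValueError("need at least 3 patients for a pseudo-time series")
    sub = patients.iloc[pidx]
    if sub["sumbox"].isna().any():
        raise ValueError("all patients must have a sumbox severity score")
    order_local = sub.sort_values(["sumbox", "id"], kind="mergesort").index
    order = np.asarray(order_local, dtype=int)

    s = patients.loc[order, "sumbox"].to_numpy(dtype=float)
    ds = np.diff(s, prepend=s[0])  # ds[0] = 0 by construction
    x = maps[order][:, seed.mask].mean(axis=1)
    Zmat, znames = covariate_design(patients.loc[order], covariates)
    Z = pd.DataFrame(Zmat, columns=znames)
    return PseudoTimeSeries(
        ids=list(patients.loc[order, "id"]), order=order, x=x, s=s, ds=ds,
        Z=Z, seed=seed,
    )


def gca_signed_path(x, y, Z=None, standardize: bool = False) -> GCAPathResult:
    """Lag-1 signed-path Granger fit of seed series ``x`` onto target ``y``.

    ``Z`` (optional, T x c) holds contemporaneous covariates entering at
    rows t = 2..T.  Returns the signed-path coefficient b, its Wald
    statistic z = b / SE(b), a two-sided p from the Student t reference with
    the residual df, and the AR coefficient a.  A constant ``y`` returns
    b = 0, z = 0 by convention; an exact fit (zero residual) returns
    z = +/-inf with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    T = len(x)
    Zm = None
    ncov = 0
    if Z is not None:
        Zm = np.asarray(Z, dtype=float)
        if Zm.ndim == 1:
            Zm = Zm[:, None]
        if Zm.shape[0] != T:
            raise ValueError("Z must have one row per time point")
        ncov = Zm.shape[1]
    n_regressors = 3 + ncov
    if T < n_regressors + 3:
        raise ValueError(
            f"series length {T} too short for {n_regressors} regressors"
        )
    if np.ptp(y) == 0.0:
        return GCAPathResult(b=0.0, z=0.0, p=1.0, a=0.0, df=T - 1 - n_regressors)
    if standardize:
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()

    yt = y[1:]
    cols = [np.ones(T - 1), y[:-1], x[:-1]]
    names = ["intercept", "y_lag", "x_lag"]
    if Zm is not None:
        cols.append(Zm[1:])
        names += [f"z{i}" for i in range(ncov)]
    D = np.column_stack(cols)
    _check_full_rank(D, names)

    G = D.T @ D
    beta = np.linalg.solve(G, D.T @ yt)
    resid = yt - D @ beta
    df = D.shape[0] - D.shape[1]
    sigma2 = float(resid @ resid) / df
    Ginv = np.linalg.inv(G)
    se = np.sqrt(max(sigma2 * Ginv[2, 2], 0.0))
    b = float(beta[2])
    if se == 0.0:
        z = 0.0 if b == 0.0 else np.sign(b) * np.inf
        p = 1.0 if b == 0.0 else 0.0
    else:
        z = b / se
        p = float(2.0 * stats.t.sf(abs(z), df))
    return GCAPathResult(b=b, z=float(z), p=p, a=float(beta[1]), df=df)


def _gca_covariate_block(pts: PseudoTimeSeries) -> np.ndarray:
    """Covariate matrix (T x c): nuisance columns plus the severity step."""
    return np.column_stack([pts.Z.to_numpy(dtype=float), pts.ds])


def cascn_map(maps, pts: PseudoTimeSeries, q: float = 0.001, extent: int = 100,
              mask: np.ndarray | None = None, mask_threshold: float = 0.1,
              connectivity: int = 26, affine=None, standardize: bool = False,
              exclude_seed: bool = True):
    """Voxel-wise signed-path GCA from the seed to the whole brain.

    ``maps`` is the array the pseudo-time series was built from (any subject
    order); it is re-ordered internally via ``pts.order``.  Positive-b voxels
    are BH-FDR corrected at ``q`` and extent-thresholded at ``extent``
    contiguous voxels; seed voxels are excluded from the reported map
    (self-influence is trivial).  Voxels whose per-voxel fit fails are
    dropped and counted in ``GCAMap.n_failed``.

    Returns ``(GCAMap, clusters)``.
    """
    maps = np.asarray(maps, dtype=np.float64)
    Y4 = maps[pts.order]
    T = Y4.shape[0]
    shape = Y4.shape[1:]
    if mask is None:
        mask = Y4.mean(axis=0) >= mask_threshold
    Zc = _gca_covariate_block(pts)

    # common regressors: intercept, x_lag, covariates at t = 2..T
    C = np.column_stack([np.ones(T - 1), pts.x[:-1], Zc[1:]])
    _check_full_rank(C, ["intercept", "x_lag"]
                     + list(pts.Z.columns) + ["ds"])
    p0 = C.shape[1]
    p_full = p0 + 1  # + voxel-specific y_lag column
    df = (T - 1) - p_full
    if df <= 0:
        raise ValueError("too few patients for the GCA design")

    flat = Y4.reshape(T, -1)[:, mask.ravel()]
    if standardize:
        sd = flat.std(axis=0)
        sd[sd == 0] = 1.0
        flat = (flat - flat.mean(axis=0)) / sd
    Yt = flat[1:]
    Ylag = flat[:-1]
    V = flat.shape[1]

    constant = np.ptp(flat, axis=0) == 0.0

    CtC = C.T @ C
    CtYt = C.T @ Yt  # (p0, V)
    CtYlag = C.T @ Ylag
    ylag2 = np.einsum("tv,tv->v", Ylag, Ylag)
    ylag_yt = np.einsum("tv,tv->v", Ylag, Yt)
    yt2 = np.einsum("tv,tv->v", Yt, Yt)

    G = np.empty((V, p_full, p_full))
    G[:, :p0, :p0] = CtC
    G[:, :p0, p0] = CtYlag.T
    G[:, p0, :p0] = CtYlag.T
    G[:, p0, p0] = ylag2
    rhs = np.empty((V, p_full))
    rhs[:, :p0] = CtYt.T
    rhs[:, p0] = ylag_yt

    ok = ~constant
    # guard singular per-voxel Gram matrices
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(G)
    ok &= np.isfinite(cond) & (cond < 1e12)
    n_failed = int((~ok & ~constant).sum())

    b = np.zeros(V)
    zval = np.zeros(V)
    pval = np.ones(V)
    if ok.any():
        Gok = G[ok]
        beta = np.linalg.solve(Gok, rhs[ok][..., None])[..., 0]  # (Vok, p_full)
        Ginv = np.linalg.inv(Gok)
        ss = yt2[ok] - np.einsum("vp,vp->v", beta, rhs[ok])
        sigma2 = np.maximum(ss, 0.0) / df
        se = np.sqrt(np.maximum(sigma2 * Ginv[:, 1, 1], 0.0))
        bo = beta[:, 1]  # x_lag is column 1 of C, hence of the full design
        with np.errstate(divide="ignore", invalid="ignore"):
            zo = np.where(se > 0, bo / se, 0.0)
        po = 2.0 * stats.t.sf(np.abs(zo), df)
        po[se == 0] = np.where(bo[se == 0] != 0, 0.0, 1.0)
        b[ok] = bo
        zval[ok] = zo
        pval[ok] = po

    b3 = np.zeros(shape)
    z3 = np.zeros(shape)
    p3 = np.ones(shape)
    b3[mask] = b
    z3[mask] = zval
    p3[mask] = pval

    eligible = mask & (b3 > 0)
    if exclude_seed and pts.seed is not None:
        eligible &= ~pts.seed.mask
    sig = np.zeros(shape, dtype=bool)
    if eligible.any():
        rej = multipletests(p3[eligible], alpha=q, method="fdr_bh")[0]
        sig[eligible] = rej
    clusters = extract_clusters(sig, stat=z3, min_extent=extent,
                                connectivity=connectivity, affine=affine)
    gmap = GCAMap(
        b=b3, z=z3, p=p3, mask=mask, df=df, n_failed=n_failed,
        meta={
            "q": q, "extent": extent, "connectivity": connectivity,
            "covariates": list(pts.Z.columns) + ["ds"],
            "standardize": standardize, "seed_excluded": exclude_seed,
            "n_sig_voxels": int(sig.sum()),
        },
    )
    return gmap, clusters


def extract_region_masks(clusters: list[ClusterRecord], shape,
                         labels: dict | None = None) -> dict:
    """One named boolean mask per cluster, pairwise disjoint.

    Names are ``r<rank>`` in cluster-sort order, with an optional label
    suffix from ``labels`` (cluster label -> anatomical name).
    """
    if not clusters:
        raise ValueError("empty cluster list: no region masks to extract")
    masks = {}
    for rank, c in enumerate(clusters, start=1):
        name = f"r{rank:02d}"
        if labels and c.label in labels:
            name += f"_{labels[c.label]}"
        masks[name] = c.mask(shape)
    return masks


class CausalCovarianceNetwork(BaseEstimator):
    """Estimator wrapper around :func:`cascn_map`.

    After :meth:`fit`, exposes ``gca_map_``, ``clusters_`` and
    ``region_masks_``.
    """

    def __init__(self, q=0.001, extent=100, connectivity=26,
                 standardize=False, mask_threshold=0.1):
        self.q = q
        self.extent = extent
        self.connectivity = connectivity
        self.standardize = standardize
        self.mask_threshold = mask_threshold

    def fit(self, maps, pts: PseudoTimeSeries, affine=None):
        self.gca_map_, self.clusters_ = cascn_map(
            maps, pts, q=self.q, extent=self.extent,
            mask_threshold=self.mask_threshold,
            connectivity=self.connectivity, affine=affine,
            standardize=self.standardize)
        self.region_masks_ = (
            extract_region_masks(self.clusters_, self.gca_map_.mask.shape)
            if self.clusters_ else {}
        )
        return self
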