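"""Event-based model (EBM) of the regional atrophy sequence.

Each regional biomarker (mean grey-matter density over a region mask) is
modelled as a two-component mixture of a "normal" and an "abnormal"
distribution, both estimated by Gaussian-kernel density estimation with
Silverman bandwidths on responsibility-weighted samples.  Treating each
biomarker's normal-to-abnormal transition as an event, the model infers the
maximum-likelihood event ordering under a uniform stage prior:

    L(S) = prod_j (1/(N+1)) sum_{k=0..N}
           prod_{i<=k} p_abn,S(i)(x_{j,S(i)}) prod_{i>k} p_norm,S(i)(x_{j,S(i)})

Sequence search uses greedy ascent (10 chains x 10,000 iterations by
default) to initialise, then Metropolis MCMC over permutations (500,000
iterations by default), tracking the highest-likelihood sequence visited.
Robustness is assessed with repeated stratified cross-validation (10 x
5-fold = 50 models) summarised as a positional variance diagram; the final
sequence sorts events by their expected position across the 50 models.

Atrophy direction is enforced: the abnormal component must sit below the
normal component (lower density = abnormal); components are swapped when
the fit violates this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from . import _kernels
from ._kernels import DENSITY_FLOOR
from .vbm_stats import covariate_design

__all__ = [
    "DegenerateBiomarkerError",
    "StratificationError",
    "BiomarkerMatrix",
    "KDEMixture",
    "EventSequence",
    "CVResult",
    "prepare_biomarkers",
    "fit_kde_mixture",
    "sequence_log_likelihood",
    "greedy_ascent",
    "mcmc_sample",
    "cross_validate",
    "stage_subject",
    "EventBasedModel",
    "plot_positional_variance",
]


class DegenerateBiomarkerError(ValueError):
    """A biomarker is constant (or otherwise unfittable); names the event."""


class StratificationError(ValueError):
    """Cross-validation folds cannot be stratified by diagnosis."""


@dataclass
class BiomarkerMatrix:
    """Subjects x events biomarker values with diagnosis labels."""

    data: pd.DataFrame  # index: subject ids, columns: event names
    labels: pd.Series  # "patient"/"control" per subject

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValueError("biomarker matrix contains missing entries")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 events")
        present = set(self.labels.unique())
        if not {"patient", "control"} <= present:
            raise ValueError("both diagnoses must be present")

    @property
    def event_names(self):
        return list(self.data.columns)


@dataclass
class EventSequence:
    """A permutation of event indices (position -> event) and its log-likelihood."""

    order: np.ndarray
    loglik: float = np.nan

    def __post_init__(self):
        o = np.asarray(self.order, dtype=np.int64)
        if sorted(o.tolist()) != list(range(len(o))):
            raise ValueError("order must be a permutation of 0..N-1")
        self.order = o


def _weighted_median(values, weights):
    idx = np.argsort(values)
    v, w = np.asarray(values)[idx], np.asarray(weights, dtype=float)[idx]
    if w.sum() <= 0:
        return np.nan
    cw = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cw, 0.5)])


@dataclass
class KDEMixture:
    """Two-component KDE mixture for one event.

    ``w`` is the weight of the *normal* component; atrophy direction is
    enforced (abnormal median < normal median).
    """

    name: str
    kde_norm: gaussian_kde
    kde_abn: gaussian_kde
    w: float
    n_iter: int = 0

    def pdf_norm(self, x):
        return self.kde_norm(np.atleast_1d(np.asarray(x, dtype=float)))

    def pdf_abn(self, x):
        return self.kde_abn(np.atleast_1d(np.asarray(x, dtype=float)))

    def posterior_abnormal(self, x):
        """P(abnormal | x) under the fitted mixture."""
        fn = self.w * self.pdf_norm(x)
        fa = (1.0 - self.w) * self.pdf_abn(x)
        denom = np.maximum(fn + fa, DENSITY_FLOOR)
        return fa / denom

    def normalization(self, n_grid: int = 512):
        """Numerical integrals of both component densities on a wide grid."""
        data = self.kde_norm.dataset.ravel()
        h = np.sqrt(max(self.kde_norm.covariance[0, 0],
                        self.kde_abn.covariance[0, 0]))
        grid = np.linspace(data.min() - 6 * h, data.max() + 6 * h, n_grid)
        return (
            float(np.trapezoid(self.pdf_norm(grid), grid)),
            float(np.trapezoid(self.pdf_abn(grid), grid)),
        )


def _as_patient_indicator(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return arr == "patient"
    return arr.astype(bool)


def _silverman_bandwidth(v, w, name):
    """Silverman bandwidth of a weighted 1-D sample, scipy conventions.

    Matches ``gaussian_kde(v, weights=w, bw_method="silverman")``:
    h = (neff * 3/4)^(-1/5) * sd_w with neff = 1/sum(w^2) and sd_w the
    square root of the unbiased weighted variance.
    """
    wn = w / w.sum()
    v2 = float((wn**2).sum())
    neff = 1.0 / v2
    denom = 1.0 - v2
    mu = float(wn @ v)
    if denom <= 0:
        raise DegenerateBiomarkerError(
            f"event {name!r}: weighted sample has a single effective point"
        )
    var = float(wn @ (v - mu) ** 2) / denom
    if var <= 0:
        raise DegenerateBiomarkerError(
            f"event {name!r}: weighted sample is constant"
        )
    return (neff * 0.75) ** (-0.2) * np.sqrt(var)


def _positive_weights(weights):
    """Floor weights so a vanished component keeps a defined density."""
    if weights.sum() <= 0 or (weights > 0).sum() < 2:
        weights = np.maximum(weights, 1e-12)
    return weights


def fit_kde_mixture(values, labels, name: str = "event", max_iter: int = 100,
                    tol: float = 1e-4) -> KDEMixture:
    """Fit the normal/abnormal KDE mixture for one event.

    The normal component is initialised from controls, the abnormal
    component from the patient tail below the control median; the fit then
    alternates (a) posterior responsibilities of each point under the
    current mixture and (b) responsibility-weighted KDE refits with mixing
    weight ``w`` = mean normal responsibility, stopping when ``w`` changes
    by less than ``tol`` or after ``max_iter`` iterations.  Controls are
    anchored to the normal component (their labels are known), so during
    the alternation only patient responsibilities move and densities only
    need evaluating at patient points; the squared-distance matrix is
    precomputed once.  The atrophy direction constraint is enforced by
    swapping components if the fit violates it.
    """
    v = np.asarray(values, dtype=float)
    pat = _as_patient_indicator(labels)
    if v.ndim != 1 or len(v) != len(pat):
        raise ValueError("values and labels must be aligned 1-D arrays")
    for grp, nm in ((pat, "patients"), (~pat, "controls")):
        if grp.sum() < 5:
            raise ValueError(f"need at least 5 {nm} to fit event {name!r}")
    if np.ptp(v) == 0.0:
        raise DegenerateBiomarkerError(f"event {name!r} has constant values")

    ctrl_median = float(np.median(v[~pat]))
    r_abn = np.where(pat & (v < ctrl_median), 1.0, 0.0)
    if r_abn.sum() < 2:  # degenerate start: seed with the two lowest patients
        low = np.argsort(np.where(pat, v, np.inf))[:2]
        r_abn[:] = 0.0
        r_abn[low] = 1.0
    w = float(1.0 - r_abn.mean())

    # support x patient-target squared distances, computed once
    D2 = (v[:, None] - v[None, pat]) ** 2
    inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)

    def density_at_patients(weights):
        weights = _positive_weights(weights)
        h = _silverman_bandwidth(v, weights, name)
        wn = weights / weights.sum()
        return (wn @ np.exp(D2 / (-2.0 * h * h))) * (inv_sqrt2pi / h)

    it = 0
    for it in range(1, max_iter + 1):
        fn = np.maximum(density_at_patients(1.0 - r_abn), DENSITY_FLOOR)
        fa = np.maximum(density_at_patients(r_abn), DENSITY_FLOOR)
        post_abn = np.zeros_like(r_abn)  # controls stay on the normal side
        post_abn[pat] = (1.0 - w) * fa / ((1.0 - w) * fa + w * fn)
        r_abn = post_abn
        w_new = float(1.0 - r_abn.mean())
        converged = abs(w_new - w) < tol
        w = w_new
        if converged or r_abn.sum() < 1e-8:
            break

    r_norm = _positive_weights(1.0 - r_abn)
    r_ab = _positive_weights(r_abn)
    kde_n = gaussian_kde(v, weights=r_norm / r_norm.sum(), bw_method="silverman")
    kde_a = gaussian_kde(v, weights=r_ab / r_ab.sum(), bw_method="silverman")
    med_a = _weighted_median(v, r_ab)
    med_n = _weighted_median(v, r_norm)
    if np.isfinite(med_a) and np.isfinite(med_n) and med_a >= med_n:
        kde_n, kde_a = kde_a, kde_n
        w = 1.0 - w
    return KDEMixture(name=name, kde_norm=kde_n, kde_abn=kde_a, w=w, n_iter=it)


def log_density_matrices(X, mixtures: list[KDEMixture]):
    """Per-subject log densities under each event's two components.

    Returns ``(logN, logA)`` of shape (n_subjects, n_events), floored at
    :data:`DENSITY_FLOOR` before the log.
    """
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    if N != len(mixtures):
        raise ValueError("one mixture per event required")
    logN = np.empty((n, N))
    logA = np.empty((n, N))
    for e, mix in enumerate(mixtures):
        logN[:, e] = np.log(np.maximum(mix.pdf_norm(X[:, e]), DENSITY_FLOOR))
        logA[:, e] = np.log(np.maximum(mix.pdf_abn(X[:, e]), DENSITY_FLOOR))
    return logN, logA


def _as_matrix(X):
    if isinstance(X, BiomarkerMatrix):
        return X.data.to_numpy(dtype=float)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def sequence_log_likelihood(X, mixtures, S) -> float:
    """log L(S) with a uniform stage prior; patients and controls both count."""
    logN, logA = log_density_matrices(_as_matrix(X), mixtures)
    order = S.order if isinstance(S, EventSequence) else np.asarray(S)
    return _kernels.log_likelihood(logN, logA, order)


def greedy_ascent(X, mixtures, n_iter: int = 10000, n_chains: int = 10,
                  rng_seed: int = 0, return_chains: bool = False):
    """Multi-chain greedy ascent over event permutations.

    Each chain starts from an independent uniform-random permutation and
    accepts a uniform-random transposition only when the log-likelihood
    strictly increases.  Returns the best :class:`EventSequence` across
    chains (optionally with per-chain diagnostics); deterministic for a
    given ``rng_seed``.
    """
    logN, logA = log_density_matrices(_as_matrix(X), mixtures)
    N = logN.shape[1]
    rng = np.random.default_rng(rng_seed)
    best = None
    chains = []
    for _ in range(n_chains):
        S = rng.permutation(N).astype(np.int64)
        init_order = S.copy()
        init_ll = _kernels.log_likelihood(logN, logA, S)
        if n_iter > 0:
            pi, pj = _kernels.transposition_proposals(rng, N, n_iter)
            ll = _kernels.greedy_chain(logN, logA, S, pi, pj)
        else:
            ll = init_ll
        chains.append({"init_order": init_order, "init_loglik": init_ll,
                       "final_order": S.copy(), "final_loglik": ll})
        if best is None or ll > best.loglik:
            best = EventSequence(order=S.copy(), loglik=ll)
    return (best, chains) if return_chains else best


def mcmc_sample(X, mixtures, init: EventSequence, n_iter: int = 500000,
                rng_seed: int = 0):
    """Metropolis MCMC over permutations from ``init``.

    Transposition proposals accepted with probability min(1, exp(delta
    logL)); returns the highest-likelihood visited sequence and the sampled
    log-likelihood trace.  Deterministic for a given ``rng_seed``.
    """
    logN, logA = log_density_matrices(_as_matrix(X), mixtures)
    N = logN.shape[1]
    rng = np.random.default_rng(rng_seed)
    pi, pj = _kernels.transposition_proposals(rng, N, n_iter)
    logu = np.log(rng.random(n_iter))
    S = np.array(init.order, dtype=np.int64)
    best_ll, best_S, trace, n_accept = _kernels.mcmc_chain(
        logN, logA, S, pi, pj, logu)
    ml = EventSequence(order=best_S, loglik=best_ll)
    ml.n_accept = n_accept
    return ml, trace


def stage_subject(x, mixtures, S) -> np.ndarray:
    """Posterior over stages k = 0..N for one biomarker row (or matrix).

    P(k | x, S) is proportional to prod_{i<=k} p_abn(x_{S(i)}) *
    prod_{i>k} p_norm(x_{S(i)}), normalised over k.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    logN, logA = log_density_matrices(x, mixtures)
    order = S.order if isinstance(S, EventSequence) else np.asarray(S, dtype=int)
    M = logN[:, order]
    B = logA[:, order]
    n, N = M.shape
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(B - M, axis=1)], axis=1)
    vals = M.sum(axis=1, keepdims=True) + cum
    vals -= vals.max(axis=1, keepdims=True)
    post = np.exp(vals)
    post /= post.sum(axis=1, keepdims=True)
    return post[0] if post.shape[0] == 1 else post


class EventBasedModel(BaseEstimator):
    """Event-based disease-progression model (scikit-learn style).

    ``fit(X, y)`` expects a subjects-x-events biomarker array (or DataFrame,
    or :class:`BiomarkerMatrix`) and per-subject diagnosis labels
    ("patient"/"control" or a boolean patient indicator).  Fitted
    attributes: ``mixtures_``, ``sequence_`` (maximum-likelihood
    :class:`EventSequence`), ``loglik_``, ``trace_``, ``event_names_``.
    ``predict(X)`` returns the most probable stage per subject and
    ``predict_proba(X)`` the full stage posterior.

    ``standardize`` z-scores each biomarker column before mixture fitting
    (default: raw densities).  ``include_controls`` keeps both cohorts in
    the sequence likelihood (the standard formulation); when False only
    patients enter the likelihood, with mixtures still fit on everyone.
    """

    def __init__(self, greedy_iters: int = 10000, n_chains: int = 10,
                 mcmc_iters: int = 500000, max_em_iter: int = 100,
                 em_tol: float = 1e-4, standardize: bool = False,
                 include_controls: bool = True,
                 random_state: int | None = None):
        self.greedy_iters = greedy_iters
        self.n_chains = n_chains
        self.mcmc_iters = mcmc_iters
        self.max_em_iter = max_em_iter
        self.em_tol = em_tol
        self.standardize = standardize
        self.include_controls = include_controls
        self.random_state = random_state

    def _transform(self, X):
        Xm = _as_matrix(X)
        if self.standardize:
            Xm = (Xm - self.scale_mean_) / self.scale_sd_
        return Xm

    def fit(self, X, y=None):
        if isinstance(X, BiomarkerMatrix):
            y = X.labels if y is None else y
            names = X.event_names
            Xm = X.data.to_numpy(dtype=float)
        else:
            names = (list(X.columns) if isinstance(X, pd.DataFrame)
                     else [f"e{i}" for i in range(np.asarray(X).shape[1])])
            Xm = _as_matrix(X)
        if y is None:
            raise ValueError("diagnosis labels are required")
        pat = _as_patient_indicator(y)
        self.scale_mean_ = Xm.mean(axis=0)
        self.scale_sd_ = Xm.std(axis=0)
        self.scale_sd_[self.scale_sd_ == 0] = 1.0
        if not self.standardize:
            self.scale_mean_ = np.zeros(Xm.shape[1])
            self.scale_sd_ = np.ones(Xm.shape[1])
        Xt = (Xm - self.scale_mean_) / self.scale_sd_
        self.event_names_ = names
        self.mixtures_ = [
            fit_kde_mixture(Xt[:, e], pat, name=names[e],
                            max_iter=self.max_em_iter, tol=self.em_tol)
            for e in range(Xt.shape[1])
        ]
        Xfit = Xt if self.include_controls else Xt[pat]
        seed = 0 if self.random_state is None else int(self.random_state)
        init = greedy_ascent(Xfit, self.mixtures_, n_iter=self.greedy_iters,
                             n_chains=self.n_chains, rng_seed=seed)
        ml, trace = mcmc_sample(Xfit, self.mixtures_, init,
                                n_iter=self.mcmc_iters, rng_seed=seed + 1)
        if init.loglik > ml.loglik:  # MCMC can only improve, but be safe
            ml = init
        self.sequence_ = ml
        self.loglik_ = ml.loglik
        self.trace_ = trace
        return self

    def predict_proba(self, X):
        post = stage_subject(self._transform(X), self.mixtures_, self.sequence_)
        return np.atleast_2d(post)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None):
        """Mean per-subject sequence log-likelihood of ``X`` under the fit."""
        Xm = self._transform(X)
        return sequence_log_likelihood(Xm, self.mixtures_, self.sequence_) / len(Xm)


@dataclass
class CVResult:
    """Cross-validated sequence ensemble and its positional variance."""

    sequences: list  # EventSequence per CV model (repeats x folds)
    positional_variance: np.ndarray  # events x positions, rows sum to 1
    final_order: np.ndarray  # events sorted by expected position
    holdout_loglik: np.ndarray  # mean held-out loglik per model
    event_names: list = field(default_factory=list)


def cross_validate(X, y=None, repeats: int = 10, folds: int = 5,
                   rng_seed: int = 0, rule: str = "expected",
                   **ebm_params) -> CVResult:
    """Repeated stratified k-fold cross-validation of the EBM.

    Folds are stratified by diagnosis; per fold, both the mixture models and
    the event sequence are refit on the training split and the held-out
    log-likelihood recorded.  The positional variance matrix P[e, pos] is
    the fraction of the repeats*folds maximum-likelihood sequences placing
    event e at position pos.  The final sequence sorts events by expected
    position (``rule="expected"``, ties by event index) or by modal
    position (``rule="modal"``).
    """
    if isinstance(X, BiomarkerMatrix):
        y = X.labels if y is None else y
        names = X.event_names
        Xm = X.data.to_numpy(dtype=float)
    else:
        names = (list(X.columns) if isinstance(X, pd.DataFrame)
                 else [f"e{i}" for i in range(np.asarray(X).shape[1])])
        Xm = _as_matrix(X)
    pat = _as_patient_indicator(y)
    for cls, nm in ((True, "patients"), (False, "controls")):
        if (pat == cls).sum() < folds:
            raise StratificationError(
                f"need at least {folds} {nm} for {folds}-fold stratification"
            )
    N = Xm.shape[1]
    rng = np.random.default_rng(rng_seed)
    sequences = []
    holdout = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        for train, test in skf.split(Xm, pat):
            model = EventBasedModel(
                random_state=int(rng.integers(0, 2**31 - 1)), **ebm_params)
            model.fit(Xm[train], pat[train])
            sequences.append(model.sequence_)
            holdout.append(model.score(Xm[test]))
    P = np.zeros((N, N))
    for seq in sequences:
        for pos, e in enumerate(seq.order):
            P[e, pos] += 1.0
    P /= len(sequences)
    if rule == "expected":
        keys = P @ np.arange(N)
    elif rule == "modal":
        keys = P.argmax(axis=1).astype(float)
    else:
        raise ValueError("rule must be 'expected' or 'modal'")
    final = np.lexsort((np.arange(N), keys))
    return CVResult(sequences=sequences, positional_variance=P,
                    final_order=np.asarray(final, dtype=np.int64),
                    holdout_loglik=np.asarray(holdout),
                    event_names=list(names))


def prepare_biomarkers(maps, masks: dict, records: pd.DataFrame,
                       adjust: bool = False,
                       covariates=("sex", "age", "education", "tiv", "site")
                       ) -> BiomarkerMatrix:
    """Mean density per region mask per subject, optionally covariate-adjusted.

    When ``adjust`` is set, each biomarker is residualised on the nuisance
    covariates with coefficients fitted in controls only, then the control
    mean is added back (W-score-style adjustment that leaves the control
    mean unchanged).
    """
    maps = np.asarray(maps, dtype=np.float64)
    names = list(masks)
    arrs = []
    seen = np.zeros(maps.shape[1:], dtype=bool)
    for name in names:
        m = masks[name].astype(bool)
        if not m.any():
            raise ValueError(f"empty region mask {name!r}")
        if (seen & m).any():
            raise ValueError("region masks must be pairwise disjoint")
        seen |= m
        arrs.append(maps[:, m].mean(axis=1))
    Y = np.column_stack(arrs)
    if adjust:
        Z, _ = covariate_design(records, covariates)
        Xd = np.column_stack([np.ones(len(records)), Z])
        ctrl = records["diagnosis"].to_numpy() == "control"
        beta = np.linalg.lstsq(Xd[ctrl], Y[ctrl], rcond=None)[0]
        Y = Y - Xd @ beta + Y[ctrl].mean(axis=0)
    data = pd.DataFrame(Y, index=list(records["id"]), columns=names)
    labels = pd.Series(records["diagnosis"].to_numpy(),
                       index=list(records["id"]), name="diagnosis")
    return BiomarkerMatrix(data=data, labels=labels)


def plot_positional_variance(P: np.ndarray, event_names=None, ax=None):
    """Positional variance diagram: events on y, positions on x, shading = P."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    N = P.shape[0]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 0.5 * N, 1.0 + 0.4 * N))
    order = np.lexsort((np.arange(N), P @ np.arange(N)))
    im = ax.imshow(P[order], cmap="Blues", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(N), [str(i + 1) for i in range(N)])
    names = event_names or [f"e{i}" for i in range(N)]
    ax.set_yticks(range(N), [names[i] for i in order])
    ax.set_xlabel("sequence position")
    ax.set_ylabel("event")
    ax.figure.colorbar(im, ax=ax, label="P(event at position)")
    ax.figure.tight_layout()
    return ax.figure
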