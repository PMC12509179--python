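"""KDE mixtures, sequence likelihood, permutation search, cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from atroseq import _kernels
from atroseq.ebm import (
    BiomarkerMatrix,
    DegenerateBiomarkerError,
    EventBasedModel,
    EventSequence,
    StratificationError,
    cross_validate,
    fit_kde_mixture,
    greedy_ascent,
    log_density_matrices,
    mcmc_sample,
    prepare_biomarkers,
    sequence_log_likelihood,
    stage_subject,
)


def staged_cohort(rng, n=200, N=3, mu_n=0.8, mu_a=0.5, sd=0.05):
    """Well-separated staged data: events flip in index order 0, 1, 2, ..."""
    n_pat = n // 2
    labels = np.array([False] * (n - n_pat) + [True] * n_pat)
    stages = np.concatenate(
        [np.zeros(n - n_pat, dtype=int), rng.integers(1, N + 1, n_pat)]
    )
    X = np.empty((n, N))
    for e in range(N):
        X[:, e] = np.where(stages > e, mu_a, mu_n) + rng.normal(0, sd, n)
    return X, labels


@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(5)
    X, labels = staged_cohort(rng)
    mixtures = [fit_kde_mixture(X[:, e], labels, name=f"e{e}")
                for e in range(X.shape[1])]
    return X, labels, mixtures


class TestKDEMixture:
    def test_separated_event_posterior(self, rng):
        values = np.concatenate([rng.normal(0.8, 0.02, 100),
                                 np.where(rng.random(100) < 0.5,
                                          rng.normal(0.4, 0.02, 100),
                                          rng.normal(0.8, 0.02, 100))])
        labels = np.array([False] * 100 + [True] * 100)
        mix = fit_kde_mixture(values, labels)
        low = values[values < 0.5]
        assert (mix.posterior_abnormal(low) > 0.95).all()

    def test_null_event_keeps_mass_normal(self, rng):
        values = rng.normal(0.8, 0.03, 200)
        labels = np.array([False] * 100 + [True] * 100)
        mix = fit_kde_mixture(values, labels)
        assert mix.w > 0.75  # almost all mass stays in the normal component

    def test_components_integrate_to_one(self, separated):
        _, _, mixtures = separated
        for mix in mixtures:
            zn, za = mix.normalization(n_grid=512)
            assert zn == pytest.approx(1.0, abs=1e-3)
            assert za == pytest.approx(1.0, abs=1e-3)

    def test_atrophy_direction_enforced(self, separated):
        _, _, mixtures = separated
        grid = np.linspace(0.2, 1.0, 400)
        for mix in mixtures:
            med_n = grid[np.cumsum(mix.pdf_norm(grid)) >=
                         mix.pdf_norm(grid).sum() / 2][0]
            med_a = grid[np.cumsum(mix.pdf_abn(grid)) >=
                         mix.pdf_abn(grid).sum() / 2][0]
            assert med_a < med_n

    def test_constant_values_named_in_error(self):
        labels = np.array([False] * 5 + [True] * 5)
        with pytest.raises(DegenerateBiomarkerError, match="putamen"):
            fit_kde_mixture(np.full(10, 0.5), labels, name="putamen")

    def test_minimum_group_size_enforced(self, rng):
        values = rng.normal(0.8, 0.05, 8)
        labels = np.array([False] * 4 + [True] * 4)
        with pytest.raises(ValueError, match="at least 5"):
            fit_kde_mixture(values, labels)

    def test_silverman_bandwidth_matches_scipy(self, rng):
        from scipy.stats import gaussian_kde

        from atroseq.ebm import _silverman_bandwidth

        v = rng.normal(0, 1, 60)
        w = rng.random(60)
        kde = gaussian_kde(v, weights=w / w.sum(), bw_method="silverman")
        h = _silverman_bandwidth(v, w, "x")
        assert h == pytest.approx(np.sqrt(kde.covariance[0, 0]), rel=1e-12)


class TestSequenceLikelihood:
    def test_single_event_collapses_to_two_stage_formula(self, rng):
        X, labels = staged_cohort(rng, n=60, N=2)
        X1 = X[:, :1]
        labels1 = labels
        mix = [fit_kde_mixture(X1[:, 0], labels1)]
        ll = sequence_log_likelihood(X1, mix, np.array([0]))
        pn = np.maximum(mix[0].pdf_norm(X1[:, 0]), 1e-250)
        pa = np.maximum(mix[0].pdf_abn(X1[:, 0]), 1e-250)
        direct = np.log((pn + pa) / 2.0).sum()
        assert ll == pytest.approx(direct, rel=1e-9)

    def test_event_relabelling_invariance(self, separated):
        X, _, mixtures = separated
        S = np.array([2, 0, 1])
        perm = np.array([1, 2, 0])  # relabel events
        Xp = X[:, perm]
        mixp = [mixtures[i] for i in perm]
        # S in relabelled space: event perm[i] -> i
        inv = np.argsort(perm)
        ll = sequence_log_likelihood(X, mixtures, S)
        llp = sequence_log_likelihood(Xp, mixp, inv[S])
        assert llp == pytest.approx(ll, rel=1e-12)

    def test_compiled_kernel_matches_reference(self, separated):
        X, _, mixtures = separated
        logN, logA = log_density_matrices(X, mixtures)
        for S in itertools.permutations(range(3)):
            ref = _kernels.loglik_reference(logN, logA, np.array(S))
            fast = _kernels.log_likelihood(logN, logA, np.array(S))
            assert fast == pytest.approx(ref, abs=1e-8)

    def test_underflow_guarded(self, separated):
        X, _, mixtures = separated
        Xbad = X.copy()
        Xbad[0, 0] = 1e6  # far outside any component's support
        ll = sequence_log_likelihood(Xbad, mixtures, np.array([0, 1, 2]))
        assert np.isfinite(ll)


class TestSearch:
    def test_brute_force_optimum_found_by_both_searches(self, separated):
        X, _, mixtures = separated
        lls = {S: sequence_log_likelihood(X, mixtures, np.array(S))
               for S in itertools.permutations(range(3))}
        brute = max(lls, key=lls.get)
        assert brute == (0, 1, 2)  # events flip in index order by design
        g = greedy_ascent(X, mixtures, n_iter=500, n_chains=5, rng_seed=3)
        assert tuple(g.order) == brute
        ml, trace = mcmc_sample(X, mixtures, g, n_iter=5000, rng_seed=4)
        assert tuple(ml.order) == brute
        assert ml.loglik == pytest.approx(lls[brute], rel=1e-9)
        assert len(trace) == 5000

    def test_greedy_zero_iterations_returns_best_initial(self, separated):
        X, _, mixtures = separated
        best, chains = greedy_ascent(X, mixtures, n_iter=0, n_chains=10,
                                     rng_seed=7, return_chains=True)
        init_lls = [c["init_loglik"] for c in chains]
        assert best.loglik == max(init_lls)

    def test_greedy_never_below_chain_inits(self, separated):
        X, _, mixtures = separated
        best, chains = greedy_ascent(X, mixtures, n_iter=200, n_chains=4,
                                     rng_seed=2, return_chains=True)
        for c in chains:
            assert c["final_loglik"] >= c["init_loglik"]
            assert best.loglik >= c["init_loglik"]

    def test_greedy_deterministic_given_seed(self, separated):
        X, _, mixtures = separated
        a = greedy_ascent(X, mixtures, n_iter=300, n_chains=3, rng_seed=11)
        b = greedy_ascent(X, mixtures, n_iter=300, n_chains=3, rng_seed=11)
        assert tuple(a.order) == tuple(b.order) and a.loglik == b.loglik

    def test_mcmc_ml_at_least_init(self, separated):
        X, _, mixtures = separated
        init = EventSequence(order=np.array([2, 1, 0]))
        init.loglik = sequence_log_likelihood(X, mixtures, init)
        ml, _ = mcmc_sample(X, mixtures, init, n_iter=2000, rng_seed=0)
        assert ml.loglik >= init.loglik

    def test_compiled_and_python_search_paths_agree(self, separated):
        """The numba kernels and the pure-Python fallbacks run the same
        trajectory for the same pre-drawn proposals."""
        X, _, mixtures = separated
        logN, logA = log_density_matrices(X, mixtures)
        rng = np.random.default_rng(17)
        S0 = rng.permutation(3).astype(np.int64)
        pi, pj = _kernels.transposition_proposals(rng, 3, 400)
        logu = np.log(rng.random(400))

        S_ref = S0.copy()
        ll_ref = _kernels._greedy_py(logN, logA, S_ref, pi, pj)
        S_fast = S0.copy()
        ll_fast = _kernels.greedy_chain(logN, logA, S_fast, pi, pj)
        assert S_ref.tolist() == S_fast.tolist()
        assert ll_fast == pytest.approx(ll_ref, abs=1e-8)

        trace_ref = np.empty(400)
        b_ref, bS_ref, na_ref = _kernels._mcmc_py(
            logN, logA, S0.copy(), pi, pj, logu, trace_ref)
        b_fast, bS_fast, trace_fast, na_fast = _kernels.mcmc_chain(
            logN, logA, S0.copy(), pi, pj, logu)
        assert bS_ref.tolist() == bS_fast.tolist()
        assert na_ref == na_fast
        assert b_fast == pytest.approx(b_ref, abs=1e-8)
        np.testing.assert_allclose(trace_fast, trace_ref, atol=1e-8)

    def test_flat_landscape_accepts_every_proposal(self):
        """exp(0) = 1: equal-likelihood proposals are always accepted."""
        logN = np.zeros((10, 4))
        logA = np.zeros((10, 4))
        rng = np.random.default_rng(0)
        pi, pj = _kernels.transposition_proposals(rng, 4, 500)
        logu = np.log(rng.random(500))
        best, bestS, trace, n_accept = _kernels.mcmc_chain(
            logN, logA, np.arange(4), pi, pj, logu)
        assert n_accept == 500
        assert np.allclose(trace, trace[0])


class TestStaging:
    def test_normal_profile_stage_zero(self, separated):
        X, _, mixtures = separated
        post = stage_subject(np.array([0.8, 0.8, 0.8]), mixtures,
                             np.array([0, 1, 2]))
        assert post.argmax() == 0
        assert post.sum() == pytest.approx(1.0)

    def test_abnormal_profile_stage_full(self, separated):
        X, _, mixtures = separated
        post = stage_subject(np.array([0.5, 0.5, 0.5]), mixtures,
                             np.array([0, 1, 2]))
        assert post.argmax() == 3

    def test_estimator_predict_matches_stage_posterior(self, separated):
        X, labels, _ = separated
        model = EventBasedModel(greedy_iters=300, n_chains=4, mcmc_iters=2000,
                                random_state=0).fit(X, labels)
        proba = model.predict_proba(X[:5])
        assert proba.shape == (5, 4)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert (model.predict(X[:5]) == proba.argmax(axis=1)).all()

    @pytest.mark.parametrize("kwargs", [
        {"standardize": True},
        {"include_controls": False},
    ])
    def test_variant_flags_recover_same_sequence(self, separated, kwargs):
        """Z-scored biomarkers / patients-only likelihood are alternative
        formulations that agree on well-separated data."""
        X, labels, _ = separated
        model = EventBasedModel(greedy_iters=300, n_chains=4,
                                mcmc_iters=2000, random_state=0,
                                **kwargs).fit(X, labels)
        assert model.sequence_.order.tolist() == [0, 1, 2]

    def test_estimator_clone_and_params(self):
        model = EventBasedModel(mcmc_iters=123, random_state=9)
        cloned = clone(model)
        assert cloned.get_params()["mcmc_iters"] == 123


class TestCrossValidation:
    def test_model_count_and_row_sums(self, separated):
        X, labels, _ = separated
        cv = cross_validate(X, labels, repeats=2, folds=5, rng_seed=0,
                            greedy_iters=200, n_chains=3, mcmc_iters=1000)
        assert len(cv.sequences) == 10
        np.testing.assert_allclose(cv.positional_variance.sum(axis=1), 1.0)
        assert cv.holdout_loglik.shape == (10,)

    def test_recovers_true_order(self, separated):
        X, labels, _ = separated
        cv = cross_validate(X, labels, repeats=2, folds=5, rng_seed=1,
                            greedy_iters=300, n_chains=4, mcmc_iters=2000)
        assert cv.final_order.tolist() == [0, 1, 2]

    def test_column_permutation_permutes_recovered_sequence(self, separated):
        X, labels, _ = separated
        perm = np.array([2, 0, 1])
        cv1 = cross_validate(X, labels, repeats=1, folds=5, rng_seed=3,
                             greedy_iters=300, n_chains=4, mcmc_iters=2000)
        cv2 = cross_validate(X[:, perm], labels, repeats=1, folds=5,
                             rng_seed=3, greedy_iters=300, n_chains=4,
                             mcmc_iters=2000)
        inv = np.argsort(perm)
        assert [inv[i] for i in perm[cv2.final_order]] == list(cv2.final_order)
        assert perm[cv2.final_order].tolist() == cv1.final_order.tolist()

    def test_no_systematic_ordering_without_abnormal_signal(self):
        """Across independent no-signal cohorts, recovered orderings are
        uniform: no event concentrates at any position (flat diagram).

        Flatness is assessed across replicate datasets rather than across
        CV folds of a single dataset: folds share the data, so sampling
        noise produces a consistent (spurious but data-fixed) ordering
        within any one cohort.
        """
        N, reps = 6, 100
        P = np.zeros((N, N))
        for r in range(reps):
            rng = np.random.default_rng(300 + r)
            X = rng.normal(0.8, 0.03, (80, N))
            labels = np.array([False] * 40 + [True] * 40)
            mixes = [fit_kde_mixture(X[:, e], labels, name=str(e))
                     for e in range(N)]
            g = greedy_ascent(X, mixes, n_iter=300, n_chains=3, rng_seed=r)
            ml, _ = mcmc_sample(X, mixes, g, n_iter=2000, rng_seed=1000 + r)
            for pos, e in enumerate(ml.order):
                P[e, pos] += 1
        P /= reps
        assert P.max() <= 2.0 / N

    def test_stratification_guard(self, rng):
        X = rng.normal(0.8, 0.05, (12, 3))
        labels = np.array([True] * 9 + [False] * 3)
        with pytest.raises(StratificationError):
            cross_validate(X, labels, repeats=1, folds=5)


class TestPrepareBiomarkers:
    def _cohort(self, rng, n=30):
        records = pd.DataFrame({
            "id": [f"s{i}" for i in range(n)],
            "diagnosis": ["patient"] * (n // 2) + ["control"] * (n - n // 2),
            "sex": rng.choice(["M", "F"], n),
            "age": rng.normal(64, 7, n),
            "education": rng.normal(13, 2, n),
            "tiv": rng.normal(1450, 100, n),
            "site": ["a"] * n,
            "sumbox": np.r_[rng.uniform(2, 22, n // 2), np.zeros(n - n // 2)],
        })
        return records

    def test_uniform_map_gives_constant_biomarker(self, rng):
        records = self._cohort(rng)
        maps = np.full((30, 6, 6, 4), 0.42)
        masks = {"a": np.zeros((6, 6, 4), bool), "b": np.zeros((6, 6, 4), bool)}
        masks["a"][0:2, 0:2, 0:2] = True
        masks["b"][4:6, 4:6, 0:2] = True
        bm = prepare_biomarkers(maps, masks, records)
        assert (bm.data.to_numpy() == 0.42).all()

    def test_adjustment_noop_without_covariate_effects(self):
        """On a cohort generated with zero covariate effects the W-score
        adjustment leaves the (severity-driven) biomarkers essentially
        unchanged."""
        from atroseq.synthetic_cohort import (
            CohortConfig, generate_cohort, region_masks)

        cfg = CohortConfig(n_patients=50, n_controls=40, beta_age=0.0,
                           beta_sex=0.0, site_offsets=(("a", 0.0),),
                           grid_shape=(12, 12, 12),
                           regions=(
                               __import__("atroseq.synthetic_cohort",
                                          fromlist=["RegionSpec"])
                               .RegionSpec("r1", onset=8.0, width=4.0,
                                           box=((2, 6), (2, 6), (2, 6))),
                               __import__("atroseq.synthetic_cohort",
                                          fromlist=["RegionSpec"])
                               .RegionSpec("r2", onset=12.0, width=4.0,
                                           box=((7, 11), (7, 11), (2, 6))),
                           ),
                           rng_seed=31)
        records, maps, _ = generate_cohort(cfg)
        masks = region_masks(cfg)
        raw = prepare_biomarkers(maps, masks, records, adjust=False)
        adj = prepare_biomarkers(maps, masks, records, adjust=True)
        for c in raw.data.columns:
            r = np.corrcoef(raw.data[c], adj.data[c])[0, 1]
            assert r > 0.99

    def test_adjustment_preserves_control_mean(self, rng):
        records = self._cohort(rng, n=60)
        maps = 0.6 + 0.05 * rng.standard_normal((60, 6, 6, 4))
        # inject an age effect so the adjustment has work to do
        maps += 0.002 * (records["age"].to_numpy() - 64)[:, None, None, None]
        masks = {"a": np.zeros((6, 6, 4), bool), "b": np.zeros((6, 6, 4), bool)}
        masks["a"][0:3, 0:3, :] = True
        masks["b"][3:6, 3:6, :] = True
        raw = prepare_biomarkers(maps, masks, records, adjust=False)
        adj = prepare_biomarkers(maps, masks, records, adjust=True)
        ctrl = records["diagnosis"] == "control"
        for c in raw.data.columns:
            assert adj.data.loc[ctrl.to_numpy(), c].mean() == pytest.approx(
                raw.data.loc[ctrl.to_numpy(), c].mean(), abs=1e-12)

    def test_overlapping_masks_rejected(self, rng):
        records = self._cohort(rng)
        maps = np.full((30, 4, 4, 4), 0.5)
        m = np.zeros((4, 4, 4), bool)
        m[:2] = True
        with pytest.raises(ValueError, match="disjoint"):
            prepare_biomarkers(maps, {"a": m, "b": m}, records)

    def test_empty_mask_rejected(self, rng):
        records = self._cohort(rng)
        maps = np.full((30, 4, 4, 4), 0.5)
        with pytest.raises(ValueError, match="empty"):
            prepare_biomarkers(maps, {"a": np.zeros((4, 4, 4), bool)}, records)


def test_biomarker_matrix_invariants():
    data = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    with pytest.raises(ValueError, match="diagnoses"):
        BiomarkerMatrix(data=data, labels=pd.Series(["patient", "patient"]))
    with pytest.raises(ValueError, match="2 events"):
        BiomarkerMatrix(data=data[["a"]],
                        labels=pd.Series(["patient", "control"]))
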