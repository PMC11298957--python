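"""Common-pathway model fitting, factor selection and loading clustering."""

import numpy as np
import pandas as pd
import pytest

from twinpath import (
    CommonPathwayModel,
    VarianceComponents,
    cluster_loadings,
    fit_cp,
    fit_univariate,
    select_n_factors,
    shared_genetic_factor,
    simulate_cp_twins,
    simulate_univariate_twins,
)
from twinpath.errors import ConfigError


def two_block_truth():
    lam = np.array(
        [[0.8, 0.0], [0.7, 0.0], [0.6, 0.0],
         [0.0, 0.9], [0.0, 0.7], [0.0, 0.6]]
    )
    fc = [VarianceComponents(a2=0.5, d2=0.2, e2=0.3)] * 2
    sc = [VarianceComponents(e2=0.3)] * 6
    return lam, fc, sc


def align_to_truth(lam, truth):
    """Column permutation + sign alignment of fitted loadings to the truth."""
    m = truth.shape[1]
    cols = list(range(m))
    best = None
    from itertools import permutations
    for perm in permutations(cols):
        cand = lam[:, perm].copy()
        for f in range(m):
            if cand[:, f] @ truth[:, f] < 0:
                cand[:, f] = -cand[:, f]
        err = np.abs(cand - truth).max()
        if best is None or err < best[0]:
            best = (err, cand)
    return best[1]


class TestFitCp:
    def test_single_phenotype_reduces_to_univariate(self):
        tab = simulate_univariate_twins(
            VarianceComponents(a2=0.3, d2=0.3, e2=0.4), 300, 200, seed=5
        )
        uni = fit_univariate(tab, "ADE", random_state=0)
        cp = fit_cp(tab, m=1, random_state=0, n_starts=3)
        assert cp.minus2ll == pytest.approx(uni.minus2ll, abs=1e-4)

    def test_zero_shared_factor_loadings_near_zero(self):
        """Two independent blocks, m=1: cross-block loadings stay small."""
        lam = np.array([[0.8], [0.7], [0.0], [0.0]])
        fc = [VarianceComponents(a2=0.6, e2=0.4)]
        sc = [VarianceComponents(e2=0.3)] * 2 + [VarianceComponents(a2=0.3, e2=0.4)] * 2
        tab = simulate_cp_twins(lam, fc, sc, 2000, 2000, seed=8)
        fit = fit_cp(tab, m=1, random_state=0, n_starts=3)
        assert np.abs(fit.loadings[2:, 0]).max() < 0.1

    def test_identification_error(self):
        tab = simulate_univariate_twins(
            VarianceComponents(a2=0.5, e2=0.5), 50, 40, seed=1
        )
        with pytest.raises(ConfigError):
            fit_cp(tab, m=2)

    def test_factor_components_sum_to_one(self):
        lam, fc, sc = two_block_truth()
        tab = simulate_cp_twins(lam, fc, sc, 300, 200, seed=9)
        fit = fit_cp(tab, m=1, random_state=0, n_starts=2)
        for f in fit.factor_components:
            assert f.total == pytest.approx(1.0, abs=1e-8)

    def test_implied_covariance_psd_and_symmetric(self):
        lam, fc, sc = two_block_truth()
        tab = simulate_cp_twins(lam, fc, sc, 300, 200, seed=10)
        fit = fit_cp(tab, m=2, random_state=0, n_starts=2)
        for zyg in ("MZ", "DZ"):
            sigma = fit.implied_covariance(zyg)
            assert np.allclose(sigma, sigma.T)
            assert np.linalg.eigvalsh(sigma).min() > -1e-10

    def test_minus2ll_nonincreasing_in_m(self):
        lam, fc, sc = two_block_truth()
        tab = simulate_cp_twins(lam, fc, sc, 400, 300, seed=11)
        f1 = fit_cp(tab, m=1, random_state=0, n_starts=2)
        f2 = fit_cp(tab, m=2, random_state=0, n_starts=2)
        assert f2.minus2ll <= f1.minus2ll + 1e-4

    def test_estimator_params_roundtrip(self):
        est = CommonPathwayModel(n_factors=2, variance_model="ACE")
        assert est.get_params()["n_factors"] == 2
        est.set_params(n_factors=1)
        assert est.n_factors == 1


class TestSelectNFactors:
    def test_one_factor_truth(self):
        lam = np.array([[0.8], [0.7], [0.6], [0.7]])
        fc = [VarianceComponents(a2=0.5, d2=0.2, e2=0.3)]
        sc = [VarianceComponents(e2=0.3)] * 4
        tab = simulate_cp_twins(lam, fc, sc, 600, 400, seed=13)
        assert select_n_factors(tab, m_max=2, n_starts=2) == 1

    def test_two_factor_truth(self):
        lam, fc, sc = two_block_truth()
        tab = simulate_cp_twins(lam, fc, sc, 800, 600, seed=14)
        assert select_n_factors(tab, m_max=3, n_starts=2) == 2

    def test_single_phenotype_upper_bound(self):
        tab = simulate_univariate_twins(
            VarianceComponents(a2=0.5, e2=0.5), 200, 150, seed=15
        )
        assert select_n_factors(tab, m_max=1, n_starts=2) == 1


class TestSharedGeneticFactor:
    def test_genetic_factor_flagged(self):
        lam = np.array([[0.8], [0.7]])
        fc = [VarianceComponents(a2=0.8, e2=0.2)]
        sc = [VarianceComponents(e2=0.4)] * 2
        tab = simulate_cp_twins(lam, fc, sc, 500, 400, seed=16)
        res = shared_genetic_factor(tab, n_starts=3)
        assert res["genetic"]
        assert np.all(res["loading_signs"] == res["loading_signs"][0])

    def test_environmental_factor_not_flagged(self):
        lam = np.array([[0.8], [0.7]])
        fc = [VarianceComponents(e2=1.0)]
        sc = [VarianceComponents(e2=0.4)] * 2
        tab = simulate_cp_twins(lam, fc, sc, 500, 400, seed=17)
        res = shared_genetic_factor(tab, n_starts=3)
        assert not res["genetic"]

    def test_sign_flip_exposed(self):
        """A phenotype entering with flipped sign loads negatively."""
        lam = np.array([[0.8], [0.7]])
        fc = [VarianceComponents(a2=0.7, e2=0.3)]
        sc = [VarianceComponents(e2=0.3)] * 2
        tab = simulate_cp_twins(lam, fc, sc, 400, 300, seed=18)
        df = tab.df.copy()
        df["phen2_t1"] = -df["phen2_t1"]
        df["phen2_t2"] = -df["phen2_t2"]
        from twinpath.table import TwinPairTable

        res = shared_genetic_factor(TwinPairTable(df), n_starts=3)
        signs = res["loading_signs"]
        assert signs[0] * signs[1] < 0


def gap_statistic_oracle(x, refs, labels_by_k):
    """Independent gap-statistic computation from shared cluster labels
    and shared reference sets (plain sums of squared distances)."""
    out = {}
    for k, (labels, ref_labels) in labels_by_k.items():
        def wss(data, lab):
            total = 0.0
            for c in np.unique(lab):
                pts = data[lab == c]
                total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        log_w = np.log(wss(x, labels))
        ref_log = np.array([np.log(wss(r, rl)) for r, rl in zip(refs, ref_labels)])
        out[k] = (ref_log.mean() - log_w,
                  ref_log.std() * np.sqrt(1 + 1 / len(refs)))
    return out


class TestClusterLoadings:
    def test_three_separated_masses(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([
            rng.normal(0, 0.05, (7, 2)),
            rng.normal(5, 0.05, (7, 2)),
            rng.normal([0, 5], 0.05, (6, 2)),
        ])
        sol = cluster_loadings(x, k_range=range(1, 7), b_refs=30, seed=0, n_init=10)
        assert sol.k == 3
        # pure clusters: each true block maps to a single label
        labels = sol.assignments.to_numpy()
        for block in (labels[:7], labels[7:14], labels[14:]):
            assert len(set(block)) == 1

    def test_identical_points_one_cluster(self):
        sol = cluster_loadings(np.ones((8, 3)), k_range=range(1, 5), b_refs=10, seed=0)
        assert sol.k == 1

    def test_gap_values_match_independent_oracle(self):
        """Gap/SE recomputed independently from shared references and
        shared k-means labels agree to 1e-6 on a fixed 20-point set."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.3, (10, 2)), rng.normal(4, 0.3, (10, 2))])
        lo, hi = x.min(axis=0), x.max(axis=0)
        refs = [np.random.default_rng(100 + b).uniform(lo, hi, x.shape) for b in range(8)]
        sol = cluster_loadings(
            x, k_range=(1, 2, 3), b_refs=0, seed=0, n_init=10, reference_sets=refs
        )
        from sklearn.cluster import KMeans

        labels_by_k = {}
        for k in (1, 2, 3):
            km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(x)
            ref_labels = [
                KMeans(n_clusters=k, n_init=10, random_state=0).fit(r).labels_
                for r in refs
            ]
            labels_by_k[k] = (km.labels_, ref_labels)
        oracle = gap_statistic_oracle(x, refs, labels_by_k)
        for i, k in enumerate((1, 2, 3)):
            assert sol.gap_curve.gap.iloc[i] == pytest.approx(oracle[k][0], abs=1e-6)
            assert sol.gap_curve.se.iloc[i] == pytest.approx(oracle[k][1], abs=1e-6)

    def test_invariant_to_phenotype_order(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 0.2, (6, 2)), rng.normal(3, 0.2, (6, 2))])
        sol = cluster_loadings(x, k_range=(1, 2, 3), b_refs=20, seed=0, n_init=10)
        perm = rng.permutation(len(x))
        sol_p = cluster_loadings(
            x[perm], k_range=(1, 2, 3), b_refs=20, seed=0, n_init=10
        )
        assert sol_p.k == sol.k
        # same partition up to label renaming
        from sklearn.metrics import adjusted_rand_score

        back = np.empty(len(x), dtype=int)
        back[perm] = sol_p.assignments.to_numpy()
        assert adjusted_rand_score(sol.assignments.to_numpy(), back) == 1.0

    def test_k_range_exceeding_points(self):
        with pytest.raises(ValueError):
            cluster_loadings(np.zeros((3, 2)), k_range=(1, 5), b_refs=5)
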