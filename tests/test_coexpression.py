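"""Co-expression network construction: adjacency, TOM, modules, kME."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import special

from pancanhub import coexpression as cx
from pancanhub import synthetic as syn


def _df(arr, prefix="G"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])],
    )


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Direct O(n^3) evaluation of the topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestSignedAdjacency:
    def test_perfect_correlation_gives_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = _df([base, 2 * base + 1])
        a = cx.signed_adjacency(m, power=6)
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation_gives_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = _df([base, -base])
        a = cx.signed_adjacency(m, power=6)
        assert a.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_closed_form(self):
        # orthogonal, zero-mean profiles: r = 0 exactly
        m = _df([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        a = cx.signed_adjacency(m, power=6)
        assert a.iloc[0, 1] == pytest.approx(0.5**6)

    def test_constant_gene_rejected(self):
        m = _df([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            cx.signed_adjacency(m, power=6)


class TestTopologicalOverlap:
    def test_empty_network_gives_zero_off_diagonal(self):
        a = pd.DataFrame(np.eye(4))
        tom = cx.topological_overlap(a).to_numpy()
        assert np.allclose(tom, np.eye(4))

    def test_three_gene_full_clique_is_all_ones(self):
        a = pd.DataFrame(np.ones((3, 3)))
        tom = cx.topological_overlap(a).to_numpy()
        # l = 1, k = 2, denominator 2 + 1 - 1 = 2, (1 + 1)/2 = 1
        assert np.allclose(tom, 1.0)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = cx.topological_overlap(pd.DataFrame(a)).to_numpy()
            expected = tom_oracle(a)
            assert np.abs(tom - expected).max() <= 1e-12

    def test_shared_neighbour_strength_raises_tom(self):
        def tom_with(w):
            a = np.array([[1, 0.1, w], [0.1, 1, w], [w, w, 1.0]])
            return cx.topological_overlap(pd.DataFrame(a)).iloc[0, 1]

        values = [tom_with(w) for w in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestSoftThreshold:
    def test_forced_single_candidate(self):
        rng = np.random.default_rng(1)
        m = _df(rng.lognormal(size=(30, 20)))
        fit = cx.pick_soft_threshold(m, candidate_powers=[6], r2_cut=-1.0)
        assert fit.chosen_power == 6

    def test_hub_structured_data_reaches_criterion(self):
        # one strong hub module + background: connectivity is heavy-tailed
        rng = np.random.default_rng(7)
        n_samples = 60
        hub = rng.standard_normal(n_samples)
        rows = []
        for i in range(60):
            beta = 0.95 * (0.97**i)  # geometric loading decay: few strong hubs
            rows.append(beta * hub + np.sqrt(1 - beta**2) * rng.standard_normal(n_samples))
        for _ in range(140):
            rows.append(rng.standard_normal(n_samples))
        fit = cx.pick_soft_threshold(_df(rows), candidate_powers=range(1, 13), r2_cut=0.8)
        best = fit.fit_table["signed_r2"].max()
        assert best >= 0.8
        assert fit.fit_table.loc[
            fit.fit_table["power"] == fit.chosen_power, "signed_r2"
        ].iloc[0] >= 0.8

    def test_fit_table_has_all_candidates(self):
        rng = np.random.default_rng(2)
        m = _df(rng.lognormal(size=(25, 15)))
        fit = cx.pick_soft_threshold(m, candidate_powers=range(1, 7), r2_cut=2.0)
        assert list(fit.fit_table["power"]) == list(range(1, 7))
        assert fit.fit_table["signed_r2"].between(-1, 1).all()


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        n = 80
        tom = np.full((n, n), 0.02)
        tom[:40, :40] = 0.95
        tom[40:, 40:] = 0.95
        np.fill_diagonal(tom, 1.0)
        tom_df = pd.DataFrame(
            tom, index=[f"G{i}" for i in range(n)], columns=[f"G{i}" for i in range(n)]
        )
        asn = cx.detect_modules(tom_df, min_module_size=30)
        assert len(asn.module_sizes) == 2
        assert set(asn.members(1)) == {f"G{i}" for i in range(40)}

    def test_no_module_smaller_than_floor(self):
        rng = np.random.default_rng(3)
        a = rng.random((50, 50)) * 0.2
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        asn = cx.detect_modules(pd.DataFrame(a), min_module_size=30)
        assert (asn.module_sizes >= 30).all()
        assert len(asn.module_sizes) <= 1

    def test_too_few_genes_all_unassigned(self):
        tom = pd.DataFrame(np.eye(5))
        asn = cx.detect_modules(tom, min_module_size=30)
        assert (asn.labels == 0).all()


class TestEigengenes:
    def test_identical_genes_give_kme_one(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        m = _df(np.tile(profile, (4, 1)) * np.array([[1], [2], [3], [4]]))
        labels = pd.Series([1, 1, 1, 1], index=m.index)
        eg = cx.module_eigengenes(m, labels)
        kme, _ = cx.module_membership(m, eg)
        assert np.allclose(kme[1].to_numpy(), 1.0)

    def test_recovers_latent_eigengene(self, standard_cohort):
        _, em, truth = standard_cohort
        log_vals = np.log2(em.values + 1e-3)
        labels = pd.Series(
            [truth.module_of_gene[g] for g in em.values.index], index=em.values.index
        )
        eg = cx.module_eigengenes(log_vals, labels)
        for m in (1, 2, 3):
            cors = [
                abs(np.corrcoef(eg.loc[l], truth.latent_eigengenes.loc[m])[0, 1])
                for l in eg.index
            ]
            assert max(cors) >= 0.95

    def test_sign_orientation_under_global_negation(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(20)
        m = _df([base + 0.1 * rng.standard_normal(20) for _ in range(5)])
        labels = pd.Series(1, index=m.index)
        eg_pos = cx.module_eigengenes(m, labels)
        eg_neg = cx.module_eigengenes(-m, labels)
        kme_pos, _ = cx.module_membership(m, eg_pos)
        kme_neg, _ = cx.module_membership(-m, eg_neg)
        assert (kme_pos[1] > 0).all() and (kme_neg[1] > 0).all()


class TestModuleMembership:
    def test_perfect_correlation_gives_zero_p(self):
        m = _df([[1.0, 2.0, 3.0, 4.0]])
        eg = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=pd.Index([1], name="module"),
                          columns=m.columns)
        kme, p = cx.module_membership(m, eg)
        assert kme.iloc[0, 0] == pytest.approx(1.0)
        assert p.iloc[0, 0] <= 1e-15  # zero within float limits

    def test_closed_form_p_for_r_09_n_50(self):
        # t = 0.9 sqrt(48 / 0.19); p via the regularised incomplete beta,
        # an independent evaluation of the t survival function
        n, r = 50, 0.9
        t_stat = r * np.sqrt((n - 2) / (1 - r**2))
        assert t_stat == pytest.approx(14.3049, abs=1e-3)
        df = n - 2
        p_indep = special.betainc(df / 2, 0.5, df / (df + t_stat**2))  # two-sided
        rng = np.random.default_rng(8)
        e = rng.standard_normal(n)
        g = r * e + np.sqrt(1 - r**2) * rng.standard_normal(n)
        # construct an exact-r pair via regression residual orthogonalisation
        resid = g - np.dot(g, e) / np.dot(e, e) * e
        g_exact = r * (e - e.mean()) / np.std(e - e.mean()) + np.sqrt(1 - r**2) * (
            (resid - resid.mean()) / np.std(resid - resid.mean())
        )
        m = _df([g_exact])
        eg = pd.DataFrame([e], index=pd.Index([1], name="module"), columns=m.columns)
        kme, p = cx.module_membership(m, eg)
        r_obs = kme.iloc[0, 0]
        t_obs = r_obs * np.sqrt((n - 2) / (1 - r_obs**2))
        p_expected = special.betainc(df / 2, 0.5, df / (df + t_obs**2))
        assert p.iloc[0, 0] == pytest.approx(p_expected, rel=1e-9)
        assert p_indep < 1e-18

    def test_null_p_values_uniform(self):
        from scipy import stats as sstats

        rng = np.random.default_rng(9)
        n = 40
        e = rng.standard_normal(n)
        genes = rng.standard_normal((300, n))
        m = _df(genes)
        eg = pd.DataFrame([e], index=pd.Index([1], name="module"), columns=m.columns)
        _, p = cx.module_membership(m, eg)
        ks = sstats.kstest(p[1].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_samples_rejected(self):
        m = _df([[1.0, 2.0]])
        eg = pd.DataFrame([[1.0, 2.0]], index=pd.Index([1], name="module"), columns=m.columns)
        with pytest.raises(ValueError):
            cx.module_membership(m, eg)


class TestModuleRecovery:
    def test_standard_cohort_recovery(self, standard_cohort):
        from sklearn.metrics import adjusted_rand_score

        _, em, truth = standard_cohort
        asn, _ = cx.analyze(em.values, candidate_powers=range(1, 13), dataset_id="T")
        labels_true = [truth.module_of_gene[g] for g in em.values.index]
        ari = adjusted_rand_score(labels_true, asn.labels.to_numpy())
        assert ari >= 0.8
        planted = [g for g, m in truth.module_of_gene.items() if m > 0]
        assigned = [g for g in planted if asn.labels[g] > 0]
        assert len(assigned) == len(planted)
        own_kme = np.array([asn.kme.at[g, asn.labels[g]] for g in assigned])
        assert own_kme.min() >= 0.8

    def test_gene_relabelling_leaves_eigengenes_invariant(self, standard_cohort):
        _, em, truth = standard_cohort
        log_vals = np.log2(em.values + 1e-3)
        labels = pd.Series(
            [truth.module_of_gene[g] for g in em.values.index], index=em.values.index
        )
        eg1 = cx.module_eigengenes(log_vals, labels)
        perm = np.random.default_rng(10).permutation(len(log_vals))
        eg2 = cx.module_eigengenes(log_vals.iloc[perm], labels.iloc[perm])
        for m in eg1.index:
            c = np.corrcoef(eg1.loc[m], eg2.loc[m])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-9)
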