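"""Filters, the per-site binomial-GLM LRT and its oracles, FDR, response
classification, effect summaries, and classical MDS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylegacy as ml
from methylegacy.dm import (ContrastSpec, bh_qvalues, classical_mds,
                            classify_responses, delta_methylation,
                            filter_coverage, filter_extremes,
                            filter_missingness, pooled_lrt, run_contrast,
                            summarize_deltas)
from methylegacy.dm import test_site as glm_site_test

from conftest import toy_matrix


class TestFilters:
    def test_coverage_masks_cells_but_keeps_partially_covered_sites(self):
        m = toy_matrix([[1, 1, 1]], [[9, 10, 11]])
        out = filter_coverage(m, min_reads=10)
        assert out.n_sites == 1
        assert np.isnan(out.total[0, 0])
        assert out.total[0, 1] == 10 and out.total[0, 2] == 11

    def test_coverage_filter_is_identity_when_all_cells_pass(self, small_sim):
        dense = filter_coverage(small_sim.matrix, min_reads=0)
        assert np.array_equal(dense.total, small_sim.matrix.total, equal_nan=True)

    def test_coverage_filter_matches_brute_force_tally(self, small_sim):
        out = filter_coverage(small_sim.matrix, min_reads=10)
        expect = (small_sim.matrix.total >= 10).sum()
        assert (~np.isnan(out.total)).sum() == expect

    def _design12(self):
        rows = [("c%d" % i, "water", "control", i) for i in range(1, 7)]
        rows += [("t%d" % i, "Cd", "curtox", i) for i in range(1, 4)]
        rows += [("s%d" % i, "Cd", "switch", i) for i in range(1, 4)]
        return ml.SampleDesign(pd.DataFrame(
            rows, columns=["sample_id", "pollutant", "treatment", "replicate"]))

    def test_missingness_rule_boundaries(self):
        design = self._design12()
        ids = design.sample_ids
        total = np.full((2, 12), 20.0)
        # site 0: 3 missing controls -> dropped
        total[0, :3] = np.nan
        # site 1: 2 missing controls, 1 curtox, 1 switch -> kept
        total[1, [0, 1, 6, 9]] = np.nan
        meth = np.where(np.isnan(total), np.nan, 1.0)
        m = ml.MethylomeMatrix(
            sites=ml.matrix.make_sites(["c1", "c1"], [10, 20], ["+", "+"]),
            meth=meth, total=total, samples=ids)
        keep = filter_missingness(m, design, "Cd")
        assert keep.tolist() == [False, True]

    def test_missingness_matches_brute_force_on_random_pattern(self):
        design = self._design12()
        rng = np.random.default_rng(3)
        total = np.where(rng.random((300, 12)) < 0.25, np.nan, 20.0)
        meth = np.where(np.isnan(total), np.nan, 1.0)
        m = ml.MethylomeMatrix(
            sites=ml.matrix.make_sites(["c1"] * 300,
                                       np.arange(1, 301) * 5, ["+"] * 300),
            meth=meth, total=total, samples=design.sample_ids)
        keep = filter_missingness(m, design, "Cd")
        miss = np.isnan(total)
        brute = ((miss[:, :6].sum(1) <= 2) & (miss[:, 6:9].sum(1) <= 1)
                 & (miss[:, 9:12].sum(1) <= 1))
        assert np.array_equal(keep, brute)

    def test_extremes_bounds_are_inclusive(self):
        # pooled percentages: 0.5%, exactly 1%, 50%, exactly 99%, 99.5%
        meth = np.array([[1.0], [2.0], [100.0], [198.0], [199.0]])
        total = np.full((5, 1), 200.0)
        m = toy_matrix(meth, total)
        keep = filter_extremes(m, m.samples, low=1.0, high=99.0)
        assert keep.tolist() == [False, True, True, True, False]

    def test_extremes_match_brute_force(self, small_sim):
        m = filter_coverage(small_sim.matrix, min_reads=10)
        keep = filter_extremes(m, m.samples)
        pct = 100 * np.nansum(m.meth, 1) / np.nansum(m.total, 1)
        assert np.array_equal(keep, (pct >= 1) & (pct <= 99))


class TestSiteTest:
    def test_equal_pooled_proportions_give_p_one(self):
        assert glm_site_test([5, 5], [10, 10], [0, 1]) == 1.0

    def test_saturated_boundary_gives_p_one(self):
        assert glm_site_test([10, 10, 10], [10, 10, 10], [0, 0, 1]) == 1.0

    def test_zero_reads_in_a_group_is_degenerate(self):
        _, p, deg = pooled_lrt([5], [10], [0], [0])
        assert p[0] == 1.0 and deg[0]

    def test_lrt_equals_independent_g_test_on_1000_random_tables(self):
        """The binomial-GLM LRT statistic must match scipy's log-likelihood
        chi-square (G-test) on the pooled 2x2 table to 1e-8."""
        rng = np.random.default_rng(11)
        n_checked = 0
        for _ in range(1000):
            t1, t0 = rng.integers(5, 200, 2)
            m1 = rng.integers(0, t1 + 1)
            m0 = rng.integers(0, t0 + 1)
            table = np.array([[m1, t1 - m1], [m0, t0 - m0]])
            if (table.sum(0) == 0).any():
                continue
            stat, p, _ = pooled_lrt([m1], [t1], [m0], [t0])
            g, p_ref, _, _ = stats.chi2_contingency(
                table, correction=False, lambda_="log-likelihood")
            assert abs(stat[0] - g) <= 1e-8
            assert p[0] == pytest.approx(p_ref, abs=1e-10)
            n_checked += 1
        assert n_checked >= 990

    def test_lrt_equals_statsmodels_binomial_glm_deviance(self):
        """Dual route: an explicitly fitted GLM with a group factor gives the
        same likelihood-ratio statistic as the closed form."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        for _ in range(25):
            t = rng.integers(10, 100, 9).astype(float)
            p_true = rng.uniform(0.05, 0.95, 2)
            g = np.array([0] * 6 + [1] * 3)
            m = rng.binomial(t.astype(int), p_true[g]).astype(float)
            endog = np.c_[m, t - m]
            x_full = sm.add_constant(g.astype(float))
            full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((9, 1)),
                          family=sm.families.Binomial()).fit()
            lrt_glm = null.deviance - full.deviance
            stat, _, _ = pooled_lrt([m[g == 1].sum()], [t[g == 1].sum()],
                                    [m[g == 0].sum()], [t[g == 0].sum()])
            assert stat[0] == pytest.approx(lrt_glm, abs=1e-8)

    def test_quasibinomial_option_is_more_conservative_on_overdispersed_data(self):
        rng = np.random.default_rng(2)
        n_sites = 300
        sites = ml.matrix.make_sites(["c1"] * n_sites,
                                     np.arange(1, n_sites + 1) * 3,
                                     ["+"] * n_sites)
        total = np.full((n_sites, 9), 50.0)
        # strong replicate overdispersion, no group effect
        p_rep = rng.beta(5, 5, size=(n_sites, 9))
        meth = rng.binomial(50, p_rep).astype(float)
        m = ml.MethylomeMatrix(sites=sites, meth=meth, total=total,
                               samples=[f"x{i}" for i in range(9)])
        spec = ContrastSpec("Cd", [f"x{i}" for i in range(6, 9)],
                            [f"x{i}" for i in range(6)])
        p_lrt = run_contrast(m, spec, method="lrt")["p"]
        p_quasi = run_contrast(m, spec, method="quasi")["p"]
        assert (p_quasi < 0.05).mean() < (p_lrt < 0.05).mean()
        assert (p_quasi < 0.05).mean() < 0.15


class TestFdrAndClassification:
    def test_bh_worked_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.9]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.9])

    def test_single_p_is_its_own_q(self):
        assert bh_qvalues(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_bh_matches_hand_rolled_step_up(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 80))
            order = np.argsort(p)
            n = len(p)
            stepped = p[order] * n / np.arange(1, n + 1)
            hand = np.minimum.accumulate(stepped[::-1])[::-1]
            q_hand = np.empty(n)
            q_hand[order] = np.minimum(hand, 1.0)
            assert bh_qvalues(p) == pytest.approx(q_hand, abs=1e-12)

    def test_q_multiset_invariant_under_permutation(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 50)
        q1 = np.sort(bh_qvalues(p))
        q2 = np.sort(bh_qvalues(rng.permutation(p)))
        assert q1 == pytest.approx(q2)

    @pytest.mark.parametrize(
        "qc,qs,expected",
        [
            (0.01, 0.2, "direct"),
            (0.01, 0.04, "persistent"),
            (0.2, 0.01, "legacy"),
            (0.9, 0.9, "none"),
            (0.05, 0.05, "none"),  # boundary: q == alpha is not significant
        ],
    )
    def test_classification_rule(self, qc, qs, expected):
        assert classify_responses(np.array([qc]), np.array([qs]))[0] == expected

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="different site universes"):
            classify_responses(np.array([0.1]), np.array([0.1, 0.2]))

    def test_classes_partition_the_significant_set(self):
        rng = np.random.default_rng(3)
        qc, qs = rng.uniform(0, 0.2, 500), rng.uniform(0, 0.2, 500)
        cls = classify_responses(qc, qs, alpha=0.05)
        sig_any = (qc < 0.05) | (qs < 0.05)
        assert np.array_equal(cls != "none", sig_any)
        assert set(np.unique(cls)) <= {"direct", "persistent", "legacy", "none"}


class TestDeltas:
    def test_signed_difference_of_pooled_percentages(self):
        m = toy_matrix([[30.0, 50.0]], [[100.0, 100.0]])
        d = delta_methylation(m, ["s1"], ["s2"])
        assert d[0] == pytest.approx(-20.0)

    def test_equal_proportions_give_zero(self):
        m = toy_matrix([[10.0, 5.0]], [[100.0, 50.0]])
        assert delta_methylation(m, ["s1"], ["s2"])[0] == pytest.approx(0.0)

    def test_summary_moments(self):
        dm = pd.DataFrame({
            "q_curtox": [0.01, 0.01, 0.2], "delta_curtox": [10.0, 30.0, 5.0],
            "q_switch": [0.01, 0.2, 0.2], "delta_switch": [-7.0, 1.0, 2.0],
        })
        s = summarize_deltas(dm)
        cur_up = s[(s.treatment == "curtox") & (s.direction == "+")].iloc[0]
        assert cur_up["n_sites"] == 2
        assert cur_up["mean_change"] == pytest.approx(20.0)
        assert cur_up["sd_change"] == pytest.approx(14.1421356, abs=1e-6)
        sw_dn = s[(s.treatment == "switch") & (s.direction == "-")].iloc[0]
        assert sw_dn["n_sites"] == 1 and np.isnan(sw_dn["sd_change"])

    def test_directional_counts_cover_all_significant_nonzero_sites(self):
        rng = np.random.default_rng(4)
        dm = pd.DataFrame({
            "q_curtox": rng.uniform(0, 0.1, 200),
            "delta_curtox": rng.normal(0, 10, 200),
            "q_switch": rng.uniform(0, 0.1, 200),
            "delta_switch": rng.normal(0, 10, 200),
        })
        s = summarize_deltas(dm)
        for treatment in ("curtox", "switch"):
            sig = dm[f"q_{treatment}"] < 0.05
            nonzero = dm[f"delta_{treatment}"] != 0
            expect = int((sig & nonzero).sum())
            got = s.loc[s.treatment == treatment, "n_sites"].sum()
            assert got == expect

    def test_planted_persistent_deltas_recovered_on_fixture(self, default_sim,
                                                            truth_lookup):
        from conftest import dm_site_ids

        dm = ml.run_dm_pollutant(default_sim.matrix, default_sim.design, "Cd")
        lookup = truth_lookup(default_sim, "Cd")
        tr = default_sim.truth[default_sim.truth["pollutant"] == "Cd"]
        deltas = dict(zip(tr["site_id"], tr["planted_delta"]))
        ids = dm_site_ids(dm)
        planted = [
            (dm["delta_curtox"].iloc[i], deltas[sid])
            for i, sid in enumerate(ids)
            if lookup.get(sid) == "persistent"
        ]
        got, want = map(np.array, zip(*planted))
        # pooled-read deltas track the planted shifts site by site
        assert np.corrcoef(got, want)[0, 1] > 0.95
        assert np.mean(got - want) == pytest.approx(0.0, abs=2.0)


class TestClassicalMds:
    def test_exact_embedding_of_planar_points(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        X = np.c_[pts, np.zeros((3, 5))]  # embed in higher dim
        coords, evals = classical_mds(X, k=2)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        assert d_out == pytest.approx(d_in, abs=1e-9)

    def test_duplicate_samples_coincide(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]])
        coords, _ = classical_mds(X, k=2)
        assert coords[0] == pytest.approx(coords[1], abs=1e-9)

    def test_distances_match_svd_oracle_at_k4(self):
        """Torgerson coordinates at k=4 must reproduce the inter-sample
        distances of a rank-4 PCA (SVD) reconstruction."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 50))
        coords, _ = classical_mds(X, k=4)
        Xc = X - X.mean(0)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        pca = U[:, :4] * s[:4]
        d_mds = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        d_pca = np.linalg.norm(pca[:, None] - pca[None], axis=-1)
        assert d_mds == pytest.approx(d_pca, abs=1e-8)

    def test_excess_k_reduced_with_warning(self):
        X = np.array([[0.0], [1.0], [2.0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords, evals = classical_mds(X, k=3)
        assert coords.shape[1] < 3

    def test_pipeline_embedding_separates_treatments(self, default_sim):
        dm = ml.run_dm_pollutant(default_sim.matrix, default_sim.design, "Cd")
        from methylegacy.dm import mds_input

        sites = default_sim.matrix.sites
        dm_sites = dm.loc[dm["response_class"] != "none",
                          ["contig", "pos", "strand"]]
        key = sites.merge(dm_sites.assign(flag=True), how="left")
        X, used = mds_input(default_sim.matrix, key["flag"].notna().to_numpy())
        coords, _ = classical_mds(X, k=2)
        labels = [
            "treated" if ("Cd" in s and "control" not in s) else "other"
            for s in default_sim.matrix.samples
        ]
        treated = coords[[l == "treated" for l in labels], 0]
        ctrl = coords[[s.startswith("water") for s in default_sim.matrix.samples], 0]
        # Cd curtox/switch samples separate from water controls on dim 1
        assert (treated.mean() - ctrl.mean()) ** 2 > 0
        gap = abs(treated.mean() - ctrl.mean())
        spread = np.std(np.r_[treated - treated.mean(), ctrl - ctrl.mean()])
        assert gap > 2 * spread
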