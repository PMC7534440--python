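"""SVE projection, weighted projection, contrast comparison, harnesses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import icamod as im
from icamod.data_model import ValidationError
from icamod.projection import _set_test_zscores


def _orthonormal_modules(n=30, k=3, seed=0):
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    return im.ExpressionMatrix(
        Q, [f"g{i}" for i in range(n)], [f"m{j+1}" for j in range(k)]
    )


class TestProject:
    def test_unit_module_contrast(self):
        S = _orthonormal_modules()
        x = pd.Series(S.values[:, 0], index=S.feature_ids)
        profile = im.project(x, S)
        np.testing.assert_allclose(profile.a, [1.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(profile.SVE, [1.0, 0.0, 0.0], atol=1e-12)

    def test_sve_arithmetic(self):
        # a = (-2, 1) -> VE = (0.8, 0.2), SVE = (-0.8, 0.2)
        S = _orthonormal_modules(k=2)
        x = pd.Series(
            -2.0 * S.values[:, 0] + 1.0 * S.values[:, 1], index=S.feature_ids
        )
        profile = im.project(x, S)
        np.testing.assert_allclose(profile.a, [-2.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(profile.VE, [0.8, 0.2], atol=1e-12)
        np.testing.assert_allclose(profile.SVE, [-0.8, 0.2], atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_sve_normalization_identity(self, seed):
        rng = np.random.default_rng(seed)
        S = _orthonormal_modules(n=25, k=4, seed=seed % 1000)
        x = pd.Series(rng.normal(size=25), index=S.feature_ids)
        profile = im.project(x, S)
        assert np.abs(profile.SVE).sum() == pytest.approx(1.0, abs=1e-10)
        assert profile.VE.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_array_equal(np.sign(profile.SVE), np.sign(profile.a))

    def test_scaling_contrast_leaves_sve_unchanged(self):
        S = _orthonormal_modules(seed=2)
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=30), index=S.feature_ids)
        p1 = im.project(x, S)
        p2 = im.project(17.0 * x, S)
        np.testing.assert_allclose(p1.SVE, p2.SVE, atol=1e-12)

    def test_zero_contrast_rejected(self):
        S = _orthonormal_modules()
        with pytest.raises(ValidationError, match="zero"):
            im.project(pd.Series(0.0, index=S.feature_ids), S)

    def test_partial_platform_alignment(self, caplog):
        """Features absent from the contrast are imputed as 0; foreign
        features are dropped."""
        S = _orthonormal_modules()
        x = pd.Series(
            np.r_[S.values[:20, 0], [5.0]], index=S.feature_ids[:20] + ["alien"]
        )
        with caplog.at_level("WARNING"):
            profile = im.project(x, S)
        assert "missing" in caplog.text and "absent" in caplog.text
        expected = np.r_[S.values[:20, 0], np.zeros(10)] @ S.values
        np.testing.assert_allclose(profile.a, expected, atol=1e-12)


class TestProjectWeighted:
    def test_zero_contrast_scores_and_z_zero(self, weighted_matrix):
        x = pd.Series(0.0, index=weighted_matrix.feature_ids)
        table = im.project_weighted(x, weighted_matrix, n_perm=50, seed=0)
        assert (table["score"] == 0).all()
        assert (table["z"] == 0).all()
        assert table["degenerate"].all()

    def test_loaded_module_annotation_attains_max_z(
        self, compendium, weighted_matrix
    ):
        X, _, S_true = compendium
        w = np.zeros(5)
        w[2] = 1.0
        x = pd.Series(
            im.generate_contrast(S_true, w, 0.05, seed=9), index=X.feature_ids
        )
        table = im.project_weighted(x, weighted_matrix, n_perm=300, seed=1)
        top = table.loc[table["z"].abs().idxmax(), "annotation"]
        assert top == "mod3_ann"

    def test_seeded_reproducibility(self, weighted_matrix, contrast_series):
        t1 = im.project_weighted(contrast_series, weighted_matrix, 100, seed=5)
        t2 = im.project_weighted(contrast_series, weighted_matrix, 100, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_decoy_z_is_standard_normal_like(self, compendium, weighted_matrix):
        """Null annotation z-scores across seeds behave like N(0, 1)."""
        X, _, S_true = compendium
        decoy_idx = weighted_matrix.annotation_ids.index("decoy1")
        zs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = pd.Series(rng.normal(size=X.n_features), index=X.feature_ids)
            t = im.project_weighted(x, weighted_matrix, n_perm=100, seed=seed)
            zs.append(t["z"].iloc[decoy_idx])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.3
        assert 0.7 < zs.std() < 1.4


class TestContrastSimilarity:
    def _profiles(self, vectors, mids=("m1", "m2", "m3", "m4")):
        out = []
        for v in vectors:
            v = np.asarray(v, dtype=float)
            a = v.copy()
            VE = a**2 / (a**2).sum()
            out.append(
                im.SVEProfile(a=a, VE=VE, SVE=np.sign(a) * VE, module_ids=list(mids))
            )
        return out

    def test_identical_profiles_correlate_perfectly(self):
        p = self._profiles([[1, 2, -1, 0.5], [1, 2, -1, 0.5]])
        table = im.contrast_similarity(p)
        assert table.loc[0, "r"] == pytest.approx(1.0)

    def test_duplicate_pair_ranks_first_after_holm(self):
        rng = np.random.default_rng(0)
        vecs = [rng.normal(size=8) for _ in range(6)]
        vecs.append(vecs[0] + rng.normal(0, 0.01, size=8))  # near-duplicate
        table = im.contrast_similarity(self._profiles(vecs, mids=[f"m{i}" for i in range(8)]))
        top = table.iloc[0]
        assert {top["contrast_1"], top["contrast_2"]} == {"c1", "c7"}
        assert top["p_holm"] < 0.05

    def test_constant_profile_skipped_with_flag(self):
        p = self._profiles([[1, 1, 1, 1], [1, 2, 3, 4], [0, 1, 0, 2]])
        table = im.contrast_similarity(p)
        flagged = table[table["constant"]]
        assert len(flagged) == 2
        assert flagged["p_holm"].isna().all()

    def test_same_group_pairs_excluded(self):
        p = self._profiles([[1, 2, 3, 4], [4, 3, 2, 1], [1, 0, 2, 0]])
        table = im.contrast_similarity(p, groups=["e1", "e1", "e2"])
        pairs = set(zip(table["contrast_1"], table["contrast_2"]))
        assert ("c1", "c2") not in pairs
        assert len(table) == 2


class TestGeneSetModuleEnrichment:
    def test_hemi_module_itself_attains_min_p(self, partitioned):
        sets = partitioned.hemi_sets()
        target = next(h for h in partitioned.hemi_ids if len(sets[h]) >= 5)
        table = im.gene_set_module_enrichment(sets[target], partitioned)
        assert table.loc[0, "hemi_module"] == target

    def test_random_set_not_significant(self, partitioned):
        rng = np.random.default_rng(7)
        qmins = []
        for _ in range(10):
            gene_set = set(rng.choice(partitioned.feature_ids, 20, replace=False))
            qmins.append(
                im.gene_set_module_enrichment(gene_set, partitioned)["q"].min()
            )
        assert np.median(qmins) > 0.1

    def test_empty_set_rejected(self, partitioned):
        with pytest.raises(ValidationError, match="empty"):
            im.gene_set_module_enrichment(set(), partitioned)

    def test_pvalues_match_enumeration_oracle(self):
        from test_enrichment import brute_force_p_over

        rng = np.random.default_rng(3)
        n = 60
        S_p = rng.choice([-1, 0, 0, 0, 1], size=(n, 2))
        P = im.PartitionedModules(
            S_p, [f"g{i}" for i in range(n)], ["m1", "m2"],
            [(3.0, -3.0)] * 2,
        )
        gene_set = set(rng.choice(P.feature_ids, 12, replace=False))
        table = im.gene_set_module_enrichment(gene_set, P).set_index("hemi_module")
        sets = P.hemi_sets()
        for h, members in sets.items():
            obs = len(members & gene_set)
            expected = brute_force_p_over(n, 12, len(members), obs)
            assert table.loc[h, "p"] == pytest.approx(expected, abs=1e-12)


class TestMethodZScores:
    def test_vectorized_statistics_match_scipy(self):
        rng = np.random.default_rng(11)
        xv = rng.normal(size=150)
        inc = rng.random((150, 5)) < 0.2
        from icamod.projection import _ks_statistics, _welch_t_statistics

        n1 = inc.sum(0).astype(float)
        n0 = 150 - n1
        ks_mine = _ks_statistics(
            inc[np.argsort(xv, kind="stable")].astype(float), n1, n0
        )
        t_mine = _welch_t_statistics(xv, inc.astype(float), n1, n0)
        for j in range(5):
            a, b = xv[inc[:, j]], xv[~inc[:, j]]
            assert ks_mine[j] == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)
            assert t_mine[j] == pytest.approx(
                stats.ttest_ind(a, b, equal_var=False).statistic, abs=1e-10
            )

    def test_annotation_without_contrast_gets_zero_z(self):
        xv = np.random.default_rng(0).normal(size=40)
        inc = np.zeros((40, 2))
        inc[:, 1] = 1.0  # no non-members
        z = _set_test_zscores(xv, inc, "ttest", 20, np.random.default_rng(1))
        np.testing.assert_array_equal(z, 0.0)


class TestNoiseRobustness:
    def test_zero_noise_correlation_is_one_and_decay_ordering(
        self, contrast_series, annotations, weighted_matrix
    ):
        table = im.evaluate_noise_robustness(
            contrast_series, annotations, weighted_matrix,
            noise_grid=(0.5, 5.0), n_perm=60, seed=0,
        )
        at_zero = table[table["noise"] == 0.0]
        assert (at_zero["spearman"] == 1.0).all()
        proj = table[table["method"] == "projection"].set_index("noise")["spearman"]
        assert proj[5.0] <= proj[0.0] + 1e-9
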