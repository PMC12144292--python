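"""Moderated t, BH correction, ddCt quantification and t-test behavior."""
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirseed import differential as dm
from mirseed.differential import EbParams, bh_adjust, delta_ct, fold_change, t_test


def _fixture_matrix(rng, n_feat=30, n=6):
    vals = rng.normal(0, 1, size=(n_feat, n)) * rng.uniform(0.5, 2.0, size=(n_feat, 1))
    df = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_feat)],
                      columns=[f"s{j}" for j in range(n)])
    groups = pd.Series(["a"] * (n // 2) + ["b"] * (n - n // 2), index=df.columns)
    return df, groups


class TestModeratedT:
    def test_closed_form_oracle(self, rng):
        """t and p reproduce a direct evaluation of the moderation equations."""
        df, groups = _fixture_matrix(rng, n_feat=8)
        out = dm.moderated_t(df, groups, "a", "b")
        prior = out.attrs["eb_prior"]
        a = df.loc[:, (groups == "a").to_numpy()].to_numpy()
        b = df.loc[:, (groups == "b").to_numpy()].to_numpy()
        n1, n2 = a.shape[1], b.shape[1]
        for i in range(len(df)):
            effect = b[i].mean() - a[i].mean()
            s2 = ((n1 - 1) * a[i].var(ddof=1) + (n2 - 1) * b[i].var(ddof=1)) / (n1 + n2 - 2)
            s2_post = (prior.d0 * prior.s0_sq + (n1 + n2 - 2) * s2) / (prior.d0 + n1 + n2 - 2)
            t = effect / np.sqrt(s2_post * (1 / n1 + 1 / n2))
            p = 2 * stats.t.sf(abs(t), n1 + n2 - 2 + prior.d0)
            assert out["t"].iloc[i] == pytest.approx(t, rel=1e-12)
            assert out["p_raw"].iloc[i] == pytest.approx(p, rel=1e-12)

    def test_equal_variances_collapse_to_ordinary_t(self):
        """Homogeneous residual variances: shrinkage is a no-op on the statistic."""
        base = np.array([1.0, -1.0, 0.5, -0.5, 2.0, -2.0])
        vals = np.vstack([base + k for k in range(5)])  # same spread, shifted
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(5)],
                          columns=[f"s{j}" for j in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=df.columns)
        out = dm.moderated_t(df, groups, "a", "b")
        assert np.isinf(out.attrs["eb_prior"].d0)
        for i in range(5):
            t_ord, _ = stats.ttest_ind(vals[i, 3:], vals[i, :3])
            assert out["t"].iloc[i] == pytest.approx(t_ord, rel=1e-10)

    def test_infinite_prior_df_limit_t_proportional_to_effect(self, rng):
        df, groups = _fixture_matrix(rng)
        prior = EbParams(s0_sq=2.0, d0=np.inf)
        out = dm.moderated_t(df, groups, "a", "b", prior=prior)
        ratio = out["t"] / out["effect"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-10)

    def test_matches_limma_on_shared_fixture(self, rng, tmp_path):
        """Independent oracle: the Bioconductor empirical-Bayes implementation."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        df, groups = _fixture_matrix(rng, n_feat=15)
        out = dm.moderated_t(df, groups, "a", "b")
        df.to_csv(tmp_path / "m.tsv", sep="\t")
        script = f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1))
design <- model.matrix(~factor(rep(c("a","b"), each=3)))
fit <- eBayes(lmFit(m, design))
write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]), "{tmp_path}/out.tsv", sep="\\t")
"""
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        np.testing.assert_allclose(out["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(out["p_raw"].to_numpy(), ref["p"].to_numpy(), rtol=1e-6)

    def test_flip_sign_gives_expression_scale(self, rng):
        df, groups = _fixture_matrix(rng)
        a = dm.moderated_t(df, groups, "a", "b")
        b = dm.moderated_t(df, groups, "a", "b", flip_sign=True)
        np.testing.assert_allclose(a["effect"].to_numpy(), -b["effect"].to_numpy())
        np.testing.assert_allclose(a["t"].to_numpy(), -b["t"].to_numpy())

    def test_untestable_features_reported_not_dropped(self, rng):
        df, groups = _fixture_matrix(rng, n_feat=4)
        df.iloc[0, :2] = np.nan  # only one "a" observation left
        out = dm.moderated_t(df, groups, "a", "b")
        assert len(out) == 4
        assert out["direction"].iloc[0] == "not_testable"
        assert np.isnan(out["p_raw"].iloc[0])

    def test_single_group_errors(self, rng):
        df, groups = _fixture_matrix(rng)
        with pytest.raises(ValueError):
            dm.moderated_t(df, groups, "a", "zzz")


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_statsmodels(self, rng):
        for _ in range(5):
            p = rng.uniform(0, 1, size=50)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_bounds_and_monotone_over_ordering(self, p):
        adj = bh_adjust(p)
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(p) - 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDdct:
    def test_delta_ct_arithmetic(self):
        t = pd.Series({"s1": 25.0, "s2": 20.0, "s3": 22.0})
        n = pd.Series({"s1": 20.0, "s2": 25.0, "s3": 22.0})
        d = delta_ct(t, n)
        assert d["s1"] == 5.0 and d["s2"] == -5.0 and d["s3"] == 0.0

    def test_delta_ct_drops_missing(self):
        t = pd.Series({"s1": 25.0, "s2": np.nan})
        n = pd.Series({"s1": 20.0, "s2": 21.0})
        assert list(delta_ct(t, n).index) == ["s1"]

    @pytest.mark.parametrize(
        "grp,ref,expected", [([3.0], [3.0], 1.0), ([2.0], [3.0], 2.0), ([4.0], [3.0], 0.5)]
    )
    def test_fold_change_arithmetic(self, grp, ref, expected):
        assert fold_change(grp, ref) == pytest.approx(expected)

    def test_fold_change_antisymmetric(self, rng):
        a = rng.normal(5, 1, 10)
        b = rng.normal(6, 1, 10)
        assert fold_change(a, b) == pytest.approx(1.0 / fold_change(b, a))

    def test_fold_change_empty_group_errors(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])


class TestTTest:
    def test_identical_samples(self):
        t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_one_tailed_matching_direction_is_half(self, rng):
        x = rng.normal(1, 1, 10)
        y = rng.normal(0, 1, 10)
        t2, p2 = t_test(x, y, tails=2)
        t1, p1 = t_test(x, y, tails=1, alternative="greater" if t2 > 0 else "less")
        assert p1 == pytest.approx(p2 / 2)
        _, p_wrong = t_test(x, y, tails=1, alternative="less" if t2 > 0 else "greater")
        assert p_wrong == pytest.approx(1 - p2 / 2)

    def test_matches_exhaustive_permutation_oracle(self):
        """Two-sided t p close to the exact label-permutation p on a 2x5 fixture."""
        from itertools import combinations

        x = np.array([3.1, 2.4, 4.0, 3.3, 2.8])
        y = np.array([1.9, 2.2, 1.4, 2.6, 2.0])
        t_obs, p_t = t_test(x, y)
        pooled = np.concatenate([x, y])
        count = 0
        total = 0
        for idx in combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(idx)] = True
            t_perm, _ = stats.ttest_ind(pooled[mask], pooled[~mask])
            count += abs(t_perm) >= abs(t_obs) - 1e-12
            total += 1
        p_perm = count / total
        assert p_t == pytest.approx(p_perm, abs=0.02)

    def test_paired_needs_equal_lengths(self):
        with pytest.raises(ValueError):
            t_test([1, 2, 3], [1, 2], paired=True)

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            t_test([1.0], [1.0, 2.0])


class TestDeCounts:
    def test_empty_table(self):
        de = pd.DataFrame({"fc_linear": [], "p_adj": []})
        assert dm.de_counts(de) == (0, 0)

    def test_inclusive_boundaries(self):
        de = pd.DataFrame({"fc_linear": [1.5, 1.0 / 1.5], "p_adj": [0.05, 0.05]})
        assert dm.de_counts(de) == (1, 1)

    def test_hand_counted_table(self):
        de = pd.DataFrame(
            {
                "fc_linear": [2.0, 0.4, 1.2, 0.5, 3.0, 0.1],
                "p_adj": [0.01, 0.01, 0.01, 0.2, 0.04, 0.06],
            }
        )
        # pass both thresholds: rows 0 (up), 1 (down), 4 (up)
        assert dm.de_counts(de) == (1, 2)


def test_null_type_one_error_calibrated():
    """Null panel data: raw p-value exceedance near nominal alpha (binomial band)."""
    from mirseed import synthetic
    from mirseed.pipeline import biomarker_discovery

    params = synthetic.CtSimParams(n_features=6000, n_planted=0, effect_delta=0.0, seed=11)
    m, _ = synthetic.gen_ct_matrix(params)
    de, _, _ = biomarker_discovery(m)
    p = de["p_raw"].dropna().to_numpy()
    n = len(p)
    assert n >= 500
    for alpha in (0.01, 0.05):
        k = int((p < alpha).sum())
        half = 1.96 * np.sqrt(n * alpha * (1 - alpha))
        assert n * alpha - half - 1 <= k <= n * alpha + half + 1


def test_planted_effect_sensitivity_on_power_design():
    """Planted features at the design effect size are recovered at BH-FDR 0.05."""
    from mirseed import synthetic
    from mirseed.pipeline import biomarker_discovery

    hits, total = 0, 0
    for seed in (0, 1, 2):
        m, truth = synthetic.gen_ct_matrix(synthetic.CtSimParams(seed=seed))
        de, _, _ = biomarker_discovery(m)
        called = set(de.loc[de["p_adj"] < 0.05, "feature_id"])
        hits += len(called & truth.planted_ids)
        total += len(truth.planted_ids)
    assert hits / total >= 0.96
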