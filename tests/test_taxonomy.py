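import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from kinotax import io_filter, taxonomy
from kinotax.exceptions import ParameterError
from kinotax.io_filter import NormalizedMatrix
from kinotax.synthetic_cohort import CohortSpec, generate_mib_cohort
from kinotax.taxonomy import (
    FeatureRanking,
    bhattacharyya_distance,
    compose_distinguishing_set,
    differential_groups,
    pan_subtype_features,
    rank_subtype_features,
    run_pca,
)


def bhattacharyya_by_integration(mu1, var1, mu2, var2):
    """Independent oracle: -ln of the numerically integrated Bhattacharyya
    coefficient between the two Gaussian densities."""

    def integrand(x):
        p = stats.norm.pdf(x, mu1, math.sqrt(var1))
        q = stats.norm.pdf(x, mu2, math.sqrt(var2))
        return math.sqrt(p * q)

    lo = min(mu1 - 12 * math.sqrt(var1), mu2 - 12 * math.sqrt(var2))
    hi = max(mu1 + 12 * math.sqrt(var1), mu2 + 12 * math.sqrt(var2))
    coeff, _ = integrate.quad(integrand, lo, hi, limit=200)
    return -math.log(coeff)


class TestPCA:
    def test_rank_one_data_concentrates_variance(self):
        u = np.arange(1, 7, dtype=float)
        v = np.array([1.0, -2.0, 0.5, 3.0])
        values = pd.DataFrame(np.outer(v, u))  # kinases x samples, rank 1
        p = run_pca(NormalizedMatrix(values))
        assert p.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.standard_normal((12, 8)))
        p = run_pca(NormalizedMatrix(values))
        X = values.T.to_numpy()
        Xc = X - X.mean(axis=0)
        recon = p.scores.to_numpy() @ p.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.standard_normal((20, 10)))
        p = run_pca(NormalizedMatrix(values))
        W = p.loadings.to_numpy()
        np.testing.assert_allclose(W.T @ W, np.eye(W.shape[1]), atol=1e-8)
        assert (np.diff(p.variance_fraction) <= 1e-12).all()
        assert p.variance_fraction.sum() <= 1 + 1e-8

    def test_agrees_with_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.standard_normal((15, 40)))
        p = run_pca(NormalizedMatrix(values))
        X = values.T.to_numpy()
        Xc = X - X.mean(axis=0)
        lam, vec = np.linalg.eigh(Xc.T @ Xc)
        lam, vec = lam[::-1], vec[:, ::-1]
        n_keep = min(values.shape)
        np.testing.assert_allclose(
            p.variance_fraction, lam[:n_keep] / lam.sum(), atol=1e-8
        )
        for c in range(3):  # sign-invariant comparison of leading loadings
            w = p.loadings.iloc[:, c].to_numpy()
            e = vec[:, c]
            assert min(np.abs(w - e).max(), np.abs(w + e).max()) < 1e-8

    def test_isotropic_data_spreads_variance(self):
        fracs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            values = pd.DataFrame(rng.standard_normal((5, 500)))
            fracs.append(run_pca(NormalizedMatrix(values)).variance_fraction)
        assert np.allclose(np.mean(fracs, axis=0), 0.2, atol=0.05)

    def test_missing_values_rejected(self):
        values = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ParameterError):
            run_pca(NormalizedMatrix(values))


class TestPanSubtypeFeatures:
    @pytest.fixture()
    def pca_254(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.standard_normal((254, 32)),
            index=[f"KIN{i:04d}" for i in range(254)],
        )
        return run_pca(NormalizedMatrix(values))

    def test_take_count_is_ceiling_of_top_decile(self, pca_254):
        pan = pan_subtype_features(pca_254, n_pcs=1, percentile=90)
        assert len(pan) == 26  # ceil(0.10 * 254)

    def test_duplicates_kept_under_first_pc(self, pca_254):
        pan = pan_subtype_features(pca_254, n_pcs=3, percentile=90)
        assert not pan["kinase"].duplicated().any()
        assert len(pan) <= 3 * 26
        # ordering: PC1 block first, descending |weight| inside each block
        comps = pan["component"].tolist()
        assert comps == sorted(comps, key=["PC1", "PC2", "PC3"].index)
        w1 = pan.loc[pan["component"] == "PC1", "weight"].abs()
        assert (w1.diff().dropna() <= 1e-12).all()

    def test_percentile_zero_takes_all(self, pca_254):
        pan = pan_subtype_features(pca_254, n_pcs=1, percentile=0)
        assert len(pan) == 254

    def test_bad_percentile_rejected(self, pca_254):
        with pytest.raises(ParameterError):
            pan_subtype_features(pca_254, percentile=100.0)


class TestBhattacharyya:
    def test_identical_distributions_zero(self):
        assert bhattacharyya_distance(1.3, 2.0, 1.3, 2.0) == 0.0

    def test_hand_evaluated_mean_shift(self):
        # mu gap 2, unit variances: D_B = 1/4 * 4 / 2 = 0.5
        assert bhattacharyya_distance(0, 1, 2, 1) == pytest.approx(0.5, abs=1e-12)

    def test_hand_evaluated_variance_ratio(self):
        # sd 1 vs 2: 1/4 ln(1/4 (1/4 + 4 + 2)) = 1/4 ln 1.5625
        expected = 0.25 * math.log(1.5625)
        assert bhattacharyya_distance(0, 1, 0, 4) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.11157, abs=5e-6)

    def test_matches_numeric_integration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            mu1, mu2 = rng.normal(0, 3, 2)
            var1, var2 = rng.uniform(0.2, 5.0, 2)
            closed = bhattacharyya_distance(mu1, var1, mu2, var2)
            oracle = bhattacharyya_by_integration(mu1, var1, mu2, var2)
            assert closed == pytest.approx(oracle, abs=1e-6)

    def test_affine_invariance(self):
        # rescaling both groups identically (x -> a x + b) leaves D_B fixed
        rng = np.random.default_rng(7)
        for _ in range(20):
            mu1, mu2 = rng.normal(0, 2, 2)
            v1, v2 = rng.uniform(0.1, 4, 2)
            a, b = rng.uniform(0.5, 3), rng.normal()
            d0 = bhattacharyya_distance(mu1, v1, mu2, v2)
            d1 = bhattacharyya_distance(a * mu1 + b, a**2 * v1, a * mu2 + b, a**2 * v2)
            assert d1 == pytest.approx(d0, rel=1e-10)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ParameterError):
            bhattacharyya_distance(0, 0.0, 1, 1.0)


class TestRankSubtypeFeatures:
    def _toy(self, seed, shift_kinase=None, shift=0.0):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.standard_normal((40, 16)),
            index=[f"K{i:02d}" for i in range(40)],
            columns=[f"s{i}" for i in range(16)],
        )
        meta = pd.DataFrame(
            {
                "cell_line": [f"L{i}" for i in range(16)],
                "subtype": ["basal-like"] * 4 + ["other"] * 12,
                "treatment": "untreated",
                "replicate": 1,
            },
            index=values.columns.rename("sample_id"),
        )
        if shift_kinase:
            values.loc[shift_kinase, values.columns[:4]] += shift
        return NormalizedMatrix(values), meta

    def test_planted_shift_ranks_first(self):
        wins = 0
        for seed in range(1, 11):
            n, meta = self._toy(seed, shift_kinase="K05", shift=3.0)
            ranking = rank_subtype_features(n, meta, "basal-like")
            wins += ranking.table.loc["K05", "rank"] == 1
        assert wins >= 9

    def test_identical_groups_score_zero(self):
        # equal-size groups carrying the same values have identical sample
        # moments, hence zero Bhattacharyya distance
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.standard_normal((5, 8)),
                              index=[f"K{i:02d}" for i in range(5)],
                              columns=[f"s{i}" for i in range(8)])
        pattern = np.array([1.0, -1.0, 0.5, 2.0])
        values.loc["K00"] = np.tile(pattern, 2)
        meta = pd.DataFrame(
            {"cell_line": [f"L{i}" for i in range(8)],
             "subtype": ["basal-like"] * 4 + ["other"] * 4,
             "treatment": "untreated", "replicate": 1},
            index=values.columns.rename("sample_id"),
        )
        ranking = rank_subtype_features(NormalizedMatrix(values), meta, "basal-like")
        assert ranking.table.loc["K00", "score"] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_null_calibrated(self):
        # under label permutation no kinase should beat the pooled null's 99th
        # percentile much more often than 1% of the time
        n, meta = self._toy(21)
        observed = rank_subtype_features(n, meta, "basal-like").table["score"]
        rng = np.random.default_rng(0)
        null = []
        for _ in range(40):
            perm = meta.copy()
            perm["subtype"] = rng.permutation(perm["subtype"].to_numpy())
            null.append(rank_subtype_features(n, perm, "basal-like").table["score"])
        null = pd.concat(null)
        cutoff = null.quantile(0.99)
        frac = (observed > cutoff).mean()
        assert frac <= 0.1

    def test_undersized_group_rejected(self):
        n, meta = self._toy(2)
        meta.loc[:, "subtype"] = ["basal-like"] + ["other"] * 15
        with pytest.raises(ParameterError):
            rank_subtype_features(n, meta, "basal-like")


def _fake_ranking(subtype, kinases, scores):
    table = pd.DataFrame(
        {"mu_in": 0.0, "mu_out": 0.0, "var_in": 1.0, "var_out": 1.0,
         "score": scores},
        index=pd.Index(kinases, name="kinase"),
    )
    table["rank"] = table["score"].rank(ascending=False).astype(int)
    return FeatureRanking(subtype, table)


class TestCompose:
    def test_top_fraction_ceiling_at_254(self, normalized_cohort):
        norm, _, meta, _ = normalized_cohort
        subtypes = sorted(meta.loc[norm.samples, "subtype"].unique())
        rankings = {s: rank_subtype_features(norm, meta, s) for s in subtypes}
        pan = pd.DataFrame(columns=["kinase", "component", "weight"])
        dset = compose_distinguishing_set(rankings, pan, cap=250)
        m = math.ceil(0.05 * len(norm.kinases))
        assert len(dset) <= 4 * m
        assert all(p.startswith("subtype-specific:") for p in dset.table["provenance"])

    def test_pan_entries_fill_to_cap(self):
        kinases = [f"K{i:03d}" for i in range(100)]
        scores = pd.Series(np.linspace(5, 0.1, 100), index=kinases)
        rankings = {
            "basal-like": _fake_ranking("basal-like", kinases, scores.to_numpy())
        }
        # top 5% of 100 = 5 specific entries; disjoint pan list of 60
        pan = pd.DataFrame(
            {"kinase": [f"P{i:03d}" for i in range(60)], "component": "PC1",
             "weight": np.linspace(3, 0.1, 60)}
        )
        dset = compose_distinguishing_set(rankings, pan, cap=50)
        assert len(dset) == 50
        n_specific = sum(
            p.startswith("subtype-specific") for p in dset.table["provenance"]
        )
        assert n_specific == 5 and 50 - n_specific == 45
        # subtype-specific entries precede pan entries
        provs = list(dset.table["provenance"])
        first_pan = next(i for i, p in enumerate(provs) if p.startswith("pan"))
        assert all(p.startswith("pan") for p in provs[first_pan:])

    def test_cap_zero_empty(self):
        kinases = ["A", "B", "C"]
        rankings = {"basal-like": _fake_ranking("basal-like", kinases, [3, 2, 1])}
        pan = pd.DataFrame({"kinase": ["D"], "component": ["PC1"], "weight": [1.0]})
        dset = compose_distinguishing_set(rankings, pan, cap=0)
        assert len(dset) == 0

    def test_round_robin_truncation_keeps_each_subtypes_best(self):
        kinases = [f"K{i:02d}" for i in range(40)]
        r1 = _fake_ranking("basal-like", kinases, np.linspace(4, 0.1, 40))
        order2 = np.linspace(0.1, 4, 40)  # reversed preference
        r2 = _fake_ranking("luminal", kinases[::-1], np.linspace(4, 0.1, 40))
        rankings = {"basal-like": r1, "luminal": r2}
        pan = pd.DataFrame(columns=["kinase", "component", "weight"])
        dset = compose_distinguishing_set(rankings, pan, cap=2, top_frac=0.5)
        provs = set(dset.table["provenance"])
        assert provs == {"subtype-specific:basal-like", "subtype-specific:luminal"}

    def test_empty_rankings_rejected(self):
        with pytest.raises(ParameterError):
            compose_distinguishing_set({}, pd.DataFrame())


class TestDifferentialGroups:
    def test_identical_groups_null_result(self):
        pattern = np.array([1.0, -0.5, 0.25, 2.0])
        values = pd.DataFrame(
            np.vstack([np.concatenate([pattern, pattern])]),
            index=["K"], columns=[f"s{i}" for i in range(8)],
        )
        out = differential_groups(
            NormalizedMatrix(values),
            [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
        )
        assert out.loc["K", "effect"] == pytest.approx(0.0)
        assert out.loc["K", "p"] == pytest.approx(1.0, abs=1e-9)

    def test_planted_shift_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(8) + 3.0
            b = rng.standard_normal(8)
            values = pd.DataFrame(
                [np.concatenate([a, b])], index=["K"],
                columns=[f"s{i}" for i in range(16)],
            )
            out = differential_groups(
                NormalizedMatrix(values),
                [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 16)],
            )
            hits += out.loc["K", "p"] < 0.05
        assert hits >= 19  # >= 95% power at a 3-SD shift

    def test_welch_matches_exhaustive_permutation(self):
        # 4v4 fixture: permutation p over all C(8,4)=70 splits of the pooled
        # values, compared with the Welch p
        a = np.array([0.8, 1.9, 1.1, 1.4])
        b = np.array([0.1, -0.9, 0.4, -0.2])
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        splits = list(itertools.combinations(range(8), 4))
        for idx in splits:
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(8) if i not in idx]]
            if abs(ga.mean() - gb.mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / len(splits)
        values = pd.DataFrame([pooled], index=["K"],
                              columns=[f"s{i}" for i in range(8)])
        out = differential_groups(
            NormalizedMatrix(values),
            [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
        )
        assert out.loc["K", "p"] == pytest.approx(p_perm, abs=0.05)

    def test_overlapping_groups_rejected(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["K"],
                              columns=["s1", "s2", "s3"])
        with pytest.raises(ParameterError):
            differential_groups(NormalizedMatrix(values), ["s1", "s2"], ["s2", "s3"])

    def test_bh_adjustment_switch(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.standard_normal((10, 8)),
                              index=[f"K{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(8)])
        out = differential_groups(
            NormalizedMatrix(values),
            [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
            adjust=True,
        )
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestPlantedRecovery:
    def test_distinguishing_set_recovers_planted_features(self, normalized_cohort,
                                                          distinguishing_set):
        norm, _, _, truth = normalized_cohort
        planted = truth.planted_pan | set().union(*truth.planted_specific.values())
        recoverable = planted & set(norm.kinases)
        got = set(distinguishing_set.kinases)
        assert len(recoverable & got) / len(recoverable) >= 0.9
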