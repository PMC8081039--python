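"""RNA-seq stack: size factors, NB exact test, BH, PCA, embedding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nemaquant import synthio
from nemaquant import transcriptome as tx


def toy_counts(rows, samples=None, genes=None):
    rows = np.atleast_2d(rows)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


class TestSizeFactors:
    def test_hand_computed_2x2_example(self):
        sf = tx.size_factors(toy_counts([[10, 20], [30, 60]]))
        assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf.iloc[1] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_columns_give_unit_factors(self):
        sf = tx.size_factors(toy_counts([[5, 5, 5], [9, 9, 9], [2, 2, 2]]))
        assert np.allclose(sf, 1.0)

    def test_gene_with_zero_excluded_from_pseudoreference(self):
        # The zero-containing gene would drag factors if included; with it
        # excluded the remaining gene determines the factors exactly.
        counts = toy_counts([[10, 0], [10, 40]])
        sf = tx.size_factors(counts)
        assert sf.iloc[0] == pytest.approx(0.5)
        assert sf.iloc[1] == pytest.approx(2.0)

    def test_scale_equivariance_of_factor_ratios(self):
        # Scaling one column by c scales its factor by c relative to the
        # others (the geometric-mean pseudoreference shifts all factors by
        # a common c**(1/n), so the invariant lives in the ratios).
        base = toy_counts([[10, 20, 15], [30, 60, 45], [8, 16, 12]])
        sf1 = tx.size_factors(base)
        scaled = base.copy()
        scaled["s1"] = scaled["s1"] * 3
        sf2 = tx.size_factors(scaled)
        assert sf2["s1"] / sf2["s0"] == pytest.approx(3 * sf1["s1"] / sf1["s0"])
        assert sf2["s2"] / sf2["s0"] == pytest.approx(sf1["s2"] / sf1["s0"])

    def test_no_all_positive_gene_errors(self):
        with pytest.raises(ValueError, match="filter"):
            tx.size_factors(toy_counts([[0, 5], [5, 0]]))


class TestNormalize:
    def test_unit_factors_identity(self):
        c = toy_counts([[4, 8], [2, 6]])
        out = tx.normalize(c, pd.Series([1.0, 1.0], index=c.columns))
        assert np.allclose(out, c)

    def test_idempotent_after_renormalization(self):
        c = toy_counts([[10, 20, 40], [30, 60, 120], [7, 14, 28]])
        once = tx.normalize(c, tx.size_factors(c))
        twice = tx.normalize(once.round().astype(int), tx.size_factors(once.round().astype(int)))
        assert np.allclose(once, twice, rtol=1e-12)

    def test_doubled_column_restored_up_to_common_rescale(self):
        c = toy_counts([[10, 20], [30, 60], [8, 16]])
        norm1 = tx.normalize(c, tx.size_factors(c))
        d = c.copy()
        d["s1"] = d["s1"] * 2
        norm2 = tx.normalize(d, tx.size_factors(d))
        # Depth distortion removed: between-sample profile ratios restored.
        assert np.allclose(
            norm2["s1"] / norm2["s0"], norm1["s1"] / norm1["s0"], rtol=1e-9
        )


class TestDispersionTrend:
    def test_constant_gene_zero_dispersion(self):
        counts, groups, _ = synthio.gen_counts(n_genes=200, n_per_group=3, frac_de=0.0, seed=0)
        norm = tx.normalize(counts, tx.size_factors(counts))
        norm.iloc[0] = 50.0  # constant gene
        model = tx.dispersion_trend(norm, groups)
        assert model.alpha_raw.iloc[0] == 0.0

    def test_parametric_fallback_with_few_genes(self):
        counts, groups, _ = synthio.gen_counts(n_genes=30, n_per_group=3, frac_de=0.0, seed=1)
        norm = tx.normalize(counts, tx.size_factors(counts))
        model = tx.dispersion_trend(norm, groups)
        assert model.method == "parametric_fallback"

    def test_poisson_data_trend_near_zero(self):
        counts, groups, _ = synthio.gen_counts(
            n_genes=2000, n_per_group=5, frac_de=0.0, trend_params=(0.0, 0.0), seed=4
        )
        norm = tx.normalize(counts, tx.size_factors(counts))
        model = tx.dispersion_trend(norm, groups)
        assert np.median(model.alpha_trend) <= 0.01

    def test_trend_recovers_generating_law(self):
        counts, groups, truth = synthio.gen_counts(
            n_genes=3000, n_per_group=5, frac_de=0.0, trend_params=(0.01, 1.0), seed=3
        )
        norm = tx.normalize(counts, tx.size_factors(counts))
        model = tx.dispersion_trend(norm, groups)
        mu = truth.gene_means.to_numpy()
        truth_alpha = 0.01 + 1.0 / mu
        lo, hi = np.percentile(mu, [5, 95])
        mid = (mu >= lo) & (mu <= hi)
        rel = np.abs(model.alpha_trend.to_numpy()[mid] / truth_alpha[mid] - 1.0)
        assert np.median(rel) <= 0.25


def brute_force_nb_pvalue(ka, kb, sa, sb, alpha):
    """Independent enumeration oracle (plain Python loop)."""
    K = ka + kb
    if K == 0:
        return 1.0
    q = K / (sa.sum() + sb.sum())
    aa = alpha * np.sum(sa**2) / sa.sum() ** 2
    ab = alpha * np.sum(sb**2) / sb.sum() ** 2

    def pmf(k, m, a):
        if a < 1e-10:
            return stats.poisson.pmf(k, m)
        r = 1.0 / a
        return stats.nbinom.pmf(k, r, r / (r + m))

    probs = [pmf(a, q * sa.sum(), aa) * pmf(K - a, q * sb.sum(), ab) for a in range(K + 1)]
    tot = sum(probs)
    obs = probs[ka]
    return min(sum(p for p in probs if p <= obs * (1 + 1e-8)) / tot, 1.0)


class TestNbTest:
    def test_balanced_identical_sums_p_one(self):
        s = np.ones(3)
        assert tx.exact_conditional_nb_pvalue(40, 40, s, s, 0.2) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_totals(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            K = int(rng.integers(1, 201))
            ka = int(rng.integers(0, K + 1))
            sa = rng.uniform(0.5, 2.0, 4)
            sb = rng.uniform(0.5, 2.0, 3)
            alpha = float(rng.uniform(0.0, 0.5))
            p_impl = tx.exact_conditional_nb_pvalue(ka, K - ka, sa, sb, alpha)
            p_oracle = brute_force_nb_pvalue(ka, K - ka, sa, sb, alpha)
            assert p_impl == pytest.approx(p_oracle, abs=1e-10)

    def test_zero_total_gene_p_one(self):
        s = np.ones(2)
        assert tx.exact_conditional_nb_pvalue(0, 0, s, s, 0.1) == 1.0

    def test_group_relabeling_invariance(self):
        counts, groups, _ = synthio.gen_counts(n_genes=100, n_per_group=4, frac_de=0.2, seed=6)
        sf = tx.size_factors(counts)
        norm = tx.normalize(counts, sf)
        model = tx.dispersion_trend(norm, groups)
        p1 = tx.nb_test(counts, sf, model, groups)
        swapped = groups.map({"control": "test", "test": "control"})
        p2 = tx.nb_test(counts, sf, model, swapped)
        assert np.allclose(p1, p2, atol=1e-12)


def brute_force_bh(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


class TestBH:
    def test_hand_computed_four_values(self):
        q = tx.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_single_value(self):
        assert np.allclose(tx.bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert tx.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            assert np.allclose(tx.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.bh_adjust([0.5, 1.5])


class TestCallDE:
    @pytest.mark.parametrize(
        "q,fold,expected",
        [(0.005, 3.0, True), (0.005, 1.5, False), (0.02, 3.0, False), (0.005, 0.2, True)],
    )
    def test_threshold_logic(self, q, fold, expected):
        res = pd.DataFrame({"q": [q], "fold_change": [fold]}, index=["g"])
        assert bool(tx.call_de(res, fdr=0.01, min_fold=2.0).iloc[0]) is expected


class TestLogCenterAndPCA:
    def test_log_center_properties(self):
        counts, _, _ = synthio.gen_counts(n_genes=50, n_per_group=3, seed=0)
        norm = tx.normalize(counts, tx.size_factors(counts))
        norm.iloc[0] = 0.0
        centered, center = tx.log_center(norm)
        assert np.allclose(centered.iloc[0], 0.0)  # all-zero gene stays zero
        assert np.allclose(centered.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(center, np.log2(norm + 1).mean(axis=1))
        # Centering is idempotent: re-subtracting row means changes nothing.
        assert np.allclose(centered.sub(centered.mean(axis=1), axis=0), centered, atol=1e-12)

    def test_collinear_data_first_fraction_one(self):
        t = np.linspace(0, 1, 6)
        mat = pd.DataFrame(
            np.outer([1.0, 2.0, -0.5], t) + np.array([[3.0], [1.0], [0.0]]),
            index=["g1", "g2", "g3"],
        )
        model, _ = tx.pca(mat, k=3)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)
        assert model.truncated

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(0, 1, (40, 8)))
        model, scores = tx.pca(mat, k=5)
        X = (mat.sub(mat.mean(axis=1), axis=0)).to_numpy().T
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        assert np.allclose(np.abs(scores.to_numpy()), np.abs(U[:, :5] * S[:5]), atol=1e-8)
        assert np.allclose(model.explained_variance_ratio, (S**2 / (S**2).sum())[:5], atol=1e-10)
        # Orthonormal components, non-increasing fractions
        C = model.components.to_numpy()
        assert np.allclose(C @ C.T, np.eye(5), atol=1e-10)
        assert (np.diff(model.explained_variance_ratio) <= 1e-12).all()
        assert model.explained_variance_ratio.sum() <= 1 + 1e-12


class TestEmbedding:
    def test_reference_projects_to_own_scores(self):
        ref, labels = synthio.gen_reference_timecourse(n_timepoints=8, n_genes=500, seed=0)
        emb = tx.embed_on_reference(ref, ref, labels, k=5)
        assert np.allclose(emb.scores, emb.reference_scores, atol=1e-8)
        assert (emb.nearest_label.to_numpy() == labels.to_numpy()).all()

    def test_midpoint_query_maps_to_adjacent_timepoint(self):
        ref, labels = synthio.gen_reference_timecourse(n_timepoints=6, n_genes=400, seed=1)
        # Query = midpoint of timepoints 3 and 4 on the log scale.
        logref = np.log2(ref + 1.0)
        mid = (logref.iloc[:, 2] + logref.iloc[:, 3]) / 2.0
        query = pd.DataFrame({"q": 2.0**mid - 1.0})
        emb = tx.embed_on_reference(query, ref, labels, k=5)
        assert emb.nearest_label.iloc[0] in (3, 4)

    def test_small_gene_overlap_rejected(self):
        ref, labels = synthio.gen_reference_timecourse(n_timepoints=4, n_genes=200, seed=2)
        query = ref.iloc[:50].copy()
        with pytest.raises(ValueError, match="overlap"):
            tx.embed_on_reference(query, ref, labels, k=3)


class TestDEPipeline:
    def test_spiked_genes_recovered_with_low_fdp(self, small_counts):
        counts, groups, truth = small_counts
        res = tx.de_table(counts, groups, fdr=0.05, min_fold=1.3)
        called = set(res.index[res.is_de])
        assert called  # recall > 0
        fdp = len(called - truth.de_genes) / len(called)
        assert fdp <= 0.3  # loose sanity bound at this small n_genes

    def test_zero_count_genes_excluded_from_universe(self):
        counts, groups, _ = synthio.gen_counts(n_genes=80, n_per_group=3, seed=2)
        counts.iloc[0] = 0
        res = tx.de_table(counts, groups)
        assert counts.index[0] not in res.index
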