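import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from myodiff import (
    ContrastSpec,
    ValidationError,
    bh_adjust,
    build_contrasts,
    fit_moderated,
    log_cpm,
    make_table1_scenario,
    normalize,
    null_config,
    simulate_counts,
    tmm_factors,
)
from myodiff.de import estimate_prior


@pytest.fixture(scope="module")
def table1_annotations():
    _, annotations, _ = simulate_counts(
        make_table1_scenario(scale=1.0, seed=0, n_genes=64)
    )
    return annotations


class TestBuildContrasts:
    def test_nt_single_contrast(self, table1_annotations, hierarchy):
        vs_rest, vs_nt = build_contrasts(table1_annotations, hierarchy, "NT")
        assert vs_nt is None
        assert len(vs_rest.group_samples) == 37
        assert len(vs_rest.reference_samples) == 632

    def test_dm_includes_subgroups(self, table1_annotations, hierarchy):
        vs_rest, vs_nt = build_contrasts(table1_annotations, hierarchy, "DM")
        assert len(vs_rest.group_samples) == 105
        assert len(vs_rest.reference_samples) == 564
        assert len(vs_nt.group_samples) == 105
        assert len(vs_nt.reference_samples) == 37

    def test_jo1_sizes(self, table1_annotations, hierarchy):
        vs_rest, _ = build_contrasts(table1_annotations, hierarchy, "Jo1")
        assert len(vs_rest.group_samples) == 37
        assert len(vs_rest.reference_samples) == 632

    def test_subgroup_rest_keeps_own_clinical_remainder(
        self, table1_annotations, hierarchy
    ):
        vs_rest, _ = build_contrasts(table1_annotations, hierarchy, "Mi2")
        dm_not_mi2 = {
            a.sample_id
            for a in table1_annotations
            if a.clinical_group == "DM" and a.autoantibody_subgroup != "Mi2"
        }
        assert dm_not_mi2 <= vs_rest.reference_samples

    def test_unknown_group_rejected(self, table1_annotations, hierarchy):
        with pytest.raises(ValidationError):
            build_contrasts(table1_annotations, hierarchy, "GENETIC")

    def test_too_small_group_rejected(self, hierarchy):
        from myodiff import SampleAnnotation

        anns = [
            SampleAnnotation("a", "IBM", None),
            SampleAnnotation("b", "NT", None),
            SampleAnnotation("c", "NT", None),
        ]
        with pytest.raises(ValidationError, match="IBM"):
            build_contrasts(anns, hierarchy, "IBM")


def two_group_logcpm(seed=0, n_genes=80, n1=6, n2=8):
    rng = np.random.default_rng(seed)
    x = rng.normal(5, 1, size=(n_genes, n1 + n2))
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    df = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    contrast = ContrastSpec(
        name="A_vs_B",
        group_samples=frozenset(cols[:n1]),
        reference_samples=frozenset(cols[n1:]),
        kind="vs_rest",
    )
    return df, contrast


class TestFitModerated:
    def test_d0_zero_equals_ordinary_t(self):
        df, contrast = two_group_logcpm()
        res = fit_moderated(df, contrast, prior_df=0.0)
        a = df[sorted(contrast.group_samples)].to_numpy()
        b = df[sorted(contrast.reference_samples)].to_numpy()
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res.t, t_ref, atol=1e-10)
        np.testing.assert_allclose(res.p, p_ref, atol=1e-10)

    def test_d0_infinite_pools_variance(self):
        df, contrast = two_group_logcpm(seed=1)
        res = fit_moderated(df, contrast, prior_df=np.inf)
        n1, n2 = len(contrast.group_samples), len(contrast.reference_samples)
        se = np.sqrt(res.prior_var * (1 / n1 + 1 / n2))
        np.testing.assert_allclose(res.t, res.log2fc / se, atol=1e-10)
        # infinite prior df -> normal tails
        np.testing.assert_allclose(
            res.p, 2 * stats.norm.sf(np.abs(res.t)), atol=1e-12
        )

    def test_moderation_shrinks_toward_prior(self):
        df, contrast = two_group_logcpm(seed=2)
        # heterogeneous gene-wise variances so the prior df is finite
        scales = np.exp(np.random.default_rng(2).normal(0, 0.8, size=len(df)))
        df = df.mul(scales, axis=0)
        res = fit_moderated(df, contrast)
        assert 0 < res.prior_df < np.inf
        post = (res.prior_df * res.prior_var + res.df_residual * res.s2) / (
            res.prior_df + res.df_residual
        )
        lo, hi = np.minimum(res.s2, res.prior_var), np.maximum(res.s2, res.prior_var)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_swap_sides_flips_sign_keeps_p(self):
        df, contrast = two_group_logcpm(seed=3)
        flipped = ContrastSpec(
            name="B_vs_A",
            group_samples=contrast.reference_samples,
            reference_samples=contrast.group_samples,
            kind="vs_rest",
        )
        r1 = fit_moderated(df, contrast)
        r2 = fit_moderated(df, flipped)
        np.testing.assert_allclose(r1.log2fc, -r2.log2fc, atol=1e-12)
        np.testing.assert_allclose(r1.t, -r2.t, atol=1e-12)
        np.testing.assert_allclose(r1.p, r2.p, atol=1e-12)
        np.testing.assert_allclose(r1.q, r2.q, atol=1e-12)

    def test_gene_permutation_equivariance(self):
        df, contrast = two_group_logcpm(seed=4)
        perm = np.random.default_rng(0).permutation(len(df))
        r1 = fit_moderated(df, contrast)
        r2 = fit_moderated(df.iloc[perm], contrast)
        np.testing.assert_allclose(r1.q[perm], r2.q, atol=1e-12)

    def test_larger_effect_larger_t_at_fixed_variance(self):
        # two genes with identical within-group spread, different mean shift
        base = np.array([4.0, 5.0, 6.0, 4.5, 5.5])
        g1 = np.concatenate([base + 1.0, base])
        g2 = np.concatenate([base + 2.0, base])
        cols = [f"s{i}" for i in range(10)]
        df = pd.DataFrame([g1, g2], index=["g1", "g2"], columns=cols)
        contrast = ContrastSpec(
            "c", frozenset(cols[:5]), frozenset(cols[5:]), "vs_rest"
        )
        res = fit_moderated(df, contrast)
        assert abs(res.t[1]) > abs(res.t[0])

    def test_degenerate_input_rejected(self):
        cols = [f"s{i}" for i in range(6)]
        df = pd.DataFrame(np.ones((5, 6)), columns=cols)
        contrast = ContrastSpec(
            "c", frozenset(cols[:3]), frozenset(cols[3:]), "vs_rest"
        )
        with pytest.raises(ValidationError, match="degenerate"):
            fit_moderated(df, contrast)

    def test_nonfinite_input_rejected(self):
        df, contrast = two_group_logcpm(seed=5)
        df.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="finite"):
            fit_moderated(df, contrast)

    def test_missing_samples_rejected(self):
        df, contrast = two_group_logcpm(seed=6)
        with pytest.raises(ValidationError, match="missing"):
            fit_moderated(df.drop(columns=["a0"]), contrast)


class TestEstimatePrior:
    def test_recovers_known_prior(self):
        # s2 ~ s02 * chi2_d0scaled F mixture: draw gene variances from the
        # hierarchical model and check moment recovery
        rng = np.random.default_rng(0)
        d0, s02, d = 8.0, 0.5, 10
        true_var = s02 * d0 / rng.chisquare(d0, size=20000)
        s2 = true_var * rng.chisquare(d, size=20000) / d
        d0_hat, s02_hat = estimate_prior(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.1
        assert abs(s02_hat - s02) / s02 < 0.05

    def test_common_variance_gives_strong_pooling(self):
        # sample variances whose spread matches pure chi-squared noise:
        # the estimated prior df must be large (or infinite), i.e. near-full
        # pooling toward s0^2
        rng = np.random.default_rng(1)
        s2 = 0.7 * rng.chisquare(12, size=5000) / 12
        d0_hat, s02_hat = estimate_prior(s2, 12)
        assert d0_hat > 100
        assert abs(s02_hat - 0.7) / 0.7 < 0.05

    def test_exactly_constant_variances_give_infinite_d0(self):
        d0_hat, s02_hat = estimate_prior(np.full(1000, 0.7), 12)
        assert np.isinf(d0_hat)
        # bias correction assumes chi-squared sampling noise in s2, so the
        # point estimate is only approximately 0.7 for literally constant input
        assert s02_hat == pytest.approx(0.7, rel=0.15)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04], atol=1e-15
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValidationError):
            bh_adjust([-0.1])

    @staticmethod
    def oracle_bh(pvals):
        """O(m^2) literal step-up: q_(i) = min over j>=i of m p_(j) / j."""
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        q = [0.0] * m
        for rank_i, idx in enumerate(order, start=1):
            candidates = [
                m * pvals[order[rank_j - 1]] / rank_j
                for rank_j in range(rank_i, m + 1)
            ]
            q[idx] = min(1.0, min(candidates))
        return q

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_oracle(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), self.oracle_bh(pvals), atol=1e-12
        )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_monotone(self, pvals):
        p = np.asarray(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_ties_get_equal_q(self):
        q = bh_adjust([0.02, 0.5, 0.02, 0.7])
        assert q[0] == q[2]


class TestNullCalibration:
    def test_no_calls_at_alpha_on_null_simulations(self):
        clean = 0
        n_seeds = 30
        for seed in range(n_seeds):
            counts, annotations, _ = simulate_counts(null_config(seed=seed))
            lc = log_cpm(counts, tmm_factors(counts))
            ids_a = [a.sample_id for a in annotations if a.clinical_group == "GROUP_A"]
            ids_b = [a.sample_id for a in annotations if a.clinical_group == "GROUP_B"]
            contrast = ContrastSpec(
                "null", frozenset(ids_a), frozenset(ids_b), "vs_rest"
            )
            res = fit_moderated(lc, contrast)
            if (res.q < 0.001).sum() == 0:
                clean += 1
        assert clean >= n_seeds - 1

    def test_null_pvalues_approximately_uniform(self):
        counts, annotations, _ = simulate_counts(null_config(seed=5))
        lc = log_cpm(counts, tmm_factors(counts))
        ids_a = [a.sample_id for a in annotations if a.clinical_group == "GROUP_A"]
        ids_b = [a.sample_id for a in annotations if a.clinical_group == "GROUP_B"]
        res = fit_moderated(
            lc, ContrastSpec("null", frozenset(ids_a), frozenset(ids_b), "vs_rest")
        )
        assert stats.kstest(res.p, "uniform").pvalue > 0.01


def test_planted_log2fc_recovery():
    """Planted log2FC = 2 at n1 = n2 = 15: mean estimated effect within 0.15."""
    from myodiff import PlantedEffect, SimulationConfig

    # 200 planted genes inside a 2000-gene universe: a modest planted
    # fraction, so TMM can absorb the composition shift
    planted = [f"PG{i:03d}" for i in range(200)]
    config = SimulationConfig(
        seed=123,
        group_sizes={"A": 15, "B": 15},
        n_genes=2000,
        planted_effects=[PlantedEffect(g, ("A",), 2.0) for g in planted],
    )
    counts, annotations, _ = simulate_counts(config)
    lc = log_cpm(counts, tmm_factors(counts))
    ids_a = [a.sample_id for a in annotations if a.clinical_group == "A"]
    ids_b = [a.sample_id for a in annotations if a.clinical_group == "B"]
    res = fit_moderated(
        lc, ContrastSpec("A_vs_B", frozenset(ids_a), frozenset(ids_b), "vs_rest")
    )
    beta = pd.Series(res.log2fc, index=res.genes)
    assert abs(beta[planted].mean() - 2.0) < 0.15
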