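"""Normalization, differential expression, BH, and the meta-combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from metatarget import simulate as sim
from metatarget.expression import (
    ExpressionStudy,
    bh_adjust,
    differential_expression,
    group_difference_test,
    heatmap_table,
    meta_combine,
    normalize_expression,
    top_k_genes,
    volcano_table,
)


def _study(X, n_case, scale="raw", label="s"):
    X = np.asarray(X, dtype=float)
    samples = [f"x{i}" for i in range(X.shape[1])]
    group = pd.Series(
        ["case"] * n_case + ["control"] * (X.shape[1] - n_case), index=samples
    )
    return ExpressionStudy(
        X=pd.DataFrame(X, index=[f"g{i}" for i in range(X.shape[0])], columns=samples),
        group=group,
        scale_flag=scale,
        label=label,
    )


class TestNormalize:
    def test_column_scale_invariance(self, rng):
        X = rng.lognormal(2, 1, size=(50, 6))
        a = normalize_expression(_study(X, 3), "uq_log2")
        X2 = X.copy()
        X2[:, 2] *= 37.5
        b = normalize_expression(_study(X2, 3), "uq_log2")
        np.testing.assert_allclose(a.X.to_numpy(), b.X.to_numpy(), atol=1e-12)

    def test_global_scale_invariance(self, rng):
        X = rng.lognormal(2, 1, size=(30, 5))
        a = normalize_expression(_study(X, 2), "uq_log2")
        b = normalize_expression(_study(2.0 * X, 2), "uq_log2")
        np.testing.assert_allclose(a.X.to_numpy(), b.X.to_numpy(), atol=1e-12)

    def test_all_ones_log2_only(self):
        s = _study(np.ones((4, 4)), 2, scale="normalized")
        out = normalize_expression(s, "log2_only")
        assert np.allclose(out.X.to_numpy(), 1.0)
        assert out.scale_flag == "log2"

    def test_uq_log2_rejects_log_scale(self, rng):
        s = _study(rng.random((5, 4)) + 1, 2, scale="log2")
        with pytest.raises(ValueError, match="raw-scale"):
            normalize_expression(s, "uq_log2")

    def test_log2_only_rejects_log_scale(self, rng):
        s = _study(rng.random((5, 4)) + 1, 2, scale="log2")
        with pytest.raises(ValueError):
            normalize_expression(s, "log2_only")


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        half = np.arange(1.0, 13.0).reshape(3, 4)
        X = np.hstack([half, half])
        de = differential_expression(_study(X, 4, scale="log2"), "plain")
        assert np.allclose(de.table["lfc"], 0.0)
        assert np.allclose(de.table["p"], 1.0)

    def test_plain_matches_textbook_t(self, rng):
        """Plain mode equals an independent pooled two-sample t per gene."""
        X = rng.normal(5, 1, size=(50, 9))
        de = differential_expression(_study(X, 5, scale="log2"), "plain")
        for i in range(50):
            t, p = stats.ttest_ind(X[i, :5], X[i, 5:], equal_var=True)
            assert de.table["t"].iloc[i] == pytest.approx(t, rel=1e-10)
            assert de.table["p"].iloc[i] == pytest.approx(p, rel=1e-10)

    def test_eb_prior_limits(self, rng):
        """d0=0 recovers plain mode; d0=inf pools variances entirely."""
        X = rng.normal(0, 1, size=(40, 10))
        st_log = _study(X, 5, scale="log2")
        plain = differential_expression(st_log, "plain")
        eb0 = differential_expression(st_log, "eb", prior=(0.0, 1.0))
        np.testing.assert_allclose(eb0.table["t"], plain.table["t"], atol=1e-12)
        np.testing.assert_allclose(eb0.table["p"], plain.table["p"], atol=1e-12)
        ebinf = differential_expression(st_log, "eb", prior=(np.inf, 0.9))
        se = np.sqrt(0.9 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(
            ebinf.table["t"], plain.table["lfc"] / se, atol=1e-10
        )

    def test_lfc_sign_matches_group_difference(self, rng):
        X = rng.normal(0, 1, size=(30, 8))
        de = differential_expression(_study(X, 4, scale="log2"), "eb")
        diff = X[:, :4].mean(axis=1) - X[:, 4:].mean(axis=1)
        assert np.all(np.sign(de.table["lfc"]) == np.sign(diff))

    def test_requires_log_scale_and_group_sizes(self, rng):
        with pytest.raises(ValueError):
            differential_expression(_study(rng.random((5, 6)) + 1, 3), "plain")
        with pytest.raises(ValueError):
            differential_expression(
                _study(rng.random((5, 3)) + 1, 1, scale="log2"), "plain"
            )

    def test_all_zero_variance_errors(self):
        X = np.ones((4, 6))
        with pytest.raises(FloatingPointError):
            differential_expression(_study(X, 3, scale="log2"), "plain")

    def test_null_type_one_error(self):
        """Fraction of p < 0.05 under the null is 0.05 +/- 0.02."""
        spec = sim.SimulationSpec(
            seed=42, n_genes=2000, studies=[sim.StudySpec(10, 10, "null")],
            planted_lfc={}, noise_sd=0.5,
        )
        study = normalize_expression(sim.gen_expression_study(spec, 0), "uq_log2")
        de = differential_expression(study, "plain")
        frac = float((de.table["p"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.02)


def _bh_oracle(p):
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j]] * n / (j + 1) for j in range(rank_i - 1, n)), 1.0
        )
    return q


class TestBH:
    def test_stepup_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_exhaustive_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)

    def test_q_geq_p(self, rng):
        p = rng.random(50)
        assert np.all(bh_adjust(p) >= p - 1e-15)


def _de_from(lfc, p, label):
    tab = pd.DataFrame(
        {"lfc": lfc, "s2": 1.0, "df": 10.0, "t": 0.0, "p": p, "q": bh_adjust(p)},
        index=[f"g{i}" for i in range(len(lfc))],
    )
    from metatarget.expression import DEResult

    return DEResult(table=tab, label=label)


class TestMetaCombine:
    def test_stouffer_closed_form(self):
        """Two studies, p = 0.05 concordant positive: Z = 2.77180."""
        de1 = _de_from([1.0, 0.5], [0.05, 0.5], "a")
        de2 = _de_from([1.0, 0.5], [0.05, 0.5], "b")
        m = meta_combine([de1, de2])
        assert m.table.loc["g0", "z"] == pytest.approx(2.77180, abs=1e-4)
        assert m.table.loc["g0", "p"] == pytest.approx(0.00556, abs=1e-4)

    def test_opposite_signs_cancel(self):
        de1 = _de_from([1.5, 1.0], [0.01, 0.5], "a")
        de2 = _de_from([-1.5, 1.0], [0.01, 0.5], "b")
        m = meta_combine([de1, de2])
        assert m.table.loc["g0", "z"] == pytest.approx(0.0, abs=1e-12)
        assert m.table.loc["g0", "clfc"] == pytest.approx(0.0, abs=1e-12)

    def test_minmax_example(self):
        de1 = _de_from([2.0, -4.0], [0.5, 0.5], "a")
        de2 = _de_from([1.0, 1.0], [0.5, 0.5], "b")
        m = meta_combine([de1, de2])
        np.testing.assert_allclose(m.table["nlfc_a"], [0.5, -1.0])

    def test_monotone_in_p(self):
        """Decreasing a concordant study p never decreases |Z|."""
        base = _de_from([1.0], [0.2], "a")
        zs = []
        for p2 in (0.5, 0.2, 0.05, 0.001):
            other = _de_from([1.0], [p2], "b")
            zs.append(abs(meta_combine([base, other]).table["z"].iloc[0]))
        assert all(b >= a - 1e-12 for a, b in zip(zs, zs[1:]))

    def test_intersection_universe_reported(self):
        de1 = _de_from([1.0, 0.5, 0.2], [0.1, 0.2, 0.3], "a")
        de2 = _de_from([1.0, 0.5], [0.1, 0.2], "b")
        m = meta_combine([de1, de2])
        assert m.genes == ["g0", "g1"]
        assert m.dropped_genes["a"] == ["g2"]

    def test_all_zero_lfc_errors(self):
        de1 = _de_from([0.0, 0.0], [0.5, 0.5], "a")
        de2 = _de_from([1.0, 0.5], [0.5, 0.5], "b")
        with pytest.raises(ValueError, match="minmax"):
            meta_combine([de1, de2])

    def test_null_combined_p_uniform(self):
        """Under the global null, combined P is approximately uniform."""
        spec = sim.SimulationSpec(
            seed=9, n_genes=2000,
            studies=[sim.StudySpec(10, 10, "a"), sim.StudySpec(7, 4, "b"),
                     sim.StudySpec(6, 3, "c")],
            planted_lfc={}, noise_sd=0.5,
        )
        des = [
            differential_expression(
                normalize_expression(sim.gen_expression_study(spec, i), "uq_log2"),
                "plain",
            )
            for i in range(3)
        ]
        m = meta_combine(des)
        ks = stats.kstest(m.table["p"], "uniform")
        assert ks.pvalue > 0.01


class TestTopK:
    def test_full_table_is_permutation(self):
        de1 = _de_from([1.0, -0.5, 0.2], [0.01, 0.2, 0.9], "a")
        de2 = _de_from([0.8, -0.4, 0.1], [0.02, 0.3, 0.8], "b")
        m = meta_combine([de1, de2])
        full = top_k_genes(m, 3)
        assert sorted(full.index) == ["g0", "g1", "g2"]

    def test_tie_broken_by_gene_id(self):
        de1 = _de_from([1.0, 1.0], [0.5, 0.5], "a")
        de2 = _de_from([1.0, 1.0], [0.5, 0.5], "b")
        m = meta_combine([de1, de2])
        assert list(top_k_genes(m, 2).index) == ["g0", "g1"]

    def test_volcano_and_heatmap_shapes(self):
        de1 = _de_from([1.0, -0.5, 0.2], [0.01, 0.2, 0.9], "a")
        de2 = _de_from([0.8, -0.4, 0.1], [0.02, 0.3, 0.8], "b")
        m = meta_combine([de1, de2])
        assert list(volcano_table(m).columns) == ["clfc", "neg_log10_q"]
        hm = heatmap_table(m, 2)
        assert hm.shape == (2, 2)


class TestGroupDifference:
    def test_identical_multisets_p_one(self):
        u, p = group_difference_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_shifted(self):
        u, p = group_difference_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_swap_symmetry(self, rng):
        a, b = rng.random(6), rng.random(5)
        u1, p1 = group_difference_test(a, b)
        u2, p2 = group_difference_test(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert u2 == pytest.approx(len(a) * len(b) - u1)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            group_difference_test([], [1.0])

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 18)
        u, p = group_difference_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)
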