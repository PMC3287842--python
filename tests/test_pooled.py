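"""Weights, the burden score statistic, and permutation p-values.

The exhaustive-enumeration oracle here re-implements each test with explicit
loops (including per-permutation threshold re-maximization for VT) and is the
independent reference for the permutation engine.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rarepool as rp
from rarepool.pooled import _TIE_RTOL, run_gene_tests


def oracle_z(C, y):
    """Score statistic computed with explicit loops."""
    C, y = np.asarray(C, float), np.asarray(y, float)
    n = len(y)
    ybar = sum(y) / n
    sd = math.sqrt(sum((v - ybar) ** 2 for v in y) / n)
    Cbar = sum(C) / n
    ss = sum((c - Cbar) ** 2 for c in C)
    if ss == 0:
        return 0.0
    num = sum(c * (v - ybar) for c, v in zip(C, y))
    return num / (sd * math.sqrt(ss))


def oracle_exhaustive_p(counts, mafs, y, test, sided="one-sided-greater"):
    """Brute-force p over all n! phenotype orderings, re-maximizing for VT."""
    counts = np.asarray(counts, float)
    mafs = np.asarray(mafs, float)
    poly = mafs > 0
    counts, mafs = counts[:, poly], mafs[poly]
    n = counts.shape[0]

    def stat(yy):
        if test in ("T1", "T5"):
            T = 0.01 if test == "T1" else 0.05
            cols = [i for i in range(len(mafs)) if mafs[i] < T]
            zs = [oracle_z(counts[:, cols].sum(axis=1), yy)]
        elif test == "WS":
            w = [1 / math.sqrt(n * p * (1 - p)) for p in mafs]
            zs = [oracle_z(counts @ np.asarray(w), yy)]
        elif test == "VT":
            zs = [
                oracle_z(counts[:, mafs <= t].sum(axis=1), yy)
                for t in sorted(set(mafs))
            ]
        if sided == "two-sided":
            zs = [abs(z) for z in zs]
        return max(zs)

    obs = stat(np.asarray(y, float))
    hits = sum(
        1
        for perm in itertools.permutations(y)
        if stat(np.asarray(perm)) >= obs - _TIE_RTOL * max(1.0, abs(obs))
    )
    return (1 + hits) / (1 + math.factorial(n))


class TestWeights:
    def test_threshold_inclusion_is_strict(self):
        np.testing.assert_array_equal(rp.threshold_weights([0.005, 0.02], 0.01), [1, 0])
        np.testing.assert_array_equal(rp.threshold_weights([0.01], 0.01), [0])
        np.testing.assert_array_equal(rp.threshold_weights([0.1, 0.3, 0.49], 0.5), [1, 1, 1])

    def test_ws_closed_form_and_monotonicity(self, rng):
        assert rp.ws_weights([0.5], 1)[0] == pytest.approx(2.0)
        p = np.sort(rng.uniform(0.001, 0.5, 20))
        w = rp.ws_weights(p, 100)
        assert np.all(np.diff(w) < 0)  # rarer variants weigh more
        np.testing.assert_allclose(w, 1 / np.sqrt(100 * p * (1 - p)))

    def test_ws_rejects_monomorphic(self):
        with pytest.raises(ValueError, match="zero"):
            rp.ws_weights([0.0, 0.1], 10)

    def test_burden_identity_and_oracle(self, rng):
        col = rng.integers(0, 3, 6)
        np.testing.assert_allclose(rp.weighted_burden(col[:, None], [1.0]), col)
        counts = rng.integers(0, 3, (6, 4))
        w = rng.uniform(0.1, 2.0, 4)
        expect = [sum(w[i] * counts[j, i] for i in range(4)) for j in range(6)]
        np.testing.assert_allclose(rp.weighted_burden(counts, w), expect)

    def test_all_zero_weights_error(self):
        with pytest.raises(rp.NoQualifyingVariants):
            rp.weighted_burden(np.ones((4, 2)), [0.0, 0.0])


class TestZStatistic:
    def test_constant_burden_is_neutral(self):
        assert rp.z_statistic(np.ones(5), np.arange(5.0)) == 0.0

    def test_constant_phenotype_rejected(self):
        with pytest.raises(rp.DegeneratePhenotype):
            rp.z_statistic(np.arange(5.0), np.ones(5))

    def test_symmetries(self, rng):
        C = rng.integers(0, 3, 12).astype(float)
        y = rng.normal(size=12)
        z = rp.z_statistic(C, y)
        assert rp.z_statistic(C, -y) == pytest.approx(-z)
        perm = rng.permutation(12)
        assert rp.z_statistic(C[perm], y[perm]) == pytest.approx(z)

    def test_matches_loop_oracle_and_slope_sign(self, rng):
        from scipy.stats import linregress

        C = rng.integers(0, 3, 10).astype(float)
        C[0] = 2  # ensure variation
        y = rng.normal(size=10)
        z = rp.z_statistic(C, y)
        assert z == pytest.approx(oracle_z(C, y), rel=1e-12)
        assert np.sign(z) == np.sign(linregress(C, y).slope)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_scale_invariance_in_weights(self, seed):
        r = np.random.default_rng(seed)
        counts = r.integers(0, 3, (8, 3)).astype(float)
        y = r.normal(size=8)
        w = r.uniform(0.1, 2, 3)
        C = counts @ w
        if np.ptp(C) == 0:
            return
        assert rp.z_statistic(C * 7.3, y) == pytest.approx(rp.z_statistic(C, y))


class TestPermutationPvalue:
    def test_extremes_and_ties(self):
        assert rp.permutation_pvalue(5.0, [1.0] * 99) == pytest.approx(1 / 100)
        assert rp.permutation_pvalue(1.0, [1.0] * 9) == 1.0

    def test_exhaustive_add_one_consistency(self):
        y = np.array([0.3, -1.0, 0.6, 1.2, -0.4, 0.0])
        C = np.array([0, 1, 0, 2, 0, 1], float)
        perms = [rp.z_statistic(C, np.asarray(p)) for p in itertools.permutations(y)]
        obs = rp.z_statistic(C, y)
        p = rp.permutation_pvalue(obs, perms)
        hits = sum(1 for z in perms if z >= obs - 1e-12)
        assert p == (1 + hits) / (1 + 720)


class TestGeneTests:
    def test_not_testable_when_no_variant_under_threshold(self, toy_gene):
        counts, mafs, y = toy_gene
        res = run_gene_tests("g", counts, np.array([0.1, 0.2, 0.3]), y, tests=("T1", "T5"))
        assert not res["T1"].testable and not res["T5"].testable
        assert res["T1"].p_value is None

    def test_monomorphic_only_gene_not_testable(self, toy_gene):
        counts, _, y = toy_gene
        res = run_gene_tests("g", counts, np.zeros(3), y)
        assert all(not r.testable for r in res.values())

    def test_exhaustive_matches_oracle_each_test(self, toy_gene):
        counts, mafs, y = toy_gene
        plan = rp.PermutationPlan(mode="exhaustive", seed=0)
        res = run_gene_tests("g", counts, mafs, y, plan=plan)
        for t in ("T1", "T5", "WS", "VT"):
            assert res[t].p_value == oracle_exhaustive_p(counts, mafs, y, t), t
            assert res[t].n_permutations == 720

    def test_two_sided_exhaustive_matches_oracle(self, toy_gene):
        counts, mafs, y = toy_gene
        plan = rp.PermutationPlan(mode="exhaustive", seed=0)
        res = run_gene_tests("g", counts, mafs, y, plan=plan, sided="two-sided")
        for t in ("WS", "VT"):
            assert res[t].p_value == oracle_exhaustive_p(counts, mafs, y, t, "two-sided")

    def test_single_variant_ws_equals_fixed(self, rng):
        counts = rng.integers(0, 3, (40, 1))
        counts[0] = 1
        y = rng.normal(size=40)
        mafs = np.array([0.02])
        plan = rp.PermutationPlan(n_perm=499, seed=3)
        res = run_gene_tests("g", counts, mafs, y, tests=("T5", "WS"), plan=plan)
        # weights differ by a positive scalar, z is scale-invariant
        assert res["WS"].p_value == res["T5"].p_value
        assert res["WS"].statistic == pytest.approx(res["T5"].statistic)

    def test_vt_collapses_to_fixed_for_single_maf(self, rng):
        counts = rng.integers(0, 2, (30, 3))
        counts[0] = 1
        mafs = np.full(3, 0.03)
        y = rng.normal(size=30)
        plan = rp.PermutationPlan(n_perm=299, seed=9)
        res = run_gene_tests("g", counts, mafs, y, tests=("T5", "VT"), plan=plan)
        assert res["VT"].p_value == res["T5"].p_value
        assert res["VT"].optimal_threshold == pytest.approx(0.03)

    def test_vt_statistic_dominates_single_thresholds(self, rng):
        for _ in range(200):
            m = rng.integers(2, 6)
            counts = rng.integers(0, 3, (25, m))
            mafs = rng.uniform(0.01, 0.4, m)
            y = rng.normal(size=25)
            res = run_gene_tests("g", counts, mafs, y, tests=("VT",),
                                 plan=rp.PermutationPlan(n_perm=1, seed=0))
            zmax = res["VT"].statistic
            for t in np.unique(mafs):
                C = counts[:, mafs <= t].sum(axis=1)
                assert zmax >= rp.z_statistic(C, y) - 1e-12

    def test_seeded_determinism(self, toy_gene):
        counts, mafs, y = toy_gene
        plan = rp.PermutationPlan(n_perm=777, seed=42)
        a = run_gene_tests("g", counts, mafs, y, plan=plan)
        b = run_gene_tests("g", counts, mafs, y, plan=plan)
        assert a == b

    def test_binary_trait_same_linear_path(self, toy_gene):
        counts, mafs, _ = toy_gene
        y01 = np.array([0, 1, 0, 0, 1, 1])
        plan = rp.PermutationPlan(n_perm=199, seed=1)
        res_int = run_gene_tests("g", counts, mafs, y01, plan=plan)
        res_float = run_gene_tests("g", counts, mafs, y01.astype(float), plan=plan)
        assert res_int == res_float
        assert res_int["WS"].p_value is not None

    def test_wrappers_slice_by_gene(self, tiny_dataset):
        ds = tiny_dataset
        y = ds.phenotypes[0].vector("Q4", 0, sample_ids=ds.genotypes.sample_ids)
        gene = next(g for g, c in ds.gene_index.items() if len(c) > 0)
        plan = rp.PermutationPlan(n_perm=99, seed=2)
        res = rp.weighted_sum_test(gene, ds.genotypes, ds.variants, ds.gene_index, y, plan)
        combined = run_gene_tests(
            gene, ds.genotypes.counts[:, ds.gene_index[gene]],
            ds.variants["maf"].to_numpy()[ds.gene_index[gene]], y, plan=plan,
        )
        assert res == combined["WS"]  # shared stream: wrapper equals combined run

    def test_custom_fixed_threshold_naming(self, toy_gene):
        counts, mafs, y = toy_gene
        ds_gm = rp.GenotypeMatrix([f"s{i}" for i in range(6)], counts)
        import pandas as pd
        variants = pd.DataFrame({"variant_id": ["a", "b", "c"], "chrom": "1",
                                 "pos": [1, 2, 3], "maf": mafs})
        idx = {"g": np.array([0, 1, 2])}
        plan = rp.PermutationPlan(n_perm=99, seed=0)
        res = rp.fixed_threshold_test("g", ds_gm, variants, idx, y, T=0.1, plan=plan)
        assert res.test_name == "fixed(0.1)"
        assert res.n_variants_used == 2  # mafs 0.005 and 0.03 qualify, 0.2 does not

    def test_exhaustive_cap_enforced(self, rng):
        counts = rng.integers(0, 2, (12, 2))
        with pytest.raises(ValueError, match="exhaustive"):
            run_gene_tests("g", counts, np.array([0.1, 0.2]), rng.normal(size=12),
                           plan=rp.PermutationPlan(mode="exhaustive"))

    def test_pvalue_lower_bound(self, toy_gene):
        counts, mafs, y = toy_gene
        res = run_gene_tests("g", counts, mafs, y, plan=rp.PermutationPlan(n_perm=49, seed=0))
        for r in res.values():
            assert r.p_value >= 1 / 50
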