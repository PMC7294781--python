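"""Statistical core: TMM, dispersion, exact test, permutation cutoff.

Each operation is checked against an independently coded oracle: a direct
transcription of the TMM formula (plus factors frozen from a Bioconductor
edgeR run on the same seeded matrix), full enumeration of the conditional
split distribution for the exact test, and a sort-based pooled-quantile
recomputation for the permutation cutoff.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from chromdiff.diffstats import (
    CountMatrix,
    TwoGroupCountModel,
    call_differential,
    estimate_common_dispersion,
    nb_exact_test,
    permutation_fc_cutoff,
    tmm_factors,
)

from conftest import groups_for, nb_matrix


def make_cm(x: np.ndarray, n_a: int, n_b: int, lib_sizes=None) -> CountMatrix:
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    df = pd.DataFrame(np.asarray(x), columns=cols)
    ls = None if lib_sizes is None else pd.Series(lib_sizes, index=cols, dtype=float)
    return CountMatrix(counts=df, group=groups_for(df), lib_sizes=ls)


# ---------------------------------------------------------------------------
# TMM oracle: direct transcription of the trimmed weighted-mean formula


def tmm_oracle(x: np.ndarray, lib: np.ndarray, ref: int,
               trim_m=0.30, trim_a=0.05) -> np.ndarray:
    def one(k):
        if k == ref:
            return 0.0
        keep = (x[:, k] > 0) & (x[:, ref] > 0)
        o, r = x[keep, k] / lib[k], x[keep, ref] / lib[ref]
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        if np.max(np.abs(m)) < 1e-6:
            return 0.0
        w = (lib[k] - x[keep, k]) / (lib[k] * x[keep, k]) + (
            lib[ref] - x[keep, ref]
        ) / (lib[ref] * x[keep, ref])
        n = m.size
        rm = pd.Series(m).rank().values
        ra = pd.Series(a).rank().values
        lo_m, lo_a = math.floor(n * trim_m) + 1, math.floor(n * trim_a) + 1
        sel = (
            (rm >= lo_m) & (rm <= n + 1 - lo_m)
            & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        )
        return np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])

    logf = np.array([one(k) for k in range(x.shape[1])])
    f = 2.0 ** logf
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_scaled_column_gives_unit_factors(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=200)
        x = np.column_stack([base, 2 * base])
        f = tmm_factors(make_cm(x, 1, 1)).factors.values
        np.testing.assert_allclose(f, [1.0, 1.0])

    def test_identical_columns_give_unit_factors(self):
        x = np.tile(np.arange(1, 101)[:, None], (1, 4))
        f = tmm_factors(make_cm(x, 2, 2)).factors.values
        np.testing.assert_allclose(f, np.ones(4))

    def test_matches_direct_formula_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n_s = int(rng.integers(2, 7))
            x = rng.negative_binomial(5, 0.05, size=(150, n_s))
            x[: rng.integers(5, 30), rng.integers(n_s)] *= int(rng.integers(2, 6))
            cm = make_cm(x, 1, n_s - 1)
            res = tmm_factors(cm)
            ref = list(cm.sample_ids).index(res.ref_sample)
            expected = tmm_oracle(x.astype(float), cm.lib_sizes.values, ref)
            np.testing.assert_allclose(res.factors.values, expected, atol=1e-8)

    def test_matches_frozen_edger_factors(self):
        """Factors agree with Bioconductor edgeR::calcNormFactors(method='TMM')
        computed once on this same seeded matrix."""
        rng = np.random.default_rng(42)
        x = rng.negative_binomial(5, 0.05, size=(200, 4))
        x[:20, 2] *= 4
        f = tmm_factors(make_cm(x, 2, 2)).factors.values
        edger = [1.052978396726, 1.045735089857, 0.863348927530, 1.051895274011]
        np.testing.assert_allclose(f, edger, atol=1e-8)

    def test_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(100, size=(300, 4))
        f1 = tmm_factors(make_cm(x, 2, 2)).factors.values
        y = x.copy()
        y[:, 1] *= 5  # global rescale of one column is absorbed by its library
        f2 = tmm_factors(make_cm(y, 2, 2)).factors.values
        # M and A are scale-free so the trim set is identical; only the
        # precision weights feel the absolute depth, leaving a tiny residual
        np.testing.assert_allclose(f1, f2, atol=1e-2)
        assert abs(np.prod(f2) - 1.0) < 1e-12


class TestCommonDispersion:
    def test_poisson_truth_estimates_near_zero(self):
        rng = np.random.default_rng(7)
        df = nb_matrix(rng, 2000, mean=100, phi=0.0)
        cm = CountMatrix(counts=df, group=groups_for(df))
        assert estimate_common_dispersion(cm) < 0.02

    @pytest.mark.parametrize("method", ["moments", "profile"])
    def test_nb_truth_recovered(self, method):
        rng = np.random.default_rng(8)
        df = nb_matrix(rng, 2000, mean=100, phi=0.1)
        cm = CountMatrix(counts=df, group=groups_for(df))
        phi = estimate_common_dispersion(cm, method=method)
        assert 0.07 <= phi <= 0.13

    def test_constant_counts_give_zero(self):
        x = np.full((50, 6), 20)
        cm = make_cm(x, 3, 3)
        assert estimate_common_dispersion(cm) == 0.0


# ---------------------------------------------------------------------------
# exact test: full-enumeration oracle


def exact_p_oracle(s_a: int, s_total: int, n_a: int, n_b: int, phi: float) -> float:
    """Enumerate all splits of S between the group sums and add up the
    probabilities of splits at most as likely as the observed one."""
    a = np.arange(s_total + 1)
    if phi == 0.0:
        p = n_a / (n_a + n_b)
        logp = (
            gammaln(s_total + 1) - gammaln(a + 1) - gammaln(s_total - a + 1)
            + a * np.log(p) + (s_total - a) * np.log1p(-p)
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            gammaln(a + r_a) - gammaln(a + 1)
            + gammaln(s_total - a + r_b) - gammaln(s_total - a + 1)
        )
        m = logp.max()
        logp = logp - (m + np.log(np.exp(logp - m).sum()))
    probs = np.exp(logp)
    return min(1.0, float(probs[probs <= probs[s_a] * (1 + 1e-9)].sum()))


class TestExactTest:
    def test_balanced_split_has_p_one(self):
        res = nb_exact_test(make_cm([[5, 5]], 1, 1, lib_sizes=[100, 100]))
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_extreme_split_matches_binomial_tail(self):
        res = nb_exact_test(make_cm([[0, 20]], 1, 1, lib_sizes=[100, 100]))
        # two-sided doubling of the most extreme split under Binomial(20, 1/2)
        assert res["p_value"].iloc[0] == pytest.approx(2 * 0.5**20, rel=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.2, 1.0])
    def test_matches_enumeration_oracle(self, phi):
        rng = np.random.default_rng(31)
        x = rng.poisson(8, size=(60, 12))
        cm = make_cm(x, 6, 6, lib_sizes=np.full(12, 5000.0))
        res = nb_exact_test(cm, dispersion=phi)
        s_a = x[:, :6].sum(axis=1)
        s = x.sum(axis=1)
        for i in range(len(s)):
            if s[i] > 200:
                continue
            expected = exact_p_oracle(int(s_a[i]), int(s[i]), 6, 6, phi)
            assert res["p_value"].iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_null_p_values_roughly_uniform(self):
        """Empirical P(p < .05) within [0.03, 0.07] on null NB data."""
        rng = np.random.default_rng(202)
        df = nb_matrix(rng, 2000, mean=100, phi=0.1)
        cm = CountMatrix(counts=df, group=groups_for(df))
        f = tmm_factors(cm)
        phi = estimate_common_dispersion(cm, f)
        res = nb_exact_test(cm, f, phi)
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(make_cm([[1, 2]], 1, 1), dispersion=-0.1)


# ---------------------------------------------------------------------------
# permutation cutoff


class TestPermutationCutoff:
    def test_identical_columns_give_zero_cutoff(self):
        x = np.tile(np.arange(10, 110)[:, None], (1, 8))
        cm = make_cm(x, 4, 4)
        cut = permutation_fc_cutoff(cm, n_permutations=50, seed=1)
        assert cut.cutoff == 0.0

    def test_literal_mode_below_upper_tail_mode(self):
        rng = np.random.default_rng(3)
        df = nb_matrix(rng, 200, mean=50, phi=0.1)
        cm = CountMatrix(counts=df, group=groups_for(df))
        lit = permutation_fc_cutoff(cm, n_permutations=100, mode="literal", seed=4)
        up = permutation_fc_cutoff(cm, n_permutations=100, mode="upper-tail", seed=4)
        assert lit.cutoff <= up.cutoff

    def test_matches_pooled_quantile_oracle(self):
        """Cutoffs equal a from-scratch recomputation: same relabelings
        (reconstructed from the seeded generator), pooled |log2fc| via
        explicit sort-based quantile."""
        rng = np.random.default_rng(17)
        df = nb_matrix(rng, 200, mean=50, phi=0.1)
        cm = CountMatrix(counts=df, group=groups_for(df))
        for mode in ("literal", "upper-tail"):
            cut = permutation_fc_cutoff(
                cm, n_permutations=100, mode=mode, seed=99
            )
            assert cut.null_pool_size == 100 * 200
            pool = _oracle_pool(cm, n_permutations=100, seed=99)
            q = 0.10 if mode == "literal" else 0.90
            assert cut.cutoff == pytest.approx(np.quantile(pool, q), abs=1e-12)

    def test_deterministic_given_seed_and_counts_distinct(self):
        rng = np.random.default_rng(23)
        df = nb_matrix(rng, 50, mean=30, phi=0.1, n_a=3, n_b=3)
        cm = CountMatrix(counts=df, group=groups_for(df))
        c1 = permutation_fc_cutoff(cm, n_permutations=100, seed=5)
        c2 = permutation_fc_cutoff(cm, n_permutations=100, seed=5)
        assert c1.cutoff == c2.cutoff
        # C(6,3) = 20 minus identity and its label swap = 18 distinct splits
        assert c1.n_distinct_used == 18

    def test_rejects_zero_permutations(self):
        df = nb_matrix(np.random.default_rng(0), 10, 10, 0.0, 2, 2)
        cm = CountMatrix(counts=df, group=groups_for(df))
        with pytest.raises(ValueError):
            permutation_fc_cutoff(cm, n_permutations=0)


def _oracle_pool(cm: CountMatrix, n_permutations: int, seed: int) -> np.ndarray:
    """Re-derive the pooled null |log2fc| values independently."""
    import itertools

    rng = np.random.default_rng(seed)
    eff = cm.lib_sizes.values  # unit factors in these tests
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.round(cm.counts.values * (common / eff)).astype(np.int64)
    mask_a, mask_b = cm.group_masks
    n_b = int(mask_b.sum())
    excluded = {frozenset(np.flatnonzero(mask_b)), frozenset(np.flatnonzero(mask_a))}
    distinct = [
        frozenset(c)
        for c in itertools.combinations(range(mask_b.size), n_b)
        if frozenset(c) not in excluded
    ]
    order = rng.permutation(len(distinct))
    picks = [distinct[i] for i in order[:n_permutations]]
    while len(picks) < n_permutations:
        picks.append(distinct[int(rng.integers(len(distinct)))])
    vals = []
    for c in picks:
        m = np.zeros(mask_b.size, dtype=bool)
        m[list(c)] = True
        mb = pseudo[:, m].sum(axis=1) / m.sum()
        ma = pseudo[:, ~m].sum(axis=1) / (mask_b.size - m.sum())
        vals.append(np.abs(np.log2((mb + 0.5) / (ma + 0.5))))
    return np.concatenate(vals)


class TestCallDifferential:
    def test_boundary_rules_are_strict(self):
        table = pd.DataFrame(
            {
                "log2fc": [1.0, 5.0, 1.5, -2.0, 0.1],
                "p_value": [0.04, 0.06, 0.04, 0.01, 0.001],
            },
            index=[f"r{i}" for i in range(5)],
        )
        out = call_differential(table, alpha=0.05, cutoff=1.0)
        # |log2fc| == cutoff fails; p == alpha would fail; both strict
        assert list(out["passes"]) == [False, False, True, True, False]
        assert list(out["direction"]) == [0, 0, 1, -1, 0]


class TestModelResults:
    def test_fit_returns_consistent_results_object(self):
        rng = np.random.default_rng(77)
        fc = np.zeros(300)
        fc[:60] = 2.0
        df = nb_matrix(rng, 300, mean=100, phi=0.1, log2fc=fc)
        model = TwoGroupCountModel(df, groups_for(df))
        res = model.fit(n_permutations=100, seed=11)
        assert set(res.table.columns) >= {
            "log2fc", "p_value", "passes", "direction"
        }
        assert res.n_significant == res.table["passes"].sum()
        # planted rows dominate the calls
        called = set(res.significant().index)
        assert len(called & set(df.index[:60])) >= 50
        text = res.summary()
        assert "dispersion" in text and str(res.n_significant) in text
        meta = res.run_metadata()
        assert meta["n_permutations"] == 100 and 0 < meta["cutoff"] < 10
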