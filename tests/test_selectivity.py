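"""d' statistic, permutation null, p-values and grouped FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gammatopo.selectivity import (
    dprime, dprime_all, permutation_null, permutation_pvalue, fdr_correct,
    selectivity_table,
)


def dprime_reference(means, sds, j):
    """Independent direct evaluation of the d' formula."""
    others = [i for i in range(len(means)) if i != j]
    num = means[j] - sum(means[i] for i in others) / len(others)
    den = (0.5 * (sds[j] ** 2
                  + sum(sds[i] ** 2 for i in others) / len(others))) ** 0.5
    return num / den


class TestDPrime:
    def test_symmetric_summaries_give_zero(self):
        m, s = np.full(5, 3.0), np.full(5, 2.0)
        assert all(dprime(m, s, j) == 0.0 for j in range(5))

    def test_unit_effect_unit_variance(self):
        m = np.array([1.0, 0, 0, 0, 0])
        s = np.ones(5)
        assert dprime(m, s, 0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_reference_formula(self, rng):
        for _ in range(50):
            m = rng.normal(0, 5, 5)
            s = rng.uniform(0.1, 3, 5)
            for j in range(5):
                assert dprime(m, s, j) == pytest.approx(
                    dprime_reference(m, s, j), rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dprime(np.zeros(5), np.zeros(5), 0)
        with pytest.raises(ValueError):
            dprime(np.array([1.0]), np.array([1.0]), 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0), st.floats(-50.0, 50.0),
           st.integers(0, 2**31 - 1))
    def test_affine_invariance(self, a, b, seed):
        """d' is unchanged when every trial value maps to a*v + b, a>0."""
        r = np.random.default_rng(seed)
        values = r.normal(0, 1, 50)
        labels = np.repeat(np.arange(5).astype(str), 10)
        d1 = dprime_all(values, labels)
        d2 = dprime_all(a * values + b, labels)
        assert np.allclose(d1, d2, rtol=1e-9, atol=1e-9)

    def test_two_category_sign_symmetry(self, rng):
        values = rng.normal(0, 1, 20)
        labels = np.repeat(["a", "b"], 10)
        d = dprime_all(values, labels)
        assert d[0] == pytest.approx(-d[1], rel=1e-9)


class TestPermutationNull:
    def test_matches_exhaustive_enumeration(self):
        """Toy case: all C(6,3)=20 assignments enumerable exactly."""
        values = np.array([0.3, -1.2, 0.7, 2.1, -0.5, 1.4])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        exact = []
        for pick in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(pick)] = "a"
            exact.append(dprime_all(values, lab, np.array(["a", "b"]))[0])
        # round to 8 decimals so fp noise between paths cannot split atoms
        exact = np.sort(np.round(exact, 8))
        null = np.round(
            permutation_null(values, labels, n_perm=10_000, seed=7)[:, 0], 8)
        # KS distance against the exact discrete CDF, evaluated at its atoms
        grid = np.unique(exact)
        f_exact = np.searchsorted(exact, grid, side="right") / exact.size
        f_null = np.searchsorted(np.sort(null), grid, side="right") / null.size
        assert np.abs(f_exact - f_null).max() < 0.05

    def test_fixed_seed_identical(self):
        values = np.arange(20.0)
        labels = np.repeat(list("abcde"), 4)
        a = permutation_null(values, labels, n_perm=200, seed=3)
        b = permutation_null(values, labels, n_perm=200, seed=3)
        assert np.array_equal(a, b)

    def test_null_quantile_uniform(self, rng):
        """Observed d' sits at a uniform quantile under exchangeability."""
        qs = []
        for _ in range(200):
            values = rng.standard_normal(25)
            labels = np.repeat(list("abcde"), 5)
            obs = dprime_all(values, labels)[0]
            null = permutation_null(values, labels, n_perm=99,
                                    seed=rng.integers(2**31))[:, 0]
            qs.append((null < obs).mean())
        assert stats.kstest(qs, "uniform").pvalue > 0.01

    def test_invalid_nperm(self):
        with pytest.raises(ValueError):
            permutation_null(np.arange(10.0), np.repeat(["a", "b"], 5), n_perm=0)


class TestPermutationPValue:
    def test_observed_above_all_null_gives_zero(self):
        assert permutation_pvalue(15.0, np.arange(10.0)) == 0.0

    def test_median_case(self):
        null = np.arange(101.0)[:, None]   # distinct, odd count
        p = permutation_pvalue(50.0, null)
        assert p == pytest.approx((101 - 1) / 2 / 101)

    def test_counting_oracle(self, rng):
        null = rng.normal(0, 1, (10, 1))
        obs = 0.3
        expected = sum(1 for v in null[:, 0] if v > obs) / 10
        assert permutation_pvalue(obs, null) == pytest.approx(expected)

    def test_ties_count_as_not_greater(self):
        null = np.array([[1.0], [1.0], [2.0]])
        assert permutation_pvalue(1.0, null) == pytest.approx(1 / 3)

    def test_conservative_correction(self):
        null = np.arange(9.0)[:, None]
        assert permutation_pvalue(10.0, null, conservative=True) == \
            pytest.approx(1 / 10)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.nan, np.ones((5, 1)))


def bh_reference(p, q):
    """Hand-executed BH step-up."""
    order = np.argsort(p)
    m = len(p)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k = rank
    flags = np.zeros(m, bool)
    flags[order[:k]] = True
    return flags


class TestFDR:
    def test_all_zero_all_flagged(self):
        flags, cutoffs = fdr_correct(np.zeros(7), q=0.01)
        assert flags.all()

    def test_hand_executed_stepup(self):
        p = np.array([0.001, 0.002, 0.5, 0.9])
        flags, cutoffs = fdr_correct(p, q=0.01)
        assert flags.tolist() == [True, True, False, False]
        assert cutoffs[0] == pytest.approx(0.002)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_reference_on_random_vectors(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(0, 1, 40) ** 3
        flags, _ = fdr_correct(p, q=0.05)
        assert np.array_equal(flags, bh_reference(p, 0.05))

    def test_order_invariance(self, rng):
        p = rng.uniform(0, 1, 30) ** 2
        fam = rng.choice(["u", "v"], 30)
        flags, _ = fdr_correct(p, fam, q=0.05)
        perm = rng.permutation(30)
        flags_p, _ = fdr_correct(p[perm], fam[perm], q=0.05)
        assert np.array_equal(flags[perm], flags_p)

    def test_families_corrected_separately(self):
        # same p-vector, flags depend on family composition
        p = np.array([0.004, 0.5, 0.6, 0.004, 0.004, 0.004])
        fam = np.array(["A", "A", "A", "B", "B", "B"])
        flags, _ = fdr_correct(p, fam, q=0.01)
        assert flags.tolist() == [False, False, False, True, True, True]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.5, 1.5]))


@pytest.fixture(scope="module")
def planted():
    """Scalar-level study: 20 electrodes, 10 with a large planted effect."""
    rng = np.random.default_rng(42)
    cats = np.array(["face", "animate", "place", "tool", "word"])
    trial_values = {}
    geo_rows = []
    truth = {}
    for e in range(20):
        labels = np.repeat(cats, 12)
        values = rng.standard_normal(labels.size)
        selective = e < 10
        if selective:
            values[labels == "face"] += 2.0
        eid = f"e{e:02d}"
        truth[eid] = selective
        trial_values[eid] = (values, labels)
        geo_rows.append({"electrode": eid, "subject": f"S{e % 4}",
                         "hemisphere": "L", "region": "VTC",
                         "x": 0.0, "y": 0.0, "z": 0.0})
    geometry = pd.DataFrame(geo_rows).set_index("electrode")
    table = selectivity_table(trial_values, geometry, cats,
                              n_perm=2000, q=0.01, seed=11)
    return table, truth


class TestSelectivityTable:
    def test_planted_recovery(self, planted):
        table, truth = planted
        face = table[table["category"] == "face"]
        hits = {r["electrode"] for _, r in face.iterrows() if r["fdr_flag"]}
        planted_set = {e for e, s in truth.items() if s}
        assert len(hits & planted_set) >= 9
        false_pos = table[table["fdr_flag"]
                          & ~table["electrode"].isin(planted_set)]
        assert len(false_pos) <= 1

    def test_global_null_few_flags(self):
        rng = np.random.default_rng(5)
        cats = np.array(["face", "animate", "place", "tool", "word"])
        trial_values = {}
        geo_rows = []
        for e in range(60):
            labels = np.repeat(cats, 8)
            trial_values[f"e{e}"] = (rng.standard_normal(labels.size), labels)
            geo_rows.append({"electrode": f"e{e}", "subject": "S0",
                             "hemisphere": "L", "region": "VTC",
                             "x": 0.0, "y": 0.0, "z": 0.0})
        geometry = pd.DataFrame(geo_rows).set_index("electrode")
        table = selectivity_table(trial_values, geometry, cats, n_perm=500,
                                  q=0.01, seed=1)
        assert table["fdr_flag"].sum() <= 2

    def test_missing_category_recorded_as_nan(self, rng):
        cats = np.array(["face", "animate", "place", "tool", "word"])
        labels = np.repeat(cats[:4], 10)   # no word trials
        trial_values = {"e0": (rng.standard_normal(labels.size), labels)}
        geometry = pd.DataFrame([{"electrode": "e0", "subject": "S0",
                                  "hemisphere": "R", "region": "VTC",
                                  "x": 0, "y": 0, "z": 0}]).set_index("electrode")
        table = selectivity_table(trial_values, geometry, cats, n_perm=100,
                                  seed=0)
        word = table[table["category"] == "word"].iloc[0]
        assert np.isnan(word["d_prime"]) and not word["fdr_flag"]
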