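"""Unit and property tests for the four DE engines and their plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degconsensus import assign_status, bh_adjust, eb_test, nb_exact_test, nb_wald_test, noise_test
from degconsensus.engines import DispersionModel, estimate_dispersion
from degconsensus.engines._eb import EBHyperparams, marginal_loglik
from degconsensus.engines._nb_exact import exact_conditional_pvalue
from degconsensus.engines._nb_wald import wald_pvalue
from degconsensus.engines._noise import noise_probability

from conftest import toy_dataset


def bh_oracle(p):
    """Independent Benjamini-Hochberg step-up: sort, scale, cummin from top."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def binomial_halves_pvalue(a, s):
    """Exact two-sided conditional p at phi=0, 1 vs 1, in integer arithmetic."""
    obs = math.comb(s, a)
    num = sum(math.comb(s, k) for k in range(s + 1) if math.comb(s, k) <= obs)
    return num / 2**s


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.5,), (0.5,)),
            ((0.005, 0.04, 0.05), (0.015, 0.05, 0.05)),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_oracle_and_is_monotone(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestAssignStatus:
    @pytest.mark.parametrize(
        "lfc, expected", [(1.5, "up"), (-0.3, "down"), (0.0, "zero_value")]
    )
    def test_examples(self, lfc, expected):
        assert assign_status(lfc) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            assign_status(float("nan"))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(allow_nan=False, allow_infinity=False))
    def test_sign_rule(self, lfc):
        status = assign_status(lfc)
        assert status == ("up" if lfc > 0 else "down" if lfc < 0 else "zero_value")


class TestExactConditional:
    def test_poisson_limit_worked_example(self):
        # total 4 split (3,1), 1 vs 1 samples: probs (1,4,6,4,1)/16, p = 10/16
        assert exact_conditional_pvalue(3, 1, 1, 1, 0.0) == pytest.approx(0.625, abs=1e-12)

    @pytest.mark.parametrize("s", [1, 5, 17, 50])
    def test_binomial_oracle_small_totals(self, s):
        for a in range(s + 1):
            assert exact_conditional_pvalue(a, s - a, 1, 1, 0.0) == pytest.approx(
                binomial_halves_pvalue(a, s), abs=1e-9
            )

    def test_balanced_observed_split_gives_p_one(self):
        assert exact_conditional_pvalue(10, 10, 2, 2, 0.1) == pytest.approx(1.0)

    def test_symmetry_in_groups(self):
        p1 = exact_conditional_pvalue(30, 5, 3, 3, 0.2)
        p2 = exact_conditional_pvalue(5, 30, 3, 3, 0.2)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_large_total_window_matches_enumeration(self):
        # window path (total above the enumeration cap) against direct
        # enumeration of all splits
        from scipy import stats

        s1, s2, n1, n2, phi = 6000, 6100, 3, 3, 0.05
        s = s1 + s2
        r = n1 / phi
        m1 = s * n1 / (n1 + n2)
        a = np.arange(s + 1)
        logp = stats.nbinom.logpmf(a, r, r / (r + m1)) + stats.nbinom.logpmf(
            s - a, r, r / (r + m1)
        )
        probs = np.exp(logp - logp.max())
        expected = probs[probs <= probs[s1] * (1 + 1e-12)].sum() / probs.sum()
        assert exact_conditional_pvalue(s1, s2, n1, n2, phi) == pytest.approx(
            expected, rel=1e-9
        )


class TestNbExactEngine:
    def test_equal_group_sums_give_p_one(self):
        counts = np.array(
            [[5, 5, 5, 5], [20, 30, 30, 20], [100, 50, 50, 100]]
        )
        ds = toy_dataset(counts, 2, 2)
        res = nb_exact_test(ds)
        np.testing.assert_allclose(res.table["raw_score"], 1.0)
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)

    def test_poisson_limit_engine_path(self):
        ds = toy_dataset(np.array([[3, 1], [1, 3]]), 1, 1)
        zeros = np.zeros(2)
        disp = DispersionModel(zeros, 0.0, zeros, zeros, 0.7, "common")
        res = nb_exact_test(ds, disp=disp)
        assert res.table.loc["g1", "raw_score"] == pytest.approx(0.625, abs=1e-9)
        assert res.table.loc["g2", "raw_score"] == pytest.approx(0.625, abs=1e-9)


class TestWald:
    def test_worked_z_example(self):
        # z = 1 / 0.5 = 2 -> p = 2 Phi(-2) = 0.0455
        assert wald_pvalue(1.0, 0.5) == pytest.approx(0.0455, abs=5e-5)

    def test_equal_means_give_null_result(self):
        counts = np.tile(np.array([[7], [40], [500]]), (1, 6))
        ds = toy_dataset(counts, 3, 3)
        res = nb_wald_test(ds)
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["raw_score"], 1.0)
        assert (res.table["status"] == "zero_value").all()


class TestNoise:
    def test_zero_signal_has_zero_probability(self):
        prob = noise_probability(0.0, 0.0, np.array([0.5, 1.0]), np.array([10.0, 20.0]))
        assert prob[0] == 0.0

    def test_dominant_signal_has_probability_one(self):
        prob = noise_probability(5.0, 100.0, np.array([0.5, 1.0]), np.array([10.0, 20.0]))
        assert prob[0] == 1.0

    def test_counting_worked_example(self):
        # exactly one of the two noise points is dominated
        prob = noise_probability(0.8, 15.0, np.array([0.5, 1.0]), np.array([10.0, 20.0]))
        assert prob[0] == pytest.approx(0.5)

    def test_requires_replicates(self):
        ds = toy_dataset(np.array([[3, 5], [8, 2]]), 1, 1)
        with pytest.raises(ValueError, match="requires replicates"):
            noise_test(ds)


class TestEb:
    def _sim_ds(self, small_sim):
        return small_sim[0]

    def test_pinned_pi_degenerate(self, small_sim):
        ds = small_sim[0]
        flat = eb_test(ds, pi_de=0.0)
        np.testing.assert_allclose(1.0 - flat.table["raw_score"], 0.0)
        full = eb_test(ds, pi_de=1.0)
        np.testing.assert_allclose(1.0 - full.table["raw_score"], 1.0)

    def test_separated_gene_scores_above_flat_gene(self):
        counts = np.array(
            [
                [50, 55, 45, 52, 48, 50],  # flat
                [10, 12, 9, 100, 110, 95],  # 10-fold separated
                [30, 28, 33, 29, 31, 30],
                [80, 75, 86, 82, 77, 79],
            ]
        )
        ds = toy_dataset(counts, 3, 3)
        hyper = EBHyperparams(alpha=2.0, beta=3.0, r=np.full(4, 10.0), pi_de=0.5)
        res = eb_test(ds, hyper=hyper)
        ppde = 1.0 - res.table["raw_score"]
        assert ppde.loc["g2"] > ppde.loc["g1"]

    def test_marginal_matches_numerical_integration(self):
        # independent oracle: integrate the beta-NB marginal numerically
        from scipy import integrate, stats

        counts = np.array([[3, 7, 5]])
        sizes = np.array([[4.0, 5.0, 6.0]])
        alpha, beta = 2.0, 3.0

        def integrand(q):
            val = stats.beta.pdf(q, alpha, beta)
            for x, r in zip(counts[0], sizes[0]):
                val *= stats.nbinom.pmf(x, r, q)
            return val

        expected, _ = integrate.quad(integrand, 0, 1)
        got = marginal_loglik(counts, sizes, alpha, beta)[0]
        assert got == pytest.approx(np.log(expected), abs=1e-8)


class TestCrossEngineContracts:
    def test_identical_gene_universes(self, small_sim):
        ds, _ = small_sim
        results = [f(ds) for f in (nb_exact_test, nb_wald_test, noise_test, eb_test)]
        universes = [tuple(r.genes) for r in results]
        assert all(u == universes[0] for u in universes[1:])

    @pytest.mark.parametrize(
        "engine", [nb_exact_test, nb_wald_test, noise_test, eb_test],
        ids=["nb_exact", "nb_wald", "noise", "eb"],
    )
    def test_label_swap_antisymmetry(self, small_sim, engine):
        ds, _ = small_sim
        fwd = engine(ds)
        rev = engine(ds.swap_conditions())
        np.testing.assert_allclose(
            rev.table["log2fc"], -fwd.table["log2fc"], atol=1e-9
        )
        np.testing.assert_allclose(
            rev.table["raw_score"], fwd.table["raw_score"], atol=1e-9
        )

    def test_dispersion_moment_estimator_recovers_truth_order(self):
        # NB data at phi=0.3 should yield raw estimates centred near 0.3
        rng = np.random.default_rng(5)
        phi = 0.3
        r = 1 / phi
        mu = 200.0
        x = rng.negative_binomial(r, r / (r + mu), size=(2000, 8)).astype(float)
        disp = estimate_dispersion(x, np.arange(4), np.arange(4, 8), mode="common")
        assert disp.common == pytest.approx(phi, rel=0.25)
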