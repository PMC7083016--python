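"""Kernels, plug-in entropy/MI and contributed information against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from npem.entropy import (
    EPS_BW,
    InfoScore,
    KernelSpec,
    MICache,
    Variable,
    contributed_information,
    entropy,
    joint_density,
    kde_aitchison_aitken,
    kde_gaussian,
    mutual_information,
    silverman_bandwidth,
)


def brute_mi_from_table(table: np.ndarray) -> float:
    """Independent oracle: empirical MI of a contingency table by double sum."""
    n = table.sum()
    p = table / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return mi


def table_to_samples(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for (i, j), c in np.ndenumerate(table):
        xs += [i] * int(c)
        ys += [j] * int(c)
    return np.array(xs), np.array(ys)


class TestSilvermanBandwidth:
    def test_two_point_sample(self):
        # 1.06 * min(sd, IQR/1.34) * n**(-1/5); IQR({0,1}) = 0.5 (linear quantiles)
        expect = 1.06 * (0.5 / 1.34) * 2 ** (-0.2)
        assert silverman_bandwidth(np.array([0.0, 1.0])) == pytest.approx(expect, rel=1e-12)

    def test_constant_sample_floored(self):
        assert silverman_bandwidth(np.full(10, 3.3)) == EPS_BW

    def test_standard_normal_scale(self, rng):
        bw = silverman_bandwidth(rng.standard_normal(100))
        assert 0.2 < bw < 0.8  # 1.06 * 1 * 100**(-0.2) ~ 0.42

    def test_too_short(self):
        with pytest.raises(ValueError):
            silverman_bandwidth(np.array([1.0]))


class TestGaussianKDE:
    def test_single_point_at_center(self):
        d = kde_gaussian(np.array([0.0]), np.array([0.0]), 1.0)
        assert d[0] == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-12)

    def test_two_point_average(self):
        d = kde_gaussian(np.array([-1.0, 1.0]), np.array([0.0]), 1.0)
        assert d[0] == pytest.approx(stats.norm.pdf(1.0), rel=1e-12)

    def test_tail_decay(self, rng):
        x = rng.normal(size=30)
        far = x.max() + 15.0  # > 10 bandwidths past the data
        assert kde_gaussian(x, np.array([far]), 0.5)[0] < 1e-8

    def test_integrates_to_one(self, rng):
        x = rng.normal(size=25)
        grid = np.linspace(x.min() - 8, x.max() + 8, 4000)
        dens = kde_gaussian(x, grid, silverman_bandwidth(x))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            kde_gaussian(np.array([0.0, 1.0]), np.array([0.0]), 0.0)


class TestAitchisonAitken:
    @pytest.mark.parametrize(
        "sample, lam, alphabet, expected",
        [
            ([0, 0, 1, 1], 0.0, None, {0: 0.5, 1: 0.5}),
            ([0, 0, 0, 0], 0.5, [0, 1], {0: 0.5, 1: 0.5}),  # maximal smoothing
            ([0, 0, 0, 1], 0.1, None, {0: 0.7, 1: 0.3}),
        ],
    )
    def test_pointwise(self, sample, lam, alphabet, expected):
        cats = np.array(sorted(expected))
        p = kde_aitchison_aitken(np.array(sample), cats, lam, alphabet)
        for c, v in expected.items():
            assert p[list(cats).index(c)] == pytest.approx(v, rel=1e-12)
        assert p.sum() == pytest.approx(1.0, rel=1e-12)

    def test_category_outside_alphabet(self):
        with pytest.raises(ValueError):
            kde_aitchison_aitken(np.array([0, 1]), np.array([2]), 0.0)

    def test_invalid_smoothing(self):
        with pytest.raises(ValueError):
            kde_aitchison_aitken(np.array([0, 1]), np.array([0]), 0.9)


class TestJointDensity:
    def test_product_of_degenerate_marginals(self):
        vars_ = [Variable(np.array([2.0])), Variable(np.array([5.0]))]
        specs = [KernelSpec("gaussian", 1.0), KernelSpec("gaussian", 2.0)]
        got = joint_density(vars_, np.array([[2.0, 5.0]]), specs)[0]
        expect = stats.norm.pdf(0, scale=1.0) * stats.norm.pdf(0, scale=2.0)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_mixed_toy_hand_computed(self):
        x = Variable(np.array([0.0, 1.0, 2.0]))
        z = Variable(np.array([0, 1, 0]), "categorical")
        specs = [KernelSpec("gaussian", 0.8), KernelSpec("aitchison_aitken", 0.1)]
        got = joint_density([x, z], np.array([[1.0, 0]]), specs)[0]
        gauss = stats.norm.pdf(np.array([1.0, 0.0, -1.0]), scale=0.8) / 1.0
        aa = np.array([0.9, 0.1, 0.9])
        assert got == pytest.approx(float((gauss * aa).mean()), rel=1e-12)

    def test_marginalizing_discrete_recovers_continuous_kde(self, rng):
        x = rng.normal(size=15)
        z = rng.integers(0, 3, size=15)
        vx, vz = Variable(x), Variable(z, "categorical")
        specs = [KernelSpec("gaussian", 0.5), KernelSpec("aitchison_aitken", 0.2)]
        pts = np.linspace(-2, 2, 7)
        total = sum(
            joint_density([vx, vz], np.column_stack([pts, np.full(7, c)]), specs)
            for c in (0, 1, 2)
        )
        marginal = kde_gaussian(x, pts, 0.5)
        np.testing.assert_allclose(total, marginal, atol=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            joint_density([Variable(np.array([0.0, 1.0]))], np.array([[0.0, 1.0]]))


class TestEntropy:
    def test_fair_binary(self):
        assert entropy(Variable(np.array([0, 1, 0, 1]), "categorical")) == pytest.approx(
            np.log(2), rel=1e-12
        )

    def test_constant_categorical(self):
        assert entropy(Variable(np.array([3, 3, 3, 3]), "categorical")) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_four_category_frequencies(self):
        # frequencies (1/2, 1/4, 1/8, 1/8) -> 1.75 bits
        x = np.array([0, 0, 0, 0, 1, 1, 2, 3])
        h = entropy(Variable(x, "categorical"))
        assert h == pytest.approx(1.75 * np.log(2), rel=1e-12)


class TestMutualInformation:
    def test_self_information(self):
        x = Variable(np.array([0, 1, 0, 1]), "categorical")
        assert mutual_information(x, x) == pytest.approx(np.log(2), abs=1e-12)

    def test_exactly_independent_table(self):
        x, y = table_to_samples(np.array([[1, 1], [1, 1]]))
        mi = mutual_information(
            Variable(x, "categorical"), Variable(y, "categorical")
        )
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_relation(self):
        x, y = table_to_samples(np.array([[10, 0], [0, 10]]))
        mi = mutual_information(
            Variable(x, "categorical"), Variable(y, "categorical")
        )
        assert mi == pytest.approx(np.log(2), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(
                Variable(np.zeros(4), "continuous"), Variable(np.zeros(5), "continuous")
            )

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_mixed_pairs(self, seed):
        rng = np.random.default_rng(seed)
        x = Variable(rng.normal(size=12))
        y = Variable(rng.integers(0, 2, 12), "categorical")
        assert abs(mutual_information(x, y) - mutual_information(y, x)) < 1e-9


class TestOracleEquivalence:
    """Plug-in categorical MI vs brute-force contingency-table MI, enumerated."""

    @pytest.mark.parametrize("n", range(3, 9))
    def test_all_two_variable_binary_tables(self, n):
        for cells in itertools.product(range(n + 1), repeat=4):
            if sum(cells) != n:
                continue
            table = np.array(cells).reshape(2, 2)
            x, y = table_to_samples(table)
            vx = Variable(x, "categorical")
            vy = Variable(y, "categorical")
            mi = mutual_information(vx, vy)
            assert abs(mi - brute_mi_from_table(table)) < 1e-12
            assert abs(mi - mutual_information(vy, vx)) < 1e-12

    def test_three_variable_binary_tables(self):
        # all 3-variable binary datasets of size n <= 6, pairwise MI vs oracle
        for n in range(3, 7):
            for cells in itertools.product(range(n + 1), repeat=8):
                if sum(cells) != n:
                    continue
                cube = np.array(cells).reshape(2, 2, 2)
                xs, ys, zs = [], [], []
                for (i, j, k), c in np.ndenumerate(cube):
                    xs += [i] * c
                    ys += [j] * c
                    zs += [k] * c
                vx = Variable(np.array(xs), "categorical")
                vy = Variable(np.array(ys), "categorical")
                mi = mutual_information(vx, vy)
                assert abs(mi - brute_mi_from_table(cube.sum(axis=2))) < 1e-12

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None)
    def test_subadditivity_categorical(self, seed):
        from npem.entropy import joint_entropy

        rng = np.random.default_rng(seed)
        x = Variable(rng.integers(0, 3, 15), "categorical")
        y = Variable(rng.integers(0, 2, 15), "categorical")
        assert joint_entropy([x, y]) <= entropy(x) + entropy(y) + 1e-9


class TestContributedInformation:
    def test_empty_prior_equals_mi(self, rng):
        x = Variable(rng.normal(size=20))
        y = Variable(rng.integers(0, 2, 20), "categorical")
        score = contributed_information(x, y)
        assert isinstance(score, InfoScore)
        assert score.value == mutual_information(x, y)  # bit-for-bit
        assert score.components["penalty"] == 0.0

    def test_self_prior_penalises_by_entropy(self):
        x = Variable(np.array([0, 1, 0, 1, 1, 0]), "categorical")
        y = Variable(np.array([0, 0, 1, 1, 0, 1]), "categorical")
        score = contributed_information(x, y, prior_set=[x])
        expect = mutual_information(x, y) - entropy(x)
        assert score.value == pytest.approx(expect, abs=1e-12)
        assert score.value <= 1e-12

    def test_matches_brute_force_three_binaries(self):
        # hand-built joint of (X, Y, W): value = MI(X,Y) - MI(X,W)/1
        x = Variable(np.array([0, 0, 1, 1, 0, 1, 0, 1]), "categorical")
        y = Variable(np.array([0, 0, 1, 1, 1, 1, 0, 0]), "categorical")
        w = Variable(np.array([0, 1, 1, 0, 0, 1, 1, 0]), "categorical")
        txy = np.zeros((2, 2), dtype=int)
        txw = np.zeros((2, 2), dtype=int)
        for a, b, c in zip(x.values, y.values, w.values):
            txy[a, b] += 1
            txw[a, c] += 1
        expect = brute_mi_from_table(txy) - brute_mi_from_table(txw)
        got = contributed_information(x, y, prior_set=[w])
        assert got.value == pytest.approx(expect, abs=1e-12)

    def test_card_squared_option(self):
        x = Variable(np.array([0, 0, 1, 1]), "categorical")
        y = Variable(np.array([0, 1, 0, 1]), "categorical")
        w1 = Variable(np.array([0, 1, 1, 0]), "categorical")
        w2 = Variable(np.array([1, 1, 0, 0]), "categorical")
        c1 = contributed_information(x, y, [w1, w2], penalty_norm="card")
        c2 = contributed_information(x, y, [w1, w2], penalty_norm="card_squared")
        pen = mutual_information(x, w1) + mutual_information(x, w2)
        assert c1.value == pytest.approx(mutual_information(x, y) - pen / 2, abs=1e-12)
        assert c2.value == pytest.approx(mutual_information(x, y) - pen / 4, abs=1e-12)


class TestMICache:
    def test_matches_direct_computation(self, rng):
        cache = MICache()
        x = Variable(rng.normal(size=18))
        y = Variable(rng.integers(0, 2, 18), "categorical")
        ix, iy = cache.add(x), cache.add(y)
        assert cache.mi(ix, iy) == pytest.approx(mutual_information(x, y), abs=1e-12)
        assert cache.mi(ix, ix) == pytest.approx(cache.h(ix), abs=1e-12)

    def test_contributed_matches_function(self, rng):
        cache = MICache()
        vs = [Variable(rng.normal(size=15)) for _ in range(4)]
        ids = [cache.add(v) for v in vs]
        got = cache.contributed(ids[0], ids[1], ids[2:])
        expect = contributed_information(vs[0], vs[1], vs[2:]).value
        assert got == pytest.approx(expect, abs=1e-12)

    def test_rejects_mismatched_length(self):
        cache = MICache()
        cache.add(Variable(np.zeros(5)))
        with pytest.raises(ValueError):
            cache.add(Variable(np.zeros(6)))


class TestFiniteSampleBias:
    def test_independent_continuous_mi_bias_positive_and_shrinking(self):
        def mean_mi(n, n_seeds=80):
            vals = []
            for s in range(n_seeds):
                rng = np.random.default_rng(1000 + s)
                vals.append(
                    mutual_information(
                        Variable(rng.normal(size=n)), Variable(rng.normal(size=n))
                    )
                )
            return np.mean(vals)

        m40, m120 = mean_mi(40), mean_mi(120)
        assert m40 > 0
        assert m120 > 0
        assert m40 > m120
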