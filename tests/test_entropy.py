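import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memdentropy.entropy import (GAUSS_K0, EmbeddingParams, KernelParams,
                                 Snippet, UndefinedEntropyError,
                                 channel_averaged_entropy, rqe, sample_entropy,
                                 shannon_kernel, silverman_bandwidth)

# --------------------------------------------------------------------------
# independent brute-force oracles (plain python loops, no shared code)


def rqe_oracle(x, sigma):
    n = len(x)
    tot = 0.0
    for i in range(n):
        for j in range(n):
            u = (x[i] - x[j]) / sigma
            tot += math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
    return -math.log2(tot / n ** 2)


def shannon_oracle(x, sigma):
    n = len(x)
    acc = 0.0
    for i in range(n):
        p = 0.0
        for j in range(n):
            u = (x[i] - x[j]) / sigma
            p += math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
        acc += math.log2(p / (n * sigma))
    return -acc / n


def sampen_oracle(data, m_vec, tau_vec, tol):
    """Direct enumeration of composite-delay-vector pairs (Chebyshev)."""
    data = np.atleast_2d(data)
    d, N = data.shape
    nmax = max(m * t for m, t in zip(m_vec, tau_vec))
    n_vec = N - nmax

    def base_vec(i):
        out = []
        for k in range(d):
            out.extend(data[k, i + j * tau_vec[k]] for j in range(m_vec[k]))
        return out

    def matches(vecs):
        cnt = 0
        for i in range(len(vecs)):
            for j in range(len(vecs)):
                if i == j:
                    continue
                if max(abs(a - b) for a, b in zip(vecs[i], vecs[j])) <= tol:
                    cnt += 1
        return cnt / (len(vecs) * (len(vecs) - 1))

    B = matches([base_vec(i) for i in range(n_vec)])
    ext = []
    for k in range(d):
        for i in range(n_vec):
            ext.append(base_vec(i) + [data[k, i + m_vec[k] * tau_vec[k]]])
    A = matches(ext)
    return -math.log(A / B)


# --------------------------------------------------------------------------


class TestSilverman:
    def test_zero_sd(self):
        assert silverman_bandwidth(0.0, 12, 1) == 0.0

    def test_known_value(self):
        # sd=1, n=4, d=1: (4/(4*3))^(1/5) = (1/3)^(1/5)
        assert silverman_bandwidth(1.0, 4, 1) == pytest.approx(
            (1 / 3) ** 0.2, abs=1e-12)

    def test_linear_in_sd(self):
        assert silverman_bandwidth(2.0, 12, 3) == pytest.approx(
            2 * silverman_bandwidth(1.0, 12, 3), abs=1e-14)

    def test_invalid(self):
        with pytest.raises(ValueError):
            silverman_bandwidth(1.0, 0, 1)


class TestRQE:
    def test_constant_snippet(self):
        kp = KernelParams(sigma=0.5)
        val = rqe(np.full((1, 12), 2.0), kp)
        assert val == pytest.approx(-math.log2(GAUSS_K0), abs=1e-12)

    def test_matches_oracle(self, rng):
        for _ in range(30):
            x = rng.standard_normal(12)
            sigma = rng.uniform(0.2, 2.0)
            assert rqe(x[None, :], KernelParams(sigma)) == pytest.approx(
                rqe_oracle(x, sigma), abs=1e-12)

    def test_two_distant_points_limit(self):
        # cross terms vanish: IP2 -> k(0)/2, H2 -> 1 - log2 k(0)
        val = rqe(np.array([[0.0, 1e9]]), KernelParams(sigma=1.0))
        assert val == pytest.approx(1 - math.log2(GAUSS_K0), abs=1e-9)

    def test_translation_invariance(self, rng):
        x = rng.standard_normal(20)
        kp = KernelParams(0.7)
        assert rqe(x[None, :], kp) == pytest.approx(
            rqe(x[None, :] + 123.4, kp), abs=1e-9)

    def test_permutation_symmetry(self, rng):
        x = rng.standard_normal(15)
        kp = KernelParams(0.7)
        assert rqe(x[None, :], kp) == pytest.approx(
            rqe(rng.permutation(x)[None, :], kp), abs=1e-12)

    def test_lower_bound(self, rng):
        # IP2 <= k(0) always, so H2 >= -log2 k(0)
        for _ in range(20):
            x = rng.standard_normal(12) * rng.uniform(0.01, 10)
            val = rqe(x[None, :], KernelParams(rng.uniform(0.05, 5)))
            assert val >= -math.log2(GAUSS_K0) - 1e-12

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            KernelParams(sigma=0.0)

    def test_gaussian_consistency_plugin_exact(self, rng):
        """Large-sample plug-in H2 approaches the closed form for a Gaussian
        convolved with the kernel: -log2 int p^2 = log2(2 sqrt(pi (v + s^2)))."""
        n = 10_000
        x = rng.standard_normal(n)
        sigma = silverman_bandwidth(x.std(), n, 1)
        val = rqe(x[None, :], KernelParams(sigma, ip_convention="plugin_exact"))
        closed = math.log2(2 * math.sqrt(math.pi * (1.0 + sigma ** 2)))
        assert abs(val - closed) < 0.15

    def test_gaussian_consistency_as_printed(self, rng):
        """As-printed IP2 estimates sigma * N(0, 2v + s^2) density at 0."""
        n = 10_000
        x = rng.standard_normal(n)
        sigma = silverman_bandwidth(x.std(), n, 1)
        val = rqe(x[None, :], KernelParams(sigma))
        closed = -math.log2(sigma / math.sqrt(2 * math.pi * (2.0 + sigma ** 2)))
        assert abs(val - closed) < 0.15


class TestShannonKernel:
    def test_translation_invariance(self, rng):
        x = rng.standard_normal(20)
        kp = KernelParams(0.6)
        assert shannon_kernel(x[None, :], kp) == pytest.approx(
            shannon_kernel(x[None, :] + 55.0, kp), abs=1e-9)

    def test_constant_snippet(self):
        sigma = 0.8
        val = shannon_kernel(np.full((1, 10), 1.0), KernelParams(sigma))
        assert val == pytest.approx(-math.log2(GAUSS_K0 / sigma), abs=1e-12)

    def test_matches_oracle(self, rng):
        for _ in range(30):
            x = rng.standard_normal(20)
            sigma = rng.uniform(0.2, 2.0)
            assert shannon_kernel(x[None, :], KernelParams(sigma)) == pytest.approx(
                shannon_oracle(x, sigma), abs=1e-12)


class TestSampleEntropy:
    def test_constant_sequence(self):
        x = np.full(30, 4.0)
        assert sample_entropy(x, EmbeddingParams((2,), (1,), 0.15), tol=0.0) == 0.0

    def test_matches_oracle_univariate(self, rng):
        x = rng.standard_normal(50)
        ep = EmbeddingParams((2,), (1,), 0.15)
        tol = 0.15 * x.std()
        assert sample_entropy(x, ep, tol=tol) == pytest.approx(
            sampen_oracle(x, (2,), (1,), tol), abs=1e-12)

    def test_matches_oracle_multivariate(self, rng):
        X = rng.standard_normal((2, 60))
        ep = EmbeddingParams((2, 2), (1, 1), 0.3)
        tol = 0.3 * X.std()
        assert sample_entropy(X, ep, tol=tol) == pytest.approx(
            sampen_oracle(X, (2, 2), (1, 1), tol), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.integers(20, 100))
    def test_oracle_property(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        tol = 0.2 * x.std()
        try:
            got = sample_entropy(x, EmbeddingParams((2,), (1,), 0.2), tol=tol)
        except UndefinedEntropyError:
            # oracle hits log(0) or 0/0 in the same degenerate situation
            with pytest.raises((ZeroDivisionError, ValueError)):
                sampen_oracle(x, (2,), (1,), tol)
            return
        assert got == pytest.approx(sampen_oracle(x, (2,), (1,), tol), abs=1e-12)

    def test_noise_exceeds_sine(self, rng):
        from .conftest import tone
        wins = 0
        for s in range(20):
            g = np.random.default_rng(s)
            noise = g.standard_normal(1000)
            sine = tone(8, 128, 1000 / 128)
            sine = sine / sine.std()
            ep = EmbeddingParams((2,), (1,), 0.15)
            se_n = sample_entropy(noise, ep, tol=0.15)
            se_s = sample_entropy(sine, ep, tol=0.15)
            wins += se_n > se_s
        assert wins == 20

    def test_undefined_when_no_matches(self):
        x = np.array([0.0, 100.0, -50.0, 200.0, -300.0, 400.0, -500.0, 600.0])
        with pytest.raises(UndefinedEntropyError):
            sample_entropy(x, EmbeddingParams((2,), (1,), 0.15), tol=1e-9)


class TestAvgKernelVariant:
    def test_single_channel_equals_rqe(self, rng):
        from memdentropy.entropy import rqe_avg_kernel
        x = rng.standard_normal(12)
        kp = KernelParams(0.5)
        assert rqe_avg_kernel(x[None, :], kp) == pytest.approx(
            rqe(x[None, :], kp), abs=1e-12)

    def test_matches_kernel_average_oracle(self, rng):
        from memdentropy.entropy import rqe_avg_kernel
        X = rng.standard_normal((2, 10))
        kps = [KernelParams(0.4), KernelParams(0.9)]
        # brute force: average the two per-channel pair sums, one log
        ips = []
        for k in range(2):
            tot = 0.0
            for i in range(10):
                for j in range(10):
                    u = (X[k, i] - X[k, j]) / kps[k].sigma
                    tot += math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
            ips.append(tot / 100)
        expected = -math.log2(0.5 * (ips[0] + ips[1]))
        assert rqe_avg_kernel(X, kps) == pytest.approx(expected, abs=1e-12)

    def test_differs_from_entropy_average(self, rng):
        """The two multivariate conventions are distinct estimators."""
        from memdentropy.entropy import rqe_avg_kernel
        X = rng.standard_normal((3, 12)) * np.array([[1.0], [3.0], [0.5]])
        kp = KernelParams(0.6)
        assert rqe_avg_kernel(X, kp) != pytest.approx(
            channel_averaged_entropy(X, "rqe", kp), abs=1e-6)


class TestChannelAveraged:
    def test_identical_channels_equal_univariate(self, rng):
        x = rng.standard_normal(12)
        kp = KernelParams(0.5)
        multi = channel_averaged_entropy(np.stack([x, x, x]), "rqe", kp)
        assert multi == pytest.approx(rqe(x[None, :], kp), abs=1e-12)

    def test_mean_of_two_known(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        kp = KernelParams(0.5)
        expected = 0.5 * (rqe(a[None, :], kp) + rqe(b[None, :], kp))
        assert channel_averaged_entropy(np.stack([a, b]), "rqe", kp) == \
            pytest.approx(expected, abs=1e-12)

    def test_matches_per_channel_oracles(self, rng):
        X = rng.standard_normal((3, 12))
        # per-channel Silverman bandwidth, oracle per channel
        expected = np.mean([
            rqe_oracle(X[k], silverman_bandwidth(X[k].std(), 12, 1))
            for k in range(3)])
        assert channel_averaged_entropy(X, "rqe") == pytest.approx(
            expected, abs=1e-12)

    def test_unknown_estimator(self):
        with pytest.raises(ValueError):
            channel_averaged_entropy(np.zeros((1, 5)) + np.arange(5), "nope")


def test_snippet_validation():
    with pytest.raises(ValueError):
        Snippet(np.array([[1.0]]))
    with pytest.raises(ValueError):
        Snippet(np.array([[1.0, np.nan]]))
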