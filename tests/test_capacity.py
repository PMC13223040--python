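"""Poisson-channel metrics against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from bvocmc import (
    ChannelSpec,
    poisson_conditional_pmf,
    mutual_information,
    conditional_entropy_gaussian,
    channel_capacity,
    awgn_binary_capacity,
)
from bvocmc.capacity import _cond_pmf_matrix


def binary_spec(xi_on: float) -> ChannelSpec:
    return ChannelSpec(input_levels=(0.0, 1.0), eta=1.0, counts_per_unit=xi_on)


class TestConditionalPmf:
    def test_degenerate_and_closed_form(self):
        assert poisson_conditional_pmf(0, 0.0, binary_spec(5.0)) == 1.0
        assert poisson_conditional_pmf(3, 0.0, binary_spec(5.0)) == 0.0
        assert poisson_conditional_pmf(0, 1.0, binary_spec(1.0)) == \
            pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            poisson_conditional_pmf(-1, 1.0, binary_spec(5.0))

    def test_truncation_covers_mass(self):
        spec = binary_spec(100.0)
        P = _cond_pmf_matrix(spec, spec.q_max())
        assert abs(1.0 - P[1].sum()) < 1e-12


def brute_force_mi(xi0, xi1, p1, qmax=400):
    q = np.arange(qmax + 1)
    P0 = np.where(q == 0, 1.0, 0.0) if xi0 == 0 else stats.poisson.pmf(q, xi0)
    P1 = stats.poisson.pmf(q, xi1)
    py = (1 - p1) * P0 + p1 * P1

    def h(v):
        v = v[v > 0]
        return -np.sum(v * np.log2(v))

    return h(py) - (1 - p1) * h(P0) - p1 * h(P1)


class TestMutualInformation:
    def test_matches_brute_force_double_sum(self):
        mi = mutual_information((0.5, 0.5), binary_spec(100.0))
        assert mi == pytest.approx(brute_force_mi(0, 100, 0.5), abs=1e-9)

    def test_degenerate_prior_zero(self):
        assert mutual_information((1.0, 0.0), binary_spec(50.0)) == 0.0

    def test_indistinguishable_levels_zero(self):
        spec = ChannelSpec(input_levels=(1.0, 1.0), eta=1.0, counts_per_unit=3.0)
        assert mutual_information((0.5, 0.5), spec) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            mutual_information((0.7, 0.7), binary_spec(5.0))


class TestGaussianEntropy:
    def test_analytic_zero_and_monotone(self):
        assert conditional_entropy_gaussian(1.0 / (2 * math.pi * math.e)) == \
            pytest.approx(0.0, abs=1e-12)
        xs = np.linspace(1.0, 200.0, 50)
        hs = [conditional_entropy_gaussian(x) for x in xs]
        assert np.all(np.diff(hs) > 0)
        with pytest.raises(ValueError):
            conditional_entropy_gaussian(0.0)

    def test_within_1pct_of_exact_at_100(self):
        exact = -np.sum(stats.poisson.pmf(np.arange(400), 100.0)
                        * np.log2(stats.poisson.pmf(np.arange(400), 100.0)
                                  + 1e-300))
        assert conditional_entropy_gaussian(100.0) == pytest.approx(exact,
                                                                    rel=0.01)

    def test_documented_divergence_at_small_xi(self):
        # the closed form goes negative for xi < 1/(2 pi e); the exact
        # entropy never does
        assert conditional_entropy_gaussian(0.01) < 0


class TestCapacity:
    def test_optimizer_matches_prior_grid(self):
        spec = binary_spec(5.0)
        cap = channel_capacity(spec).capacity_bits
        ps = np.arange(1e-4, 1.0, 1e-4)
        grid = max(mutual_information((1 - p, p), spec) for p in ps)
        assert abs(cap - grid) < 1e-6

    def test_limits(self):
        assert channel_capacity(ChannelSpec(eta=0.0)).capacity_bits == \
            pytest.approx(0.0, abs=1e-12)
        strong = channel_capacity(binary_spec(5000.0)).capacity_bits
        assert strong == pytest.approx(1.0, abs=1e-6)
        cap = channel_capacity(binary_spec(7.0)).capacity_bits
        assert 0.0 <= cap <= 1.0

    def test_monotone_in_eta(self):
        caps = [channel_capacity(ChannelSpec(input_levels=(0.0, 1.0),
                                             eta=e, counts_per_unit=50.0)
                                 ).capacity_bits
                for e in (0.1, 0.3, 1.0)]
        assert np.all(np.diff(caps) > 0)

    def test_blahut_arimoto_agrees_with_binary_optimizer(self):
        spec = binary_spec(8.0)
        cap2 = channel_capacity(spec).capacity_bits
        # trick BA into running by passing a 3-level alphabet with a
        # duplicated level; capacity is unchanged
        spec3 = ChannelSpec(input_levels=(0.0, 1.0, 1.0), eta=1.0,
                            counts_per_unit=8.0)
        cap3 = channel_capacity(spec3).capacity_bits
        assert cap3 == pytest.approx(cap2, abs=1e-6)

    def test_gaussian_approx_method_close_at_high_counts(self):
        spec = binary_spec(200.0)
        exact = channel_capacity(spec, method="exact").capacity_bits
        approx = channel_capacity(spec, method="gaussian_approx").capacity_bits
        assert approx == pytest.approx(exact, abs=0.02)


class TestAwgn:
    def test_endpoints(self):
        assert awgn_binary_capacity(0.0) == 0.0
        assert awgn_binary_capacity(1e6) == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            awgn_binary_capacity(-1.0)

    def test_against_gauss_hermite_oracle(self):
        """Independent Gauss-Hermite evaluation of the binary-input AWGN
        mutual information at snr = 10."""
        a = math.sqrt(10.0)
        nodes, weights = np.polynomial.hermite.hermgauss(201)
        # E over y ~ N(a, 1) of log2(p(y)) with p the symmetric mixture
        y = math.sqrt(2.0) * nodes + a
        p = 0.5 * (np.exp(-0.5 * (y - a) ** 2) + np.exp(-0.5 * (y + a) ** 2)) \
            / math.sqrt(2 * math.pi)
        h_y = -np.sum(weights * np.log2(p)) / math.sqrt(math.pi)
        oracle = h_y - 0.5 * math.log2(2 * math.pi * math.e)
        assert awgn_binary_capacity(10.0) == pytest.approx(oracle, abs=1e-6)

    def test_monotone_and_bounded(self):
        snrs = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0]
        caps = [awgn_binary_capacity(s) for s in snrs]
        assert np.all(np.diff(caps) > 0)
        assert all(0.0 <= c <= 1.0 for c in caps)
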