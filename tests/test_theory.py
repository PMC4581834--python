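"""Expectation formulas: closed forms, moment machinery, growth recursion."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.special import exp1

import hafscore as hs
from hafscore.params import WrongRegimeError
from hafscore.theory import expx_e1


# ------------------------------------------------------------------ oracles

def stirling2_by_partition_count(ell, q):
    """Brute force: count set partitions of {0..ell-1} into q nonempty blocks."""
    if ell == 0:
        return 1 if q == 0 else 0
    count = 0
    # assign each element a block label; count surjections / q!
    for labels in itertools.product(range(q), repeat=ell):
        if len(set(labels)) == q:
            count += 1
    return count // math.factorial(q)


def enumerate_clade_moments(n, k, ell, rising=True):
    """Exact E[(W_{k,i})^(ℓ)] (or ordinary power) by enumerating all merge
    sequences of the labeled coalescent, each equally likely."""
    total = Fraction(0)
    total_weight = Fraction(0)

    def rec(clades, weight):
        nonlocal total, total_weight
        if len(clades) == k:
            acc = Fraction(0)
            for c in clades:
                w = len(c)
                acc += (
                    Fraction(hs.rising_factorial(w, ell))
                    if rising
                    else Fraction(w**ell)
                )
            total += weight * acc / k
            total_weight += weight
            return
        pairs = list(itertools.combinations(range(len(clades)), 2))
        for i, j in pairs:
            merged = [c for t, c in enumerate(clades) if t not in (i, j)]
            merged.append(clades[i] | clades[j])
            rec(merged, weight / len(pairs))

    rec([frozenset([i]) for i in range(n)], Fraction(1))
    assert total_weight == 1
    return total


# -------------------------------------------------------------- constant size

class TestConstantSize:
    def test_headline_value(self):
        p = hs.DemographyParams(theta=48, n=200)
        assert hs.expected_ell_haf_constant(p, 1) == 4776.0

    def test_ell2_closed_form(self):
        p = hs.DemographyParams(theta=48, n=200)
        assert hs.expected_ell_haf_constant(p, 2) == 48 * 199 * 399 / 6 == 635208.0

    def test_n2_single_term(self):
        p = hs.DemographyParams(theta=7.5, n=2)
        assert hs.expected_ell_haf_constant(p, 1) == 7.5 / 2

    def test_growth_params_rejected(self):
        p = hs.DemographyParams(theta=48, n=200, alpha=10)
        with pytest.raises(WrongRegimeError):
            hs.expected_ell_haf_constant(p, 1)

    @pytest.mark.parametrize("ell", [1, 2])
    def test_epoch_machinery_matches_closed_form_exactly(self, ell, rng):
        """The rising-factorial epoch route and the SFS route agree as
        exact rationals for random (theta, n)."""
        for _ in range(20):
            theta = Fraction(int(rng.integers(1, 400)), int(rng.integers(1, 7)))
            n = int(rng.integers(2, 40))
            closed = (
                Fraction(theta) * sum(w**ell for w in range(1, n)) / n
            )
            assert hs.expected_ell_haf_constant_epoch(theta, n, ell) == closed


class TestCladeMoments:
    def test_rising_factorial_values(self):
        assert hs.rising_factorial(3, 2) == 12
        assert hs.rising_factorial(9, 0) == 1
        assert hs.rising_factorial(1, 5) == 120

    @pytest.mark.parametrize("ell,q,expected", [(3, 2, 3), (4, 2, 7)])
    def test_stirling_table_values(self, ell, q, expected):
        assert hs.stirling2(ell, q) == expected

    def test_stirling_matches_partition_counter(self):
        for ell in range(0, 6):
            for q in range(0, ell + 1):
                assert hs.stirling2(ell, q) == stirling2_by_partition_count(ell, q)

    def test_w_rising_simple_cases(self):
        assert hs.expected_w_rising(6, 2, 1) == 3          # n/k
        assert hs.expected_w_rising(7, 7, 1) == 1          # k = n: singleton clades
        assert hs.expected_w_rising(4, 2, 1) == 2

    @pytest.mark.parametrize("n,k,ell", [(4, 2, 1), (4, 3, 2), (5, 2, 1), (5, 3, 2), (5, 4, 1)])
    def test_w_rising_against_enumeration(self, n, k, ell):
        assert hs.expected_w_rising(n, k, ell) == enumerate_clade_moments(n, k, ell)

    def test_w_power_eq10_and_consistency(self):
        assert hs.expected_w_power(6, 2, 2) == Fraction(6 * (12 - 2 + 1), 2 * 3) == 11
        assert hs.expected_w_power(9, 4, 1) == hs.expected_w_rising(9, 4, 1)

    @pytest.mark.parametrize("n,k,ell", [(5, 3, 3), (4, 2, 3)])
    def test_w_power_against_enumeration(self, n, k, ell):
        assert hs.expected_w_power(n, k, ell) == enumerate_clade_moments(
            n, k, ell, rising=False
        )

    def test_w_power_monte_carlo(self, rng):
        """Mean clade-size cube over simulated neutral topologies (n=5, k=3)."""
        n, k, ell, reps = 5, 3, 3, 30_000
        vals = np.empty(reps)
        ii = rng.integers(0, np.arange(n, k, -1), size=(reps, n - k))
        jj = rng.integers(0, np.arange(n - 1, k - 1, -1), size=(reps, n - k))
        for r in range(reps):
            clades = [1] * n
            for step in range(n - k):
                i = int(ii[r, step])
                j = int(jj[r, step])
                if j >= i:
                    j += 1
                a = clades[i] + clades[j]
                clades = [c for t, c in enumerate(clades) if t not in (i, j)] + [a]
            vals[r] = np.mean([c**ell for c in clades])
        se = vals.std() / math.sqrt(reps)
        assert abs(vals.mean() - float(hs.expected_w_power(n, k, ell))) < 3 * se

    def test_clade_sizes_partition_sample(self):
        n = 11
        for k in range(2, n + 1):
            assert k * hs.expected_w_rising(n, k, 1) == n

    def test_bad_epoch_index_rejected(self):
        with pytest.raises(ValueError):
            hs.expected_w_rising(5, 1, 1)
        with pytest.raises(ValueError):
            hs.expected_w_power(5, 6, 2)


# -------------------------------------------------------------------- growth

class TestExponentialGrowth:
    def test_expx_e1_matches_scipy_and_is_continuous(self):
        for x in [1e-3, 0.5, 1, 10, 100, 499.9, 500.1, 700, 1e4, 1e8]:
            if x < 500:
                ref = math.exp(x) * exp1(x)
            else:
                # asymptotic series: (1/x)(1 - 1/x + 2/x^2 - 6/x^3 + 24/x^4)
                ref = (1 - 1 / x + 2 / x**2 - 6 / x**3 + 24 / x**4) / x
            assert abs(expx_e1(x) - ref) / ref < 1e-9

    def test_neutral_limit_of_epoch_times(self):
        """alpha -> 0+: t_k -> 2N/(k(k-1)) generations."""
        p = hs.DemographyParams(theta=48, n=30, alpha=1e-6, N=20_000)
        et = hs.epoch_times_exponential(p)
        for k in (2, 3, 10, 30):
            assert et.t[k] == pytest.approx(2 * p.N / (k * (k - 1)), rel=1e-4)

    def test_epoch_times_decrease_with_more_lineages(self):
        p = hs.DemographyParams(theta=48, n=200, alpha=80, N=20_000)
        et = hs.epoch_times_exponential(p)
        ts = [et.t[k] for k in range(2, 201)]
        assert all(a > b for a, b in zip(ts, ts[1:]))
        taus = [et.tau[k] for k in range(2, 201)]
        assert all(a >= b for a, b in zip(taus, taus[1:]))  # tau non-increasing in k

    def test_epoch_times_match_growth_simulator(self):
        """n=20, alpha=40: theory within 3 SE of simulated epoch durations."""
        p = hs.DemographyParams(theta=10, n=20, alpha=40, N=20_000)
        et = hs.epoch_times_exponential(p)
        reps = 8000
        durs = {k: np.empty(reps) for k in (2, 5, 10, 20)}
        for i, s in enumerate(hs.simulate_exponential_growth(p, reps, seed=99)):
            d = s.genealogy.epoch_durations()
            for k in durs:
                durs[k][i] = d[k] * p.N
        for k, arr in durs.items():
            se = arr.std() / math.sqrt(reps)
            assert abs(arr.mean() - et.t[k]) < 3 * se, f"epoch {k}"

    def test_headline_growth_value(self):
        p = hs.DemographyParams(theta=48, n=200, alpha=80, N=20_000)
        assert hs.expected_ell_haf_exponential(p, 1) == pytest.approx(126.9, abs=0.1)

    def test_growth_alpha_to_zero_recovers_constant(self):
        p0 = hs.DemographyParams(theta=48, n=200, alpha=1e-6)
        assert hs.expected_ell_haf_exponential(p0, 1) == pytest.approx(4776.0, rel=1e-3)
        assert hs.expected_ell_haf_exponential(p0, 2) == pytest.approx(635208.0, rel=1e-3)

    def test_wrong_regime_rejected(self):
        with pytest.raises(WrongRegimeError):
            hs.epoch_times_exponential(hs.DemographyParams(theta=48, n=10, alpha=0))


# --------------------------------------------------------------------- sweeps

class TestSweepExpectations:
    def params(self, theta=48, n=200):
        return hs.DemographyParams(theta=theta, n=n, N=20_000)

    def test_single_carrier_reduces_to_neutral_mean(self):
        p = self.params()
        st = hs.SweepState(nu=1 / p.n, s=0.05, params=p)
        neutral = hs.expected_ell_haf_constant(p, 1)
        assert hs.expected_haf_carrier(st) == pytest.approx(neutral, rel=1e-12)
        assert hs.expected_haf_noncarrier(st) == pytest.approx(neutral, rel=1e-12)

    def test_carrier_noncarrier_difference(self):
        p = self.params()
        for nu in (0.1, 0.5, 0.9):
            st = hs.SweepState(nu=nu, s=0.05, params=p)
            diff = hs.expected_haf_carrier(st) - hs.expected_haf_noncarrier(st)
            assert diff == pytest.approx(p.theta * p.n * (nu / 2 - 1 / (2 * p.n)))
        d1 = hs.SweepState(nu=0.3, s=0.05, params=p)
        d2 = hs.SweepState(nu=0.6, s=0.05, params=p)
        assert hs.expected_haf_carrier(d2) > hs.expected_haf_carrier(d1)

    def test_peak_is_maximum_of_carrier_curve(self):
        p = self.params()
        nus = np.linspace(0, 1, 20_001)
        curve = p.theta * p.n * ((nus + 1) / 2 - 1 / ((1 - nus) * p.n + 1))
        assert hs.haf_peak(p) == pytest.approx(curve.max(), rel=1e-6)
        assert hs.haf_peak(p) == pytest.approx(
            p.theta * p.n * (1 - 1 / math.sqrt(2 * p.n)) ** 2
        )

    def test_peak_approaches_theta_n(self):
        ratios = [
            hs.haf_peak(self.params(n=n)) / (48 * n) for n in (50, 500, 5000)
        ]
        assert ratios == sorted(ratios)
        assert ratios[-1] > 0.97

    def test_weak_selection_warns(self):
        with pytest.warns(UserWarning, match="Ns"):
            hs.SweepState(nu=0.5, s=1e-4, params=self.params())

    def test_nu_near_one_noncarrier_warns(self):
        st = hs.SweepState(nu=0.999, s=0.05, params=self.params())
        with pytest.warns(UserWarning, match="non-carriers"):
            hs.expected_haf_noncarrier(st)
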