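"""Growth, mortality, maturation and smolting rate functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ibsem import demography as dem
from ibsem.demography import (
    AlevinParams,
    GrowthParams,
    MaturationParams,
    MortalityParams,
    SmoltingParams,
)


@pytest.fixture
def growth():
    return GrowthParams()


@pytest.fixture
def mort():
    return MortalityParams()


class TestAlevinLength:
    def test_deterministic_without_noise(self):
        p = AlevinParams(intercept_mm=12.0, slope_mm_per_g=120.0, noise_sd_mm=0.0)
        assert dem.alevin_length_at_emergence(0.09, p) == pytest.approx(22.8)

    def test_mean_matches_linear_relation(self, rng):
        p = AlevinParams(intercept_mm=12.0, slope_mm_per_g=120.0, noise_sd_mm=1.0)
        draws = dem.alevin_length_at_emergence(np.full(10_000, 0.09), p, rng)
        assert draws.mean() == pytest.approx(22.8, abs=3 * 1.0 / 100)

    def test_larger_eggs_make_longer_alevins_in_expectation(self, rng):
        p = AlevinParams(noise_sd_mm=1.0)
        small = dem.alevin_length_at_emergence(np.full(4000, 0.07), p, rng)
        large = dem.alevin_length_at_emergence(np.full(4000, 0.12), p, rng)
        assert large.mean() > small.mean()

    def test_nonpositive_egg_size_rejected(self):
        with pytest.raises(ValueError):
            dem.alevin_length_at_emergence(0.0, AlevinParams())


class TestEffectiveDensity:
    def test_empty_population_is_zero(self, mort):
        assert dem.effective_density([], 100.0, mort.ed) == 0.0

    def test_gamma_zero_reduces_to_plain_density(self, mort):
        ed = dem.EffectiveDensityParams(gamma=0.0, w_ref_g=2.9)
        w = np.array([0.5, 4.0, 17.0])
        assert dem.effective_density(w, 10.0, ed) == pytest.approx(3 / 10)

    def test_mass_weighted_sum(self, mort):
        ed = dem.EffectiveDensityParams(gamma=1.0, w_ref_g=2.0)
        w = np.array([8.0, 2.0])  # 4x reference + 1x reference
        assert dem.effective_density(w, 5.0, ed) == pytest.approx(5.0 / 5.0)

    def test_doubling_area_halves_density(self, mort):
        w = np.full(100, 3.0)
        assert dem.effective_density(w, 200.0, mort.ed) == pytest.approx(
            dem.effective_density(w, 100.0, mort.ed) / 2.0)


class TestGrowth:
    def test_no_growth_outside_temperature_window(self, growth):
        assert dem.temperature_factor(1.9, growth.ramp_parr, growth) == 0.0
        assert dem.temperature_factor(22.5, growth.ramp_parr, growth) == 0.0
        assert dem.temperature_factor(14.0, growth.ramp_parr, growth) == 1.0

    def test_farm_genotype_grows_faster(self, growth):
        inc_wild = dem.growth_increment(5.0, 0.9, 1.0, 1.0, 1.0, 0.0, growth, 1.0)
        inc_farm = dem.growth_increment(5.0, 0.1, 1.0, 1.0, 1.0, 0.0, growth, 1.0)
        assert inc_farm > inc_wild

    def test_genotype_neutral_at_zero_differential_scale(self, growth):
        inc_wild = dem.growth_increment(5.0, 0.9, 1.0, 1.0, 1.0, 0.0, growth, 0.0)
        inc_farm = dem.growth_increment(5.0, 0.1, 1.0, 1.0, 1.0, 0.0, growth, 0.0)
        assert inc_wild == pytest.approx(inc_farm)

    def test_density_reduces_growth_monotonically(self, growth):
        factors = [dem.density_growth_factor(ed, growth) for ed in (0.0, 0.5, 2.0)]
        assert factors[0] == 1.0
        assert factors[0] > factors[1] > factors[2]

    def test_increments_nonnegative_under_extreme_noise(self, growth, rng):
        inc = dem.growth_increment(np.full(2000, 5.0), 0.9, 1.0, 1.0, 1.0,
                                   2.0, growth, 1.0, rng)
        assert (inc >= 0.0).all()

    def test_length_never_decreases(self, growth):
        L = dem.length_from_weight(1.0, 120.0, growth.condition_factor_juv)
        assert L == 120.0  # weight implies a shorter fish; length is kept

    def test_sea_growth_asymptote(self, growth):
        inc = dem.sea_length_increment(growth.l_inf_mm, 2, 0.9, 1.0, growth, 1.0)
        assert inc == 0.0
        inc_small = dem.sea_length_increment(200.0, 0, 0.9, 1.0, growth, 1.0)
        assert inc_small > 0.0


class TestEggMortality:
    def test_density_free_limit(self, mort):
        m = dem.egg_mortality_prob(0.9, 0.09, 0.0, mort)
        expected = 1.0 - np.clip(
            (mort.egg_base + mort.egg_size_slope * 0.09), 0, 1)
        assert m == pytest.approx(expected)

    def test_exponential_density_response_exact(self, mort):
        s1 = 1.0 - dem.egg_mortality_prob(0.9, 0.09, 4.0, mort)
        s2 = 1.0 - dem.egg_mortality_prob(0.9, 0.09, 8.0, mort)
        assert s2 / s1 == pytest.approx(np.exp(-mort.egg_density_coef * 4.0))

    def test_wild_eggs_survive_better(self, mort):
        assert dem.egg_mortality_prob(0.1, 0.09, 5.0, mort) > dem.egg_mortality_prob(
            0.9, 0.09, 5.0, mort)


class TestJuvenileMortality:
    def test_mortality_decreases_with_freshwater_age(self, mort):
        ms = [dem.juvenile_mortality_prob(a, "warm", 0.5, 0.9, mort)
              for a in ("p0", "p1", "p2")]
        assert ms[0] > ms[1] > ms[2]

    def test_resting_season_is_safer(self, mort):
        for age in ("p0", "p1", "p2"):
            warm = dem.juvenile_mortality_prob(age, "warm", 0.5, 0.9, mort)
            rest = dem.juvenile_mortality_prob(age, "resting", 0.5, 0.9, mort)
            assert rest < warm

    def test_zero_density_gives_baseline(self, mort):
        m = dem.juvenile_mortality_prob("p0", "warm", 0.0, 0.9, mort)
        assert m == pytest.approx(mort.juv_warm[0])

    def test_density_never_decreases_mortality(self, mort):
        lo = dem.juvenile_mortality_prob("p0", "warm", 0.1, 0.9, mort)
        hi = dem.juvenile_mortality_prob("p0", "warm", 2.0, 0.9, mort)
        assert hi >= lo

    def test_smolt_rate_same_in_both_seasons(self, mort):
        assert dem.juvenile_mortality_prob("smolt", "warm", 1.0, 0.9, mort) == (
            dem.juvenile_mortality_prob("smolt", "resting", 1.0, 0.9, mort))


class TestMarineMortality:
    def test_larger_fish_survive_better(self, mort):
        assert dem.marine_mortality_prob(1, 700.0, 0.9, mort) < (
            dem.marine_mortality_prob(1, 300.0, 0.9, mort))

    def test_wild_genotype_survives_better(self, mort):
        assert dem.marine_mortality_prob(1, 500.0, 0.9, mort) < (
            dem.marine_mortality_prob(1, 500.0, 0.1, mort))

    def test_neutral_at_zero_scale(self, mort):
        a = dem.marine_mortality_prob(1, 500.0, 0.9, mort, scale=0.0)
        b = dem.marine_mortality_prob(1, 500.0, 0.1, mort, scale=0.0)
        assert a == pytest.approx(b)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(L=st.floats(10, 2000), S=st.floats(0, 1),
           scale=st.sampled_from([0.0, 0.5, 1.0, 2.0]), age=st.integers(0, 3))
    def test_probability_always_valid(self, L, S, scale, age):
        m = dem.marine_mortality_prob(age, L, S, MortalityParams(), scale)
        assert 0.0 <= m <= 1.0


class TestApplyMortality:
    def test_certain_survival_and_death(self, rng):
        assert dem.apply_mortality(np.zeros(100), rng).all()
        assert not dem.apply_mortality(np.ones(100), rng).any()

    def test_binomial_survivor_count(self, rng):
        n = 10_000
        survivors = dem.apply_mortality(np.full(n, 0.5), rng).sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= survivors <= hi

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            dem.apply_mortality(np.array([1.5]), rng)


class TestMaturation:
    def test_repeat_spawner_doubling_capped_at_one(self):
        p = MaturationParams()
        # length where the base probability is 0.6
        L = p.parr_midpoint_mm + p.parr_steepness_mm * np.log(0.6 / 0.4)
        assert dem.parr_maturation_prob(L, False, p) == pytest.approx(0.6)
        assert dem.parr_maturation_prob(L, True, p) == 1.0

    def test_tiny_parr_never_mature(self):
        assert dem.parr_maturation_prob(1.0, False, MaturationParams()) < 1e-3

    def test_midpoint_gives_half(self):
        p = MaturationParams()
        assert dem.parr_maturation_prob(p.parr_midpoint_mm, False, p) == (
            pytest.approx(0.5))

    def test_wild_adults_return_earlier(self):
        p = MaturationParams()
        assert dem.adult_return_prob(1, 0.9, p) > dem.adult_return_prob(1, 0.1, p)

    def test_max_sea_age_always_returns(self):
        assert dem.adult_return_prob(3, 0.1, MaturationParams()) == 1.0

    def test_first_sea_year_never_returns(self):
        assert dem.adult_return_prob(0, 0.9, MaturationParams()) == 0.0


class TestSmolting:
    def test_below_threshold_is_zero(self):
        p = SmoltingParams()
        assert dem.smolt_decision_prob(89.0, p) == 0.0
        assert dem.smolt_decision_prob(89.99, p) == 0.0

    def test_half_probability_at_midpoint(self):
        assert dem.smolt_decision_prob(103.0, SmoltingParams()) == pytest.approx(0.5)

    def test_asymptote_for_large_parr(self):
        assert dem.smolt_decision_prob(500.0, SmoltingParams()) == pytest.approx(1.0)
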