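"""Spawning, mate allocation, straying and escapee injection."""

import numpy as np
import pytest
from scipy import stats

from ibsem import genetics, reproduction
from ibsem.population import Origin, Phase, Population, Sex
from ibsem.reproduction import EscapeeParams, SpawningParams, StrayingParams


def make_pop(n, *, length=500.0, weight=None, sex=Sex.MALE, origin=Origin.WILD,
             geno_freq=None, geno=None, seed=0):
    rng = np.random.default_rng(seed)
    pop = Population(n)
    pop.uid = np.arange(n, dtype=np.int64)
    pop.sex = np.full(n, sex, dtype=np.uint8)
    pop.phase = np.full(n, Phase.ADULT, dtype=np.uint8)
    pop.length = np.full(n, float(length))
    pop.weight = np.full(n, 1.22e-5 * length**3 if weight is None else float(weight))
    pop.origin = np.full(n, origin, dtype=np.uint8)
    if geno is not None:
        pop.geno = np.broadcast_to(geno, (n, 3, 21, 2)).copy().astype(np.uint8)
    elif geno_freq is not None:
        pop.geno = genetics.init_genotypes(n, geno_freq, rng)
    prof = genetics.make_effect_profile()
    pop.S = genetics.sum_all_effects(pop.geno, prof)
    return pop


ALL_ONES = np.ones((3, 21, 2), dtype=np.uint8)
ALL_ZEROS = np.zeros((3, 21, 2), dtype=np.uint8)


class TestFecundity:
    def test_exact_linearity_without_noise(self):
        p = SpawningParams(fecundity_intercept=100.0, fecundity_slope_per_g=1.5)
        (c1, c2), _ = reproduction.fecundity_and_egg_size(np.array([1000.0, 2000.0]), p)
        assert c1 == round(100 + 1.5 * 1000)
        assert c2 == round(100 + 1.5 * 2000)

    def test_heavier_females_make_more_and_heavier_eggs(self, rng):
        p = SpawningParams()
        c_small, w_small = reproduction.fecundity_and_egg_size(
            np.full(2000, 2000.0), p, rng)
        c_big, w_big = reproduction.fecundity_and_egg_size(
            np.full(2000, 8000.0), p, rng)
        assert c_big.mean() > c_small.mean()
        assert w_big.mean() > w_small.mean()

    def test_zero_weight_limit(self):
        p = SpawningParams(fecundity_intercept=0.0)
        count, _ = reproduction.fecundity_and_egg_size(1e-9, p)
        assert count[0] == 0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            reproduction.fecundity_and_egg_size(-5.0, SpawningParams())


class TestSpawn:
    def setup_method(self):
        self.params = SpawningParams(fecundity_sd_frac=0.0, egg_weight_sd_frac=0.0)
        self.profile = genetics.make_effect_profile()

    def test_no_males_no_eggs(self, rng):
        fem = make_pop(3, sex=Sex.FEMALE, geno=ALL_ONES)
        eggs = reproduction.spawn(fem, Population(0), Population(0),
                                  self.params, self.profile, rng)
        assert len(eggs) == 0

    def test_total_eggs_equals_summed_fecundity(self, rng):
        fem = make_pop(4, sex=Sex.FEMALE, length=600.0, geno=ALL_ONES)
        males = make_pop(3, geno=ALL_ONES, seed=1)
        eggs = reproduction.spawn(fem, males, Population(0),
                                  self.params, self.profile, rng)
        expected, _ = reproduction.fecundity_and_egg_size(fem.weight, self.params)
        assert len(eggs) == expected.sum()

    def test_adult_shares_proportional_to_weight(self, rng):
        """Two adult sires with weights 2:1 fertilise eggs 2/3 : 1/3."""
        fem = make_pop(6, sex=Sex.FEMALE, length=700.0, geno=ALL_ZEROS)
        males = make_pop(2, geno=ALL_ONES, seed=1)
        males.weight = np.array([4000.0, 2000.0])
        # sire A all-'1' everywhere, sire B all-'1' except neutral locus
        males.geno[1, :, 20, :] = 0
        eggs = reproduction.spawn(fem, males, Population(0),
                                  self.params, self.profile, rng)
        from_b = (eggs.geno[:, 0, 20, 1] == 0)
        frac_a = 1.0 - from_b.mean()
        assert frac_a == pytest.approx(2 / 3, abs=0.03)

    def test_mean_parr_share_is_thirty_percent(self, rng):
        fem = make_pop(60, sex=Sex.FEMALE, length=600.0, geno=ALL_ZEROS)
        adults = make_pop(10, geno=ALL_ZEROS, seed=1)
        parr = make_pop(40, length=110.0, geno=ALL_ONES, seed=2)
        eggs = reproduction.spawn(fem, adults, parr, self.params, self.profile, rng)
        # paternal allele '1' marks a parr sire
        parr_frac = eggs.geno[:, 0, 0, 1].mean()
        assert parr_frac == pytest.approx(0.30, abs=0.04)

    def test_egg_allele_frequency_matches_parental_mean(self, rng):
        fem = make_pop(30, sex=Sex.FEMALE, length=600.0, geno_freq=0.6, seed=3)
        males = make_pop(30, geno_freq=0.6, seed=4)
        eggs = reproduction.spawn(fem, males, Population(0),
                                  self.params, self.profile, rng)
        assert eggs.geno.mean() == pytest.approx(0.6, abs=0.02)

    def test_offspring_sex_ratio_is_even(self, rng):
        fem = make_pop(10, sex=Sex.FEMALE, length=600.0, geno=ALL_ONES)
        males = make_pop(5, geno=ALL_ONES, seed=1)
        eggs = reproduction.spawn(fem, males, Population(0),
                                  self.params, self.profile, rng)
        n = len(eggs)
        males_n = int((eggs.sex == Sex.MALE).sum())
        chi2 = (males_n - n / 2) ** 2 / (n / 2) * 2
        assert chi2 < stats.chi2.ppf(0.99, df=1)


class TestPrePostSpawnMortality:
    def test_degenerate_ranges(self, rng):
        parr = make_pop(200, length=110.0, geno=ALL_ONES)
        p_none = SpawningParams(parr_prespawn_mortality_range=(0.0, 0.0))
        p_all = SpawningParams(parr_prespawn_mortality_range=(1.0, 1.0))
        assert reproduction.prespawn_parr_mortality(parr, p_none, rng).all()
        assert not reproduction.prespawn_parr_mortality(parr, p_all, rng).any()

    def test_invalid_range_rejected(self, rng):
        bad = SpawningParams(parr_prespawn_mortality_range=(0.8, 0.2))
        with pytest.raises(ValueError):
            reproduction.prespawn_parr_mortality(make_pop(5), bad, rng)

    def test_yearly_rate_uniform_over_range(self, rng):
        """Realized yearly mortality follows the configured uniform range."""
        p = SpawningParams(parr_prespawn_mortality_range=(0.2, 0.4))
        rates = []
        for _ in range(150):
            parr = make_pop(3000, length=110.0, geno=ALL_ONES)
            alive = reproduction.prespawn_parr_mortality(parr, p, rng)
            rates.append(1.0 - alive.mean())
        d, pval = stats.kstest(rates, stats.uniform(0.2, 0.2).cdf)
        assert pval > 0.01

    def test_postspawn_extremes_and_flags(self, rng):
        spawners = make_pop(300, geno=ALL_ONES)
        spawners.mature[:] = True
        keep = reproduction.postspawn_adult_fate(
            spawners, SpawningParams(adult_postspawn_mortality=0.0), rng)
        assert keep.all()
        assert spawners.matured_prev.all()
        assert not spawners.mature.any()
        dead = reproduction.postspawn_adult_fate(
            make_pop(300, geno=ALL_ONES),
            SpawningParams(adult_postspawn_mortality=1.0), rng)
        assert not dead.any()

    def test_postspawn_kelt_count_binomial(self, rng):
        spawners = make_pop(1000, geno=ALL_ONES)
        keep = reproduction.postspawn_adult_fate(
            spawners, SpawningParams(adult_postspawn_mortality=0.8), rng)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.2)
        assert lo <= keep.sum() <= hi


class TestStraying:
    def setup_method(self):
        self.profile = genetics.make_effect_profile()

    def test_empty_pool_unchanged(self, rng):
        pop = Population(0)
        n = reproduction.apply_straying(pop, StrayingParams(), self.profile, rng)
        assert n == 0 and len(pop) == 0

    def test_five_percent_of_436_returners_is_22(self, rng):
        pop = make_pop(436, geno=ALL_ONES)
        n = reproduction.apply_straying(pop, StrayingParams(), self.profile, rng)
        assert n == 22
        assert int((pop.origin == Origin.STRAYER).sum()) == 22
        assert len(pop) == 436  # population size preserved exactly

    def test_strayer_copies_phenotype_and_resets_genotype(self, rng):
        pop = make_pop(200, length=654.3, geno=ALL_ZEROS)
        reproduction.apply_straying(pop, StrayingParams(), self.profile, rng)
        assert (pop.length == 654.3).all()  # phenotype replicated
        swapped = pop.origin == Origin.STRAYER
        freq = pop.geno[swapped].mean()
        assert freq == pytest.approx(0.8, abs=0.04)

    def test_mirror_mode_preserves_allele_frequency_in_expectation(self, rng):
        p0 = 0.37
        pop = make_pop(400, geno_freq=p0, seed=9)
        before = pop.geno.mean()
        params = StrayingParams(stray_fraction=0.5, mirror_mode=True)
        reproduction.apply_straying(pop, params, self.profile, rng)
        # each strayer re-draws alleles at the outgoing fish's own frequency
        assert pop.geno.mean() == pytest.approx(before, abs=0.02)


class TestEscapees:
    def test_zero_escapees(self, rng):
        pop = reproduction.make_escapees(0, EscapeeParams(),
                                         genetics.make_effect_profile(), 1.22e-5, rng)
        assert len(pop) == 0

    def test_injected_farm_adults(self, rng):
        prof = genetics.make_effect_profile()
        pop = reproduction.make_escapees(300, EscapeeParams(), prof, 1.22e-5, rng)
        assert len(pop) == 300
        assert (pop.origin == Origin.FARM).all()
        assert pop.mature.all()
        assert pop.S.mean() == pytest.approx(0.1, abs=0.02)
        assert set(np.unique(pop.sea_age)) <= {1, 2, 3}

    def test_escapee_competitive_weight_reduced(self):
        p = SpawningParams(escapee_success_factor=0.33)
        pop = make_pop(2, weight=1000.0)
        pop.origin[1] = Origin.FARM
        eff = reproduction._effective_weight(pop, p)
        assert eff[0] == 1000.0
        assert eff[1] == pytest.approx(330.0)
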