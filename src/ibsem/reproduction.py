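"""Reproduction: mate pairing, fecundity, egg creation, straying, escapees.

Spawning happens once a year at the end of October.  Each female is paired
with up to 2 mature adult males and up to 5 sexually mature male parr; the
fraction of her eggs fertilised by parr is drawn from a truncated Gaussian
(mean 30%, SD 10%) and, within each pool, fertilisation opportunities are
allocated proportionally to body weight.  Farmed escapees compete with their
weight multiplied by a spawning-success factor < 1.

Mates are drawn weight-proportionally *without replacement* per female rather
than deterministically taking the largest males: with realistically small
spawner pools the deterministic rule funnels every egg through the same
handful of sires and erases the population's genetic diversity, while
weighted sampling preserves the size advantage the biology calls for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genetics
from .population import Origin, Phase, Population, Sex


@dataclass
class SpawningParams:
    fecundity_slope_per_g: float = 1.77  # eggs per g female weight
    fecundity_intercept: float = 0.0
    fecundity_sd_frac: float = 0.10  # SD as fraction of the mean
    egg_weight_intercept_g: float = 0.07
    egg_weight_slope_per_g: float = 4.0e-6  # g egg per g female weight
    egg_weight_sd_frac: float = 0.10
    egg_weight_min_g: float = 0.03
    max_adult_mates: int = 2
    max_parr_mates: int = 5
    parr_share_mean: float = 0.30
    parr_share_sd: float = 0.10
    parr_prespawn_mortality_range: tuple[float, float] = (0.3, 0.6)
    adult_postspawn_mortality: float = 0.9
    escapee_success_factor: float = 0.33


@dataclass
class StrayingParams:
    stray_fraction: float = 0.05  # of the adult returners
    incoming_wild_freq: float = 0.8
    mirror_mode: bool = False  # strayer copies the outgoing fish's frequency


@dataclass
class EscapeeParams:
    """Size/age make-up of injected farm escapees."""

    n_per_year: float = 0.0  # at full river scale
    sea_age_probs: tuple[float, float, float] = (0.2, 0.6, 0.2)  # 1SW..3SW
    length_mean_mm: tuple[float, float, float] = (590.0, 700.0, 840.0)
    length_sd_frac: float = 0.05
    wild_allele_freq: float = 0.1


def fecundity_and_egg_size(female_weight, params: SpawningParams, rng=None):
    """Realized egg count and mean egg weight (g) for each female.

    Means are linear in body weight; realized values are Gaussian around the
    means (egg counts rounded, both truncated to their valid supports).
    """
    w = np.atleast_1d(np.asarray(female_weight, dtype=float))
    if (w <= 0).any():
        raise ValueError("female weight must be positive")
    fec_mean = params.fecundity_intercept + params.fecundity_slope_per_g * w
    egg_mean = params.egg_weight_intercept_g + params.egg_weight_slope_per_g * w
    if rng is None:
        fec, egg = fec_mean, egg_mean
    else:
        fec = rng.normal(fec_mean, params.fecundity_sd_frac * fec_mean)
        egg = rng.normal(egg_mean, params.egg_weight_sd_frac * egg_mean)
    count = np.maximum(np.rint(fec), 0.0).astype(np.int64)
    egg = np.maximum(egg, params.egg_weight_min_g)
    return count, egg


def _effective_weight(pop: Population, params: SpawningParams) -> np.ndarray:
    w = pop.weight.astype(float).copy()
    w[pop.origin == Origin.FARM] *= params.escapee_success_factor
    return w


def _sample_mates(rng, eff_w: np.ndarray, k: int) -> np.ndarray:
    """Indices of up to k mates, weight-proportional, without replacement."""
    n = len(eff_w)
    if n == 0 or k == 0:
        return np.empty(0, dtype=np.int64)
    k = min(k, n)
    tot = eff_w.sum()
    p = None if tot <= 0 else eff_w / tot
    return rng.choice(n, size=k, replace=False, p=p)


def spawn(
    females: Population,
    adult_males: Population,
    mature_parr: Population,
    params: SpawningParams,
    profile: genetics.EffectProfile,
    rng: np.random.Generator,
    uid_start: int = 0,
) -> Population:
    """Create the egg cohort for one spawning season.

    Returns a :class:`Population` of eggs; each egg carries an inherited
    genotype, its clutch egg weight, a random sex, and the midparent
    reference length used by the heritability estimator.
    """
    eggs = Population(0)
    n_f = len(females)
    if n_f == 0 or (len(adult_males) == 0 and len(mature_parr) == 0):
        return eggs

    counts, egg_w = fecundity_and_egg_size(females.weight, params, rng)
    eff_adult = _effective_weight(adult_males, params)
    eff_parr = _effective_weight(mature_parr, params)

    order = rng.permutation(n_f)
    mother_rows, father_geno, father_ref, clutch_w = [], [], [], []
    for i in order:
        n_eggs = int(counts[i])
        if n_eggs == 0:
            continue
        ad_idx = _sample_mates(rng, eff_adult, params.max_adult_mates)
        pr_idx = _sample_mates(rng, eff_parr, params.max_parr_mates)
        if len(ad_idx) == 0 and len(pr_idx) == 0:
            continue
        if len(pr_idx) == 0:
            q = 0.0
        elif len(ad_idx) == 0:
            q = 1.0
        else:
            q = float(np.clip(rng.normal(params.parr_share_mean, params.parr_share_sd), 0, 1))
        # per-egg sire: parr pool with probability q, then weight shares within pool
        from_parr = rng.random(n_eggs) < q
        sire_geno = np.empty((n_eggs, genetics.N_SETS, genetics.N_LOCI, 2), np.uint8)
        sire_ref = np.full(n_eggs, np.nan)
        for mask, pool, idx in (
            (~from_parr, adult_males, ad_idx),
            (from_parr, mature_parr, pr_idx),
        ):
            k = int(mask.sum())
            if k == 0 or len(idx) == 0:
                continue
            w = _effective_weight(pool, params)[idx]
            share = w / w.sum() if w.sum() > 0 else np.full(len(idx), 1 / len(idx))
            pick = idx[rng.choice(len(idx), size=k, p=share)]
            sire_geno[mask] = pool.geno[pick]
            sire_ref[mask] = pool.ref_length[pick]
        mother_rows.append(np.full(n_eggs, i))
        father_geno.append(sire_geno)
        father_ref.append(sire_ref)
        clutch_w.append(np.full(n_eggs, egg_w[i]))

    if not mother_rows:
        return eggs
    mother_rows = np.concatenate(mother_rows)
    father_geno = np.concatenate(father_geno)
    father_ref = np.concatenate(father_ref)
    n = len(mother_rows)

    geno = genetics.inherit(females.geno[mother_rows], father_geno, rng)
    out = Population(n)
    out.uid = np.arange(uid_start, uid_start + n, dtype=np.int64)
    out.sex = (rng.random(n) < 0.5).astype(np.uint8)  # equal sex ratio at birth
    out.phase = np.full(n, Phase.EGG, dtype=np.uint8)
    out.egg_size = np.concatenate(clutch_w)
    out.origin = np.full(n, Origin.PROGENY, dtype=np.uint8)
    out.geno = geno
    out.S = genetics.sum_all_effects(geno, profile)
    out.midparent_ref = 0.5 * (females.ref_length[mother_rows] + father_ref)
    return out


def prespawn_parr_mortality(
    mature_parr: Population, params: SpawningParams, rng: np.random.Generator
) -> np.ndarray:
    """Survivor mask for mature male parr before spawning.

    One mortality probability is drawn uniformly from the configured range
    each year and applied as an independent Bernoulli trial per parr.
    """
    lo, hi = params.parr_prespawn_mortality_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("parr pre-spawning mortality range must be within [0, 1]")
    m = rng.uniform(lo, hi)
    return rng.random(len(mature_parr)) >= m


def postspawn_adult_fate(
    spawners: Population, params: SpawningParams, rng: np.random.Generator
) -> np.ndarray:
    """Survivor (kelt) mask for adult spawners; survivors re-join the sea.

    Kelts are flagged as previous spawners so that repeat maturation rules
    apply on their next return.
    """
    m = params.adult_postspawn_mortality
    if not 0 <= m <= 1:
        raise ValueError("adult post-spawning mortality must be in [0, 1]")
    keep = rng.random(len(spawners)) >= m
    spawners.matured_prev[keep] = True
    spawners.mature[keep] = False
    return keep


def apply_straying(
    returners: Population,
    params: StrayingParams,
    profile: genetics.EffectProfile,
    rng: np.random.Generator,
    uid_start: int = 0,
) -> int:
    """Swap a fixed fraction of returners for immigrant strayers, in place.

    The number swapped is the round-half-even of ``fraction * N``.  Each
    incoming strayer copies the outgoing fish's phenotype and carries a fresh
    genotype at the incoming wild-allele frequency — or, in mirror mode, at
    the outgoing individual's own '1'-allele frequency, which preserves the
    population allele frequencies in expectation.
    """
    if not 0 <= params.stray_fraction <= 1:
        raise ValueError("stray_fraction must be in [0, 1]")
    n = len(returners)
    n_swap = int(np.rint(params.stray_fraction * n))
    if n_swap == 0:
        return 0
    idx = rng.choice(n, size=n_swap, replace=False)
    if params.mirror_mode:
        freqs = returners.geno[idx].mean(axis=(1, 2, 3))
        geno = (
            rng.random((n_swap, genetics.N_SETS, genetics.N_LOCI, 2))
            < freqs[:, None, None, None]
        ).astype(np.uint8)
    else:
        geno = genetics.init_genotypes(n_swap, params.incoming_wild_freq, rng)
    returners.geno[idx] = geno
    returners.S[idx] = genetics.sum_all_effects(geno, profile)
    returners.origin[idx] = Origin.STRAYER
    returners.uid[idx] = np.arange(uid_start, uid_start + n_swap)
    returners.midparent_ref[idx] = np.nan
    returners.cohort[idx] = -1
    returners.has_returned[idx] = False
    return n_swap


def make_escapees(
    n: int,
    params: EscapeeParams,
    profile: genetics.EffectProfile,
    condition_factor_adult: float,
    rng: np.random.Generator,
    uid_start: int = 0,
) -> Population:
    """Create ``n`` mature adult salmon of farm origin for the spawner pool."""
    if n < 0:
        raise ValueError("n must be >= 0")
    pop = Population(n)
    if n == 0:
        return pop
    pop.uid = np.arange(uid_start, uid_start + n, dtype=np.int64)
    pop.sex = (rng.random(n) < 0.5).astype(np.uint8)
    pop.phase = np.full(n, Phase.ADULT, dtype=np.uint8)
    age = rng.choice((1, 2, 3), size=n, p=np.asarray(params.sea_age_probs) / sum(params.sea_age_probs))
    pop.sea_age = age.astype(np.int8)
    mean_l = np.asarray(params.length_mean_mm, float)[age - 1]
    pop.length = np.maximum(rng.normal(mean_l, params.length_sd_frac * mean_l), 200.0)
    pop.weight = condition_factor_adult * pop.length**3
    pop.mature = np.ones(n, dtype=bool)
    pop.origin = np.full(n, Origin.FARM, dtype=np.uint8)
    pop.geno = genetics.init_genotypes(n, params.wild_allele_freq, rng)
    pop.S = genetics.sum_all_effects(pop.geno, profile)
    return pop
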