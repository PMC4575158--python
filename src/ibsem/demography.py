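"""Stochastic life-rate processes: growth, mortality, maturation, smolting.

All rates are monthly probabilities or monthly increments and depend, where
the biology calls for it, on size, age, season, water temperature, juvenile
density and the additive genetic score ``S`` of the relevant gene set.
Genotype modifiers are linear in ``S`` between the wild (S ≈ 0.9) and farm
(S ≈ 0.1) endpoints; their strength is multiplied by a global
``fitness_differential_scale`` so the wild–farm gap can be halved, doubled,
or switched off (a scale of 0 makes every rate genotype-neutral).

Probabilities are clamped to [0, 1] after every modifier; growth increments
are truncated at zero so fork length never decreases.

The numeric defaults below are the shipped calibration: they were fitted, in
the staged order documented in ``docs/methods.md``, so that the emergent
equilibrium of an undisturbed wild population reproduces the reference
demographic statistics (juvenile densities and lengths, smolt production,
marine return rates, parr maturity fractions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

S_WILD = 0.9  # additive score of the reference wild genotype


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class AlevinParams:
    """Egg size -> emergence length (mm): linear + Gaussian noise."""

    intercept_mm: float = 12.4
    slope_mm_per_g: float = 120.0
    noise_sd_mm: float = 1.0


@dataclass
class GrowthParams:
    # length-weight conversion W = c * L^3 (condition-factor form)
    condition_factor_juv: float = 1.05e-5  # g / mm^3
    condition_factor_adult: float = 1.22e-5
    allometric_b: float = 0.85
    t_min: float = 2.0  # hard temperature window (°C)
    t_max: float = 22.0
    # linear ramp (lo, hi) inside the window, per habitat/sub-phase
    ramp_parr: tuple[float, float] = (7.0, 12.0)
    ramp_smolt: tuple[float, float] = (0.0, 10.0)
    ramp_sea: tuple[float, float] = (4.0, 8.0)
    # freshwater allometric coefficients per phase/age (g^(1-b) per month)
    a_parr: tuple[float, float, float] = (1.0, 0.55, 0.33)  # p0, p1, p2
    a_smolt: float = 0.30
    # marine growth: von Bertalanffy in length towards l_inf, rate per sea age
    l_inf_mm: float = 1100.0
    kappa_sea: tuple[float, float, float, float] = (0.055, 0.041, 0.048, 0.080)
    density_coef: float = 0.5  # growth reduction 1/(1 + c*ED), parr only
    genotype_gain: float = 0.15  # farm fish grow faster
    noise_sd_parr: float = 0.30
    noise_sd_smolt: float = 0.20
    noise_sd_sea: float = 0.25
    alevin: AlevinParams = field(default_factory=AlevinParams)


@dataclass
class EffectiveDensityParams:
    """Mass-weighted competition index ED = sum((W/W_ref)^gamma) / area."""

    gamma: float = 1.0
    w_ref_g: float = 2.9  # mean parr0 autumn weight


@dataclass
class MortalityParams:
    # embryonic: survival = (s0 + s1*egg_size) * exp(-k*egg_density) * phi(S)
    egg_base: float = 0.88
    egg_size_slope: float = 1.0  # per g
    egg_density_coef: float = 0.12  # per (eggs/m^2)
    egg_genotype_gain: float = 0.20
    alevin_monthly: float = 0.03
    # juvenile monthly baselines (survival = 1 - m); calibrated
    juv_warm: tuple[float, float, float] = (0.24, 0.012, 0.011)  # p0, p1, p2
    juv_rest: tuple[float, float, float] = (0.032, 0.022, 0.019)
    smolt_monthly: float = 0.030  # same Nov–Feb and Mar–Apr
    juv_density_coef: tuple[float, float, float] = (0.45, 0.08, 0.08)
    juv_genotype_gain: float = 0.03
    # marine: m = m_inf + A * exp(-L / L_s), survival scaled by psi(S)
    marine_m_inf: float = 0.018
    marine_amplitude: float = 3.0
    marine_length_scale_mm: float = 250.0
    marine_genotype_gain: float = 0.04
    marine_age_mult: tuple[float, float, float, float] = (2.7, 1.0, 1.0, 1.0)
    ed: EffectiveDensityParams = field(default_factory=EffectiveDensityParams)


@dataclass
class MaturationParams:
    parr_midpoint_mm: float = 105.0
    parr_steepness_mm: float = 12.0
    repeat_multiplier: float = 2.0  # capped to probability 1
    adult_base: tuple[float, float, float] = (0.41, 0.88, 1.0)  # 1SW..3SW
    adult_genotype_gain: float = 0.35  # lower S delays return


@dataclass
class SmoltingParams:
    threshold_mm: float = 90.0
    midpoint_mm: float = 103.0  # 50% smolting probability
    steepness_mm: float = 3.0


@dataclass
class RateParams:
    growth: GrowthParams = field(default_factory=GrowthParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    maturation: MaturationParams = field(default_factory=MaturationParams)
    smolting: SmoltingParams = field(default_factory=SmoltingParams)
    fitness_differential_scale: float = 1.0


# ---------------------------------------------------------------------------
# genotype modifiers (linear between wild and farm endpoints)


def survival_factor(S, gain: float, scale: float):
    """Multiplier on survival; 1 at the wild endpoint, < 1 for farm fish."""
    return np.maximum(0.0, 1.0 + gain * scale * (np.asarray(S, float) - S_WILD))


def growth_factor(S, gain: float, scale: float):
    """Multiplier on growth; 1 at the wild endpoint, > 1 for farm fish."""
    return np.maximum(0.0, 1.0 + gain * scale * (S_WILD - np.asarray(S, float)))


# ---------------------------------------------------------------------------
# growth


def alevin_length_at_emergence(egg_size, params: AlevinParams, rng=None):
    """Fork length (mm) at emergence, linear in egg weight plus noise."""
    egg_size = np.asarray(egg_size, dtype=float)
    if (egg_size <= 0).any():
        raise ValueError("egg_size must be positive")
    mean = params.intercept_mm + params.slope_mm_per_g * egg_size
    if rng is None or params.noise_sd_mm == 0:
        out = mean
    else:
        out = mean + rng.normal(0.0, params.noise_sd_mm, size=egg_size.shape)
    return np.maximum(out, 5.0)


def effective_density(weights_g, area_m2: float, params: EffectiveDensityParams):
    """Mass-weighted fish density of the juvenile (parr) population."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    w = np.asarray(weights_g, dtype=float)
    if w.size == 0:
        return 0.0
    return float(((w / params.w_ref_g) ** params.gamma).sum() / area_m2)


def temperature_factor(T: float, ramp: tuple[float, float], g: GrowthParams) -> float:
    """Growth scaling in [0, 1]: zero outside the hard window, linear ramp inside."""
    if T <= g.t_min or T >= g.t_max:
        return 0.0
    lo, hi = ramp
    return float(np.clip((T - lo) / (hi - lo), 0.0, 1.0))


def growth_increment(
    weight,
    S,
    a,
    f_temp: float,
    g_density: float,
    noise_sd: float,
    params: GrowthParams,
    scale: float,
    rng=None,
):
    """Monthly weight increment a * W^b * f(T) * g(ED) * h(S) * (1 + eps), >= 0."""
    w = np.asarray(weight, dtype=float)
    h = growth_factor(S, params.genotype_gain, scale)
    inc = np.asarray(a, float) * w**params.allometric_b * f_temp * g_density * h
    if rng is not None and noise_sd > 0:
        inc = inc * (1.0 + rng.normal(0.0, noise_sd, size=w.shape))
    return np.maximum(inc, 0.0)


def length_from_weight(weight, length, condition_factor: float):
    """Update fork length from weight; length never decreases."""
    return np.maximum(length, (np.asarray(weight, float) / condition_factor) ** (1.0 / 3.0))


def density_growth_factor(ed: float, params: GrowthParams) -> float:
    return 1.0 / (1.0 + params.density_coef * ed)


def sea_length_increment(
    length,
    sea_age,
    S,
    f_temp: float,
    params: GrowthParams,
    scale: float,
    rng=None,
):
    """Monthly marine fork-length increment, von Bertalanffy towards ``l_inf``.

    Post-smolt growth decelerates as fish approach the asymptotic size, which
    bounds adult size even for long-lived repeat spawners; the growth rate is
    highest in the first sea year and is set per sea age.
    """
    L = np.asarray(length, dtype=float)
    kappa = np.asarray(params.kappa_sea, float)[np.clip(np.asarray(sea_age), 0, 3)]
    h = growth_factor(S, params.genotype_gain, scale)
    inc = kappa * np.maximum(params.l_inf_mm - L, 0.0) * f_temp * h
    if rng is not None and params.noise_sd_sea > 0:
        inc = inc * (1.0 + rng.normal(0.0, params.noise_sd_sea, size=L.shape))
    return np.maximum(inc, 0.0)


# ---------------------------------------------------------------------------
# mortality (all monthly probabilities unless stated)


def _clip_survival(surv, stage: str):
    """Clamp survival to [0, 1]; out-of-range values are logged (debug)."""
    arr = np.asarray(surv, float)
    n_out = int(np.count_nonzero((arr < 0.0) | (arr > 1.0)))
    if n_out:
        logger.debug("%s survival clamped for %d individuals", stage, n_out)
    return np.clip(arr, 0.0, 1.0)


def egg_mortality_prob(S_emb, egg_size, egg_density, params: MortalityParams,
                       scale: float = 1.0):
    """Compound egg-to-emergence mortality, applied once on 1 April.

    Survival is linear in egg size, exponentially decreasing in egg density
    and reduced for farm genotypes.
    """
    surv = (
        (params.egg_base + params.egg_size_slope * np.asarray(egg_size, float))
        * np.exp(-params.egg_density_coef * np.asarray(egg_density, float))
        * survival_factor(S_emb, params.egg_genotype_gain, scale)
    )
    return 1.0 - _clip_survival(surv, "egg")


_JUV_AGES = {"p0": 0, "p1": 1, "p2": 2}


def juvenile_mortality_prob(age: str, season: str, ed: float, S_juv,
                            params: MortalityParams, scale: float = 1.0):
    """Monthly freshwater mortality for parr (density-dependent) and smolts.

    Parr baselines decrease with freshwater age and are lower in the resting
    season; smolts use a single baseline in all months of the sub-phase and
    carry no density dependence.
    """
    if age == "smolt":
        base = params.smolt_monthly
        dens = 1.0
    else:
        i = _JUV_AGES[age]
        if season == "warm":
            base = params.juv_warm[i]
            # density-dependent competition acts while parr feed
            dens = np.exp(-params.juv_density_coef[i] * ed)
        elif season == "resting":
            base = params.juv_rest[i]
            dens = 1.0
        else:
            raise ValueError(f"unknown season {season!r}")
    surv = (1.0 - base) * dens * survival_factor(S_juv, params.juv_genotype_gain, scale)
    return 1.0 - _clip_survival(surv, "juvenile")


def marine_mortality_prob(sea_age, fork_length, S_adult, params: MortalityParams,
                          scale: float = 1.0):
    """Monthly sea mortality, decreasing in fork length and in S (wild safer)."""
    sea_age = np.asarray(sea_age)
    mult = np.asarray(params.marine_age_mult, float)[np.clip(sea_age, 0, 3)]
    m = params.marine_m_inf + params.marine_amplitude * np.exp(
        -np.asarray(fork_length, float) / params.marine_length_scale_mm
    )
    m = np.clip(m * mult, 0.0, 1.0)
    surv = (1.0 - m) * survival_factor(S_adult, params.marine_genotype_gain, scale)
    return 1.0 - _clip_survival(surv, "marine")


def apply_mortality(m, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli survival draw: returns a boolean *survivor* mask.

    Each individual dies iff the uniform draw r < m.
    """
    m = np.asarray(m, dtype=float)
    if ((m < 0) | (m > 1)).any():
        raise ValueError("mortality probabilities must lie in [0, 1]")
    return rng.random(m.shape) >= m


# ---------------------------------------------------------------------------
# maturation and smolting


def parr_maturation_prob(fork_length, matured_previously, params: MaturationParams):
    """Sigmoidal (in length) October maturation probability for male parr.

    Fish that matured the previous season get a doubled probability, capped
    at one.
    """
    L = np.asarray(fork_length, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(L - params.parr_midpoint_mm) / params.parr_steepness_mm))
    p = np.where(
        np.asarray(matured_previously, bool),
        np.minimum(1.0, params.repeat_multiplier * p),
        p,
    )
    return p


def adult_return_prob(sea_age, S_adult, params: MaturationParams, scale: float = 1.0):
    """Probability of returning to spawn this October, per sea age.

    0SW fish never return; fish at the maximum sea age (3SW) always do.
    Lower S shifts the probability down, delaying the return of farm fish.
    """
    sea_age = np.asarray(sea_age)
    base = np.asarray((0.0,) + tuple(params.adult_base), float)[np.clip(sea_age, 0, 3)]
    p = np.clip(
        base + params.adult_genotype_gain * scale * (np.asarray(S_adult, float) - S_WILD),
        0.0,
        1.0,
    )
    p = np.where(sea_age >= 3, 1.0, p)
    return np.where(sea_age < 1, 0.0, p)


def smolt_decision_prob(fork_length, params: SmoltingParams):
    """End-of-October probability of smolting next May: hard 90 mm threshold,
    then a logistic of length equal to 0.5 at the 103 mm midpoint."""
    L = np.asarray(fork_length, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(L - params.midpoint_mm) / params.steepness_mm))
    return np.where(L < params.threshold_mm, 0.0, p)
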