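"""Monthly scheduler, annual calendar, and scenario execution.

One simulated year follows the fixed life-history calendar:

* 1 January — sea-age increment for oceanic adults.
* 1 April — eggs hatch/emerge: compound egg mortality, then alevins.
* 1 May — alevins become young-of-the-year parr, parr ages increment, and
  flagged smolts migrate to sea as 0SW adults.
* October — begin-month: male parr maturation decision (maturing parr skip
  October growth); end-month: adult return decision, straying swap, escapee
  injection, spawner census, mature-parr pre-spawning mortality, spawning
  (egg creation), adult post-spawning fate (kelts re-join the sea), and the
  end-of-October smolt decision for parr.
* 1 November — flagged parr enter the smolt sub-phase.

Within every month the operation order is: begin-month calendar events,
temperature draw, growth, mortality, end-month calendar events.  An
individual-count ledger (births + immigrants − deaths − emigrants) is
balanced every month.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import demography as dem
from . import genetics, reproduction
from .environment import season_of
from .monitoring import Monitor, estimate_heritability, sample_population, summarize
from .population import Origin, Phase, Population, Sex

# independent RNG sub-streams per replicate
_STREAMS = ("environment", "growth", "mortality", "reproduction", "genetics", "init")


@dataclass
class ScenarioSpec:
    """Schedule and conditions for one simulation experiment."""

    scenario_id: int = 1
    years: int = 200
    monitor_start: int = 100
    replicates: int = 10
    scale: float = 1.0  # multiplies river area and all absolute abundances
    init_wild_freq: float = 0.9
    fitness_differential_scale: float = 1.0
    mirror_straying: bool = False
    escapees_per_year: float = 0.0  # at full river scale
    introgression_start: int = 0
    introgression_end: int = 0

    def __post_init__(self) -> None:
        if self.years < 1 or self.replicates < 1:
            raise ValueError("years and replicates must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


_ESCAPEE_CASES = {"mild": 25.0, "intermediate": 100.0, "high": 250.0}


def scenario_preset(
    scenario_id: int,
    *,
    introgression: str = "high",
    replicates: int | None = None,
    scale: float = 1.0,
) -> ScenarioSpec:
    """Built-in experiment schedules.

    1 — wild population: 100 y settling + 100 y monitoring.
    2 — farm-initialized population (wild allele frequency 0.1), 200 y.
    3/4/5 — 50 y settling, 200 y of farm-escapee introgression, 200 y of
    recovery, with the wild–farm differential at ×1, ×0.5 and ×2, and
    frequency-mirroring strayers.
    """
    if scenario_id == 1:
        spec = ScenarioSpec(1, years=200, monitor_start=100)
    elif scenario_id == 2:
        spec = ScenarioSpec(2, years=200, monitor_start=0, init_wild_freq=0.1)
    elif scenario_id in (3, 4, 5):
        fds = {3: 1.0, 4: 0.5, 5: 2.0}[scenario_id]
        spec = ScenarioSpec(
            scenario_id,
            years=450,
            monitor_start=50,
            fitness_differential_scale=fds,
            mirror_straying=True,
            escapees_per_year=_ESCAPEE_CASES[introgression],
            introgression_start=50,
            introgression_end=250,
        )
    else:
        raise ValueError(f"unknown scenario {scenario_id}")
    if replicates is not None:
        spec = replace(spec, replicates=replicates)
    return replace(spec, scale=scale)


class SimulationState:
    """Mutable per-replicate state: population, environment, RNG streams."""

    def __init__(self, spec: ScenarioSpec, cfg, seed_seq: np.random.SeedSequence,
                 replicate: int = 0):
        self.spec = spec
        self.cfg = cfg
        self.replicate = replicate
        self.env = cfg.environment.scaled(spec.scale)
        self.profile = genetics.make_effect_profile(decay=cfg.genetics_decay)
        self.rates = cfg.rates
        self.spawning = cfg.spawning
        self.straying = replace(cfg.straying, mirror_mode=spec.mirror_straying)
        self.escapee = cfg.escapee
        self.fds = spec.fitness_differential_scale
        children = seed_seq.spawn(len(_STREAMS))
        self.rng = {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}
        self.year = 0
        self.month = 5  # simulations start in May
        self._uid = 0
        self.pop = self._initial_population()
        self.returns_by_cohort: dict[int, int] = {}
        self.smolt_out: dict[int, int] = {}
        self.ledger: list[tuple[int, int, int, int]] = []  # year, month, expected, actual
        self.monitor: Monitor | None = None

    # ------------------------------------------------------------------
    def next_uids(self, n: int) -> np.ndarray:
        out = np.arange(self._uid, self._uid + n, dtype=np.int64)
        self._uid += n
        return out

    def _make_cohort(self, n, phase, parr_age, sea_age, len_mean, len_sd,
                     freq, rng, juvenile=True) -> Population:
        g = self.rates.growth
        pop = Population(n)
        pop.uid = self.next_uids(n)
        pop.sex = (rng.random(n) < 0.5).astype(np.uint8)
        pop.phase = np.full(n, phase, dtype=np.uint8)
        pop.parr_age = np.full(n, parr_age, dtype=np.int8)
        pop.sea_age = np.full(n, sea_age, dtype=np.int8)
        pop.length = np.maximum(rng.normal(len_mean, len_sd, n), 10.0)
        c = g.condition_factor_juv if juvenile else g.condition_factor_adult
        pop.weight = c * pop.length**3
        pop.geno = genetics.init_genotypes(n, freq, rng)
        pop.S = genetics.sum_all_effects(pop.geno, self.profile)
        return pop

    def _initial_population(self) -> Population:
        """May start: parr cohorts plus oceanic adults spread over sea ages."""
        cfg, spec = self.cfg, self.spec
        rng = self.rng["init"]
        ini = cfg.initial
        freq = spec.init_wild_freq
        sc = spec.scale
        pop = Population(0)
        for n, age, L, sd in (
            (ini.n_p0, 0, ini.len_p0_mm, ini.len_sd_p0_mm),
            (ini.n_p1, 1, ini.len_p1_mm, ini.len_sd_parr_mm),
            (ini.n_p2, 2, ini.len_p2_mm, ini.len_sd_parr_mm),
        ):
            n = int(round(n * sc))
            if n:
                pop.append(self._make_cohort(n, Phase.PARR, age, -1, L, sd, freq, rng))
        n_ad = int(round(ini.n_adult * sc))
        base, extra = divmod(n_ad, 4)
        for age in range(4):
            n = base + (1 if age < extra else 0)
            if n:
                L = ini.len_adult_mm[age]
                pop.append(
                    self._make_cohort(n, Phase.ADULT, -1, age, L,
                                      ini.len_sd_adult_frac * L, freq, rng,
                                      juvenile=False)
                )
        return pop


# ---------------------------------------------------------------------------
# monthly step


def initialize_population(spec: ScenarioSpec, cfg, seed: int | np.random.SeedSequence = 0,
                          replicate: int = 0) -> SimulationState:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return SimulationState(spec, cfg, ss, replicate)


def _grow_group(state: SimulationState, mask: np.ndarray, a_values, f_temp: float,
                g_density: float, noise_sd: float, condition_factor: float) -> None:
    if not mask.any() or f_temp == 0.0:
        return
    P = state.pop
    g = state.rates.growth
    inc = dem.growth_increment(
        P.weight[mask], P.S[mask, 1], a_values, f_temp, g_density,
        noise_sd, g, state.fds, state.rng["growth"],
    )
    P.weight[mask] = P.weight[mask] + inc
    P.length[mask] = dem.length_from_weight(P.weight[mask], P.length[mask], condition_factor)


def _grow_sea(state: SimulationState, mask: np.ndarray, f_temp: float) -> None:
    if not mask.any() or f_temp == 0.0:
        return
    P = state.pop
    g = state.rates.growth
    inc = dem.sea_length_increment(
        P.length[mask], P.sea_age[mask], P.S[mask, 2], f_temp, g, state.fds,
        state.rng["growth"],
    )
    P.length[mask] = P.length[mask] + inc
    P.weight[mask] = np.maximum(
        P.weight[mask], g.condition_factor_adult * P.length[mask] ** 3
    )


def step_month(state: SimulationState) -> None:
    """Advance the simulation by one month (in place)."""
    P = state.pop
    spec = state.spec
    month = state.month
    area = state.env.river_area_m2
    n_start = len(P)
    births = immigrants = deaths = emigrants = 0
    mon = state.monitor

    # ---- begin-of-month calendar events -------------------------------
    if month == 1:
        at_sea = P.mask(phase=Phase.ADULT)
        P.sea_age[at_sea] = np.minimum(P.sea_age[at_sea] + 1, 3)

    if month == 4:
        egg = P.mask(phase=Phase.EGG)
        n_eggs = int(egg.sum())
        if n_eggs:
            d_egg = n_eggs / area
            m_egg = dem.egg_mortality_prob(
                P.S[egg, 0], P.egg_size[egg], d_egg, state.rates.mortality, state.fds
            )
            survive = dem.apply_mortality(m_egg, state.rng["mortality"])
            dead = egg.copy()
            dead[egg] = ~survive
            deaths += int(dead.sum())
            P.keep(~dead)
            al = P.mask(phase=Phase.EGG)  # survivors still flagged EGG
            P.phase[al] = Phase.ALEVIN
            P.length[al] = dem.alevin_length_at_emergence(
                P.egg_size[al], state.rates.growth.alevin, state.rng["growth"]
            )
            P.weight[al] = state.rates.growth.condition_factor_juv * P.length[al] ** 3

    if month == 5:
        # smolts migrate to sea as 0SW adults
        sm = P.mask(phase=Phase.SMOLT)
        state.smolt_out[state.year] = int(sm.sum())
        P.phase[sm] = Phase.ADULT
        P.sea_age[sm] = 0
        P.parr_age[sm] = -1
        P.cohort[sm] = state.year
        P.smolt_flag[sm] = False
        # parr age up, then alevins recruit as young-of-the-year parr
        pr = P.mask(phase=Phase.PARR)
        P.parr_age[pr] = np.minimum(P.parr_age[pr] + 1, 2)
        al = P.mask(phase=Phase.ALEVIN)
        P.phase[al] = Phase.PARR
        P.parr_age[al] = 0
        P.egg_size[al] = np.nan
        if mon:
            mon.add(sample_population(P, area, "may"))

    if month == 11:
        presmolt = P.mask(phase=Phase.PARR) & P.smolt_flag
        P.phase[presmolt] = Phase.SMOLT
        if mon:
            # h² census: young-of-the-year length on 1 November
            p0 = P.mask(phase=Phase.PARR, parr_age=0)
            P.ref_length[p0] = P.length[p0]
            mon.add(sample_population(P, area, "nov"))
            rec = {
                "h2": estimate_heritability(P.midparent_ref[p0], P.length[p0]),
                "S_emb_all": float(P.S[:, 0].mean()) if len(P) else np.nan,
                "S_juv_all": float(P.S[:, 1].mean()) if len(P) else np.nan,
                "S_adult_all": float(P.S[:, 2].mean()) if len(P) else np.nan,
                "locus21_freq": float(P.geno[:, :, 20, :].mean()) if len(P) else np.nan,
            }
            if len(P):
                freqs = P.geno.mean(axis=(0, 3))  # (3 sets, 21 loci)
                for s, tag in enumerate(("emb", "juv", "adult")):
                    for locus in state.cfg.tracked_loci:
                        rec[f"freq_{tag}_l{locus}"] = float(freqs[s, locus - 1])
            mon.add(rec)

    # ---- October maturation decision (before growth) -------------------
    if month == 10:
        males = P.mask(phase=Phase.PARR, sex=Sex.MALE)
        if males.any():
            p = dem.parr_maturation_prob(
                P.length[males], P.matured_prev[males], state.rates.maturation
            )
            P.mature[males] = state.rng["mortality"].random(p.shape) < p
        if mon:
            mon.add(sample_population(P, area, "oct1"))

    # ---- temperature, growth -------------------------------------------
    env_rng = state.rng["environment"]
    t_river = state.env.get_temperature(month, "river", env_rng)
    t_sea = state.env.get_temperature(month, "sea", env_rng)
    g = state.rates.growth
    parr = P.mask(phase=Phase.PARR)
    ed = dem.effective_density(P.weight[parr], area, state.rates.mortality.ed)

    if season_of(month) == "warm":
        grow = parr & ~(P.mature if month == 10 else np.zeros(len(P), bool))
        a = np.asarray(g.a_parr)[np.clip(P.parr_age[grow], 0, 2)]
        _grow_group(state, grow, a, dem.temperature_factor(t_river, g.ramp_parr, g),
                    dem.density_growth_factor(ed, g), g.noise_sd_parr,
                    g.condition_factor_juv)
    sm = P.mask(phase=Phase.SMOLT)
    _grow_group(state, sm, g.a_smolt, dem.temperature_factor(t_river, g.ramp_smolt, g),
                1.0, g.noise_sd_smolt, g.condition_factor_juv)
    ad = P.mask(phase=Phase.ADULT)
    _grow_sea(state, ad, dem.temperature_factor(t_sea, g.ramp_sea, g))

    # ---- mortality ------------------------------------------------------
    mparams = state.rates.mortality
    m = np.zeros(len(P))
    if month == 4:
        m[P.mask(phase=Phase.ALEVIN)] = mparams.alevin_monthly
    season = season_of(month)
    for age, tag in ((0, "p0"), (1, "p1"), (2, "p2")):
        sel = P.mask(phase=Phase.PARR, parr_age=age)
        if sel.any():
            # in March-April parr are 11 months from emergence and about to be
            # promoted on 1 May; the next age class's baseline applies
            eff = f"p{min(age + 1, 2)}" if month in (3, 4) else tag
            m[sel] = dem.juvenile_mortality_prob(
                eff, season, ed, P.S[sel, 1], mparams, state.fds
            )
    sel = P.mask(phase=Phase.SMOLT)
    if sel.any():
        m[sel] = dem.juvenile_mortality_prob("smolt", season, ed, P.S[sel, 1],
                                             mparams, state.fds)
    sel = P.mask(phase=Phase.ADULT)
    if sel.any():
        m[sel] = dem.marine_mortality_prob(P.sea_age[sel], P.length[sel],
                                           P.S[sel, 2], mparams, state.fds)
    survive = dem.apply_mortality(m, state.rng["mortality"])
    deaths += int((~survive).sum())
    P.keep(survive)

    # ---- end-of-month calendar events ----------------------------------
    if month == 9 and mon:
        mon.add(sample_population(P, area, "sep"))

    if month == 10:
        rng_rep = state.rng["reproduction"]
        # adult return decision
        at_sea = P.mask(phase=Phase.ADULT)
        p_ret = dem.adult_return_prob(P.sea_age, P.S[:, 2], state.rates.maturation,
                                      state.fds)
        p_ret[~at_sea] = 0.0
        returning = rng_rep.random(len(P)) < p_ret
        # first-time returns per smolt year-class (before straying swaps)
        first = returning & ~P.has_returned & (P.cohort >= 0)
        for c, k in zip(*np.unique(P.cohort[first], return_counts=True)):
            state.returns_by_cohort[int(c)] = state.returns_by_cohort.get(int(c), 0) + int(k)
        P.has_returned[returning] = True
        P.mature[returning] = True

        spawners = P.select(returning)
        P.keep(~returning)
        n_out = reproduction.apply_straying(
            spawners, state.straying, state.profile, rng_rep,
            uid_start=state._uid,
        )
        state._uid += n_out
        emigrants += n_out
        immigrants += n_out
        if mon:
            # native returners (strayers swapped in, escapees not yet added)
            mon.add({"returners_n": len(spawners)})
        # farm escapees join the pool after straying
        if spec.introgression_start <= state.year < spec.introgression_end:
            n_esc = int(round(spec.escapees_per_year * spec.scale))
            if n_esc:
                esc = reproduction.make_escapees(
                    n_esc, state.escapee, state.profile,
                    g.condition_factor_adult, rng_rep, uid_start=state._uid,
                )
                state._uid += n_esc
                spawners.append(esc)
                immigrants += n_esc
        if mon:
            mon.add(sample_population(spawners, area, "spawners"))

        # mature male parr: pre-spawning mortality, then join as sires
        mat_parr = P.mask(phase=Phase.PARR) & P.mature
        parr_pool = P.select(mat_parr)
        alive = reproduction.prespawn_parr_mortality(parr_pool, state.spawning, rng_rep)
        deaths += int((~alive).sum())
        # remove the casualties from the river population
        dead_rows = np.flatnonzero(mat_parr)[~alive]
        keep_mask = np.ones(len(P), bool)
        keep_mask[dead_rows] = False
        P.keep(keep_mask)
        parr_pool.keep(alive)

        # spawning
        fem = spawners.select(spawners.sex == Sex.FEMALE)
        mal = spawners.select(spawners.sex == Sex.MALE)
        eggs = reproduction.spawn(fem, mal, parr_pool, state.spawning,
                                  state.profile, rng_rep, uid_start=state._uid)
        state._uid += len(eggs)
        births += len(eggs)
        if mon:
            mon.add(sample_population(eggs, area, "eggs"))

        # post-spawning fate: kelts re-join the sea population on 1 November
        kelt = reproduction.postspawn_adult_fate(spawners, state.spawning, rng_rep)
        deaths += int((~kelt).sum())
        spawners.keep(kelt)
        P.append(spawners)
        P.append(eggs)

        # mature parr survivors are flagged as previous spawners
        mat_parr = P.mask(phase=Phase.PARR) & P.mature
        P.matured_prev[mat_parr] = True
        P.mature[mat_parr] = False

        # end-of-October smolt decision
        pr = P.mask(phase=Phase.PARR)
        p_sm = dem.smolt_decision_prob(P.length[pr], state.rates.smolting)
        P.smolt_flag[pr] = rng_rep.random(p_sm.shape) < p_sm

    if month == 4 and mon:
        mon.add(sample_population(P, area, "apr"))

    # ---- ledger and clock ----------------------------------------------
    expected = n_start + births + immigrants - deaths - emigrants
    state.ledger.append((state.year, month, expected, len(P)))
    state.month = month % 12 + 1
    if month == 12:
        state.year += 1


# ---------------------------------------------------------------------------
# scenario execution


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    frames: list[pd.DataFrame]
    extras: list[dict] = field(default_factory=list)

    def monitored(self) -> list[pd.DataFrame]:
        return [f[f.year >= self.spec.monitor_start] for f in self.frames]

    def summary(self) -> pd.DataFrame:
        return summarize(self.monitored())


def run_replicate(spec: ScenarioSpec, cfg, seed_seq, replicate: int = 0):
    """Run one replicate; returns (annual records, extras dict)."""
    state = initialize_population(spec, cfg, seed_seq, replicate)
    mon = Monitor(replicate)
    state.monitor = mon
    mon.begin_year(0)
    for _ in range(spec.years * 12):
        step_month(state)
        if state.month == 1:
            mon.begin_year(state.year)
    extras = {
        "returns_by_cohort": state.returns_by_cohort,
        "smolt_out": state.smolt_out,
        "ledger": state.ledger,
        "final_size": len(state.pop),
    }
    frame = mon.to_frame()
    # the run ends in April of the final calendar year; drop that stub row
    return frame[frame.year < spec.years].reset_index(drop=True), extras


def run_scenario(spec: ScenarioSpec, cfg, master_seed: int = 0) -> ScenarioResult:
    """Run all replicates with independent seeded streams."""
    root = np.random.SeedSequence(master_seed)
    frames, extras = [], []
    for rep, child in enumerate(root.spawn(spec.replicates)):
        f, e = run_replicate(spec, cfg, child, rep)
        frames.append(f)
        extras.append(e)
    return ScenarioResult(spec, frames, extras)
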