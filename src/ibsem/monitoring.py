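"""Sampling calendar, summary statistics and emergent heritability.

The monitoring calendar mirrors the field surveys the simulator is judged
against: parr on 1 May and 1 November, smolts on 1 November and at the end of
April (just before seaward migration), oceanic salmon at the end of September
(before returns), spawners at pool formation in October, and the egg cohort
right after spawning.

Heritability of fork length is an *emergent* quantity here: it is estimated
each year by regressing offspring length on midparent length, both measured
at the same fixed census (young-of-the-year parr on 1 November).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .population import Phase, Population, Sex

logger = logging.getLogger(__name__)

SAMPLE_LABELS = ("may", "oct1", "spawners", "eggs", "nov", "apr", "sep")


def _moments(x: np.ndarray, prefix: str) -> dict:
    out = {f"{prefix}_n": int(x.size)}
    if x.size:
        out[f"{prefix}_mean"] = float(np.mean(x))
        out[f"{prefix}_sd"] = float(np.std(x))
    else:  # empty stage: moments undefined
        out[f"{prefix}_mean"] = np.nan
        out[f"{prefix}_sd"] = np.nan
    return out


def sample_population(pop: Population, area_m2: float, label: str) -> dict:
    """Stage-resolved census for one calendar date label."""
    rec: dict = {}
    if label == "may":
        for age, tag in ((0, "p0"), (1, "p1"), (2, "p2")):
            m = pop.mask(phase=Phase.PARR, parr_age=age)
            rec.update(_moments(pop.length[m], f"{tag}_may_len"))
            rec[f"{tag}_may_density"] = m.sum() / area_m2
    elif label == "oct1":
        for age, tag in ((1, "p1"), (2, "p2")):
            males = pop.mask(phase=Phase.PARR, parr_age=age, sex=Sex.MALE)
            n = int(males.sum())
            rec[f"{tag}_male_n"] = n
            rec[f"{tag}_male_mature_frac"] = (
                float(pop.mature[males].mean()) if n else np.nan
            )
    elif label == "nov":
        juv = 0
        for age in (0, 1, 2):
            for ph, tag in ((Phase.PARR, f"p{age}"), (Phase.SMOLT, f"smolt{age}")):
                m = pop.mask(phase=ph, parr_age=age)
                rec.update(_moments(pop.length[m], f"{tag}_nov_len"))
                rec[f"{tag}_nov_density"] = m.sum() / area_m2
                juv += int(m.sum())
        rec["juvenile_nov_density"] = juv / area_m2
        sm = pop.mask(phase=Phase.SMOLT)
        rec["S_juv_mean"] = float(pop.S[sm, 1].mean()) if sm.any() else np.nan
    elif label == "apr":
        for age in (0, 1, 2):
            m = pop.mask(phase=Phase.SMOLT, parr_age=age)
            rec.update(_moments(pop.length[m], f"smolt{age}_apr_len"))
            rec[f"smolt{age}_apr_density"] = m.sum() / area_m2
        al = pop.mask(phase=Phase.ALEVIN)
        rec["S_emb_mean"] = float(pop.S[al, 0].mean()) if al.any() else np.nan
    elif label == "sep":
        for age in (0, 1, 2, 3):
            m = pop.mask(phase=Phase.ADULT, sea_age=age)
            rec.update(_moments(pop.length[m], f"sea{age}_sep_len"))
            rec[f"sea{age}_sep_n"] = int(m.sum())
        ad = pop.mask(phase=Phase.ADULT)
        rec["S_adult_mean"] = float(pop.S[ad, 2].mean()) if ad.any() else np.nan
        # young-of-the-year at the end of the warm feeding months, before the
        # October maturation and spawning events (end-of-summer survivors)
        rec["p0_sep_density"] = pop.mask(phase=Phase.PARR, parr_age=0).sum() / area_m2
    elif label == "spawners":
        for age in (1, 2, 3):
            m = pop.sea_age == age
            rec.update(_moments(pop.length[m], f"spawner{age}_len"))
            rec[f"spawner{age}_n"] = int(m.sum())
        rec["spawners_n"] = len(pop)
    elif label == "eggs":
        rec["eggs_laid"] = len(pop)
        rec["egg_density"] = len(pop) / area_m2
    else:
        raise ValueError(f"unknown sample label {label!r}; expected one of {SAMPLE_LABELS}")
    return rec


class Monitor:
    """Accumulates one flat record per simulated year."""

    def __init__(self, replicate: int = 0):
        self.replicate = replicate
        self.records: list[dict] = []
        self._current: dict | None = None

    def begin_year(self, year: int) -> None:
        self.end_year()
        self._current = {"replicate": self.replicate, "year": year}

    def add(self, values: dict) -> None:
        if self._current is not None:
            self._current.update(values)

    def end_year(self) -> None:
        if self._current is not None:
            self._derive_rates(self._current)
            self.records.append(self._current)
            self._current = None

    @staticmethod
    def _derive_rates(rec: dict) -> None:
        """Within-year interval mortality rates from the census counts."""
        for age in (0, 1, 2):
            may = rec.get(f"p{age}_may_density")
            nov = rec.get(f"p{age}_nov_density", 0.0)
            nov += rec.get(f"smolt{age}_nov_density", 0.0)
            if may and may > 0 and nov is not None:
                rec[f"p{age}_warm_mortality"] = 1.0 - nov / may

    def to_frame(self) -> pd.DataFrame:
        self.end_year()
        return pd.DataFrame(self.records)


def summarize(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Average/Stdev/Min/Max table across years and replicates.

    Mean and SD are computed within each replicate over its years and then
    averaged across replicates; min and max pool all years and replicates.
    """
    if not frames:
        raise ValueError("need at least one replicate record")
    num = [f.drop(columns=["replicate", "year"], errors="ignore").select_dtypes("number")
           for f in frames]
    means = pd.concat([f.mean() for f in num], axis=1).mean(axis=1)
    sds = pd.concat([f.std(ddof=0) for f in num], axis=1).mean(axis=1)
    pooled = pd.concat(num)
    return pd.DataFrame(
        {"Average": means, "Stdev": sds, "Min": pooled.min(), "Max": pooled.max()}
    )


def population_snapshot(pop: Population) -> pd.DataFrame:
    """Individual-level snapshot with genotype serialization.

    One row per fish: state columns, the additive score per phase, and the
    '1'-allele count (0/1/2) per locus for each gene set, as columns
    ``set_<phase>_locus_<i>``.
    """
    data = {
        "uid": pop.uid, "sex": pop.sex, "phase": pop.phase,
        "parr_age": pop.parr_age, "sea_age": pop.sea_age,
        "length_mm": pop.length, "weight_g": pop.weight,
        "mature": pop.mature, "origin": pop.origin,
        "S_embryonic": pop.S[:, 0], "S_juvenile": pop.S[:, 1],
        "S_adult": pop.S[:, 2],
    }
    counts = pop.geno.sum(axis=3)  # (n, 3, 21)
    for s, tag in enumerate(("embryonic", "juvenile", "adult")):
        for locus in range(counts.shape[2]):
            data[f"set_{tag}_locus_{locus + 1}"] = counts[:, s, locus]
    return pd.DataFrame(data)


def equilibrium_metrics(result, river_area_m2: float) -> dict:
    """Key wild-equilibrium statistics from a monitored scenario run.

    Pools the monitoring years of every replicate: cumulative egg-to-autumn-
    parr mortality (cohort-matched across years), overall smolt-to-returner
    survivorship per smolt year-class, juvenile densities, census mean
    lengths and parr maturity fractions.
    """
    frames = result.monitored()
    start = result.spec.monitor_start
    end = result.spec.years

    egg_mort, egg_mort_sep = [], []
    for f in result.frames:
        fi = f.set_index("year")
        for y in range(max(start - 1, 0), end - 1):
            if y in fi.index and y + 1 in fi.index:
                eggs = fi.loc[y, "eggs_laid"]
                if np.isfinite(eggs) and eggs > 0:
                    p0 = fi.loc[y + 1, "p0_nov_density"] * river_area_m2
                    egg_mort.append(1.0 - p0 / eggs)
                    if "p0_sep_density" in fi.columns:
                        p0s = fi.loc[y + 1, "p0_sep_density"] * river_area_m2
                        egg_mort_sep.append(1.0 - p0s / eggs)

    ret_rates = []
    for e in result.extras:
        sm, rb = e["smolt_out"], e["returns_by_cohort"]
        for y in sorted(sm):
            # only cohorts whose returns are fully resolved by the end of run
            if start <= y <= end - 6 and sm.get(y, 0) > 30:
                ret_rates.append(rb.get(y, 0) / sm[y])

    def pooled_mean(col):
        vals = [f[col].to_numpy(dtype=float) for f in frames if col in f]
        allv = np.concatenate(vals) if vals else np.array([np.nan])
        return float(np.nanmean(allv))

    smolt_prod = float(np.nanmean(np.concatenate([
        (f["smolt0_apr_density"] + f["smolt1_apr_density"]
         + f["smolt2_apr_density"]).to_numpy(dtype=float) for f in frames])))

    return {
        "egg_to_p0_mortality_pct": 100.0 * float(np.nanmean(egg_mort)),
        # paper-style accounting: egg deposition to end-of-summer (30 Sep) p0
        "egg_to_p0_sep_mortality_pct": (
            100.0 * float(np.nanmean(egg_mort_sep)) if egg_mort_sep else float("nan")),
        "smolt_to_returner_pct": 100.0 * float(np.nanmean(ret_rates)),
        "juvenile_nov_density": pooled_mean("juvenile_nov_density"),
        "smolt_production": smolt_prod,
        "p1_maturity_pct": 100.0 * pooled_mean("p1_male_mature_frac"),
        "p2_maturity_pct": 100.0 * pooled_mean("p2_male_mature_frac"),
        "spawner_1sw_len": pooled_mean("spawner1_len_mean"),
        "p1_may_len": pooled_mean("p1_may_len_mean"),
        "p1_nov_len": pooled_mean("p1_nov_len_mean"),
        "smolt1_apr_len": pooled_mean("smolt1_apr_len_mean"),
        "egg_density": pooled_mean("egg_density"),
        "spawners_n": pooled_mean("spawners_n"),
        "n_years": int(sum(len(f) for f in frames)),
    }


def estimate_heritability(
    midparent: np.ndarray,
    offspring: np.ndarray,
    min_pairs: int = 100,
    method: str = "midparent",
) -> float:
    """Heritability of fork length from parent–offspring regression.

    ``midparent`` regression returns the slope directly; the single-parent
    variant doubles it.  The estimate is clamped to [0, 1]; with fewer than
    ``min_pairs`` complete pairs the value is undefined (NaN).
    """
    if method not in ("midparent", "single_parent"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(midparent, float)
    y = np.asarray(offspring, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_pairs or np.var(x[ok]) == 0:
        return float("nan")
    slope = np.polyfit(x[ok], y[ok], 1)[0]
    if method == "single_parent":
        slope *= 2.0
    if not 0.0 <= slope <= 1.0:
        logger.debug("heritability slope %.3f clamped to [0, 1]", slope)
    return float(np.clip(slope, 0.0, 1.0))
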