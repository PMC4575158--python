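"""Diploid multi-locus genetics: genotypes, additive effects, inheritance.

Each individual carries three independent sets of 21 diploid biallelic loci,
one set per main life phase (embryonic, juvenile, adult).  Allele ``1`` is the
"wild" allele and allele ``0`` the "farm" allele.  Per-locus effect sizes
decline exponentially across loci 1..20 and locus 21 is a completely neutral
marker used to track introgression.  Effects are additive: the phase score
``S`` is the effect-weighted count of wild alleles, normalized so that a
genotype homozygous for ``1`` at every locus scores exactly 1 and the all-``0``
genotype scores 0.

Genotypes are stored as ``uint8`` arrays of shape ``(n, N_SETS, N_LOCI, 2)``
(batch) or ``(N_SETS, N_LOCI, 2)`` (single individual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_SETS = 3
N_LOCI = 21

#: index of each phase's gene set
EMBRYONIC, JUVENILE, ADULT = 0, 1, 2
PHASE_SETS = {"embryonic": EMBRYONIC, "juvenile": JUVENILE, "adult": ADULT}


@dataclass(frozen=True)
class EffectProfile:
    """Per-locus additive effect weights for one gene set layout.

    ``weights[i] ∝ exp(-decay * i)`` for loci ``0..19`` (1-based 1..20), the
    last locus has weight 0, and the vector is normalized so that the diploid
    all-wild genotype sums to exactly 1 (``2 * weights.sum() == 1``).
    """

    weights: np.ndarray
    decay: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


def make_effect_profile(n_loci: int = N_LOCI, decay: float = 0.3) -> EffectProfile:
    """Build the exponentially declining effect profile.

    Parameters
    ----------
    n_loci : int
        Number of loci per set; the model uses 21, the last being neutral.
    decay : float
        Exponential decay rate of effect size across loci (> 0).
    """
    if decay <= 0:
        raise ValueError(f"decay must be positive, got {decay}")
    if n_loci < 2:
        raise ValueError(f"n_loci must be >= 2, got {n_loci}")
    w = np.exp(-decay * np.arange(n_loci - 1, dtype=float))
    w = np.append(w, 0.0)  # neutral tracer locus
    w /= 2.0 * w.sum()  # diploid all-'1' genotype -> exactly 1
    return EffectProfile(weights=w, decay=decay)


def _check_genotype(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g)
    if g.shape[-3:] != (N_SETS, N_LOCI, 2):
        raise ValueError(
            f"genotype must have trailing shape ({N_SETS}, {N_LOCI}, 2), got {g.shape}"
        )
    if g.dtype != np.uint8:
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("alleles must all be 0 or 1")
        g = g.astype(np.uint8)
    return g


def init_genotypes(n: int, wild_allele_freq: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` genotypes with i.i.d. alleles ('1' with the given frequency).

    Wild fish are initialised at frequency 0.9, farm fish at 0.1 and incoming
    strayers at 0.8.
    """
    if not 0.0 <= wild_allele_freq <= 1.0:
        raise ValueError(f"wild_allele_freq must be in [0, 1], got {wild_allele_freq}")
    return (
        rng.random((n, N_SETS, N_LOCI, 2)) < wild_allele_freq
    ).astype(np.uint8)


def init_genotype(wild_allele_freq: float, rng: np.random.Generator) -> np.ndarray:
    """Single-genotype convenience wrapper around :func:`init_genotypes`."""
    return init_genotypes(1, wild_allele_freq, rng)[0]


def sum_genetic_effects(
    g: np.ndarray, phase: str | int, profile: EffectProfile
) -> np.ndarray | float:
    """Additive genetic score ``S`` in [0, 1] for one life phase's gene set.

    Accepts a single genotype ``(3, 21, 2)`` or a batch ``(n, 3, 21, 2)``.
    """
    g = _check_genotype(g)
    idx = PHASE_SETS[phase] if isinstance(phase, str) else int(phase)
    if idx not in (EMBRYONIC, JUVENILE, ADULT):
        raise ValueError(f"unknown phase {phase!r}")
    sub = g[..., idx, :, :]
    s = sub.sum(axis=-1, dtype=np.uint8) @ profile.weights
    return float(s) if np.ndim(s) == 0 else s


def sum_all_effects(g: np.ndarray, profile: EffectProfile) -> np.ndarray:
    """``S`` for all three phases at once; returns shape ``(..., 3)``."""
    g = _check_genotype(g)
    counts = g.sum(axis=-1, dtype=np.uint8)  # '1'-allele count per locus
    return counts @ profile.weights


def inherit(
    mothers: np.ndarray, fathers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian inheritance: one maternal + one paternal allele per locus.

    ``mothers`` and ``fathers`` are batches of parental genotypes aligned by
    offspring (shape ``(n, 3, 21, 2)``); loci segregate independently.
    """
    mothers = _check_genotype(mothers)
    fathers = _check_genotype(fathers)
    single = mothers.ndim == 3
    if single:
        mothers = mothers[None]
        fathers = fathers[None]
    n = mothers.shape[0]
    pick_m = rng.integers(0, 2, size=(n, N_SETS, N_LOCI), dtype=np.uint8).astype(bool)
    pick_f = rng.integers(0, 2, size=(n, N_SETS, N_LOCI), dtype=np.uint8).astype(bool)
    off = np.empty((n, N_SETS, N_LOCI, 2), dtype=np.uint8)
    off[..., 0] = np.where(pick_m, mothers[..., 1], mothers[..., 0])
    off[..., 1] = np.where(pick_f, fathers[..., 1], fathers[..., 0])
    return off[0] if single else off


def allele_frequency_summary(
    genotypes: np.ndarray, phase: str | int, locus: int
) -> float:
    """Population frequency of the wild '1' allele at one locus (0-based)."""
    g = _check_genotype(genotypes)
    if g.ndim != 4 or g.shape[0] == 0:
        raise ValueError("need a non-empty population of genotypes")
    if not 0 <= locus < N_LOCI:
        raise ValueError(f"locus must be in [0, {N_LOCI}), got {locus}")
    idx = PHASE_SETS[phase] if isinstance(phase, str) else int(phase)
    return float(g[:, idx, locus, :].mean())


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """'1'-allele frequency per set and locus; shape ``(3, 21)``."""
    g = _check_genotype(genotypes)
    if g.ndim != 4 or g.shape[0] == 0:
        raise ValueError("need a non-empty population of genotypes")
    return g.mean(axis=(0, 3))
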