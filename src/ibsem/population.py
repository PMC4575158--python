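"""Array-backed population container.

The simulator tracks tens of thousands of fish per replicate, so individuals
are stored column-wise in numpy arrays rather than as Python objects.  A
:class:`Population` behaves like a growable table keyed by attribute name;
:meth:`Population.view` materialises a single row as an :class:`Individual`
for inspection and unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .genetics import N_LOCI, N_SETS


class Phase(IntEnum):
    EGG = 0
    ALEVIN = 1
    PARR = 2
    SMOLT = 3
    ADULT = 4


class Origin(IntEnum):
    WILD = 0
    FARM = 1
    STRAYER = 2
    PROGENY = 3


class Sex(IntEnum):
    FEMALE = 0
    MALE = 1


# column name -> (dtype, fill value for "missing")
_COLUMNS = {
    "uid": (np.int64, -1),
    "sex": (np.uint8, 0),
    "phase": (np.uint8, Phase.EGG),
    "parr_age": (np.int8, -1),     # 0,1,2 for p0,p1,p2; smolts keep theirs
    "sea_age": (np.int8, -1),      # 0..3 for 0SW..3SW
    "length": (np.float64, np.nan),  # fork length, mm
    "weight": (np.float64, np.nan),  # g
    "egg_size": (np.float64, np.nan),  # egg weight (g), embryonic only
    "mature": (bool, False),
    "matured_prev": (bool, False),
    "smolt_flag": (bool, False),   # smolt next 1 November / migrate next May
    "has_returned": (bool, False),
    "origin": (np.uint8, Origin.WILD),
    "cohort": (np.int32, -1),      # smolt year-class (year of sea entry)
    "ref_length": (np.float64, np.nan),   # own p0 1-Nov length (h² census)
    "midparent_ref": (np.float64, np.nan),  # midparent p0 1-Nov length
    "S": (np.float64, np.nan),     # (n, 3) additive genetic scores
    "geno": (np.uint8, 0),         # (n, 3, 21, 2)
}


@dataclass
class Individual:
    """Read-only snapshot of one fish (for tests and debugging)."""

    uid: int
    sex: Sex
    phase: Phase
    parr_age: int
    sea_age: int
    length: float
    weight: float
    egg_size: float
    mature: bool
    matured_prev: bool
    smolt_flag: bool
    origin: Origin
    genotype: np.ndarray
    S: np.ndarray


class Population:
    """Column-store of individuals; supports masking, concatenation, views."""

    def __init__(self, n: int = 0):
        self.arrays: dict[str, np.ndarray] = {}
        for name, (dtype, fill) in _COLUMNS.items():
            if name == "S":
                arr = np.full((n, N_SETS), fill, dtype=dtype)
            elif name == "geno":
                arr = np.zeros((n, N_SETS, N_LOCI, 2), dtype=dtype)
            else:
                arr = np.full(n, fill, dtype=dtype)
            self.arrays[name] = arr

    def __len__(self) -> int:
        return len(self.arrays["uid"])

    def __getattr__(self, name: str) -> np.ndarray:
        try:
            return self.__dict__["arrays"][name]
        except KeyError:
            raise AttributeError(name) from None

    def __setattr__(self, name, value):
        if name != "arrays" and "arrays" in self.__dict__ and name in self.arrays:
            self.arrays[name] = value
        else:
            super().__setattr__(name, value)

    # -- structural operations -------------------------------------------

    def select(self, mask: np.ndarray) -> "Population":
        out = Population(0)
        for k, v in self.arrays.items():
            out.arrays[k] = v[mask]
        return out

    def keep(self, mask: np.ndarray) -> None:
        """In-place filtering (survivors of a mortality draw, etc.)."""
        for k in self.arrays:
            self.arrays[k] = self.arrays[k][mask]

    def append(self, other: "Population") -> None:
        for k in self.arrays:
            self.arrays[k] = np.concatenate([self.arrays[k], other.arrays[k]])

    def view(self, i: int) -> Individual:
        a = self.arrays
        return Individual(
            uid=int(a["uid"][i]),
            sex=Sex(int(a["sex"][i])),
            phase=Phase(int(a["phase"][i])),
            parr_age=int(a["parr_age"][i]),
            sea_age=int(a["sea_age"][i]),
            length=float(a["length"][i]),
            weight=float(a["weight"][i]),
            egg_size=float(a["egg_size"][i]),
            mature=bool(a["mature"][i]),
            matured_prev=bool(a["matured_prev"][i]),
            smolt_flag=bool(a["smolt_flag"][i]),
            origin=Origin(int(a["origin"][i])),
            genotype=a["geno"][i].copy(),
            S=a["S"][i].copy(),
        )

    # -- convenience masks -----------------------------------------------

    def mask(self, phase: Phase | None = None, parr_age: int | None = None,
             sea_age: int | None = None, sex: Sex | None = None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if phase is not None:
            m &= self.phase == phase
        if parr_age is not None:
            m &= self.parr_age == parr_age
        if sea_age is not None:
            m &= self.sea_age == sea_age
        if sex is not None:
            m &= self.sex == sex
        return m
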