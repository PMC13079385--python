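"""Nearest-neighbor energy model parameters.

The package ships a Turner-style parameter table (Watson-Crick and G.U
wobble stacks, size-indexed loop initiation penalties, duplex initiation,
terminal A.U/G.U penalty, and the symmetry correction for self-complementary
duplexes) as a plain-text data file. The model is deliberately simple and
fully self-consistent: the same loop decomposition scores enumerated
structures, the single-strand recursions, and multistrand complexes.

Model conventions (documented in docs/methods.md):

* multiloop closure carries no penalty;
* exterior loops, and any loop containing a strand nick, carry no penalty;
* two-sided loops (bulges and internal loops) are limited to
  ``two_loop_max`` unpaired bases in total;
* no coaxial stacking, no dangles, no terminal mismatches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

GAS_CONSTANT = 0.0019872  # kcal / (mol K)

#: pair-type codes used throughout the DP kernels
PAIR_STRINGS = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_CODE = {p: i for i, p in enumerate(PAIR_STRINGS)}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def _pair_type_matrix() -> np.ndarray:
    m = -np.ones((4, 4), dtype=np.int8)
    for p, code in PAIR_CODE.items():
        m[_BASE_INDEX[p[0]], _BASE_INDEX[p[1]]] = code
    return m


#: 4x4 matrix of pair codes (A=0, C=1, G=2, U=3); -1 where no pair is allowed
PAIR_TYPE = _pair_type_matrix()


class ParameterError(ValueError):
    """Raised for malformed or inconsistent parameter tables."""


def _mirror(outer: str, inner: str) -> tuple[str, str]:
    # Reading the same stacked dimer from the opposite strand:
    # 5'-x1 x2-3' / 3'-y1 y2-5'  ==  5'-y2 y1-3' / 3'-x2 x1-5'
    x1, y1 = outer
    x2, y2 = inner
    return y2 + x2, y1 + x1


@dataclass(frozen=True)
class EnergyParams:
    """Immutable bundle of nearest-neighbor parameters.

    ``stack[p, q]`` is the stacking free energy of outer pair-code p on inner
    pair-code q (+inf where either pair is not a legal stack partner).
    Loop tables are stored as dense arrays indexed by loop size; sizes past
    the table end are extrapolated as ``dG(end) + 1.75 kBT ln(size/end)``.
    """

    temperature: float
    duplex_init: float
    terminal_au: float
    symmetry_correction: float
    min_hairpin: int
    two_loop_max: int
    stack: np.ndarray
    hairpin_table: np.ndarray  # hairpin_table[k] valid for k >= min_hairpin
    bulge_table: np.ndarray
    internal_table: np.ndarray
    version: str = "1"
    kBT: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kBT", GAS_CONSTANT * self.temperature)
        if self.symmetry_correction <= 0:
            raise ParameterError("symmetry_correction must be > 0")
        for name in ("hairpin_table", "bulge_table", "internal_table"):
            tab = getattr(self, name)
            lo = int(np.argmin(tab))
            if np.any(np.diff(tab[lo:]) < -1e-12):
                raise ParameterError(f"{name} decreases beyond its minimum")

    # -- loop energies ------------------------------------------------------

    def _loop_energy(self, table: np.ndarray, size: int) -> float:
        end = len(table) - 1
        if size <= end:
            return float(table[size])
        return float(table[end]) + 1.75 * self.kBT * math.log(size / end)

    def hairpin_energy(self, size: int) -> float:
        if size < self.min_hairpin:
            return math.inf
        return self._loop_energy(self.hairpin_table, size)

    def bulge_energy(self, size: int) -> float:
        if size < 1 or size > self.two_loop_max:
            return math.inf
        return self._loop_energy(self.bulge_table, size)

    def internal_energy(self, size: int) -> float:
        if size < 2 or size > self.two_loop_max:
            return math.inf
        return self._loop_energy(self.internal_table, size)

    def terminal_penalty(self, pair_code: int) -> float:
        """Helix-end penalty: applied to A.U and G.U closing pairs."""
        return self.terminal_au if "U" in PAIR_STRINGS[pair_code] else 0.0

    @property
    def terminal_penalty_by_code(self) -> np.ndarray:
        return np.array(
            [self.terminal_au if "U" in p else 0.0 for p in PAIR_STRINGS]
        )

    def loop_weight_tables(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Boltzmann-weight loop tables extended to size ``n`` (weights, not energies)."""
        hp = np.zeros(n + 1)
        for k in range(self.min_hairpin, n + 1):
            hp[k] = math.exp(-self.hairpin_energy(k) / self.kBT)
        cap = self.two_loop_max
        bu = np.zeros(cap + 1)
        for k in range(1, cap + 1):
            bu[k] = math.exp(-self.bulge_energy(k) / self.kBT)
        il = np.zeros(cap + 1)
        for k in range(2, cap + 1):
            il[k] = math.exp(-self.internal_energy(k) / self.kBT)
        return hp, bu, il

    @property
    def stack_weights(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(-self.stack / self.kBT) * np.isfinite(self.stack)

    @property
    def terminal_weights(self) -> np.ndarray:
        return np.exp(-self.terminal_penalty_by_code / self.kBT)


def load_params(path=None, temperature: float | None = None) -> EnergyParams:
    """Load an energy-parameter table (defaults to the shipped v1 table).

    The stack table is completed under strand-reversal symmetry and checked
    for internal consistency; loop tables must be non-decreasing beyond their
    minimum.
    """
    if path is None:
        ref = resources.files("rnapal").joinpath("data/nn_params_v1.tsv")
        text = ref.read_text()
        version = "1"
    else:
        with open(path) as fh:
            text = fh.read()
        version = str(path)

    scalars: dict[str, float] = {}
    stacks: dict[tuple[str, str], float] = {}
    loops: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParameterError(f"line {lineno}: expected 3 tab-separated fields")
        kind, key, value = fields
        if kind == "scalar":
            scalars[key] = float(value)
        elif kind == "stack":
            dimer = key
            if len(dimer) != 5 or dimer[2] != "/":
                raise ParameterError(f"line {lineno}: bad stack key {key!r}")
            outer = dimer[0] + dimer[3]
            inner = dimer[1] + dimer[4]
            if outer not in PAIR_CODE or inner not in PAIR_CODE:
                raise ParameterError(f"line {lineno}: {key!r} is not a legal stack")
            stacks[(outer, inner)] = float(value)
        elif kind in loops:
            loops[kind][int(key)] = float(value)
        else:
            raise ParameterError(f"line {lineno}: unknown record type {kind!r}")

    # complete the stack table under strand-reversal symmetry
    complete: dict[tuple[str, str], float] = {}
    for (outer, inner), dg in stacks.items():
        for k in ((outer, inner), _mirror(outer, inner)):
            if k in complete and abs(complete[k] - dg) > 1e-9:
                raise ParameterError(f"stack table inconsistent at {k}")
            complete[k] = dg
    stack = np.full((6, 6), np.inf)
    for (outer, inner), dg in complete.items():
        stack[PAIR_CODE[outer], PAIR_CODE[inner]] = dg

    def dense(d: dict[int, float], min_size: int) -> np.ndarray:
        end = max(d)
        tab = np.full(end + 1, np.inf)
        for k in range(min_size, end + 1):
            if k not in d:
                raise ParameterError(f"loop table missing size {k}")
            tab[k] = d[k]
        return tab

    min_hp = int(scalars["min_hairpin"])
    temp = temperature if temperature is not None else scalars["temperature"]
    return EnergyParams(
        temperature=temp,
        duplex_init=scalars["duplex_init"],
        terminal_au=scalars["terminal_au"],
        symmetry_correction=scalars["symmetry_correction"],
        min_hairpin=min_hp,
        two_loop_max=int(scalars["two_loop_max"]),
        stack=stack,
        hairpin_table=dense(loops["hairpin"], min_hp),
        bulge_table=dense(loops["bulge"], 1),
        internal_table=dense(loops["internal"], 2),
        version=version,
    )


@lru_cache(maxsize=4)
def default_params(temperature: float = 310.15) -> EnergyParams:
    """The shipped parameter table at the given temperature (37 C default)."""
    return load_params(temperature=temperature)
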