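"""Multi-strand complex free energies and single-species mass action.

A complex of m strands in a fixed circular order is scored over all nested,
nick-legal, *connected* secondary structures of the concatenation. The
inside recursion counts connected and disconnected structures together; the
connected part is recovered by inclusion-exclusion over the component
containing the first strand. In a nested (non-crossing) diagram that
component may arc over other strands, so its strand set S is any subset
containing strand 1; the remaining strands fall into independent gap
windows between consecutive strands of S (and after the last strand of S),
each carrying an unconstrained ensemble. Loops spanning a gap contain a
nick and carry no penalty, so the Boltzmann weight factorizes exactly. For
m identical strands this closes over counts alone:

    Z_all(m) = sum_k Q_conn(k) * B_k(m - k),
    B_k(r)   = sum over compositions g_1 + ... + g_k = r of prod_i Z_all(g_i)

solved for Q_conn(m) in log space, with every term expressed as a fraction
of Z_all(m) so the subtraction stays numerically stable. The complex free
energy then adds the association penalty (m - 1) * duplex_init and the
rotational-symmetry term kBT ln(symmetry_factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .fold import fold
from .params import EnergyParams, default_params
from .sequence import RnaSequence, as_rna

#: connected weight below this fraction of the unconstrained ensemble is
#: reported as "complex does not form" (+inf free energy); see docs/methods.md
CONNECTED_RTOL = 1e-12

DEFAULT_MAX_TOTAL_LENGTH = 600


class ResourceError(RuntimeError):
    """Raised when a complex exceeds the configured size cap."""


@dataclass(frozen=True)
class ComplexSpec:
    """Ordered (circular) list of strands plus its rotational symmetry.

    For a homomultimer of m identical strands the single circular ordering
    has symmetry_factor m; a heterodimer has symmetry_factor 1.
    """

    strands: tuple
    symmetry_factor: int = 1

    def __post_init__(self) -> None:
        strands = tuple(as_rna(s) for s in self.strands)
        object.__setattr__(self, "strands", strands)
        if len(strands) < 1:
            raise ValueError("complex needs at least one strand")
        if len(strands) % self.symmetry_factor != 0:
            raise ValueError("symmetry_factor must divide the strand count")

    @classmethod
    def homomultimer(cls, seq, m: int) -> "ComplexSpec":
        seq = as_rna(seq)
        return cls(strands=tuple([seq] * m), symmetry_factor=m)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.strands)


@dataclass(frozen=True)
class ComplexFreeEnergy:
    """Partition function and free energy of one connected complex."""

    size: int
    lnQ: float  # -inf when no connected structure exists
    kBT: float

    @property
    def Q(self) -> float:
        try:
            return math.exp(self.lnQ)
        except OverflowError:
            return math.inf

    @property
    def dG(self) -> float:
        """kcal/mol; +inf sentinel when the complex cannot form."""
        if self.lnQ == -math.inf:
            return math.inf
        return -self.kBT * self.lnQ


def _connected_ln_q(ln_z: list) -> list:
    """ln Q_conn(k) for k = 1..m identical strands.

    ``ln_z[k]`` is ln Z_all over any window of k consecutive strands
    (``ln_z[0] = 0``). Returns a list indexed 1..m (element 0 unused).
    """
    m = len(ln_z) - 1
    # lnB[k][r]: compositions of r gap strands into k ordered gaps
    lnB = [None, list(ln_z)]
    for k in range(2, m + 1):
        row = []
        for r in range(0, m + 1):
            row.append(
                float(logsumexp([ln_z[g] + lnB[k - 1][r - g] for g in range(r + 1)]))
            )
        lnB.append(row)
    ln_c = [None] * (m + 1)
    for size in range(1, m + 1):
        acc = 1.0
        for k in range(1, size):
            if ln_c[k] == -math.inf:
                continue
            acc -= math.exp(ln_c[k] + lnB[k][size - k] - ln_z[size])
        ln_c[size] = -math.inf if acc <= CONNECTED_RTOL else math.log(acc) + ln_z[size]
    return ln_c


def complex_partition_function(
    spec: ComplexSpec,
    params: EnergyParams | None = None,
    max_total_length: int = DEFAULT_MAX_TOTAL_LENGTH,
) -> ComplexFreeEnergy:
    """Partition function of the connected complex in the given ordering.

    A size-1 spec reduces exactly to the single-strand partition function.
    Heteromultimers are supported up to two strands (the screening pipelines
    need homomultimers and dimers only).
    """
    params = params or default_params()
    if spec.total_length > max_total_length:
        raise ResourceError(
            f"complex length {spec.total_length} exceeds cap {max_total_length}"
        )
    m = len(spec.strands)
    res = fold(list(spec.strands), params)
    if m == 1:
        return ComplexFreeEnergy(size=1, lnQ=res.lnQ, kBT=params.kBT)

    offsets = [0]
    for s in spec.strands:
        offsets.append(offsets[-1] + len(s))

    homogeneous = len({s.bases for s in spec.strands}) == 1
    if homogeneous:
        ln_z = [0.0]
        for k in range(1, m + 1):
            zv = res.z[0, offsets[k]]
            ln_z.append(math.log(zv) + offsets[k] * res.ln_sigma)
        ln_q_conn = _connected_ln_q(ln_z)[m]
    elif m == 2:
        def ln_window(a: int, b: int) -> float:
            return math.log(res.z[offsets[a], offsets[b]]) + (
                offsets[b] - offsets[a]
            ) * res.ln_sigma

        ln_tot = ln_window(0, 2)
        acc = 1.0 - math.exp(ln_window(0, 1) + ln_window(1, 2) - ln_tot)
        ln_q_conn = -math.inf if acc <= CONNECTED_RTOL else math.log(acc) + ln_tot
    else:
        raise NotImplementedError(
            "heteromultimers beyond two strands are out of scope"
        )

    if ln_q_conn == -math.inf:
        return ComplexFreeEnergy(size=m, lnQ=-math.inf, kBT=params.kBT)
    lnQ = (
        ln_q_conn
        - (m - 1) * params.duplex_init / params.kBT
        - math.log(spec.symmetry_factor)
    )
    return ComplexFreeEnergy(size=m, lnQ=lnQ, kBT=params.kBT)


def dimer_energies(seq1, seq2, params: EnergyParams | None = None):
    """(dG11, dG22, dG12): homodimer free energies of each sequence and the
    heterodimer free energy of the pair (symmetry factors 2, 2, 1)."""
    params = params or default_params()
    s1, s2 = as_rna(seq1, "seq1"), as_rna(seq2, "seq2")
    g11 = complex_partition_function(ComplexSpec.homomultimer(s1, 2), params).dG
    g22 = complex_partition_function(ComplexSpec.homomultimer(s2, 2), params).dG
    g12 = complex_partition_function(
        ComplexSpec(strands=(s1, s2), symmetry_factor=1), params
    ).dG
    return g11, g22, g12


def homomultimer_energies(
    seq,
    max_size: int = 10,
    params: EnergyParams | None = None,
    max_total_length: int = DEFAULT_MAX_TOTAL_LENGTH,
) -> list:
    """Connected-complex free energies dG_m for m = 1..max_size.

    One inside pass over the max_size-fold concatenation provides every
    window partition function, so the whole ladder costs a single DP.
    """
    params = params or default_params()
    seq = as_rna(seq)
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    n_total = max_size * len(seq)
    if n_total > max_total_length:
        raise ResourceError(
            f"{max_size} x {len(seq)} nt exceeds cap {max_total_length}"
        )
    res = fold([seq] * max_size, params)
    L = len(seq)
    ln_z = [0.0]
    for k in range(1, max_size + 1):
        zv = res.z[0, k * L]
        ln_z.append(math.log(zv) + k * L * res.ln_sigma)
    ln_c = _connected_ln_q(ln_z)
    out = []
    for m in range(1, max_size + 1):
        if m == 1:
            out.append(ComplexFreeEnergy(size=1, lnQ=ln_z[1], kBT=params.kBT))
            continue
        if ln_c[m] == -math.inf:
            out.append(ComplexFreeEnergy(size=m, lnQ=-math.inf, kBT=params.kBT))
            continue
        lnQ = ln_c[m] - (m - 1) * params.duplex_init / params.kBT - math.log(m)
        out.append(ComplexFreeEnergy(size=m, lnQ=lnQ, kBT=params.kBT))
    return out


@dataclass(frozen=True)
class ClusterDistribution:
    """Fraction of strands found in clusters of each size m = 1..M."""

    fraction_in_size: dict
    monomer_conc: float = math.nan  # molar, free monomer at equilibrium

    def higher_order_fraction(self, threshold: int = 4) -> float:
        """Fraction of strands in clusters of at least `threshold` molecules."""
        return float(
            sum(f for m, f in self.fraction_in_size.items() if m >= threshold)
        )


def equilibrium_cluster_distribution(
    seq_or_energies,
    total_conc: float,
    max_size: int = 10,
    params: EnergyParams | None = None,
) -> ClusterDistribution:
    """Single-species mass action over cluster sizes 1..max_size.

    With per-size complex partition functions Q_m (1 M standard state), the
    concentration of m-mers is c0 Q_m x^m where x is the monomer activity;
    x is found by monotone root finding on sum_m m c_m = total_conc.
    """
    params = params or default_params()
    if total_conc <= 0:
        raise ValueError("total_conc must be > 0")
    if isinstance(seq_or_energies, (str, RnaSequence)):
        energies = homomultimer_energies(seq_or_energies, max_size, params)
    else:
        energies = list(seq_or_energies)
    ln_q = np.array([e.lnQ for e in energies])
    sizes = np.arange(1, len(ln_q) + 1)
    finite = np.isfinite(ln_q)
    ln_target = math.log(total_conc)  # c0 = 1 M

    def g(ln_x: float) -> float:
        terms = ln_q[finite] + sizes[finite] * ln_x + np.log(sizes[finite])
        return logsumexp(terms) - ln_target

    # bracket: the monomer term alone makes g(hi) >= 0 near the upper bound
    hi = ln_target - float(ln_q[0]) + 1.0
    lo = hi - 50.0
    while g(lo) > 0:
        lo -= 50.0
        if lo < -4000:
            raise RuntimeError("mass-action bracket failure")
    ln_x = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)

    fracs = np.zeros(len(ln_q))
    fracs[finite] = np.exp(
        ln_q[finite] + sizes[finite] * ln_x + np.log(sizes[finite]) - ln_target
    )
    total = fracs.sum()
    if abs(total - 1.0) > 1e-9:
        raise RuntimeError(f"strand conservation violated: {total}")
    return ClusterDistribution(
        fraction_in_size={int(m): float(f) for m, f in zip(sizes, fracs)},
        monomer_conc=math.exp(float(ln_q[0]) + ln_x),
    )


def higher_order_fraction(dist: ClusterDistribution, threshold: int = 4) -> float:
    return dist.higher_order_fraction(threshold)
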