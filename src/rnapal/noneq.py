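"""Nonequilibrium (initial-contact) binding strength between folded RNAs.

Hybridization between folded molecules is modelled as a single binding event
at a pair of complementary regions that are both accessible (unpaired) in
their molecules' equilibrium ensembles. A contact of strength dG_ij survives
a characteristic time t* = exp(-dG*/kBT) / k (k an attempt frequency) with
probability

    S(dG_ij) = exp(-exp((dG_ij - dG*) / kBT)),

the double exponential arising from exponentially distributed dissociation
waiting times. The nonequilibrium binding strength of two molecules is

    dG_noneq / kBT = -log sum_{i,j} p_i^free p_j^free S(dG_ij)

over complementary region pairs {i, j}. Restricting the sum to palindromic
self-contacts (region_i == region_j) gives the palindromic weight
W_pal = exp(-dG_noneq;pal / kBT).

Weights (sums of non-negative terms) are the primitive quantity; free
energies are derived views, with an empty sum mapping to weight 0 and the
+inf free-energy sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .fold import FoldResult, fold, region_pfree
from .palindrome import RegionPair, find_complementary_pairs, find_palindromes
from .params import EnergyParams, default_params
from .sequence import as_rna


@dataclass(frozen=True)
class NoneqParams:
    """Parameters of the nonequilibrium binding score.

    dG_star : kcal/mol, dissociation threshold (default -12).
    attempt_rate_k : 1/s attempt frequency (default 1e7).
    min_region_len : minimum complementary-region length in the contact sum.
    pfree_mode : 'sampled' (default, n_samples Boltzmann samples per
        molecule) or 'exact' (constrained partition function per region).
    """

    dG_star: float = -12.0
    attempt_rate_k: float = 1e7
    min_region_len: int = 4
    pfree_mode: str = "sampled"
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attempt_rate_k <= 0:
            raise ValueError("attempt_rate_k must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class ContactCandidate:
    """One complementary region pair with accessibilities and survival."""

    region_pair: RegionPair
    p_free_i: float
    p_free_j: float
    survival: float

    @property
    def weight(self) -> float:
        return self.p_free_i * self.p_free_j * self.survival


def survival_probability(dG_ij: float, p: NoneqParams, kBT: float | None = None) -> float:
    """Probability that a bond of strength dG_ij outlives t*; strictly
    decreasing in dG_ij, ->1 as dG_ij -> -inf, ->0 as dG_ij -> +inf."""
    kBT = kBT if kBT is not None else default_params().kBT
    x = (dG_ij - p.dG_star) / kBT
    if x > 700:
        return 0.0
    return math.exp(-math.exp(x))


def characteristic_time(p: NoneqParams, kBT: float | None = None) -> float:
    """t* = exp(-dG*/kBT) / k, in seconds."""
    kBT = kBT if kBT is not None else default_params().kBT
    return math.exp(-p.dG_star / kBT) / p.attempt_rate_k


class _PfreeCache:
    """Per-molecule region accessibilities from one fold (and one sample set)."""

    def __init__(self, seq, p: NoneqParams, params: EnergyParams):
        self.seq = as_rna(seq)
        self.p = p
        self.params = params
        self.fold_result: FoldResult = fold(self.seq, params)
        self._samples = None
        self._cache: dict = {}

    def _ensure_samples(self):
        if self._samples is None:
            samples = self.fold_result.sample(self.p.n_samples, self.p.seed)
            self._samples = [s.paired_positions for s in samples]

    def pfree(self, region: tuple) -> float:
        if region in self._cache:
            return self._cache[region]
        start, length = region
        if self.p.pfree_mode == "exact":
            val = region_pfree(
                self.seq, region, self.params, mode="exact",
                _fold_result=self.fold_result,
            )
        elif self.p.pfree_mode == "sampled":
            self._ensure_samples()
            pos = set(range(start, start + length))
            free = sum(1 for paired in self._samples if not (paired & pos))
            val = free / len(self._samples)
        else:
            raise ValueError(f"unknown pfree mode {self.p.pfree_mode!r}")
        self._cache[region] = val
        return val


def noneq_binding_strength(
    seq1,
    seq2,
    p: NoneqParams | None = None,
    params: EnergyParams | None = None,
    _cache1: _PfreeCache | None = None,
    _cache2: _PfreeCache | None = None,
):
    """(dG_noneq, contacts) for a pair of molecules.

    Contacts are the maximal complementary region pairs; each is weighted by
    the accessibilities of its two regions in the molecules' own monomer
    ensembles and by its survival probability. Identical sequences are
    treated as two copies of one molecule (homodimer contact set).
    """
    p = p or NoneqParams()
    params = params or default_params()
    s1, s2 = as_rna(seq1, "seq1"), as_rna(seq2, "seq2")
    pairs = find_complementary_pairs(s1, s2, p.min_region_len, params)
    c1 = _cache1 if _cache1 is not None else _PfreeCache(s1, p, params)
    c2 = (
        c1
        if s2.bases == s1.bases
        else (_cache2 if _cache2 is not None else _PfreeCache(s2, p, params))
    )
    contacts = []
    weight = 0.0
    for rp in pairs:
        pf_i = c1.pfree(rp.region_i)
        pf_j = c2.pfree(rp.region_j)
        surv = survival_probability(rp.dG_ij, p, params.kBT)
        contacts.append(
            ContactCandidate(region_pair=rp, p_free_i=pf_i, p_free_j=pf_j, survival=surv)
        )
        weight += pf_i * pf_j * surv
    dg = math.inf if weight <= 0.0 else -params.kBT * math.log(weight)
    return dg, contacts


def palindromic_noneq_weight(
    seq,
    p: NoneqParams | None = None,
    params: EnergyParams | None = None,
    _cache: _PfreeCache | None = None,
) -> float:
    """W_pal: the contact sum restricted to palindromic self-contacts.

    Zero when the sequence has no palindrome; non-decreasing in dG_star.
    """
    p = p or NoneqParams()
    params = params or default_params()
    s = as_rna(seq)
    cache = _cache if _cache is not None else _PfreeCache(s, p, params)
    pairs = find_complementary_pairs(s, s, p.min_region_len, params)
    weight = 0.0
    for rp in pairs:
        if not rp.is_self:
            continue
        pf = cache.pfree(rp.region_i)
        weight += pf * pf * survival_probability(rp.dG_ij, p, params.kBT)
    return weight


def accessible_strong_palindromes(
    seq,
    dG_star: float,
    pfree_min: float = 0.1,
    p: NoneqParams | None = None,
    params: EnergyParams | None = None,
    _cache: _PfreeCache | None = None,
):
    """Palindromes that bind strongly (dG_s <= dG_star) and are highly
    accessible (pfree >= pfree_min). Returns (count, list of (Palindrome,
    pfree))."""
    p = p or NoneqParams(dG_star=dG_star)
    params = params or default_params()
    s = as_rna(seq)
    cache = _cache if _cache is not None else _PfreeCache(s, p, params)
    hits = []
    for pal in find_palindromes(s, p.min_region_len, params=params):
        if pal.dG_s > dG_star:
            continue
        pf = cache.pfree(pal.region)
        if pf >= pfree_min:
            hits.append((pal, pf))
    return len(hits), hits


def homo_vs_hetero_noneq(
    seq1,
    seq2,
    p: NoneqParams | None = None,
    params: EnergyParams | None = None,
    _cache1: _PfreeCache | None = None,
    _cache2: _PfreeCache | None = None,
) -> float:
    """2 dG12_noneq - (dG11_noneq + dG22_noneq): the nonequilibrium
    propensity to form heterodimers rather than homodimers (negative favors
    heterodimers).

    Sentinel arithmetic (documented): weights are primitive. If a molecule
    is inert (its self weight and the cross weight are both zero) the two
    infinities cancel and the result is minus the partner's self term; if
    only the cross weight vanishes the result is +inf; if the cross weight
    is positive but a self weight vanishes, -inf; identical sequences give
    exactly 0.
    """
    p = p or NoneqParams()
    params = params or default_params()
    s1, s2 = as_rna(seq1, "seq1"), as_rna(seq2, "seq2")
    if s1.bases == s2.bases:
        return 0.0
    c1 = _cache1 if _cache1 is not None else _PfreeCache(s1, p, params)
    c2 = _cache2 if _cache2 is not None else _PfreeCache(s2, p, params)
    g11, _ = noneq_binding_strength(s1, s1, p, params, _cache1=c1)
    g22, _ = noneq_binding_strength(s2, s2, p, params, _cache1=c2)
    g12, _ = noneq_binding_strength(s1, s2, p, params, _cache1=c1, _cache2=c2)
    inf = math.inf
    if g12 < inf and g11 < inf and g22 < inf:
        return 2 * g12 - (g11 + g22)
    if g12 < inf:  # a self channel is absent but cross binding exists
        return -inf
    # g12 infinite: inert-molecule cancellation
    if g11 == inf and g22 == inf:
        return 0.0
    if g11 == inf:  # seq1 inert: 2 dG12 - dG11 := 0
        return -g22
    if g22 == inf:
        return -g11
    return inf  # both selfs finite, no cross contacts
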