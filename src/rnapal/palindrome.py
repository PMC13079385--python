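"""Self-complementary (palindromic) regions and complementary region pairs.

An RNA palindrome is a substring equal to its own strict Watson-Crick
reverse complement (e.g. GCAUGC, ACAUGU); two copies of the same molecule
can form a perfect duplex at such a region. Palindromes are necessarily of
even length since no base is self-complementary.

The aggregate palindrome binding strength of a sequence is

    dG_pal = -kBT log sum_s exp(-dG_s / kBT)

over its palindromic regions s, with dG_s the free energy of the
self-duplex. An empty set gives weight 0, i.e. a +inf sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import logsumexp

from .energy import duplex_energy
from .params import EnergyParams, default_params
from .sequence import WC_COMPLEMENT, as_rna


@dataclass(frozen=True)
class Palindrome:
    """A located self-complementary region with its self-duplex energy."""

    start: int
    length: int
    subseq: str
    dG_s: float

    @property
    def region(self) -> tuple:
        return (self.start, self.length)


@dataclass(frozen=True)
class RegionPair:
    """Two exactly reverse-complementary regions on two molecules.

    ``region_i`` lives on molecule 1 and ``region_j`` on molecule 2, both as
    (start, length); ``dG_ij`` is the perfect-duplex free energy.
    """

    region_i: tuple
    region_j: tuple
    dG_ij: float

    @property
    def is_self(self) -> bool:
        return self.region_i == self.region_j


def find_palindromes(
    seq,
    min_len: int = 4,
    maximal_only: bool = True,
    params: EnergyParams | None = None,
) -> list:
    """All strict-WC palindromic substrings of length >= min_len.

    With ``maximal_only`` (default) a palindrome strictly contained in
    another palindromic interval is dropped; palindromes around one center
    are nested, so this keeps the longest expansion per center that is not
    swallowed by a longer neighbor. Results are sorted by start.
    """
    params = params or default_params()
    rna = as_rna(seq)
    b = rna.bases
    n = len(b)
    if min_len % 2 != 0 or min_len < 2:
        raise ValueError("min_len must be an even integer >= 2")

    # maximal expansion around each center (between c-1 and c)
    expansions = []  # (start, length) of the maximal palindrome per center
    for c in range(1, n):
        k = 0
        while c - 1 - k >= 0 and c + k < n and WC_COMPLEMENT[b[c - 1 - k]] == b[c + k]:
            k += 1
        if 2 * k >= min_len:
            expansions.append((c - k, 2 * k))

    if maximal_only:
        regions = [
            (s, l)
            for s, l in expansions
            if not any(
                (s2, l2) != (s, l) and s2 <= s and s2 + l2 >= s + l
                for s2, l2 in expansions
            )
        ]
    else:
        regions = []
        for s, l in expansions:
            for sub in range(min_len, l + 1, 2):
                off = (l - sub) // 2
                regions.append((s + off, sub))
        regions = sorted(set(regions))

    out = []
    for s, l in sorted(regions):
        sub = b[s : s + l]
        out.append(
            Palindrome(start=s, length=l, subseq=sub, dG_s=duplex_energy(sub, sub, params))
        )
    return out


def palindrome_binding_strength(
    seq,
    params: EnergyParams | None = None,
    min_len: int = 4,
    maximal_only: bool = True,
) -> float:
    """dG_pal (kcal/mol); +inf when the sequence has no palindrome."""
    params = params or default_params()
    pals = find_palindromes(seq, min_len=min_len, maximal_only=maximal_only, params=params)
    if not pals:
        return math.inf
    return -params.kBT * float(logsumexp([-p.dG_s / params.kBT for p in pals]))


def find_complementary_pairs(
    seq1,
    seq2,
    min_region_len: int = 4,
    params: EnergyParams | None = None,
) -> list:
    """All maximal perfectly WC-complementary region pairs between two
    molecules, with perfect-duplex energies.

    Regions pair antiparallel: base t of region_i pairs with base
    (length-1-t) of region_j. When the two sequences are identical the
    enumeration is the self mode: mirror-duplicate pairs are reported once,
    and pairs with region_i == region_j are exactly the (maximal)
    palindromes.
    """
    params = params or default_params()
    r1, r2 = as_rna(seq1, "seq1"), as_rna(seq2, "seq2")
    b1, b2 = r1.bases, r2.bases
    n1, n2 = len(b1), len(b2)
    self_mode = b1 == b2

    out = []
    # cells (p, q) with b1[p] WC-complementary to b2[q] lie on anti-diagonals
    # p + q = d; maximal runs along an anti-diagonal are maximal region pairs
    for d in range(0, n1 + n2 - 1):
        p_lo = max(0, d - (n2 - 1))
        p_hi = min(n1 - 1, d)
        run = 0
        p = p_lo
        while p <= p_hi + 1:
            inside = p <= p_hi and WC_COMPLEMENT[b1[p]] == b2[d - p]
            if inside:
                run += 1
            else:
                if run >= min_region_len:
                    start_i = p - run
                    start_j = d - (p - 1)
                    if not (self_mode and start_j < start_i):
                        ra = b1[start_i : start_i + run]
                        rb = b2[start_j : start_j + run]
                        out.append(
                            RegionPair(
                                region_i=(start_i, run),
                                region_j=(start_j, run),
                                dG_ij=duplex_energy(ra, rb, params),
                            )
                        )
                run = 0
            p += 1
    out.sort(key=lambda rp: (rp.region_i, rp.region_j))
    return out
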