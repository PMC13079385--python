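"""Structure scoring by loop decomposition, perfect-duplex energies, and the
exhaustive enumeration oracle.

A secondary structure of one or more strands is a nested set of base pairs
on the concatenated sequence, with recorded nick positions between strands.
Its energy is the sum over loops:

* hairpin / bulge / internal loop initiation penalties (size-indexed),
* stacking energies for adjacent pairs,
* zero for multiloops, exterior loops, and any loop containing a nick,
* a terminal penalty for every A.U or G.U pair bordering a non-stack loop.

The same decomposition is used by the dynamic-programming kernels, so the
enumeration functions here serve as an independent oracle for them only in
the sense of summing over explicitly generated structures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .params import EnergyParams, PAIR_TYPE, default_params
from .sequence import BASE_INDEX, RnaSequence, as_rna, is_wc_pair, revcomp


class StructureError(ValueError):
    """Raised for an illegal secondary structure."""


class ComplementarityError(ValueError):
    """Raised when duplex regions are not perfect WC reverse complements."""


@dataclass(frozen=True)
class SecondaryStructure:
    """Nested base pairs on the concatenation of one or more strands.

    ``pairs`` holds (i, j) with i < j in concatenation coordinates;
    ``nicks`` holds positions p such that a strand break lies between
    p and p+1. For a single strand ``nicks`` is empty.
    """

    n: int
    pairs: frozenset
    nicks: tuple = ()

    @property
    def paired_positions(self) -> set:
        out = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out

    def dot_bracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        for p in sorted(self.nicks, reverse=True):
            chars.insert(p + 1, "+")
        return "".join(chars)


def _pair_code(bases: str, i: int, j: int) -> int:
    return int(PAIR_TYPE[BASE_INDEX[bases[i]], BASE_INDEX[bases[j]]])


def concat_with_nicks(strands) -> tuple[str, tuple]:
    """Concatenate strand base strings; return (bases, nick positions)."""
    seqs = [as_rna(s).bases for s in strands]
    nicks = []
    off = 0
    for s in seqs[:-1]:
        off += len(s)
        nicks.append(off - 1)
    return "".join(seqs), tuple(nicks)


def _build_tree(n: int, pairs) -> dict:
    """Children map for a nested pair set; key None is the exterior loop.

    Raises StructureError on crossing pairs or reused indices.
    """
    seen = set()
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise StructureError(f"pair ({i},{j}) out of range")
        if i in seen or j in seen:
            raise StructureError(f"index reused in pair ({i},{j})")
        seen.add(i)
        seen.add(j)
    children: dict = {None: []}
    stack = [None]
    opens = {i: (i, j) for i, j in pairs}
    closes = {j: (i, j) for i, j in pairs}
    for pos in range(n):
        if pos in closes:
            if stack[-1] != closes[pos]:
                raise StructureError("pairs are not nested (pseudoknot)")
            stack.pop()
        if pos in opens:
            pr = opens[pos]
            children.setdefault(pr, [])
            children[stack[-1]].append(pr)
            stack.append(pr)
    return children


def structure_energy(strands, pairs, params: EnergyParams | None = None) -> float:
    """Energy (kcal/mol) of one nested structure; raises on illegal structures.

    ``strands`` may be a single sequence/str or a list (complex with nicks).
    The returned energy excludes the per-strand association penalty and the
    rotational-symmetry term; those belong to the complex free energy and are
    applied in :mod:`rnapal.multistrand`.
    """
    params = params or default_params()
    if isinstance(strands, (str, RnaSequence)):
        strands = [strands]
    bases, nicks = concat_with_nicks(strands)
    n = len(bases)
    nick_set = set(nicks)
    children = _build_tree(n, pairs)

    def codes(pr):
        c = _pair_code(bases, pr[0], pr[1])
        if c < 0:
            raise StructureError(f"pair {pr} is not a legal base pair")
        return c

    energy = 0.0
    # exterior loop: terminal penalties only
    for child in children[None]:
        energy += params.terminal_penalty(codes(child))

    for key, kids in children.items():
        if key is None:
            continue
        i, j = key
        pc = codes((i, j))
        spans = [(k, l) for k, l in kids]
        loop_nicks = [
            p
            for p in nick_set
            if i <= p < j and not any(k <= p < l for k, l in spans)
        ]
        if loop_nicks:
            energy += params.terminal_penalty(pc)
            for child in spans:
                energy += params.terminal_penalty(codes(child))
        elif not spans:
            size = j - i - 1
            if size < params.min_hairpin:
                raise StructureError(
                    f"hairpin closed by ({i},{j}) has only {size} unpaired bases"
                )
            energy += params.hairpin_energy(size) + params.terminal_penalty(pc)
        elif len(spans) == 1:
            k, l = spans[0]
            g1, g2 = k - i - 1, j - l - 1
            inner = codes((k, l))
            if g1 == 0 and g2 == 0:
                st = params.stack[pc, inner]
                if not st < float("inf"):
                    raise StructureError(f"no stack parameter for ({i},{j})/({k},{l})")
                energy += float(st)
            else:
                size = g1 + g2
                if size > params.two_loop_max:
                    raise StructureError(
                        f"two-sided loop of size {size} exceeds cap {params.two_loop_max}"
                    )
                pen = (
                    params.bulge_energy(size)
                    if min(g1, g2) == 0
                    else params.internal_energy(size)
                )
                energy += pen + params.terminal_penalty(pc) + params.terminal_penalty(inner)
        else:
            energy += params.terminal_penalty(pc)
            for child in spans:
                energy += params.terminal_penalty(codes(child))
    return energy


def is_connected(strands, pairs) -> bool:
    """True iff every strand is linked to every other through base pairs."""
    if isinstance(strands, (str, RnaSequence)):
        strands = [strands]
    lengths = [len(as_rna(s).bases) for s in strands]
    m = len(lengths)
    if m == 1:
        return True
    bounds = list(itertools.accumulate(lengths))

    def strand_of(pos: int) -> int:
        for s, b in enumerate(bounds):
            if pos < b:
                return s
        raise IndexError(pos)

    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        a, b = find(strand_of(i)), find(strand_of(j))
        if a != b:
            parent[a] = b
    return len({find(s) for s in range(m)}) == 1


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_structures(
    strands,
    params: EnergyParams | None = None,
    max_total_length: int = 16,
    connected_only: bool = False,
):
    """All legal nested structures of the strand(s), with energies.

    A test oracle: exponential in length, guarded by ``max_total_length``.
    Yields (SecondaryStructure, energy) with every legal structure exactly
    once, including the open chain.
    """
    params = params or default_params()
    if isinstance(strands, (str, RnaSequence)):
        strands = [strands]
    bases, nicks = concat_with_nicks(strands)
    n = len(bases)
    if n > max_total_length:
        raise ValueError(
            f"total length {n} exceeds enumeration cap {max_total_length}"
        )
    nick_set = set(nicks)
    idx = [BASE_INDEX[b] for b in bases]

    def pairable(i, j):
        return PAIR_TYPE[idx[i], idx[j]] >= 0

    def nick_between(i, j):
        return any(i <= p < j for p in nick_set)

    def gen(i, j):
        # all nested pair sets on [i..j]; local hairpin pre-check only
        if i >= j:
            yield frozenset()
            return
        for s in gen(i + 1, j):
            yield s
        for k in range(i + 1, j + 1):
            if not pairable(i, k):
                continue
            for inner in gen(i + 1, k - 1):
                if (
                    not inner
                    and not nick_between(i, k)
                    and k - i - 1 < params.min_hairpin
                ):
                    continue
                head = frozenset({(i, k)}) | inner
                for rest in gen(k + 1, j):
                    yield head | rest

    for pairs in gen(0, n - 1):
        if connected_only and not is_connected(strands, pairs):
            continue
        try:
            e = structure_energy(strands, pairs, params)
        except StructureError:
            continue
        yield SecondaryStructure(n=n, pairs=pairs, nicks=nicks), e


# ---------------------------------------------------------------------------
# perfect duplexes
# ---------------------------------------------------------------------------

def duplex_energy(a, b, params: EnergyParams | None = None) -> float:
    """Free energy of the perfect duplex of two exactly reverse-complementary
    regions (strict Watson-Crick), as used for palindrome self-binding.

    Sum of stacks along the helix + duplex initiation + terminal penalties at
    both ends + the symmetry correction iff the duplex is self-complementary
    (the two regions are the same sequence).
    """
    params = params or default_params()
    sa = as_rna(a).bases
    sb = as_rna(b).bases
    if len(sa) < 2 or len(sb) < 2:
        raise ComplementarityError("duplex regions must have length >= 2")
    if len(sa) != len(sb) or revcomp(sb) != sa:
        raise ComplementarityError(
            f"regions {sa!r} and {sb!r} are not WC reverse complements"
        )
    L = len(sa)
    # pair t: (sa[t], sb[L-1-t]); all WC by construction
    e = params.duplex_init
    codes = [_pair_code(sa + sb, t, L + (L - 1 - t)) for t in range(L)]
    # terminal penalties at both helix ends
    e += params.terminal_penalty(codes[0]) + params.terminal_penalty(codes[-1])
    for t in range(L - 1):
        st = params.stack[codes[t], codes[t + 1]]
        e += float(st)
    if sa == sb:
        e += params.symmetry_correction
    return e
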