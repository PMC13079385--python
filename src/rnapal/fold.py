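"""Single-strand and concatenation folding: partition functions, base-pair
probabilities, Boltzmann sampling, and region accessibility (pfree).

The inside recursion lives in :mod:`rnapal._kernels`; this module prepares
parameter arrays, chooses the per-base scaling needed to keep weights in
double-precision range, and implements the outside algorithm and stochastic
traceback in terms of the inside matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import inside
from .params import EnergyParams, PAIR_TYPE, default_params
from .sequence import RnaSequence, as_rna

# per-base ln(scale) ladder tried until the inside matrices are finite
_LN_SIGMA_LADDER = (0.0, 0.75, 1.5, 3.0, 6.0)


class FoldError(ValueError):
    pass


@dataclass
class FoldResult:
    """Inside matrices and derived quantities for one strand or concatenation.

    ``lnQ`` is the log partition function over all legal nested structures
    (including disconnected ones, for multistrand concatenations); the
    connected-complex bookkeeping is done in :mod:`rnapal.multistrand`.
    """

    seqs: list
    bases: str
    nicks: tuple
    params: EnergyParams
    qb: np.ndarray
    w: np.ndarray
    z: np.ndarray
    ln_sigma: float
    lnQ: float
    # prepared arrays reused by traceback
    _idx: np.ndarray = None
    _stack_w: np.ndarray = None
    _tau_w: np.ndarray = None
    _hp_w: np.ndarray = None
    _bulge_w: np.ndarray = None
    _int_w: np.ndarray = None
    _pow_inv: np.ndarray = None

    @property
    def n(self) -> int:
        return len(self.bases)

    @property
    def Q(self) -> float:
        try:
            return math.exp(self.lnQ)
        except OverflowError:
            return math.inf

    @property
    def dG(self) -> float:
        return -self.params.kBT * self.lnQ

    # ------------------------------------------------------------------
    # outside algorithm and pair probabilities (single strand)
    # ------------------------------------------------------------------

    def pair_probabilities(self) -> "PairProbabilities":
        """Exact equilibrium base-pair probabilities (single strand only)."""
        if self.nicks:
            raise FoldError("pair probabilities are implemented for single strands")
        if self.ln_sigma != 0.0:
            raise FoldError(
                "sequence too long for the unscaled outside recursion"
            )
        n = self.n
        p = self.params
        cap = p.two_loop_max
        idx = self._idx
        qb, w, z = self.qb, self.w, self.z
        stack_w, tau_w = self._stack_w, self._tau_w
        bulge_w, int_w = self._bulge_w, self._int_w
        Z = z[0, n]
        qh = np.zeros((n, n))
        qht = np.zeros((n, n))  # qh * tau, used in multiloop sums

        for s in range(n - 1, 0, -1):
            for i in range(0, n - s):
                j = i + s
                if qb[i, j] <= 0.0:
                    continue
                pt = int(PAIR_TYPE[idx[i], idx[j]])
                val = z[0, i] * tau_w[pt] * z[j + 1, n]
                # inner pair of a stack
                if i >= 1 and j <= n - 2:
                    pto = int(PAIR_TYPE[idx[i - 1], idx[j + 1]])
                    if pto >= 0 and qh[i - 1, j + 1] > 0.0:
                        val += stack_w[pto, pt] * qh[i - 1, j + 1]
                # inner pair of a bulge / internal loop
                for k in range(max(0, i - 1 - cap), i):
                    g1 = i - k - 1
                    for l in range(j + 1, min(n, j + 2 + (cap - g1))):
                        g2 = l - j - 1
                        if g1 + g2 < 1 or qh[k, l] <= 0.0:
                            continue
                        pto = int(PAIR_TYPE[idx[k], idx[l]])
                        lw = bulge_w[g1 + g2] if min(g1, g2) == 0 else int_w[g1 + g2]
                        val += lw * tau_w[pto] * tau_w[pt] * qh[k, l]
                # helix inside a multiloop closed by (k, l)
                if i >= 1 and j <= n - 2:
                    sub = qht[0:i, j + 1 : n]
                    if sub.size and sub.any():
                        zl = z[1 : i + 1, i]  # z[k+1, i] for k = 0..i-1
                        zr = z[j + 1, j + 1 : n]  # z[j+1, l] for l = j+1..n-1
                        val += tau_w[pt] * (zl @ sub @ zr - sub.sum())
                qh[i, j] = val
                qht[i, j] = val * tau_w[pt]

        p_pair = qb * qh / Z
        return PairProbabilities(p_pair=p_pair)

    # ------------------------------------------------------------------
    # stochastic traceback
    # ------------------------------------------------------------------

    def sample(self, n_samples: int, seed: int) -> list:
        """i.i.d. Boltzmann samples of secondary structures (single strand)."""
        from .energy import SecondaryStructure

        if self.nicks:
            raise FoldError("sampling is implemented for single strands")
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_samples):
            pairs = self._sample_one(rng)
            out.append(SecondaryStructure(n=self.n, pairs=frozenset(pairs)))
        return out

    def _sample_one(self, rng) -> list:
        n = self.n
        pairs: list = []
        stack: list = []  # ("Z", a, b) plain tiling | ("B", i, j) pair | ("M", a, b, need)
        stack.append(("Z", 0, n - 1))
        while stack:
            task = stack.pop()
            kind = task[0]
            if kind == "Z":
                _, a, b = task
                self._trace_tiling(a, b, 0, rng, pairs, stack)
            elif kind == "M":
                _, a, b, need = task
                self._trace_tiling(a, b, need, rng, pairs, stack)
            else:
                _, i, j = task
                pairs.append((i, j))
                self._trace_pair(i, j, rng, pairs, stack)
        return pairs

    def _trace_tiling(self, a, b, need, rng, pairs, stack) -> None:
        """Sample an exterior-style tiling of [a..b] with >= `need` helices."""
        z, w, pw = self.z, self.w, self._pow_inv
        pos = a
        while pos <= b:
            if need > 0:
                # choose the leftmost helix (k, l)
                opts = []
                wts = []
                for k in range(pos, b):
                    for l in range(k + 1, b + 1):
                        if w[k, l] <= 0.0:
                            continue
                        rest_len = b - l
                        rest = z[l + 1, b + 1]
                        if need > 1:
                            rest -= pw[rest_len]
                        if rest <= 0.0:
                            continue
                        opts.append((k, l))
                        wts.append(pw[k - pos] * w[k, l] * rest)
                k, l = opts[_pick(wts, rng)]
                stack.append(("B", k, l))
                pos = l + 1
                need -= 1
            else:
                # step: pos unpaired, or pos paired with k
                wts = [self._pow_inv[1] * z[pos + 1, b + 1]]
                opts = [None]
                for k in range(pos + 1, b + 1):
                    if w[pos, k] > 0.0:
                        opts.append(k)
                        wts.append(w[pos, k] * z[k + 1, b + 1])
                choice = opts[_pick(wts, rng)]
                if choice is None:
                    pos += 1
                else:
                    stack.append(("B", pos, choice))
                    pos = choice + 1

    def _trace_pair(self, i, j, rng, pairs, stack) -> None:
        """Sample the loop type closed by pair (i, j)."""
        p = self.params
        idx = self._idx
        qb, w, z, pw = self.qb, self.w, self.z, self._pow_inv
        tau_w, stack_w = self._tau_w, self._stack_w
        hp_w, bulge_w, int_w = self._hp_w, self._bulge_w, self._int_w
        cap = p.two_loop_max
        s = j - i
        pt = int(PAIR_TYPE[idx[i], idx[j]])
        opts = []
        wts = []
        if hp_w[s - 1] > 0.0:
            opts.append(("H",))
            wts.append(hp_w[s - 1] * tau_w[pt] * pw[s + 1])
        for k in range(i + 1, min(i + 1 + cap, j - 2) + 1):
            g1 = k - i - 1
            for l in range(j - 1, max(k + 1, j - 1 - (cap - g1)) - 1, -1):
                if qb[k, l] <= 0.0:
                    continue
                g2 = j - l - 1
                pt2 = int(PAIR_TYPE[idx[k], idx[l]])
                if g1 == 0 and g2 == 0:
                    wgt = stack_w[pt, pt2] * qb[k, l] * pw[2]
                elif min(g1, g2) == 0:
                    wgt = bulge_w[g1 + g2] * tau_w[pt] * tau_w[pt2] * qb[k, l] * pw[g1 + g2 + 2]
                else:
                    wgt = int_w[g1 + g2] * tau_w[pt] * tau_w[pt2] * qb[k, l] * pw[g1 + g2 + 2]
                if wgt > 0.0:
                    opts.append(("L", k, l))
                    wts.append(wgt)
        if j - i >= 2:
            m_val = z[i + 1, j] - pw[s - 1]
            if s >= 3:
                m_val -= self._ss(i + 1, j - 1)
            if m_val > 0.0:
                opts.append(("M",))
                wts.append(tau_w[pt] * m_val * pw[2])
        choice = opts[_pick(wts, rng)]
        if choice[0] == "L":
            stack.append(("B", choice[1], choice[2]))
        elif choice[0] == "M":
            stack.append(("M", i + 1, j - 1, 2))

    def _ss(self, a, b) -> float:
        """Single-helix tilings of [a..b] (recomputed; small intervals only)."""
        w, pw = self.w, self._pow_inv
        tot = 0.0
        for k in range(a, b):
            for l in range(k + 1, b + 1):
                if w[k, l] > 0.0:
                    tot += w[k, l] * pw[(k - a) + (b - l)]
        return tot


@dataclass(frozen=True)
class PairProbabilities:
    """Equilibrium pairing probabilities of a single strand.

    ``p_pair`` is symmetric-by-construction upper-triangular content stored
    densely: entry (i, j), i < j, is the probability that i pairs with j.
    """

    p_pair: np.ndarray

    @property
    def p_unpaired(self) -> np.ndarray:
        full = self.p_pair + self.p_pair.T
        return 1.0 - full.sum(axis=1)


def _pick(weights, rng) -> int:
    tot = float(sum(weights))
    r = rng.random() * tot
    acc = 0.0
    for ix, wt in enumerate(weights):
        acc += wt
        if r <= acc:
            return ix
    return len(weights) - 1


# ---------------------------------------------------------------------------
# folding entry points
# ---------------------------------------------------------------------------

def fold(
    strands,
    params: EnergyParams | None = None,
    forced_unpaired=None,
) -> FoldResult:
    """Run the inside recursion on one strand or an ordered strand list.

    ``forced_unpaired`` is an optional iterable of concatenation positions
    that may not pair (used for constrained / accessibility partition
    functions).
    """
    from .energy import concat_with_nicks

    params = params or default_params()
    if isinstance(strands, (str, RnaSequence)):
        strands = [strands]
    strands = [as_rna(s) for s in strands]
    bases, nicks = concat_with_nicks(strands)
    n = len(bases)

    idx = np.array([ "ACGU".index(b) for b in bases], dtype=np.int8)
    can_pair = np.ones(n, dtype=np.uint8)
    if forced_unpaired is not None:
        for pos in forced_unpaired:
            if not 0 <= pos < n:
                raise FoldError(f"constraint position {pos} out of range")
            can_pair[pos] = 0
    ncum = np.zeros(n + 1, dtype=np.int64)
    nick_set = set(nicks)
    for x in range(1, n + 1):
        ncum[x] = ncum[x - 1] + (1 if (x - 1) in nick_set else 0)

    stack_w = params.stack_weights
    tau_w = params.terminal_weights
    hp_w, bulge_w, int_w = params.loop_weight_tables(n)

    last_err = None
    for ln_sigma in _LN_SIGMA_LADDER:
        inv_sigma = math.exp(-ln_sigma)
        qb, w, ss, z = inside(
            idx, can_pair, ncum, PAIR_TYPE, stack_w, tau_w,
            hp_w, bulge_w, int_w, np.int64(params.two_loop_max), inv_sigma,
        )
        zfull = z[0, n]
        if np.isfinite(zfull) and zfull > 0.0 and np.isfinite(qb).all() and np.isfinite(z).all():
            lnQ = math.log(zfull) + n * ln_sigma
            pow_inv = inv_sigma ** np.arange(n + 2)
            return FoldResult(
                seqs=strands, bases=bases, nicks=nicks, params=params,
                qb=qb, w=w, z=z, ln_sigma=ln_sigma, lnQ=max(lnQ, 0.0) if not nicks and forced_unpaired is None else lnQ,
                _idx=idx, _stack_w=stack_w, _tau_w=tau_w,
                _hp_w=hp_w, _bulge_w=bulge_w, _int_w=int_w, _pow_inv=pow_inv,
            )
        last_err = f"overflow at ln_sigma={ln_sigma}"
    raise FoldError(f"inside recursion did not stabilize: {last_err}")


def partition_function(seq, params: EnergyParams | None = None):
    """(Q, dG1) of a single strand over all nested structures incl. the open
    chain. Q >= 1, hence dG1 <= 0; dG1 = 0 iff no legal pair exists."""
    res = fold(seq, params)
    return res.Q, res.dG


def pair_probabilities(seq, params: EnergyParams | None = None) -> PairProbabilities:
    return fold(seq, params).pair_probabilities()


def sample_structures(seq, n: int, seed: int, params: EnergyParams | None = None):
    """n i.i.d. Boltzmann samples via stochastic traceback; reproducible by seed."""
    return fold(seq, params).sample(n, seed)


def region_pfree(
    seq,
    region,
    params: EnergyParams | None = None,
    mode: str = "sampled",
    n_samples: int = 10_000,
    seed: int = 0,
    _fold_result: FoldResult | None = None,
) -> float:
    """Probability that the whole region (start, length) is unpaired in the
    equilibrium ensemble of the molecule.

    exact mode: ratio of the region-constrained partition function to the
    full one. sampled mode: fraction of Boltzmann samples with every region
    base unpaired.
    """
    rna = as_rna(seq)
    start, length = region
    if start < 0 or length < 1 or start + length > len(rna.bases):
        raise FoldError(f"region {region} out of bounds for length {len(rna.bases)}")
    positions = range(start, start + length)
    if mode == "exact":
        base = _fold_result if _fold_result is not None else fold(rna, params)
        constrained = fold(rna, params, forced_unpaired=positions)
        return min(1.0, math.exp(constrained.lnQ - base.lnQ))
    if mode == "sampled":
        base = _fold_result if _fold_result is not None else fold(rna, params)
        samples = base.sample(n_samples, seed)
        region_set = set(positions)
        free = sum(1 for s in samples if not (s.paired_positions & region_set))
        return free / n_samples
    raise ValueError(f"unknown pfree mode {mode!r}")
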