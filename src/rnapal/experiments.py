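"""Seeded sequence ensembles and the in-silico screening pipelines.

The pipelines quantify how palindrome content drives homotypic association:

* ``homo_vs_hetero_experiment`` — for random sequence pairs, compare the
  total homodimer free energy dG11 + dG22 against the heterodimer channel
  2 dG12; random RNAs favor homodimers roughly twice as often as
  heterodimers, and palindrome-free controls invert the ratio.
* ``multimer_screen`` — homomultimer mass action per sequence; the fraction
  of strands in higher-order clusters correlates with palindrome strength.
* ``dimer_gap_screen`` — dG11 - 2 dG1 against dG_pal.
* ``noneq_screen`` / ``wpal_curve`` — nonequilibrium propensities.
* ``select_length_matched`` — length-window selection plus Smith-Waterman
  near-duplicate removal for user-supplied transcript sets.

Every pipeline is deterministic given (seed, config); sub-seeds are derived
with numpy SeedSequence spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .multistrand import (
    dimer_energies,
    equilibrium_cluster_distribution,
    homomultimer_energies,
)
from .noneq import NoneqParams, _PfreeCache, homo_vs_hetero_noneq, palindromic_noneq_weight
from .palindrome import find_palindromes, palindrome_binding_strength
from .params import EnergyParams, default_params
from .sequence import RnaSequence, as_rna

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs shared by the screening pipelines (desk-scale defaults).

    The published ensembles are larger (1e4 pairs, 5e4 sequences, 1e5
    structure samples); these defaults shrink them to sizes a laptop runs in
    minutes while preserving every qualitative readout. Scale up by
    replacing the counts.
    """

    seed: int = 0
    n_pairs: int = 500
    pair_length: int = 30
    n_seqs: int = 300
    lengths: tuple = (20, 21, 22, 23, 24, 25)
    dimer_lengths: tuple = (20, 25, 30, 35)
    n_per_length: int = 20
    dG_star_grid: tuple = (-12.5, -11.5, -10.5, -9.5, -8.5)
    conc_prefactor_mM: float = 4.0
    conc_ref_length: int = 20
    conc_exponent: float = 2.5
    max_cluster_size: int = 10
    higher_order_threshold: int = 4
    bin_width: float = 2.0
    min_bin_count: int = 30
    min_palindrome_len: int = 4
    tie_tol: float = 1e-9

    def concentration(self, L: int) -> float:
        """Per-length input concentration in molar: 4 (20/L)^2.5 mM."""
        return (
            self.conc_prefactor_mM
            * 1e-3
            * (self.conc_ref_length / L) ** self.conc_exponent
        )


# ---------------------------------------------------------------------------
# sequence ensembles
# ---------------------------------------------------------------------------

def random_sequences(n: int, L: int, seed: int, prefix: str = "rnd") -> list:
    """n iid-uniform RNA sequences of length L (25% per base), seeded."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        bases = "".join(_BASES[rng.integers(0, 4, size=L)])
        out.append(RnaSequence(id=f"{prefix}_{L}nt_{k}", bases=bases))
    return out


def palindrome_free_sequences(
    n: int,
    L: int,
    min_len: int = 4,
    seed: int = 0,
    max_tries_per_seq: int = 100_000,
    prefix: str = "palfree",
) -> list:
    """Rejection-sample iid-uniform sequences with no palindrome >= min_len."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        for _ in range(max_tries_per_seq):
            bases = "".join(_BASES[rng.integers(0, 4, size=L)])
            if not find_palindromes(bases, min_len=min_len):
                out.append(RnaSequence(id=f"{prefix}_{L}nt_{k}", bases=bases))
                break
        else:
            raise RuntimeError(
                f"no palindrome-free sequence of length {L} found in "
                f"{max_tries_per_seq} tries"
            )
    return out


def _spawn_seeds(seed: int, n: int) -> list:
    """n reproducible child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# homodimer vs heterodimer competition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomoHeteroResult:
    frac_homo: float
    frac_hetero: float
    frac_tie: float
    table: pd.DataFrame = field(repr=False, compare=False, default=None)

    @property
    def ratio(self) -> float:
        """homo-favored : hetero-favored ratio (inf if no hetero pairs)."""
        if self.frac_hetero == 0:
            return math.inf
        return self.frac_homo / self.frac_hetero


def homo_vs_hetero_experiment(
    cfg: ExperimentConfig,
    palindrome_free: bool = False,
    params: EnergyParams | None = None,
) -> HomoHeteroResult:
    """Classify random sequence pairs by sign of (dG11 + dG22) - 2 dG12.

    The comparison is made on labeled-strand dimer ensembles: the
    rotational-symmetry division in the homodimer complex free energies is
    undone (kBT ln 2 per homodimer), so the two channels count dimers of
    distinguishable molecules on an equal footing and a sequence paired
    with itself scores as an exact tie, never as hetero-favored.

    Exact ties (within ``tie_tol`` kcal/mol, or both channels absent) are
    reported separately rather than folded into either fraction.
    """
    params = params or default_params()
    seed_a, seed_b = _spawn_seeds(cfg.seed, 2)
    maker = palindrome_free_sequences if palindrome_free else random_sequences
    kwargs = {"min_len": cfg.min_palindrome_len} if palindrome_free else {}
    group_a = maker(cfg.n_pairs, cfg.pair_length, seed=seed_a, prefix="a", **kwargs)
    group_b = maker(cfg.n_pairs, cfg.pair_length, seed=seed_b, prefix="b", **kwargs)

    ln2 = params.kBT * math.log(2)
    rows = []
    n_homo = n_het = n_tie = 0
    for sa, sb in zip(group_a, group_b):
        g11, g22, g12 = dimer_energies(sa, sb, params)
        g_hom = g11 + g22 - 2 * ln2  # labeled homodimer ensembles
        g_het = 2 * g12
        if math.isinf(g_hom) and math.isinf(g_het):
            cls = "tie"
        elif g_hom < g_het - cfg.tie_tol:
            cls = "homo"
        elif g_het < g_hom - cfg.tie_tol:
            cls = "hetero"
        else:
            cls = "tie"
        n_homo += cls == "homo"
        n_het += cls == "hetero"
        n_tie += cls == "tie"
        rows.append(
            dict(id_a=sa.id, id_b=sb.id, dG11=g11, dG22=g22, dG12=g12, favored=cls)
        )
    n = len(rows)
    return HomoHeteroResult(
        frac_homo=n_homo / n,
        frac_hetero=n_het / n,
        frac_tie=n_tie / n,
        table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# homomultimer screen (palindrome strength vs higher-order clustering)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n_used: int
    n_excluded: int  # sentinel (palindrome-free) sequences left out


@dataclass(frozen=True)
class MultimerCorrelation:
    """Association between palindrome strength and higher-order clustering.

    ``spearman_*``: rank correlation of -dG_pal against the higher-order
    strand fraction over all sequences; palindrome-free sequences enter with
    the weakest possible palindrome strength (-inf), which ranks make exact.
    ``pearson_*``: linear correlation over the finite-dG_pal rows only.
    """

    spearman_r: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    n_total: int
    n_no_palindrome: int


def multimer_screen(
    cfg: ExperimentConfig,
    params: EnergyParams | None = None,
):
    """Per-sequence dG_pal and higher-order strand fraction, plus the binned
    curve and the correlation between -dG_pal and the higher-order fraction.

    Sequences are drawn uniformly per length in ``cfg.lengths``; each is
    screened at concentration 4 (20/L)^2.5 mM with clusters up to
    ``max_cluster_size`` and the >= ``higher_order_threshold`` readout.
    The headline statistic is the rank correlation over all sequences
    (palindrome-free ones rank weakest); the linear Pearson correlation over
    finite-dG_pal rows is reported alongside.
    """
    params = params or default_params()
    seeds = _spawn_seeds(cfg.seed, len(cfg.lengths))
    per_len = max(1, cfg.n_seqs // len(cfg.lengths))
    rows = []
    for L, sd in zip(cfg.lengths, seeds):
        for seq in random_sequences(per_len, L, seed=sd):
            gpal = palindrome_binding_strength(
                seq, params, min_len=cfg.min_palindrome_len
            )
            energies = homomultimer_energies(seq, cfg.max_cluster_size, params)
            dist = equilibrium_cluster_distribution(
                energies, cfg.concentration(L), cfg.max_cluster_size, params
            )
            rows.append(
                dict(
                    seq_id=seq.id,
                    L=L,
                    dG_pal=gpal,
                    higher_order_fraction=dist.higher_order_fraction(
                        cfg.higher_order_threshold
                    ),
                )
            )
    table = pd.DataFrame(rows)

    finite = table[np.isfinite(table.dG_pal)]
    if len(finite) >= 3 and finite.dG_pal.nunique() > 1:
        pr, pp = stats.pearsonr(-finite.dG_pal, finite.higher_order_fraction)
        sr, sp = stats.spearmanr(
            -table.dG_pal.to_numpy(), table.higher_order_fraction.to_numpy()
        )
    else:
        pr = pp = sr = sp = math.nan
    corr = MultimerCorrelation(
        spearman_r=float(sr), spearman_p=float(sp),
        pearson_r=float(pr), pearson_p=float(pp),
        n_total=len(table), n_no_palindrome=len(table) - len(finite),
    )

    # per-length binned curves, dropping bins with < min_bin_count points
    curves = []
    for L, sub in finite.groupby("L"):
        bins = np.floor(sub.dG_pal / cfg.bin_width) * cfg.bin_width
        for lo, grp in sub.groupby(bins):
            if len(grp) < cfg.min_bin_count:
                continue
            curves.append(
                dict(
                    L=L,
                    bin_low=float(lo),
                    bin_mid=float(lo) + cfg.bin_width / 2,
                    mean_higher_order=float(grp.higher_order_fraction.mean()),
                    n=len(grp),
                )
            )
    curve_table = pd.DataFrame(
        curves, columns=["L", "bin_low", "bin_mid", "mean_higher_order", "n"]
    )
    return table, curve_table, corr


# ---------------------------------------------------------------------------
# dimer-gap screen (dG11 - 2 dG1 vs dG_pal)
# ---------------------------------------------------------------------------

def dimer_gap_screen(
    cfg: ExperimentConfig,
    extra_sequences: list | None = None,
    params: EnergyParams | None = None,
):
    """Per-sequence (dG1, dG11, dG_pal) and Pearson r of dG11 - 2 dG1 vs
    dG_pal over finite rows. ``extra_sequences`` (e.g. natural transcripts
    from FASTA) join the random set, tagged by origin."""
    params = params or default_params()
    seeds = _spawn_seeds(cfg.seed, len(cfg.dimer_lengths))
    seqs = []
    for L, sd in zip(cfg.dimer_lengths, seeds):
        seqs.extend((s, "random") for s in random_sequences(cfg.n_per_length, L, seed=sd))
    for s in extra_sequences or []:
        seqs.append((as_rna(s), "supplied"))

    rows = []
    for seq, origin in seqs:
        energies = homomultimer_energies(seq, 2, params)
        g1, g11 = energies[0].dG, energies[1].dG
        gpal = palindrome_binding_strength(seq, params, min_len=cfg.min_palindrome_len)
        rows.append(
            dict(
                seq_id=seq.id, L=len(seq), origin=origin,
                dG1=g1, dG11=g11, dG_pal=gpal,
                gap=g11 - 2 * g1 if math.isfinite(g11) else math.inf,
            )
        )
    table = pd.DataFrame(rows)
    mask = np.isfinite(table.gap) & np.isfinite(table.dG_pal)
    finite = table[mask]
    if len(finite) >= 3 and finite.dG_pal.nunique() > 1 and finite.gap.nunique() > 1:
        r, pval = stats.pearsonr(finite.gap, finite.dG_pal)
        corr = CorrelationResult(
            r=float(r), p_value=float(pval),
            n_used=len(finite), n_excluded=len(table) - len(finite),
        )
    else:
        corr = CorrelationResult(
            r=math.nan, p_value=math.nan,
            n_used=len(finite), n_excluded=len(table) - len(finite),
        )
    return table, corr


# ---------------------------------------------------------------------------
# nonequilibrium screens
# ---------------------------------------------------------------------------

def noneq_screen(
    group_a: list,
    group_b: list,
    p: NoneqParams | None = None,
    params: EnergyParams | None = None,
) -> pd.DataFrame:
    """All-pairs matrix of 2 dG12_noneq - (dG11_noneq + dG22_noneq) between
    two sequence groups, as a tidy table (one row per pair)."""
    p = p or NoneqParams()
    params = params or default_params()
    group_a = [as_rna(s) for s in group_a]
    group_b = [as_rna(s) for s in group_b]
    caches_a = {s.id: _PfreeCache(s, p, params) for s in group_a}
    caches_b = {}
    for s in group_b:
        caches_b[s.id] = _PfreeCache(s, p, params)
    rows = []
    for sa in group_a:
        for sb in group_b:
            val = homo_vs_hetero_noneq(
                sa, sb, p, params,
                _cache1=caches_a[sa.id], _cache2=caches_b[sb.id],
            )
            rows.append(dict(id_a=sa.id, id_b=sb.id, hetero_vs_homo=val))
    df = pd.DataFrame(rows)
    df.attrs["dG_star"] = p.dG_star
    return df


def wpal_curve(
    seq,
    dG_star_grid,
    p: NoneqParams | None = None,
    params: EnergyParams | None = None,
) -> pd.DataFrame:
    """W_pal as a function of dG_star (non-decreasing); one fold per call."""
    p = p or NoneqParams()
    params = params or default_params()
    seq = as_rna(seq)
    cache = _PfreeCache(seq, p, params)
    rows = []
    for g_star in dG_star_grid:
        w = palindromic_noneq_weight(seq, replace(p, dG_star=g_star), params, _cache=cache)
        rows.append(dict(seq_id=seq.id, dG_star=float(g_star), W_pal=w))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alignment-based selection of length-matched sequence sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentScore:
    """Smith-Waterman local alignment score under (+1, -2, -2) scoring."""

    score: int
    match: int = 1
    mismatch: int = -2
    gap: int = -2


def smith_waterman(seq1, seq2, scoring: tuple = (1, -2, -2)) -> AlignmentScore:
    """Best local-alignment score with linear gap penalty."""
    from Bio import Align

    b1 = as_rna(seq1, "a").bases if seq1 else ""
    b2 = as_rna(seq2, "b").bases if seq2 else ""
    match, mismatch, gap = scoring
    if not b1 or not b2:
        return AlignmentScore(score=0, match=match, mismatch=mismatch, gap=gap)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    score = int(aligner.score(b1, b2))
    return AlignmentScore(score=score, match=match, mismatch=mismatch, gap=gap)


def select_length_matched(
    sequences: list,
    target_length: int,
    window: int,
    dedup_fraction: float = 0.8,
    scoring: tuple = (1, -2, -2),
) -> list:
    """Sequences with target_length - window < L < target_length + window
    (strict inequalities), with near-duplicates removed.

    Two sequences are near-duplicates when their Smith-Waterman score is at
    least ``dedup_fraction`` times the shorter length (duplicates score close
    to their length, unrelated pairs far below); the later member of each
    flagged pair is dropped.
    """
    pool = [
        as_rna(s)
        for s in sequences
        if target_length - window < len(as_rna(s)) < target_length + window
    ]
    dropped = set()
    for i in range(len(pool)):
        if i in dropped:
            continue
        for j in range(i + 1, len(pool)):
            if j in dropped:
                continue
            sc = smith_waterman(pool[i], pool[j], scoring).score
            if sc >= dedup_fraction * min(len(pool[i]), len(pool[j])):
                dropped.add(j)
    return [s for k, s in enumerate(pool) if k not in dropped]
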