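# Methods

`rnapal` asks how an RNA molecule can recognize copies of itself. Its core
observation is structural: a *palindrome* — a subsequence equal to its own
strict Watson–Crick reverse complement, such as `GCAUGC` — is the only kind
of region whose complement is guaranteed to exist on every other copy of the
same molecule. The package quantifies this idea with equilibrium
thermodynamics (partition functions of monomers, dimers and homomultimers)
and with a kinetic, accessibility-weighted score for the first contact
between two folded molecules.

## Energy model

Secondary structures are nested sets of base pairs (Watson–Crick plus G·U
wobble) with no pseudoknots. The shipped nearest-neighbor table
(`data/nn_params_v1.tsv`, version 1) contains:

| parameter | value / range | notes |
|---|---|---|
| temperature | 310.15 K (37 °C) | configurable; kBT = 0.61633 kcal/mol |
| WC×WC stacks | −0.93 … −3.42 kcal/mol | Xia-style 37 °C values |
| wobble stacks | −2.51 … +1.29 kcal/mol | Turner-style values |
| duplex initiation | +4.09 kcal/mol | once per strand added to a complex |
| terminal A·U/G·U penalty | +0.45 kcal/mol | per helix end bordering a non-stack loop |
| symmetry correction | +0.43 kcal/mol | self-complementary perfect duplexes (≈ kBT ln 2) |
| hairpin / bulge / internal loops | size-indexed tables | log-extrapolated past the table end |
| min hairpin size | 3 unpaired bases | |
| two-sided loop cap | 30 unpaired bases | structural constraint of the ensemble |

Deliberate simplifications, applied identically everywhere: multiloop
closure costs zero; exterior loops and any loop containing a strand nick
cost zero; no coaxial stacking, dangling ends, or terminal mismatches. The
loop-decomposition scorer (`energy.structure_energy`), the exhaustive
enumerator, and the dynamic programs all implement exactly this one model,
which is what makes oracle tests to 1e−9 relative error meaningful. The
table is loaded from plain text, completed under strand-reversal symmetry,
and validated (loop tables non-decreasing beyond their minimum, consistent
duplicates rejected). Absolute agreement with any particular published
parameter set is a non-goal; the package's claims are statistical and
verified against its own model.

## Inside recursion, sampling, accessibility

The inside DP (`_kernels.inside`, numba-compiled) follows the McCaskill
scheme over the concatenation of one or more strands with recorded nicks.
For the pair matrix `qb(i,j)` the loop closed by (i, j) is split into:
hairpin (no nick), stack/bulge/internal (no nick, inner size ≤ cap), and an
aggregate term for "multiloop or nicked loop", computed from the
exterior-tiling matrix `z` by subtracting the empty tiling and all
single-helix tilings (tracked in an auxiliary inclusion–exclusion matrix).
Because multiloops and nicked loops cost zero, this aggregate needs no
further decomposition. All weights are scaled per base by exp(−lnσ), with
lnσ chosen from a small ladder (0 … 6) until the matrices are finite and
positive; scaling cancels in traceback ratios and is undone in reported
free energies.

Base-pair probabilities come from an outside recursion mirroring the inside
cases (implemented in Python over the kernel's matrices; practical to a few
hundred nt). Boltzmann sampling is a stochastic traceback of `qb`/`z` with
explicit seeds; identical seeds reproduce identical structure lists.

Region accessibility `pfree(region)` — the probability that every base of a
region is unpaired in the monomer ensemble — has two modes: `exact`
(constrained partition function with the region forced unpaired, divided by
the full one) and `sampled` (fraction of sampled structures leaving the
region free; default 10^4 samples). Exact mode is used throughout the test
suite; the sampled default mirrors how accessibilities are estimated for
long molecules.

## Multistrand complexes

A complex of m strands in a fixed circular order is scored over connected,
nested, nick-legal structures. The inside pass counts connected and
disconnected structures together; the connected part is recovered by
inclusion–exclusion over the component containing the first strand. In a
non-crossing diagram that component may arc over other strands, so the
remaining strands fall into independent gap windows; for identical strands
the recursion closes over counts of gap compositions (see the module
docstring). Terms are computed as fractions of the total window partition
function, so the subtraction is stable; a connected fraction below 1e−12 of
the unconstrained ensemble is reported as "complex does not form" (+∞).
Heteromultimers are supported up to two strands — the screens need only
homomultimers and dimers.

Complex free energies add (m−1) × duplex initiation and the rotational
symmetry term kBT ln(symmetry factor): ΔG11 is the symmetry-divided
homodimer value, ΔG12 the heterodimer. One known approximation is shared
with standard practice: rotationally symmetric homodimer structures (a
perfect palindromic duplex is one) are undercounted by the uniform division,
by at most kBT ln 2.

The homodimer-vs-heterodimer classification compares *labeled* ensembles:
ΔG11 + ΔG22 − 2 kBT ln 2 against 2 ΔG12. This counts dimers of
distinguishable molecules on an equal footing, so a sequence compared with
itself scores an exact tie rather than spuriously favoring "hetero" by the
bookkeeping constant. Ties are resolved at 1e−9 kcal/mol and reported
separately.

Single-species mass action: with per-size partition functions Q_m at 1 M
standard state, m-mer concentration is c0 Q_m x^m; the monomer activity x
solves Σ m c_m = c_total by monotone root finding in log space (Brent,
conservation enforced to 1e−9). The screens use the per-length input
concentration 4 (20/L)^2.5 mM so that different lengths are comparable, and
call clusters of ≥ 4 strands "higher-order".

## Palindromes and the aggregate binding strength

Palindromes are found by center expansion under strict WC complementarity
(G·U does not count toward palindrome identity, though wobble pairs still
appear in folded structures). No base is self-complementary, so palindromes
have even length; the default enumeration keeps maximal palindromes (not
contained in a longer palindromic interval), with a flag for all
sub-palindromes — the aggregate is insensitive to the choice because the
strongest palindrome dominates exponentially. Each palindrome s is scored by
the perfect-duplex free energy ΔG_s of two copies bound to each other
(stacks + initiation + terminal penalties + symmetry correction), and the
sequence-level strength is the log-sum-exp aggregate

    ΔG_pal = −kBT log Σ_s exp(−ΔG_s / kBT),

with weight 0 (ΔG_pal = +∞, serialized as `inf`) for palindrome-free
sequences. Complementary region *pairs* between two molecules are maximal
runs along anti-diagonals of the complementarity matrix; when both molecules
are the same sequence, mirror duplicates are reported once and the
self-pairs (region_i = region_j) are exactly the maximal palindromes.

## Nonequilibrium first-contact score

Hybridization between folded molecules is modelled as a single contact at a
complementary region pair, formed without unfolding: each region must be
accessible in its molecule's own equilibrium ensemble, and the bond of
strength ΔG_ij must outlive the characteristic time t* = exp(−ΔG*/kBT)/k,
with k = 10^7 s⁻¹ an attempt frequency. Exponentially distributed
dissociation waiting times give the double-exponential survival probability
exp(−exp((ΔG_ij − ΔG*)/kBT)) — 1/e exactly at threshold, monotone in ΔG_ij.
The pair score is

    ΔG_noneq / kBT = −log Σ_{i,j} p_i^free p_j^free exp(−exp((ΔG_ij − ΔG*)/kBT)),

summed over the same maximal-region grammar as above (one grammar for both
the equilibrium and nonequilibrium sums, so the palindromic weight
W_pal — the sum restricted to region_i = region_j — is a strict restriction
of the full self sum). Weights are the primitive quantity; free energies
are views, and differences involving +∞ sentinels are evaluated on weights:
an inert molecule (no self and no cross contacts) cancels out of
2ΔG12 − ΔG11 − ΔG22, leaving minus the partner's self term; identical
sequences give exactly 0. Default ΔG* is −12 kcal/mol with sweeps over
−12.5 … −8.5; the census counts palindromes with ΔG_s ≤ ΔG* and
pfree ≥ 0.1.

## Synthetic ensembles and what passing tests show

The generator draws iid-uniform sequences (25% per base) and, for the null
ensemble, rejection-samples until no palindrome of length ≥ 4 remains —
these are the stated study conditions, not tuning knobs. Desk-scale defaults
shrink the published ensemble sizes (10^4 → 500 pairs per seed, pooled over
three seeds; 5×10^4 → 300 sequences; 10^5 → 10^4 structure samples) while
preserving every qualitative readout; full-scale settings are plain config
values. Random ensembles emulate length and composition, not biology: no
codon structure, UTR organization, modification, or protein binding. Tests
passing on them show that the *method* behaves as claimed on its stated
input distribution — not that any particular transcript clusters in vivo.
Natural sequences enter only as optional FASTA input.

Key measured outcomes at desk scale (recomputed by `scripts/acceptance.py`):
random 30-mer pairs favor homodimers roughly 2:1; palindrome-free controls
drop below 1:1 on average, though the inversion is thin in this energy
model (mean ratio ≈ 0.92, occasionally above 1.0 for a single 1500-pair
draw); palindrome strength predicts higher-order clustering (rank
correlation ≈ 0.3–0.5 at n = 300) and the homodimer gap ΔG11 − 2ΔG1
correlates with ΔG_pal (Pearson r ≈ 0.6).

## Numerical choices

* per-base scaling ladder lnσ ∈ {0, 0.75, 1.5, 3, 6}, first value that
  keeps all matrices finite and positive;
* connected-fraction floor 1e−12 (below it a complex reports +∞);
* mass-action root found on ln x with xtol 1e−14, conservation asserted to
  1e−9;
* tie resolution for free-energy comparisons at 1e−9 kcal/mol;
* enumeration oracle capped at 16 nt total (explicit guard);
* complex DP capped at 600 nt total concatenation by default;
* Smith–Waterman local alignment (match +1, mismatch −2, linear gap −2) via
  Biopython's PairwiseAligner; near-duplicates flagged at score ≥ 0.8 × the
  shorter length (duplicates score near their length, unrelated pairs ≲ 20).

## Limitations

No pseudoknots, coaxial stacking, dangles, or terminal mismatches; no
temperature melting curves; heteromultimers beyond dimers unsupported;
pair-probability and sampling recursions are intended for monomer-scale
lengths (up to a few hundred nt), not full mRNAs; the nonequilibrium score
ranks initial contacts and is not a kinetic simulation of cluster growth.
Accessibility estimates inherit all the usual uncertainty of in-silico
structure prediction for long RNAs in vivo.
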