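# Methods

This note records the models, algorithms, default parameters and design
choices behind `rnaphylo`, and what the synthetic data generator does and
does not emulate.

## Secondary-structure engine

Structures are nested base-pair tables (dot-bracket equivalent) with an
involution/no-pseudoknot invariant, a minimum hairpin span `min_loop` = 3
unpaired positions, and the allowed-pair set {AU, UA, GC, CG, GU, UG}. The
default folding engine maximises the number of base pairs (Nussinov
dynamic program) rather than free energy: the downstream pipeline needs a
valid, deterministic, dependency-free nested structure, not a thermodynamic
ensemble. Traceback tie-breaks are fixed — pairing the left end is
preferred over leaving it unpaired, and the smallest admissible partner is
taken — so folding is reproducible byte-for-byte. `fold_thermodynamic`
exposes ViennaRNA's minimum-free-energy folder through the same return type
for users who want an energy model; nothing downstream depends on which
engine produced the structure.

Suboptimal enumeration returns every nested structure within
`within_delta_pairs` of the maximum, ordered by pair count then
lexicographic dot-bracket. The enumeration is exponential in sequence
length and intended for domain-sized inputs (tens of nt); candidate
contrasting against published template models uses F1 agreement between
pair sets (ties: more pairs, then enumeration order) because the historical
practice of "contrasting candidate low-energy foldings against prior
models" is not otherwise specified as an algorithm.

Domain annotation labels one domain per stem rooted in the exterior loop,
DI, DII, … in 5′→3′ order, each spanning the two sides of its basal pair;
inter-domain single strands are reported alongside. Internal coordinates
are 0-based half-open; all user-facing tables and error messages are
1-based inclusive.

CBC detection operates on positionally homologous helices supplied by the
caller (hand-curated conserved motifs from an alignment), not on
automatically matched helices. Categories per pair position: *unchanged*
(both partners identical), *CBC* (both substituted, new pair still in the
allowed set), *hemi-CBC* (exactly one substituted, pairing preserved),
*pairing-lost* (the derived duplex position cannot pair). Hemi-CBCs are
reported separately and never added to the CBC count. ITS2 delimitation
trims between user-supplied 5.8S-tail and 28S-head flank motifs; no default
motifs are hard-coded because delimitation conventions follow the
annotation of the sequences at hand. (The literature sometimes calls the
processing-site consensus the "8S" cleavage site; this is presumably the
5.8S and is left as the user finds it.)

## 12-state encoding and alignment

The encoding is the cross product of 4 bases with 3 structural states;
IUPAC ambiguity codes encode as a missing symbol `N` that scores zero
against everything and acts as fully missing in likelihoods; the gap is a
distinct 13th alignment symbol. The published eukaryote-ITS2
sequence-structure scoring matrix is not public, so the default scheme is a
transparent sum of a nucleotide component (+2 match / −1 mismatch) and a
structure component (+1 match / −1 mismatch), with affine gaps (first gap
residue −5, each further residue −1), all overridable from a TSV file.
Pairwise alignment is exact global Gotoh with deterministic traceback
(diagonal, then up, then left). Progressive alignment builds an NJ guide
tree from first-pass pairwise p-distances and merges profiles in guide-tree
order with mean-of-pairs column scoring; COI/28S-style plain nucleotide
data run through the same machinery with a 4×4 scheme. Hand-curated
structure-guided refinements (as practised for 16S) are out of scope:
externally curated alignments are accepted as input instead.

## Distances and the barcoding gap

K2P distances follow d = −½ln(1−2P−Q) − ¼ln(1−2Q) on the usable columns of
each pair. Complete deletion removes every column containing a gap *or
ambiguity code* in any row before any comparison (ambiguity codes count as
gaps for deletion — the behaviour of the standard distance tools); pairwise
deletion removes per pair. Pairs whose log arguments are non-positive are
flagged saturated, excluded from summaries and listed, rather than raising.
Distances are kept in substitutions/site with percent views (×100) in every
report, since barcoding thresholds are conventionally quoted in percent.
The gap is min-interspecific minus max-intraspecific after synonym-set
merging; species with fewer than two sequences simply contribute no
intraspecific values, and if no intraspecific pair exists at all the
maximum intraspecific distance is taken as 0.

## Substitution models and likelihood

Models are reversible GTR-family CTMCs with exchangeabilities S (one entry
fixed at 1), stationary frequencies π, discrete Γ(α) with k = 4
mean-category rates, and invariant fraction p_inv; Q is rescaled so the
expected substitution rate of the full +I+Γ mixture is 1 per unit branch
length. 4-state presets: JC, K80, HKY, TN, TVM, GTR (substitution free
parameters 0/1/4/5/7/8 including frequencies). The 12-state model is a free
GTR over the encoded alphabet (65 free exchangeabilities, 11 free
frequencies); columns are treated as independent — pairing correlation
enters the analysis only through the generator and the encoding, not the
likelihood. Stationary frequencies are fixed at their empirical counts (+F
convention) rather than co-optimised; exchangeabilities start at 1. α and
p_inv are co-estimated within bounds (α ∈ [0.02, 100], p_inv ∈ [0, 0.99],
branch lengths ∈ [1e-8, 20], exchangeabilities ∈ [1e-4, 1e4]) — the usual
caveat about +I+Γ identifiability at short alignments applies, and no
reparameterisation is attempted.

The pruning engine compresses site patterns, treats gaps and fully missing
symbols as all-ones partial vectors and ambiguity codes as indicator
vectors, and adds the invariant-site term only for patterns compatible with
a constant site. Branch lengths are optimised by exact 1-D coordinate
ascent: a post-order pass caches below-edge conditionals, a pre-order pass
re-optimises each edge by bounded Brent against above-edge partials updated
on the way down, so lnL is monotone across a sweep; convergence is declared
at improvement < 1e-6 or 50 sweeps. No per-node likelihood rescaling is
performed — partials stay comfortably inside double range for the tens of
taxa this package targets; hundreds of taxa would need rescaling.

## Tree search, support and model selection

The centre tree is NJ (canonical, deterministic label-order tie-breaks,
negative estimates clamped to 0) with optimised branch lengths and,
optionally, model. Each search start is a random walk of `walk_length`
(default 5 — the historical "equidistant random walks" leave the length
unstated) random NNIs from the centre, followed by best-improvement NNI
hill climbing. NNI candidates are screened cheaply by re-optimising only
the central branch from cached partials; candidates are then verified in
rank order with full branch re-optimisation, because the screen keeps all
other branches at values tuned for the current topology and can badly
under-rate a neighbour masked by a compensatorily stretched branch (a
failure mode we observed and test against). Typical rounds therefore pay
for one full re-optimisation; the final, stagnant round verifies all
candidates. Search is fully seed-deterministic (`default_rng([seed,
start])` per start).

Bootstrap resamples sites with replacement and re-runs the search per
replicate at reduced settings (defaults n_starts = 2, walk_length = 2 — a
deliberate desk-scale reduction of the full search); supports are the
percentage of replicates containing each bipartition, mapped onto the best
tree; majority-rule consensus keeps exactly the bipartitions with frequency
strictly above the threshold. AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with k =
substitution free parameters + (2n−3) branch lengths; candidates whose k
leaves no residual degrees of freedom are skipped with a warning. Rankings
compare preset × {+G, +I, +I+G} on a fixed topology. Partitioned datasets
share topology and branch lengths with per-partition rate multipliers
(positive, geometric mean 1, so a pair like (2, ½) is a pure rate-time
reallocation); multipliers are user-supplied, not estimated.

## Synthetic data: what it emulates, and what it does not

`simulate_yule_tree` is a pure-birth process (exponential waiting times at
rate k·λ). `simulate_columns` evolves independent columns of any state
count under the exact CTMC — this is how 12-state data distributed
precisely as the inference model assumes are produced for recovery
experiments. `simulate_alignment` adds base-pair co-evolution at
nucleotide level: paired columns evolve by event-level (Gillespie)
simulation in which each substitution is instantaneously compensated on the
partner (Watson-Crick complement) with probability c; this minimal
mechanism plants CBCs and exercises the 12-state encoding without a
16-state doublet model, but it is *not* a thermodynamically motivated
doublet process, and the inference model never sees the pairing
correlation.

`make_its2_family` builds a ~116 nt four-domain layout (stems of 7–10 bp,
single-strand spacers, the CAGAC motif planted single-stranded between DII
and DIII, conserved basal triplets) on a Yule tree, then plants a full CBC
in the DI basal triplet of one root clade (CGG/CCG → CGA/UCG). The layout
is a deliberately compact stand-in — real ITS2 runs 400–550 nt with far
more heterogeneous domain sizes, intra-individual variants and indel-rich
spacers, none of which are modelled; optional spacer-length jitter provides
length variation for the alignment stage, but true indel evolution is not
simulated. Passing tests therefore demonstrate correctness of the
machinery under the assumed models, not robustness to real-data alignment
ambiguity or model misspecification beyond the co-evolution mechanism.

`make_species_complex` hangs star-shaped within-species samples (radius =
intra_scale) off a Yule species tree rescaled so the minimum species-pair
path is 2·(inter_scale − intra_scale); tip-to-tip expectations are then
≈ 2·intra_scale within species and ≥ 2·inter_scale between, and setting the
two scales equal collapses the species tree so the intra/inter ranges
overlap — the two regimes used to exercise barcoding-gap detection, with
defaults (intra 0.005, inter 0.10, 620 sites, 5 species × 3 samples)
mirroring a clean COI-like barcoding setting.

## Recovery experiments: problem sizes and conventions

The 16-taxon/2000-site/12-state recovery sweep clamps all generating
branch lengths to ≥ 0.05 substitutions/site after scaling tree height to 1:
unconstrained Yule trees routinely contain internal branches of 0.003–0.02
at which 2000 sites genuinely cannot resolve the split (the search then
returns a different topology with equal or better likelihood — an
estimation tie, not a search failure). This mirrors the convention used for
the small worked recovery example (internal branches ≥ 0.2 at 6 taxa). In
that sweep the search runs as a plain hill-climb from the NJ centre
(n_starts = 1, walk_length = 0, the documented degenerate form) and α is
profiled together with branch lengths while exchangeabilities stay at
their starting values: α recovery is insensitive to that choice, whereas a
full 65-parameter coordinate sweep per seed would dominate runtime; the
full exchangeability optimisation is exercised on smaller fixtures. Yule
trees, not fixed balanced trees, are used so tree shape varies across
seeds.

## Known limitations

- No thermodynamic folding, pseudoknots, or ITS2-template databases in the
  default engine.
- No Bayesian inference, relaxed clocks, or multi-species coalescent; no
  SPR/TBR rearrangements.
- No indel simulation; alignment stages are exercised on length-jittered
  records instead.
- The 12-state likelihood assumes column independence; paired-site
  correlation is a generator-side property only.
- No likelihood rescaling: intended for tens, not hundreds, of taxa.
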