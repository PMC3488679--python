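# Methods

This note documents the models, parameter defaults, numerical choices and
limitations behind `guildnet`. It describes what the code computes; every
empirical number quoted in the README is produced by the code itself
(`guildnet run`, the test suite, or `scripts/acceptance.py`).

## The two markers

**Fungal ITS.** The ITS region is delimited by exact/IUPAC-aware anchor
search: the *last* occurrence of the 18S (rns) terminus `AAGGATCATTA` and the
*first* subsequent occurrence of the rnl terminus `RTTGACCTCGGATCAGGTAGG`
(R = A/G). Last/first search direction guards against chance internal hits
of the short 5′ anchor. Coordinates are 0-based half-open throughout. A
missing anchor degrades to the corresponding sequence end and is flagged;
both anchors missing is an error. Accepted ITS lengths outside a
plausibility window (default 400–600 bp; the empirically observed range in
*Nephroma* is 485–515 bp) are flagged, not rejected.

Genotype collapsing is **exact string identity**. Ambiguity codes collapse
only with identical strings — tolerant matching would require a similarity
policy with no principled cutoff at this divergence scale. Collapsing is
species-scoped by default (codes NP1, NB2, … from species initials), with a
global mode for cross-species dereplication; a genotype whose members carry
several species labels is flagged rather than rejected.

**tRNA-Leu (UAA) intron.** Annotation is anchored on a `ReferenceProfile`
(YAML): conserved flank motifs for the P5b and P6b stem loops, Class 1 and
Class 2 heptanucleotide repeat consensus patterns, the per-unit match
threshold, the indel-element catalogue, and the offset mapping the P5b
anchor to reference coordinate 71. **The bundled default profile is
synthetic**: the published reference alignment behind the real coordinate
system is not redistributed, so the default anchors/consensus are an
internally consistent stand-in used by both the annotator and the synthetic
generator. Annotating real sequences requires editing one YAML file; the
algorithms are agnostic to the concrete motifs.

### Hairpin folding

The P6b fold is combinatorial, not thermodynamic: Nussinov-style
maximum-base-pair dynamic programming over nested structures with
Watson–Crick and G·T wobble pairs and minimum hairpin loop 3, with traceback
preferring the outermost pair (longest contiguous stem on ties). The DP fill
is numba-compiled with a pure-numpy fallback. Folding is used to delineate
the central loop and to check that the repeats form a hairpin — not to
estimate stability, which is why a maximisation objective is adequate.

**Central-loop delineation.** Base-pair maximisation happily closes a lone
pair across a short loop (e.g. the A·T in a loop `AGTCTTA`), which
thermodynamic folding rejects as an unstable lone pair closing a tri-loop.
The central loop is therefore defined as the interior of the innermost pair
of the *chained main stem*: the chain starts at the outermost helix and
extends inward only onto helices of ≥ 2 stacked pairs, tolerating bulges of
up to 3 nt per side. Lone pairs inside the terminal interior do not redefine
the loop; single mismatch bulges in the stem (point mutations in one arm) do
not break it.

### Repeat decomposition

Each P6b stem arm is tiled greedily left-to-right into 7-mers scored against
the Class 1 and Class 2 consensus (each pattern also tried
reverse-complemented, since the 3′ arm carries the repeats in the opposite
orientation; Class 1 wins ties). A window with ≥ `repeat_match_threshold`
matching positions (default 5/7) is a repeat unit. Where no window passes,
the tiler scans forward for a resumption point; a candidate resumption
window must be followed by another passing unit (one-unit look-ahead),
otherwise windows straddling an indel/repeat junction can misalign the
tiling. The skipped stretch becomes an indel element, tagged from the
profile catalogue (`*`, `**`, `***`, `^^`; either strand) or positionally
(`@<pos>`) when unknown. Tiling is conservative:
|P6b| = 7·(#units) + Σ|indels| + |central loop| (tested property).

### Signatures and lineage call

* `sig_3T` — base 3 (1-based) of the central loop is T. Loop-relative
  numbering is a deliberate convention; the published shorthand does not
  define it, and loop-relative is the only executable reading that survives
  loop-length variation.
* `sig_71T` — T at P5b-anchor start + `position71_offset` (default 14). The
  anchored ungapped offset isolates the uncertain reference-numbering
  convention in one profile field.
* `sig_AGTCTTM` — the central loop IUPAC-matches `AGTCTTM` (M = A/C),
  requiring loop length exactly 7.

Lineage: `BIPARTITE_TYPE` iff Class 1 ∧ 3T ∧ 71T; `TRIPARTITE_TYPE` iff
AGTCTTM ∧ ¬71T; otherwise `AMBIGUOUS`. The rules are mutually exclusive by
construction (one requires 71T, the other its negation).

## Genotyping and subgroups

Genotypes are exact-identity classes over the full intron. Sequences with
> 2 % ambiguous bases are excluded (exact identity is meaningless for
low-quality reads). "Major P6b difference" — the subgroup criterion — is
operationalised as: different catalogue indel-element content, or total
repeat counts separated by ≥ `major_repeat_delta` (default 4) under
single-linkage grouping. Single-linkage makes the strata order-invariant;
the default of 4 units keeps ±1-unit slippage variants together while
separating genuinely different repeat-count classes. Subgroup labels:
letters by decreasing specimen count (ties: lexicographically smallest
representative) for the bipartite lineage; `Y0…` / `X1…` for tripartite
Class 1 / Class 2; `U1…` for ambiguous material. Within a subgroup,
genotype codes number by decreasing member count then first appearance; a
labelmap can pin published codes to known sequences.

## Median-joining network

Input is an alignment of distinct haplotypes over {A, C, G, T, −} with
positive site weights (default 1); the gap is a fifth state. Unaligned
input is aligned by a progressive multiple aligner (biotite's
`align_multiple`) with match +1 / mismatch −1 and affine gaps (open 8,
extend 2); pre-aligned input passes through untouched, keeping externally
built alignments auditable.

The ε-relaxed minimum spanning network contains edge (u, v) iff
d(u, v) ≤ minimax(u, v) + ε, where minimax is the largest edge on the MST
path; ε = 0 (the default, and the reference program's default) gives exactly
the union of all minimum spanning trees. Quasi-median candidates are
generated from triplets — all triplets while the vector set is small (≤ 12),
otherwise the canonical scheme of triplets sharing MSN edges, which keeps
the candidate pool tractable on realistic inputs. The per-site quasi-median
is the majority state; sites where all three states differ branch over the
three observed states (never an unobserved one), capped at 4 such sites per
triplet. Candidates are inserted while they reduce the Steiner connection
cost (MST weight over the vector set), best first, ties lexicographic; when
no single candidate helps, a depth-2 lookahead tries candidate pairs (some
medians only pay off jointly). After convergence, obsolete vectors — medians
whose removal does not increase the connection cost — are deleted. All tie
rules are deterministic, so re-runs are byte-identical. Full
maximum-parsimony post-pruning of the reference program is deliberately
reduced to obsolete-vector deletion (documented divergence; scope control).

On every random instance with ≤ 6 haplotypes tested (seeds 0–199), the
greedy-plus-lookahead construction reaches the exact minimum Steiner cost
computed by Dreyfus–Wagner search over the observed-state candidate lattice
(test-suite oracle); this is a property of small instances, not a general
guarantee — median joining remains a heuristic.

## Selectivity and the geographic mosaic

The association table cross-tabulates paired specimens by (species, region,
genotype). Guild structure is the bipartite species×genotype graph and its
species projection (edge weight = number of shared genotypes), with
per-species predicates `shares_with_other` and `single_genotype`.

"Higher selectivity locally than globally" is made quantitative as the
**mosaic ratio** m(s) = mean over supported regions of k(s, r)/k(s). Region
cells with fewer than `thin_support` (default 2) specimens are excluded from
m(s) — single-specimen cells make richness ratios degenerate. The
permutation null shuffles region labels within species (1000 permutations by
default), preserving per-species specimen counts and per-region totals; the
one-sided p-value is add-one smoothed. Per-species p-values are reported raw
and Benjamini–Hochberg-adjusted at the conventional 0.05 — the correction is
this package's choice, as is the m(s) construction itself (the qualitative
pattern it quantifies is stated in the field without a test statistic).
Region granularity follows the metadata labels; choosing the granularity is
the analyst's responsibility (continent-level vs country-level labels answer
different questions).

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline is validated under.

**Intron templates.** An intron is core5 (56 nt, placing the P5b signature
at intron coordinate 71) + P5b (anchor, 6-bp arm, 4-nt terminal loop
carrying the 71 site, arm, anchor) + spacer + P6b (anchor, repeat arm,
7-nt central loop, reverse-complement arm, anchor) + core3. Each subgroup
template fixes its indel elements (inserted mid-arm, mirrored as the
reverse complement on the 3′ arm so the hairpin still folds) and base repeat
count; the default 16 subgroups (7 bipartite A–G analogues, 5 tripartite
Class 1, 4 Class 2) hold 40 genotypes in total. Generated lengths fall in
283–353 bp, inside the configured 270–365 bound, with all length variation
in P6b. Bipartite templates carry loop `CCTCCCC` (3T; internally unpairable,
so the fold-derived loop is exact) and a T at the 71 site; tripartite
templates carry `AGTCTTM` and no 71T.

**Genotype branching.** Genotypes derive sequentially (g₀ → g₁ → …): whole
7-mer-unit slippage with probability `branch_slippage_rate` (0.4) and
Poisson(`branch_substitutions` = 2.0) substitutions per step in the mutable
zones (cores, spacer, repeat arms — arms capped at 2 deviations per unit so
units stay above the match threshold). Diagnostic sites (anchors, loops, the
71 site) are conserved within lineages — that conservation is precisely what
makes them signatures. A sequential chain is not a coalescent; it is enough
to create the nested haplotype structure the network construction needs, and
is documented as a non-biological simplification.

**Member noise.** Emitted per-specimen copies receive per-site substitution
noise at `member_mutation_rate` (default 1e-4, the scale of curated Sanger
data; 0 turns it off). Branching rates at zero collapse each subgroup to
identical sequences — the degenerate zero-variation limit, warned about
explicitly.

**ITS.** Per-species backbones diverge from a common ancestor at 8 %
substitutions with length adjusted uniformly into 485–515 bp; within-species
genotypes at 0.4 %. Amplicons are padding + `AAGGATCATTA` + ITS + an
R-variant of the rnl anchor + padding. Rejection sampling guarantees the
anchors are unique in every emitted amplicon (they are, in real rDNA, which
is why they work as anchors).

**Sampling.** Each species draws a photobiont pool (8 of the 28 bipartite
genotypes; tripartite hosts draw from the 12 tripartite genotypes) with
global Dirichlet(1) weights; each region then draws frequencies from
Dirichlet(`founder_concentration` · pool size · global weights).
Low concentration (default 0.3) makes one or few genotypes regionally
dominant — the founder-effect mosaic; concentration ≳ 200 approaches the
exchangeable (null-true) regime. Default sampling: 5 paired + 1 fungal-only
+ 2 photobiont-only specimens per species×region cell over 10 species
(9 bipartite + 1 tripartite analogue) × 4 regions, one planted
trans-regional (fungal genotype, photobiont genotype) pair, and one extra
single-symbiont specimen per otherwise-unsampled genotype (mirroring how
archive singletons supplement paired surveys). One RNG stream per run;
identical (config, seed) gives byte-identical files.

**What passing tests do and do not show.** The generator plants exactly the
structure the annotator expects (shared reference profile, perfect hairpins,
conserved signatures). Recovery tests therefore validate the algorithms and
their edge cases — not robustness to real-world deviations such as
homoplasy, recombination, chimeric reads, profile mismatch, or indels
outside P6b. The member-noise model is substitution-only by default.

## Problem sizes and determinism

Default validation runs use ~40 planted intron genotypes across 335
specimens, 1000-permutation mosaic tests, 200 random network instances
against the exact Steiner oracle, and 500 random fold regions against
exhaustive enumeration; the full suite and the acceptance script each run in
well under a minute of CPU after JIT warm-up. All stochastic components take
explicit seeds; every tie rule in the network construction and naming is
deterministic.

## Known limitations

* The default reference profile is synthetic; results on real introns depend
  on transcribing a real profile into the YAML.
* Exact-identity genotyping splits genotypes on any surviving sequencing
  error (quantified in tests: adjusted Rand ≥ 0.95 at the default noise).
* Median joining is heuristic beyond small instances; ε > 0 and triplet
  restriction trade completeness for tractability.
* The mosaic ratio treats regions as exchangeable sampling units and ignores
  unequal regional effort beyond the thin-support filter.
* No phylogenetic inference: species identities come from metadata, and the
  network is not a tree substitute.
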