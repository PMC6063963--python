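# Methods

This note documents the models, conventions and numerical choices behind
`pairscreen`, and what the synthetic-data tests do and do not demonstrate
about real screens.

## Error-correcting DNA barcodes

Barcodes are words over {A,C,G,T} read as digits mod 4 (A=0, C=1, G=2,
T=3). The default 15-nt layout is a shortened quaternary SECDED code: ten
data bases, four checksum bases at the power-of-two positions 1, 2, 4 and
8, and one overall parity base at position 15. A check at position *c*
covers the data positions whose 1-based index shares a bit with *c*; the
parity base covers positions 1–14. Check and parity digits are the mod-4
*negation* of their covered sum, so a word is a codeword exactly when
every covered sum is ≡ 0 (mod 4). This convention — rather than the
non-negated sum — is the shipped default because it is the variant whose
filtered pool size matches the published figure for this barcode family
(812,547 of 1,048,576 candidates after excluding homopolymers >3 nt and
GC outside 30–70% inclusive; the non-negated twin gives 812,888).

The code has minimum Hamming distance 3, so any single substitution is
correctable. Decoding is by syndrome lookup: the syndrome of an error of
magnitude *e* at position *p* is `e·H[:,p]`, and all 45 single-error
syndromes are distinct for the default layout (verified at spec
construction; for degraded toy layouts, ambiguous syndromes decode to
*fail*, never to a guess). Syndrome lookup is provably equivalent to
nearest-codeword search within radius 1 — the test suite checks this
exhaustively against a brute-force oracle on small codebooks — but runs in
constant time per read.

Arithmetic is over integers mod 4, not GF(4). For a coefficient-1 parity
check matrix the two coincide in the only property used here: distinct
single-error patterns have distinct syndromes.

Subsampling to a minimum pairwise Levenshtein distance (indel robustness)
uses a seeded shuffle followed by greedy accept-if-far, with edlib's
banded distance and an early-exit bound. If the requested count is
unreachable the partial set is returned with an explicit incomplete flag.

## Library design conventions

* **Positions are PAM-proximal**: position 1 is the base adjacent to the
  PAM (the 3′-most target base as written 5′→3′). All variant
  descriptors, penalty matrices and reports use this convention.
* **Spacer groups**: a group draws one random 24-mer; its 18 3′ (PAM
  proximal) bases are the shared core, and the length-*L* spacer is the
  3′-most *L* bases with the 5′ base forced to G (so the 19-mer is
  G + core18, and longer spacers nest at the 5′ end). When a reference
  FASTA is supplied, any group whose core18+PAM occurs in it (either
  strand) is redrawn, with bounded retries.
* **Mismatches live in the target DNA**, never in the spacer, so sgRNA
  secondary structure is identical across a group. Double transversions
  place one of the two purine↔pyrimidine swaps at each of the two
  positions (4 variants per position pair). An extra target base is a
  DNA bulge; a deleted target base is an RNA bulge. Indel variants that
  collapse to identical sequences (within homopolymer runs) are
  deduplicated with recorded multiplicity.
* **Scrambled controls** are seeded permutations of the matched target
  constrained to differ from it at ≥50% of positions.
* **Cassette** (sequenced strand, 5′→3′): constant prefix, spacer,
  scaffold constant, 8-nt rBC, second scaffold constant, target, PAM
  (CAGGGT), 7-nt constant, 15-nt Hamming barcode, suffix. With a blunt
  cut 3 bp 5′ of the PAM, the barcode begins 16 bp downstream of the cut,
  far enough that typical repair products leave it intact. The constant
  segments are configurable; the defaults are plausible stand-ins, not a
  particular vendor construct.

## Synthetic screens (the simulator)

The generator emulates the data-generating process the quantification
pipeline is designed for, with every draw derived from a single seed:

* **Ground truth**: guide activities `g ~ Beta(2,2)` (spanning weak to
  strong guides); per-length penalty matrices with `ΔΔG ~ Exp(mean 1)`
  and `f = exp(−ΔΔG)` — i.e. exactly the prior the inference model
  assumes; bulge factors of 0.05 at PAM-proximal positions 1–18 and 0.9
  PAM-distally (bulges are tolerated essentially only at the distal end);
  scrambled targets never edit.
* **Synthesis errors** hit the synthesized variable region (spacer,
  target, Hamming barcode): per-base substitutions (default 2%, which
  leaves roughly a quarter of cassettes error-free — the regime of
  array-synthesized pools) and a per-oligo single indel (default 10%).
  The rBC comes from a separately synthesized oligo and is error-free.
* **Integrations**: Poisson per member (default mean 30 ≈ a 300×-coverage
  screen after the ≥20-rBC filter), each tagged with a unique random 8-nt
  rBC. Uniqueness is enforced globally by default so that the ground-truth
  bookkeeping is unambiguous; with ~10⁴–10⁵ integrations, chance 8-mer
  collisions across members are rare and the pipeline's conflict rule
  exists to reject them (`unique_rbc="member"` re-enables them for
  studying that rule).
* **Editing** is a cassette-level event: each integration is edited with
  probability `g·Πf·saturation(day)`, and all its reads share the repair
  outcome. Day 0 never edits. Repair outcomes are deletions spanning the
  cut (geometric sizes, capped at 10) or 1–2-nt insertions at the cut.
  The quantifier must not depend on this spectrum — only on indels
  overlapping the cut window.
* **Reads**: 2×150 pairs; read 1 covers the cassette start through the
  rBC, read 2 (reverse strand) covers barcode, PAM and target.
  Per-base sequencing substitutions at 0.1% by default. Gzip output is
  written with zeroed metadata so identical configurations are
  byte-identical.

What the simulator does **not** model: PCR duplicates and jackpots,
chromatin effects, lentiviral recombination, re-cutting dynamics, or
quality-score structure. Passing tests therefore demonstrate correctness
of the bookkeeping and estimators under the stated error processes, not
robustness to every artifact of a real sequencing run.

## Quantification

* **Parsing** locates constant anchors allowing one substitution each.
  Read 2 is anchored on the scaffold (left) and cassette suffix (right);
  the Hamming barcode occupies a fixed offset left of the suffix, and the
  compared "target region" is everything between the anchors (target +
  PAM + 7-nt constant). Right-anchoring keeps deletions that chew into
  the PAM inside the compared window. Unparseable reads are counted,
  never silently dropped.
* **Whitelist**: a (member, rBC) cassette is admitted iff every
  supporting Day-0 read has intact anchors, an *exactly* matching Hamming
  barcode (a corrected barcode implies the cassette itself carries an
  error), spacer and target regions identical to the design, and ≥2
  supporting reads (the read floor is configurable; the published
  pipelines state only "sufficiently represented"). An rBC seen under two
  members is rejected outright. Day-N membership is Day-0-only.
* **Indel calling**: exact match → intact. Same length and explainable by
  substitutions alone → discard (substitutions cannot be nuclease
  products; ties between substitution-only and indel interpretations
  resolve to discard). Otherwise a global alignment (edlib) is scanned
  for insertions/deletions overlapping the cut ± 8 bp window; indels
  entirely outside the window are discarded, not called.
  `indel_rate = n_indel / (n_reads − n_discarded)`.
* **Off:on ratios** divide a member's rate by the matched member of the
  same group and spacer length, computed only where the matched rate
  exceeds 2%. Members below the ≥20-rBC floor are flagged excluded;
  members never observed are reported as dropouts.
* **Aggregations** (mean ratio ± 1.96·SEM) stratify by position, spacer
  length, RNA:DNA mismatch class, category, or position pair; replicate
  concordance reports Pearson R² and retained fraction as the rBC floor
  rises.

## Specificity model

Likelihood `I ~ Normal(g·exp(−ΣΔΔG), σ)` with σ = 0.1 (a
replicate-derived noise scale), prior `ΔΔG ~ Exp(mean β = 1)`, `g ∈ [0,1]`
with a uniform prior. Raw indel rates (not off:on ratios) are the
response, with `g_j` absorbing on-target activity; each spacer length is
fitted on disjoint data, giving a separate `f_L`. Bulged and scrambled
members are outside the model. The Gaussian likelihood is *not* truncated
to [0,1]; this is a known approximation, mildly biasing cells whose
predicted rates sit near 0.

Two modes:

* **map** — L-BFGS-B on the negative log posterior with analytic
  gradients, bounds `g ∈ [10⁻⁶, 1]`, `ΔΔG ∈ [0, 50]`. Deterministic;
  used wherever reproducibility matters. Cells with no covering
  observation sit at the prior mode (ΔΔG = 0) and are flagged
  prior-dominated.
* **mcmc** — a self-contained Hamiltonian Monte Carlo sampler (leapfrog
  integration with jittered step counts, dual-averaging step-size
  adaptation to 0.8 acceptance, diagonal mass estimated from the second
  warmup half) over the unconstrained parameterisation `g = sigmoid(v)`,
  `ΔΔG = exp(u)` with the appropriate Jacobians. Chains are independent
  with seeds spawned from the master seed and overdispersed uniform(−2,2)
  inits; R-hat (arviz, rank-normalised) over all parameters defines
  convergence at the 1.1 threshold. Defaults mirror a production fit
  (8 chains × 1500 samples, 500 warmup); the test suite uses reduced
  chains sized to finish in seconds, at the cost of R-hat values that can
  sit above threshold on short runs — the flag reports this honestly.
  Posterior summaries are means with 2.5/97.5% intervals; uncovered cells
  reproduce the exponential prior (posterior mean ΔΔG ≈ β), which the
  suite checks.

Guides with near-zero activity are weakly identified — attenuation of
nothing is unmeasurable — and their penalty posteriors are wide; the
suite asserts this known failure regime rather than hiding it.

Scoring a candidate site is `Π f` over its featurized mismatches (1 for a
perfect match, monotone non-increasing in the mismatch set). Ranking
breaks ties by mismatch count then lexicographic site for determinism;
bulged candidates get no score, with a reason. A Spearman rank
correlation against user-supplied measured activities (e.g. GUIDE-seq
read fractions) is emitted when available.

## Problem sizes in the test suite

The suite's simulations are sized for quick, repeatable runs: libraries
of one group (393 members, trimmed to 120–200 where speed matters),
20–30 integrations per member, 2–5 reads per rBC, 20 replicate
simulations for the rate-recovery property, and penalty-model recovery
with 20 guides × (all singles + 200 doubles). These are deliberate
scaled-down analogues of a full screen; the estimators themselves are
size-agnostic.
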