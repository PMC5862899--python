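# Methods

This note documents the models and procedures implemented in `winelattice`,
the parameter defaults and why they were chosen, what the synthetic corpus
generator does and does not emulate, and the numerical conventions.

## Text standardisation

Free-text tasting blurbs (typically 10–40 words) are reduced to a *set* of
canonical aroma descriptors per wine. The procedure is a deterministic,
auditable approximation of the manual clean-up a sensory researcher would
perform:

1. **Tokenisation** — lower-casing, punctuation stripping, hyphenated
   compounds kept whole (`sweet-ripe` is one token).
2. **Greedy longest-match segmentation** — at each position the longest
   phrase key wins among synonym phrases ("granny smith apple"), whitelisted
   bigram descriptors ("ripe fruit", "citrus fruit"), non-sensory phrases
   ("perfect for summer lunches") and stop words. Longest-first matching is
   what makes "crisp apple" collapse to *apple* while a lone "crisp" remains
   the descriptor *crisp*.
3. **Drop-by-default** — tokens matching nothing are discarded and logged.
   Hedonic, occasion and technical words that the curated non-sensory list
   misses are therefore still excluded; the cost is that a genuinely novel
   sensory word is silently dropped until added to the lexicon. The
   standardisation log exists precisely so those drops can be audited.
4. **Connotation rules**, applied in lexicon order, operating on the
   original token sequence:
   - `NEGATION_DROP` — a descriptor mention is void if a cue word occurs
     within ±3 tokens ("lacking acidity"; comparative cues such as
     "more/less/compared/previous" use the same mechanism). The window of 3
     is configurable; it spans the short noun phrases these blurbs use
     without reaching across clause boundaries.
   - `STANDALONE_ONLY` — *fresh* and *rich* count only when not immediately
     modifying another sensory word ("fresh apple" yields *apple* alone).
   - `ALWAYS_KEEP` — *oak* and *balance* count whenever mentioned (nose or
     palate).
   A descriptor survives if at least one of its mentions survives.

Within-description duplicates collapse by set semantics. Citation counting
downstream is therefore per-wine binary: an attribute mentioned twice in one
blurb counts once. (Whether published citation tallies were taken before or
after deduplication is not documented anywhere we know of; binary counting
is the convention here and is used consistently for the filter, the
contingency tables and the co-occurrence matrix.)

The packaged default lexicon covers the standardisation examples and the
high-frequency descriptors of South African Chenin blanc and Sauvignon
blanc. *Passion fruit* maps to *passionfruit* but *granadilla* is kept as
its own descriptor, since published citation tables list the two separately
even though they denote the same fruit.

## Formal concept analysis

A context (G, M, I) has derivation operators A′ (attributes common to all
objects of A) and B′ (objects carrying all attributes of B); concepts are
the closure pairs (A, B) = (B′, A′), ordered by extent inclusion into a
complete lattice.

- **Enumeration** is NextClosure: closures visited in lectic order of
  intents, deterministic for a fixed attribute order. Incidence rows are
  held as integer bitsets; closure of a candidate attribute set is one pass
  over objects. A brute-force powerset-closure oracle (≤ 20 attributes) is
  retained in the package and the test suite asserts set-equality of the
  two enumerations on fixtures and random contexts.
- **Hasse diagram** — transitive reduction of extent inclusion. An
  integrity check verifies pairwise meet-closure (extent intersections must
  be extents) before building. Reduced labelling: an attribute labels its
  maximal concept, an object its minimal one.
- **Queries** — implications `premise → premise″ \ premise`; generality
  `|{m}′|`; and the association sliding scale
  `b(m) = r₂/(r₁+r₂)` with `r_g = |{m}′ ∩ group_g| / |group_g|`.
  Within-group *relative* frequencies are used so that unequal group sizes
  (thousands of wines of one varietal vs hundreds of the other) do not bias
  the scale. The group order is an explicit argument; swapping it maps
  b → 1 − b.
- **Layout** — layer = longest-path depth from the top concept; horizontal
  positions by 8 fixed barycenter sweeps (ties broken by lexicographic
  intent, so the layout is deterministic); per-attribute centreline offset
  2·b(m) − 1 ∈ [−1, 1]. This is a documented approximation of generic
  layered graph drawing, not a reproduction of any specific tool's output.

Varietal aggregate nodes arise by giving each wine its varietal name as an
extra attribute (`with_varietal_nodes`), the standard FCA idiom: the
varietal's attribute concept is then the node from which its wines hang.

The packaged animals context (8 life forms × 9 biological attributes) is a
reconstruction: the classic worked example's incidence table does not
survive text extraction unambiguously, so the incidence was chosen as the
one consistent with all five printed readouts (unambiguous frog
identification from {has limbs, lives in water}; the leach ⊂ bream ⊂ frog
intent chain; 2-leaf germination ⟹ chlorophyll ∧ land; the Reed/Frog and
Leach/Spike-weed common-attribute sets) plus the 50/50 water/land split.

## Statistical validation chain

- **Co-occurrence similarity**: S(a,b) = 100·|D_a ∩ D_b|/|D_a ∪ D_b| with
  D_x the set of wines citing x — a Jaccard index expressed as the
  percentage of reviews mentioning both words among reviews mentioning
  either. Diagonal 100, symmetric, zero iff never co-mentioned.
- **MDS**: distances d = 100 − S (the simplest monotone complement; the
  similarity, not the distance, is the primitive quantity, so this is a
  documented convention). Default embedding is classical (Torgerson):
  double-centre −½d², eigendecompose, scale the top eigenvectors — fully
  deterministic, exact for Euclidean configurations. Optional SMACOF
  refinement (fixed seed) for lower stress; Kruskal stress-1 is reported
  either way. Requesting more dimensions than the configuration's rank is
  an error rather than padding with noise axes.
- **Correspondence analysis** of the attribute × style citation table:
  P = N/n, standardised residuals D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD,
  principal coordinates F = D_r^{−1/2}UΣ and G = D_c^{−1/2}VΣ. Per-axis
  inertia σ_k²; the total equals χ²/n exactly (asserted against an
  independent chi-square computation to 1e-10 relative error). Zero rows or
  columns raise an error naming the offending label.
- **CART**: greedy binary splits on attribute presence/absence maximising
  Gini impurity decrease; defaults max_depth = 5, min_leaf = 20, no
  cost-complexity pruning. Exact ties in impurity decrease go to the lowest
  attribute index, making the fit deterministic. The CART machinery is
  implemented here (rather than delegated) because the deterministic
  tie-break and the permutation-invariance guarantee are part of the
  contract; scikit-learn's tree is used in the tests as an independent
  cross-check of the root split, never as the implementation. The leaf
  report (`cart_report`) gives, for a named attribute family, the style
  breakdown among wines citing any member — the bar-graph statistic that
  accompanies a fitted tree.

No hypothesis tests or multiple-testing corrections are attached to these
outputs: they are exploratory/descriptive statistics by design.

## Synthetic corpus generator

The generator emulates the statistical structure the analyses assume, with
these study conditions as defaults:

- **Cell sizes**: the real per-varietal/style census totals scaled by 1/10
  for fast runs — Chenin blanc 149/85/41 (unwooded dry / wooded dry /
  semi-dry) and Sauvignon blanc 408/27 (unwooded / wooded), 710 wines per
  corpus. The scale preserves the strong class imbalance (Sauvignon ≫
  Chenin; semi-dry rare) that the statistics must cope with.
- **Vocabulary** of 26 descriptors in five exclusivity classes: shared,
  Chenin-specific, Sauvignon-specific, wood-maturation markers (*oak* 0.80
  in wooded styles vs 0.10 elsewhere, *vanilla* 0.60/0.08, *nuts* 0.40/0.05,
  *spice* 0.35/0.10) and residual-sugar markers planted exclusively in the
  Chenin semi-dry class (*sweet* 0.70, *semi-dry* 0.60). Base rates
  (0.10–0.45) sit in the range implied by published citation counts
  relative to corpus sizes.
- **Pole coupling**: Sauvignon wines draw a latent pole (herbaceous vs
  fruity, 50/50); pool descriptors' probabilities are scaled by (1 ± c).
  The mechanism's neutral value is c = 0 (fully independent draws), but the
  packaged default corpus sets c = 0.9 so that the herbaceous/fruity
  co-occurrence axis the MDS analysis looks for actually exists.
- **Rendering noise**: each planted descriptor surfaces as a random
  lexicon-known synonym variant (p = 0.5) interleaved with non-sensory
  filler phrases (0.35/slot) and stop words (0.30/slot). Because all noise
  is lexicon-known, standardisation must recover the planted sets exactly;
  this 100% round trip is asserted in the tests.

Ground truth carries the planted sets, the probability table and latent
poles, and computes analytic style posteriors
P(s | group cited) ∝ n_s · P(any group member cited | s) by Bayes' rule
(marginalising the pole where relevant); CART leaf reports are checked
against these within three binomial standard errors.

**What the generator does not emulate**: real blurb syntax and discourse
structure, vocabulary drift over vintages, panellist idiosyncrasies,
negative-connotation phrasings, within-wine descriptor correlations beyond
the single latent pole, and out-of-lexicon sensory words. Passing the
round-trip and recovery tests therefore demonstrates correctness of the
pipeline's mechanics under its stated assumptions — not that the default
lexicon would capture an arbitrary real corpus without curation.

## Problem sizes and numerical choices

The test suite and the acceptance script run the oracle-equivalence check
on 202 contexts of at most 12 attributes, the statistical identities on 100
random tables, and the recovery analyses on ten corpora of 710 wines;
lattices in the end-to-end pipeline are built on the top-cited attributes
(default cap 24) because concept counts grow steeply with attribute count
and the readouts of interest involve the most-cited descriptors.
Degenerate inputs are errors, not silent fixes: empty corpora, unknown
attributes/objects/groups, zero-margin contingency rows, attributes absent
from both sides of the association scale. The citation filter warns (but
returns a valid empty-attribute context) when nothing survives. Floating
comparisons in tests use explicit tolerances (1e-9 for exact-embedding
claims, 1e-10 relative for the inertia identity).

## Known limitations

- The association scale and centreline offsets are defined for two-group
  partitions only.
- The barycenter layout minimises crossings heuristically; it is stable and
  deterministic but not optimal, and no claim is made that it matches any
  published drawing.
- NextClosure is quadratic-ish per concept in context size; corpora with
  hundreds of attributes should be filtered (citation threshold, attribute
  cap) before lattice construction, as the pipeline does.
- Incremental lattice update on newly arriving wines is out of scope; the
  lattice is rebuilt from the corpus.
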