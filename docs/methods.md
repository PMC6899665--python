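# Methods

## Lineage model

A lineage is a prefix of a fixed rank ladder (default: the seven
Linnaean ranks, kingdom → species). Truncation encodes limited
resolution; there are no internal gaps. When an input lineage string
skips a rank, the gap is filled with a deterministic placeholder
`unk_<rank>_<childname>` derived from the nearest named descendant, so
identical gaps in different rows parse identically and placeholders
match only themselves in comparisons. Ranks below species and sparse
(non-prefix) ladders are not modelled: the merge logic only reasons over
order/family/genus/species, and representing coarser detections by
truncation keeps the prefix relation a simple list comparison.

Lineage B *extends* A when A's names are a prefix of B's (equality
included). The relation is reflexive, transitive and antisymmetric, and
`deepest_common_rank` of an extension pair equals the coarse lineage's
depth — both properties are enforced by tests.

Taxa not resolved to species carry a marker-local MOTU number
("Carabidae 1"). Labels are reused across samples for the same marker
cluster but never compared across markers.

## ESV filtering cascade

Stages run in a fixed order per marker; the runner
(`run_marker_pipeline`) enforces it.

1. **Length window** (closed interval). Defaults for the four bundled
   marker configurations: 94–153 bp (18S), 72–119 bp (IN16STK 16S),
   155–159 bp (ZBJ COI), 30–93 bp (trnL).
2. **One-off denoising.** ESV A is removed when some B has unit edit
   distance to A, a strictly larger total read count, and A never occurs
   in a PCR product without B. "One base pair" is unit-cost Levenshtein
   distance 1 — substitutions *and* single indels, because short plant
   amplicons are length-variable and error models operating on
   alignments treat both. The rule is applied in a single pass against
   the original table: removing A never enables a cascading removal of a
   neighbour of A. A consequence tested as an invariant: the
   highest-total-count ESV of a marker can never be removed.
3. **PCR failure.** Products with fewer than 100 total reads (strict
   inequality) are dropped and logged. Negative controls are processed
   identically and reported; counts are never subtracted.
4. **Relative abundance.** Within each remaining PCR product, counts
   strictly below 1% of that product's total are zeroed; all-zero ESVs
   drop out. The totals are those of this stage's own input (i.e.
   computed after the failure filter), so the stage must run exactly
   once — it is not idempotent, unlike the other filters. Whether the 1%
   denominator should be taken before or after denoising is genuinely
   open; we fixed "after" and document it here.
5. **LCA assignment.** Per ESV, hits within a tolerance (default 1.0
   identity percentage point) of the best hit are equally plausible; the
   assignment is truncated at the deepest rank where they all agree. An
   ESV whose retained hits disagree at kingdom is flagged unassigned.
   The tolerance is exposed (`--tolerance`) because "similar identity"
   has no canonical value.
6. **MOTU clustering.** ESVs assigned above species level are clustered
   within each (marker, lineage) group by single linkage at pairwise
   identity ≥ 98% (identity = 1 − Levenshtein/max length, via edlib).
   Clusters are numbered by decreasing total reads, ties by smallest ESV
   id, for deterministic labels. This replaces a manual
   neighbour-joining-plus-inspection delimitation; it is an
   approximation, and per-marker MOTU counts on real data may differ
   from manually curated ones.
7. **Exclusion.** Detections outside the allowed kingdoms (default
   Plantae, Animalia) or under an excluded clade (default Aves,
   Mammalia, Nematoda, Tenebrionidae and the non-vascular plant phyla)
   are removed with a logged reason. Excluded clades are matched by
   taxon name at any rank (optionally rank-qualified `rank:Name`) rather
   than as full lineage prefixes — equivalent for gap-free lineages and
   far less error-prone to configure.

Every record-level action is appended to a machine-readable provenance
log (stage, record id, action, reason) so tests and users can assert on
*why* something was removed.

## Merge objective and algorithm

The merge is formalised as a minimum-cardinality partition of one
sample's detections into groups that are (a) marker-disjoint and (b)
chains under lineage extension. Minimality encodes conservatism:
detections that *can* be the same ingested item are assumed to be.
Key consequences, all tested:

* group count is bounded below by the largest single-marker detection
  count and above by the detection count;
* a coarse detection compatible with several finer taxa joins exactly
  one group (partition semantics), never both, so it cannot inflate
  occurrence counts;
* equal lineages from different markers merge (equality is mutual
  extension).

The solver first splits the detections into connected components of the
pairwise compatibility graph — detections in different components can
never co-group, and the minimum is additive — then runs an exact
depth-first branch-and-bound within each component, assigning detections
in canonical order (decreasing depth, then lineage string, marker, MOTU)
to an existing compatible group or a new one. Among minimum partitions
the tie-break prefers maximal summed representative depth, then the
lexicographically smallest multiset of representative lineage strings;
with the component decomposition this also keeps the enumeration of
equally-good partitions cheap. Determinism under input permutation is a
tested invariant. Real per-sample instances are small (≈5–13 taxa), so
exact search is the default; a greedy first-fit fast path exists but the
exhaustive-oracle equivalence test (1,000 random instances of ≤8
detections) is run against the exact path.

Which of two equally deep candidates absorbs a coarse detection is a
convention (the count is unaffected); the tie-break above fixes it.

## Dietary descriptors

* **FOO**: fraction of a method's samples containing a taxon, at full
  taxon-label resolution or truncated to a rank (two MOTUs of one family
  count once at family level). Denominators are per-method — a sample
  counts only if the method produced a usable result for it — and can be
  overridden where a method analysed samples in which it detected
  nothing.
* **Richness**: `level="taxon"` counts merge groups (species plus
  higher-rank MOTUs); a rank counts distinct truncated lineages.
  SE = sample SD (ddof 1) / √n.
* **Czekanowski overlap** `1 − ½ Σ|pᵢ − qᵢ|`: by default FOO vectors are
  first normalised to proportions (the resource-utilization convention
  of null-model niche-overlap analyses); `normalize=False` gives the
  raw-FOO reading, since published usage is ambiguous between the two.
  The index is 1 on identical profiles, 0 on disjoint support, symmetric
  and unaffected by taxa at zero frequency in both profiles.
* **Resolution profile**: distinct taxa and occurrences per deepest
  assigned rank.

Mixed-model and multivariate comparisons between methods are out of
scope; the TSV outputs are tidy so external statistics tools can consume
them directly.

## Synthetic data

`generate_detection_fixture` emulates a four-marker faecal study:
115 samples; pools of 124 plant and 250 animal taxa; per-sample ingested
taxa Poisson-distributed with means 5.3 (plants) and 7.9 (animals),
clamped to ≥1; marker scopes 18S = both kingdoms, trnL = plants,
16S/COI = animals; per-marker rank-resolution distributions chosen so
the share of genus/species-level reports is ≈19% (18S), ≈54% (trnL),
≈31% (16S) and ≈42% (COI); and a cross-marker redundancy rate of 0.30
(the probability each non-primary in-scope marker also detects an
ingested taxon), which yields roughly a third of occurrences redundant.
These values approximate a published multi-marker bird-diet study design
and are fixed as the package's reference conditions.

True taxa receive lineages whose names are unique at every rank below
kingdom. That makes the truth table exact — detections of different taxa
can never chain, so the expected post-merge count per sample is simply
the number of taxa detected by ≥1 marker — but it also means the fixture
has *no* shared orders or families between taxa. Real data do share
higher ranks, where a coarse detection can be absorbed by a congener's
group; passing fixture tests therefore demonstrates correct redundancy
removal, not immunity to that (deliberate, conservative) ambiguity.
A side effect is that simulated order-level richness equals taxon-level
richness.

`generate_esv_fixture` plants error structure with the exact signature
the cascade targets: true ESVs pairwise ≥3 edits apart (so the one-off
rule cannot touch a true pair), error children one substitution away at
0.3% of the parent's per-PCR count (below both the parent and the 1%
floor), present only where the parent is, plus one PCR forced under the
100-read threshold. It does not emulate chimeras, index hopping,
cross-contamination or abundance-correlated error rates.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Problem sizes and numerical choices

The bundled checks use 1,000 random merge instances of ≤8 detections
(the exhaustive oracle enumerates set partitions, so 12 detections is
its hard ceiling), ESV fixtures of 20 true sequences × 12 PCR products,
and the 115-sample detection fixture; the whole suite runs in a few
seconds. Floating-point comparisons in tests use pytest's default
relative tolerance; the only genuinely numerical step, identity
computation, is integer edit distance over max length and is exact.

## Known limitations

* Identity-threshold MOTU clustering approximates manual tree-based
  delimitation.
* Lineage vocabularies must be caller-normalised; no synonym resolution
  or taxonomy-database lookups.
* Secondary ingestion (prey of the prey) is flagged in interpretation,
  not corrected algorithmically.
* Read counts are used only for filtering and label ordering, never to
  weight the merge.
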