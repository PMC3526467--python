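# Methods

## Problem and scope

`cladecarve` reimplements, as a reusable pipeline, the procedure by which
large glycoside hydrolase (GH) families are subdivided into named
subfamilies: catalytic-module sequences plus per-sequence metadata and a
phylogeny go in; a disjoint, monophyletic, named subfamily partition with
functional (EC number), taxonomic and catalytic-integrity annotation comes
out. The package targets the GH5 protocol specifically (anchor tags A1-A10,
reserved numerals 3 and 6, the two catalytic glutamates of clan GH-A), but
every constant is a parameter and the machinery is family-agnostic.

Maximum-likelihood tree inference is deliberately out of scope: trees are
consumed as newick input, and an uncorrected-distance neighbor-joining tree
serves as a desk-scale stand-in when only an alignment is available. The
delineation logic is agnostic to the tree's provenance.

## Pipeline stages and their parameters

1. **Filtering** (`ClusterParams`): sequences shorter than `min_length`
   (default 150 residues) or with more than `max_ambig_frac` (default 5%)
   ambiguous `X` residues are discarded with a per-sequence reason. These
   two declarative rules replace the manual alignment inspection a curator
   would perform; they are necessarily cruder.
2. **Two-set preparation**: biochemically characterized and
   activity-tested sequences are always retained in full; the
   uncharacterized remainder is reduced to the centroids of a single-pass
   greedy clustering at `identity_threshold` (default 0.75). Sequences are
   processed longest-first (ties by id) and join the first centroid at or
   above the threshold. The characterized-set bypass is not overridable:
   it is the protocol's defining design choice.
3. **Identity metric**: Needleman-Wunsch global alignment under BLOSUM62
   with affine gap costs (a gap of length L costs 10 + 0.5*(L-1)) and free
   terminal gaps; identity is identical aligned residue pairs divided by
   alignment columns excluding terminal-gap overhangs (internal gap columns
   count in the denominator). The original protocol's clustering tool does
   not document its denominator or gap costs, so these are fixed here
   exactly; replaying the original 1957-to-971 reduction is therefore not
   a goal. When several alignments are co-optimal the aligner's
   deterministic first traceback is used, computed on a canonically
   ordered pair so identity is exactly symmetric. For very dissimilar
   short pairs the optimal free-end-gap alignment may contain no
   non-overhang columns; identity is then defined as 0.
4. **Tree**: p-distances (mismatches over columns with neither gap nor X,
   excluded pairwise) feed classical neighbor joining; negative branch
   estimates are clamped to zero. Optional column-resampling bootstrap
   attaches to each internal bipartition of the reference tree the
   fraction of replicate trees containing it. The tree is then
   midpoint-rooted; supports are carried on bipartitions, not node
   identities, so rerooting preserves them.
5. **Delineation** (`DelineationParams`): described below.
6. **Annotation**: subfamily EC unions, specificity classes, taxonomy
   rendering, representative PDB codes, catalytic-integrity screen, and a
   family-level report with coverage and counters.

## The delineation criterion

Anchored clades come first: leaves tagged with historical subfamily tokens
define, per anchor group, the MRCA clade; groups whose clades overlap are
merged (the GH5 defaults pre-merge A3+A4 into numeral 4 and A5+A6 into 5,
mirroring the historical fusions; an undeclared merge takes the smallest
numeral). A merged clade swallowing more than 90% of all leaves aborts.

For the remaining tree, a clade is a subfamily candidate when all of the
following hold:

- node support >= `support_min` (default 0.7; nodes without a support
  value count as `missing_support`, default 1.0, because externally
  inferred trees often omit trivial supports — set it to 0.0 for a
  conservative reading);
- at least `min_size` leaves (default 5) spanning at least `min_organisms`
  distinct organism strings (default 5; distinctness is exact match after
  whitespace normalization and case folding);
- **distinctness**: the clade's stem branch is at least `min_stem_ratio`
  (default 0.5) times its within-clade leaf-to-leaf diameter. This is the
  operational surrogate for a curator "visually identifying distinct
  nodes" on a phylogram: a subfamily should hang from a stem comparable to
  the diversity inside it. It is also what prevents the degenerate
  solution in which ever-larger clades — ultimately the root, which has no
  stem — swallow the whole family: a support/size/self-containment
  predicate alone cannot exclude them, because self-containment is
  vacuously true for a clade with a small or empty complement;
- **self-containment**: for at least `self_containment_frac` of members
  (default 1.0), the member's highest-identity sequence in the whole
  dataset lies inside the candidate, ties within `separation_margin`
  (default 0) resolving in favor of containment. This replaces the manual
  all-against-all search queries of the original protocol with a fully
  specified nearest-neighbor criterion on global identities, computed
  lazily and cached.

Valid clades are made maximal — a valid clade with a valid ancestor is
discarded in favor of the ancestor — which guarantees disjointness.
Everything else is unassigned. New subfamilies are numbered by the
pre-order position of their clade root, starting after the highest
anchored numeral and skipping reserved numerals; names render as
`<family_label>_<numeral>`.

The "at least five sequences from different organisms" rule is read
strictly: >= 5 sequences spanning >= 5 distinct organisms, each bound
independently configurable.

## Specificity classes

The union of member EC tokens decides the class: empty = uncharacterized,
one distinct token = monospecific, two or more = polyspecific. A partial
token (`3.2.1.-`) counts as one distinct activity, and cross-class
transferase tokens (`2.4.1.-`) count like any other; a subfamily whose
only evidence is partial is reported monospecific with an explicit
partial-EC qualifier, keeping the ambiguity visible rather than resolved.
On the bundled GH5 table this yields 11 polyspecific and 20 uncharacterized
subfamilies; the monospecific remainder (20) includes 5 partial-EC-only
rows, which is why it is reported with the qualifier rather than as a
single headline number.

## Catalytic-integrity screen

`CatalyticSpec` names alignment columns (0-based) and the residues allowed
there (default `{E}` at each column, the clan GH-A acid/base and
nucleophile glutamates). A sequence is intact iff every catalytic column
holds an allowed residue; a gap or any other residue is "lacking". A
subfamily is flagged non-catalytic only when *all* members are lacking;
partial losses are reported as mixed with the offending members listed.
Catalytic columns must be supplied by configuration: the screen is generic
and no automatic detection from structure is attempted.

## The synthetic generator

`simulate_family` plants known structure so every stage is testable
without any download:

- one stem per subfamily (length `between_depth`, default 1.0 expected
  substitution events/site) with a random ultrametric birth-style subtree
  inside (tips exactly `within_depth`, default 0.1, below the subfamily
  root), plus `n_outliers` lone leaves attached at the root with branch
  `outlier_depth` (default 2.0, twice the stem depth so the midpoint of
  the tree's diameter falls at or near the true root);
- sites evolve independently under a lazy uniform-replacement chain:
  substitution events are Poisson with rate 1 per site per unit branch
  length and each event draws the new residue uniformly from all 20, so a
  site is unchanged over a path of length t with probability
  1/20 + (19/20) e^(-t). With the defaults this puts within-subfamily
  identity at >= 0.8 and between-subfamily identity at <= 0.55;
- organisms are assigned round-robin from disjoint per-subfamily pools of
  `organisms_per_subfamily` (default 5) names; outliers get unique
  organisms and no ECs, emulating the unassignable fraction of real
  families;
- each subfamily carries one EC drawn from `ec_pool` (two with probability
  `polyspecific_prob`); a `frac_characterized` fraction of members is
  marked characterized and carries those ECs;
- catalytic columns evolve like any site but are restored to the allowed
  residue in all non-knockout leaves after simulation, while members of
  `knockout_subfamilies` receive a non-allowed residue at every catalytic
  column — a clean positive/negative surface for the integrity screen;
- indels are off by default, making the true alignment trivial. When on,
  they are modeled as deletions only (never spanning catalytic columns),
  so the alignment keeps the root coordinate frame and both gapped and
  ungapped variants are emitted.

Everything derives from a single integer seed; identical configs are
byte-identical.

What the generator does *not* emulate: empirical substitution preferences
(no WAG/LG), rate heterogeneity across sites, insertions, domain
rearrangements, alignment error, or the ragged taxon sampling of real
databases. Passing the planted-recovery benchmark therefore shows the
pipeline is correct and internally consistent under clade-structured
divergence with a clear within/between identity gap — not that it
reproduces any particular curated classification, whose judgment calls
(visual clade selection) the delineation predicate only approximates.

## Benchmarks the package ships with

- **Planted recovery**: 20 seeds of the standard scenario (3-6 subfamilies
  of 5-40 sequences, >= 5 organisms each, 3 outliers); the end-to-end
  chain simulate -> p-distance -> NJ -> midpoint root -> delineate must
  recover the planted partition exactly (adjusted Rand index 1.0, with
  unassigned leaves scored as singletons) in >= 95% of seeds. The
  redundancy-clustering step is skipped here because the truth is defined
  over all leaves and within-subfamily identity sits above the clustering
  threshold by design.
- **Oracle equivalence**: alignment scores against an independent DP on
  200 random pairs (length <= 12) and identity against full alignment
  enumeration on tiny pairs; adjusted Rand index against direct pair
  counting; greedy clustering against a naive replay of its definition.
- **NJ consistency**: exact topology recovery on 50 random additive
  matrices (<= 12 leaves); exact three-point branch lengths.
- **Simulator closed form**: observed pairwise identity at 1000 sites
  within the 99% binomial interval of 1/20 + (19/20) e^(-t) across ten
  (t, seed) combinations.
- **Catalytic screen**: knockouts flagged in 100% of 20 seeds with zero
  false subfamily-level flags.

Problem sizes (20 seeds, <= ~170 leaves per scenario, 300-residue
sequences) were chosen as the smallest scale at which every failure mode
the delineation criterion guards against (union clades, root swallowing,
outlier attraction, support gating) actually occurs.

## Numerical choices and degenerate inputs

- NJ Q-criterion ties resolve to the library's deterministic first
  minimum; negative branch estimates clamp to 0.
- Midpoint rooting breaks diameter ties by (distance, leaf name); an
  all-zero-length tree roots at the first traversal node with a warning;
  rebuilt children are ordered by their smallest leaf name, making the
  rooted tree canonical and rooting idempotent.
- Newick internal labels are always supports, never names; values in
  (1, 100] are bootstrap percentages and divide by 100; missing branch
  lengths read as 0; the writer emits lengths and supports with up to six
  trimmed decimals, and write-then-parse is the identity on this
  canonical form.
- Bootstrap bipartitions are normalized to the side not containing a
  fixed reference taxon (the lexicographically smallest), so rooted
  representations compare correctly as unrooted splits.
- A candidate clade of size < 2 is a hard error for the self-containment
  predicate; delineation never evaluates it (leaves are not candidates).

## Known limitations

- The identity denominator and gap-cost convention approximate, but
  cannot replicate, the original clustering tool; absolute cluster counts
  on real data will differ.
- The distinctness ratio (stem vs within-clade diameter) is a geometric
  surrogate for expert judgment; on trees with severe rate variation a
  genuine subfamily on a short stem would be missed, and the threshold
  may need lowering.
- `missing_support = 1.0` is permissive by design; external trees with
  genuinely unassessed nodes should be run with 0.0 or with bootstrap.
- Specificity classes count distinct EC tokens only; they do not model
  the relation between a partial token and fuller tokens of the same
  sub-subclass.
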