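# Methods

## Scope and model

The package reconstructs, as reusable library code, a gene-order
comparative-genomics workflow: synteny-block construction between two
genomes from one-to-one ortholog markers, breakpoint (syntenic
disruption) detection and lineage polarization against outgroups,
presence/absence-based classification of candidate novel genes across
a clade panel, association of novel genes with breakpoints, and
parent-vs-duplicate comparisons of domain architecture and expression
evidence. Everything operates at gene resolution: markers are genes,
rearrangement breaks fall between genes, and no sequence alignment is
computed — alignment hits, domain tables and tissue calls are inputs.

## Coordinates

External tables are 1-based inclusive (browser convention); all
in-memory intervals are 0-based half-open. Conversion happens only in
`oscinova.io`, so read-then-write is the identity and all gap/overlap
arithmetic is off-by-one-free.

## Synteny blocks

A homologous synteny block (HSB) is a maximal run of ≥ 2 markers
(`min_block_genes`) such that consecutive markers (i) share both
chromosomes, (ii) lie within `max_marker_gap` (default 1 Mb) on both
genomes, (iii) have monotone target coordinates in one direction, and
(iv) agree in relative strand. Runs shorter than 2 markers are
singletons, never blocks. `min_report_length` (2 Mb) filters a
reporting view only; short blocks are kept internally so SD positions
are not lost. `jump_distance` (2 Mb) is the displacement tolerance
before a collinear block is considered transposed.

Construction is a greedy left-to-right sweep per reference chromosome.
Because run validity is prefix-closed, the sweep yields the longest
valid run at each starting marker — a maximal partition with ties
resolved toward the upstream block. The test suite checks equivalence
against an independently written brute-force oracle on 1,000 random
instances.

The relative-strand condition (iv) deserves a note: with coordinates
alone, the first marker of an inverted segment can legally extend the
preceding collinear run (its target coordinate continues the upward
trend), which would shift the block boundary one marker off the true
inversion breakpoint and make the resulting junction unpolarizable
(both junction adjacencies look ancestral). Since markers carry
strands and an inversion flips them, requiring uniform relative strand
within a block pins boundaries to the planted breakpoints; noise-free
simulations then recover 100% of breakpoints within one inter-marker
gap.

Rearrangement labels are assigned per reference chromosome: blocks off
the marker-weighted majority target chromosome are translocations;
minority-orientation blocks are inversions; majority-orientation
blocks displaced by more than `jump_distance` from both neighbours are
transpositions; the rest are collinear.

## Syntenic disruptions and polarization

An SD is the reference interval between consecutive blocks whose
target context changes (different target chromosome, orientation flip,
or displacement > `jump_distance`). Blocks separated only by marker
sparsity yield no SD. Runs of adjacent SDs separated by blocks shorter
than `min_report_length` share a `tandem_group`; SDs between blocks on
different target chromosomes are flagged `interchrom`.

Polarization compares the junction gene adjacency (the ordered pair of
genes flanking the junction, matched order- and strand-agnostically)
against each outgroup genome: an outgroup showing the reference
adjacency implies the arrangement is ancestral in the reference, hence
the break occurred on the target branch, and symmetrically. Votes are
taken by majority over resolvable outgroups; ties or no resolvable
outgroup give AMBIGUOUS. This is antisymmetric under swapping the
genome roles, which the suite asserts on simulated instances.

"Near" an SD is operationalized as a placement within `flank_genes`
(default 3, matching the synteny window used for presence calls) of a
block terminus; *at* an SD means START, END or WITHIN. Only the latter
three count as SD-associated. A gene matching several SDs goes to the
nearest, ties to the lower SD id. The raw SD interval is reported
as-is; no manual refinement of gene positions within SDs is attempted.

## Presence, origin and curation

Hits must score strictly above `min_hit_score` (50). Syntenic context
is the fraction of `flank_genes` upstream/downstream neighbours
conserved around a hit, order-aware but orientation-agnostic (the
flanks are also compared with sides swapped); the threshold for a
syntenic presence call is `context_threshold` = 0.5, i.e. ≥ 3 of 6
flanking genes — the source analysis verified synteny qualitatively,
so the cut-off is explicit and configurable. A hit above score
threshold without context support is PRESENT_UNPLACED; it still vetoes
absence. Absence tolerates `max_missing` = 0 missing species by
default (one presence outside the focal clade vetoes the call); the
tolerance is exposed for noisier panels.

Origin calls, in evaluation order: present in exactly one species →
single-species suspect (likely allele/assembly artefact); present in
all songbirds and nowhere else → songbird-unique; present in a proper
subset of songbirds → finch-specific; in exactly the passerines →
passerine; widely present but absent from galliforms and non-avians →
neoaves-or-galliform-loss; otherwise not novel.

The curation cascade (first match wins, so categories partition the
candidates): split models (two adjacent models covering disjoint
ranges of one ortholog), tandem/interchromosomal false positives (best
subject is a distinct family member), shared duplications (present
syntenically beyond passerines), fragments of known genes,
uncharacterized genes with an ortholog, retrocopies (intronless copy
of an intron-bearing parent with flanking repeats), assembly suspects
(tandem, gap-flanked, identity > `allele_identity` = 95%), deferred
mega-families (> `large_family_cap` members), else passes curation.

**Novel-gene counting.** A family whose ancestral copy cannot be
identified ("dash-numbered" tandem families) contributes *k − 1* novel
genes for *k* qualifying copies — one copy stands for the parent. A
de novo gene (no parent anywhere) contributes 1; known-parent paralogs
contribute 1 each. This rule is what reconciles the 12
songbird-labelled loci of the published table with its stated 10 novel
genes (A4GALT: 3 copies → 2; CASC1: 2 copies → 1), and the same cap is
applied to the family's SD-associated count (A4GALT: 3 flagged copies
→ 2; CASC1: 1 flagged copy → 1), which reproduces the published
6-of-10 association.

## Association and the permutation layer

The association report counts, per origin category, novel genes at vs
not at SDs under the counting rule, and lists SDs harbouring multiple
events. The permutation test is an extension — the original claim was
qualitative — and is kept out of the descriptive report: the observed
statistic is the per-locus SD-associated count among focal genes; each
permutation redraws that many genes uniformly without replacement from
the curated gene universe; `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`,
reproducible for a fixed seed. Calibration and power are verified in
the suite (null p-values approximately uniform; power ≥ 0.95 at
α = 0.05 when 90% of duplications are planted at breakpoints).

## Domain architecture and expression

Domain identity is by name after an optional vocabulary map; positions
never affect the verdict, matching the qualitative treatment of domain
gains/losses. COMPLETE = identical sets; PARTIAL = any loss (loss
dominates mixed cases); EXTENDED = gains only; DIVERGED only on
caller-supplied divergence evidence (alignment-score arguments are not
recomputed here). A duplicate abutting an assembly gap carries a
`caveat_gap` flag, since missing domains may be unsequenced.

EST assignment requires a unique locus via (a) a single passing hit,
(b) an exon label present at only one candidate locus, or (c) a
percent-identity margin ≥ `identity_margin` (1.0 point — the decisive
published cases differ by at least this); otherwise the clone is
ambiguous with its tied loci listed. Only locus-specific brain clones
count as brain evidence; any non-brain clone or RNA-seq tissue call
counts as non-brain evidence; the four categories are NONE,
NON_BRAIN_ONLY, BRAIN_ONLY, BRAIN_AND_OTHER. In-situ hybridization
scoring is qualitative and carried only as an optional annotation.

## Synthetic data

The generator emulates the study design, not sequences: an ancestor of
`n_chroms` × `n_genes` markers (default 2 × 500 at 100 kb spacing —
large enough to exercise the 1 Mb/2 Mb thresholds, small enough for
sub-second tests) evolves by inversions and translocations on the
reference branch; the target genome keeps the ancestral order and
doubles as a clean outgroup. Events are applied at inter-gene
positions, on disjoint segments kept ≥ 3 genes apart and ≥ 3 genes
from chromosome ends so every inter-event run can form a block.
Translocated segments span more than `jump_distance`: a shorter
excision is indistinguishable from marker sparsity at gene resolution,
so it would not constitute a plantable breakpoint for any gene-order
method. Planted breakpoints are derived structurally (reference
adjacencies absent from the ancestor), independently of the block
code; the event log replays exactly, and replay identity is asserted
in the tests.

Duplications land inside breakpoint intervals with probability
`p_at_breakpoint`, else uniformly elsewhere; presence evidence gives
each origin-clade species a high-scoring syntenic hit (score 100–300,
full context), with dropout applied to non-songbird species (emulating
incomplete new assemblies) and spurious sub-threshold hits (score
≤ 50) injected at a configurable rate. What passing tests show about
real data is therefore limited: real ortholog sets have mapping
errors, unequal marker density, and assembly fragmentation that the
generator does not model; the fixtures demonstrate correctness of the
inference rules, not robustness to every failure mode of real
annotation.

The published 38-locus table ships as a programmatic fixture. Its
extraction has a handful of formatting ambiguities (blank SD cells,
a duplicated EST id); each interpretation is recorded in
`table1.CELL_NOTES`. One consequence of the strict locus-specific
brain-evidence rule: a locus whose brain clones all cross-align to
several family copies computes as NON_BRAIN_ONLY even where
qualitative in-situ data showed brain expression (see the URB1L3
note).

## Numerical and degenerate-input choices

- Tie-breaks: a marker that could extend either neighbouring block
  joins the upstream one; two-marker blocks with equal target
  coordinates get orientation `+`; equal-score hits prefer the longer
  aligned span, then the lower subject coordinate; placement ties go
  to the lower SD id.
- Empty inputs return empty outputs everywhere; an SD map of size zero
  yields zero associated genes, not an error.
- `*_random` and `chrUn` sequence names are accepted but flagged;
  "chromosome Unknown" loci are meant to be excluded from novelty
  calls upstream of classification (they are enriched for allelic
  variants). Hits to unplaced scaffolds are treated symmetrically in
  the panel screen.
- Determinism: identical inputs and config give byte-identical output
  tables; all simulators and the permutation test are seeded.

## Known limitations

- Polarization votes on a single junction adjacency per SD; real
  analyses sometimes use longer flanking windows when outgroup
  assemblies are fragmented. The adjacency is computed from marker
  orders, so outgroups must share the marker namespace.
- The supplementary-scale association figures for novel genes *not*
  unique to songbirds are exercised only against a synthetic stand-in
  mirroring their published aggregate structure, because the
  per-locus supplementary rows are not available in machine-readable
  form; that check validates the counting machinery, not an
  independent reproduction.
- Genome-scale totals (ortholog-pair counts, curated-model category
  sizes) depend on a specific annotation release and manual curation
  and are out of scope; the property-based suites stand in for them.
- No repeat-element analysis at SDs, no sequence evolution, no HMM
  domain scanning, no RNA-seq quantification.
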