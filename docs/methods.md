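# Methods

This note documents the models behind each stage, the parameters that
matter, and the design choices made where the underlying study left the
procedure open.

## Lineage groups and emergence times

Ten chordate lineage groups anchor every analysis, each with the
emergence time (MYA, million years ago) of its earliest known ancestor:
jawed fish 410, jawless fish 360, amphibia 350, squamata 330, crocodilia
240, testudines 210, monotremata 110, aves 70, marsupialia 65,
placentalia 62.5.  These constants order presence-matrix rows and provide
the x-axis of every timescale; they are overridable per run
(`timescale.mya_overrides`), and changing them moves points along x only,
never in y.

## Synthetic data

The generator's purpose is to produce inputs with the same structure and
magnitudes as the collated study data, together with an event-level truth
log, so that every downstream computation can be checked against known
ground truth.

**Species tree.** Each group forms a clade hanging off the root, with the
leaf depth equal to the group's emergence time (half on the stem, half on
the terminal branch).  This is a deliberate simplification — a star
phylogeny by group, not an estimate of chordate topology — chosen so that
a species' divergence from the root is exactly its group's age, which is
the relationship the similarity-versus-time analysis assumes.

**Protein families.** Sequences evolve down the tree under a
Jukes–Cantor-style amino-acid model: per branch of length *t* (MY) and
current length *L*, the substitution count is Poisson with mean
*r·t·L*, each substitution replacing one uniformly chosen residue by a
uniform choice among the 19 alternatives.  The default rate
*r* = 0.002 substitutions/site/MY makes expected identity to the root
fall from ≈88% at 62.5 MY to ≈45% at 410 MY
(P(identical) = 1/20 + (19/20)·e^(−20rt/19)), matching the magnitude of
the published receptor conservation range.  Indels are single-residue
insertions/deletions at 10⁻⁴ events/site/MY — enough to exercise
coverage handling without a full indel-length model.  Whole-gene loss
happens with probability `gene_loss_rate` per branch (default 0.03) and
is inherited by the subtree; every loss is logged.

**Genome orders.** Per-species gene orders derive from a reference by
three event types, each logged with the positional detail needed to
replay it: independent per-gene loss (default 0.02–0.1 per gene depending
on the experiment), segmental inversions of 2–6 gene windows (reversed,
strands flipped; Poisson count with mean `inversion_rate · n_genes`), and
single-gene translocations to a uniform position on a uniform chromosome.
Outputs are produced *by replaying the log*, so "every absence is
explained by exactly one logged event" holds by construction and is also
asserted in tests.  The homology between generation and replay is
deliberate; what the tests check independently is that the *classifier*,
which sees only final gene positions, recovers the fate implied by which
events actually hit the focal gene.

**Blood counts.** Counts are Gamma-distributed per group and cell type:
mean *μ* from the profile, dispersion *d* as a coefficient of variation
(shape 1/d², scale μd²; default d = 0.5, a realistic cross-species
spread), degenerating to the exact mean at d = 0.  Gamma was chosen
because counts are non-negative and right-skewed; the underlying study
states no distribution, and this choice is a stand-in, not an inference.
Default group profiles use the published absolute counts for the dominant
granulocyte of each group (e.g. aves heterophils 12.7×10⁹/L, placental
neutrophils 5.2×10⁹/L) and derive the remaining cell types from the
published composition percentages; where the printed absolute count and
percentage disagree (squamata monocytes, crocodilian azurophils) the
absolute count wins, and where neither is given (jawless fish; avian
eosinophils/basophils) small plausible values were fixed once.

**Randomness.** One `numpy` Generator per stage, seeded by
`(seed, crc32(stage name))`.  Fixed seed ⇒ bit-identical outputs.

What the generator does *not* emulate: codon-level evolution, rate
heterogeneity across sites or lineages, segmental duplications, assembly
or annotation error, intra-species blood-count variation by sex or
season.  Passing tests therefore demonstrate correctness of the
*computations* under a clean generative model, not robustness to the
noise sources of real assemblies and veterinary literature.

## Blood-count meta-analysis

Inclusion rules: adult and sub-adult records only; all lymphoid counts
excluded; records flagged non-standardised at parse time dropped.  Each
representative record (e.g. one per sex) counts as one observation —
no weighting is invented.  Composition is computed from per-group means
of each cell type by default; averaging per-species compositions first is
available as `mode="per_species"` because group-level composition admits
both readings and the source is ambiguous.  Azurophils are a distinct
cell type throughout.  An unrecorded cell type contributes nothing to the
composition denominator; an explicit zero does — absence of a measurement
is not a measurement of absence.

## Synteny classification

The manual syntenic-map procedure is made algorithmic with three
parameters:

- `flank_size` (default 10 genes per side): candidate flank around the
  focal gene; large enough to contain every flanking gene named in the
  narrated loci.
- `k` anchors (3–5, default 4), ranked by gene-order distance to the
  focal gene, ties broken downstream before upstream, then
  alphabetically.  Anchors must be present in every query genome; if
  fewer than three qualify the requirement relaxes to presence in ≥ 80%
  of species (`presence_fraction`), and the relaxation is logged —
  multiple anchors exist precisely to buffer random gene loss.
- `window` W (default 10 gene positions): the quantitative stand-in for
  "immediately adjacent"; a focal gene within W of any anchor on the same
  chromosome is retained in its block.

Classification uses gene-order indices only, so calls are invariant to
coordinate shifts and chromosome renaming.  Anchors are classified
relative to the focal gene when present, otherwise relative to the
chromosome holding most surviving anchors (median index as the reference
point).  A focal gene present while *no* anchor survives anywhere is
called `translocated_other_chromosome` — the block context is gone, and
the enumeration "present only where no anchor is" covers it; this corner
is rare and worth knowing about.  Orientation is the sign of the Spearman
correlation between reference and query positions of co-located block
genes; it needs at least two shared genes and is otherwise undefined.

## Homology scoring

The aligner is a full Smith–Waterman/Gotoh dynamic program (no seeding
heuristics): BLOSUM62, gap of length *g* costing 11 + g, one optimal
traceback with ties broken diagonal > up > left.  The ambiguity code X
scores 0 against everything.  Scores are verified in the test suite
against exhaustive enumeration on short pairs and against `blastp` raw
scores (compositional adjustment and masking disabled) on longer pairs.

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with the gapped
constants λ = 0.267, K = 0.041 commonly quoted for BLOSUM62 11/1; they
are plain fields of `ScoringScheme`, not estimated.  Composition-based
score adjustment and low-complexity filtering are not implemented, which
can shift percent identities by a point or two relative to the standard
search tool's defaults.

The acceptance rule is query coverage ≥ 0.40 **and** E ≤ 10⁻²⁰, both
boundaries inclusive.  The e-value interval as printed in the source
("between 0 × 10⁻²⁰ – 0") is ambiguous; E ≤ 10⁻²⁰ is the only reading
that yields a usable filter.  Coverage is defined on the query (the human
orthologue) because that is the sequence "examined".  "Percent
similarity" is percent identity over alignment columns by default, with
percent positives (pairs scoring > 0) available via `mode="positives"` —
the source does not say which was meant, so both are first-class.  One
sequence per species (the longest isoform, when a choice exists).

## Timescales

Points are ordered oldest-first; spread is min–max for composition
(floating bars) and ± one standard deviation for similarity
trajectories.  Placental mammals are excluded from similarity
trajectories by default (the reference species belongs to that group and
its values sit far above the rest); `include_placentalia_similarity`
restores them.  The two-period split is fish→squamata and
squamata→placentalia, squamata shared.

## Pipeline

One YAML config drives the run; a single seed fans out to per-stage
streams.  Stages run in dependency order (simulate → cbc → homology →
presence → synteny → timescale); presence calls derive from the homology
calls when that stage is enabled, else from simulated gene survival.  A
failing stage writes a `FAILED` marker and skips downstream stages,
keeping partial outputs.  The manifest records the seed, a hash of the
scientific config (output directory excluded) and a SHA-256 per output
file; tabular outputs are byte-reproducible, image files may not be
(SVG embeds a timestamp).

## Problem sizes and tolerances

The test suite and acceptance script run at deliberately modest sizes
chosen to estimate each quantity with comfortable margins: 200 species
for blood-count recovery (3 standard errors), 1,000 random pairs of
length ≤ 8 for exact aligner equality, 100 simulated genomes at event
rates ≤ 0.1 per gene for synteny fate recovery (≥ 95% required; the
classifier scores 100% at these rates), 10–20 replicates of a ten-group
panel with 120–250-residue proteins for the similarity-versus-time rank
correlation.  Composition sums are asserted to 10⁻⁶ of a percentage
point.

## Known limitations

- Gene matching in the synteny module is by symbol (plus a user synonym
  table); no sequence-level orthology is attempted there.
- The aligner is O(mn) per pair in pure Python/NumPy — fine for panels of
  hundreds of proteins, not for proteome-scale search.
- Karlin–Altschul constants are fixed per scheme, so E-values for
  non-default matrices/penalties require user-supplied λ and K.
- The reconstruction of real published per-order similarity values would
  require fetching the original accessions; the package deliberately
  operates on curated or synthetic inputs only.
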