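# Methods

## Study design and comparison groups

The pipeline is organised around a five-sample crossing design: one
individual of parental species A, two individuals of parental species B,
and two F2 hybrids.  Roles are always declared in configuration — never
inferred from sample names — and induce four groups over the ten unordered
sample pairs: parent–parent interspecific (2 pairs), parental
intraspecific (1 pair), hybrid–hybrid (1 pair) and parent–hybrid (6
pairs).  Intraspecific pairs form within *either* parental species role;
the grouping is driven by role semantics, so a second individual of
species A would contribute intraspecific pairs in the same way.

## Ortholog curation

Input is a ProteinOrtho v6-style TSV (header `# Species  Genes
Alg.-Conn.`, `*` for absence, `,` between co-orthologs).  Curation keeps
groups with exactly one contig in every sample, then drops loci whose ORF
is shorter than `min_orf_nt` (default 300 nt = 100 aa; the boundary is
strict, 300 is kept and 299 is not), then applies three annotation rules
in order: (1) any contig with a lineage label outside the accepted
spermatophyte set is a putative contaminant; (2) a reference gene claimed
by more than one distinct contig marks all involved loci as putative
paralogs; (3) a contig matching several reference genes is removed only
when the mapped fragments overlap on the transcript (half-open intervals;
a single shared base counts as overlap — the conservative reading).
Unannotated loci flow through the whole analysis flagged `annotated=false`
and are only separated at the final cascade step.  Every filter logs one
discard reason per locus, is idempotent, and preserves
`retained + discarded = input`.

The ORF-length filter is applied after single-copy selection, following
the order in which the steps are described for the original protocol.

## Alignment preparation

dN/dS counting operates on codons, so all block operations snap to codon
columns of the frame anchored at alignment column 0.  Codon columns
containing a stop codon in any sample are removed for all samples.  The
majority-rule consensus takes the most frequent base among {A,C,G,T} per
column (gaps and N excluded, all-gap columns omitted), with ties broken to
the alphabetically smallest base for determinism.  Trimming returns the
single longest run of codon columns free of gaps and N across all samples,
provided it reaches `min_block_aa` (default 30 codons); shorter loci are
dropped with verdict `below_min_block`.  Equal-length runs tie-break to
the leftmost, and qualifying blocks are never concatenated — one block per
locus, so downstream identity and selection statistics describe the same
region.

## Nei–Gojobori counting with Jukes–Cantor correction

Sites: each codon position contributes a synonymous fraction equal to the
share of its three single-base neighbours coding the same amino acid.
Neighbours that would be stop codons are counted as nonsynonymous, which
keeps S + N = 3L exact (the implementation accumulates integer
ninth-counts so the identity holds in floating point, not just
mathematically).  Per pair, S and N are means of the two sequences'
counts.

Differences: a codon pair differing at k positions is scored by averaging
the synonymous/nonsynonymous step classification over all k! substitution
orderings, excluding orderings that pass through a stop codon.  Should
every ordering be blocked, the contract scores all k differences
nonsynonymous and flags the pair — in practice this branch is unreachable
under the standard genetic code (a test asserts that every sense-codon
pair admits at least one stop-free ordering).  Sd + Nd always equals the
nucleotide Hamming distance.

Distances and ratio: pS = Sd/S and pN = Nd/N are corrected with
d = −(3/4)·ln(1 − (4/3)·p); p ≥ 3/4 raises a saturation error, the pair is
excluded from all means, and the locus is flagged.  The reported ratio is
ω = (dN + c)/(dS + c) with c = 0.01, so two identical sequences score
ω = 1 and loci lacking synonymous changes stay finite.  Only the standard
genetic code (translation table 1) is supported; model-based (ML)
estimation, site/branch models and codon-frequency corrections are
deliberately out of scope — the counting method is the conservative
choice.

Per-locus group means are arithmetic means of the pairwise ω values within
a group (`average="mean_of_ratios"`); whether a per-locus average should
instead pool counts is genuinely open, so a `pooled` mode (pseudo-counted
ratio of group-mean distances) is available but not default.

The pseudo-count matters for interpretation: at low divergence it shrinks
ω toward 1 (with dS ≈ 0.015 and true ratio 4, the pseudo-counted statistic
is ≈ 2.9).  This is intentional for filtering — weakly informative loci
should not produce extreme ratios — but it means calibration of the
*simulator* is checked on the raw dN/dS ratio, while the cascade and the
neutral-calibration check use the pseudo-counted statistic that the
filters actually consume.

## Filter cascade

Rules apply sequentially to the four group means; the first match wins and
the categories partition the loci: parent–parent mean > 1.0 (divergent
between the parental species; would segregate in the F2 and fake
parent–hybrid substitutions), intraspecific mean > 1.0, hybrid–hybrid
mean > 4.0 (not shared between hybrids, so irrelevant for a shared trait),
parent–hybrid mean ≤ 1.0 → purifying, else diversifying
(annotated/not annotated).  The selection boundary is strict: a mean of
exactly 1.0 is purifying.  A locus with a missing group mean (saturation)
is reported as `unscored` outside the partition.  Report percentages are
rounded half-up to two decimals.

## Heterozygosity

mpileup text is parsed directly (read-start/end markers, indel spans,
deletion placeholders and reference skips stripped; `.`/`,` resolve to the
line's reference base).  A position is heterozygous when the
second-most-frequent base reaches `minor_fraction_min` of the reported
read depth (default 0.10, boundary inclusive).  "Minor" is the second
count, not the sum of all non-major bases — the diploid reading; with more
than two observed bases the extra counts are ignored.  `min_depth`
defaults to 1 because no minimum was part of the original rule; both
choices are configurable.  Per-locus summaries are percentages over
positions with data; per-sample values are unweighted means across loci.

## Identity profiles

Exact string equality over the trimmed block, per group: identical within
hybrids, identical within parents, and — when parents vary — whether the
variability is between species (any A vs B difference) or within a
parental species (difference between same-role individuals).  Flag-
combination counts feed a Venn-style summary.

## GO reproduction subset and stages

Ontology traversal uses `is_a` edges only (the conservative default;
`part_of` would enlarge the subtree and is not asserted by the protocol).
Obsolete terms are excluded with a warning; `alt_id` aliases resolve to
their primary term.  A locus is reproduction-linked when any of its terms
lies in the union of the subtrees rooted at GO:0048229, GO:0000003,
GO:0022414, GO:1903046, GO:0048236 and GO:0000741.  The term → stage
assignment (flower/ovule formation, meiosis, embryo sac development and
gametogenesis, embryo/seed formation, male functions) is shipped as an
editable TSV (`data/stage_map.tsv`) rather than code, because category
names do not determine per-term membership; unassigned terms are reported
rather than guessed.

## Synthetic data

The simulator emulates the five-sample design end to end and is the source
of every test input.

Per locus, an ancestral stop-free sequence (codons uniform over the 61
sense codons) evolves along a species split; each parental branch receives
a Poisson number of substitutions.  Selection intensity is enforced by
acceptance–rejection on proposed single-base changes: proposals uniform
over sites and alternative bases, stop-creating proposals rejected
outright, nonsynonymous proposals accepted with min(1, ω), synonymous with
min(1, 1/ω).  Branch lengths count accepted substitutions, so configured
rates are realized divergences.  Because stop-adjacent changes are never
realized but are counted as nonsynonymous sites, the counting estimator
reads a ~4–5% deficit in dN on neutral data — visible as neutral mean ω
≈ 0.96, well inside the 0.15 calibration band.

Defaults are the study conditions: 5 samples (1 + 2 parents, 2 hybrids),
300-codon loci, species divergence 0.05 substitutions/site, background
ω = 0.2, heterozygous-site density 0.02, pileup depth 50, sequencing error
10⁻³.  Two rates are not fixed by the protocol and are the package's own
choices, made analytically before any end-to-end run:

* `intraspecific_divergence_sub_per_site = 0.005` — one tenth of the
  species divergence, a plausible polymorphism level for outcrossing
  herbs; it reproduces the observed phenomenon that a few percent of loci
  fail the intraspecific filter purely through sampling noise at low
  divergence.
* `hybrid_branch_sub_per_site = 0.10` — chosen from a dilution argument:
  every parent–hybrid pair carries ≈ 0.025 substitutions/site of
  segregating parental divergence at background ω, which dilutes the
  hybrid-branch signal; for the parent–hybrid mean to clear 1 under a
  hybrid-branch ω of 4, the hybrid branch needs roughly
  0.9·h > 0.05 ⇒ h ≳ 0.06, and 0.10 gives comfortable margin.  This is a
  sensitivity-calibration device, not a per-generation mutation model — a
  real F2 would carry orders of magnitude fewer private substitutions, and
  no desk-scale simulation can reproduce discovery power on two
  generations of real mutation input.

F2 sequences are Mendelian mosaics: one recombination breakpoint per
locus, uniform on codon boundaries, each segment drawing the species-A
allele or one of the two species-B alleles — reproducing the segregation
confound the parental filters exist for — followed by the private hybrid
branch under background or injected ω.  Diploid genotypes add a companion
haplotype with heterozygous sites at the configured density (stop-free by
construction); pileups draw each read's haplotype uniformly at fixed
depth with symmetric base errors.  Everything is deterministic given the
seed, and a truth table records per-locus branch ω, injection status,
annotation flags and per-sample heterozygous positions.

What the simulator does **not** emulate: indels and alignment error
(alignments are generated gap-free, so trimming is exercised by unit
fixtures rather than the simulator), assembly artefacts, read-mapping
bias, more than one recombination breakpoint, within-locus rate
heterogeneity, and realistic codon/base composition.  Passing tests
therefore demonstrate correctness and calibration of the estimators and
filters, not discovery power on real transcriptome assemblies.

The bundled miniature ontology (≤ 50 terms) contains the six reproduction
roots, a multi-level descendant chain under each, every annotation-table
GO id exactly once, and metabolic decoys with no path into any
reproduction root.  Its topology only loosely follows the real Gene
Ontology and is labelled synthetic.

## Numerical and engineering choices

* Pairwise codon-difference contributions are precomputed for all 61×61
  sense-codon pairs at import, making long-alignment scans dictionary
  lookups.
* S + N = 3L holds exactly in floating point (integer ninth-count
  accumulation); Sd + Nd equals the Hamming distance to 1e−9.
* Report tables print 6 decimals; percentages round half-up to 2 decimals.
* Problem sizes in tests and the acceptance script (e.g. 20 neutral
  replicates of 3000 codons; 200 loci × 300 codons for recovery; 30 loci ×
  300 nt × 5 samples for heterozygosity) were chosen to make the binomial
  and calibration bands informative at desk scale.
* The cascade's category accounting is verified as an arithmetic twin on
  the study-scale category counts; the upstream curation counts of the
  original study derive from raw sequencing data and are not reproducible
  from simulation.

## Known limitations

* Counting-based estimation only; no likelihood model, no transition/
  transversion asymmetry (Jukes–Cantor assumes uniform rates).
* The intraspecific filter is noisy at low divergence by construction
  (few substitutions per pair); this matches its behaviour in practice
  and is documented rather than patched.
* The ω-control scheme cannot represent saturation-level divergence or
  branch-specific codon models; it calibrates a counting estimator, not a
  generative evolutionary model.
* GO stage assignment is a curated table; terms outside it are reported
  as unassigned, never auto-classified.
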