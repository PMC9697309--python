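# aposcan

A selection-scan pipeline for detecting loci under diversifying selection
between sexual parental plants and early-generation (F2) hybrids that
express apospory — asexual embryo-sac formation, one component of apomixis.

## The scientific problem

When two sexual plant species hybridise, the F2 generation segregates
parental alleles and can express novel reproductive phenotypes such as
apospory.  Genes driving such a phenotype are expected to carry an excess
of amino-acid-changing substitutions between hybrids and parents
(diversifying selection, dN/dS > 1), while most of the transcriptome stays
under purifying selection (dN/dS ≤ 1).  The confounder is that ordinary
parental divergence and within-species polymorphism also segregate in the
F2 and mimic hybrid-specific substitutions.  `aposcan` implements the
post-assembly part of such a study for a five-sample design — one
individual of parental species A, two of parental species B, and two F2
hybrids — and removes the confounded loci with an explicit filter cascade.

## The statistic at its core

For every locus and every unordered sample pair, counting-based
Nei–Gojobori estimation on the longest shared gap-free codon block:

* synonymous and nonsynonymous **sites** per codon from the fraction of
  single-base neighbours that preserve the amino acid (stop neighbours
  count as nonsynonymous, so S + N = 3·codons exactly),
* observed **differences** per codon pair averaged over all substitution
  orderings, excluding orderings that pass through a stop codon,
* Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p) applied to
  pS = Sd/S and pN = Nd/N,
* ω = (dN + c)/(dS + c) with pseudo-count c = 0.01, so loci without
  synonymous (or nonsynonymous) change remain comparable.

Group-mean ω values per locus then pass through the cascade (first match
wins): parent–parent mean > 1 → parental divergence; intraspecific mean
> 1 → parental polymorphism; hybrid–hybrid mean > 4 → not shared by the
hybrids; parent–hybrid mean ≤ 1 → purifying; otherwise the locus is a
diversifying-selection candidate, split by annotation status.

Around the core sit single-copy ortholog curation (ProteinOrtho-style
tables, ORF length ≥ 300 nt, contaminant/paralog/chimera removal), pileup
heterozygosity (a position is heterozygous when the minor base reaches 10%
of read depth), within-group sequence-identity profiles, and GO annotation
propagated through `is_a` ancestors to a six-root reproduction subset,
sorted into five reproductive-stage categories.

A pedigree-structured codon simulator generates every input with known
per-branch dN/dS (acceptance–rejection on proposed single-base changes),
Mendelian-mosaic F2 sequences, diploid genotypes and read pileups — so the
whole pipeline is testable against ground truth.

## Worked example

```bash
cat > demo.yaml <<'EOF'
seed: 11
simulation:
  n_loci: 60
  codons_per_locus: 300
  injected_loci: [[0, 4.0], [1, 4.0], [2, 4.0], [3, 4.0], [4, 4.0], [5, 4.0]]
EOF
aposcan all --config demo.yaml --outdir demo
cat demo/table_report.tsv
```

```
category                   count  percent
parental_divergence        0      0.0
intraspecific_polymorphism 3      5.0
hybrid_hybrid_divergence   0      0.0
parent_hybrid_purifying    51     85.0
diversifying_not_annotated 2      3.33
diversifying_annotated     4      6.67
total                      60     100.0
```

Sixty loci were simulated with background ω = 0.2 and six loci whose
hybrid branches evolved under ω = 4.  The cascade recovered all six as
diversifying candidates (`demo/classification.tsv` lists them as loci
00000–00005); three background loci were removed by the intraspecific
polymorphism filter, the expected false-positive mode when a low-divergence
pair happens to draw mostly nonsynonymous changes.  Per-sample
heterozygosity (`demo/het_samples.tsv`) averages 1.96–2.06%, matching the
simulated 2% heterozygous-site density, and `demo/stage_counts.json`
tallies the reproduction-linked GO terms of the annotated loci by
reproductive stage.

Every stage can also be run separately (`aposcan simulate`, `curate`,
`trim`, `dnds`, `filter`, `het`, `identity`, `go`) on the previous stage's
files; each writes a manifest with the seed, parameters and input hashes.
Filter thresholds are overridable (`aposcan filter --pp-max 1.0
--intra-max 1.0 --hh-max 4.0 --ph-min 1.0`).

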