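# rsnpscan

Prioritize candidate **regulatory SNPs** (rSNPs): single-nucleotide
variants that fall inside a predicted transcription-factor binding
site (TFBS) and change how well that site matches its binding model.
Such variants can alter a factor's binding affinity and, downstream,
the expression of the regulated gene. `rsnpscan` is a library plus
command-line tool for scanning both alleles of each variant against a
library of binding-site models and ranking variants by the score
change they induce — a screening aid for choosing which variants to
take into experimental validation, aimed at researchers analyzing
promoter variants, GWAS hits or site-directed mutagenesis panels.

## Method

A binding-site model is a position-specific log-odds matrix (PSSM)
built from an alignment of known sites. With counts *c<sub>jb</sub>*
for base *b* at column *j*, pseudocount *α* and background
probabilities *q<sub>b</sub>*:

```
p_jb = (c_jb + α·q_b) / (Σ_b c_jb + α)        M_jb = log10(p_jb / q_b)
```

A window *w* of the model's width scores `S(w) = Σ_j M[j, w_j]`; it is
a **hit** when `S(w) > 0` (a negative score means the window is not
considered a real site). Both strands are scanned at every position.

For each variant the two allele sequences are scanned over the windows
covering the variant, and hits are matched on (model, strand, start)
into **hit pairs**:

* both alleles hit, equal scores → unaffected, dropped;
* both alleles hit, different scores → **score change** `Δ = |S_wt − S_mut|`;
* one allele hit only → singleton pair, `Δ =` the known hit's score
  (the sub-threshold score is unknown and assumed 0), a lower bound on
  the true impact — the site is created (*gain*) or deleted (*loss*).

Since scores are base-10 log-odds, `Δ ≥ 2` means the site is at least
100× more (or less) likely under one allele; such pairs are flagged
significant. Per-model percentile thresholds calibrated against the
background score distribution make hit-quality cutoffs comparable
across models. Results can be filtered, sorted, annotated with
conservation, and exported as delimited text, alignments, BED or GFF.

## Worked example

Build an Sp-1-style GC-box model from 50 aligned sites, then ask what
a C→T substitution inside a promoter's GC-box does to it:

```bash
rsnpscan run --models models.tsv --fasta promoter.fasta \
             --variant "485C>T" --sort score_change -o pairs.tsv
```

stderr summary:

```
variants analyzed: 1 (of 1; 0 skipped)
hit pairs displayed: 1 out of 1
significant pairs (score change >= threshold): 1
```

`pairs.tsv`:

```
#variant_id  notation  wt_score  mut_score  score_change  model_id  factor_name  strand  chrom  start  end  conserved  significant
485C>T       C485T     5.92134   3.61814    2.3032        SP1.1     Sp-1         +       .      481    490  no         yes
```

The wildtype GC-box scores 5.92; the T allele still scores above 0
(3.62) but loses 2.30 log10 units — the mutant sequence is ~200×
less likely to be a real Sp-1 site, so the pair is flagged
significant and the variant is a strong rSNP candidate. Had the
mutant window dropped below 0, the pair would instead be reported as
a site deletion with score change 5.92 (the missing score treated as
0, a conservative lower bound).

Variants can also come from a TSV table, a (SNV-only) VCF, a
user-supplied rs-ID lookup table, or base-by-base comparison of a
second, mutant sequence (`--mut-fasta`). Positions may be written
absolute or relative to the TSS/ATG (promoter convention, no
position 0: `A-26G` is 26 bp upstream of the anchor). See
`rsnpscan --help` for the `build`, `calibrate`, `scan`, `diff`,
`run` and `simulate` subcommands.

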