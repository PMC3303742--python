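# Methods

## Model and statistic

`rsnpscan` evaluates the impact of a single-nucleotide substitution on
predicted transcription-factor binding sites. Binding preferences are
represented as position-specific log-odds matrices. From per-column
observation counts `c[j][b]` (tallied from an ungapped alignment of
known sites, or read from a JASPAR-style count matrix) the emission
probability is estimated with background-weighted Dirichlet smoothing

    p[j][b] = (c[j][b] + α·q[b]) / (rowsum[j] + α)

where `q` is the background mononucleotide distribution and `α` the
pseudocount mass. The matrix entry is `M[j][b] = log(p[j][b]/q[b]) /
log(base)`. A window of the model's width scores as the sum of its
per-column entries; columns are treated as independent, as in all PWM
scoring. The model assumes binding affinity is additive over
positions — cooperative or flanking effects are not represented.

A window is a *hit* when its score strictly exceeds the model's hit
threshold. The default threshold is 0: under the log-odds reading, a
non-positive score means the window is no more likely under the motif
than under the background, i.e. not a credible site.

For a variant, the wildtype and mutant sequences are scanned over
exactly the windows covering the variant position, on both strands
(minus-strand hits are scored on the reverse-complement and reported
in forward coordinates). Hits are matched across alleles on the key
(model, strand, window start) — valid because substitutions preserve
length. The *score change* of a matched pair is the absolute score
difference. When only one allele yields a hit, the other window's
score is below threshold and is treated as unknown and assumed 0, so
the score change equals the surviving hit's score. This is a
deliberate lower bound: using the raw sub-threshold (possibly very
negative) score would overstate confidence in the tail of the score
distribution, where PWM scores are least meaningful. The rule is
applied even when the raw score is computable.

Because a single substitution touches one column per window, the
score change of a pair where both windows remain hits has a closed
form: `|M[k][alt] − M[k][ref]|` at the variant's column `k` (alleles
read on the model strand). The test suite verifies the pipeline
against this identity on every simulated truth record.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `log_base` | 10 | base of the log-odds; with base 10, a score change of 2 = 100-fold likelihood-ratio change. Base 2 reproduces bit-score conventions. |
| `pseudocount` | 1.0 | total smoothing mass per column, distributed by the background. Zero is allowed only for strictly positive counts. |
| background | uniform (0.25 each) | null model; can be estimated from a supplied sequence's mononucleotide frequencies. |
| `hit_threshold` | 0 | strict lower bound for reporting a window as a hit (score units). |
| significance threshold | 2 | score change at or above which a pair is flagged (inclusive, direction-independent). A prioritization aid, not a hypothesis test. |
| percentile `sample_size` | 10 000 | background windows drawn per model when calibrating percentile thresholds. |

Percentile calibration draws i.i.d. windows from the background and
stores the full sorted sample; quantiles are evaluated by type-7
linear interpolation (the convention matters — other estimators give
different cutoffs at small samples). Calibration is exact for the
stored knots and deterministic for a fixed seed.

## Coordinate conventions

Three position systems are supported: absolute (1-based), relative to
the transcription start site, and relative to the A of the start
codon. Relative systems follow the promoter convention with no
position 0: +1 is the anchor base and −1 the base immediately 5' of
it. On minus-strand genes relative positions count against the
genomic direction (+2 lies at anchor−1). Conversions are bijective
and round-trip exactly. Region strings (`chrN:xxx-yyy`) are 1-based
inclusive; BED output converts to 0-based half-open; GFF stays
1-based inclusive.

Variant inputs: compact notations (`posA>B`, `AposB`), a TSV table
(`id pos ref alt`, with bare rs IDs resolved through a user-supplied
lookup table), a minimal VCF (SNVs only; indels and MNVs are skipped
with a warning, multi-allelic records expand to one variant per
alternate allele), or base-by-base comparison of an equal-length
mutant sequence. Each variant is analyzed independently on the
otherwise-wildtype sequence; haplotype combinations are out of scope.
A declared reference allele that disagrees with the sequence is a
hard error at the operation level and a logged skip at the pipeline
level.

## Synthetic studies and what they show

The generator (`simulate_library` / `simulate_study`) emulates a
motif-scanning study with known answers. Each simulated factor gets
an alignment of 50 sites whose bases match a random consensus with
probability `0.25 + 0.75·ic` (information content `ic`, default 0.9);
models are built from these alignments with the default pseudocount
and background. At 50 sites and `ic = 1` a monomorphic column spans
≈ 2.30 log10 units between its best and worst base, so a single-base
disruption of a planted site produces a score change at or above the
significance mark — the regime the method is meant to detect. The
defaults were fixed once, from this design argument.

A background sequence is drawn from the background distribution;
consensus sites are planted non-overlapping, each at least one
maximum model width away from its neighbours, on a random strand.
Disrupting SNVs substitute the worst-scoring base at the most
informative column of a planted site; neutral SNVs land at least one
maximum model width away from every planted site. For every variant
the generator emits per-(model, strand, window) truth records
computed by an intentionally naive per-column reference scorer plus
the pairing rule — an oracle independent of the vectorized scanner.

What passing these checks shows: the scanner, pairing arithmetic and
reporting are correct, and planted effects of known size are
recovered and ranked above background. What they do not show:
performance on real genomes, where binding sites are degenerate, the
background is non-uniform and autocorrelated, models are imperfect,
and most high-scoring windows are not functional sites. Score change
ranks candidates; it does not measure regulatory effect size.

The reference study used by the tests and the acceptance script is
10 kb with 10 models (widths 8–12), 25 planted sites, 25 disrupting
and 25 neutral SNVs — small enough to run in seconds while giving
every stage (both strands, singleton and double pairs, background
chance hits) realistic exercise.

## Numerical and edge-case choices

* Windows containing any non-ACGT character are skipped entirely
  (never scored 0), so masked or ambiguous regions cannot produce
  fake neutral hits.
* Hit thresholds are strict (`score > threshold`); identical-score
  matches across alleles are dropped by exact float equality, which
  is safe because unchanged windows produce bitwise-identical sums.
* Minus-strand scores are computed by scanning forward with the
  reverse-complemented matrix; this reverses summation order and can
  differ from a naive reverse-complement scan by ~1e-15, which is why
  oracle tests compare scores at 1e-9 rather than bitwise.
* A site whose start position shifts under the variant is reported as
  one loss pair plus one gain pair (the matching key is exact); no
  heuristic "shift" merging is attempted in the core.
* `best_per_variant` ties break by higher maximum hit score, then
  lexicographically smaller model ID, so output is deterministic.
* Sorting is stable; magnitudes (score, score change) sort
  descending, positions and names ascending.
* BED scores scale the score change by 250 and cap at 1000 (browser
  display range).

## Known limitations

* PWM additivity: no dinucleotide dependence, no profile-HMM scoring
  (the model TSV format and scanner interface would admit an
  alternative scorer, but none is bundled).
* SNVs only; indels change window framing and are out of scope.
* The significance flag is a fixed likelihood-ratio heuristic, not
  calibrated to a false-discovery rate.
* rs-ID resolution requires a user-supplied lookup table; no external
  database access of any kind.
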