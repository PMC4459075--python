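# Methods

`cosmidbias` studies a compositional artifact of large-insert (cosmid/fosmid)
metagenomic libraries: after cloning in an *E. coli* host, the library's
sequence composition can shift several percent GC away from the source
community. The package implements the analysis chain needed to interrogate
one mechanistic hypothesis — that clones are lost roughly in proportion to
how much *constitutive transcription* their insert can initiate in the host,
so that a genome's density of sigma-70 (rpoD) consensus promoter sequence,
for which GC content is partly a proxy, predicts its depletion — together
with a generative simulator of the library-construction process on which the
whole chain can be exercised with known ground truth.

## Consensus motif model and matching semantics

A sigma-factor consensus is modeled as ordered conserved blocks interleaved
with bounded variable-length spacers. A conserved position is a set over
{A,C,G,T} (singleton = fixed base, `[A/T]` = degenerate class); a spacer
position matches any base including N, while N never satisfies a conserved
position. Five built-in motifs are provided:

| name    | pattern                                  | role |
|---------|------------------------------------------|------|
| rpoD    | `TTGACA N15-19 TATAAT`                   | sigma-70 housekeeping consensus (−35, spacer, −10 Pribnow box) |
| rpoE    | `GGAACTT N15-19 TCAAA`                   | control (sigma-24) |
| rpoH    | `TTG[A/T][A/T][A/T] N13-14 CCCCAT[A/T]T` | control (sigma-32) |
| rpoN    | `TGGCA N7 TGC`                           | control (sigma-54, GC-rich) |
| sigABfr | `TTTG N19-21 TA N2 TTTG`                 | control (*Bacteroides* primary sigma factor, not recognized by *E. coli*) |

Matching is **leftmost, greedy, non-overlapping**: scanning proceeds left to
right; at a given start the longest admissible spacer vector that completes a
match is reported (earlier spacers take priority), one hit per start; after a
hit, scanning resumes at its end. These are the default semantics of standard
bounded-repetition pattern engines, and the implementation uses one (Python
`re` with greedy `{m,n}` quantifiers), but the contract is defined
independently of the engine and the test suite verifies exact agreement with
a brute-force candidate-enumeration oracle across all motifs, strands, and GC
regimes. The choice matters: overlapping counting would give systematically
higher hit counts. Both strands are scanned by default (insert orientation in
a vector is random); minus-strand hits are reported in forward coordinates.
Hits are confined to single reads or contigs — reads are never joined.

Dataset-level promoter content is reported as hits per Mb, with megabases
counted once regardless of strand mode; the normalization unit is a package
convention (any per-amount-of-data unit would do).

### Chance background

For i.i.d. sequence with P(A)=P(T)=(1−gc)/2 and P(G)=P(C)=gc/2, the expected
hit rate is (number of admissible spacer-length combinations) × Π
P(base ∈ position-set) per position, × 10⁶ per Mb, × 2 for both strands.
Overlap corrections are ignored — adequate in the rare-motif regime that all
five motifs occupy (≲ tens of hits per Mb). For rpoD at 50 % GC this gives
2·5·10⁶/4¹² ≈ 0.596 hits/Mb; because the consensus has ten A/T and two G/C
conserved positions, the rate at 30 % GC exceeds the rate at 70 % GC by
(0.35/0.15)⁸ ≈ 880-fold. This closed form is the quantitative version of the
observation that AT-rich genomes look promoter-dense to *E. coli* purely by
chance. A "hit" here means consensus-level identity only; no claim is made
about promoter strength (no PWM or thermodynamic scoring — out of scope).

## Host/vector subtraction

A read is removed iff its full sequence occurs exactly, 100 % identity over
the whole read length on either strand, in one of the supplied references
(hash-set membership of every reference window of the read's length;
references flagged circular are indexed across the origin junction). This is
the strictest reading of a "conservative 100 % identity" screen: a local
aligner at 100 % identity may also remove perfect partial matches, so counts
from this module are a lower bound relative to partial-span screens. Reads
containing N are never removed; a read matching several references is
attributed to the first in the provided order (host before vector by
convention) and counted once, so report counts always sum to the input.

## The library-construction simulator

The generative stand-in reproduces the pipeline stages with truth labels:

1. **Community genomes** — i.i.d. bases at a target GC, with a requested
   number of rpoD consensus sites (`TTGACA` + random 15–19 nt spacer +
   `TATAAT`, random strand) overwritten at non-overlapping uniform positions.
   The scanner finds every plant by construction; the genome records its
   *measured* (scanned) count, which can exceed the planted count through
   chance background hits.
2. **Crude extract** — fragments pick a source genome with probability equal
   to its relative abundance (defined as share of community DNA), then draw a
   length from a short "debris" distribution with probability
   `debris_fraction` (default 0.3; crude DNA preparations show a smear of
   sheared material) and otherwise from a high-molecular-weight distribution
   (default uniform 30–100 kb); starts are uniform, truncated at genome ends.
   Length distributions are uniform within their ranges — a deliberate
   simplification; only the location of the ranges relative to the selection
   window matters for the analyses here.
3. **Size selection** — exact closed-window length filter, default 40–70 kb
   (a pulsed-field electrophoresis cut).
4. **Cloning with promoter-dependent loss** — each fragment survives
   independently with probability exp(−λ·k), where k is its both-strand rpoD
   consensus count and λ ≥ 0 (default 1.0) is the per-promoter loss rate.
   The mechanism by which constitutive transcription destabilizes clones has
   no established functional form; an independent per-site hazard is the
   simplest monotone choice and makes λ identifiable from the truth table.
   k counts both strands because insert orientation is random. No empirical
   magnitude for λ is available; analyses treat it as a free parameter and
   rely on self-consistency (recovery) rather than an external value.
5. **Sequencing** — error-free 90-base paired-end reads from ~350 bp
   templates (mate gap 170), sampled over fragments weighted by length;
   `origin_label` carries the source genome. Error-free reads keep the
   subtraction and scanning tests exact; uniform substitution noise is
   opt-in.

Every stage is deterministic given the top-level seed (per-stage child seeds
are derived and logged). Size selection partitions its input; cloning's
retained + lost = input.

One internal tension in the study conditions is acknowledged: a 40–70 kb
selection window is wider than a ~28 kb mean insert. Both the window and the
fragment-length distributions are configurable so either regime can be
simulated; defaults follow the selection-window description.

### λ recovery

`estimate_retention_rate` groups the fragment truth table by k and regresses
−log(p̂ₖ) on k through the origin with inverse-variance weights n·p̂/(1−p̂)
(the delta-method variance of −log p̂ under binomial survival). k = 0 groups
carry no information about λ; groups with degenerate survival (p̂ ∈ {0,1})
have no finite variance estimate and are excluded. At ≥ 2,000 fragments with
k̄ ≈ 1.5–2 the estimator's standard error is ≈ 0.03 at λ = 1.

## Bias statistic and predictor comparison

Per-genome abundance profiles (percent, summing to 100) are computed from
read truth labels — a stand-in for read-based taxonomic profiling, which is
out of scope. Bias is the fold change of percent abundance, cosmid library /
crude extract, reported with its log10 ("depicted on a log scale" is the
natural presentation; base 10 is the package's choice). Genomes absent from a
sample get a sentinel (CE_0 / CL_0, CE_0 taking precedence) instead of a fold
change; sentinel records are excluded from correlations — including them
would require an arbitrary pseudo-abundance — and the excluded counts are
always reported.

`correlate_bias` reports Pearson and Spearman correlations of log10 fold
change against percent GC and against rpoD consensus density per Mb (raw
counts are also exposed; per-Mb is primary since genome sizes differ),
requiring ≥ 3 sentinel-free records. `fragments_per_genome` is the tiling
arithmetic (genome length / mean insert length, rounded): a 2.25 Mb genome at
~28 kb inserts is ~80 fragments, so a genome with tens of consensus sites
leaves few insert-sized windows promoter-free.

## Canonical studies (`cosmidbias.studies`) and problem sizes

The packaged studies fix desk-scale conditions under which each signature is
separated from sampling noise:

* **Background Monte-Carlo**: 100 × 100 kb i.i.d. replicates; observed mean
  hits/Mb vs the closed form, judged at 3 standard errors.
* **GC gradient** (`gc_gradient_params`): four 300 kb genomes at 35/45/55/65 %
  GC with planted rpoD densities 60/40/20/0 /Mb (AT-rich = promoter-dense),
  600 fragments, 35 % debris, 5,000 read pairs per stage. With λ = 0 all
  stages agree in GC (between-fragment GC spread gives ≈ 0.7 points standard
  error on a stage difference, so agreement is judged at 2.5 points); with
  λ = 1 the library shifts ≈ +8 to +9 GC points.
* **Promoter contrast** (`promoter_contrast_params`): six 2 Mb genomes at
  equal 38 % GC, half planted at 150 rpoD sites/Mb, 2,000 fragments, 30,000
  read pairs per stage. Control-motif rates are dominated by a handful of
  genomic sites resampled by reads, so genomes are large and read depth
  moderate to keep that clustering noise (±0.7 log10 with pseudocounts) well
  below the rpoD depression (≈ −1.5 to −1.9 log10). Hit-rate ratios use a
  0.5 pseudocount.
* **Bias correlation**: ten 250 kb genomes, GC ~ U(0.40, 0.65) and planted
  density ~ U(0, 40)/Mb independent, λ = 1, 400 fragments, 10,000 read pairs.
  Spearman |bias ~ rpoD/Mb| exceeds |bias ~ GC| in ≳ 95 % of replicates.
* **λ recovery**: one 400 kb genome at 300 sites/Mb, 2,500 × 6 kb fragments
  (k̄ ≈ 1.8 gives several informative k groups); λ recovered well within 15 %.

Passing these studies shows the chain is internally consistent under the
generative model; it does **not** show that real libraries follow an
exp(−λk) loss law, that real communities look like i.i.d.-plus-plants
genomes, or that consensus identity equals promoter activity. The simulator
omits sequencing-error profiles, chimeras, amplification bias, vector
read-through, and gene-product toxicity.

## Conventions and degenerate inputs

Coordinates are 0-based half-open throughout. Sequences are uppercased on
ingestion and IUPAC ambiguity codes other than N map to N (keeps the scanner
alphabet closed). Percent GC excludes N from numerator and denominator and is
undefined (error) on all-N input; it is printed to one decimal in summaries.
Forward and reverse read files of a paired-end dataset are treated as
separate datasets. Empty scan input, a zero-base dataset, fewer than three
correlatable genomes, non-positive tiling lengths, and unplaceable plant
requests all raise errors rather than returning silent defaults. All TSV
outputs of the CLI carry `#` headers with version, config hash, and seed; the
`bias` subcommand emits both the per-genome records and the correlation
report (no separate `report` command).
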