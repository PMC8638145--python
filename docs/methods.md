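# Methods

`prolaminkit` characterizes the prolamin (gliadin and glutenin) gene
family of a Triticeae genome: it finds candidate loci by nucleotide
homology, classifies each gene into a subfamily, decides whether it can
still encode a complete storage protein, computes molecular weight and
isoelectric point for the functional proteins, groups tandem-duplicated
copies, chains micro-collinear blocks between genomes, profiles
celiac-disease (CD) epitopes, and summarizes developmental expression
from a count matrix. A synthetic-genome generator plants known truth for
every one of these stages so the whole pipeline is testable offline.

## Locus discovery

Known prolamin coding sequences are used as nucleotide queries against
the genome in a seed–chain–extend search. Exact k-mers (default k = 11)
are looked up in a sorted-array index of the genome; seeds that share a
diagonal band are chained; chains whose projected genomic windows
overlap are pooled (prolamin repeat domains produce off-register seed
clouds, and extending a partial chain would clip the alignment window);
each pooled chain is extended by a glocal affine-gap alignment — the
query aligned end-to-end, the genomic window free at both ends — with
blastn-like scores (match +1, mismatch −2, gap open −5, extend −2).
Because one chain over a tandem array can span several gene copies, the
seeds left of and right of each reported alignment are re-queued, so
every copy in an array is extended in turn.

Hits are filtered by an expected-random-hit count of Karlin–Altschul
form, `E = K · m · n · exp(−λS)`, with λ solved exactly for the score
matrix over uniform base frequencies (λ ≈ 1.333 for +1/−2), K fixed at
0.3 as an order-of-magnitude constant, m the query length and n the
total genome length. The default cutoff is 1e−10, the conventional
stringent threshold for cross-species gene-family searches. Two
practical guards keep the search well-behaved on repeat-rich targets:
k-mers with more than 150 genomic occurrences are not used as seeds
(polyglutamine and proline-rich codon runs would otherwise seed every
prolamin locus against every query), and a chain must hold at least 4
seeds (chance pairs are common in composition-matched background; four
co-linear seeds essentially never are).

Overlapping hits on one chromosome and strand are merged into candidate
loci when their spans lie within 2 kb (prolamin genes are intronless and
compact); each locus reports the longest complete open reading frame
(ATG to stop) within ±1 kb. When a gene annotation is supplied, loci are
matched to the gene models they cover and coding sequences are taken
from the annotation; the ORF is a fallback for unannotated genomes.

The identity a hit reports counts matches over all alignment columns,
including internal gap columns; terminal overhangs are free and
excluded. This is one convention among several; it is stated here
because printed identity values are not comparable across conventions.

## Subfamily classification and pseudogene calling

Classification uses an explicit rule set — repeat-unit motif counts,
whole-protein cysteine count, length range, and subfamily-specific
signatures — as a reproducible stand-in for classification by curated
homology:

| subfamily | repeat motif (min count) | cysteines | length (aa) | extra signature |
|---|---|---|---|---|
| alpha | `PQPQP[FY]` (5) | 5–7 | 250–350 | two polyglutamine tracts ≥ 6 Q |
| gamma | `PQQP[FY]PQ` (5) | 8–9 | 250–350 | — |
| omega | `PQQP[FY]` (8) | 0–1 | 300–450 | — |
| LMW | `[QP]QQPPFS` (3) | 7–9 | 280–400 | MKTF… signal, SHIPGL mature start |
| HMW x/y | `GYYPTS|PGQGQQ` (15) | 3–5 / 5–8 | 600–900 | x: < 5 C in first 120 aa; y: ≥ 5 |
| delta | `QQPQQ` (3) | 6–7 | 150–280 | no alpha-type repeat region |

The highest-scoring satisfied rule wins (score = motif count over the
rule's minimum; ties break in a fixed subfamily order). Every threshold
is a configuration value. A translation that satisfies no rule — typical
for badly degraded pseudogenes — falls back to the subfamily hint of its
best-scoring homology query, the same homology-first logic a manual
curation applies.

A gene is a pseudogene when its CDS cannot produce a complete protein;
the defect list records which test failed: `no_start` (first codon not
ATG), `internal_stop` (premature stop; rendered as X in the translation
with its codon index recorded), `no_terminal_stop`, `frameshift` (length
not a multiple of 3), `structure_incomplete` (repeat-motif evidence
below the subfamily minimum). Codons containing N translate to X and
never to a stop, keeping the calls conservative under ambiguous
sequence. The pseudogene rate of a subfamily is pseudogenes over all
genes, reported at one decimal with round-half-up to match conventional
printed precision.

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da); the isoelectric point is the zero of the
Henderson–Hasselbalch net-charge function under the Bjellqvist pKa set
(the one behind the familiar web pI calculator, including the
residue-specific N-terminal and C-terminal exceptions), found by
bisection to 0.01 pH units. The charge function is strictly decreasing
and changes sign on [0, 14] for any peptide with free termini, so the
bracket is always valid. Both the mass table and the pKa set are plain
data and swappable; printed MW/pI values are pKa-set dependent.

## Tandem duplication

Two genes are a tandem pair when all three rules hold strictly: same
chromosome and less than 100 kb apart (inner gap, end of the upstream
gene to start of the downstream one, 0 if they overlap); the aligned
region covers more than 70% of the longer sequence; and the aligned
sequences are more than 70% identical. Identity and coverage come from a
free-end-gap global alignment of the CDS nucleotides. The relation is
closed transitively — if A–B and B–C qualify, {A, B, C} is one cluster
even when A–C fails — so clusters are connected components of the
tandem-pair graph. Tandem proportions are reported with explicit
numerator (genes in clusters of size ≥ 2) and denominator (subfamily
size), because printed proportions can hide the denominator choice.

## Micro-collinearity

Between two ordered gene lists, reciprocal-best identity pairs (with an
identity floor of 50% and coverage above 50%, screening out
cross-subfamily pairings) become anchors. Maximal strictly monotone
chains are peeled off greedily, longest first — forward (both indices
increasing) preferred over inverted (second index decreasing) on ties,
lexicographically smallest chain on residual ties, making the
decomposition deterministic — until no chain of length ≥ 2 remains.
Left-over anchors are reported as isolated genes, the pattern a
transposed or singleton copy produces in real cross-genome comparisons.

## CD epitope profiling

Scanning is a literal, overlap-aware substring count over the deduced
functional proteins only: every start position of an exact occurrence
counts once, so the proteolysis-resistant 33-mer fragment
(`LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF`) by itself contains one
DQ2.5-glia-a1a, two DQ2.5-glia-a1b and three DQ2.5-glia-a2. No
deamidation or mismatch model is applied. The default table holds the
six classic alpha-gliadin entries; two spellings of DQ2.5-glia-a3
circulate in the literature (9-mer `FRPQQPYPQ`, 10-mer `FRPQQQPYPQ`) —
the 9-mer is active by default and the 10-mer ships as a selectable
constant. Genome summaries report per-epitope carrier fractions over
functional alpha-gliadins, the fraction carrying a1a or a3, and the
fraction whose only epitope is DQ8-glia-a1/DQ8.5-glia-a1.

## Expression

TPM divides each count by the gene's effective length (spliced CDS
length — prolamin genes are intronless) and rescales every sample to
1e6. Stage profiles average the three replicates per stage and label the
trajectory: `rise_then_fall` when an interior peak has both neighbors at
least 20% below it (the storage-protein burst peaking around the
half-grain stage), `rising` when means are non-decreasing to the last
stage within a 5% step tolerance, `flat` when max/min ≤ 1.5, else
`other`. The 20% and 1.5 thresholds are configuration values chosen to
separate the planted trajectory shapes by a wide margin; they have no
privileged biological meaning.

## The synthetic study conditions

The generator is the package's ground truth and its defaults are the
study conditions every acceptance number is measured under:

* **Gene grammars.** Each subfamily is generated as signal peptide +
  repeat domain + cysteine-bearing unique domains, satisfying its
  classification rule by construction. Repeat units cycle
  deterministically (real prolamin repeat domains are homogeneous), so
  cross-gene nucleotide divergence comes from synonymous codon choice
  and unit count; independently drawn same-subfamily genes sit near
  75–80% nucleotide identity, and array members derived from one base
  gene are pushed to a controlled divergence (default 5%) by synonymous
  codon churn, which never disturbs planted protein-level truth.
* **The E-genome complement.** 19 alpha-gliadins (a 10-array plus 5
  singletons on chromosome 6E and an isolated 4-array on 7E), 9 gamma
  (8-array + singleton), 19 omega (8- and 5-arrays + 6 singletons), 5
  LMW (2-array + 3 singletons) and one x- plus one y-type HMW glutenin
  on 1E. Pseudogenes are planted by exact count — 16/19 alpha (all four
  7E genes among them), 7/9 gamma, 9/19 omega, 1/5 LMW — cycling
  premature-stop, frameshift and lost-start defects, so the rates
  84.2% and 77.8% and the tandem fractions 14/19 = 73.7%,
  8/9 = 88.9%, 13/19 = 68.4% are deterministic consequences of the
  layout, not fitted quantities. The omega and LMW pseudogene counts are
  modelling choices (only the alpha and gamma rates are constrained by
  the study conditions).
* **Placement.** Array members sit 2.5–6 kb apart, separate placement
  units > 100 kb apart, so the planted arrays are exactly the sets the
  distance rule can join. Intergenic background is an order-2 Markov
  chain fitted to the gene set — uniform background would make homology
  specificity trivially easy.
* **Epitope repertoires.** Epitope peptides are spliced in after the
  signal peptide of chosen functional alpha-gliadins (with a serine
  spacer so a peptide's tail cannot combine with the repeat domain into
  an unplanned second epitope). Per-genome plans: A — 14 of 15
  functional alpha-gliadins carry a1a or a3 (93.3%); B — 2 of 7 carry
  DQ8 and nothing else (28.6%); D — all six types present, three genes
  carrying the full 33-mer; E — 2 of 3 carry DQ8 only. The A/B fractions
  are the study conditions; the D and E carrier counts beyond "all six
  types" / "one type only" are modelling choices.
* **Expression.** Six stages × 3 replicates of negative-binomial counts
  (variance m + φm², default dispersion φ = 0.1) around planted
  stage-mean shapes: a burst peaking at half-grain for alpha/LMW/omega
  and x-type HMW, rising to the grain stage for gamma and y-type HMW,
  low and flat for pseudogenes (base 4.0, roughly a tenth of the
  functional bases, keeping "functional ≫ pseudogene" while staying out
  of the count regime where a flatness call is statistically
  meaningless). The two functional gamma genes differ by a planted
  5.5× factor. 400 stage-constant background genes emulate the rest of
  the transcriptome: TPM is compositional, and without a stable
  denominator the storage-protein burst would flatten its own profile —
  the same reason real TPM is computed genome-wide.

What the generator does **not** emulate: transposable-element
landscapes, introns, segmental duplications, sequencing error,
alignment/quantification noise upstream of the count matrix, deamidation
variants of epitopes, and real promoter-level expression variation.
Passing tests therefore demonstrate that the pipeline's logic recovers
planted structure under controlled divergence and counting noise — not
that it is robust to assembly artifacts or annotation errors in real
genomes.

## Numerical choices and problem sizes

Alignment DP runs in float32 over integer scores (exact up to 2²⁴);
traceback tie-breaks prefer substitution over gap states
deterministically. Insertion–deletion adjacency is not modelled in the
affine DP; with any scheme where a mismatch is cheaper than two gap
openings it is never optimal. The pI bisection uses a bracket of
[0, 14] and tolerance 0.01. Percentages print at one decimal,
round-half-up.

The default test and acceptance runs use the full planted E genome
(~2.8 Mb over three chromosomes, 54 genes, seven query sequences),
chosen so a complete discovery-to-report cycle takes about a minute on
one CPU; the generator scales to larger layouts through
`SyntheticGenomeSpec`. Pattern-recovery rates are quoted at dispersion
0.01 (the ≥ 95% all-genes check) and at the study-level dispersion 0.1
for the functional subfamily patterns and the gamma fold; at φ = 0.1 the
irreducible stage-mean noise (CV ≈ √(0.1/3) ≈ 0.18) makes a max/min
flatness call on a six-point profile unreliable no matter how deep the
sequencing, which is a property of the statistic, not of the
implementation.

## Known limitations

* The subfamily rule set is a reproducible proxy for curation by
  homology; on real proteins with unusual domain architecture it will
  return `unclassified` rather than guess, and the homology-hint
  fallback then decides.
* The Karlin–Altschul K is a constant, not fitted for gapped alignment;
  the e-value surrogate is a filter, not a calibrated p-value.
* `beta`-gliadins are treated under alpha, and x/y HMW typing is by
  cysteine signature, not phylogeny.
* Tandem clustering aligns all same-chromosome pairs within the distance
  window; for gene families much denser than prolamin loci the O(n²)
  window alignment would need batching.
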