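# Methods

`mirpipe` re-implements, as a tested pipeline over fully synthetic data, a
small-RNA workflow for discovering known and novel miRNAs in two wheat
genotypes (salt-tolerant "ST" and salt-sensitive "SM") under control and
100 mM NaCl, classifying their salinity response, predicting mRNA targets,
and ranking enriched functional terms.  No real wheat data is used anywhere:
the simulator plants a complete experiment with known truth, which is what
the test suite and the acceptance script score against.

## Synthetic data model

`mirpipe.simulate` builds a random genome (default 60 kb, GC 0.50) and lays
out, left to right with a 320-bp gap:

* **miRNA precursors** (default 30; half copied into the known-mature
  reference): a 20–24-nt 5p arm, a 6–12-nt loop, and a 3p arm formed by
  reverse-complementing the 5p arm with a per-base substitution rate of 0.05.
  At least one substitution is always present — perfectly complementary arms
  would make the precursor an exact inverted repeat, so each arm read would
  align to both arms and be discarded as multi-mapped, which is also why
  real pipelines rarely see perfect duplexes.  Strand is random; both arms
  of "known" miRNAs enter the mature reference (as curated references do),
  plus a handful of decoy matures absent from the genome.
* **ncRNA decoy loci** (rRNA/tRNA/snRNA/snoRNA, 90–200 bp each) that source
  fragment reads for the ≥90%-overlap exclusion stage.
* **Transcripts** (default 60 × 600 nt) with 0–2 planted near-complementary
  target sites each, and a gene→term table over GO-style and pathway-style
  term ids.

**Counts.** A log-normal draw (σ = 0.8) sets per-miRNA control means; the
treated mean is the control mean × 2^(intended log2 fold change).  Per-arm
means follow a configurable 5p:3p ratio (default drawn in [0.9, 1.1]).
Counts are negative-binomial via a gamma–Poisson mixture with quadratic
overdispersion a (Var = m + a·m²; default a = 0.05).  `dispersion=0`
short-circuits to deterministic rounding of the means — the oracle mode used
by the parameter-recovery tests; `a → 0⁺` approaches Poisson, the sampling
model under which the exact conditional DE test is calibrated.

**Library composition.** Each library holds exactly `reads_per_library`
reads per pseudo-replicate (two replicates per library; collapsed counts are
averaged, which is why half-integer counts appear downstream).  The genome-
mappable pool (miRNA + ncRNA reads) has the *same size in every library*:
the miRNA budget is sized against the genotype with the largest aggregate
fold-change multiplier, and ncRNA fragments fill the pool's remainder (the
configured ncRNA fraction is a floor).  Equal mapped totals make the TPM
fold change of every miRNA equal its planted count fold change; without
this, strong asymmetric fold-change plans shift all measured log2 fold
changes by the log-ratio of mapped totals (a compositional bias TPM cannot
remove), which would systematically misclassify effects near the |log2fc|=1
boundary.  Random unmappable background fills each replicate to its exact
read total.  Reads are adapter-ligated (3' adapter appended, padded to a
50-nt instrument read), with configurable fractions of low-quality,
adapter-less and poly-A reads to exercise every cleaning rule.

What the generator does **not** emulate: sequencing errors inside the
insert, isomiR 5'/3' end variation, multi-locus miRNA families with
identical matures, gapped/spliced alignment, and genome-scale repeat
structure.  Passing the recovery tests therefore shows the pipeline's logic
is correct under its stated assumptions, not that it is robust to real-data
artifacts outside them.

## Pre-processing

The 3' adapter is located by exact match of its first 8 nt, then by a scan
allowing one mismatch in that seed.  A read is discarded — with a tally that
partitions all removals — when the adapter is absent, the 5' adapter occurs
internally, more than 10% of insert bases are below Q20, one base makes up
≥80% of the insert, or the trimmed length is outside 18–30 nt.  The
cleaning thresholds (Q20 rule, homopolymer 80%, adapter seed) are
configurable; retained tags are uppercase T-alphabet sequences.  Collapsing
produces one tag per distinct sequence with replicate-averaged per-library
counts.  Reported percentages are always recomputed from the counts next to
them and printed round-half-even to 2 decimals.  Note that the percentage
row of a published-style summary table need not reproduce from its own
printed counts (denominators before/after intermediate filters differ);
this package always reports 100·clean/raw.

## Mapping and annotation

Tags map to both genome strands allowing ≤2 mismatches.  Completeness comes
from the pigeonhole principle: any ≤2-mismatch hit of an 18+-nt tag has an
exact third, whose leading 6-mer is probed in an exact k-mer index; every
candidate offset is then verified by Hamming count.  Only the best
(fewest-mismatch) stratum is kept, and a tag whose best stratum holds more
than one hit is discarded as multi-mapped — the "-v 2 -best -strata -m 1"
contract.  An exhaustive Hamming scan over every offset is kept as an
independent oracle and the two are asserted identical on a 10-kb genome.

A mapped tag overlapping an annotated ncRNA interval over ≥90% of its
length (strand-aware; ties across classes resolved by a fixed precedence
rRNA > tRNA > snRNA > snoRNA > siRNA > phasiRNA > NOR) is categorized and
removed.  Survivors are compared to the mature reference ungapped, sliding
the shorter sequence within the longer for length differences ≤2; the
minimum-mismatch mature with ≤2 mismatches wins, ties breaking
lexicographically.  The mapped-read total per library (the TPM denominator)
counts reads of uniquely mapped tags.

## Hairpin folding and precursor evaluation

Folding is a Zuker-style interval dynamic program under a simplified
nearest-neighbour model: Watson–Crick and G:U stacking free energies
(standard published values to two decimals, completed by strand-reading
symmetry), length-dependent hairpin, bulge and internal-loop penalties with
Jacobson–Stockmayer log extrapolation, an affine multiloop cost
(3.4 + 0.4/branch + 0.4/unpaired kcal/mol), minimum hairpin loop 3 nt,
interior loops capped at 30 unpaired bases, no dangles or coaxial stacking.
The same energy function is exposed as an explicit-structure evaluator, and
an exhaustive enumerator of pseudoknot-free structures provides the oracle:
DP energy equals enumeration over ≥200 seeded sequences of length ≤12.
Traceback uses a fixed case order, so results are deterministic; the open
chain is always admissible, hence reported MFE ≤ 0.

Candidate precursors are excised around each unmatched unique hit twice —
tag as 5p arm (20 nt near flank, 150 nt far flank) and the mirror — then
folded.  Because the window carries ~150 nt of unstructured flank, MFE/AMFE/
MFEI are computed on the *trimmed* precursor: the maximal simple stem-loop
containing the mature, found by anchoring on the majority stem (the
contiguous partner cluster pairing the most mature bases) and ascending
single-child enclosing pairs while the interior gap stays ≤8 unpaired bases.
The trimmed sequence is re-folded and scored: MFE (kcal/mol, ×4.184 for the
kJ/mol filter), AMFE = MFE/length×100, MFEI = |AMFE|/GC%.  Duplex geometry is
valid when the mature lies on one arm (no loop overlap), ≥60% of its bases
pair, ≤4 mature bases are unpaired in the duplex, and mature/star unpaired
counts differ by ≤2; the star span follows the 2-nt 3' overhang convention.
These geometry thresholds are package choices (the upstream method cites a
predictor without printing its internals).

## Six-criterion calling

A candidate is called iff (1) TPM ≥ 100 in ≥1 library, TPM = count·10⁶ /
genome-mapped total; (2) mature length 20–24 nt; (3) both arms detected and
the 5p/3p or 3p/5p count ratio > 0.9 — read literally this is satisfied by
any positive pair (one of the reciprocal ratios always exceeds 0.9), so the
default reduces to "both arms detected"; a strict min/max > 0.9 mode is a
flag; (4) precursor MFE < −37 kJ/mol; (5) MFEI > 0.85; (6) valid hairpin.
Threshold senses are exactly as printed (≥, strict <, strict >).  Known
(reference-matched) miRNAs are accepted by identity and criteria 4–6 are
waived by default (flag-controlled); each arm of a known miRNA is its own
record, as mature references list them.  Novel tags are clustered by
overlapping best-precursor intervals; the most abundant tag is the mature,
and the cluster's precursor evaluation is the most hairpin-like one over
all member tags' windows (a star arm's window sometimes folds into the
cleaner stem-loop).  Every rejected candidate records its first failing
criterion in filter order.

## Differential expression

Per genotype, fold change is log2((TPM_T + c)/(TPM_CK + c)) with
pseudocount c = 0.01 TPM (both-zero → 0).  Significance is an exact
conditional binomial test: conditioning on n = treated + control counts,
the treated count is Binomial(n, N_T/(N_T+N_CK)) under the null; the
two-sided p sums all outcomes no more likely than the observed one (the
"minlike" convention).  This is the package's stand-in for count-based
two-library DE testing; replicate-averaged half counts are rounded
half-to-even first.  Classes: up iff log2fc ≥ 1 and p ≤ 0.01; down iff
log2fc ≤ −1 and p ≤ 0.01; otherwise unchanged (including log2fc = 0).  Raw
p-values are used — the class gate is deliberately not multiplicity-
adjusted.  Cross-genotype structure is reported as a 3×3 contingency and
per-class Venn counts over the shared miRNA universe.

## Targets and enrichment

Target scanning scores each transcript offset against the mature read
antiparallel: complementary 0, G:U wobble 0.5, mismatch 1, penalties doubled
at mature positions 2–13; hits need penalty ≤ 4.0 and ≤3 true mismatches,
and a miRNA with no qualifying site reports its single lowest-penalty site
as the putative target.  The cutoff 4.0 and the position-2–13 doubling are
the common plant-miRNA scoring convention, not values printed in the source
method.  Enrichment is hypergeometric (upper tail P(X ≥ k) for k of n
target genes against K of N universe genes), Bonferroni-corrected over the
terms represented in the target set, significant at corrected p < 0.05; the
rich factor is k/K.  The universe is every gene in the annotation table.
Pathway summaries keep the 20 smallest-p terms with p < 0.05, ties broken
by term id.

## Problem sizes and determinism

Default analysis runs use 30 miRNAs and 4×2×50k reads (~1 min end to end);
the parameter-recovery experiment uses 40 miRNAs (20 known / 20 novel),
100k reads per library, dispersion 0, intended log2 fold changes cycled
over {−2, −1.5, 0, +1.5, +2} (~2 min); the null calibration uses 1,000
miRNAs at near-Poisson dispersion.  All randomness flows from a single
integer seed through `numpy.random.default_rng`; identical seeds give
byte-identical FASTA/FASTQ/BED outputs and identical run summaries.

## Known limitations

* The energy model is deliberately reduced; absolute MFE values differ from
  full nearest-neighbour implementations, so the −37 kJ/mol and 0.85 MFEI
  filters are meaningful relative to this model's scale (planted hairpins
  clear them by a wide margin; random windows do not).
* The exact conditional test assumes Poisson-level within-library noise;
  with strong overdispersion between biological replicates it is
  anticonservative, which is why calibration is stated at dispersion → 0.
* Known-miRNA arm counts rely on the reference listing both arms; a
  one-armed reference entry leaves criterion 3 unevaluable for that mature.
* Genome mapping is ungapped and the index assumes chromosomes fit in
  memory; both are fine at the synthetic scale this package targets.
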