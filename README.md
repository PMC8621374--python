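# mirpipe

A small-RNA sequencing analysis pipeline for miRNA discovery and salinity
differential expression in two contrasting genotypes, exercised entirely on
synthetic data with planted ground truth.

Plant miRNAs (~21-nt regulatory RNAs excised from hairpin precursors)
reshape gene expression under salt stress.  A typical discovery study
sequences small-RNA libraries from control and NaCl-treated roots of a
tolerant and a sensitive cultivar, cleans and collapses the reads, maps them
to the genome, removes rRNA/tRNA/snRNA/snoRNA fragments, splits the rest
into reference-matched (known) and hairpin-supported (novel) miRNAs,
classifies each miRNA's salinity response per genotype, and interprets the
responders through their predicted mRNA targets.  `mirpipe` implements that
entire chain as a reusable, tested library — plus a simulator that generates
the whole experiment in silico so every stage can be validated against known
truth, since studies of this kind often deposit no raw data.

## The core methods

* **Novel-miRNA support** — candidate precursors are folded with a
  Zuker-style dynamic program under a simplified nearest-neighbour energy
  model and scored by minimum free energy (MFE, kcal/mol; filter applied in
  kJ/mol), the length-adjusted AMFE = MFE/L×100, and the minimal free energy
  index MFEI = |AMFE| / GC%, together with miRNA-like duplex geometry
  (mature on one arm, ≥60% paired, bounded bulges, 2-nt 3' overhang star).
* **Six-criterion calling** — TPM ≥ 100 in ≥1 library
  (TPM = C·10⁶/N, N = genome-mapped reads), mature length 20–24 nt, both
  arms detected with 5p/3p or 3p/5p ratio > 0.9, MFE < −37 kJ/mol,
  MFEI > 0.85, and a valid hairpin.
* **Differential expression** — per genotype,
  log2fc = log2(TPM_NaCl/TPM_control) with an exact conditional binomial
  test; up iff log2fc ≥ 1 and p ≤ 0.01, down iff log2fc ≤ −1 and p ≤ 0.01,
  otherwise unchanged.
* **Targets and enrichment** — complementarity penalty scanning (mismatch 1,
  G:U 0.5, doubled at mature positions 2–13, cutoff 4.0; best match kept
  when nothing passes), then hypergeometric term enrichment with Bonferroni
  correction and the rich factor k/K.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```sh
python analysis/01_simulate.py          # reference + 4 libraries -> results/data/
python analysis/02_run_pipeline.py      # full pipeline -> results/run/
python analysis/03_evaluate_recovery.py # score against planted truth
python analysis/04_null_calibration.py  # type-I calibration of the DE test
```

prints, for the default seed (7):

```
reference: 60,000 bp genome, 30 planted miRNAs (15 known), 20 ncRNA loci, 60 transcripts
called 44 miRNAs (30 known, 14 novel); 10 candidates rejected
  ST: down=14, unchanged=23, up=7
  SM: down=10, unchanged=23, up=11
planted-miRNA recovery: 96.7% (29/30); missed: mir-029
DE-class agreement, all intended effects: 80.0%
DE-class agreement, |log2fc| in {0, >=1.5}: 94.4%
null simulation, n=1000, seed=7: fraction with p <= 0.01 = 0.0070 (target <= 0.03)
```

Reading this: the pipeline re-identified 29 of the 30 planted miRNAs (the
30 known records are the two arms of 15 reference miRNAs).  Agreement with
the intended expression class is high for strong (|log2fc| ≥ 1.5) and null
effects; it is intentionally lower over *all* planted effects because the
default simulation also plants |log2fc| = 1 effects sitting exactly on the
class boundary and sub-threshold 0.5 shifts, which overdispersed counts can
push either way.  The null calibration shows the exact conditional test
holds its 1% level.

The same pipeline is scriptable via `mirpipe simulate|run|all` (one YAML
config, `--seed`, `--outdir`) for running on other simulated — or externally
provided — FASTQ + reference bundles.

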