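"""Ground-truthed simulator for a two-genotype salinity small-RNA experiment.

The generator builds a complete in-silico reference bundle — genome, ncRNA
annotation, mature-miRNA reference with family and species tables, transcript
set, gene-to-term table — and then four sequencing libraries (two genotypes x
{control, 100 mM NaCl}), each as two pseudo-replicates whose collapsed counts
are averaged downstream.  Every planted quantity (precursor interval, mature
arm sequences, per-library counts, intended log2 fold change and expression
class) is recorded in a :class:`GroundTruth` object so pipeline stages can be
scored against truth.

Counts follow a negative-binomial model: a log-normal abundance draw sets the
per-miRNA control mean, the treated mean is scaled by 2**(intended log2 fold
change), and reads are drawn gamma-Poisson with configurable overdispersion.
``dispersion=0`` degenerates to deterministic rounding of the means, the mode
used by parameter-recovery oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .util import revcomp, write_fasta

LIBRARIES = ("ST-CK", "ST-T", "SM-CK", "SM-T")
GENOTYPES = ("ST", "SM")
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")

#: intended per-genotype log2 fold changes cycled over miRNAs by default;
#: includes |lfc| >= 1 (clear up/down), sub-threshold shifts, and nulls.
DEFAULT_LFC_CHOICES = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment (defaults are the study conditions)."""

    seed: int = 7
    genome_length: int = 60_000
    n_true_mirnas: int = 30
    known_fraction: float = 0.5
    n_ncrna_loci: dict = field(
        default_factory=lambda: {"rRNA": 6, "tRNA": 6, "snRNA": 4, "snoRNA": 4}
    )
    n_transcripts: int = 60
    transcript_length: int = 600
    reads_per_library: int = 50_000
    n_replicates: int = 2
    # (length, weight) modes of the small-RNA length distribution; applied to
    # ncRNA fragments and background reads (mature arms are 20-24 nt)
    length_modes: tuple = ((19, 0.30), (21, 0.40), (24, 0.30))
    arm_len_range: tuple = (20, 24)
    loop_len_range: tuple = (6, 12)
    mismatch_rate: float = 0.05
    arm_ratio_range: tuple = (0.9, 1.1)  # 5p:3p expected-count ratio
    abundance_dispersion: float = 0.05
    abundance_sigma: float = 0.8  # log-normal spread of per-miRNA means
    background_fraction: float = 0.10
    ncrna_fraction: float = 0.15
    lowq_read_fraction: float = 0.02
    no_adapter_fraction: float = 0.01
    polya_fraction: float = 0.005
    qual_hi: int = 38
    qual_lo: int = 11
    read_length: int = 50
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    lfc_choices: tuple = DEFAULT_LFC_CHOICES
    de_plan: dict | None = None  # {mirna_id: {"ST": lfc, "SM": lfc}}
    gc_content: float = 0.5

    def validate(self) -> None:
        if self.n_true_mirnas < 1:
            raise ValueError("n_true_mirnas must be >= 1")
        if not 0 <= self.known_fraction <= 1:
            raise ValueError("known_fraction must be in [0, 1]")
        if self.reads_per_library < 1:
            raise ValueError("reads_per_library must be positive")


@dataclass
class PlantedMiRNA:
    mirna_id: str
    chrom: str
    start: int  # precursor interval, 0-based half-open
    end: int
    strand: str
    mature_arm: str  # which arm is the annotated mature
    mature_5p: str
    mature_3p: str
    known: bool
    lfc: dict  # genotype -> intended log2 fold change
    base_mean: float = 0.0
    arm_ratio: float = 1.0  # expected 5p:3p count ratio
    true_counts: dict = field(default_factory=dict)  # lib -> {"5p": n, "3p": n}

    @property
    def mature_seq(self) -> str:
        return self.mature_5p if self.mature_arm == "5p" else self.mature_3p

    def intended_class(self, genotype: str) -> str:
        lfc = self.lfc[genotype]
        if lfc >= 1:
            return "up"
        if lfc <= -1:
            return "down"
        return "unchanged"


@dataclass
class GroundTruth:
    mirnas: dict  # mirna_id -> PlantedMiRNA
    ncrna_intervals: list  # (chrom, start, end, strand, rna_class)
    target_sites: dict  # transcript_id -> [(mirna_id, start, end)]

    def to_json(self, path) -> None:
        data = {
            "mirnas": {
                mid: {
                    "chrom": m.chrom,
                    "start": m.start,
                    "end": m.end,
                    "strand": m.strand,
                    "mature_arm": m.mature_arm,
                    "mature_5p": m.mature_5p,
                    "mature_3p": m.mature_3p,
                    "known": m.known,
                    "lfc": m.lfc,
                    "base_mean": m.base_mean,
                    "arm_ratio": m.arm_ratio,
                    "true_counts": m.true_counts,
                }
                for mid, m in self.mirnas.items()
            },
            "ncrna_intervals": self.ncrna_intervals,
            "target_sites": self.target_sites,
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        mirnas = {
            mid: PlantedMiRNA(mirna_id=mid, **d) for mid, d in data["mirnas"].items()
        }
        return cls(
            mirnas=mirnas,
            ncrna_intervals=[tuple(x) for x in data["ncrna_intervals"]],
            target_sites={k: [tuple(s) for s in v] for k, v in data["target_sites"].items()},
        )


@dataclass
class ReferenceBundle:
    genome: dict  # chrom -> sequence (T alphabet)
    annotation: list  # BED6 rows (chrom, start, end, name, rna_class, strand)
    matures: dict  # mature_id -> sequence (known reference)
    family_table: "object"  # DataFrame: mature_id, family
    species_table: "object"  # DataFrame: family x species 0/1
    transcripts: dict  # transcript_id -> sequence
    gene_terms: "object"  # DataFrame: gene_id, term_id, domain
    truth: GroundTruth
    outdir: Path | None = None


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append("ACGT"[(("ACGT".index(c)) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(c)
    return "".join(out)


def _length_distribution(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Lengths 18..30 with extra mass on the configured modes."""
    lengths = np.arange(18, 31)
    w = np.full(len(lengths), 0.02)
    for length, weight in config.length_modes:
        w[length - 18] += weight
    return lengths, w / w.sum()


def build_reference(config: SimulationConfig, outdir=None) -> ReferenceBundle:
    """Construct the full reference bundle with planted ground truth.

    Raises ``ValueError`` if the genome is too short to host all requested
    loci without overlap.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    genome_arr = list(_random_seq(rng, config.genome_length, config.gc_content))
    chrom = "chr1"

    # --- lay out loci left to right with a safety gap ---------------------
    gap = 320
    cursor = gap
    mirnas: dict[str, PlantedMiRNA] = {}
    n_known = round(config.n_true_mirnas * config.known_fraction)
    lo_r, hi_r = config.arm_ratio_range
    for k in range(config.n_true_mirnas):
        mid = f"mir-{k + 1:03d}"
        arm_len = int(rng.integers(config.arm_len_range[0], config.arm_len_range[1] + 1))
        loop_len = int(rng.integers(config.loop_len_range[0], config.loop_len_range[1] + 1))
        arm5 = _random_seq(rng, arm_len, config.gc_content)
        arm3 = _mutate(rng, revcomp(arm5), config.mismatch_rate)
        if arm3 == revcomp(arm5):
            # at least one substitution: perfectly complementary arms would
            # make the precursor an exact inverted repeat, so each arm would
            # align to both arms and be discarded as multi-mapped
            p = int(rng.integers(2, arm_len - 2))
            alt = "ACGT"[("ACGT".index(arm3[p]) + int(rng.integers(1, 4))) % 4]
            arm3 = arm3[:p] + alt + arm3[p + 1 :]
        loop = _random_seq(rng, loop_len, config.gc_content)
        pre = arm5 + loop + arm3
        start, end = cursor, cursor + len(pre)
        if end + gap > config.genome_length:
            raise ValueError(
                f"genome_length={config.genome_length} too short for requested loci"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genome_arr[start:end] = list(pre if strand == "+" else revcomp(pre))
        if config.de_plan and mid in config.de_plan:
            lfc = dict(config.de_plan[mid])
        else:
            lfc = {
                g: float(config.lfc_choices[(2 * k + gi) % len(config.lfc_choices)])
                for gi, g in enumerate(GENOTYPES)
            }
        mirnas[mid] = PlantedMiRNA(
            mirna_id=mid,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            mature_arm="5p" if rng.random() < 0.5 else "3p",
            mature_5p=arm5,
            mature_3p=arm3,
            known=k < n_known,
            lfc=lfc,
            arm_ratio=float(rng.uniform(lo_r, hi_r)),
        )
        cursor = end + gap

    # --- ncRNA decoy loci --------------------------------------------------
    annotation = []
    ncrna_intervals = []
    for rna_class in NCRNA_CLASSES:
        for k in range(config.n_ncrna_loci.get(rna_class, 0)):
            length = int(rng.integers(90, 200))
            start, end = cursor, cursor + length
            if end + gap > config.genome_length:
                raise ValueError(
                    f"genome_length={config.genome_length} too short for requested loci"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"{rna_class}-{k + 1}"
            annotation.append((chrom, start, end, name, rna_class, strand))
            ncrna_intervals.append((chrom, start, end, strand, rna_class))
            cursor = end + gap

    genome = {chrom: "".join(genome_arr)}

    # --- mature-miRNA reference (known subset, both arms) -------------------
    matures: dict[str, str] = {}
    for m in mirnas.values():
        if m.known:
            matures[f"tae-{m.mirna_id}-5p"] = m.mature_5p
            matures[f"tae-{m.mirna_id}-3p"] = m.mature_3p
    # a few decoy matures absent from the genome, as a real reference has
    for k in range(5):
        matures[f"osa-decoy-{k + 1}"] = _random_seq(rng, 21, config.gc_content)

    # --- family and species-occurrence tables -------------------------------
    known_ids = sorted(matures)
    families = {}
    for i, mat_id in enumerate(known_ids):
        families[mat_id] = f"MIR{900 + (i % max(1, len(known_ids) * 2 // 3))}"
    family_table = pd.DataFrame(
        {"mature_id": list(families), "family": list(families.values())}
    )
    species = [f"sp{j + 1:02d}" for j in range(37)]
    fam_names = sorted(set(families.values()))
    occ = rng.random((len(fam_names), len(species))) < 0.4
    species_table = pd.DataFrame(occ.astype(int), index=fam_names, columns=species)
    species_table.index.name = "family"

    # --- transcripts with planted target sites ------------------------------
    transcripts: dict[str, str] = {}
    target_sites: dict[str, list] = {}
    mirna_ids = list(mirnas)
    for t in range(config.n_transcripts):
        tid = f"gene{t + 1:04d}.1"
        seq = list(_random_seq(rng, config.transcript_length, config.gc_content))
        sites = []
        n_sites = int(rng.choice([0, 0, 1, 1, 2]))
        for _ in range(n_sites):
            mid = mirna_ids[int(rng.integers(len(mirna_ids)))]
            mature = mirnas[mid].mature_seq
            site = _mutate(rng, revcomp(mature), 0.04)
            pos = int(rng.integers(50, config.transcript_length - len(site) - 50))
            seq[pos : pos + len(site)] = list(site)
            sites.append((mid, pos, pos + len(site)))
        transcripts[tid] = "".join(seq)
        if sites:
            target_sites[tid] = sites

    # --- gene -> term annotation -------------------------------------------
    domains = ["BP", "CC", "MF", "pathway"]
    terms = [(f"GO:{7000 + i}", domains[i % 3]) for i in range(24)] + [
        (f"ko{100 + i:03d}", "pathway") for i in range(8)
    ]
    rows = []
    for tid in transcripts:
        gene = tid.rsplit(".", 1)[0]
        k = int(rng.integers(1, 5))
        for term, domain in [terms[int(i)] for i in rng.choice(len(terms), k, replace=False)]:
            rows.append((gene, term, domain))
    gene_terms = pd.DataFrame(rows, columns=["gene_id", "term_id", "domain"]).drop_duplicates()

    truth = GroundTruth(mirnas=mirnas, ncrna_intervals=ncrna_intervals, target_sites=target_sites)
    bundle = ReferenceBundle(
        genome=genome,
        annotation=annotation,
        matures=matures,
        family_table=family_table,
        species_table=species_table,
        transcripts=transcripts,
        gene_terms=gene_terms,
        truth=truth,
        outdir=Path(outdir) if outdir else None,
    )
    if outdir:
        write_reference(bundle, outdir)
    return bundle


def write_reference(bundle: ReferenceBundle, outdir) -> None:
    """Serialize the reference bundle (FASTA/BED/TSV/JSON) into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", bundle.genome.items())
    with open(outdir / "ncrna.bed", "w") as fh:
        for chrom, start, end, name, rna_class, strand in bundle.annotation:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{rna_class}\t{strand}\n")
    with open(outdir / "precursors.bed", "w") as fh:
        for m in bundle.truth.mirnas.values():
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.mirna_id}\tprecursor\t{m.strand}\n")
    write_fasta(outdir / "matures.fa", bundle.matures.items())
    bundle.family_table.to_csv(outdir / "families.tsv", sep="\t", index=False)
    bundle.species_table.to_csv(outdir / "species.tsv", sep="\t")
    write_fasta(outdir / "transcripts.fa", bundle.transcripts.items())
    bundle.gene_terms.to_csv(outdir / "gene_terms.tsv", sep="\t", index=False)
    bundle.truth.to_json(outdir / "ground_truth.json")


# --------------------------------------------------------------------------
# count model and library simulation
# --------------------------------------------------------------------------


def draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Counts from the generator's negative-binomial model.

    ``dispersion`` is the quadratic overdispersion coefficient a in
    Var = m + a * m**2.  a = 0 degenerates to deterministic rounding of the
    means (the oracle mode); small a approaches Poisson sampling.
    """
    means = np.asarray(means, dtype=float)
    if dispersion == 0:
        return np.rint(means).astype(int)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means / shape)
    return rng.poisson(lam)


def simulate_null_counts(
    n_mirnas: int,
    *,
    seed: int,
    mean_scale: float = 500.0,
    sigma: float = 0.8,
    dispersion: float = 1e-6,
):
    """Paired control/treated counts with intended fold change 0.

    Used for null calibration of the differential-expression test: per-miRNA
    means are log-normal, both conditions share the mean, and sampling is
    near-Poisson by default (the within-library noise model the exact
    conditional test assumes).  Returns a DataFrame with columns
    control/treated.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    means = mean_scale * rng.lognormal(0.0, sigma, n_mirnas)
    control = draw_counts(rng, means, dispersion)
    treated = draw_counts(rng, means, dispersion)
    return pd.DataFrame({"control": control, "treated": treated})


def simulate_libraries(
    bundle: ReferenceBundle, config: SimulationConfig, outdir=None
) -> dict:
    """Simulate the four libraries as FASTQ pseudo-replicates.

    Returns ``{library_id: [fastq_path_rep1, ...], "truth_counts": DataFrame}``;
    FASTQ files are written under `outdir` (required).  Each replicate holds
    exactly ``config.reads_per_library`` reads: mature-arm reads
    (negative-binomial counts around intended means; treated mean = control
    mean x 2**lfc), ncRNA-locus fragments, and random background, each with
    the 3' adapter appended and padded to the instrument read length.
    """
    import pandas as pd

    if outdir is None:
        raise ValueError("outdir is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    total = config.reads_per_library
    mirna_budget = round(total * (1 - config.background_fraction - config.ncrna_fraction))
    # Every library receives the same genome-mappable read total (miRNA +
    # ncRNA); the ncRNA pool absorbs whatever the miRNA fold-change plan does
    # not use (configured ncrna_fraction is its floor).  Equal mapped totals
    # keep TPM fold changes equal to the planted count fold changes.
    mapped_target = round(total * (1 - config.background_fraction))

    mirnas = list(bundle.truth.mirnas.values())
    # Per-miRNA control-condition base means from a log-normal draw.  The
    # miRNA budget is sized against the heaviest library: treated means are
    # control means x 2**lfc, so the genotype with the largest aggregate
    # fold-change multiplier must still fit, background absorbing the slack.
    w = rng.lognormal(0.0, config.abundance_sigma, len(mirnas))
    w /= w.sum()
    multipliers = [1.0]
    for g in GENOTYPES:
        multipliers.append(sum(wi * 2.0 ** m.lfc[g] for wi, m in zip(w, mirnas)))
    scale = mirna_budget / max(multipliers)
    for m, wi in zip(mirnas, w):
        m.base_mean = float(wi * scale)

    lengths, lweights = _length_distribution(config)
    ncrna_loci = bundle.truth.ncrna_intervals
    chrom_seq = bundle.genome["chr1"]

    paths: dict[str, list] = {}
    truth_rows = []
    for lib in LIBRARIES:
        genotype, condition = lib.split("-")
        lib_paths = []
        rep_counts = []
        for rep in range(1, config.n_replicates + 1):
            reads: list[str] = []
            per_mirna: dict[str, dict] = {}
            # --- mature-arm reads ---
            for m in mirnas:
                mean = m.base_mean
                if condition == "T":
                    mean *= 2.0 ** m.lfc[genotype]
                # split the locus mean over arms by the configured 5p:3p ratio
                mean5 = mean * m.arm_ratio / (1.0 + m.arm_ratio)
                mean3 = mean - mean5
                c5, c3 = draw_counts(rng, [mean5, mean3], config.abundance_dispersion)
                per_mirna[m.mirna_id] = {"5p": int(c5), "3p": int(c3)}
                reads.extend([m.mature_5p] * int(c5))
                reads.extend([m.mature_3p] * int(c3))
            if len(reads) > total:
                reads = reads[:total]
            # --- ncRNA fragments fill the mapped pool to its fixed size ---
            n_slack = max(0, min(mapped_target - len(reads), total - len(reads)))
            if config.ncrna_fraction > 0 and ncrna_loci:
                for _ in range(n_slack):
                    chrom, s, e, strand, cls = ncrna_loci[int(rng.integers(len(ncrna_loci)))]
                    flen = int(rng.choice(lengths, p=lweights))
                    flen = min(flen, e - s)
                    off = int(rng.integers(s, e - flen + 1))
                    frag = chrom_seq[off : off + flen]
                    if strand == "-":
                        frag = revcomp(frag)
                    reads.append(frag)
            elif n_slack > 0:
                # no ncRNA requested: pad with arm reads proportional to the
                # library's arm means so every read still maps to a precursor
                arm_seqs = []
                arm_key = []
                arm_w = []
                for m in mirnas:
                    mean = m.base_mean * (
                        2.0 ** m.lfc[genotype] if condition == "T" else 1.0
                    )
                    for arm, arm_seq, share in (
                        ("5p", m.mature_5p, m.arm_ratio / (1 + m.arm_ratio)),
                        ("3p", m.mature_3p, 1.0 / (1 + m.arm_ratio)),
                    ):
                        arm_seqs.append(arm_seq)
                        arm_key.append((m.mirna_id, arm))
                        arm_w.append(mean * share)
                w_arr = np.asarray(arm_w) / sum(arm_w)
                for idx in rng.choice(len(arm_seqs), n_slack, p=w_arr):
                    reads.append(arm_seqs[int(idx)])
                    mid, arm = arm_key[int(idx)]
                    per_mirna[mid][arm] += 1
            # --- random background fills to the exact library size ---
            while len(reads) < total:
                blen = int(rng.choice(lengths, p=lweights))
                reads.append(_random_seq(rng, blen, config.gc_content))
            rep_counts.append(per_mirna)
            path = outdir / f"{lib}_rep{rep}.fastq"
            _write_fastq(path, reads, config, rng)
            lib_paths.append(path)
        paths[lib] = lib_paths
        # replicate-averaged true counts
        for m in mirnas:
            avg5 = float(np.mean([rc[m.mirna_id]["5p"] for rc in rep_counts]))
            avg3 = float(np.mean([rc[m.mirna_id]["3p"] for rc in rep_counts]))
            m.true_counts[lib] = {"5p": avg5, "3p": avg3}
            truth_rows.append((m.mirna_id, lib, avg5, avg3))

    truth_counts = pd.DataFrame(
        truth_rows, columns=["mirna_id", "library", "count_5p", "count_3p"]
    )
    truth_counts.to_csv(outdir / "true_counts.tsv", sep="\t", index=False)
    paths["truth_counts"] = truth_counts
    return paths


def _write_fastq(path, inserts, config: SimulationConfig, rng: np.random.Generator) -> None:
    """Adapter-ligate, pad to read length, assign qualities, write FASTQ."""
    L = config.read_length
    q_hi = chr(33 + config.qual_hi)
    q_lo = chr(33 + config.qual_lo)
    n = len(inserts)
    kinds = rng.random(n)
    lowq = rng.random(n) < config.lowq_read_fraction
    with open(path, "w") as fh:
        for i, insert in enumerate(inserts):
            if kinds[i] < config.polya_fraction:
                insert = "A" * len(insert)
            raw = insert + config.adapter3
            if config.polya_fraction <= kinds[i] < (
                config.polya_fraction + config.no_adapter_fraction
            ):
                raw = insert + _random_seq(rng, len(config.adapter3), 0.5)
            if len(raw) < L:
                raw = raw + _random_seq(rng, L - len(raw), 0.5)
            raw = raw[:L]
            if lowq[i]:
                # ~15% of insert bases below Q20 to exercise the Q20 statistic
                qual = list(q_hi * L)
                n_lo = max(1, int(0.15 * len(insert)))
                for p in rng.choice(len(insert), n_lo, replace=False):
                    qual[int(p)] = q_lo
                qual = "".join(qual)
            else:
                qual = q_hi * L
            fh.write(f"@read{i + 1}\n{raw}\n+\n{qual}\n")
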