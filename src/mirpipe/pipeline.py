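"""End-to-end pipeline orchestration and paper-shaped reporting.

``run_pipeline`` drives the stages in order — simulate (or load provided
files) -> clean -> collapse -> map -> ncRNA exclusion -> known matching ->
hairpin evaluation -> six-criterion calling -> differential expression ->
target prediction -> enrichment — writing each stage's tables under the run
directory plus a machine-readable ``run_summary.json``.  All thresholds
default to the printed values of the study design (100 TPM, 20-24 nt, arm
ratio 0.9, -37 kJ/mol, MFEI 0.85, |log2fc| >= 1 with p <= 0.01, Bonferroni
0.05) and every stage is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, diffexpr, discovery, enrichment, hairpin, preprocess, targets
from .simulate import (
    GENOTYPES,
    LIBRARIES,
    GroundTruth,
    ReferenceBundle,
    SimulationConfig,
    build_reference,
    simulate_libraries,
)
from .util import read_fasta

logger = logging.getLogger("mirpipe")

TABLE1_ROWS = (
    "Total raw reads",
    "Total clean reads",
    "Clean tag (%)",
    "Q20 of clean tag (%)",
    "Mapped reads",
    "Total miRNAs reads",
    "Known miRNAs reads",
    "Novel miRNAs reads",
)


@dataclass
class RunConfig:
    """Every knob of a pipeline run; defaults are the study thresholds."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    mode: str = "simulate"  # "simulate" or "provided"
    input_dir: str | None = None  # reference + FASTQ dir for mode="provided"
    min_tpm: float = 100.0
    min_mature_len: int = 20
    max_mature_len: int = 24
    arm_ratio_min: float = 0.9
    strict_arm_ratio: bool = False
    mfe_kj_max: float = -37.0
    mfei_min: float = 0.85
    waive_structure_for_known: bool = True
    lfc_min: float = 1.0
    p_max: float = 0.01
    pseudocount: float = 0.01
    max_target_penalty: float = 4.0
    max_target_mismatches: int = 3
    enrich_alpha: float = 0.05
    flank_near: int = 20
    flank_far: int = 150
    max_map_mismatch: int = 2
    max_known_mismatch: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**data.pop("sim", {}))
        return cls(sim=sim, **data)

    def to_yaml(self, path) -> None:
        import yaml

        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_reference(indir) -> ReferenceBundle:
    """Load a serialized reference bundle (the simulator's on-disk format)."""
    indir = Path(indir)
    genome = read_fasta(indir / "genome.fa")
    annotation = []
    with open(indir / "ncrna.bed") as fh:
        for line in fh:
            chrom, start, end, name, rna_class, strand = line.split()
            annotation.append((chrom, int(start), int(end), name, rna_class, strand))
    matures = read_fasta(indir / "matures.fa")
    family_table = pd.read_csv(indir / "families.tsv", sep="\t")
    species_table = pd.read_csv(indir / "species.tsv", sep="\t", index_col=0)
    transcripts = read_fasta(indir / "transcripts.fa")
    gene_terms = pd.read_csv(indir / "gene_terms.tsv", sep="\t")
    truth_path = indir / "ground_truth.json"
    truth = GroundTruth.from_json(truth_path) if truth_path.exists() else GroundTruth({}, [], {})
    return ReferenceBundle(
        genome=genome,
        annotation=annotation,
        matures=matures,
        family_table=family_table,
        species_table=species_table,
        transcripts=transcripts,
        gene_terms=gene_terms,
        truth=truth,
        outdir=indir,
    )


def _fastq_paths(indir, n_replicates: int) -> dict:
    indir = Path(indir)
    return {
        lib: [indir / f"{lib}_rep{r}.fastq" for r in range(1, n_replicates + 1)]
        for lib in LIBRARIES
    }


def _novel_candidates(unmatched, survivors, genome, config: RunConfig, tag_counts):
    """Evaluate hairpins for unmatched tags and group them into loci.

    Returns a list of :class:`discovery.MiRNACandidate` (one per locus) and a
    dict of per-tag evaluations for reporting.
    """
    evaluations = {}
    placed = []
    for tag in unmatched:
        aln = survivors[tag]
        best = None
        best_iv = None
        for window, mspan, _arm, (wa, wb) in hairpin.excise_precursors(
            genome[aln.chrom],
            aln.start,
            aln.end,
            aln.strand,
            flank_near=config.flank_near,
            flank_far=config.flank_far,
        ):
            ev = hairpin.evaluate_precursor(window, mspan)
            key = (ev.valid_hairpin, ev.mfei)  # most hairpin-like first
            if best is None or key > (best.valid_hairpin, best.mfei):
                best = ev
                lo = ev.window_offset
                if aln.strand == "+":
                    best_iv = (wa + lo, wa + lo + len(ev.precursor_seq))
                else:
                    best_iv = (wb - lo - len(ev.precursor_seq), wb - lo)
        if best is None:
            continue
        evaluations[tag] = (best, best_iv)
        placed.append((aln.chrom, best_iv[0], best_iv[1], tag))
    # cluster tags whose best precursor intervals overlap on the same chrom
    placed.sort(key=lambda x: (x[0], x[1], x[2], x[3]))
    clusters: list[list[str]] = []
    cur_chrom, cur_end = None, -1
    for chrom, start, end, tag in placed:
        if chrom == cur_chrom and start < cur_end:
            clusters[-1].append(tag)
            cur_end = max(cur_end, end)
        else:
            clusters.append([tag])
            cur_chrom, cur_end = chrom, end
    candidates = []
    for idx, cluster in enumerate(clusters, start=1):
        # mature = the most abundant tag of the locus; the precursor
        # evaluation may come from any member tag (same duplex, and a star
        # arm's window sometimes folds into the cleaner stem-loop)
        mature_tag = max(cluster, key=lambda t: (sum(tag_counts[t].values()), t))
        ev = max(
            (evaluations[t][0] for t in cluster),
            key=lambda e: (e.valid_hairpin, e.mfei),
        )
        arm_counts = {"5p": {}, "3p": {}}
        for t in cluster:
            t_ev, _ = evaluations[t]
            arm = t_ev.mature_arm if t_ev.mature_arm in ("5p", "3p") else "5p"
            for lib, c in tag_counts[t].items():
                arm_counts[arm][lib] = arm_counts[arm].get(lib, 0.0) + c
        candidates.append(
            discovery.MiRNACandidate(
                mirna_id=f"novel-mir{idx:03d}",
                status="novel",
                mature_seq=mature_tag,
                arm=evaluations[mature_tag][0].mature_arm,
                counts=dict(tag_counts[mature_tag]),
                counts_5p=arm_counts["5p"],
                counts_3p=arm_counts["3p"],
                precursor_id=f"novel-pre{idx:03d}",
                hairpin=ev,
            )
        )
    return candidates, evaluations


def _known_candidates(assigned, tag_counts, matures, family_table):
    """Group known-matched tags by mature id into candidates."""
    fam_of = dict(zip(family_table["mature_id"], family_table["family"]))
    by_mature: dict[str, list] = {}
    for tag, a in assigned.items():
        by_mature.setdefault(a.mature_id, []).append(tag)
    # arm-specific counts come from the sibling mature (-5p / -3p) groups
    def lib_sum(tags_):
        out: dict[str, float] = {}
        for t in tags_:
            for lib, c in tag_counts[t].items():
                out[lib] = out.get(lib, 0.0) + c
        return out

    candidates = []
    for mid in sorted(by_mature):
        tags_ = by_mature[mid]
        counts = lib_sum(tags_)
        if mid.endswith("-5p") or mid.endswith("-3p"):
            base, arm = mid[:-3], mid[-2:]
            sib = base + ("-3p" if arm == "5p" else "-5p")
            sib_counts = lib_sum(by_mature.get(sib, []))
        else:
            arm = "?"
            sib_counts = {}
        counts_5p = counts if arm == "5p" else sib_counts
        counts_3p = counts if arm == "3p" else sib_counts
        candidates.append(
            discovery.MiRNACandidate(
                mirna_id=mid,
                status="known",
                mature_seq=matures[mid].upper().replace("U", "T"),
                arm=arm,
                counts=counts,
                counts_5p=counts_5p,
                counts_3p=counts_3p,
                precursor_id=None,
                hairpin=None,
                family=fam_of.get(mid),
            )
        )
    return candidates


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage; write artifacts + run_summary.json; return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run_pipeline seed=%s mode=%s", config.sim.seed, config.mode)
    summary: dict = {"seed": config.sim.seed, "mode": config.mode, "stages": {}}

    # --- stage: inputs ------------------------------------------------------
    if config.mode == "simulate":
        refdir = outdir / "reference"
        bundle = build_reference(config.sim, outdir=refdir)
        fq = simulate_libraries(bundle, config.sim, outdir=outdir / "reads")
        fastqs = {lib: fq[lib] for lib in LIBRARIES}
    elif config.mode == "provided":
        if not config.input_dir:
            raise ValueError("mode='provided' requires input_dir")
        bundle = load_reference(Path(config.input_dir) / "reference")
        fastqs = _fastq_paths(Path(config.input_dir) / "reads", config.sim.n_replicates)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # --- stage: preprocess --------------------------------------------------
    clean_lists: dict[str, list] = {}
    raw_counts: dict[str, float] = {}
    q20: dict[str, float] = {}
    discard_tally: dict[str, dict] = {}
    for lib in LIBRARIES:
        reps = []
        n_raw, q20b, totb = [], 0, 0
        tally: dict[str, int] = {}
        for path in fastqs[lib]:
            res = preprocess.clean_reads(
                path, config.sim.adapter3, config.sim.adapter5
            )
            reps.append(res.reads)
            n_raw.append(res.n_raw)
            q20b += res.q20_bases
            totb += res.total_bases
            for k, v in res.discards.items():
                tally[k] = tally.get(k, 0) + v
        clean_lists[lib] = reps
        raw_counts[lib] = sum(n_raw) / len(n_raw)
        q20[lib] = 100.0 * q20b / totb if totb else 0.0
        discard_tally[lib] = tally
    tags = preprocess.collapse_tags(clean_lists)
    preprocess.write_tags(tags, outdir / "tags.fa", outdir / "tags.tsv")
    clean_counts = {lib: float(tags[lib].sum()) for lib in LIBRARIES}
    summary["stages"]["preprocess"] = {
        "raw_reads": raw_counts,
        "clean_reads": clean_counts,
        "q20_pct": {k: round(v, 2) for k, v in q20.items()},
        "discards": discard_tally,
        "n_unique_tags": int(len(tags)),
    }

    # --- stage: mapping -----------------------------------------------------
    tag_list = list(tags.index)
    alignments, status = annotate.map_tags(
        tag_list, bundle.genome, max_mismatch=config.max_map_mismatch
    )
    tag_counts = {
        t: {lib: float(tags.at[t, lib]) for lib in LIBRARIES} for t in tag_list
    }
    mapped_totals = {
        lib: sum(tag_counts[t][lib] for t in alignments) for lib in LIBRARIES
    }
    aln_rows = [
        (a.tag, a.chrom, a.start, a.end, a.strand, a.mismatches)
        for a in alignments.values()
    ]
    pd.DataFrame(
        aln_rows, columns=["tag", "chrom", "start", "end", "strand", "mismatches"]
    ).to_csv(outdir / "alignments.tsv", sep="\t", index=False)
    summary["stages"]["mapping"] = {
        "n_unique": sum(1 for s in status.values() if s == "unique"),
        "n_multi": sum(1 for s in status.values() if s == "multi"),
        "n_unmapped": sum(1 for s in status.values() if s == "unmapped"),
        "mapped_reads": mapped_totals,
    }

    # --- stage: ncRNA exclusion --------------------------------------------
    categorized, survivors = annotate.exclude_ncrna(alignments, bundle.annotation)
    class_reads = {
        lib: {} for lib in LIBRARIES
    }
    for tag, cls in categorized.items():
        for lib in LIBRARIES:
            class_reads[lib][cls] = class_reads[lib].get(cls, 0.0) + tag_counts[tag][lib]
    summary["stages"]["ncrna"] = {
        "n_categorized_tags": len(categorized),
        "reads_per_class": class_reads,
    }

    # --- stage: known/novel matching + hairpins -----------------------------
    assigned, unmatched = annotate.match_known(
        survivors, bundle.matures, max_mismatch=config.max_known_mismatch
    )
    known_reads = {
        lib: sum(tag_counts[t][lib] for t in assigned) for lib in LIBRARIES
    }
    novel_reads = {
        lib: sum(tag_counts[t][lib] for t in unmatched) for lib in LIBRARIES
    }
    known_cands = _known_candidates(assigned, tag_counts, bundle.matures, bundle.family_table)
    novel_cands, evaluations = _novel_candidates(
        unmatched, survivors, bundle.genome, config, tag_counts
    )
    hairpin.write_vienna(
        outdir / "precursors.vienna",
        [
            (c.mirna_id, c.hairpin.precursor_seq, c.hairpin.structure, c.hairpin.mfe)
            for c in novel_cands
            if c.hairpin is not None
        ],
    )
    family_summary = annotate.assign_family_and_conservation(
        assigned, bundle.family_table, bundle.species_table
    )
    family_summary.to_csv(outdir / "families_summary.tsv", sep="\t")

    # --- stage: discovery ---------------------------------------------------
    records, rejected = discovery.call_mirnas(
        known_cands + novel_cands,
        mapped_totals,
        min_tpm=config.min_tpm,
        min_len=config.min_mature_len,
        max_len=config.max_mature_len,
        arm_ratio_min=config.arm_ratio_min,
        strict_arm_ratio=config.strict_arm_ratio,
        mfe_kj_max=config.mfe_kj_max,
        mfei_min=config.mfei_min,
        waive_structure_for_known=config.waive_structure_for_known,
    )
    mirna_table = pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "status": r.status,
                "family": r.family,
                "arm": r.arm,
                "length": r.length,
                "mature_seq": r.mature_seq,
                **{f"count_{lib}": r.counts.get(lib, 0.0) for lib in LIBRARIES},
                **{f"tpm_{lib}": r.tpm.get(lib, 0.0) for lib in LIBRARIES},
                **{f"pass_{c}": r.criteria_flags[c] for c in discovery.CRITERIA},
            }
            for r in records
        ]
    )
    mirna_table.to_csv(outdir / "mirnas.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (r.mirna_id, r.status, r.failed_criterion)
            for r in rejected
        ],
        columns=["mirna_id", "status", "failed_criterion"],
    ).to_csv(outdir / "rejected_candidates.tsv", sep="\t", index=False)
    summary["stages"]["discovery"] = {
        "n_called": len(records),
        "n_known": sum(1 for r in records if r.status == "known"),
        "n_novel": sum(1 for r in records if r.status == "novel"),
        "n_rejected": len(rejected),
    }

    # --- stage: differential expression -------------------------------------
    if records:
        counts_mat = pd.DataFrame(
            {lib: [r.counts.get(lib, 0.0) for r in records] for lib in LIBRARIES},
            index=[r.mirna_id for r in records],
        )
    else:
        counts_mat = pd.DataFrame(columns=list(LIBRARIES))
    de_tables = {}
    for genotype in GENOTYPES:
        de_tables[genotype] = diffexpr.genotype_de_table(
            counts_mat,
            genotype=genotype,
            control_lib=f"{genotype}-CK",
            treated_lib=f"{genotype}-T",
            totals=mapped_totals,
            pseudocount=config.pseudocount,
        )
        de_tables[genotype].to_csv(outdir / f"de_{genotype}.tsv", sep="\t")
    overlap = diffexpr.overlap_sets(de_tables["ST"], de_tables["SM"])
    overlap["contingency"].to_csv(outdir / "de_contingency.tsv", sep="\t")
    summary["stages"]["diffexpr"] = {
        "class_counts": {
            g: de_tables[g]["de_class"].value_counts().to_dict() for g in GENOTYPES
        },
        "venn": overlap["venn"],
        "n_shared_universe": overlap["n"],
    }

    # --- stage: targets + enrichment ----------------------------------------
    de_mirnas = sorted(
        set().union(
            *(
                set(de_tables[g].index[de_tables[g]["de_class"] != "unchanged"])
                for g in GENOTYPES
            )
        )
    )
    seq_of = {r.mirna_id: r.mature_seq for r in records}
    hit_rows = []
    target_genes = set()
    for mid in de_mirnas:
        for h in targets.predict_targets(
            mid,
            seq_of[mid],
            bundle.transcripts,
            max_penalty=config.max_target_penalty,
            max_mismatches=config.max_target_mismatches,
        ):
            hit_rows.append(
                (
                    h.mirna_id,
                    h.transcript_id,
                    h.site_start,
                    h.site_end,
                    h.penalty_score,
                    h.mismatches,
                    h.gu_pairs,
                    h.is_best_match,
                )
            )
            target_genes.add(h.transcript_id.rsplit(".", 1)[0])
    pd.DataFrame(
        hit_rows,
        columns=[
            "mirna_id",
            "transcript_id",
            "site_start",
            "site_end",
            "penalty",
            "mismatches",
            "gu_pairs",
            "is_best_match",
        ],
    ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    universe = set(bundle.gene_terms["gene_id"])
    terms = enrichment.enrich(
        target_genes & universe,
        bundle.gene_terms,
        universe,
        alpha=config.enrich_alpha,
    )
    enrichment.enrichment_table(terms).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    pathways = enrichment.summarize_pathways(
        [t for t in terms if t.domain == "pathway"]
    )
    pathways.to_csv(outdir / "pathways_top.tsv", sep="\t", index=False)
    summary["stages"]["targets_enrichment"] = {
        "n_de_mirnas": len(de_mirnas),
        "n_target_hits": len(hit_rows),
        "n_target_genes": len(target_genes),
        "n_terms_tested": len(terms),
        "n_terms_significant": sum(1 for t in terms if t.significant),
    }

    # --- Table-1-shaped report ----------------------------------------------
    stats = [
        preprocess.library_stats(
            lib,
            raw_reads=raw_counts[lib],
            clean_reads=clean_counts[lib],
            q20_pct=q20[lib],
            mapped_reads=mapped_totals[lib],
            known_mirna_reads=known_reads[lib],
            novel_mirna_reads=novel_reads[lib],
        )
        for lib in LIBRARIES
    ]
    t1 = table1_report(stats)
    t1.to_csv(outdir / "table1.tsv", sep="\t")
    summary["stages"]["table1"] = {
        lib: {
            "raw": raw_counts[lib],
            "clean": clean_counts[lib],
            "clean_pct": stats[i].clean_pct,
            "q20_pct": stats[i].q20_pct,
            "mapped": mapped_totals[lib],
            "mapped_pct": stats[i].mapped_pct,
            "mirna_total": stats[i].mirna_reads_total,
            "known": known_reads[lib],
            "novel": novel_reads[lib],
        }
        for i, lib in enumerate(LIBRARIES)
    }

    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _fmt_count(x: float) -> str:
    if x == int(x):
        return f"{int(x):,}"
    return f"{x:,.1f}"


def table1_report(stats_list) -> pd.DataFrame:
    """Library-summary table in the classic layout (rows x libraries).

    Percentages are recomputed from the counts in the same table and
    formatted round-half-even to 2 decimals; mapped reads print as
    "count (pct%)".
    """
    cols = {}
    for s in stats_list:
        cols[s.library_id] = [
            _fmt_count(s.raw_reads),
            _fmt_count(s.clean_reads),
            f"{s.clean_pct:.2f}",
            f"{s.q20_pct:.2f}",
            f"{_fmt_count(s.mapped_reads)} ({s.mapped_pct:.2f}%)",
            _fmt_count(s.mirna_reads_total),
            _fmt_count(s.known_mirna_reads),
            _fmt_count(s.novel_mirna_reads),
        ]
    return pd.DataFrame(cols, index=pd.Index(TABLE1_ROWS, name="Library Type"))
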