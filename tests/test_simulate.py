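"""Simulator contracts: determinism, exact read budgets, planted-truth
consistency, and degenerate (oracle) modes."""

import filecmp
import math

import numpy as np
import pytest

from mirpipe import hairpin
from mirpipe.simulate import (
    LIBRARIES,
    SimulationConfig,
    build_reference,
    draw_counts,
    simulate_libraries,
)
from mirpipe.util import transcribe


def small_config(**kw):
    base = dict(
        seed=7,
        n_true_mirnas=8,
        known_fraction=0.5,
        reads_per_library=2000,
        genome_length=20_000,
        n_transcripts=20,
        abundance_dispersion=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestReference:
    def test_known_fraction_controls_reference_content(self, tmp_path):
        cfg = small_config(seed=7, n_true_mirnas=20, known_fraction=0.5, genome_length=30_000)
        bundle = build_reference(cfg, outdir=tmp_path / "ref")
        planted_known = {
            mid for mid, m in bundle.truth.mirnas.items() if m.known
        }
        assert len(planted_known) == 10
        ref_bases = {mid[4:-3] for mid in bundle.matures if mid.startswith("tae-")}
        assert ref_bases == planted_known

    def test_seeded_runs_byte_identical(self, tmp_path):
        cfg = small_config()
        b1 = build_reference(cfg, outdir=tmp_path / "a")
        simulate_libraries(b1, cfg, outdir=tmp_path / "a" / "reads")
        b2 = build_reference(cfg, outdir=tmp_path / "b")
        simulate_libraries(b2, cfg, outdir=tmp_path / "b" / "reads")
        for rel in ["genome.fa", "ncrna.bed", "matures.fa", "transcripts.fa"]:
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel, shallow=False)
        for lib in LIBRARIES:
            for rep in (1, 2):
                assert filecmp.cmp(
                    tmp_path / "a" / "reads" / f"{lib}_rep{rep}.fastq",
                    tmp_path / "b" / "reads" / f"{lib}_rep{rep}.fastq",
                    shallow=False,
                )

    def test_mature_is_substring_of_precursor(self, tmp_path):
        bundle = build_reference(small_config())
        for m in bundle.truth.mirnas.values():
            genome_pre = bundle.genome[m.chrom][m.start : m.end]
            pre = genome_pre if m.strand == "+" else _revcomp(genome_pre)
            assert m.mature_5p in pre and m.mature_3p in pre

    def test_planted_precursors_fold_below_zero(self):
        bundle = build_reference(small_config())
        for m in list(bundle.truth.mirnas.values())[:4]:
            seg = bundle.genome[m.chrom][m.start : m.end]
            pre = seg if m.strand == "+" else _revcomp(seg)
            _, mfe = hairpin.fold_mfe(transcribe(pre))
            assert mfe < 0

    def test_genome_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            build_reference(small_config(genome_length=1500, n_true_mirnas=10))

    def test_intended_class_consistent_with_lfc(self):
        bundle = build_reference(small_config(n_true_mirnas=12))
        for m in bundle.truth.mirnas.values():
            for g, lfc in m.lfc.items():
                cls = m.intended_class(g)
                if lfc >= 1:
                    assert cls == "up"
                elif lfc <= -1:
                    assert cls == "down"
                else:
                    assert cls == "unchanged"


class TestLibraries:
    def test_exact_read_budget_per_replicate(self, tmp_path):
        cfg = small_config()
        bundle = build_reference(cfg)
        simulate_libraries(bundle, cfg, outdir=tmp_path)
        for lib in LIBRARIES:
            for rep in (1, 2):
                n = sum(1 for line in open(tmp_path / f"{lib}_rep{rep}.fastq")) // 4
                assert n == cfg.reads_per_library

    def test_null_plan_zero_dispersion_preserves_fold_changes(self, tmp_path):
        cfg = small_config(lfc_choices=(0.0,), reads_per_library=20_000)
        bundle = build_reference(cfg)
        out = simulate_libraries(bundle, cfg, outdir=tmp_path)
        counts = out["truth_counts"]
        for mid, sub in counts.groupby("mirna_id"):
            sub = sub.set_index("library")
            for g in ("ST", "SM"):
                c_ck = sub.loc[f"{g}-CK", ["count_5p", "count_3p"]].sum()
                c_t = sub.loc[f"{g}-T", ["count_5p", "count_3p"]].sum()
                if c_ck > 0:
                    assert abs(math.log2(c_t / c_ck)) < 0.1

    def test_no_background_reads_all_from_precursors(self, tmp_path):
        cfg = small_config(
            background_fraction=0.0,
            ncrna_fraction=0.0,
            lowq_read_fraction=0.0,
            no_adapter_fraction=0.0,
            polya_fraction=0.0,
            reads_per_library=1000,
        )
        bundle = build_reference(cfg)
        simulate_libraries(bundle, cfg, outdir=tmp_path)
        arms = set()
        for m in bundle.truth.mirnas.values():
            arms.add(m.mature_5p)
            arms.add(m.mature_3p)
        with open(tmp_path / "ST-CK_rep1.fastq") as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    raw = line.strip()
                    insert = raw.split(cfg.adapter3)[0]
                    assert insert in arms

    def test_unit_arm_ratio_zero_dispersion_gives_equal_arms(self, tmp_path):
        cfg = small_config(arm_ratio_range=(1.0, 1.0))
        bundle = build_reference(cfg)
        out = simulate_libraries(bundle, cfg, outdir=tmp_path)
        counts = out["truth_counts"]
        assert (counts["count_5p"] == counts["count_3p"]).all()


class TestCountModel:
    def test_zero_dispersion_is_deterministic_rounding(self, rng):
        means = np.array([0.2, 1.6, 10.49, 10.51, 1000.0])
        out = draw_counts(rng, means, 0.0)
        assert out.tolist() == [0, 2, 10, 11, 1000]

    def test_small_dispersion_matches_poisson_moments(self):
        rng = np.random.default_rng(5)
        draws = draw_counts(rng, np.full(4000, 100.0), 1e-8)
        assert abs(draws.mean() - 100) < 1.0
        assert abs(draws.var() - 100) < 10.0

    def test_large_dispersion_is_overdispersed(self):
        rng = np.random.default_rng(5)
        draws = draw_counts(rng, np.full(4000, 100.0), 0.2)
        assert draws.var() > 3 * draws.mean()


def _revcomp(s):
    from mirpipe.util import revcomp

    return revcomp(s)
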