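"""Ground-truth consistency and determinism of the synthetic generator."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from peroximir.discover import HairpinCriteria, evaluate_hairpin, excise_and_fold
from peroximir.annotate import GenomeHit
from peroximir.reads import collapse_tags, trim_and_filter
from peroximir.simulate import (
    SimulationConfig,
    generate,
    generate_reference,
    simulate_libraries,
)


def _hash_dir(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(path).iterdir())
        if p.is_file()
    }


class TestGenerateReference:
    def test_fixed_seed_is_byte_identical(self, tiny_config, tmp_path):
        generate(tiny_config, tmp_path / "a")
        generate(tiny_config, tmp_path / "b")
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_no_mirnas_means_no_loci(self, tmp_path):
        cfg = SimulationConfig(
            seed=3, n_planted_mirnas=0, n_known_mirnas=0, n_genes=5,
            n_target_genes=0, n_planted_ncrnas=2, n_chromosomes=1,
            chromosome_length=15_000, repeat_copy_numbers=(),
        )
        truth = generate_reference(cfg)
        assert truth.mirnas == [] and truth.target_sites == []

    def test_planted_matures_reextract_from_genome(self, default_run):
        truth = default_run.truth
        for m in truth.mirnas:
            assert truth.genome[m.chrom][m.start : m.end] == m.precursor
            assert m.mature in m.precursor
            assert truth.genome[m.chrom][m.mature_start : m.mature_start + len(m.mature)] == m.mature

    def test_planted_loci_do_not_overlap(self, default_run):
        truth = default_run.truth
        intervals: dict[str, list[tuple[int, int]]] = {}
        for m in truth.mirnas:
            intervals.setdefault(m.chrom, []).append((m.start, m.end))
        for _, _, chrom, s, e in truth.ncrnas:
            intervals.setdefault(chrom, []).append((s, e))
        for g in truth.genes:
            intervals.setdefault(g.chrom, []).append((g.start, g.end))
        for chrom, ivs in intervals.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2, f"overlap on {chrom}"

    def test_every_planted_precursor_passes_hairpin_criteria(self, default_run):
        """The design guarantee: re-fold in genomic context and re-evaluate."""
        truth = default_run.truth
        criteria = HairpinCriteria()
        for m in truth.mirnas[:8]:  # a sample keeps the fold budget small
            hit = GenomeHit(
                m.mature, m.chrom, m.mature_start, m.mature_start + len(m.mature), "+", 1
            )
            cands = excise_and_fold(m.mature, [hit], truth.genome, criteria)
            assert any(evaluate_hairpin(c, criteria).passes for c in cands), m.id

    def test_collision_raises_generation_error(self):
        cfg = SimulationConfig(
            seed=5, n_chromosomes=1, chromosome_length=2_000,
            n_planted_mirnas=6, n_known_mirnas=0, n_planted_ncrnas=0,
            n_genes=0, n_target_genes=0, repeat_copy_numbers=(),
        )
        with pytest.raises(RuntimeError, match="collision|overflow"):
            generate_reference(cfg)


class TestSimulateLibraries:
    def test_count_table_sums_to_signal_depth(self, tiny_config, tmp_path):
        truth = generate_reference(tiny_config)
        res = simulate_libraries(tiny_config, truth, tmp_path)
        depth = tiny_config.library_depth_cs
        expected = depth - round(tiny_config.noise_fraction * depth)
        assert sum(v[0] for v in res["counts"].values()) == expected
        assert sum(v[1] for v in res["counts"].values()) == expected

    def test_zero_depth_yields_empty_valid_fastq(self, tiny_config, tmp_path):
        cfg = SimulationConfig(**{**tiny_config.__dict__})
        cfg.library_depth_cs = 0
        cfg.library_depth_ts = 0
        truth = generate_reference(cfg)
        res = simulate_libraries(cfg, truth, tmp_path)
        assert Path(res["paths"]["reads_cs"]).read_text() == ""

    def test_collapsed_tags_match_expected_count_table(self, tiny_config, tmp_path):
        truth = generate_reference(tiny_config)
        res = simulate_libraries(tiny_config, truth, tmp_path)
        clean_cs, _ = trim_and_filter(
            str(res["paths"]["reads_cs"]), tiny_config.adapter_seq
        )
        clean_ts, _ = trim_and_filter(
            str(res["paths"]["reads_ts"]), tiny_config.adapter_seq
        )
        tags = collapse_tags(clean_cs, clean_ts)
        for seq, (cs, ts) in res["counts"].items():
            if cs or ts:
                assert (tags[seq].count_cs, tags[seq].count_ts) == (cs, ts)

    def test_no_noise_means_every_read_maps(self, tmp_path):
        cfg = SimulationConfig(
            seed=11, n_chromosomes=1, chromosome_length=15_000,
            n_planted_mirnas=3, n_known_mirnas=1, n_planted_ncrnas=2,
            n_genes=4, n_target_genes=2, library_depth_cs=800,
            library_depth_ts=800, noise_fraction=0.0, repeat_copy_numbers=(),
        )
        truth = generate_reference(cfg)
        res = simulate_libraries(cfg, truth, tmp_path)
        clean, _ = trim_and_filter(str(res["paths"]["reads_cs"]), cfg.adapter_seq)
        joined = {c: truth.genome[c] for c in truth.genome}
        from peroximir.sequtil import revcomp

        for seq in set(clean):
            assert any(
                seq in chrom_seq or revcomp(seq) in chrom_seq
                for chrom_seq in joined.values()
            )

    def test_fold_change_scales_treatment_expectation(self, tmp_path):
        """TS mean for a 4x miRNA lands within 3 SE of 4x the CS expectation."""
        base = SimulationConfig(
            seed=2, n_chromosomes=1, chromosome_length=15_000,
            n_planted_mirnas=4, n_known_mirnas=0, n_planted_ncrnas=2,
            n_genes=0, n_target_genes=0, library_depth_cs=100_000,
            library_depth_ts=100_000, noise_fraction=0.0, repeat_copy_numbers=(),
        )
        truth = generate_reference(base)
        target = truth.mirnas[0].id
        # pin abundances and folds: the target sits at ~200 expected CS reads
        base.per_mirna_fold_change = {target: 4.0}
        base.mirna_abundance = {m.id: (1.0 if m.id == target else 165.25) for m in truth.mirnas}
        truth = generate_reference(base)
        mature = truth.mirnas[0].mature
        cs_counts, ts_counts = [], []
        for rep in range(12):
            base.seed = 100 + rep
            res = simulate_libraries(base, truth, tmp_path / str(rep))
            cs_counts.append(res["counts"][mature][0])
            ts_counts.append(res["counts"][mature][1])
        cs_mean, ts_mean = np.mean(cs_counts), np.mean(ts_counts)
        n = len(ts_counts)
        sem = np.sqrt(
            np.var(ts_counts, ddof=1) / n + 16 * np.var(cs_counts, ddof=1) / n
        )
        assert abs(ts_mean - 4.0 * cs_mean) <= 3 * max(sem, 10.0)
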