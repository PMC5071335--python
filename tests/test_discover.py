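"""Hairpin evaluation, candidate selection and novel miRNA recovery."""

import pandas as pd
import pytest

from peroximir.annotate import GenomeHit
from peroximir.discover import (
    PrecursorCandidate,
    cluster_families,
    evaluate_hairpin,
    excise_and_fold,
    first_nucleotide_bias,
    NovelMiRNA,
    select_candidates,
)
from peroximir.fold import default_engine, pair_table
from peroximir.reads import UniqueTag
from peroximir.sequtil import revcomp, to_dna


class TestPairTable:
    def test_partners_are_symmetric(self):
        pt = pair_table("((..((...))..))")
        assert pt[0] == 14 and pt[14] == 0 and pt[4] == 10 and pt[5] == 9
        assert pt[2] == -1

    @pytest.mark.parametrize("bad", ["((.", ".))", "(.x)"])
    def test_unbalanced_or_invalid_raises(self, bad):
        with pytest.raises(ValueError):
            pair_table(bad)


def _hits(seq, n):
    return [GenomeHit(seq, "chr1", 0, len(seq), "+", n)] * n


class TestSelectCandidates:
    def _tag(self, seq, category=None):
        return UniqueTag(seq, count_cs=5, category=category)

    @pytest.mark.parametrize("n_hits,kept", [(1, True), (10, True), (11, False)])
    def test_genome_hit_limit_boundary(self, n_hits, kept):
        """More than 10 genomic hits removes a tag; exactly 10 keeps it."""
        seq = "ACGTGCATTCAGGTCAGATCA"
        tags = {seq: self._tag(seq)}
        out = select_candidates(tags, {seq: _hits(seq, n_hits)})
        assert (len(out) == 1) == kept

    def test_ncrna_and_known_tags_never_reach_selection(self):
        seq = "ACGTGCATTCAGGTCAGATCA"
        for category in ("rRNA", "snoRNA", "known_miRNA"):
            tags = {seq: self._tag(seq, category)}
            assert select_candidates(tags, {seq: _hits(seq, 1)}) == []

    def test_length_window_20_to_24(self):
        for n, kept in ((19, False), (20, True), (24, True), (25, False)):
            seq = ("ACGT" * 7)[:n]
            tags = {seq: self._tag(seq)}
            assert (len(select_candidates(tags, {seq: _hits(seq, 1)})) == 1) == kept

    def test_unmapped_tags_skipped(self):
        seq = "ACGTGCATTCAGGTCAGATCA"
        assert select_candidates({seq: self._tag(seq)}, {}) == []


class TestEvaluateHairpin:
    def _candidate(self, precursor, structure, mfe, mature, mature_start):
        return PrecursorCandidate(
            id="c", chrom="chr1", start=0, end=len(precursor), strand="+",
            precursor_seq=precursor, structure=structure, mfe=mfe,
            mature_seq=mature, mature_start=mature_start,
        )

    def test_designed_hairpin_passes(self):
        mature = "ACGTGCATTCAGGTCAGATCAT"
        loop = "TTTTCGAAATTTCG"
        precursor = mature + loop + revcomp(mature)
        structure, mfe = default_engine()(precursor)
        cand = self._candidate(precursor, structure, mfe, mature, 0)
        assert evaluate_hairpin(cand).passes
        assert cand.mature_arm == "5p"
        assert cand.star_seq and cand.star_seq in precursor

    def test_mature_straddling_loop_fails(self):
        stem = "ACGTGCATTCAGGTCAGATCAT"
        loop = "TTTTCGAAATTTCG"
        precursor = stem + loop + revcomp(stem)
        structure, mfe = default_engine()(precursor)
        mature = precursor[19 : 19 + 21]  # spans stem, loop and back stem
        cand = self._candidate(precursor, structure, mfe, mature, 19)
        assert not evaluate_hairpin(cand).passes
        assert not cand.diagnostics["one_arm"]

    def test_weak_mfe_fails_default_threshold(self):
        mature = "ACGTGCATTCAGGTCAGATCAT"
        precursor = mature + "TTTTCGAAATTTCG" + revcomp(mature)
        structure, _ = default_engine()(precursor)
        cand = self._candidate(precursor, structure, -15.0, mature, 0)
        assert not evaluate_hairpin(cand).passes
        cand2 = self._candidate(precursor, structure, -18.0, mature, 0)
        assert evaluate_hairpin(cand2).passes

    def test_unstructured_window_fails(self):
        seq = "A" * 120
        structure, mfe = default_engine()(seq)
        cand = self._candidate(seq, structure, mfe, "A" * 21, 40)
        assert not evaluate_hairpin(cand).passes

    def test_unbalanced_structure_is_contract_violation(self):
        cand = self._candidate("ACGT" * 20, "(" * 80, -30.0, "ACGT" * 5, 10)
        with pytest.raises(ValueError):
            evaluate_hairpin(cand)


class TestExciseAndFold:
    def test_deterministic_and_windows_cover_both_arms(self, default_run):
        truth = default_run.truth
        m = truth.mirnas[0]
        hit = GenomeHit(m.mature, m.chrom, m.mature_start,
                        m.mature_start + len(m.mature), "+", 1)
        a = excise_and_fold(m.mature, [hit], truth.genome)
        b = excise_and_fold(m.mature, [hit], truth.genome)
        assert len(a) == 2
        assert [(c.structure, c.mfe) for c in a] == [(c.structure, c.mfe) for c in b]
        for c in a:
            assert c.precursor_seq[c.mature_start : c.mature_start + len(m.mature)] == m.mature

    def test_short_clipped_window_skipped(self):
        genome = {"chr1": "ACGTGCATTCAGGTCAGATCATACGTAGC"}
        tag = genome["chr1"][:21]
        hit = GenomeHit(tag, "chr1", 0, 21, "+", 1)
        assert excise_and_fold(tag, [hit], genome) == []


class TestDiscoveryOnPipeline:
    def test_planted_novel_mirnas_recovered(self, default_run):
        """At least 90% of unlabelled planted miRNAs pass discovery."""
        novel = pd.read_csv(default_run.config.outdir / "novel_mirnas.tsv", sep="\t")
        found = {to_dna(m) for m in novel["mature"]}
        unlabelled = default_run.truth.novel_mirnas
        recovered = [m for m in unlabelled if m.mature in found]
        assert len(recovered) >= 0.9 * len(unlabelled)

    def test_reported_mfe_matches_refold(self, default_run):
        novel = pd.read_csv(default_run.config.outdir / "novel_mirnas.tsv", sep="\t")
        from Bio import SeqIO

        engine = default_engine()
        records = list(
            SeqIO.parse(str(default_run.config.outdir / "novel_hairpins.fa"), "fasta")
        )
        assert len(records) == len(novel)
        for rec, mfe in list(zip(records, novel["mfe"]))[:6]:
            _, refold_mfe = engine(str(rec.seq))
            assert refold_mfe <= 0
            assert abs(refold_mfe - float(mfe)) < 0.005


class TestFamiliesAndBias:
    def test_identical_mature_joins_family(self):
        nov = NovelMiRNA("n1", "ACGTGCATTCAGGTCAGATCA", 3, 1,
                         loci=[_fake_locus("ACGTGCATTCAGGTCAGATCA")])
        cluster_families([nov], {"osa-miR-x": "ACGTGCATTCAGGTCAGATCA"})
        assert nov.family == "osa-miR-x"

    def test_three_mismatches_stays_species_specific(self):
        mature = "ACGTGCATTCAGGTCAGATCA"
        other = "TTTTGCATTCAGGTCAGATCA"  # 3 substitutions at the 5' end
        nov = NovelMiRNA("n1", mature, 3, 1, loci=[_fake_locus(mature)])
        cluster_families([nov], {"osa-miR-x": other})
        assert nov.family == "species_specific"

    def test_precursor_containing_known_hairpin_joins_family(self):
        known_mature = "GCATTCAGGTCAGATCATACG"
        hairpin = known_mature + "TTTCGAAAT" + revcomp(known_mature)
        nov = NovelMiRNA("n1", "AAAACCCCGGGGTTTTAACCG", 3, 1,
                         loci=[_fake_locus("AAAA" + hairpin + "CCCC")])
        cluster_families([nov], {"bdi-miR-y": known_mature}, {"bdi-miR-y": hairpin})
        assert nov.family == "bdi-miR-y"

    def test_first_nucleotide_bias_trivial_and_normalized(self):
        novs = [
            NovelMiRNA("n1", "C" + "ACGTGCATTCAGGTCAGATC", 7, 0, [_fake_locus("x")]),
            NovelMiRNA("n2", "T" + "ACGTGCATTCAGGTCAGATC", 3, 0, [_fake_locus("x")]),
        ]
        table = first_nucleotide_bias(novs)
        overall = table[table["length"] == "all"].set_index("nucleotide")
        assert overall.loc["C", "pct_cs"] == 70.0
        assert overall.loc["U", "pct_cs"] == 30.0
        assert abs(overall["pct_cs"].sum() - 100.0) < 0.05

    def test_single_c_start_is_100_percent(self):
        nov = NovelMiRNA("n1", "CCGTGCATTCAGGTCAGATCA", 7, 0, [_fake_locus("x")])
        table = first_nucleotide_bias([nov])
        row = table[(table["length"] == "all") & (table["nucleotide"] == "C")]
        assert float(row["pct_cs"].iloc[0]) == 100.0


def _fake_locus(precursor: str):
    return PrecursorCandidate(
        id="L", chrom="chr1", start=0, end=len(precursor), strand="+",
        precursor_seq=precursor, structure="." * len(precursor), mfe=-30.0,
        mature_seq=precursor[:21], mature_start=0,
    )
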