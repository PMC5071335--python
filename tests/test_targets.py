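"""Target-site scoring, positional rules and cleavage validation."""

import numpy as np
import pytest

from peroximir.sequtil import is_watson_crick, is_wobble, revcomp
from peroximir.targets import (
    map_cleavage,
    render_duplex,
    scan_transcriptome,
    schwab_filter,
    score_site,
    intersect_predictions,
)

MIR = "TGGAGCTCCCTTCAATCCAAA"  # 21 nt


def _weight(pos1: int) -> float:
    return 2.0 if 2 <= pos1 <= 13 else 1.0


def brute_force_score(mir: str, window: str) -> float:
    """Independent exhaustive alignment enumerator (<= 1 gap).

    Recursively consumes miRNA positions and reverse-complemented
    target bases, charging 1.0 per mismatch, 0.5 per G:U wobble and 2.0
    per gap, doubled at miRNA positions 2-13; target-base insertions
    are internal only.
    """
    t = revcomp(window)
    best = [float("inf")]

    def pen(a: str, b: str) -> float:
        # b is a base of revcomp(window): pairing means equality
        if a == b:
            return 0.0
        if (a, b) in (("G", "A"), ("T", "C")):
            return 0.5
        return 1.0

    def walk(i: int, j: int, gaps: int, acc: float) -> None:
        if acc >= best[0]:
            return
        if i == len(mir) and j == len(t):
            best[0] = acc
            return
        if i < len(mir) and j < len(t):
            walk(i + 1, j + 1, gaps, acc + pen(mir[i], t[j]) * _weight(i + 1))
        if i < len(mir) and gaps < 1:  # miRNA base unpaired (target deletion)
            walk(i + 1, j, gaps + 1, acc + 2.0 * _weight(i + 1))
        if j < len(t) and gaps < 1 and 0 < i < len(mir):  # target bulge
            walk(i, j + 1, gaps + 1, acc + 2.0 * _weight(i + 1))
    walk(0, 0, 0, 0.0)
    return best[0]


class TestScoreSite:
    def test_perfect_complement_scores_zero(self):
        site = score_site(MIR, revcomp(MIR))
        assert site.score == 0.0
        assert site.n_mismatch == site.n_gu == site.n_gap == 0
        assert all(s == "match" for s in site.status)

    @pytest.mark.parametrize(
        "pos,expected",
        [(20, 1.0), (10, 2.0), (1, 1.0), (13, 2.0), (14, 1.0)],
    )
    def test_single_mismatch_weighting(self, pos, expected):
        """Mismatches at positions 2-13 cost double."""
        window = list(revcomp(MIR))
        idx = len(MIR) - pos  # window base paired to miRNA position `pos`
        mir_base = MIR[pos - 1]
        bad = next(
            b for b in "ACGT"
            if not is_watson_crick(mir_base, b) and not is_wobble(mir_base, b)
        )
        window[idx] = bad
        site = score_site(MIR, "".join(window))
        assert site.score == expected
        assert site.status[pos - 1] == "mismatch"

    def test_single_wobble_at_position_5_scores_one(self):
        # miRNA position 5 is G; a target T makes a G:U wobble (0.5 doubled)
        assert MIR[4] == "G"
        window = list(revcomp(MIR))
        window[len(MIR) - 5] = "T"
        site = score_site(MIR, "".join(window))
        assert site.score == 1.0
        assert site.status[4] == "wobble" and site.n_gu == 1

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            score_site("ACGTN" + MIR[5:], revcomp(MIR))

    def test_agrees_with_exhaustive_enumeration(self):
        """Minimum S equals a brute-force search over all alignments."""
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for trial in range(400):
            mir = "".join(rng.choice(bases, size=21))
            lw = 21 + int(rng.integers(-1, 2))
            if rng.random() < 0.5:  # near-complement windows exercise low scores
                window = list(revcomp(mir))
                for _ in range(int(rng.integers(0, 4))):
                    window[int(rng.integers(len(window)))] = str(rng.choice(bases))
                window = "".join(window)[:lw].ljust(lw, "A")
            else:
                window = "".join(rng.choice(bases, size=lw))
            assert score_site(mir, window).score == pytest.approx(
                brute_force_score(mir, window)
            ), (mir, window)

    def test_strand_convention_invariance(self):
        """Scoring the reverse complement window in flipped orientation matches."""
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            mir = "".join(rng.choice(bases, size=21))
            window = "".join(rng.choice(bases, size=21))
            direct = score_site(mir, window).score
            # complement both strands: penalties must be identical because
            # WC pairs map to WC pairs and G:U wobbles map to G:U wobbles
            flipped = score_site(revcomp(revcomp(mir)), revcomp(revcomp(window))).score
            assert direct == flipped


class TestSchwabRules:
    def _site(self, mutate_pos=None, extra=()):
        window = list(revcomp(MIR))
        for pos in ([mutate_pos] if mutate_pos else []) + list(extra):
            idx = len(MIR) - pos
            mir_base = MIR[pos - 1]
            window[idx] = next(
                b for b in "ACGT"
                if not is_watson_crick(mir_base, b)
                and not is_wobble(mir_base, b)
            )
        return score_site(MIR, "".join(window))

    def test_perfect_site_passes(self):
        assert schwab_filter(self._site())

    @pytest.mark.parametrize("pos", [10, 11])
    def test_cleavage_position_mismatch_always_rejected(self, pos):
        assert not schwab_filter(self._site(pos))

    def test_single_seed_mismatch_allowed(self):
        assert schwab_filter(self._site(4))

    def test_two_seed_mismatches_rejected(self):
        assert not schwab_filter(self._site(4, extra=[7]))

    def test_three_tail_mismatches_rejected(self):
        assert not schwab_filter(self._site(15, extra=[17, 19]))

    def test_consecutive_mismatch_run_rejected(self):
        site = self._site(15, extra=[16, 17])
        assert not schwab_filter(site)


class TestScanAndIntersect:
    def test_planted_perfect_site_recovered(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        tx = "".join(rng.choice(bases, size=400))
        site_seq = revcomp(MIR)
        tx = tx[:150] + site_seq + tx[150 + len(site_seq):]
        sites = scan_transcriptome({"mir": MIR}, {"tx.1": tx})
        perfect = [s for s in sites if s.score == 0.0]
        assert len(perfect) == 1
        s = perfect[0]
        assert (s.start, s.end) == (150, 171)
        assert s.cleavage_pos == 150 + 21 - 10
        assert s in intersect_predictions(sites)

    def test_scan_agrees_with_score_site_on_candidates(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        tx = "".join(rng.choice(bases, size=300))
        mir = "".join(rng.choice(bases, size=21))
        # embed a few corrupted near-sites so the cutoff region is populated
        for pos, k in ((40, 2), (120, 4), (200, 6)):
            site = list(revcomp(mir))
            for _ in range(k):
                site[int(rng.integers(21))] = str(rng.choice(bases))
            tx = tx[:pos] + "".join(site) + tx[pos + 21:]
        for s in scan_transcriptome({"m": mir}, {"t.1": tx}, allen_max_s=6.0):
            assert s.score == pytest.approx(
                score_site(mir, tx[s.start : s.end]).score
            )
            assert s.score <= 6.0

    def test_shuffled_mirna_negative_control(self):
        """True miRNAs with planted sites hit far more than shuffled ones."""
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        transcripts = {}
        for i in range(12):
            tx = "".join(rng.choice(bases, size=350))
            tx = tx[:100] + revcomp(MIR) + tx[121:]
            transcripts[f"t{i}.1"] = tx
        true_sites = intersect_predictions(scan_transcriptome({"m": MIR}, transcripts))
        shuffled = "".join(rng.permutation(list(MIR)))
        null_sites = intersect_predictions(
            scan_transcriptome({"s": shuffled}, transcripts)
        )
        assert len(true_sites) >= 12
        assert len(true_sites) >= 10 * max(len(null_sites), 1) or len(null_sites) == 0

    def test_score_above_cutoff_not_retained(self):
        window = list(revcomp(MIR))
        # three doubled mismatches -> S = 6 > 4: must not appear at default cutoff
        for pos in (3, 6, 9):
            idx = len(MIR) - pos
            mir_base = MIR[pos - 1]
            window[idx] = next(
                b for b in "ACGT"
                if not is_watson_crick(mir_base, b)
                and not is_wobble(mir_base, b)
            )
        tx = "A" * 60 + "".join(window) + "A" * 60
        sites = scan_transcriptome({"m": MIR}, {"t.1": tx})
        assert all(s.score <= 4.0 for s in sites)
        assert not any(s.start == 60 and s.score == 6.0 for s in sites)


class TestCleavage:
    def _site(self):
        s = score_site(MIR, revcomp(MIR))
        s.transcript_id, s.mirna_id = "t.1", "m"
        s.start, s.end = 100, 121
        s.cleavage_pos = 100 + 21 - 10
        return s

    def test_seven_of_ten_clones_validates(self):
        site = self._site()
        ev = map_cleavage({site.cleavage_pos: 7, 105: 2, 118: 1}, site)
        assert ev.canonical_fraction == pytest.approx(0.7)
        assert ev.validated

    def test_uniform_clones_do_not_validate(self):
        site = self._site()
        # ten positions spread around (and including) the canonical cut
        ends = {site.cleavage_pos - 4 + i: 1 for i in range(10)}
        ev = map_cleavage(ends, site)
        assert ev.canonical_fraction == pytest.approx(0.1)
        assert not ev.validated

    def test_all_clones_canonical(self):
        site = self._site()
        ev = map_cleavage({site.cleavage_pos: 10}, site)
        assert ev.canonical_fraction == 1.0 and ev.validated

    def test_too_few_clones_do_not_validate(self):
        site = self._site()
        assert not map_cleavage({site.cleavage_pos: 5}, site).validated

    def test_zero_clones_is_an_error(self):
        with pytest.raises(ValueError):
            map_cleavage({}, self._site())


class TestRendering:
    def test_duplex_text_marks_pairing(self):
        site = score_site(MIR, revcomp(MIR))
        site.transcript_id, site.mirna_id = "t.1", "m"
        text = render_duplex(site)
        lines = text.split("\n")
        assert lines[1].strip() == "|" * 21
        assert lines[0].startswith("5'") and lines[2].startswith("3'")
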