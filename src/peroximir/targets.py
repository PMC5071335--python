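"""Plant miRNA target prediction and cleavage-site validation.

Sites are scored with the classic plant complementarity penalty scheme:
the miRNA (5'->3') is aligned against the reverse complement of a
candidate mRNA window, each mismatch costs 1.0, each G:U wobble 0.5 and
each gap 2.0, with penalties doubled at miRNA positions 2-13 (the 5'
"seed-plus-core" region); at most one gap is allowed and the score S is
minimized over all alignments. Candidate sites (S at or below a
cutoff, default 4.0) are then passed through positional rules that are
strictest around the cleavage site (miRNA positions 10-11); only sites
passing both rule-sets - emulating the practice of intersecting two
independent predictors - are reported as targets. RACE-style 5'-end
clone pileups validate a site when they concentrate on the transcript
base paired to miRNA position 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequtil import revcomp, to_dna, to_rna

# penalty lookup in reverse-complement space: the miRNA is compared
# base-by-base against revcomp(window), so Watson-Crick pairing means
# equality and the two G:U wobbles appear as (G,A) and (T,C).
_CODE = {c: i for i, c in enumerate("ACGT")}
PENALTY = np.ones((4, 4))
for _i in range(4):
    PENALTY[_i, _i] = 0.0
PENALTY[_CODE["G"], _CODE["A"]] = 0.5
PENALTY[_CODE["T"], _CODE["C"]] = 0.5

GAP_PENALTY = 2.0
DOUBLED_REGION = (2, 13)  # 1-based miRNA positions with doubled penalties


@dataclass
class SchwabRules:
    """Positional constraints on a functional plant target duplex."""

    cleavage_positions: tuple[int, int] = (10, 11)  # perfect WC required
    max_mismatch_2_12: int = 1
    max_mismatch_12_21: int = 2
    max_consecutive: int = 2


@dataclass
class TargetSite:
    """A scored miRNA:mRNA site; coordinates are 0-based half-open."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    score: float
    n_mismatch: int
    n_gu: int
    n_gap: int
    # per miRNA position (1-based index-1): "match" | "wobble" | "mismatch" | "gap"
    status: tuple[str, ...]
    alignment: tuple[str, str, str]
    cleavage_offset: int  # window coordinate opposite miRNA position 10
    cleavage_pos: int | None = None  # transcript coordinate
    passes_allen: bool = False
    passes_schwab: bool = False
    predicted: bool = False


@dataclass
class CleavageEvidence:
    """5'-RACE clone ends mapped onto a predicted site."""

    transcript_id: str
    mirna_id: str
    clone_ends: dict[int, int]
    canonical_pos: int
    canonical_fraction: float
    n_clones: int
    validated: bool


def _position_weight(pos1: int) -> float:
    lo, hi = DOUBLED_REGION
    return 2.0 if lo <= pos1 <= hi else 1.0


def _alignments(m: int, lw: int):
    """Yield alignments as per-miRNA-position target_rc offsets (None=gap).

    With at most one gap: equal lengths give the gapless alignment; a
    one-shorter window deletes one miRNA base; a one-longer window
    inserts one target base (internal only). Each alignment also carries
    the list of inserted target_rc indices.
    """
    if lw == m:
        yield [p for p in range(m)], []
    elif lw == m - 1:
        for g in range(m):
            yield [p if p < g else (None if p == g else p - 1) for p in range(m)], []
    elif lw == m + 1:
        for g in range(1, m):
            yield [p if p < g else p + 1 for p in range(m)], [g]
    else:
        raise ValueError(f"window length {lw} incompatible with miRNA length {m}")


def score_site(mirna_seq: str, target_window: str) -> TargetSite:
    """Score one miRNA against one mRNA window; S minimized over alignments.

    ``target_window`` is the mRNA site in sense orientation (5'->3').
    A deletion gap takes the (possibly doubled) weight of the deleted
    miRNA position; an inserted target base takes the weight of the
    miRNA position on its 3' side. Ties between alignments resolve to
    the first enumerated (gap closest to the miRNA 5' end).
    """
    mir = to_dna(mirna_seq)
    window = to_dna(target_window)
    if set(mir) - set("ACGT") or set(window) - set("ACGT"):
        raise ValueError("sequences must contain only A/C/G/T(U) bases")
    m = len(mir)
    t_rc = revcomp(window)
    best = None
    for offsets, insertions in _alignments(m, len(window)):
        s = 0.0
        status = []
        n_mm = n_gu = n_gap = 0
        for p, off in enumerate(offsets):
            w = _position_weight(p + 1)
            if off is None:
                s += GAP_PENALTY * w
                n_gap += 1
                status.append("gap")
                continue
            pen = PENALTY[_CODE[mir[p]], _CODE[t_rc[off]]]
            s += pen * w
            if pen == 0.0:
                status.append("match")
            elif pen == 0.5:
                n_gu += 1
                status.append("wobble")
            else:
                n_mm += 1
                status.append("mismatch")
        for g in insertions:
            s += GAP_PENALTY * _position_weight(g + 1)
            n_gap += 1
            # a bulged target base disturbs pairing at its 3'-side position
            status[g] = "gap"
        if best is None or s < best[0]:
            best = (s, offsets, insertions, tuple(status), n_mm, n_gu, n_gap)
    s, offsets, insertions, status, n_mm, n_gu, n_gap = best
    aln = _render_alignment(mir, t_rc, offsets, insertions)
    # transcript-sense offset of the window base paired to miRNA position 10
    off10 = offsets[9] if len(offsets) > 9 and offsets[9] is not None else None
    if off10 is None:  # miRNA position 10 deleted: take the 3' neighbour
        off10 = next((o for o in offsets[10:] if o is not None), 0)
    cleavage_offset = len(window) - 1 - off10
    return TargetSite(
        mirna_id="",
        transcript_id="",
        start=0,
        end=len(window),
        score=float(s),
        n_mismatch=n_mm,
        n_gu=n_gu,
        n_gap=n_gap,
        status=status,
        alignment=aln,
        cleavage_offset=cleavage_offset,
    )


def _render_alignment(mir, t_rc, offsets, insertions) -> tuple[str, str, str]:
    """miRNA 5'->3' / match line / site (revcomp orientation) triple."""
    top, mid, bot = [], [], []
    for p, off in enumerate(offsets):
        if insertions and p in insertions:
            top.append("-")
            mid.append(" ")
            bot.append(t_rc[offsets[p] - 1])
        top.append(mir[p])
        if off is None:
            mid.append(" ")
            bot.append("-")
        else:
            pen = PENALTY[_CODE[mir[p]], _CODE[t_rc[off]]]
            mid.append("|" if pen == 0.0 else ("o" if pen == 0.5 else " "))
            bot.append(t_rc[off])
    return "".join(top), "".join(mid), "".join(bot)


def schwab_filter(site: TargetSite, rules: SchwabRules | None = None) -> bool:
    """Positional rule filter; strictest at the cleavage site.

    Requires perfect Watson-Crick pairing at miRNA positions 10-11, at
    most one mismatch/gap in positions 2-12, at most two in positions
    12-21, and never more than two consecutive mismatches. G:U wobbles
    count as pairing everywhere except the cleavage positions.
    """
    rules = rules or SchwabRules()
    status = site.status

    def bad(p1: int) -> bool:  # 1-based position is a mismatch or gap
        return 0 < p1 <= len(status) and status[p1 - 1] in ("mismatch", "gap")

    for p1 in rules.cleavage_positions:
        if 0 < p1 <= len(status) and status[p1 - 1] != "match":
            site.passes_schwab = False
            return False
    if sum(bad(p1) for p1 in range(2, 13)) > rules.max_mismatch_2_12:
        site.passes_schwab = False
        return False
    if sum(bad(p1) for p1 in range(12, 22)) > rules.max_mismatch_12_21:
        site.passes_schwab = False
        return False
    run = best_run = 0
    for st in status:
        run = run + 1 if st in ("mismatch", "gap") else 0
        best_run = max(best_run, run)
    site.passes_schwab = best_run <= rules.max_consecutive
    return site.passes_schwab


def _scan_one(mir: str, t_rc_codes: np.ndarray, allen_max_s: float) -> list[tuple[int, int]]:
    """Candidate (rc_start, window_len) pairs with min-S <= cutoff.

    Vectorized exact minimization over gapless and single-gap
    alignments, using prefix/suffix penalty sums; candidates are then
    re-scored by :func:`score_site` for full per-site detail.
    """
    m = len(mir)
    n = len(t_rc_codes)
    mir_codes = np.array([_CODE[c] for c in mir])
    weights = np.array([_position_weight(p + 1) for p in range(m)])
    out: list[tuple[int, int]] = []

    def pen_matrix(shift: int, n_starts: int) -> np.ndarray:
        # out-of-range cells (first/last row of the shifted frames) are
        # never read by the prefix/suffix sums below; clip for safety
        idx = np.arange(m)[:, None] + np.arange(n_starts)[None, :] + shift
        idx = np.clip(idx, 0, n - 1)
        return weights[:, None] * PENALTY[mir_codes[:, None], t_rc_codes[idx]]

    # gapless
    if n >= m:
        a = pen_matrix(0, n - m + 1)
        s0 = a.sum(axis=0)
        out += [(u, m) for u in np.nonzero(s0 <= allen_max_s)[0]]
    # deletion of one miRNA base (window one shorter)
    if n >= m - 1:
        nu = n - (m - 1) + 1
        a = pen_matrix(0, nu)
        b = pen_matrix(-1, nu)
        pref = np.vstack([np.zeros(nu), np.cumsum(a, axis=0)])
        suf = np.vstack([np.cumsum(b[::-1], axis=0)[::-1], np.zeros(nu)])
        sdel = np.min(
            pref[:m] + (GAP_PENALTY * weights)[:, None] + suf[1:], axis=0
        )
        out += [(u, m - 1) for u in np.nonzero(sdel <= allen_max_s)[0]]
    # insertion of one target base (window one longer)
    if n >= m + 1:
        nu = n - (m + 1) + 1
        a = pen_matrix(0, nu)
        c = pen_matrix(1, nu)
        pref = np.vstack([np.zeros(nu), np.cumsum(a, axis=0)])
        suf = np.vstack([np.cumsum(c[::-1], axis=0)[::-1], np.zeros(nu)])
        gs = np.arange(1, m)
        sins = np.min(
            pref[gs] + (GAP_PENALTY * weights[gs])[:, None] + suf[gs], axis=0
        )
        out += [(u, m + 1) for u in np.nonzero(sins <= allen_max_s)[0]]
    return out


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    allen_max_s: float = 4.0,
    rules: SchwabRules | None = None,
) -> list[TargetSite]:
    """Score all windows of all transcripts against all miRNAs.

    Windows of miRNA length and one shorter/longer are scanned; windows
    with S <= ``allen_max_s`` are retained (``passes_allen``) and also
    evaluated against the positional rules. Overlapping candidate sites
    of the same miRNA/transcript pair are collapsed to the best-scoring
    one (gapless preferred on ties).
    """
    rules = rules or SchwabRules()
    sites: list[TargetSite] = []
    for tx_id in sorted(transcripts):
        seq = to_dna(transcripts[tx_id])
        n = len(seq)
        t_rc_codes = np.array([_CODE.get(c, 0) for c in revcomp(seq)])
        for mir_id in sorted(mirnas):
            mir = to_dna(mirnas[mir_id])
            candidates = _scan_one(mir, t_rc_codes, allen_max_s)
            scored: list[TargetSite] = []
            for rc_start, lw in candidates:
                start = n - rc_start - lw
                site = score_site(mir, seq[start : start + lw])
                site.mirna_id = mir_id
                site.transcript_id = tx_id
                site.start = start
                site.end = start + lw
                site.cleavage_pos = start + site.cleavage_offset
                site.passes_allen = site.score <= allen_max_s
                schwab_filter(site, rules)
                scored.append(site)
            # collapse overlapping windows onto the best-scoring site
            scored.sort(key=lambda s: (s.score, s.n_gap, s.start))
            kept: list[TargetSite] = []
            for site in scored:
                if all(site.end <= k.start or k.end <= site.start for k in kept):
                    kept.append(site)
            sites.extend(sorted(kept, key=lambda s: s.start))
    return sites


def intersect_predictions(sites: list[TargetSite]) -> list[TargetSite]:
    """Final targets: sites passing both rule-sets (the shared predictions)."""
    for site in sites:
        site.predicted = site.passes_allen and site.passes_schwab
    return [s for s in sites if s.predicted]


def targets_per_mirna(predicted: list[TargetSite]) -> dict[str, list[str]]:
    """Sorted unique target transcripts per miRNA."""
    table: dict[str, set[str]] = {}
    for site in predicted:
        table.setdefault(site.mirna_id, set()).add(site.transcript_id)
    return {m: sorted(v) for m, v in sorted(table.items())}


def map_cleavage(
    clone_ends: dict[int, int],
    site: TargetSite,
    min_fraction: float = 0.5,
    min_clones: int = 10,
) -> CleavageEvidence:
    """Validate a predicted site from 5'-RACE clone-end positions.

    The canonical cut leaves a 5' end at the transcript base paired to
    miRNA position 10 (cleavage between the bases opposite positions 10
    and 11). The site validates when at least ``min_clones`` clones
    were sequenced and at least ``min_fraction`` of them pile up at the
    canonical position.
    """
    total = sum(clone_ends.values())
    if total < 1:
        raise ValueError("cleavage evidence requires at least one clone")
    canonical = site.cleavage_pos if site.cleavage_pos is not None else site.cleavage_offset
    fraction = clone_ends.get(canonical, 0) / total
    return CleavageEvidence(
        transcript_id=site.transcript_id,
        mirna_id=site.mirna_id,
        clone_ends=dict(sorted(clone_ends.items())),
        canonical_pos=canonical,
        canonical_fraction=fraction,
        n_clones=total,
        validated=total >= min_clones and fraction >= min_fraction,
    )


def render_duplex(site: TargetSite) -> str:
    """Figure-style duplex text: target 5'->3' on top, miRNA 3'->5' below.

    Vertical bars mark Watson-Crick pairs, circles mark G:U wobbles.
    """
    mir_line, match_line, site_line = site.alignment
    top = to_rna(site_line[::-1])
    mid = match_line[::-1]
    bot = to_rna(mir_line[::-1])
    return (
        f"5' {top} 3'  {site.transcript_id}\n"
        f"   {mid}\n"
        f"3' {bot} 5'  {site.mirna_id}"
    )


def write_targets_tsv(sites: list[TargetSite], path, gene_of=None) -> None:
    gene_of = gene_of or (lambda tx: tx.rsplit(".", 1)[0])
    with open(path, "w") as fh:
        fh.write(
            "mirna\tgene\ttranscript\tstart\tend\tscore\tn_mismatch\tn_gu\tn_gap"
            "\tpasses_allen\tpasses_schwab\tpredicted\tcleavage_pos\n"
        )
        for s in sorted(sites, key=lambda s: (s.mirna_id, s.transcript_id, s.start)):
            fh.write(
                f"{s.mirna_id}\t{gene_of(s.transcript_id)}\t{s.transcript_id}"
                f"\t{s.start}\t{s.end}\t{s.score:g}\t{s.n_mismatch}\t{s.n_gu}"
                f"\t{s.n_gap}\t{s.passes_allen}\t{s.passes_schwab}\t{s.predicted}"
                f"\t{s.cleavage_pos}\n"
            )
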