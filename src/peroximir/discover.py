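"""Novel miRNA discovery from unannotated, genome-mapped sRNA tags.

Candidate tags (20-24 nt, at most ``max_genome_hits`` perfect genomic
loci, not previously classified as non-coding RNA or known miRNA) have
genomic windows excised around each locus and folded. A candidate
passes if the fold shows a canonical plant pre-miRNA hairpin: the
mature sequence lies on a single arm, pairs extensively with a star arm
(few mismatched bases, no large asymmetric bulge), and the structure is
thermodynamically stable (MFE at or below a threshold). Passing
candidates are clustered into known families by mature-sequence
similarity or precursor containment, else labelled species-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import GenomeHit
from .fold import FoldEngine, default_engine, pair_table
from .reads import NCRNA_CLASSES, UniqueTag
from .sequtil import revcomp, to_rna


@dataclass
class HairpinCriteria:
    """Structural thresholds for accepting a pre-miRNA hairpin.

    Defaults follow consensus plant miRNA annotation practice: at most 4
    mismatched bases in the miRNA/miRNA* duplex, asymmetric bulges of at
    most 2 nt, at least 16 of the mature bases paired, and an MFE no
    higher than -18 kcal/mol. Tags with more than 10 perfect genomic
    hits are treated as repeats and removed before folding.
    """

    max_duplex_mismatches: int = 4
    max_asymmetric_bulge: int = 2
    min_paired_mature: int = 16
    mfe_threshold: float = -18.0
    max_genome_hits: int = 10
    min_mature_len: int = 20
    max_mature_len: int = 24
    flank_long: int = 200
    flank_short: int = 30


@dataclass
class PrecursorCandidate:
    """An excised genomic window with its fold and hairpin verdict."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    precursor_seq: str
    structure: str
    mfe: float
    mature_seq: str
    mature_start: int
    mature_arm: str | None = None
    star_seq: str | None = None
    passes: bool = False
    family: str = "species_specific"
    diagnostics: dict = field(default_factory=dict)


@dataclass
class NovelMiRNA:
    """A mature tag accepted as a novel miRNA, with all passing loci."""

    id: str
    mature_seq: str
    count_cs: int
    count_ts: int
    loci: list[PrecursorCandidate] = field(default_factory=list)
    family: str = "species_specific"

    @property
    def best_locus(self) -> PrecursorCandidate:
        return min(self.loci, key=lambda c: c.mfe)


def select_candidates(
    tags: dict[str, UniqueTag],
    hits: dict[str, list[GenomeHit]],
    criteria: HairpinCriteria | None = None,
) -> list[UniqueTag]:
    """Tags eligible for hairpin evaluation, in a deterministic order.

    Eligible tags are genome-mapped, 20-24 nt, not assigned to an
    ncRNA class or a known miRNA by the annotation cascade, and have at
    most ``max_genome_hits`` genomic loci (repeat removal; a tag with
    exactly the limit is retained, one more is removed).
    """
    criteria = criteria or HairpinCriteria()
    excluded = set(NCRNA_CLASSES) | {"known_miRNA"}
    out = []
    for seq in sorted(tags):
        tag = tags[seq]
        if tag.category in excluded:
            continue
        tag_hits = hits.get(seq)
        if not tag_hits:
            continue
        if tag_hits[0].n_total_hits > criteria.max_genome_hits:
            continue
        if not (criteria.min_mature_len <= len(seq) <= criteria.max_mature_len):
            continue
        out.append(tag)
    out.sort(key=lambda t: (-t.total, t.sequence))
    return out


def excise_and_fold(
    tag_seq: str,
    tag_hits: list[GenomeHit],
    genome: dict[str, str],
    criteria: HairpinCriteria | None = None,
    engine: FoldEngine | None = None,
) -> list[PrecursorCandidate]:
    """Excise and fold two precursor windows per genomic locus.

    For each locus the mature may sit on either arm, so two windows are
    tried: short upstream / long downstream flank, and the mirror. The
    window is oriented to the hit strand before folding. Windows that
    end up shorter than the tag plus 40 nt after clipping at chromosome
    ends are skipped.
    """
    criteria = criteria or HairpinCriteria()
    engine = engine or default_engine()
    out: list[PrecursorCandidate] = []
    for hit in tag_hits:
        chrom_seq = genome[hit.chrom]
        for up, down in (
            (criteria.flank_short, criteria.flank_long),
            (criteria.flank_long, criteria.flank_short),
        ):
            if hit.strand == "-":
                up, down = down, up  # flanks are relative to the mature 5' end
            ws = max(0, hit.start - up)
            we = min(len(chrom_seq), hit.end + down)
            if we - ws < len(tag_seq) + 40:
                continue
            window = chrom_seq[ws:we]
            if hit.strand == "-":
                window = revcomp(window)
                mature_start = we - hit.end
            else:
                mature_start = hit.start - ws
            structure, mfe = engine(window)
            out.append(
                PrecursorCandidate(
                    id=f"{hit.chrom}:{ws}-{we}:{hit.strand}",
                    chrom=hit.chrom,
                    start=ws,
                    end=we,
                    strand=hit.strand,
                    precursor_seq=window,
                    structure=structure,
                    mfe=mfe,
                    mature_seq=tag_seq,
                    mature_start=mature_start,
                )
            )
    return out


def evaluate_hairpin(
    candidate: PrecursorCandidate, criteria: HairpinCriteria | None = None
) -> PrecursorCandidate:
    """Apply the hairpin criteria; returns the candidate with verdict.

    The verdict is True iff (a) the mature lies entirely on one arm of
    the stem (never straddling the terminal loop), (b) the mature/star
    duplex has at most ``max_duplex_mismatches`` mismatched bases and no
    asymmetric bulge longer than ``max_asymmetric_bulge``, (c) at least
    ``min_paired_mature`` mature bases are paired, and (d) the MFE is at
    or below ``mfe_threshold``. The star sequence is read off the
    structure with the canonical 2-nt 3' overhang.
    """
    criteria = criteria or HairpinCriteria()
    pt = pair_table(candidate.structure)  # raises on contract violations
    m0 = candidate.mature_start
    m1 = m0 + len(candidate.mature_seq)
    region = candidate.structure[m0:m1]
    diag = candidate.diagnostics

    opens = "(" in region
    closes = ")" in region
    diag["one_arm"] = not (opens and closes)
    paired = [i for i in range(m0, m1) if pt[i] != -1]
    diag["paired_mature"] = len(paired)

    mismatches = 0
    max_bulge = 0
    if paired:
        mismatches += (paired[0] - m0) + (m1 - 1 - paired[-1])
        for i, j in zip(paired, paired[1:]):
            a = j - i - 1
            b = abs(pt[i] - pt[j]) - 1
            mismatches += min(a, b)
            max_bulge = max(max_bulge, abs(a - b))
    diag["duplex_mismatches"] = mismatches
    diag["max_asymmetric_bulge"] = max_bulge

    passes = (
        diag["one_arm"]
        and bool(paired)
        and mismatches <= criteria.max_duplex_mismatches
        and max_bulge <= criteria.max_asymmetric_bulge
        and len(paired) >= criteria.min_paired_mature
        and candidate.mfe <= criteria.mfe_threshold
    )
    candidate.passes = passes
    if paired:
        candidate.mature_arm = "5p" if opens else "3p"
        lo = min(pt[i] for i in paired)
        hi = max(pt[i] for i in paired)
        candidate.star_seq = candidate.precursor_seq[lo : min(hi + 3, len(candidate.precursor_seq))]
    return candidate


def discover_novel(
    tags: dict[str, UniqueTag],
    hits: dict[str, list[GenomeHit]],
    genome: dict[str, str],
    criteria: HairpinCriteria | None = None,
    engine: FoldEngine | None = None,
) -> list[NovelMiRNA]:
    """Full discovery pass: select, excise, fold, evaluate, label.

    A tag passing at several loci is reported once with all passing
    loci. Novel ids are assigned in decreasing total-abundance order.
    """
    criteria = criteria or HairpinCriteria()
    engine = engine or default_engine()
    novel: list[NovelMiRNA] = []
    for tag in select_candidates(tags, hits, criteria):
        candidates = excise_and_fold(tag.sequence, hits[tag.sequence], genome, criteria, engine)
        passing = [c for c in (evaluate_hairpin(c, criteria) for c in candidates) if c.passes]
        if passing:
            novel.append(
                NovelMiRNA(
                    id=f"novel_mir_{len(novel) + 1}",
                    mature_seq=tag.sequence,
                    count_cs=tag.count_cs,
                    count_ts=tag.count_ts,
                    loci=passing,
                )
            )
    return novel


def _min_hamming(a: str, b: str) -> int:
    """Minimum mismatch count sliding the shorter sequence along the longer."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for off in range(len(b) - len(a) + 1):
        d = sum(x != y for x, y in zip(a, b[off : off + len(a)]))
        best = min(best, d)
    return best


def cluster_families(
    novel: list[NovelMiRNA],
    known_matures: dict[str, str],
    known_hairpins: dict[str, str] | None = None,
    max_mismatches: int = 2,
) -> list[NovelMiRNA]:
    """Label novel miRNAs with known families where similarity allows.

    A candidate joins a known family if its mature matches a known plant
    mature with at most ``max_mismatches`` substitutions (no indels), or
    if one of its precursors contains a known hairpin's mature sequence;
    otherwise it stays species-specific.
    """
    known_hairpins = known_hairpins or {}
    for nov in novel:
        label = None
        for mir_id, mature in known_matures.items():
            if abs(len(mature) - len(nov.mature_seq)) <= max_mismatches and _min_hamming(
                nov.mature_seq, mature
            ) <= max_mismatches:
                label = mir_id
                break
        if label is None:
            for mir_id, hairpin in known_hairpins.items():
                mature = known_matures.get(mir_id)
                precs = (c.precursor_seq for c in nov.loci)
                if mature and any(mature in p or hairpin in p or p in hairpin for p in precs):
                    label = mir_id
                    break
        nov.family = label or "species_specific"
        for c in nov.loci:
            c.family = nov.family
    return novel


def first_nucleotide_bias(novel: list[NovelMiRNA]) -> pd.DataFrame:
    """Read-weighted 5'-first-nucleotide composition, overall and by length.

    Returns a tidy table (length, nucleotide, count_cs, pct_cs,
    count_ts, pct_ts) with an "all" stratum; nucleotides are rendered in
    the RNA alphabet as in published first-position bias figures.
    """
    rows: dict[tuple[str, str], list[int]] = {}
    for nov in novel:
        nt = to_rna(nov.mature_seq[0])
        for stratum in (str(len(nov.mature_seq)), "all"):
            c = rows.setdefault((stratum, nt), [0, 0])
            c[0] += nov.count_cs
            c[1] += nov.count_ts
    records = []
    strata = sorted({k[0] for k in rows})
    for stratum in strata:
        tot_cs = sum(v[0] for (s, _), v in rows.items() if s == stratum)
        tot_ts = sum(v[1] for (s, _), v in rows.items() if s == stratum)
        for nt in "ACGU":
            cs, ts = rows.get((stratum, nt), (0, 0))
            records.append(
                {
                    "length": stratum,
                    "nucleotide": nt,
                    "count_cs": cs,
                    "pct_cs": round(100.0 * cs / tot_cs, 2) if tot_cs else 0.0,
                    "count_ts": ts,
                    "pct_ts": round(100.0 * ts / tot_ts, 2) if tot_ts else 0.0,
                }
            )
    return pd.DataFrame.from_records(records)


def write_novel_tsv(novel: list[NovelMiRNA], path) -> None:
    """Novel miRNA report: one row per miRNA, all passing loci listed."""
    with open(path, "w") as fh:
        fh.write(
            "id\tmature\tlength\tloci\tarm\tmfe\tfamily\tcount_cs\tcount_ts\n"
        )
        for nov in novel:
            best = nov.best_locus
            loci = ",".join(f"{c.chrom}:{c.start}-{c.end}:{c.strand}" for c in nov.loci)
            fh.write(
                f"{nov.id}\t{to_rna(nov.mature_seq)}\t{len(nov.mature_seq)}\t{loci}"
                f"\t{best.mature_arm}\t{best.mfe:.2f}\t{nov.family}"
                f"\t{nov.count_cs}\t{nov.count_ts}\n"
            )


def write_hairpins(novel: list[NovelMiRNA], fasta_path, structure_path) -> None:
    """Best precursor per novel miRNA as FASTA plus dot-bracket sidecar."""
    with open(fasta_path, "w") as fa, open(structure_path, "w") as db:
        for nov in novel:
            best = nov.best_locus
            header = f"{nov.id} {best.chrom}:{best.start}-{best.end}:{best.strand} MFE={best.mfe:.2f}"
            fa.write(f">{header}\n{to_rna(best.precursor_seq)}\n")
            db.write(f">{header}\n{best.structure}\n")
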