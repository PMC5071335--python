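"""Ordered annotation cascade for unique sRNA tags.

Each tag is assigned at most one of seven categories, mirroring the
standard sRNA triage: structured non-coding RNA classes first (rRNA,
tRNA, snRNA, snoRNA, scRNA), then known mature miRNAs, then gene-model
overlap of perfect genome hits (exon/intron x sense/antisense), and
finally "unknown" for everything else. A tag that matches a non-coding
RNA never re-enters the cascade, so it can never become a miRNA
candidate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from .reads import NCRNA_CLASSES, UniqueTag
from .sequtil import fmt_pct, revcomp, to_dna

CATEGORY_ORDER = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "known_miRNA",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unknown",
)

# fixed classification priority among genome-hit overlaps
_GENIC_PRIORITY = ("exon_sense", "exon_antisense", "intron_sense", "intron_antisense")


@dataclass
class GenomeHit:
    """One perfect genomic match of a tag (0-based half-open interval)."""

    tag_seq: str
    chrom: str
    start: int
    end: int
    strand: str
    n_total_hits: int = 0


@dataclass
class AnnotationSummary:
    """Per-category redundant/unique counts for both libraries."""

    counts: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = [
            "category\tredundant_cs\tredundant_cs_pct\tunique_cs\tunique_cs_pct"
            "\tredundant_ts\tredundant_ts_pct\tunique_ts\tunique_ts_pct"
        ]
        tot = [0, 0, 0, 0]
        for cat in CATEGORY_ORDER:
            for i, v in enumerate(self.counts.get(cat, (0, 0, 0, 0))):
                tot[i] += v
        for cat in CATEGORY_ORDER:
            rc, uc, rt, ut = self.counts.get(cat, (0, 0, 0, 0))
            lines.append(
                f"{cat}\t{rc}\t{fmt_pct(rc, tot[0])}\t{uc}\t{fmt_pct(uc, tot[1])}"
                f"\t{rt}\t{fmt_pct(rt, tot[2])}\t{ut}\t{fmt_pct(ut, tot[3])}"
            )
        lines.append(f"total\t{tot[0]}\t100.00\t{tot[1]}\t100.00\t{tot[2]}\t100.00\t{tot[3]}\t100.00")
        return "\n".join(lines) + "\n"


def load_fasta(path) -> dict[str, str]:
    """Ordered id -> DNA sequence map from a FASTA file."""
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def match_ncrna(tags: dict[str, UniqueTag], ncrna_ref: dict[str, str]) -> int:
    """Assign non-coding RNA classes by exact substring containment.

    Reference ids must be prefixed with their class (e.g. ``rRNA_17``).
    Sense and antisense containment both count; the first reference in
    file order wins, which makes cross-class ties deterministic.
    Returns the number of tags assigned.
    """
    assigned = 0
    for tag in tags.values():
        if tag.category is not None:
            continue
        rc = revcomp(tag.sequence)
        for ref_id, ref_seq in ncrna_ref.items():
            if tag.sequence in ref_seq or rc in ref_seq:
                cls = ref_id.split("_")[0]
                if cls not in NCRNA_CLASSES:
                    raise ValueError(f"ncRNA reference id {ref_id!r} has no class prefix")
                tag.category = cls
                assigned += 1
                break
    return assigned


def map_genome(
    tags: dict[str, UniqueTag], genome: dict[str, str]
) -> dict[str, list[GenomeHit]]:
    """All perfect occurrences of each tag on both genome strands."""
    hits: dict[str, list[GenomeHit]] = {}
    for seq in tags:
        found: list[GenomeHit] = []
        rc = revcomp(seq)
        for chrom, chrom_seq in genome.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                start = chrom_seq.find(query)
                while start != -1:
                    found.append(GenomeHit(seq, chrom, start, start + len(seq), strand))
                    start = chrom_seq.find(query, start + 1)
        for h in found:
            h.n_total_hits = len(found)
        if found:
            hits[seq] = found
    return hits


def identify_known(
    tags: dict[str, UniqueTag],
    mature_ref: dict[str, str],
    hairpin_ref: dict[str, str],
    shift: int = 2,
) -> dict[str, tuple[int, int]]:
    """Assign tags to known miRNAs; returns per-miRNA (cs, ts) counts.

    A tag matches a known miRNA if it equals the mature sequence, or is
    an exact substring of that miRNA's hairpin whose 5'/3' ends are each
    within ``shift`` nt of the annotated mature ends (isomiR-style
    offsets, no internal mismatches).
    """
    for mir_id, mature in mature_ref.items():
        hairpin = hairpin_ref.get(mir_id)
        if hairpin is None or mature not in hairpin:
            raise ValueError(f"mature {mir_id} absent from its hairpin reference")
    counts: dict[str, tuple[int, int]] = {m: (0, 0) for m in mature_ref}
    for tag in tags.values():
        if tag.category is not None:
            continue
        for mir_id, mature in mature_ref.items():
            if tag.sequence == mature:
                matched = True
            else:
                hairpin = hairpin_ref[mir_id]
                m = hairpin.find(mature)
                p = hairpin.find(tag.sequence)
                matched = (
                    p != -1
                    and abs(p - m) <= shift
                    and abs((p + len(tag.sequence)) - (m + len(mature))) <= shift
                )
            if matched:
                tag.category = "known_miRNA"
                cs, ts = counts[mir_id]
                counts[mir_id] = (cs + tag.count_cs, ts + tag.count_ts)
                break
    return {m: c for m, c in counts.items() if c != (0, 0)}


def load_gene_features(gff3_path) -> dict[str, list[tuple[int, int, str, str]]]:
    """Exon/intron intervals per chromosome from a GFF3 file.

    Returns ``chrom -> [(start0, end0, strand, "exon"|"intron"), ...]``
    with 0-based half-open coordinates. Introns are the gaps between
    consecutive exons of a gene.
    """
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several parse error types
        raise ValueError(f"{gff3_path}: malformed GFF3: {exc}") from exc
    features: dict[str, list[tuple[int, int, str, str]]] = {}
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        )
        per_chrom = features.setdefault(gene.seqid, [])
        for s, e in exons:
            per_chrom.append((s, e, gene.strand, "exon"))
        for (_, prev_end), (next_start, _) in zip(exons, exons[1:]):
            if next_start > prev_end:
                per_chrom.append((prev_end, next_start, gene.strand, "intron"))
    return features


def categorize(
    tags: dict[str, UniqueTag],
    hits: dict[str, list[GenomeHit]],
    gene_features: dict[str, list[tuple[int, int, str, str]]],
) -> AnnotationSummary:
    """Classify remaining tags by gene-model overlap and summarize all.

    A multi-locus tag is classified once, by the highest-priority
    overlap among all its hits (exon beats intron, sense beats
    antisense); mapped tags overlapping no gene, and unmapped tags,
    fall through to "unknown".
    """
    for tag in tags.values():
        if tag.category is not None:
            continue
        best: int | None = None
        for hit in hits.get(tag.sequence, []):
            for fs, fe, fstrand, kind in gene_features.get(hit.chrom, []):
                if hit.start < fe and fs < hit.end:
                    orient = "sense" if hit.strand == fstrand else "antisense"
                    rank = _GENIC_PRIORITY.index(f"{kind}_{orient}")
                    if best is None or rank < best:
                        best = rank
        tag.category = _GENIC_PRIORITY[best] if best is not None else "unknown"

    summary = AnnotationSummary()
    for tag in tags.values():
        cat = tag.category or "unknown"
        rc, uc, rt, ut = summary.counts.get(cat, (0, 0, 0, 0))
        summary.counts[cat] = (
            rc + tag.count_cs,
            uc + (1 if tag.count_cs else 0),
            rt + tag.count_ts,
            ut + (1 if tag.count_ts else 0),
        )
    return summary


def extract_transcripts(genome: dict[str, str], gff3_path) -> dict[str, str]:
    """Spliced transcript sequences (5'->3') from gene models.

    Exons are concatenated in genomic order and reverse-complemented
    for minus-strand genes; one transcript per mRNA feature.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        seq = "".join(genome[mrna.seqid][s:e] for s, e in exons)
        transcripts[mrna.id] = revcomp(seq) if mrna.strand == "-" else seq
    return transcripts
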