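"""Raw-read processing: adapter trimming, length filtering, tag collapsing.

Library construction enriches 18-30 nt RNAs and ligates a 3' adapter, so
each usable read is ``insert + adapter[ + anything]``. Trimming locates
the adapter as the longest adapter *prefix* matching a read suffix
(exact match, configurable minimum overlap) and keeps inserts inside the
clean length window (default 18-30 nt; shorter inserts are discarded).
Clean reads from the control (CS) and treated (TS) libraries are then
collapsed into unique tags with exact per-library counts.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

from .sequtil import fmt_pct

CATEGORIES = (
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

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA")


class FastqParseError(ValueError):
    """Malformed FASTQ input, annotated with the offending line number."""


@dataclass
class UniqueTag:
    """A collapsed unique sRNA sequence with per-library counts."""

    sequence: str
    count_cs: int = 0
    count_ts: int = 0
    category: str | None = None

    @property
    def total(self) -> int:
        return self.count_cs + self.count_ts


@dataclass
class LibraryStats:
    """Bookkeeping counters for one sequencing library."""

    raw_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0
    mapped_unique_tags: int = 0
    # length -> (redundant count, unique count)
    length_histogram: dict[int, tuple[int, int]] = field(default_factory=dict)

    def clean_pct(self) -> str:
        return fmt_pct(self.clean_reads, self.raw_reads)

    def mapped_pct(self) -> str:
        return fmt_pct(self.mapped_unique_tags, self.unique_tags)


def _iter_fastq(path) -> Iterator[str]:
    """Yield read sequences (upper-case DNA) from a Phred+33 FASTQ file."""
    record_no = 0
    try:
        with open(path) as handle:
            for record in SeqIO.parse(handle, "fastq"):
                record_no += 1
                yield str(record.seq).upper()
    except ValueError as exc:
        # SeqIO does not track line numbers; reconstruct from record count
        # (4 lines per record in the files this pipeline writes and reads).
        raise FastqParseError(
            f"{path}: malformed FASTQ near line {record_no * 4 + 1}: {exc}"
        ) from exc


def locate_adapter(read: str, adapter: str, min_overlap: int = 6) -> int:
    """Insert length after trimming, or -1 if no adapter hit.

    The adapter is located by the longest prefix of ``adapter`` matching
    a suffix (or internal run to the read end side) of the read with zero
    mismatches; ties resolve to the leftmost (longest) match.
    """
    full = read.find(adapter)
    if full != -1:
        return full
    max_olap = min(len(adapter), len(read))
    for olap in range(max_olap, min_overlap - 1, -1):
        i = len(read) - olap
        if read[i : i + olap] == adapter[:olap]:
            return i
    return -1


def trim_and_filter(
    reads: Iterable[str] | str,
    adapter: str,
    min_len: int = 18,
    max_len: int = 30,
    min_overlap: int = 6,
    drop_n: bool = True,
) -> tuple[list[str], LibraryStats]:
    """Trim the 3' adapter and apply the clean-length window.

    ``reads`` is a FASTQ path or an iterable of sequences. Returns the
    clean inserts plus partial library stats (raw/clean counts). Reads
    with no adapter hit are kept untrimmed if they already fall inside
    the length window, otherwise discarded; reads containing N are
    discarded so that downstream exact-match genome mapping is meaningful.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = _iter_fastq(reads)
    stats = LibraryStats()
    clean: list[str] = []
    for read in reads:
        stats.raw_reads += 1
        cut = locate_adapter(read, adapter, min_overlap)
        insert = read[:cut] if cut != -1 else read
        if not (min_len <= len(insert) <= max_len):
            continue
        if drop_n and "N" in insert:
            continue
        clean.append(insert)
        stats.clean_reads += 1
    return clean, stats


def collapse_tags(
    clean_cs: Iterable[str], clean_ts: Iterable[str]
) -> dict[str, UniqueTag]:
    """Collapse clean reads of both libraries into unique tags.

    The result is keyed and ordered by sequence, so it is independent of
    input read order.
    """
    cs = Counter(clean_cs)
    ts = Counter(clean_ts)
    tags = {
        seq: UniqueTag(seq, count_cs=cs.get(seq, 0), count_ts=ts.get(seq, 0))
        for seq in sorted(set(cs) | set(ts))
    }
    return tags


def length_distribution(
    tags: dict[str, UniqueTag] | Iterable[UniqueTag],
) -> dict[str, dict[int, tuple[int, int]]]:
    """Per-library length histograms over collapsed tags.

    Returns ``{"cs": {length: (redundant, unique)}, "ts": ...}`` where
    redundant counts are read-weighted and unique counts tag-weighted.
    """
    if isinstance(tags, dict):
        tags = tags.values()
    hist: dict[str, dict[int, list[int]]] = {"cs": {}, "ts": {}}
    for tag in tags:
        n = len(tag.sequence)
        for lib, count in (("cs", tag.count_cs), ("ts", tag.count_ts)):
            if count > 0:
                red, uniq = hist[lib].setdefault(n, [0, 0])
                hist[lib][n][0] = red + count
                hist[lib][n][1] = uniq + 1
    return {
        lib: {n: (red, uniq) for n, (red, uniq) in sorted(d.items())}
        for lib, d in hist.items()
    }


def length_distribution_table(tags: dict[str, UniqueTag]) -> str:
    """TSV rendering of the length distribution with two-decimal percentages."""
    hist = length_distribution(tags)
    lengths = sorted(set(hist["cs"]) | set(hist["ts"]))
    totals = {
        lib: {
            "red": sum(v[0] for v in hist[lib].values()),
            "uniq": sum(v[1] for v in hist[lib].values()),
        }
        for lib in ("cs", "ts")
    }
    out = io.StringIO()
    out.write(
        "length\tredundant_cs\tredundant_cs_pct\tunique_cs\tunique_cs_pct"
        "\tredundant_ts\tredundant_ts_pct\tunique_ts\tunique_ts_pct\n"
    )
    for n in lengths:
        row = [str(n)]
        for lib in ("cs", "ts"):
            red, uniq = hist[lib].get(n, (0, 0))
            row += [
                str(red),
                fmt_pct(red, totals[lib]["red"]),
                str(uniq),
                fmt_pct(uniq, totals[lib]["uniq"]),
            ]
        out.write("\t".join(row) + "\n")
    return out.getvalue()


def write_tags_tsv(tags: dict[str, UniqueTag], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount_cs\tcount_ts\tcategory\n")
        for seq in sorted(tags):
            t = tags[seq]
            fh.write(f"{t.sequence}\t{t.count_cs}\t{t.count_ts}\t{t.category or ''}\n")


def read_tags_tsv(path) -> dict[str, UniqueTag]:
    tags: dict[str, UniqueTag] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            seq, cs, ts, cat = line.rstrip("\n").split("\t")
            tags[seq] = UniqueTag(seq, int(cs), int(ts), cat or None)
    return tags
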