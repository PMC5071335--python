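"""Pipeline orchestration: stage functions over a shared work directory.

Each stage reads the files earlier stages wrote, so stages are
individually re-runnable and idempotent; ``run_pipeline`` executes the
full cascade. Bookkeeping numbers accumulate in ``stats.json`` and feed
the final summary report. Missing upstream inputs raise an error that
names the producing stage before any computation starts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, diffexp, discover, network, reads, report, simulate, targets
from .sequtil import to_dna, to_rna


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters; echoed into output headers."""

    outdir: Path = Path("peroximir_out")
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    criteria: discover.HairpinCriteria = field(default_factory=discover.HairpinCriteria)
    min_len: int = 18
    max_len: int = 30
    min_adapter_overlap: int = 6
    known_shift: int = 2
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    allen_max_s: float = 4.0
    cleavage_min_fraction: float = 0.5
    cleavage_min_clones: int = 10
    go_alpha: float = 0.01

    def __post_init__(self):
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "sim":
                for k, v in value.items():
                    if not hasattr(cfg.sim, k):
                        raise ValueError(f"unknown simulation parameter {k!r}")
                    setattr(cfg.sim, k, v)
            elif key == "criteria":
                for k, v in value.items():
                    if not hasattr(cfg.criteria, k):
                        raise ValueError(f"unknown hairpin criterion {k!r}")
                    setattr(cfg.criteria, k, v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        cfg.outdir = Path(cfg.outdir)
        return cfg


def _require(config: PipelineConfig, stage: str, producer: str, *names: str) -> None:
    for name in names:
        if not (config.outdir / name).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs {name}, produced by stage '{producer}' - run it first"
            )


def _load_stats(config: PipelineConfig) -> dict:
    path = config.outdir / "stats.json"
    return json.loads(path.read_text()) if path.exists() else {}


def _save_stats(config: PipelineConfig, stats: dict) -> None:
    (config.outdir / "stats.json").write_text(json.dumps(stats, indent=1, sort_keys=True))


def stage_simulate(config: PipelineConfig) -> simulate.GroundTruth:
    config.outdir.mkdir(parents=True, exist_ok=True)
    truth, _ = simulate.generate(config.sim, config.outdir)
    return truth


def stage_process(config: PipelineConfig) -> dict[str, reads.UniqueTag]:
    _require(config, "process", "simulate", "reads_cs.fastq", "reads_ts.fastq")
    out = config.outdir
    adapter = config.sim.adapter_seq
    clean = {}
    stats = _load_stats(config)
    for lib in ("cs", "ts"):
        clean[lib], lib_stats = reads.trim_and_filter(
            str(out / f"reads_{lib}.fastq"),
            adapter,
            config.min_len,
            config.max_len,
            config.min_adapter_overlap,
        )
        stats[f"raw_reads_{lib}"] = lib_stats.raw_reads
        stats[f"clean_reads_{lib}"] = lib_stats.clean_reads
    tags = reads.collapse_tags(clean["cs"], clean["ts"])
    stats["unique_tags_cs"] = sum(1 for t in tags.values() if t.count_cs)
    stats["unique_tags_ts"] = sum(1 for t in tags.values() if t.count_ts)
    reads.write_tags_tsv(tags, out / "tags.tsv")
    for lib in ("cs", "ts"):
        with open(out / f"clean_{lib}.fa", "w") as fh:
            i = 0
            for seq in sorted(tags):
                count = getattr(tags[seq], f"count_{lib}")
                if count:
                    i += 1
                    fh.write(f">tag_{i} x{count}\n{seq}\n")
    (out / "length_distribution.tsv").write_text(reads.length_distribution_table(tags))
    _save_stats(config, stats)
    return tags


def stage_annotate(config: PipelineConfig):
    _require(config, "annotate", "simulate", "genome.fa", "ncrna.fa", "mirna_mature.fa",
             "mirna_hairpin.fa", "genes.gff3")
    _require(config, "annotate", "process", "tags.tsv")
    out = config.outdir
    tags = reads.read_tags_tsv(out / "tags.tsv")
    for tag in tags.values():
        tag.category = None
    ncrna_ref = annotate.load_fasta(out / "ncrna.fa")
    annotate.match_ncrna(tags, ncrna_ref)
    genome = annotate.load_fasta(out / "genome.fa")
    hits = annotate.map_genome(tags, genome)
    known = annotate.identify_known(
        tags,
        annotate.load_fasta(out / "mirna_mature.fa"),
        annotate.load_fasta(out / "mirna_hairpin.fa"),
        config.known_shift,
    )
    summary = annotate.categorize(tags, hits, annotate.load_gene_features(out / "genes.gff3"))
    (out / "annotation_summary.tsv").write_text(summary.to_tsv())
    with open(out / "known_mirna_counts.tsv", "w") as fh:
        fh.write("mirna\tcount_cs\tcount_ts\n")
        for mir_id in sorted(known):
            cs, ts = known[mir_id]
            fh.write(f"{mir_id}\t{cs}\t{ts}\n")
    with open(out / "genome_hits.tsv", "w") as fh:
        fh.write("sequence\tchrom\tstart\tend\tstrand\tn_total_hits\n")
        for seq in sorted(hits):
            for h in hits[seq]:
                fh.write(f"{seq}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.n_total_hits}\n")
    reads.write_tags_tsv(tags, out / "tags.tsv")
    stats = _load_stats(config)
    stats["mapped_unique_tags_cs"] = sum(
        1 for t in tags.values() if t.count_cs and t.sequence in hits
    )
    stats["mapped_unique_tags_ts"] = sum(
        1 for t in tags.values() if t.count_ts and t.sequence in hits
    )
    stats["known_mirnas_cs"] = sum(1 for c in known.values() if c[0] > 0)
    stats["known_mirnas_ts"] = sum(1 for c in known.values() if c[1] > 0)
    stats["known_mirnas_both"] = sum(1 for c in known.values() if c[0] > 0 and c[1] > 0)
    stats["known_mirnas_total"] = len(known)
    stats["reads_per_known_mirna"] = {m: known[m][0] + known[m][1] for m in sorted(known)}
    _save_stats(config, stats)
    return tags, hits, known, summary


def _read_hits(path) -> dict[str, list[annotate.GenomeHit]]:
    hits: dict[str, list[annotate.GenomeHit]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            seq, chrom, start, end, strand, n = line.rstrip("\n").split("\t")
            hits.setdefault(seq, []).append(
                annotate.GenomeHit(seq, chrom, int(start), int(end), strand, int(n))
            )
    return hits


def stage_discover(config: PipelineConfig) -> list[discover.NovelMiRNA]:
    _require(config, "discover", "annotate", "tags.tsv", "genome_hits.tsv")
    _require(config, "discover", "simulate", "genome.fa", "mirna_mature.fa", "mirna_hairpin.fa")
    out = config.outdir
    tags = reads.read_tags_tsv(out / "tags.tsv")
    hits = _read_hits(out / "genome_hits.tsv")
    genome = annotate.load_fasta(out / "genome.fa")
    novel = discover.discover_novel(tags, hits, genome, config.criteria)
    discover.cluster_families(
        novel,
        annotate.load_fasta(out / "mirna_mature.fa"),
        annotate.load_fasta(out / "mirna_hairpin.fa"),
    )
    discover.write_novel_tsv(novel, out / "novel_mirnas.tsv")
    discover.write_hairpins(novel, out / "novel_hairpins.fa", out / "novel_hairpins.db")
    discover.first_nucleotide_bias(novel).to_csv(
        out / "first_nt_bias.tsv", sep="\t", index=False
    )
    stats = _load_stats(config)
    stats["novel_mirnas"] = len(novel)
    stats["novel_family_clustered"] = sum(1 for n in novel if n.family != "species_specific")
    stats["novel_species_specific"] = sum(1 for n in novel if n.family == "species_specific")
    stats["novel_mfes"] = [round(n.best_locus.mfe, 2) for n in novel]
    _save_stats(config, stats)
    return novel


def stage_diffexp(config: PipelineConfig) -> pd.DataFrame:
    _require(config, "diffexp", "annotate", "known_mirna_counts.tsv")
    _require(config, "diffexp", "discover", "novel_mirnas.tsv")
    out = config.outdir
    stats = _load_stats(config)
    totals = diffexp.LibraryTotals(stats["clean_reads_cs"], stats["clean_reads_ts"])
    mature_ref = annotate.load_fasta(out / "mirna_mature.fa")
    records: list[diffexp.ExpressionRecord] = []
    known = pd.read_csv(out / "known_mirna_counts.tsv", sep="\t")
    for row in known.itertuples():
        records.append(
            diffexp.ExpressionRecord(
                row.mirna, mature_ref.get(row.mirna, ""), int(row.count_cs), int(row.count_ts)
            )
        )
    novel = pd.read_csv(out / "novel_mirnas.tsv", sep="\t")
    for row in novel.itertuples():
        records.append(
            diffexp.ExpressionRecord(
                row.id, to_dna(row.mature), int(row.count_cs), int(row.count_ts)
            )
        )
    diffexp.normalize_and_adjust(records, totals)
    up, down = diffexp.screen_responsive(records, totals, config.fc_threshold, config.p_threshold)
    table = diffexp.diffexp_table(records)
    header = (
        f"# fc_threshold={config.fc_threshold} p_threshold={config.p_threshold} "
        f"N1={totals.n1} N2={totals.n2}\n"
    )
    with open(out / "diffexp.tsv", "w") as fh:
        fh.write(header)
        table.to_csv(fh, sep="\t", index=False)
    for name, subset in (("up", up), ("down", down)):
        with open(out / f"responsive_{name}.tsv", "w") as fh:
            fh.write("sequence\tname\tlog2_t_over_c\tp_value\n")
            for rec in subset:
                fh.write(
                    f"{to_rna(rec.sequence)}\t{rec.mirna_id}\t{rec.log2fc:.2f}"
                    f"\t{rec.p_value:.3g}\n"
                )
    stats["responsive_up"] = len(up)
    stats["responsive_down"] = len(down)
    _save_stats(config, stats)
    return table


def stage_targets(config: PipelineConfig) -> list[targets.TargetSite]:
    _require(config, "targets", "simulate", "genome.fa", "genes.gff3")
    _require(config, "targets", "annotate", "known_mirna_counts.tsv")
    _require(config, "targets", "discover", "novel_mirnas.tsv")
    out = config.outdir
    genome = annotate.load_fasta(out / "genome.fa")
    transcripts = annotate.extract_transcripts(genome, out / "genes.gff3")
    catalog: dict[str, str] = {}
    mature_ref = annotate.load_fasta(out / "mirna_mature.fa")
    known = pd.read_csv(out / "known_mirna_counts.tsv", sep="\t")
    for row in known.itertuples():
        if row.mirna in mature_ref:
            catalog[row.mirna] = mature_ref[row.mirna]
    novel = pd.read_csv(out / "novel_mirnas.tsv", sep="\t")
    for row in novel.itertuples():
        catalog[row.id] = to_dna(row.mature)
    sites = targets.scan_transcriptome(catalog, transcripts, config.allen_max_s)
    predicted = targets.intersect_predictions(sites)
    targets.write_targets_tsv(sites, out / "targets.tsv")
    stats = _load_stats(config)
    stats["predicted_target_transcripts"] = len({(s.mirna_id, s.transcript_id) for s in predicted})
    stats["predicted_target_genes"] = len(
        {(s.mirna_id, s.transcript_id.rsplit(".", 1)[0]) for s in predicted}
    )
    _save_stats(config, stats)
    return sites


def stage_cleavage(config: PipelineConfig) -> list[targets.CleavageEvidence]:
    _require(config, "cleavage", "simulate", "race_clones.tsv")
    _require(config, "cleavage", "targets", "targets.tsv")
    out = config.outdir
    race = pd.read_csv(out / "race_clones.tsv", sep="\t")
    site_table = pd.read_csv(out / "targets.tsv", sep="\t")
    evidence: list[targets.CleavageEvidence] = []
    rows = []
    # RACE products are anchored to a transcript position; match them to
    # the predicted site covering that position (catalog miRNA names may
    # differ from the names in the evidence file)
    for (tx, tx_start), group in race.groupby(["transcript", "site_tx_start"], sort=True):
        match = site_table[
            (site_table["transcript"] == tx)
            & (site_table["start"] <= int(tx_start))
            & (site_table["end"] > int(tx_start))
            & site_table["predicted"]
        ]
        if match.empty:
            continue
        mir = str(match.iloc[0]["mirna"])
        site = targets.TargetSite(
            mirna_id=mir, transcript_id=tx,
            start=int(match.iloc[0]["start"]), end=int(match.iloc[0]["end"]),
            score=float(match.iloc[0]["score"]), n_mismatch=0, n_gu=0, n_gap=0,
            status=(), alignment=("", "", ""),
            cleavage_offset=0, cleavage_pos=int(match.iloc[0]["cleavage_pos"]),
        )
        ends = {int(r.position): int(r.clones) for r in group.itertuples()}
        ev = targets.map_cleavage(
            ends, site, config.cleavage_min_fraction, config.cleavage_min_clones
        )
        evidence.append(ev)
        rows.append(
            f"{mir}\t{tx}\t{ev.canonical_pos}\t{ev.n_clones}"
            f"\t{ev.canonical_fraction:.2f}\t{ev.validated}"
        )
    with open(out / "cleavage.tsv", "w") as fh:
        fh.write("mirna\ttranscript\tcanonical_pos\tn_clones\tcanonical_fraction\tvalidated\n")
        for row in rows:
            fh.write(row + "\n")
    stats = _load_stats(config)
    stats["validated_cleavage_sites"] = sum(1 for e in evidence if e.validated)
    _save_stats(config, stats)
    return evidence


def stage_network(config: PipelineConfig):
    _require(config, "network", "simulate", "ppi.tsv", "tf_list.txt")
    _require(config, "network", "diffexp", "diffexp.tsv")
    _require(config, "network", "targets", "targets.tsv")
    out = config.outdir
    de = pd.read_csv(out / "diffexp.tsv", sep="\t", comment="#")
    responsive_fc = {
        str(r.name_): float(r.log2_t_over_c)
        for r in de.rename(columns={"name": "name_"}).itertuples()
        if r.responsive
    }
    site_table = pd.read_csv(out / "targets.tsv", sep="\t")
    predicted = site_table[site_table["predicted"]]
    target_map: dict[str, list[str]] = {}
    for r in predicted.itertuples():
        target_map.setdefault(str(r.mirna), [])
        if str(r.gene) not in target_map[str(r.mirna)]:
            target_map[str(r.mirna)].append(str(r.gene))
    ppi = [
        (str(r.protein_a), str(r.protein_b), float(r.score))
        for r in pd.read_csv(out / "ppi.tsv", sep="\t").itertuples()
    ]
    tf_genes = set((out / "tf_list.txt").read_text().split())
    g = network.build_network(responsive_fc, target_map, ppi, tf_genes)
    network.export_network(g, out / "network.sif", "sif")
    network.export_network(g, out / "network.graphml", "graphml")
    ppi_deg, mir_deg = network.degree_summary(g)
    with open(out / "degrees.tsv", "w") as fh:
        fh.write("node\tkind\tdegree\n")
        for node, deg in ppi_deg:
            fh.write(f"{node}\tprotein_ppi\t{deg}\n")
        for node, deg in mir_deg:
            fh.write(f"{node}\tmirna_targets\t{deg}\n")
    stats = _load_stats(config)
    stats["network_nodes"] = g.number_of_nodes()
    stats["network_edges"] = g.number_of_edges()
    _save_stats(config, stats)
    return g


def stage_enrich(config: PipelineConfig) -> list[network.EnrichmentResult]:
    _require(config, "enrich", "simulate", "go_map.tsv")
    _require(config, "enrich", "diffexp", "diffexp.tsv")
    _require(config, "enrich", "targets", "targets.tsv")
    out = config.outdir
    go = pd.read_csv(out / "go_map.tsv", sep="\t")
    go_map: dict[str, set[str]] = {}
    for r in go.itertuples():
        go_map.setdefault(str(r.gene), set()).add(str(r.go_term))
    de = pd.read_csv(out / "diffexp.tsv", sep="\t", comment="#")
    responsive = {str(r[2]) for r in de.itertuples() if r.responsive}  # name column
    site_table = pd.read_csv(out / "targets.tsv", sep="\t")
    genes = {
        str(r.gene)
        for r in site_table[site_table["predicted"]].itertuples()
        if str(r.mirna) in responsive
    }
    results = network.go_enrichment(genes & set(go_map), go_map, alpha=config.go_alpha)
    (out / "enrichment.tsv").write_text(network.enrichment_tsv(results))
    stats = _load_stats(config)
    stats["significant_go_terms"] = sum(1 for r in results if r.significant)
    _save_stats(config, stats)
    return results


def stage_report(config: PipelineConfig) -> str:
    _require(config, "report", "process", "tags.tsv")
    stats = _load_stats(config)
    text = report.summary_report(stats)
    (config.outdir / "report.tsv").write_text(text)
    return text


STAGES = (
    ("simulate", stage_simulate),
    ("process", stage_process),
    ("annotate", stage_annotate),
    ("discover", stage_discover),
    ("diffexp", stage_diffexp),
    ("targets", stage_targets),
    ("cleavage", stage_cleavage),
    ("network", stage_network),
    ("enrich", stage_enrich),
    ("report", stage_report),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in cascade order; returns the final stats."""
    for _name, fn in STAGES:
        fn(config)
    return _load_stats(config)
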