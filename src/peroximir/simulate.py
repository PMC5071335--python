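"""Self-consistent synthetic dataset generator with known ground truth.

The generator emulates a two-library sRNA sequencing experiment on a
small model-grass-like genome: miRNA hairpin loci (a subset labelled
"known", the rest left for novel discovery), structured ncRNA
contaminants, protein-coding genes with exon/intron structure and
planted miRNA target sites, repeat-derived tags at controlled copy
number, a GO annotation map with one deliberately enriched term among
stress-responsive targets, and a PPI edge list with a planted hub.

Reads are drawn per library from a multinomial over species, with
per-miRNA fold changes applied to the treatment library; random
unmappable noise reads and uniform genomic "degradation" fragments make
the annotation cascade non-trivial. Reads carry the 3' adapter and
constant high quality, and are simulated without sequencing errors so
exact-match mapping stays meaningful. Every planted precursor is
re-excised from the assembled genome and verified to pass the default
hairpin criteria at generation time, so downstream recovery is a true
pipeline property rather than luck.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import GenomeHit
from .discover import HairpinCriteria, evaluate_hairpin, excise_and_fold
from .fold import FoldEngine, default_engine
from .sequtil import revcomp

NCRNA_CLASS_CYCLE = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment (defaults = study conditions)."""

    seed: int = 1
    n_chromosomes: int = 2
    chromosome_length: int = 60_000
    n_planted_mirnas: int = 30
    n_known_mirnas: int = 10
    n_planted_ncrnas: int = 10
    n_genes: int = 60
    n_target_genes: int = 28
    library_depth_cs: int = 50_000
    library_depth_ts: int = 50_000
    per_mirna_fold_change: dict[str, float] | None = None
    n_up: int = 6  # default responsive design: 6 up at 4x, 6 down at 0.25x
    n_down: int = 6
    responsive_fold: float = 4.0
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length_range: tuple[int, int] = (20, 24)
    noise_fraction: float = 0.05
    degradation_share: float = 0.15
    ncrna_share: float = 0.28
    repeat_share: float = 0.02
    repeat_copy_numbers: tuple[int, ...] = (10, 11)
    mirna_abundance: dict[str, float] | None = None
    error_rate: float = 0.0  # sequencing errors off by default
    first_nt_probs: tuple[float, float, float, float] = (0.10, 0.50, 0.08, 0.32)  # A C G T(U)
    max_design_tries: int = 60

    def validate(self) -> None:
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.n_known_mirnas > self.n_planted_mirnas:
            raise ValueError("n_known_mirnas cannot exceed n_planted_mirnas")
        if self.per_mirna_fold_change is not None:
            if any(f <= 0 for f in self.per_mirna_fold_change.values()):
                raise ValueError("fold changes must be strictly positive")
        if self.read_length_range[0] < 18:
            raise ValueError("read lengths below the 18 nt clean window are unusable")


@dataclass
class PlantedMiRNA:
    id: str
    mature: str
    star: str
    precursor: str
    chrom: str = ""
    start: int = 0  # precursor interval, 0-based half-open
    end: int = 0
    strand: str = "+"
    arm: str = "5p"
    known: bool = False
    fold_change: float = 1.0

    @property
    def mature_start(self) -> int:
        off = self.precursor.find(self.mature)
        return self.start + off


@dataclass
class GeneModel:
    id: str
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)  # absolute, 0-based
    transcript: str = ""

    @property
    def transcript_id(self) -> str:
        return f"{self.id}.1"


@dataclass
class GroundTruth:
    config: SimulationConfig
    genome: dict[str, str]
    mirnas: list[PlantedMiRNA]
    ncrnas: list[tuple[str, str, str, int, int]]  # (class_id, seq, chrom, start, end)
    genes: list[GeneModel]
    target_sites: list[tuple[str, str, int]]  # (mirna_id, gene_id, transcript pos)
    repeat_tags: list[tuple[str, int]]
    go_map: dict[str, set[str]]
    enriched_term: str
    ppi_edges: list[tuple[str, str, float]]
    hub_gene: str
    tf_genes: set[str]
    race_cases: list[dict]

    @property
    def true_responsive(self) -> set[str]:
        return {m.id for m in self.mirnas if abs(np.log2(m.fold_change)) >= 1.0}

    @property
    def known_mirnas(self) -> list[PlantedMiRNA]:
        return [m for m in self.mirnas if m.known]

    @property
    def novel_mirnas(self) -> list[PlantedMiRNA]:
        return [m for m in self.mirnas if not m.known]


def _random_seq(rng: np.random.Generator, n: int, probs=None) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _design_hairpin(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, str, str, str]:
    """One hairpin design attempt: (mature, star, precursor, arm)."""
    m_len = int(rng.integers(cfg.read_length_range[0], cfg.read_length_range[1] + 1))
    first = rng.choice(list("ACGT"), p=cfg.first_nt_probs)
    mature = first + _random_seq(rng, m_len - 1)
    star = list(revcomp(mature))
    for pos in rng.choice(np.arange(2, m_len - 2), size=int(rng.integers(0, 3)), replace=False):
        star[pos] = rng.choice([c for c in "ACGT" if c != star[pos]])
    star_seq = "".join(star)
    loop = _random_seq(rng, int(rng.integers(12, 19)))
    arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        precursor = mature + loop + star_seq
    else:
        precursor = star_seq + loop + mature
    return mature, star_seq, precursor, arm


def _verify_planted(
    element: str,
    mature: str,
    mature_off: int,
    criteria: HairpinCriteria,
    engine: FoldEngine,
) -> bool:
    """Would the discovery stage accept this locus? (same code path)."""
    hit = GenomeHit(mature, "tmp", mature_off, mature_off + len(mature), "+", 1)
    for cand in excise_and_fold(mature, [hit], {"tmp": element}, criteria, engine):
        if evaluate_hairpin(cand, criteria).passes:
            return True
    return False


def generate_reference(
    config: SimulationConfig,
    criteria: HairpinCriteria | None = None,
    engine: FoldEngine | None = None,
) -> GroundTruth:
    """Build the genome, annotations and all reference sets.

    Deterministic for a fixed seed. Raises a generation error when an
    element cannot be placed or a hairpin cannot be designed within the
    bounded retry budget.
    """
    config.validate()
    criteria = criteria or HairpinCriteria()
    engine = engine or default_engine()
    rng = np.random.default_rng(config.seed)
    pad = criteria.flank_long  # private flank so excision windows stay local

    # --- miRNA loci -----------------------------------------------------
    mirnas: list[PlantedMiRNA] = []
    known_idx = set(
        rng.choice(config.n_planted_mirnas, size=config.n_known_mirnas, replace=False)
        if config.n_planted_mirnas
        else []
    )
    for i in range(config.n_planted_mirnas):
        for attempt in range(config.max_design_tries):
            mature, star, precursor, arm = _design_hairpin(rng, config)
            element = _random_seq(rng, pad) + precursor + _random_seq(rng, pad)
            if element.count(mature) != 1:
                continue
            if _verify_planted(element, mature, element.find(mature), criteria, engine):
                break
        else:
            raise RuntimeError(
                f"generation error: no acceptable hairpin for locus syn-miR-{i + 1:03d} "
                f"after {config.max_design_tries} tries"
            )
        mirnas.append(
            PlantedMiRNA(
                id=f"syn-miR-{i + 1:03d}",
                mature=mature,
                star=star,
                precursor=precursor,
                arm=arm,
                known=i in known_idx,
            )
        )
        mirnas[-1]._element = element  # type: ignore[attr-defined]

    # fold-change design: defaults plant n_up 4x up- and n_down 4x down-regulated
    if config.per_mirna_fold_change is not None:
        folds = dict(config.per_mirna_fold_change)
    else:
        folds = {}
        n_resp = min(config.n_up + config.n_down, len(mirnas))
        resp = rng.choice(len(mirnas), size=n_resp, replace=False) if mirnas else []
        for j, idx in enumerate(resp):
            f = config.responsive_fold if j < config.n_up else 1.0 / config.responsive_fold
            folds[mirnas[idx].id] = f
    for m in mirnas:
        m.fold_change = folds.get(m.id, 1.0)

    # --- ncRNA loci -----------------------------------------------------
    ncrnas: list[list] = []
    for i in range(config.n_planted_ncrnas):
        cls = NCRNA_CLASS_CYCLE[i % len(NCRNA_CLASS_CYCLE)]
        seq = _random_seq(rng, int(rng.integers(80, 151)))
        ncrnas.append([f"{cls}_{i + 1:03d}", seq])

    # --- genes with planted target sites --------------------------------
    genes: list[GeneModel] = []
    target_sites: list[tuple[str, str, int]] = []
    responsive_ids = [m.id for m in mirnas if m.fold_change != 1.0]
    mature_of = {m.id: m.mature for m in mirnas}
    n_targets = min(config.n_target_genes, config.n_genes)
    gene_local: list[dict] = []
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(2, 4))
        exon_lens = rng.integers(120, 251, size=n_ex)
        intron_lens = rng.integers(60, 121, size=n_ex - 1)
        parts: list[str] = []
        local_exons: list[tuple[int, int]] = []
        cursor = 0
        for k in range(n_ex):
            ex = _random_seq(rng, int(exon_lens[k]))
            local_exons.append((cursor, cursor + len(ex)))
            parts.append(ex)
            cursor += len(ex)
            if k < n_ex - 1:
                intr = _random_seq(rng, int(intron_lens[k]))
                parts.append(intr)
                cursor += len(intr)
        gid = f"g{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        seq = "".join(parts)
        gene_local.append(
            {"id": gid, "seq": seq, "exons": local_exons, "strand": strand, "sites": []}
        )
    # plant perfect (S = 0) target sites for responsive miRNAs in the
    # first n_targets genes, cycling through the responsive set
    if responsive_ids and n_targets:
        for t in range(n_targets):
            g = gene_local[t]
            mir_id = responsive_ids[t % len(responsive_ids)]
            mature = mature_of[mir_id]
            site = revcomp(mature)
            exon_order = rng.permutation(len(g["exons"]))
            placed = False
            for ei in exon_order:
                s, e = g["exons"][ei]
                if e - s < len(site) + 10:
                    continue
                off = int(rng.integers(s + 3, e - len(site) - 3))
                g["seq"] = g["seq"][:off] + site + g["seq"][off + len(site):]
                g["sites"].append((mir_id, off))
                placed = True
                break
            if not placed:
                raise RuntimeError(f"generation error: no exon can host a site in {g['id']}")
        # a couple of genes get a second miRNA (multi-regulated genes)
        for t in range(min(3, n_targets)):
            g = gene_local[t]
            mir_id = responsive_ids[(t + 1) % len(responsive_ids)]
            site = revcomp(mature_of[mir_id])
            s, e = g["exons"][-1]
            if e - s >= len(site) + 10:
                off = int(rng.integers(s + 3, e - len(site) - 3))
                if all(abs(off - o) > 2 * len(site) for _, o in g["sites"]):
                    g["seq"] = g["seq"][:off] + site + g["seq"][off + len(site):]
                    g["sites"].append((mir_id, off))

    # --- repeat tags ----------------------------------------------------
    repeat_tags = [
        (_random_seq(rng, 21), int(copies)) for copies in config.repeat_copy_numbers
    ]

    # --- assemble chromosomes -------------------------------------------
    elements: list[tuple[str, object, str]] = []
    for m in mirnas:
        elements.append(("mirna", m, m._element))  # type: ignore[attr-defined]
    for nc in ncrnas:
        elements.append(("ncrna", nc, nc[1]))
    for g in gene_local:
        seq = g["seq"] if g["strand"] == "+" else revcomp(g["seq"])
        elements.append(("gene", g, seq))
    for seq, copies in repeat_tags:
        for _ in range(copies):
            elements.append(("repeat", seq, seq))

    order = rng.permutation(len(elements))
    chrom_elements: list[list[int]] = [[] for _ in range(config.n_chromosomes)]
    for idx in order:
        chrom_elements[int(rng.integers(config.n_chromosomes))].append(int(idx))

    genome: dict[str, str] = {}
    placed_ncrnas: list[tuple[str, str, str, int, int]] = []
    genes_out: dict[str, GeneModel] = {}
    for ci, elem_ids in enumerate(chrom_elements):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        cursor = 0
        for idx in elem_ids:
            kind, obj, seq = elements[idx]
            gap = int(rng.integers(80, 241))
            parts.append(_random_seq(rng, gap))
            cursor += gap
            start, end = cursor, cursor + len(seq)
            if end > config.chromosome_length:
                label = obj.id if kind == "mirna" else (obj["id"] if kind == "gene" else str(obj)[:24])
                raise RuntimeError(
                    f"generation error: planting collision on {chrom} at element {label}: "
                    f"chromosome_length {config.chromosome_length} exhausted"
                )
            parts.append(seq)
            cursor = end
            if kind == "mirna":
                pad_len = (len(obj._element) - len(obj.precursor)) // 2
                obj.chrom = chrom
                obj.start = start + pad_len
                obj.end = obj.start + len(obj.precursor)
                obj.strand = "+"
            elif kind == "ncrna":
                placed_ncrnas.append((obj[0], obj[1], chrom, start, end))
            elif kind == "gene":
                gm = GeneModel(
                    id=obj["id"], chrom=chrom, start=start, end=end, strand=obj["strand"]
                )
                L = len(obj["seq"])
                for s, e in obj["exons"]:
                    if gm.strand == "+":
                        gm.exons.append((start + s, start + e))
                    else:
                        gm.exons.append((start + (L - e), start + (L - s)))
                gm.exons.sort()
                gm.transcript = "".join(
                    obj["seq"][s:e] for s, e in obj["exons"]
                )
                genes_out[obj["id"]] = gm
                for mir_id, off in obj["sites"]:
                    tx_pos = _genomic_to_transcript_offset(obj["exons"], off)
                    target_sites.append((mir_id, obj["id"], tx_pos))
        if cursor > config.chromosome_length:
            raise RuntimeError(f"generation error: {chrom} overflow")
        parts.append(_random_seq(rng, config.chromosome_length - cursor))
        genome[chrom] = "".join(parts)
    genes = [genes_out[g["id"]] for g in gene_local if g["id"] in genes_out]
    target_sites.sort()

    for m in mirnas:  # consistency: re-extracted precursor equals the design
        del m._element  # type: ignore[attr-defined]
        assert genome[m.chrom][m.start : m.end] == m.precursor

    # --- GO map, PPI edges, TF list -------------------------------------
    go_map: dict[str, set[str]] = {g.id: set() for g in genes}
    pool = [f"GO:{i + 1:07d}" for i in range(20)]
    for g in genes:
        for term in rng.choice(pool, size=int(rng.integers(2, 6)), replace=False):
            go_map[g.id].add(str(term))
    enriched_term = "GO:7777777"
    target_gene_ids = sorted({gid for _, gid, _ in target_sites})
    for gid in target_gene_ids[: min(10, len(target_gene_ids))]:
        go_map[gid].add(enriched_term)

    hub_gene = target_gene_ids[0] if target_gene_ids else ""
    ppi_edges: list[tuple[str, str, float]] = []
    partners = [g for g in target_gene_ids[1:]][:24]
    for p in partners:
        ppi_edges.append((hub_gene, p, float(np.round(rng.uniform(0.4, 0.99), 3))))
    all_gene_ids = [g.id for g in genes]
    for _ in range(30):
        if len(all_gene_ids) < 2:
            break
        a, b = rng.choice(all_gene_ids, size=2, replace=False)
        if a != hub_gene and b != hub_gene:
            ppi_edges.append((str(a), str(b), float(np.round(rng.uniform(0.4, 0.99), 3))))

    tf_pool = [g for g in all_gene_ids if g != hub_gene]
    tf_genes = {hub_gene} if hub_gene else set()
    if tf_pool:
        tf_genes |= {
            str(g) for g in rng.choice(tf_pool, size=min(12, len(tf_pool)), replace=False)
        }

    # --- RACE-style cleavage evidence -----------------------------------
    race_cases: list[dict] = []
    for i, (mir_id, gid, tx_pos) in enumerate(target_sites[:4]):
        m_len = len(mature_of[mir_id])
        canonical = tx_pos + m_len - 10
        if i < 3:  # concentrated on the canonical cut (7/10 clones)
            ends = {canonical: 7, canonical - 2: 1, canonical + 2: 1, canonical + 4: 1}
        else:  # diffuse background case
            ends = {canonical + d: 1 for d in range(-5, 5)}
        race_cases.append(
            {
                "mirna_id": mir_id,
                "gene_id": gid,
                "transcript_id": f"{gid}.1",
                "site_tx_start": tx_pos,
                "clone_ends": ends,
            }
        )

    return GroundTruth(
        config=config,
        genome=genome,
        mirnas=mirnas,
        ncrnas=placed_ncrnas,
        genes=genes,
        target_sites=target_sites,
        repeat_tags=repeat_tags,
        go_map=go_map,
        enriched_term=enriched_term,
        ppi_edges=ppi_edges,
        hub_gene=hub_gene,
        tf_genes=tf_genes,
        race_cases=race_cases,
    )


def _genomic_to_transcript_offset(local_exons: list[tuple[int, int]], off: int) -> int:
    tx = 0
    for s, e in local_exons:
        if s <= off < e:
            return tx + (off - s)
        tx += e - s
    raise ValueError("site offset not inside an exon")


# --- library simulation --------------------------------------------------


def _build_species(rng: np.random.Generator, truth: GroundTruth):
    """Species (sequence, cs-weight, ts-weight) for the read multinomial."""
    cfg = truth.config
    species: dict[str, list[float]] = {}

    def add(seq: str, w_cs: float, fold: float = 1.0) -> None:
        if w_cs <= 0 or not seq:
            return
        rec = species.setdefault(seq, [0.0, 0.0])
        rec[0] += w_cs
        rec[1] += w_cs * fold

    mir_share = max(0.0, 1.0 - cfg.ncrna_share - cfg.degradation_share - cfg.repeat_share)
    if truth.mirnas:
        if cfg.mirna_abundance is not None:
            weights = np.array([cfg.mirna_abundance.get(m.id, 0.0) for m in truth.mirnas])
        else:
            weights = rng.lognormal(mean=0.0, sigma=1.2, size=len(truth.mirnas))
        weights = weights / weights.sum() * mir_share
        for m, w in zip(truth.mirnas, weights):
            add(m.mature, float(w), m.fold_change)
    if truth.ncrnas:
        n_frag = 8 * len(truth.ncrnas)
        w = rng.dirichlet(np.full(n_frag, 0.6)) * cfg.ncrna_share
        for i in range(n_frag):
            _, seq, _, _, _ = truth.ncrnas[int(rng.integers(len(truth.ncrnas)))]
            ln = int(rng.integers(18, 29))
            if len(seq) <= ln:
                continue
            off = int(rng.integers(0, len(seq) - ln))
            add(seq[off : off + ln], float(w[i]))
    if cfg.degradation_share > 0 and truth.genome:
        n_frag = 150
        w = rng.dirichlet(np.full(n_frag, 0.6)) * cfg.degradation_share
        chroms = sorted(truth.genome)
        for i in range(n_frag):
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = truth.genome[chrom]
            ln = int(rng.integers(18, 29))
            off = int(rng.integers(0, len(seq) - ln))
            frag = seq[off : off + ln]
            if int(rng.integers(2)):
                frag = revcomp(frag)
            add(frag, float(w[i]))
    for seq, _copies in truth.repeat_tags:
        add(seq, cfg.repeat_share / max(1, len(truth.repeat_tags)))
    return species


def simulate_libraries(
    config: SimulationConfig, truth: GroundTruth, outdir
) -> dict[str, object]:
    """Draw both read libraries and write FASTQ plus the truth count table.

    Treatment-library species probabilities are the control weights
    multiplied by the per-miRNA fold change and renormalized (the usual
    compositional effect of sequencing to fixed depth). The realized
    per-species counts are written to ``expected_counts.tsv`` as the
    oracle for tag collapsing; noise reads are excluded from it, so its
    column sums equal ``(1 - noise_fraction) * depth`` up to rounding.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1_000_003)
    species = _build_species(rng, truth)
    seqs = sorted(species)
    w_cs = np.array([species[s][0] for s in seqs])
    w_ts = np.array([species[s][1] for s in seqs])
    counts: dict[str, np.ndarray] = {}
    noise_reads: dict[str, list[str]] = {}
    for lib, depth, w in (("cs", config.library_depth_cs, w_cs), ("ts", config.library_depth_ts, w_ts)):
        n_noise = int(round(config.noise_fraction * depth))
        n_signal = depth - n_noise
        if n_signal and len(seqs) and w.sum() > 0:
            counts[lib] = rng.multinomial(n_signal, w / w.sum())
        else:
            counts[lib] = np.zeros(len(seqs), dtype=int)
        # noise: mostly unmappable random inserts of clean length, plus a
        # tranche of too-short inserts that the 18 nt rule must discard
        n_short = n_noise * 3 // 10
        noise = []
        taken = set(seqs)
        while len(noise) < n_noise:
            if len(noise) < n_short:
                ln = int(rng.integers(8, 18))
            else:
                ln = int(rng.integers(config.read_length_range[0], config.read_length_range[1] + 1))
            seq = _random_seq(rng, ln)
            if seq not in taken:
                noise.append(seq)
        noise_reads[lib] = noise

    paths = {
        "reads_cs": outdir / "reads_cs.fastq",
        "reads_ts": outdir / "reads_ts.fastq",
        "expected_counts": outdir / "expected_counts.tsv",
    }
    for lib in ("cs", "ts"):
        with open(paths[f"reads_{lib}"], "w") as fh:
            rid = 0
            for seq, count in zip(seqs, counts[lib]):
                read = seq + config.adapter_seq
                qual = "I" * len(read)
                for _ in range(int(count)):
                    rid += 1
                    fh.write(f"@{lib.upper()}_{rid:07d}\n{read}\n+\n{qual}\n")
            for seq in noise_reads[lib]:
                read = seq + config.adapter_seq
                rid += 1
                fh.write(f"@{lib.upper()}_{rid:07d}\n{read}\n+\n{'I' * len(read)}\n")
    with open(paths["expected_counts"], "w") as fh:
        fh.write("sequence\tcount_cs\tcount_ts\n")
        for i, seq in enumerate(seqs):
            fh.write(f"{seq}\t{int(counts['cs'][i])}\t{int(counts['ts'][i])}\n")
    table = {
        seq: (int(counts["cs"][i]), int(counts["ts"][i])) for i, seq in enumerate(seqs)
    }
    return {"paths": paths, "counts": table}


# --- reference file output -----------------------------------------------


def write_reference(truth: GroundTruth, outdir) -> dict[str, object]:
    """Write the genome and all annotation/reference files for the pipeline.

    Emits genome FASTA, GFF3 gene models (1-based closed intervals),
    the ncRNA reference, mature + hairpin FASTA for the miRNAs labelled
    "known", the GO map, PPI edge list, TF list, RACE-style clone-end
    evidence, and a ground-truth miRNA table for test oracles.
    """
    from pathlib import Path

    from .sequtil import to_rna

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        name: outdir / fname
        for name, fname in (
            ("genome", "genome.fa"),
            ("gff3", "genes.gff3"),
            ("ncrna", "ncrna.fa"),
            ("mature", "mirna_mature.fa"),
            ("hairpin", "mirna_hairpin.fa"),
            ("go_map", "go_map.tsv"),
            ("ppi", "ppi.tsv"),
            ("tf_list", "tf_list.txt"),
            ("race", "race_clones.tsv"),
            ("truth_mirnas", "truth_mirnas.tsv"),
        )
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(truth.genome):
            fh.write(f">{chrom}\n")
            seq = truth.genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.genes:
            base = f"{g.chrom}\tsynsim"
            fh.write(f"{base}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n")
            fh.write(
                f"{base}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.id}\n"
            )
            for k, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{base}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.transcript_id}.exon{k + 1};Parent={g.transcript_id}\n"
                )
    with open(paths["ncrna"], "w") as fh:
        for cls_id, seq, chrom, start, end in truth.ncrnas:
            fh.write(f">{cls_id} {chrom}:{start}-{end}\n{seq}\n")
    with open(paths["mature"], "w") as fh:
        for m in truth.known_mirnas:
            fh.write(f">{m.id}\n{to_rna(m.mature)}\n")
    with open(paths["hairpin"], "w") as fh:
        for m in truth.known_mirnas:
            fh.write(f">{m.id}\n{to_rna(m.precursor)}\n")
    with open(paths["go_map"], "w") as fh:
        fh.write("gene\tgo_term\n")
        for gene in sorted(truth.go_map):
            for term in sorted(truth.go_map[gene]):
                fh.write(f"{gene}\t{term}\n")
    with open(paths["ppi"], "w") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for a, b, score in truth.ppi_edges:
            fh.write(f"{a}\t{b}\t{score}\n")
    with open(paths["tf_list"], "w") as fh:
        for gene in sorted(truth.tf_genes):
            fh.write(gene + "\n")
    with open(paths["race"], "w") as fh:
        fh.write("mirna\tgene\ttranscript\tsite_tx_start\tposition\tclones\n")
        for case in truth.race_cases:
            for pos in sorted(case["clone_ends"]):
                fh.write(
                    f"{case['mirna_id']}\t{case['gene_id']}\t{case['transcript_id']}\t"
                    f"{case['site_tx_start']}\t{pos}\t{case['clone_ends'][pos]}\n"
                )
    with open(paths["truth_mirnas"], "w") as fh:
        fh.write(
            "id\tknown\tmature\tstar\tprecursor\tchrom\tstart\tend\tstrand\tarm\tfold_change\n"
        )
        for m in truth.mirnas:
            fh.write(
                f"{m.id}\t{m.known}\t{m.mature}\t{m.star}\t{m.precursor}\t{m.chrom}"
                f"\t{m.start}\t{m.end}\t{m.strand}\t{m.arm}\t{m.fold_change}\n"
            )
    return paths


def generate(config: SimulationConfig, outdir) -> tuple[GroundTruth, dict[str, object]]:
    """Generate references and both libraries under ``outdir``."""
    truth = generate_reference(config)
    paths = write_reference(truth, outdir)
    sim = simulate_libraries(config, truth, outdir)
    paths.update(sim["paths"])
    return truth, {"paths": paths, "counts": sim["counts"]}
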