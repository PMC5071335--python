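"""Regulatory-network assembly and GO over-representation analysis.

The stress-response network joins directed miRNA -> target edges (from
the prediction stage, restricted to responsive miRNAs) with undirected
protein-protein interaction edges between target proteins. Nodes carry
the miRNA fold change and a transcription-factor flag, matching how
such networks are drawn in Cytoscape. Enrichment of GO terms among
target genes uses the one-sided Fisher exact (hypergeometric) test with
Bonferroni and Benjamini-Hochberg adjustment; a term is called
significant only when both the Bonferroni-adjusted p and the BH FDR
fall below the threshold (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # target genes annotated with the term
    n: int  # target-set size
    big_k: int  # background genes annotated with the term
    big_n: int  # background size
    p_raw: float
    p_bonferroni: float
    fdr_bh: float
    significant: bool


def build_network(
    responsive_fc: dict[str, float],
    targets: dict[str, list[str]],
    ppi_edges: list[tuple[str, str, float]],
    tf_genes: set[str] | None = None,
) -> nx.DiGraph:
    """Assemble the miRNA-mediated regulatory network.

    ``responsive_fc`` maps responsive miRNA ids to log2 fold changes;
    ``targets`` maps miRNA ids to predicted target genes. PPI edges are
    kept only when both proteins are targets in the network, stored
    once in canonical order; edges naming unknown proteins are dropped
    (the count is recorded in graph metadata).
    """
    tf_genes = tf_genes or set()
    g = nx.DiGraph()
    for mir in sorted(responsive_fc):
        if mir not in targets:
            continue
        g.add_node(mir, kind="miRNA", log2fc=float(responsive_fc[mir]), is_tf=False)
        for gene in targets[mir]:
            if gene not in g:
                g.add_node(gene, kind="protein", is_tf=gene in tf_genes)
            g.add_edge(mir, gene, kind="targeting")
    dropped = 0
    proteins = {n for n, d in g.nodes(data=True) if d["kind"] == "protein"}
    for a, b, score in ppi_edges:
        if a not in proteins or b not in proteins:
            dropped += 1
            continue
        a, b = sorted((a, b))
        if not g.has_edge(a, b):
            g.add_edge(a, b, kind="ppi", score=float(score))
    g.graph["dropped_ppi_edges"] = dropped
    return g


def degree_summary(g: nx.DiGraph) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """(protein PPI degree, miRNA targeting out-degree), sorted descending.

    PPI degree counts undirected interaction partners only; targeting
    edges do not contribute. Isolated targets report degree 0.
    """
    ppi_deg: dict[str, int] = {
        n: 0 for n, d in g.nodes(data=True) if d["kind"] == "protein"
    }
    mir_deg: dict[str, int] = {
        n: 0 for n, d in g.nodes(data=True) if d["kind"] == "miRNA"
    }
    for a, b, d in g.edges(data=True):
        if d["kind"] == "ppi":
            ppi_deg[a] += 1
            ppi_deg[b] += 1
        else:
            mir_deg[a] += 1
    order = lambda items: sorted(items, key=lambda kv: (-kv[1], kv[0]))
    return order(ppi_deg.items()), order(mir_deg.items())


def go_enrichment(
    target_genes: set[str],
    go_map: dict[str, set[str]],
    background: set[str] | None = None,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided Fisher (hypergeometric) over-representation per GO term.

    The universe is every term annotating at least one target gene (the
    behaviour of standard agricultural-GO servers); the background
    defaults to all annotated genes and must contain the target set.
    """
    background = background if background is not None else set(go_map)
    if not background:
        raise ValueError("background gene set is empty")
    if not target_genes <= background:
        raise ValueError("background must contain every target gene")
    targets_annot = {g: go_map.get(g, set()) for g in target_genes}
    terms = sorted(set().union(*targets_annot.values()) if targets_annot else set())
    n = len(target_genes)
    big_n = len(background)
    results: list[EnrichmentResult] = []
    for term in terms:
        members = {g for g in background if term in go_map.get(g, set())}
        k = len(target_genes & members)
        big_k = len(members)
        # P(X >= k), X ~ Hypergeom(big_n, big_k, n)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        results.append(EnrichmentResult(term, k, n, big_k, big_n, p, 1.0, 1.0, False))
    if results:
        raw = [r.p_raw for r in results]
        bonf = multipletests(raw, method="bonferroni")[1]
        bh = multipletests(raw, method="fdr_bh")[1]
        for r, pb, q in zip(results, bonf, bh):
            r.p_bonferroni = float(pb)
            r.fdr_bh = float(q)
            r.significant = r.p_bonferroni < alpha and r.fdr_bh < alpha
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def export_network(g: nx.DiGraph, path, fmt: str) -> None:
    """Write the network as SIF or GraphML (Cytoscape-compatible)."""
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b, d in sorted(g.edges(data=True)):
                fh.write(f"{a}\t{d['kind']}\t{b}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True, edge_id_from_attribute=None)
    else:
        raise ValueError(f"unsupported network format: {fmt!r}")


def import_network(path, fmt: str) -> nx.DiGraph:
    if fmt != "graphml":
        raise ValueError("round-trip import is supported for graphml only")
    return nx.read_graphml(path, node_type=str)


def enrichment_tsv(results: list[EnrichmentResult]) -> str:
    lines = ["term\tk\tn\tK\tN\tp_raw\tp_bonferroni\tfdr_bh\tsignificant"]
    for r in results:
        lines.append(
            f"{r.term_id}\t{r.k}\t{r.n}\t{r.big_k}\t{r.big_n}"
            f"\t{r.p_raw:.6g}\t{r.p_bonferroni:.6g}\t{r.fdr_bh:.6g}\t{r.significant}"
        )
    return "\n".join(lines) + "\n"
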