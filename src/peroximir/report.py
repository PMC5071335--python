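"""Summary reporting of pipeline bookkeeping statistics.

Reproduces the headline accounting style of published sRNA studies:
clean-read percentages, unique-tag and mapped fractions, known/novel
miRNA counts with both-library overlap, read-abundance tiers, precursor
MFE range and responsive miRNA counts. All percentages are rendered to
two decimals with half-away-from-zero rounding (0.977552 -> "97.76").
"""

from __future__ import annotations

from .sequtil import fmt_pct

ABUNDANCE_TIERS = (100, 1_000, 10_000, 100_000)


def abundance_tiers(
    reads_per_mirna: dict[str, int], thresholds: tuple[int, ...] = ABUNDANCE_TIERS
) -> dict[int, tuple[int, str]]:
    """Count and percentage of miRNAs above each total-read threshold."""
    n = len(reads_per_mirna)
    out: dict[int, tuple[int, str]] = {}
    for thr in thresholds:
        k = sum(1 for v in reads_per_mirna.values() if v > thr)
        out[thr] = (k, fmt_pct(k, n))
    return out


def summary_report(stats: dict) -> str:
    """Render the pipeline summary as a two-column metric/value TSV.

    ``stats`` is the merged stage bookkeeping dictionary; metrics whose
    inputs are absent are omitted rather than guessed. Every percentage
    equals ``round_half_away(100 * numerator / denominator, 2)`` for
    counts that appear alongside it, which a self-consistency test can
    audit directly.
    """
    lines: list[str] = ["metric\tvalue"]

    def put(metric: str, value) -> None:
        lines.append(f"{metric}\t{value}")

    for lib in ("cs", "ts"):
        raw = stats.get(f"raw_reads_{lib}")
        clean = stats.get(f"clean_reads_{lib}")
        if raw is not None and clean is not None:
            put(f"raw_reads_{lib}", raw)
            put(f"clean_reads_{lib}", clean)
            put(f"clean_reads_{lib}_pct", fmt_pct(clean, raw))
        uniq = stats.get(f"unique_tags_{lib}")
        mapped = stats.get(f"mapped_unique_tags_{lib}")
        if uniq is not None:
            put(f"unique_tags_{lib}", uniq)
            if mapped is not None:
                put(f"mapped_unique_tags_{lib}", mapped)
                put(f"mapped_unique_tags_{lib}_pct", fmt_pct(mapped, uniq))

    known_total = stats.get("known_mirnas_total")
    if known_total is not None:
        put("known_mirnas_total", known_total)
        put("known_mirnas_cs", stats.get("known_mirnas_cs", 0))
        put("known_mirnas_ts", stats.get("known_mirnas_ts", 0))
        both = stats.get("known_mirnas_both", 0)
        put("known_mirnas_both", both)
        put("known_mirnas_both_pct", fmt_pct(both, known_total))

    reads_per_known = stats.get("reads_per_known_mirna")
    if reads_per_known:
        for thr, (k, pct) in abundance_tiers(reads_per_known).items():
            put(f"known_gt_{thr}_reads", k)
            put(f"known_gt_{thr}_reads_pct", pct)

    if stats.get("novel_mirnas") is not None:
        put("novel_mirnas", stats["novel_mirnas"])
        put("novel_family_clustered", stats.get("novel_family_clustered", 0))
        put("novel_species_specific", stats.get("novel_species_specific", 0))
    mfes = stats.get("novel_mfes") or []
    if mfes:
        put("novel_mfe_min", f"{min(mfes):.2f}")
        put("novel_mfe_max", f"{max(mfes):.2f}")
        put("novel_mfe_mean", f"{sum(mfes) / len(mfes):.2f}")

    if stats.get("responsive_up") is not None:
        put("responsive_up", stats["responsive_up"])
        put("responsive_down", stats["responsive_down"])
        put("responsive_total", stats["responsive_up"] + stats["responsive_down"])

    if stats.get("predicted_target_transcripts") is not None:
        put("predicted_target_transcripts", stats["predicted_target_transcripts"])
        put("predicted_target_genes", stats["predicted_target_genes"])
    if stats.get("network_nodes") is not None:
        put("network_nodes", stats["network_nodes"])
        put("network_edges", stats["network_edges"])
    if stats.get("significant_go_terms") is not None:
        put("significant_go_terms", stats["significant_go_terms"])
    return "\n".join(lines) + "\n"
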