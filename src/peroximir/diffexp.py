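"""Differential miRNA expression between two pooled sRNA libraries.

Counts are normalized to tags-per-million of clean reads (TPM), with
the digital-count conventions used for single-library-pair designs:
a TPM of exactly zero is revised to 0.01 so fold changes stay finite,
and species below 1 TPM in both libraries are excluded as too shallow
to call. Significance uses the Audic-Claverie exact statistic for tag
counts: given x tags in a library of depth N1, the probability of
observing y tags in a library of depth N2 is

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

computed in log-space; the reported p-value is the two-sided tail
(twice the smaller of the lower/upper cumulative sums, capped at 1).
The point probability is also exposed, since published tables do not
always say which form they print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .sequtil import to_rna


@dataclass
class LibraryTotals:
    """Total clean reads in the control (N1) and treatment (N2) library."""

    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")


@dataclass
class ExpressionRecord:
    """Per-miRNA counts, normalized expression and test results."""

    mirna_id: str
    sequence: str
    x: int
    y: int
    tpm_cs: float = 0.0
    tpm_ts: float = 0.0
    tpm_cs_adj: float = 0.0
    tpm_ts_adj: float = 0.0
    log2fc: float | None = None
    p_value: float | None = None
    point_p: float | None = None
    excluded: bool = False
    responsive: bool = False


def _log_point(k: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log p(k|x) for the Audic-Claverie point probability."""
    k = np.asarray(k, dtype=float)
    return (
        k * log_r
        + gammaln(x + k + 1.0)
        - gammaln(x + 1.0)
        - gammaln(k + 1.0)
        - (x + k + 1.0) * np.logaddexp(0.0, log_r)
    )


def ac_point_probability(x: int, y: int, totals: LibraryTotals) -> float:
    """Audic-Claverie point probability p(y|x)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    log_r = math.log(totals.n2) - math.log(totals.n1)
    return float(np.exp(_log_point(np.array([y]), x, log_r))[0])


def _upper_tail(y: int, x: int, log_r: float) -> float:
    """Sum of p(k|x) for k >= y, extended until the remainder is negligible."""
    chunk = 256
    total = -np.inf
    k0 = y
    while True:
        ks = np.arange(k0, k0 + chunk)
        lp = _log_point(ks, x, log_r)
        total = np.logaddexp(total, logsumexp(lp))
        last = lp[-1]
        k_next = k0 + chunk
        # beyond the mode the term ratio is < 1 and decreasing
        ratio = (x + k_next + 1) / (k_next + 1) * math.exp(log_r - np.logaddexp(0.0, log_r))
        if ratio < 1.0 and last + math.log(ratio / (1 - ratio)) < total + math.log(1e-16):
            break
        k0 = k_next
        chunk = min(chunk * 2, 1 << 20)
    return float(np.exp(total))


def audic_claverie_p(x: int, y: int, totals: LibraryTotals) -> tuple[float, float]:
    """Two-sided tail p-value and point probability for counts (x, y).

    The two-sided tail is 2*min(P(k<=y), P(k>=y)), capped at 1; both
    cumulative sums include the observed y.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    log_r = math.log(totals.n2) - math.log(totals.n1)
    lower = float(np.exp(logsumexp(_log_point(np.arange(0, y + 1), x, log_r))))
    upper = _upper_tail(y, x, log_r)
    two_sided = min(1.0, 2.0 * min(lower, upper))
    point = float(np.exp(_log_point(np.array([y]), x, log_r))[0])
    return two_sided, point


def normalize_and_adjust(
    records: list[ExpressionRecord], totals: LibraryTotals
) -> list[ExpressionRecord]:
    """Compute TPM, apply the 0.01 zero-revision and the <1 TPM exclusion."""
    for rec in records:
        if rec.x < 0 or rec.y < 0:
            raise ValueError(f"{rec.mirna_id}: negative count")
        rec.tpm_cs = rec.x * 1_000_000.0 / totals.n1
        rec.tpm_ts = rec.y * 1_000_000.0 / totals.n2
        rec.tpm_cs_adj = rec.tpm_cs if rec.tpm_cs > 0 else 0.01
        rec.tpm_ts_adj = rec.tpm_ts if rec.tpm_ts > 0 else 0.01
        rec.excluded = rec.tpm_cs_adj < 1.0 and rec.tpm_ts_adj < 1.0
    return records


def log2_fold_change(rec: ExpressionRecord) -> float | None:
    """log2(treatment TPM / control TPM) on adjusted values."""
    if rec.excluded:
        rec.log2fc = None
        return None
    rec.log2fc = math.log2(rec.tpm_ts_adj / rec.tpm_cs_adj)
    return rec.log2fc


def screen_responsive(
    records: list[ExpressionRecord],
    totals: LibraryTotals,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> tuple[list[ExpressionRecord], list[ExpressionRecord]]:
    """Flag stress-responsive miRNAs and split them by direction.

    A species is responsive iff it is not excluded, |log2 fold change|
    is at least ``fc_threshold`` (two-fold by default) and the
    two-sided Audic-Claverie p-value is at most ``p_threshold``.
    Returns (upregulated, downregulated), each sorted by fold change.
    """
    for rec in records:
        log2_fold_change(rec)
        if rec.excluded:
            rec.responsive = False
            continue
        rec.p_value, rec.point_p = audic_claverie_p(rec.x, rec.y, totals)
        rec.responsive = abs(rec.log2fc) >= fc_threshold and rec.p_value <= p_threshold
    up = sorted(
        (r for r in records if r.responsive and r.log2fc > 0), key=lambda r: r.log2fc
    )
    down = sorted(
        (r for r in records if r.responsive and r.log2fc < 0), key=lambda r: r.log2fc
    )
    return up, down


def diffexp_table(records: list[ExpressionRecord]) -> "pd.DataFrame":
    """Tabular view of all tested species, with a BH-FDR column.

    The screen itself uses raw p-values (single-pair digital designs
    are conventionally reported unadjusted); the Benjamini-Hochberg
    column is emitted for transparency.
    """
    import pandas as pd

    tested = [r for r in records if not r.excluded and r.p_value is not None]
    fdr = {}
    if tested:
        _, qvals, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
        fdr = {r.mirna_id: q for r, q in zip(tested, qvals)}
    rows = [
        {
            "sequence": to_rna(r.sequence),
            "name": r.mirna_id,
            "count_cs": r.x,
            "count_ts": r.y,
            "tpm_cs": r.tpm_cs,
            "tpm_ts": r.tpm_ts,
            "log2_t_over_c": r.log2fc,
            "p_value": r.p_value,
            "point_probability": r.point_p,
            "fdr_bh": fdr.get(r.mirna_id),
            "excluded": r.excluded,
            "responsive": r.responsive,
        }
        for r in records
    ]
    return pd.DataFrame.from_records(rows)
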