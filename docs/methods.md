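# Methods

## Scope and model of the experiment

The package analyses the classic unreplicated two-library plant sRNA
design: total small RNA from control (CS) and stress-treated (TS)
seedlings, size-selected to 18–30 nt, 3′-adapter-ligated and sequenced
deeply. All sequences are held internally in the DNA alphabet (U→T);
tables that mimic published miRNA reports render U. Genomic
coordinates are 0-based half-open internally and 1-based closed in
GFF3 output.

## Read processing

The adapter is located as the longest prefix of the adapter sequence
matching a read suffix with zero mismatches (full internal occurrence
preferred), requiring at least 6 nt of overlap. Reads whose insert
falls outside the 18–30 nt clean window are discarded; reads with no
adapter hit are kept untrimmed only if they already lie in the window.
Reads containing N are dropped because every downstream mapping step
is exact-match. Quality values are ignored by default: the design
relies on exact sequence identity, and no principled quality threshold
exists for this analysis style; a mean-quality filter can be added at
the trimming call if needed.

## Annotation cascade

Category assignment is first-match-wins in a fixed priority: ncRNA
classes → known miRNA → exon/intron (sense before antisense, exon
before intron) → unknown. Rationale for the notable choices:

- ncRNA matching is exact substring containment in either orientation;
  at 18–30 nt, heuristic alignment against a curated ncRNA set is
  effectively exact matching, and the deterministic first-reference
  tie-break makes reruns reproducible.
- Known-miRNA assignment accepts end offsets of up to 2 nt provided
  the tag remains an exact substring of that miRNA's hairpin
  (isomiR-style 5′/3′ heterogeneity, no internal mismatches). The
  offset is configurable (`known_shift`).
- A multi-locus tag is categorized once using the highest-priority
  overlap among all its hits, not fractionally — each unique tag
  contributes to exactly one category, so categories partition clean
  reads.

## Novel miRNA discovery

Eligible tags (20–24 nt, unannotated, ≤10 perfect genomic hits — more
than 10 hits is treated as repeat-derived) have two windows excised
per locus: 30 nt upstream + 200 nt downstream of the mature, and the
mirror, covering both possible arms. Windows are folded by the
pluggable engine; the default is the ViennaRNA thermodynamic folder
with default parameters, the standard tool for plant pre-miRNA
structure. Any callable `seq -> (dot-bracket, mfe)` that returns
nested structures deterministically can be substituted.

Hairpin acceptance (all configurable via `HairpinCriteria`):

| criterion | default | reasoning |
|---|---|---|
| mature on one arm | required | mature spanning the terminal loop is not Dicer-processable |
| duplex mismatched bases | ≤ 4 | consensus plant miRNA annotation practice |
| asymmetric bulge | ≤ 2 nt | same |
| paired mature bases | ≥ 16 | same |
| MFE | ≤ −18 kcal/mol | matches the weakest hairpins accepted in comparable published catalogs |
| genomic hits | ≤ 10 | repeat removal |

Mismatched bases are counted as the symmetric part of each interior
gap between consecutive paired mature bases (plus unpaired mature
ends); the asymmetric remainder is the bulge length. The star sequence
is read off the pair table with a 2-nt 3′ overhang, the canonical
Dicer signature. Candidates passing at several loci are reported once
with all loci listed. Families: a novel mature within 2 substitutions
of a known mature (no indels), or a precursor containing a known
hairpin's mature, joins that family; otherwise it is species-specific.

## Differential expression

TPM = count × 10⁶ / total clean reads of the library. Zero TPM is
revised to 0.01 before fold-change computation; species below 1 TPM in
both libraries are excluded. Significance uses the Audic–Claverie
exact statistic for digital counts; the reported p-value is the
two-sided tail 2·min(P(k≤y), P(k≥y)) capped at 1, with both sums
including the observed count. The point probability is exposed
alongside, since published tables of this kind do not state which form
they print. Numerics: log-gamma factorials, log-sum-exp tail
accumulation, and a geometric-ratio truncation bound that extends the
upper tail until the remainder is below 10⁻¹⁶ of the accumulated mass.
Note one property deliberately *not* claimed: the doubled-tail
two-sided p is not exactly invariant under swapping (x, N₁) with
(y, N₂); the exact swap identity holds for the point probability
(p(x|y; 1/r) = r·p(y|x; r)), and the tests assert that identity.

The default screen is |log₂ fold| ≥ 1 and p ≤ 0.05. The p cutoff is a
package choice — analyses in this style print raw p-values without
stating the threshold used alongside the two-fold rule — and is echoed
into the output header; a Benjamini–Hochberg column is emitted for
transparency, but the screen itself uses raw p-values as is
conventional for single-pair digital designs.

## Target prediction and cleavage validation

Scoring follows the plant complementarity penalty scheme: the miRNA
(5′→3′) is aligned to the reverse complement of an mRNA window;
mismatch 1.0, G:U wobble 0.5, gap 2.0, all doubled at miRNA positions
2–13; at most one gap (window length = miRNA length ± 1); S is
minimized over alignments, ties resolving to the gap nearest the 5′
end. A deletion takes the weight of the deleted miRNA position; an
inserted target base takes the weight of the position on its 3′ side
and marks that position as disturbed. The transcriptome scan evaluates
every window exactly using a vectorized prefix/suffix-sum
minimization, then re-scores candidate windows through the scalar
scorer (the two routes are asserted equal in tests); overlapping
candidate windows of one miRNA/transcript pair collapse to the
best-scoring site. Sites need S ≤ 4 *and* the positional rules:
perfect Watson–Crick at positions 10–11 (wobble not accepted at the
cleavage site), ≤1 mismatch/gap in 2–12, ≤2 in 12–21, never more than
two consecutive — the intersection of the two rule-sets emulates the
practice of keeping only predictions shared by two independent
predictors; this is an emulation of that workflow, not a
binary-compatible port of either tool.

Cleavage validation: the canonical cut leaves a 5′ end at the
transcript base paired to miRNA position 10; evidence validates a
site when ≥10 clones were sequenced (the conventional cloning depth)
and ≥50% of them pile up at the canonical base. Translational
repression without cleavage therefore never validates but remains in
the candidate table.

## Network and GO enrichment

Targeting edges run miRNA→protein; PPI edges are undirected, stored in
canonical order, and restricted to pairs where both proteins are
targets of responsive miRNAs (edges naming unknown proteins are
dropped and counted). Degree summaries count PPI partners separately
from targeting out-degree. Enrichment is a one-sided Fisher
(hypergeometric upper tail) per GO term annotating at least one target
gene — the universe choice of the common agricultural GO servers —
against the full annotated gene background; a term is significant only
when Bonferroni-adjusted p < 0.01 *and* BH FDR < 0.01, implementing
the conjunction of the two stated thresholds. GO ancestry propagation
is not performed (flat map); a pre-propagated map may be supplied.

## Synthetic data generator

The generator emulates the full experiment on a toy genome (default: 2
chromosomes × 60 kb) so every stage has known ground truth:

- 30 miRNA hairpin loci (10 labelled "known" and written to the
  mature/hairpin references; 20 left for discovery). Hairpins are
  designed as mature + loop (12–18 nt) + near-reverse-complement star
  (0–2 substitutions), embedded in 200 nt private flanks, and
  rejection-sampled until the *discovery code path itself* accepts the
  locus — recovery downstream is therefore a designed-in property.
- 12 responsive miRNAs (6 up at 4×, 6 down at 0.25×), the rest at 1×.
- 10 ncRNA contaminant loci cycling through the five classes; reads
  are drawn as 18–28 nt fragments.
- 60 genes (2–3 exons, both strands); 28 carry planted perfect target
  sites of responsive miRNAs inside exons; one target gene is a PPI
  hub wired to 24 other target genes; one GO term is planted on 10
  target genes; ~13 genes are flagged TFs.
- Two repeat-derived 21-mers planted at exactly 10 and 11 copies to
  exercise the repeat filter boundary.
- RACE-style clone evidence for 4 planted sites: three concentrated
  (7/10 clones at the canonical base) and one diffuse.

Libraries default to 50,000 reads each: species counts are multinomial
with treatment weights = control weights × fold change, renormalized
(the compositional effect of sequencing to fixed depth; with the
default small responsive mass the renormalization shifts expectations
by ~1%). Noise (5%) is random unmappable inserts, of which ~30% are
deliberately short (8–17 nt) so the length filter acts; 15% of signal
mass is uniform genomic "degradation" fragments and 28% ncRNA
fragments. Reads are error-free with constant quality "I" — exact-match
mapping is the modelling assumption, and an error rate field exists
but defaults to 0. Depths and genome size are chosen so the full run
stays under a minute on one CPU while every planted structure remains
comfortably detectable.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sequencing error and quality
profiles, isomiR end-heterogeneity, biased ligation, repeat families
beyond the planted tags, realistic transcriptome complexity
(alternative isoforms, UTR structure), GO term hierarchy, and hairpins
embedded in structured (non-random) genomic context. Notably, folding
random genome-derived fragments with a true thermodynamic engine does
occasionally produce windows that satisfy all hairpin criteria, so
zero false discovery is guaranteed only for unmappable noise — as in
real pipelines, genic fragments can fold.

## Numerical and degenerate-input choices

- Percentages print at two decimals with half-away-from-zero rounding
  (0.977552 → "97.76"), with a zero-denominator guard printing "0.00".
- Structure strings are validated (balanced brackets) before pair-table
  construction; an unbalanced engine output is a contract violation.
- Windows clipped at chromosome ends shorter than mature + 40 nt are
  skipped rather than folded.
- Zero-depth libraries yield empty, valid FASTQ; an empty transcript
  set yields an empty target table; an empty network exports valid
  empty SIF/GraphML.
- Everything iterates in sorted order and all randomness flows from a
  single integer seed, so a rerun of any stage on identical inputs is
  byte-identical.

## Known limitations

Single library pair (no replicate dispersion modelling — the exact
test conditions on totals only); no phased-siRNA or isomiR cataloguing;
no degradome-wide analysis (only site-level clone evidence); exact
substring mapping would need a proper index for genome sizes beyond
the tens of megabases; GO DAG reasoning and live database queries are
out of scope.
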