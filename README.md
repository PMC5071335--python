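# peroximir

A small RNA sequencing analysis pipeline for identifying plant miRNAs
that respond to oxidative (H₂O₂) stress, built for the classic
two-library design: one control library and one stress-treated library
of adapter-ligated 18–30 nt small RNAs, sequenced deeply and compared
without replicates. It is aimed at plant small-RNA researchers and at
method developers who need a fully self-contained, testable
re-implementation of this analysis style, including a synthetic-data
generator with known ground truth.

The pipeline covers:

1. **Read processing** — 3′ adapter trimming (longest exact
   adapter-prefix match, minimum overlap 6 nt), the ≥18 nt length rule,
   and collapsing of clean reads into unique tags with per-library
   counts.
2. **Annotation cascade** — each tag is assigned once, in a fixed
   priority: ncRNA classes (rRNA/tRNA/snRNA/snoRNA/scRNA, by exact
   containment in a reference), known mature miRNAs (exact match or
   ≤2 nt end offsets inside the annotated hairpin), then exon/intron ×
   sense/antisense by perfect genome mapping, else unknown.
3. **Novel miRNA discovery** — unannotated tags with ≤10 perfect
   genomic hits have flanking windows (30/200 nt) excised and folded
   (ViennaRNA, default parameters). A candidate passes if the mature
   sits on one arm of a stem–loop, pairs with a star arm with ≤4
   mismatched bases and no asymmetric bulge >2 nt, has ≥16 mature bases
   paired, and MFE ≤ −18 kcal/mol.
4. **Differential expression** — TPM normalization
   (`count × 10⁶ / clean reads`), zero values revised to 0.01, species
   under 1 TPM in both libraries excluded, log₂(treatment/control) fold
   change, and the Audic–Claverie exact tag-count statistic

   p(y|x) = (N₂/N₁)ʸ · (x+y)! / ( x! · y! · (1+N₂/N₁)^(x+y+1) )

   evaluated in log space; a species is stress-responsive at ≥2-fold
   change and two-sided p ≤ 0.05.
5. **Target prediction** — plant complementarity scoring (mismatch 1,
   G:U wobble 0.5, gap 2, penalties doubled at miRNA positions 2–13,
   ≤1 gap, S ≤ 4) intersected with positional rules that are strictest
   at the cleavage site (positions 10–11), plus validation of
   RACE-style 5′-end clone pileups at the base paired to miRNA
   position 10.
6. **Network & GO** — miRNA→target edges merged with a PPI edge list
   restricted to target proteins, SIF/GraphML export, and one-sided
   Fisher (hypergeometric) GO over-representation with Bonferroni and
   Benjamini–Hochberg control (significant only if both < 0.01).

## Worked example

Score a near-perfect target site and test a count pair for
differential expression:

```python
from peroximir import LibraryTotals, score_site, schwab_filter
from peroximir.diffexp import ExpressionRecord, normalize_and_adjust, screen_responsive
from peroximir.targets import render_duplex
from peroximir.sequtil import revcomp

mir = "TCATTGAGTGCAGCGTTGATG"
window = list(revcomp(mir)); window[2] = "A"     # one mismatch, miRNA 3' half
site = score_site(mir, "".join(window))
site.mirna_id, site.transcript_id = "bdi-miR397a", "Bradi1g66720.1"
print("S =", site.score, "positional rules:", schwab_filter(site))
print(render_duplex(site))

totals = LibraryTotals(17_811_109, 17_708_762)   # clean reads per library
rec = ExpressionRecord("bdi-miR397a", mir, 1200, 8030)
normalize_and_adjust([rec], totals)
screen_responsive([rec], totals)
print(round(rec.tpm_cs, 2), round(rec.tpm_ts, 2), round(rec.log2fc, 2), rec.responsive)
```

prints

```
S = 1.0 positional rules: True
5' GUUGUUGCGACGUGAGUUACU 3'  Bradi1g66720.1
   || ||||||||||||||||||
3' GUAGUUGCGACGUGAGUUACU 5'  bdi-miR397a
67.37 453.45 2.75 True
```

The single mismatch sits outside the doubled 2–13 core (S = 1.0) and
away from positions 10–11, so the site passes both rule-sets; the
count pair is ~6.7-fold up (log₂ = 2.75) and significant.

The whole pipeline runs from the shell on a simulated experiment:

```bash
peroximir run-all --outdir demo_run
```

which generates the synthetic genome and libraries, then writes
`tags.tsv`, `annotation_summary.tsv`, `novel_mirnas.tsv`,
`diffexp.tsv`, `targets.tsv`, `cleavage.tsv`, `network.graphml`,
`enrichment.tsv` and a two-column `report.tsv` of headline statistics
(clean-read percentages, unique/mapped tag counts, known/novel miRNA
counts, abundance tiers, MFE range, responsive up/down counts). On the
default configuration the run takes well under a minute and recovers
all 20 unlabelled planted miRNAs, all planted target sites, the
24-partner PPI hub and the planted enriched GO term.

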