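# plastinet

Post-alignment analysis of phenotypic plasticity in gene regulation for a
2×2 factorial design — age (young / aged) × mating status (virgin / mated) —
as used to study mating- and aging-induced changes in female *Drosophila
melanogaster*. The package identifies phenotypically plastic miRNAs,
transcripts and histone-mark (H3K4me1, H3K4me3, H3K9ac) peaks, flags
epigenetic markers of mating-induced accelerated aging, and assembles
three-layer miRNA–target–partner regulatory networks with a histone-mark
overlay. A synthetic-data generator with planted ground truth makes every
stage testable without sequencing data.

It is aimed at computational biologists who already have post-alignment
objects in hand: feature-by-sample count tables, per-sample peak calls
(BED-like), length-tagged small-RNA read intervals, a gene annotation, and
miRNA→target / gene–gene interaction tables.

## The statistical core

For each feature (a miRNA, transcript, or merged ChIP peak) the normalized
abundance is modeled by a one-way ANOVA over the four conditions,

    Y = μ + C + ε,

where μ is the grand mean, C the four-level condition effect and ε the
residual. Significance is assessed by **permutation**: the p-value is the
fraction of condition-label assignments (the identity included) whose F
statistic is at least the observed F. For the 4 × 2 design the 8!/(2!)⁴ =
2520 distinct assignments are enumerated exhaustively; larger designs use
seeded Monte Carlo. The p-vector is adjusted with **Benjamini–Yekutieli**
FDR, valid under arbitrary dependence, with q(i) = min over j≥i of
p(j)·m·c(m)/j and c(m) = Σ 1/k. Post hoc, the four pairwise contrasts —
mated − virgin within each age, aged − young within each mating status —
are called when the omnibus q < α **and** |Δ| exceeds one **pooled SD**
(the square root of the within-condition mean-square error).

Around that core:

* **chipseq** — merges per-sample peak calls (single-linkage overlap,
  support ≥ 2 samples, merged width > 146 bp — the mono-nucleosome span),
  computes FPKM = count / ((width/10³)·(library/10⁶)), subtracts each
  sample's median FPKM over 1 kb non-peak bins, quantile-normalizes, and
  assigns candidate genes within ±2 kb of each peak.
* **smallrna** — read-length histograms (miRNA mode at 22 nt, rasiRNA at
  30 nt) and calling of genes that shed 15–18 nt degradation fragments
  exclusively in young mated females.
* **plasticity** — contrast membership, Venn overlap structure, persistent
  post-mating marks and accelerated-aging markers (persistent marks whose
  change also arises, in the same direction, with aging in virgins).
* **network** — miRNAs → differentially expressed targets → interaction
  partners linked to more than one target, with per-gene histone-mark
  annotations; lossless TSV/GraphML export, SIF for viewers.
* **validation** — the miRNA-overexpression effect rule (significant
  virgin-vs-mated difference in exactly one of the control/overexpression
  crosses), pooled-variance t-tests, and Dunnett's many-to-one test for
  egg-laying counts.
* **simulate / pipeline** — planted-truth generators for every input, and a
  one-config orchestrator with a checksummed run manifest.

## Worked example

The package ships a 20-row qPCR summary table (virgin-vs-mated p-values for
candidate target genes under control and miRNA-overexpression crosses).
Applying the effect rule:

```sh
$ plastinet validate-effects --out effects.tsv
14/20 target genes affected (70%) -> effects.tsv
```

Fourteen of twenty target genes change their mating response when the
upstream miRNA is overexpressed — evidence that the network edges are
causal, not just correlational.

Egg laying for simulated overexpression lines (10 replicate vials of 5
mated females each), compared against the control line with Dunnett's test:

```sh
$ plastinet simulate --outdir sim --seed 3
$ plastinet eggs --counts sim/eggs.tsv --seed 3 --out eggs_result.tsv
   line  mean  percent_change   p_adjusted
mir-286 281.3       12.655186 1.385209e-02
 mir-34 167.0      -33.119744 5.001765e-10
mir-92b 162.3      -35.002002 3.806068e-10
mir-988 330.0       32.158590 1.357865e-09
```

Lines overexpressing mir-34 and mir-92b lay ~33–35% fewer eggs than
control; mir-286 and mir-988 lay more — all familywise-significant.

A full synthetic run (`plastinet run --config run.yaml`) executes
simulate → differential analysis → degradation calling → ChIP signal →
plasticity → network → validation and writes a `manifest.json` whose
checksums are identical across reruns with the same config.

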