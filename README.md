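# polykit

Subgenome-level analysis of allopolyploid genomes: differential k-mer
subgenome phasing, telomere/centromere/TE landscapes with LTR
insertion-time dating, weighted DNA-methylation profiling with
gene-body-methylation (gbM) classification, homeolog expression-bias
calling, and Nei–Gojobori Ka/Ks comparison across subgenomes.

The package targets the kind of question raised by octoploid strawberry
(*Fragaria × ananassa*, subgenomes A–D) and similar allopolyploids: which
subgenome is *dominant* — retaining more genes, fewer transposable
elements, lower DNA methylation, higher homeolog expression and stronger
purifying selection — and which subgenomes evolve in parallel?  Every
stage runs end-to-end on a built-in synthetic allopolyploid generator with
truth tables, so no external download is needed to exercise or validate
the methods.

## The statistics at the core

* **Phasing.** 15-mers are counted per chromosome; k-mers whose per-Mb
  frequency within a homoeologous group spans ≥ 2-fold are *differential*;
  k-means over the differential frequency profiles assigns chromosomes to
  subgenomes (with PCA, silhouette diagnostics, per-window enrichment by
  one-sided binomial tests, and a neighbour-joining tree over subgenome
  consensus profiles).
* **Repeats.** Telomeres are maximal tandem runs of `(TTTAGGG)n` near
  chromosome ends; centromeric satellites are detected as the period
  *p\** maximising the self-match fraction `seq[i] == seq[i+p]` (smallest
  period on ties); LTR retrotransposons are dated from twin-LTR divergence
  via Jukes–Cantor, `K = −(3/4)·ln(1 − 4p/3)`, `T = K / (2μ)` with
  `μ = 1.3×10⁻⁸` substitutions·site⁻¹·yr⁻¹ by default.
* **Methylome.** The weighted level of a region is `Σ n_meth / Σ coverage`
  over context-matching cytosines with coverage ≥ 2.  A gene is **gbM**
  when its methylated-site count is binomially enriched over the
  coding-region background in CG (one-sided tail, BH-corrected per
  context) while CHG and CHH are not.
* **Bias.** Homeolog pairs are classified A-biased / X-biased by direct
  CPM comparison, and by an exact conditional binomial test of the A-copy
  count against the pair total (`π` from library sizes, BH across pairs).
* **Selection.** NG86 Ka/Ks (equal-weight minimal mutational pathways,
  stop-codon pathways excluded, JC correction) per gene copy against an
  outgroup anchor, compared across subgenomes with paired Wilcoxon
  signed-rank tests.

## Worked example

```bash
polykit simulate --out out/sim --seed 1
polykit phase    --genome out/sim/genome.fa --window 50000 --out out/phase
polykit repeats  --genome out/sim/genome.fa --genes out/sim/genes.gff3 \
                 --tes out/sim/tes.gff3 --out out/repeats
polykit methylome --cx out/sim/cytosines.tsv --genes out/sim/genes.gff3 \
                 --tes out/sim/tes.gff3 --out out/methylome
polykit bias     --counts out/sim/counts.tsv --pairs out/sim/pairs.tsv \
                 --states out/methylome/states.tsv --out out/bias
polykit kaks     --pairs out/sim/pairs.tsv --cds out/sim/cds.fa \
                 --outgroup-cds out/sim/outgroup_cds.fa --out out/kaks
polykit report   --dir out --out out/report.json
```

`out/report.json` for seed 1 contains (abridged):

```json
{
  "telomere_calls": 56,
  "monomer_periods": [147, 147, "... x28"],
  "phasing": {"clusters": {"A": 7, "B": 7, "C": 7, "D": 7}},
  "te_total_fraction": {"A": 0.106, "B": 0.186, "C": 0.186, "D": 0.186},
  "ltr_median_T_years": {"A": 2.06e6, "B": 2.13e6, "C": 2.27e6, "D": 1.99e6},
  "gbm": {"gbM": 252, "unmethylated": 588},
  "kaks_median_ratio": {"A": 0.267, "B": 0.460, "C": 0.458, "D": 0.471}
}
```

Reading: all 28 chromosomes carry telomere arrays at both ends (56
calls); every centromeric satellite is recovered with its 147-bp period;
k-means phases the four subgenomes perfectly (7 chromosomes each);
subgenome A carries roughly half the TE load of B/C/D; twin-LTR dating
puts the planted insertions near 2 Mya; 252/840 genes (30%) are called
gbM, matching the planted fraction; and the median Ka/Ks of subgenome A
is well below B/C/D — the signature of a dominant subgenome under
stronger purifying selection.

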