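# Methods

This note documents the models behind each polykit stage, the synthetic
data generator whose seeded outputs the test-suite validates against, the
numerical choices that were genuinely open, and what passing tests do and
do not establish about real data.

## Synthetic allopolyploid generator (`polykit.sim`)

The generator emulates a chromosome-level allopolyploid assembly with four
subgenomes A–D in seven homoeologous groups of 300 kb chromosomes
(`chr_1A` … `chr_7D`).  All randomness derives from a single integer seed;
identical configurations produce byte-identical output files.

**Progenitor divergence.**  One ancestral sequence per homoeologous group
is evolved down a rooted progenitor topology, default
`(A:4,(B:0.6,(C:0.5,D:0.5):0.15):3)`, with i.i.d. per-site substitution to
a uniformly chosen different base at `branch_sub_rate` (default
0.02/site/unit length) — a Jukes–Cantor-like single-round model chosen so
the dating correction used downstream is exact for the planting process.
The branch lengths encode a deep split of the A progenitor and a rapid,
near-simultaneous radiation of the B/C/D progenitors with C and D
splitting last.  That geometry is what produces the characteristic
phasing picture in allopolyploids with one distant and three closely
related progenitors: PC1 of the differential k-mer profiles isolates A
from B/C/D, and the subgenome tree recovers the `{A,B} | {C,D}` quartet.
Mutations on shared internal branches are shared by all descendant
subgenomes, which is what makes them correlated.

**TE families.**  Diagnostic LTR families (alternating Copia/Gypsy)
descend along the same topology: an ancestral 5′LTR + internal backbone is
evolved per branch at `te_family_divergence` (0.03/unit), and each leaf's
family consensus receives a leaf-private 31-bp seed motif planted verbatim
three times in the internal region.  31 > 2·15 − 1, so each motif is
guaranteed to contribute all 17 of its 15-mers as unambiguous
subgenome-diagnostic k-mers; the evolved backbone contributes the shared
descent structure.  Element copies drift 1% from the consensus, and the
3′LTR of each copy is the 5′LTR mutated at `ltr_divergence` (default
0.052 — about 2.1 Mya at the default clock, inside the range expected for
post-polyploidization insertions).  Subgenome A receives half the copy
number of B/C/D (`te_load`), reproducing the dominant-subgenome pattern
of a lighter TE load; LINE, DNA and Simple families are shared verbatim
genome-wide and are therefore non-diagnostic.  Setting
`te_families_per_subgenome = 0` removes all diagnostic signal; the
phasing stage must then flag the assignment non-separable.

**Telomeres, centromeres.**  `(TTTAGGG) × telomere_copies` is planted at
the 5′ end and its reverse complement at the 3′ end of every chromosome
(`telomere_missing` ends can be left bare to emulate incomplete
assemblies); one centromeric array of `monomer_copies` copies of a random
147-bp monomer (0.5% per-copy divergence) sits mid-chromosome.

**Genes.**  Single-exon CDSs (ATG + random non-stop codons, 600 bp, no
terminal stop) are placed at group-shared slots so gene order is conserved
across subgenomes.  CDS evolution is codon-aware: proposed substitutions
that create stops are rejected and nonsynonymous changes are accepted
with probability `omega` (0.15 for subgenome A, 0.5 elsewhere), planting
stronger purifying selection on A.  An outgroup copy of each gene evolves
on its own branch and anchors the per-subgenome Ka/Ks values.

**Methylome.**  Every cytosine on both strands receives its context from
the reference trinucleotide (CG / CHG / CHH, H ∉ {G}; the last two bases
of each strand are skipped as context-undefined).  The per-site true level
is Beta-distributed around the mean of the innermost containing feature
class — TE ≫ gbM gene body (CG only) ≫ background — with overdispersion
ρ = 0.1 (no noise model is available to copy, so ρ is a placeholder, not
an estimate).  Depth is Poisson around `read_depth` (default 30), with 2%
of sites redrawn at ~Poisson(0.7) so the coverage ≥ 2 filter is always
exercised.  Defaults: background CG/CHG/CHH = 0.10/0.05/0.02, gbM body
CG = 0.60, TEs = 0.85/0.65/0.30.

**Counts.**  Per homeolog anchor, expression is lognormal around 200;
each planted A-biased (X-biased) pair gives the favored copy a
`bias_effect`-fold expected advantage; `bias_fraction_A` defaults to 0.52
with the remainder X-biased.  Noise model: per (anchor, replicate) a
shared Gamma(1/φ, φ) biological factor multiplies the expected value of
*both* copies before Poisson sampling (φ = 0.1).  Marginal counts are
negative binomial, yet conditioning on a pair's total leaves an exactly
binomial split under the null — the statistically coherent way to make
both contracts hold at once ("negative-binomial counts" and "the exact
conditional binomial test is calibrated").  Biologically this says the
two homeolog copies share their trans environment within a sample, which
is the component of biological variance that pair-internal comparisons
cancel.  Two replicates by default.

**What the generator does not emulate:** introns and isoforms, indels and
structural variation, homoeologous exchanges between subgenomes,
read-level artifacts (mapping bias, bisulfite conversion failure beyond a
constant error rate), cell-type mixtures, and realistic TE
superfamily/age structure.  Passing recovery tests therefore shows the
estimators are correct and calibrated under their stated models — not
that real octoploid data meets those models.

## Phasing (`polykit.phasing`)

Canonical 15-mer counts per chromosome (N-containing windows skipped;
canonical = lexicographic min of k-mer and reverse complement) are
restricted to k-mers with genome-wide total ≥ 10.  A k-mer is
*differential* when, within a homoeologous group, its maximum per-Mb
frequency is ≥ `min_fold` (2) times its minimum and ≥ `min_freq` (5/Mb),
in at least half the groups (rounded up).  These thresholds are explicit
replacements for an external phasing tool's undocumented criteria and are
configurable.  K-means (fixed seed 42, 20 restarts) runs on the per-Mb
frequency matrix; clusters map to subgenome names by majority of the
chromosome-name labels when present, else stable `SG1..SGn`.  A
silhouette below 0.25 — or an empty differential set — flags the
assignment non-separable rather than failing.  Cluster-specific k-mer
sets (mean frequency ≥ 2× every other cluster) drive per-window
enrichment: one-sided binomial tests of the window's own-subgenome count
against the genome-wide proportion of that set, BH-corrected over all
windows; windows with no diagnostic k-mer have undefined proportions and
carry no flag.  The subgenome tree is neighbour joining on
1 − cosine-similarity of cluster consensus profiles — an explicitly
heuristic stand-in for phylogenetic inference, with no likelihood claim.

## Repeat landscape (`polykit.repeats`)

*Telomeres*: within 10 kb of each terminus (motif at 5′, reverse
complement at 3′), maximal chains of tandem motif copies allowing ≤ 1/7
mismatches per copy, ≥ 10 copies.  *Satellite monomers*: for periods
50–200, positions where the windowed self-match fraction at some period
reaches 0.8 seed candidate regions; per region the period maximising the
match fraction is chosen, with the smallest period taken among near-ties
(tolerance 0.02) so a 147-bp monomer is not reported as 294; boundaries
are extended period-wise and trimmed by per-copy identity to the majority
consensus.  Random sequence sits near a 0.25 match fraction, far below
threshold, giving a zero false-call rate by construction.  *Composition*:
per-class fractions after per-class interval merging, so overlapping
annotations are not double-counted.  *Distances*: nearest-edge gap (0 on
overlap); genes on TE-free chromosomes get undefined distances, excluded
from the within-cutoff fraction and counted separately.  *Dating*:
`p` over N-free sites, `K = −(3/4)ln(1 − 4p/3)` (undefined and flagged
saturated at p ≥ 0.75), `T = K/(2μ)`.  μ defaults to the widely used
plant LTR clock 1.3×10⁻⁸ /site/yr and is configurable; per-subgenome 95%
CIs are empirical 2.5/97.5% quantiles rather than a parametric interval.

## Methylome (`polykit.methylome`)

Weighted levels aggregate numerators and denominators (never means of
means), so they are invariant to region partitioning, and return NaN —
never zero — when no context-matching site with coverage ≥ 2 exists.
Site binarization for the gbM test: a site is methylated when a one-sided
binomial test of its methylated reads against a bisulfite
non-conversion/error rate (default 0.005) rejects at 0.05; sites too
shallow for that test to ever reject fall back to a ≥ 0.5 proportion
rule.  The background π₀ per context is the methylated-site fraction over
the coding-region reference set (the read-weighted p₀ is reported
alongside).  Per gene and context, P(X ≥ m | n, π₀) is BH-corrected
across genes within the context; classes are gbM (CG significant, CHG and
CHH not), CHG/CHH-methylated, unmethylated, or undetermined when any
context has fewer than 5 eligible sites.  The CG-only combination rule is
the standard gbM definition; it is the central interpretive decision and
is configurable through the per-context q-values in the output.  Metagene
profiles use 10 fixed-width bins per 1-kb flank and 20 length-normalised
body bins, axis-reversed for minus-strand features; every eligible site
falls in exactly one bin.

## Homeolog bias (`polykit.bias`)

Sequence-mode pairing is a deliberate simplification of synteny
anchoring: reciprocal best CDS k-mer (k = 8) Jaccard similarity within
the homoeologous group, filtered to the longest increasing subsequence of
positional ranks.  Method *direct* compares mean CPM between copies
(ties only at exact equality; all-zero pairs are tied and flagged);
whether "transcript numbers" means raw or normalised counts is ambiguous
in the field, so both are exposed (`normalization="raw"`).  Method *test*
is an exact conditional binomial test of the summed A-copy count against
the pair total with expectation π from library sizes, two-sided,
BH-corrected — a fully specified, oracle-checkable replacement for
negative-binomial DE machinery.  When the two copies are quantified
against separate subgenome alignments, per-side library sizes can be
supplied.  The gbM association selects the top-n pairs per class by
|log2FC| (pair id breaks ties) and reports favored/unfavored gbM
fractions with a Fisher exact test on the 2×2 of bias direction × favored
copy gbM.

## Ka/Ks (`polykit.kaks`)

NG86 with the classic conventions: per-position synonymous-site fractions
(changes to stops count as nonsynonymous sites, so N + S = 3 × codons
exactly), equal-weight averaging over minimal mutational pathways with
stop-traversing pathways excluded (all pathways used only if every one is
blocked), ambiguous codons skipped pairwise, JC correction of pN and pS.
The counting model is a documented choice — results are comparable
run-to-run, with no claim of numeric identity to any unnamed external
calculator.  Per-subgenome values come from dating each gene copy against
its outgroup anchor, giving the paired samples the dominance comparison
needs; the paired Wilcoxon drops zero differences and uses the exact null
up to n = 25, a continuity-corrected normal approximation beyond.
Records with Ks = 0 have undefined ratios and are excluded from medians
(their count is reported).

## Problem sizes and seeds

The test-suite and the acceptance script run the generator at its default
conditions: the full 28-chromosome genome (8.4 Mb) for phasing, repeats
and selection; a 2-group, 100-kb-chromosome configuration (200 genes,
~0.4 M cytosines) for methylome recovery runs; 2000 pairs for bias
calibration; 500 pairs for dating recovery.  These sizes keep every
recovery estimate's Monte-Carlo error well inside its acceptance band
while the whole suite stays desk-scale.  All stochastic tests fix their
seeds; the acceptance script derives every stream from its `--seed`.

## Known limitations

Single-exon gene models only; no support for BAM/compressed input; the
NJ tree is not a phylogeny; the tandem-monomer detector reports one call
per contiguous candidate region and can merge abutting arrays of
different periods; the exact binomial bias test inherits the
shared-environment assumption — with strongly copy-independent biological
noise it would be anti-conservative, which is precisely why packages with
explicit dispersion estimation exist for real data.
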