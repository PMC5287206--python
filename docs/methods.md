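# Methods

`lad_shift` reimplements, as a tested pipeline, the analysis of lamin-B1
DamID data used to map nuclear-peripheral genome organization across cell
conditions: per-GATC-fragment quantification, LAD calling by circular
binary segmentation, differential peripheral regions (DRs), cross-condition
LAD clustering, and integration with differential gene expression. A
synthetic-data generator supplies study-shaped inputs with known ground
truth so every stage is testable without any external download.

## Signal model

DamID fuses *E. coli* Dam methylase to lamin B1 so DNA contacting the
nuclear lamina is adenine-methylated at GATC motifs; a Dam-alone sample
controls for accessibility. Reads from each sample are assigned to DpnI
fragments — the intervals between consecutive GA^TC cut sites (DpnI cuts
blunt, 2 bp into the motif; GATC is its own reverse complement, so one
forward scan finds all sites). A read is assigned to the fragment
containing its midpoint: unambiguous for reads spanning a cut and
consistent with fragment-centric quantification. Reads are counted as
given; no deduplication is applied (noted in the logs).

The per-fragment signal is

    log2( (lamin_i / N_lamin + p) / (dam_i / N_dam + p) )

with library sizes `N` and pseudocount `p = 0.5 / min(N)` (half a read in
the shallower library). Scaling by library size makes conditions of
unequal depth comparable; the pseudocount keeps single-sample zeros
finite. Fragments with zero counts in both samples are missing (NaN).
Positive signal indicates preferential association with the nuclear
periphery.

Tracks from all conditions are then quantile normalized jointly (each
rank replaced by the cross-track mean at that rank; ties receive the mean
of the tied ranks' values; unequal missingness is aligned by linear
interpolation of the sorted-value functions) so that between-condition
comparisons are not driven by distributional differences.

Smoothing (running mean over the ±50 nearest fragments per chromosome,
truncated at chromosome ends, missing values excluded) is applied to the
**profile tracks written for display only**. Segmentation runs on the
unsmoothed normalized track: a running mean induces strong short-range
autocorrelation that violates the exchangeability assumption of the
permutation test below (empirically producing massive over-segmentation),
and it attenuates features shorter than the ~26 kb window span below the
15 kb minimum-size filter. At the 1/256-bp GATC density the ±50-fragment
window spans ~26 kb (median), the scale customarily quoted for DamID
profile smoothing.

## LAD calling (circular binary segmentation)

Each chromosome's track is recursively partitioned. For the values
`y[0..n)` of a segment, every arc `y[i:j)` is compared with its (circular)
complement by the absolute pooled two-sample t-statistic; the maximal
statistic is tested against a permutation null at level `alpha` (default
0.01, permutations default 1000). If significant, the segment is split at
the arc boundaries and the parts are re-examined; recursion stops when no
split is significant. Missing fragments are skipped by the statistic but
boundaries snap to fragment start coordinates, and segments tile each
chromosome. No "undo" pruning is applied.

Three numerical devices keep the search tractable at chromosome scale
without changing its logic:

* **Arc-length grid for the permutation test.** The permutation maximum is
  evaluated over all short arc lengths (≤ 32) plus a geometric ladder
  (ratio 1.15) and its mirror. Observed and permuted maxima use the same
  grid, so exchangeability — hence test validity — is preserved; the grid
  only makes the test marginally conservative. Breakpoint *localization*
  always uses the exhaustive scan over all arcs
  (`locate_change_point`), so the located breakpoint equals the argmax of
  the two-sample t-statistic.
* **Binning of long segments.** Segments with more than 500 informative
  fragments are tested on 500 adjacent-fragment bin means; significant
  breakpoints are then refined at full resolution within one bin of the
  coarse optimum.
* **Curtailed permutation sampling.** Permutations are drawn in blocks of
  100 and stop as soon as the decision at `alpha` cannot change: when the
  exceedance count passes `alpha*(n_perm+1) - 1` (futility) or when 200
  permutations have produced no exceedance (the running p-value estimate
  is ≤ 1/201, far below the default alpha).

These choices mean segment boundaries are not claimed to be bit-identical
to DNAcopy's; the algorithmic core (arc t-statistic, permutation
significance, recursive splitting) is the same.

LADs are then the positive-mean tracts, merged when separated by < 5 kb
(strict inequality) and discarded when shorter than 15 kb. "Positive"
means segment mean strictly > 0. A gene is "in a LAD" if it overlaps one
by ≥ 1 bp (0-based half-open intervals throughout; adjacency is not
overlap).

Intrinsic limits worth knowing: the permutation test at alpha = 0.01 has
no power on segments of ~10 points with a strong two-level split (a random
permutation regroups the high values contiguously with probability above
alpha), and child segments are falsely split at about the alpha rate —
both properties of any faithful permutation CBS, visible in the test
suite's calibration checks.

## Differential regions

Candidate windows are CBS segments rebuilt from the union of the two
conditions' segment boundaries (symmetric in the conditions, rather than
fixed-width bins). A window is highlighted when

* (a) its mean signal is positive in one condition and negative **or
  missing** in the other (missing-vs-missing is never highlighted), or
* (b) both means are positive and one is at least `ratio_factor` (default
  2.0) times the other. Rule (b) is only applied when the larger mean
  clears a floor of 0.05: below that, a two-fold ratio between near-zero
  numbers is noise, not signal.

Straight LAD set differences between the two conditions are added to the
candidate list. Same-direction candidates are merged when < 5 kb apart
(opposite directions never merge; overlaps between them are kept and
logged), regions below 15 kb are dropped, and the survivors are classified
IP (signal gain in the NET condition: interior → periphery) or PI (signal
loss: periphery → interior).

Enrichment over chance is assessed by iterated Fisher tests: each
iteration circularly shifts **both** tracks jointly along the fragment
backbone by one random offset — randomizing the signal relative to the
windows while preserving each track's autocorrelation and the paired
relation between the conditions — and re-runs the composite filter over
the same windows. Genuine DRs are aligned with their windows, so shifts
dilute highlights; a 2×2 table (highlighted vs not, observed vs shifted)
per iteration yields a Fisher exact p, summarized as the median across
iterations (default 100). Shifting only one track was rejected: it
destroys the correlation between conditions and *creates* spurious
disagreement highlights, inverting the direction of the test.
Benjamini–Hochberg correction is applied across DR sets when several NET
conditions are tested. A table with a zero margin, or no observed
highlights at all, reports p = 1 with a warning.

## LAD comparison across conditions

LAD boundaries rarely coincide exactly between conditions, so LADs are
grouped into clusters by single-linkage over ≥ 1 bp interval overlap
across all conditions. Each cluster's signature is the set of conditions
contributing a member; per-signature cluster counts and coverages (union
of the member LADs — for singleton signatures this equals the footprint)
are the numbers behind proportional Venn / Chow-Ruskey accounting.
Summary tables report counts, coverage in bp and % of the declared genome
size, size range/mean/median, and the number of overlapping genes.
Diagram rendering is out of scope.

## Expression integration

Differential expression is called from log2-intensity replicate matrices
with an empirical-Bayes moderated t: per-gene residual variances are
shrunk toward a prior fitted by moment matching of the log variances to a
scaled-F model (prior df from a Newton inversion of the trigamma
function), the moderated t gets `df_residual + df_prior` degrees of
freedom, p-values are Benjamini–Hochberg adjusted, and a gene is up/down
when |log2FC| > 0.5 at FDR < 0.05, else "nc". The implementation is
checked in the test suite against limma's `lmFit`/`eBayes` on the same
matrix (agreement to 4-5 significant digits); the two-group moderated t
is the implemented case, which is equivalent to the moderated F for a
two-condition comparison.

Genes are classified positionally between a control and a NET condition:
overlap with an IP DR → IP, with a PI DR → PI, with both → AMB; without
any DR, in LADs of both conditions → PP, in neither → II, and in exactly
one → AMB (position apparently changed without a supporting DR — the
conservative reading of "could not be determined"). The classes partition
the genes.

`gene_window_delta` reports the NET-minus-control mean signal over a
100 kb window centered on the gene midpoint (strand-agnostic, truncated
at chromosome ends, fragments enter by midpoint). Concordance tabulates
the {IP, PI} × {up, down} counts over genes that are both repositioned
and differentially expressed; the expected-direction fraction is
(IP∧down + PI∧up)/total — peripheral recruitment with downregulation,
release with upregulation — with a two-sided Fisher exact p, plus ecdfs
of |window delta| per class-direction group. Reference-differentiation
programs (gene → log2FC tables) are compared by two-sample KS tests of
the reference fold changes of NET-up (and NET-down) genes against all
assayed genes present in the reference (two-sided by default; the gene
universe is the intersection of the assayed genes and the reference
table), and genes above the reference 2-fold upregulation threshold are
flagged with NET-direction counts. Cross-system gene-set overlaps are
tested hypergeometrically.

## Synthetic data generator

The generator emulates the study design: a control line and lines
overexpressing tissue-specific nuclear envelope transmembrane proteins
(NETs), each with one Dam-LaminB1/Dam-alone DamID pair and replicate
expression arrays.

**Genome.** GATC motifs are inserted at exponential spacing (mean
1/`gatc_rate`, default 1/256 bp — the expected density in random
sequence) into random background scrubbed of accidental motifs, so the
emitted FragmentMap is exactly the digestion of the emitted FASTA.
Defaults: 5 chromosomes × 2 Mb (≈ 39k fragments), desk-scale while large
enough for chromosome-scale segmentation.

**Planted architecture.** Per condition: long constitutive LADs
(3 × 400–600 kb, shared by all conditions), shared facultative LADs
(6 × 30–80 kb), and per NET 20 IP regions (LADs only in that NET) and 20
PI regions (LADs everywhere *except* that NET), 18–35 kb each — the
facultative-LAD size scale. Features are laid out non-overlapping with
≥ 20 kb spacing (so distinct features cannot be bridged by the 5 kb merge
rule). Planted LADs cover ≈ 1/3 of the genome in every condition —
realistic for mammalian genomes, and it centres the library-size-normalized
log-ratios on the planted means (the normalization offset
−log2(Σ lenfrac·2^planted) vanishes when 2·f + 0.5·(1−f) ≈ 1, i.e.
f ≈ 1/3 for planted ±1).

**Reads.** Dam-alone rates are proportional to fragment length
(accessibility control); lamin rates multiply that by
2^(planted log2 + N(0, noise_sd)), with planted +1 inside the condition's
LADs and −1 outside by default and noise sd 0.5 per fragment. Counts are
negative-binomial via gamma-Poisson mixing (variance m + dispersion·m²,
default dispersion 0.05; Poisson at 0) — DamID counts are overdispersed,
and this stresses the normalizer. Default depth 500k reads per sample
(≈ 13 reads/fragment) is chosen for desk-scale runtime, not fidelity to
any particular sequencing depth. Read intervals (default 75 bp) are
placed entirely within their fragment, so midpoint assignment round-trips
the counts exactly. Sequencing error, mappability bias, PCR duplicates
and copy-number variation are not simulated — passing tests say nothing
about robustness to those.

**Expression.** Gene baselines ~ N(8, 1.5) log2 intensity; replicates add
N(0, 0.3) noise (3 replicates by default). Per NET, 200 DE genes with
true log2FC ± 1.5: half drawn from genes overlapping that NET's planted
DRs (configurable via `de_repositioned_fraction`), the rest from
elsewhere. Repositioned DE genes move in the expected direction
(IP → down, PI → up) with probability `concordance_rate` (default 0.7,
the magnitude of direction agreement reported for this kind of analysis);
non-repositioned DE genes get random directions. The
reference-differentiation table reuses the expression machinery with an
independent DE set overlapping the NET's at `ref_overlap_rate` (default
0.3), returning noisy mean log2FCs.

All randomness flows from one seed through named substreams
(genome/truth/reads-per-condition/expression/reference), so a fixed seed
fixes every output byte-for-byte and each stage can be regenerated
independently.

## Problem sizes and calibration checks

The test suite and the acceptance script run the default ("standard")
simulation — 10 Mb, ≈ 39k fragments, 4 conditions, noise sd 0.5 — through
the full pipeline in about a minute on one CPU, recovering planted LADs at
base-pair Jaccard ≈ 0.99 and planted DRs at base-pair precision and recall
≈ 0.99. Concordance calibration uses 100 seeded truth+expression
simulations with 500 repositioned+DE genes each. The change-point locator
is compared with an exhaustive two-sample-t split search on 100 seeded
single-change-point series (n ≤ 30), and the composite filter against a
direct restatement of its rules on an exhaustive sign/ratio/missing grid.

## Known limitations

* Exact DNAcopy/limma equality is not claimed; the equivalent cores are
  implemented and cross-checked (limma to numerical agreement, CBS to
  oracle agreement on localization).
* Single DamID library per condition; no replicate-aware segmentation or
  DR calling.
* No GC/mappability correction; the generator plants none.
* The Fisher-enrichment null (joint circular shift) is one defensible
  randomization; per-fragment shuffles would destroy autocorrelation and
  overstate significance.
* The moderated statistic covers two-group comparisons; multi-group
  moderated F is not implemented.
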