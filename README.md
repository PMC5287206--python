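# lad-shift

Analysis of lamin-B1 DamID data: mapping which parts of a genome sit at
the nuclear periphery, how that organization changes between cell
conditions, and how positional changes relate to gene expression.

The nuclear lamina is a repressive environment, and tissue-specific
nuclear envelope transmembrane proteins (NETs) can reposition specific
genes and chromosomes to it. DamID tethers *E. coli* Dam methylase to
lamin B1 so peripheral DNA is adenine-methylated at GATC motifs; a
Dam-alone sample controls for accessibility. `lad-shift` takes aligned
read intervals from such paired samples and produces:

* **per-DpnI-fragment signal**: `log2(lamin/Dam-alone)` with library-size
  scaling, quantile normalization across conditions, and ±50-fragment
  profile smoothing;
* **LADs** (lamina-associated domains): positive-signal tracts from
  circular binary segmentation (CBS) — recursive arc-vs-complement
  two-sample-t change-point search with permutation significance — merged
  when < 5 kb apart, discarded when < 15 kb;
* **DRs** (differential regions) between a control and a NET condition: a
  composite filter over CBS windows (sign flip, or ≥ 2-fold ratio between
  positive signals) plus straight LAD subtraction, classified
  IP (interior → periphery) or PI (periphery → interior), with
  iterated-Fisher enrichment against a circularly shifted null;
* **cross-condition LAD clusters** (single-linkage by overlap) with
  membership-signature counts and coverages — the numbers behind
  proportional Venn / Chow-Ruskey comparisons;
* **position–expression integration**: moderated-t differential
  expression (empirical-Bayes shrunk variances, BH-FDR 5%, |log2FC| > 0.5),
  II/PP/IP/PI/AMB gene classes, 100 kb gene-window signal deltas, and the
  expected-direction concordance (IP with down, PI with up; Fisher exact),
  plus KS comparison against reference differentiation programs.

A synthetic-data module generates study-shaped inputs — genome FASTA with
realistic GATC spacing, paired read sets with planted LAD/DR structure,
replicate expression matrices coupled to the planted positional shifts —
so the whole pipeline is testable end to end with known ground truth.

## Worked example

```python
import lad_shift as ls
from lad_shift.intervals import jaccard

cfg = ls.SimulationConfig(seed=7, n_chromosomes=2, chrom_length_bp=500_000,
                          n_constitutive_lads=2, constitutive_lad_len_bp=(80_000, 120_000),
                          n_facultative_lads=3, facultative_lad_len_bp=(20_000, 40_000),
                          n_drs_per_class=4, dr_len_bp=(18_000, 30_000),
                          n_genes=200, n_de_genes=60, reads_per_sample=100_000,
                          net_conditions=("NET29",))
sequences, fmap = ls.simulate_genome(cfg)
truth = ls.simulate_truth(cfg)

raw = {}
for cond in cfg.conditions:
    lamin, dam = ls.simulate_damid_counts(cfg, truth, cond, fmap)
    raw[cond] = ls.log2_ratio(ls.CountTrack(lamin, fragment_map=fmap),
                              ls.CountTrack(dam, fragment_map=fmap), condition=cond)
tracks = {t.condition: t for t in ls.quantile_normalize(list(raw.values()))}

segments, lads = {}, {}
for i, cond in enumerate(cfg.conditions):
    segments[cond] = ls.cbs_segment(tracks[cond], seed=[0, i])
    lads[cond] = ls.call_lads(segments[cond], condition=cond)
    print(f"{cond}: {len(lads[cond])} LADs, Jaccard vs planted "
          f"{jaccard(lads[cond], truth.lads_by_condition[cond]):.3f}")

windows = ls.union_windows(segments["WT"], segments["NET29"])
drs = ls.call_drs(windows, ls.window_means(windows, tracks["WT"]),
                  ls.window_means(windows, tracks["NET29"]), lads["WT"], lads["NET29"])
print(drs.groupby("dr_class").size().to_string())

expr = ls.simulate_expression(cfg, truth)
de = ls.call_de(expr["NET29"], expr["WT"])
genes = truth.genes.join(de[["log2fc", "adj_p", "de_call"]])
genes["position_class"] = ls.classify_position(genes, lads["WT"], lads["NET29"], drs)
genes["damid_delta"] = ls.gene_window_delta(genes, tracks["WT"], tracks["NET29"])
res = ls.concordance(genes)
print(f"{res.n_genes} genes repositioned and differentially expressed; "
      f"{100 * res.expected_direction_fraction:.0f}% in the expected direction "
      f"(Fisher p = {res.fisher_p:.2g})")
```

Output:

```
WT: 9 LADs, Jaccard vs planted 0.986
NET29: 9 LADs, Jaccard vs planted 0.990
dr_class
IP    4
PI    4
30 genes repositioned and differentially expressed; 63% in the expected direction (Fisher p = 0.26)
```

The simulated control genome carries 9 planted LADs; all are recovered
with near-exact boundaries (base-pair Jaccard 0.99). All 4 planted
IP and all 4 planted PI regions are called. Of the 30 genes that both
moved and changed expression, 63% moved in the expected direction —
close to the configured 70% coupling rate at this small sample size —
and with only 30 genes the Fisher test is, correctly, not significant.

## Command line

```sh
lad-shift simulate --config sim.json --outdir study/ --seed 3   # synthetic study
lad-shift run --manifest manifest.json --outdir run/            # full pipeline
lad-shift validate --manifest manifest.json                     # check inputs
lad-shift digest --fasta genome.fa --out fragments.bed          # GATC fragment map
lad-shift count --fasta genome.fa --reads reads.bed --out counts.tsv
```

The manifest is a JSON file naming the genome FASTA, per-condition
lamin/Dam-alone read BEDs, gene annotation (BED4+ or GFF3), expression
TSVs, an optional reference fold-change table, and a parameter block
(all thresholds; defaults: smoothing half-window 50 fragments, CBS alpha
0.01 with 1000 permutations, merge gap 5 kb, minimum size 15 kb, ratio
factor 2.0, gene window 100 kb, FDR 0.05, |log2FC| 0.5). Outputs (BED,
bedGraph, TSV) carry the manifest hash; reruns with the same manifest and
seed are byte-identical.

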