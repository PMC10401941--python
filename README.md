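# cernakit

Inference and validation of lncRNA:miRNA **sponge circuits** (competing
endogenous RNA, ceRNA) from comparative Argonaute CLIP occupancy and bulk
RNA-seq derepression data.

A lncRNA that binds a miRNA family can titrate that family away from its
mRNA targets. The biochemical signature of such a circuit is a chain of
comparative observations across genotypes — a wild type, a *sponge-site
point mutant* (`scr`, the lncRNA site scrambled), and a *miRNA-family
knockout* (`ko`):

1. the sponge lncRNA is among the most heavily Argonaute-bound lncRNAs,
   with a dominant binding peak containing a canonical seed site;
2. binding at that site collapses in `scr` (sequence-specific) and in `ko`
   (miRNA-dependent), while the rest of the transcript is unchanged;
3. across the transcriptome, the miRNA family's occupancy at mRNA 3'UTR
   seed sites *rises* in `scr` (the freed miRNA redistributes) and
   *vanishes* in `ko`;
4. target-gene expression falls in `scr` and rises in `ko`, reciprocally,
   while unrelated miRNA families are untouched.

cernakit implements every statistical stage of that chain as a reusable
library, plus a synthetic-data generator that plants a known circuit so
each stage is verifiable by parameter recovery.

## The statistics at the core

* **Annotation occupancy and ranking** — CLIP reads integrated per
  annotation (with optional repeat masking by interval subtraction),
  ranked within feature class; percentile over annotations with >0 reads.
* **Peak calling** — read starts binned (30 nt default), a zero-truncated
  negative binomial fit to positive bin counts by bounded ML (robust
  bulk fit), upper-tail p per bin, Benjamini–Hochberg across bins,
  adjacent significant bins merged.
* **Seed-site occupancy fraction** — for site *i* in 3'UTR *u*,
  `f_i = reads(site_i) / reads(u)`, a library-size-free per-site binding
  share. Genotypes are compared by a paired t test on
  `logit(f)` (ε-clamped), with percent changes reported on the raw
  fraction scale; control miRNA families run the identical chain as a
  specificity screen (BH across families).
* **Canonical seed matching** — 8mer / 7mer-m8 / 7mer-A1 / 6mer site
  classes from the 7-nt seed (miRNA positions 2–8), best class per locus.
* **Expression validation** — mean-CPM filter (≥ 2), median-of-ratios
  size factors, pseudocount log2 fold changes, Welch t on log2 normalized
  counts with BH; two-sample Kolmogorov–Smirnov target-vs-background ECDF
  shift per contrast; sign-concordance Venn over the target set;
  threshold gene sets (log2FC > 1.5, padj < 0.001); hierarchical
  clustering of samples on z-scored gene-set expression (Euclidean,
  complete linkage); `2^-ΔCt` qPCR quantification.

## Worked example

```bash
python examples/seed_site_shift.py
```

```
supported sites: 200 in 200 genes
WT -> scr: mean site share of UTR binding 38.3% -> 45.9% (+19.8%), paired t = 8.62, p = 2.1e-15
WT -> ko: mean site share of UTR binding 38.3% -> 5.8% (-84.8%), paired t = -22.34, p = 3.8e-56

family screen (BH-adjusted p, WT vs scr):
 * miR-15/16    n=200  padj=1.03e-14
   miR-101      n=100  padj=0.736
   let-7        n=100  padj=0.736
   miR-21       n=100  padj=0.736
   miR-142-3p   n=100  padj=0.736
```

Reading: at the 200 supported miR-15/16 sites, the average share of each
3'UTR's Argonaute binding rises from 38.3% to 45.9% when the sponge site
is mutated — the freed miRNA redistributes onto its mRNA targets — and
collapses to 5.8% when the family is knocked out. Only the focal family
moves; the four control families are null, so the effect is
sequence-specific to the sponge site.

The other `examples/*.py` scripts cover fixture generation, occupancy
ranking + peak calling, target-set derepression (KS/Venn), and
costimulation gene-set clustering. The whole chain runs from one config:

```bash
cernakit all --outdir out --seed 1          # writes out/report.json
cernakit simulate --outdir fixture --seed 1 # just the synthetic fixture
```

Reports are byte-identical for identical (config, seed).

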