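# Methods

cernakit tests a single biological hypothesis — that a lncRNA acts as a
sequence-specific sponge for one miRNA family — by chaining four
statistical stages over three genotypes (wild type `WT`, sponge-site
mutant `scr`, miRNA-family knockout `ko`, plus the knockout's floxed
control `fl` on the expression side). This note documents the models,
the tunable parameters, the synthetic-data generator, and the numerical
choices, in that order.

## 1. Occupancy integration and ranking

CLIP reads are intervals (BED6); annotations are classed features (GFF3).
All coordinates are 0-based half-open internally; GFF3 converts at the
I/O boundary and the conversion is its own inverse on round trip.

For each annotation, total occupancy is the number of reads overlapping
the annotation by at least `min_overlap` nt (default 1), after optional
masking: confounder intervals (e.g. rRNA repeats) are subtracted from the
annotation and a read counts if it overlaps any surviving piece (once per
annotation). A read overlapping two annotations counts toward both — no
fractional assignment. Strand is ignored by default (a `same_strand` flag
exists).

Within a feature class, annotations are ranked by total reads
descending, ties broken lexicographically by id so ranks are a
deterministic permutation. Percentiles are computed only over
annotations with more than zero reads:
`percentile = 100·(1 − (rank−1)/n_nonzero)`. Class-to-class comparisons
(e.g. "the median 3'UTR vs the median lncRNA") use medians over the
same >0-read restriction; `class_median_ratio(A, B)` returns
`median(B)/median(A)`.

## 2. Peak calling (zero-truncated negative binomial bins)

Regions (annotation intervals) are tiled into fixed bins (default 30 nt,
the read-length scale; last bin truncated) and **read starts** are
counted per bin. A zero-truncated negative binomial (ZTNB) is fit to the
positive bin counts pooled across regions; each positive bin gets an
upper-tail p-value `P(X ≥ c | X > 0)` under the fit, BH adjustment is
applied across those bins, bins with adjusted p ≤ α (default 0.05)
become significant, and adjacent significant bins merge into one peak.
Peak read counts are recomputed by overlap on the merged interval;
density is reads per nt; peaks are ranked among a reference peak set by
density with the same percentile formula as above.

Numerical choices, made after direct experimentation:

* **Bulk fit.** The ZTNB likelihood on *all* positive bins is maximized,
  on realistically contaminated data, by a degenerate heavy-tail limit
  (mean → 0, dispersion → ∞; effectively a log-series distribution) that
  absorbs true binding-site spikes into the "background" and destroys
  sensitivity. The background model is therefore fit on the bulk of the
  positive counts: bins above the 95th percentile of positive counts are
  excluded from the fit (only from the fit — they are still tested).
  `trim_quantile=1` restores the unrestricted MLE. Null calibration is
  unaffected (≈0.4% of pure-background bins called at α = 0.05).
* **Optimizer.** L-BFGS-B on (log mean, log dispersion) with box bounds
  (mean ∈ [1e−6, 1e6], dispersion ∈ [1e−8, 1e4]) keeping the search off
  the Poisson (k → 0) and heavy-tail walls; tolerance 1e−8, max 500
  iterations; moments initialization. On optimizer failure the model
  falls back to (truncation-unadjusted) method-of-moments with a logged
  warning.
* Zero bins are untestable under a zero-truncated model and can never be
  peaks; BH is applied across positive bins only, which makes the
  "fraction of all bins called ≤ α" property hold a fortiori.

Covariate regression (expression-corrected peak calling) is deliberately
not implemented; peak *counts* from this simplified caller are therefore
not comparable to covariate-aware callers and are never interpreted as
such.

## 3. The seed-site occupancy fraction

Canonical sites of a family with seed `s₂…s₈` (miRNA positions 2–8) are,
on the mRNA: 7mer-m8 = revcomp(s₂…s₈), 8mer = 7mer-m8 + A, 7mer-A1 =
revcomp(s₂…s₇) + A, 6mer = revcomp(s₂…s₇). Every locus containing the
6mer core is reported once with its strongest class
(8mer > 7mer-m8 > 7mer-A1 > 6mer). T and U are equivalent on input.

A predicted site is **supported** for a genotype pair if at least one
read overlaps it by the full site (min_overlap 8 nt, capped at the site
length for 6/7-nt sites) in *both* genotypes. The 8-nt requirement
avoids 1-nt grazing overlaps inflating support and is exposed as a flag.

For each supported site, the **occupancy fraction** is
`f = reads(site) / reads(UTR)` — the site's share of its 3'UTR's total
Argonaute binding. Because numerator and denominator come from the same
library, the fraction is library-size free (duplicating every read
changes nothing), which is what makes cross-genotype comparison valid
without depth normalization. Sites in a zero-read UTR are flagged
undefined and excluded from testing with a logged count.

Fractions are compared between genotypes by a **paired t test on logit
fractions**, `logit(f) = ln(f′/(1−f′))` with `f′` clamped to
[ε, 1−ε], ε = 1e−3 (so fractions of exactly 0 or 1 stay in the test).
Summary means and the reported percent change are on the raw fraction
scale. Degenerate difference vectors are resolved by convention: all
differences zero → p = 1; constant nonzero difference → p = 0. Multiple
sites in one UTR are independent pairs (sites are counted distinctly
from genes throughout).

The **control screen** runs the identical supported-sites → fractions →
paired-test chain for every configured family and BH-adjusts across
families; families with fewer than two testable sites are flagged
untestable and excluded from the adjustment.

## 4. Expression validation

The differential-expression stack is deliberately compact and fully
specified here: mean-CPM filter (gene kept iff mean CPM across all
samples ≥ 2; boundary inclusive), median-of-ratios size factors
(reference = genes nonzero in every sample), fold changes
`log2[(mean_A + 0.5)/(mean_B + 0.5)]` on normalized counts (the
pseudocount keeps zero-mean groups finite; "A_vs_B > 0" always means
higher in A), Welch t per gene on `log2(normalized + 0.5)`, BH
adjustment. It is not a negative-binomial Wald engine and makes no
dispersion-shrinkage claims; the set-level quantities consumed
downstream (fold-change signs, ECDF shifts, threshold memberships) are
robust to this substitution, which is the reason it is acceptable here.

Set-level statistics:

* **ECDF shift** — two-sample KS (asymptotic p) on log2 fold changes,
  target set vs all other tested genes (the background definition is a
  flag); direction = sign of the median difference.
* **Concordance Venn** — each target gene is classified by
  `lfc(WT vs scr) > 0` (down in the sponge mutant) and
  `lfc(fl vs ko) < 0` (up in the knockout), strict inequalities; the
  four cells partition the target set; targets missing from either DE
  table are reported and excluded from the denominator.
* **Threshold gene set** — genes with log2FC > 1.5 and padj < 0.001
  (both strict) in a stimulation contrast; thresholds recorded in the
  set's provenance.
* **Sample clustering** — genes of a set are z-scored across samples;
  samples are clustered on Euclidean distance with complete linkage (the
  classic heatmap default); constant genes are dropped with a warning;
  scipy's agglomeration is deterministic for a fixed column order, which
  the pipeline fixes. Flat labels come from cutting at a requested k.
* **qPCR** — relative expression `2^−(Ct_target − Ct_reference)`;
  technical duplicates are averaged before the subtraction.

## 5. The synthetic-data generator

The generator is first-class, tested code: it builds the complete study
so that every stage above has a planted ground truth.

**Transcriptome.** One contig carries `n_mrna` genes (500 nt CDS + a
3'UTR of 200–500 nt) and `n_lncrna` lncRNAs (1–3 kb), non-overlapping
with 200 nt gaps. One lncRNA is the sponge and carries exactly one
focal-family 8mer; `n_target_genes` UTRs carry one focal 8mer each;
control families get 8mers scattered over randomly chosen UTRs. All
remaining sequence is rejection-sampled against the 6mer cores of every
configured family (every canonical site class contains the core, so a
core-free sequence is site-free), and each finished sequence is verified
by exhaustive re-scan: the emitted site table *is* the complete site
truth. Impossible placements raise an error naming the gene.

**CLIP reads.** Background reads (fixed 30 nt, recorded as intervals)
start uniformly within each transcript at `background_rate` per kb;
site reads start uniformly in `[site_start − 30 + 8, site_start]` so
each fully covers the 8mer, with Poisson means per genotype: WT =
`site_enrichment_wt` (sponge: `sponge_site_strength`); scr =
WT × `scr_gain` at mRNA focal sites and 0 at the sponge site; ko =
WT × `ko_loss` at all focal sites; control families identical across
genotypes.

**Counts.** Gene base means are log-normal (log-mean 5, sigma 1);
target genes are multiplied by `2^−de_effect_scr` in scr samples and
`2^+de_effect_ko` in ko samples; module genes by `2^module_effect`
under costimulation (optionally attenuated per genotype); per-sample
depth factors are log-normal (sigma 0.15); counts are negative binomial
with dispersion `nb_dispersion` (variance μ + kμ²).

**Determinism.** Every stage draws from an independent generator derived
from the master seed via SHA-256 of a (stage, genotype) label used as a
`SeedSequence` spawn key — adding a genotype or stage never perturbs the
draws of another. All outputs are pure functions of (config, seed); the
written fixture round-trips losslessly and rewrites byte-identically.

**Default study conditions** (chosen once, for the reasons given):

| parameter | default | why |
|---|---|---|
| n_mrna / n_lncrna | 2000 / 20 | targets must be a minority (~10%) or median-of-ratios normalization would absorb the planted effect; matches a few-hundred-targets-among-all-genes regime |
| n_target_genes | 200 | a few-hundred-site supported set, the scale at which the paired test operates |
| utr_len_range | 200–500 nt | typical 3'UTR scale, room for sites |
| background_rate | 50 reads/kb | gives each UTR ~10–25 background reads so fractions are informative but noisy |
| site_enrichment_wt | 10 reads | a visible but not overwhelming per-site pileup |
| sponge_site_strength | 500 reads | the sponge site is the dominant lncRNA peak by construction; it must dwarf background fluctuations on 1–3 kb transcripts |
| scr_gain / ko_loss | 1.5 / 0.0 | redistribution gain in the mutant; complete family loss in the knockout |
| de_effect_scr / de_effect_ko | 0.5 / 0.5 | half-log2 target repression/derepression, a realistic miRNA-scale effect |
| module_size / module_effect | 40 / 2.0 | the costimulation set is *defined* by log2FC > 1.5, so the planted effect must exceed that threshold |
| nb_dispersion | 0.05 | bulk-RNA-seq-like overdispersion |
| n_replicates | 6 | per genotype × stimulation |

**What the generator does not emulate** — and hence what passing
recovery tests do and do not show: no raw sequencing reads or alignment
error (reads are intervals), no crosslink-induced deletions or UMI
structure, no multi-site UTR clustering of real TargetScan predictions,
no expression-coupled CLIP coverage (background is uniform per
transcript, whereas real Ago2 coverage tracks expression), no repeat
families or rRNA contamination (the mask machinery is exercised on
synthetic masks), no batch effects. Recovery on this fixture
demonstrates that the *statistics* are implemented correctly and are
calibrated; it does not certify performance on real CLIP libraries.

## 6. Pipeline and discovery logic

`run_pipeline` executes data → CLIP → seed statistic → expression and
writes per-stage TSV/BED files plus one `report.json` (sorted keys) that
is byte-identical across reruns of the same (config, seed). The sponge
candidate is *discovered*, not read from truth: the top-ranked lncRNA's
largest peak is scanned for canonical sites of the configured families,
and the family whose site lies inside the peak is nominated focal; the
supported-site gene set defines the expression-side target list. Stage
failures abort with the stage name and a stage-specific exit code.

## 7. Problem sizes used by the verification studies

The test suite verifies the stack at sizes chosen to make each property
measurable with comfortable margins: counting primitives against
per-base oracles on 100 randomized instances each; type-I error of the
paired occupancy test over 400 re-simulated read sets (binomial 99% CI
around 5%); power and control-family specificity over 100 runs at the
default conditions; DE false-discovery calibration over 200 null count
matrices of 2000 genes; peak-caller null calibration over 200 background
regions; expression-circuit recovery and clustering recovery at the
default conditions (10 seeds for clustering). These sizes are the
package's verification design, and the margins observed are wide
(e.g. power 100/100 at the defaults).

## 8. Known limitations

* The peak caller has no covariate model; its peak counts are not
  comparable to covariate-aware callers on real data.
* The DE stack is a Welch-t substitute, adequate for signs and set-level
  statistics, not for per-gene inference at small fold changes.
* Site discovery is canonical-seed only (no 3'-compensatory or centered
  sites, no context scoring, no conservation filtering).
* The paired occupancy test treats sites as independent; sites sharing a
  UTR share a denominator, a dependence the synthetic fixture mostly
  avoids (one focal site per UTR) but real data would not.
* BAM/CRAM input is out of scope; convert to BED upstream.
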