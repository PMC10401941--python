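"""Expression-side validation: target-set ECDF shifts and concordance.

If the sponge keeps the miRNA away from its mRNA targets, mutating the
sponge site should *repress* targets (more free miRNA) while knocking the
miRNA family out should *derepress* them.  Both predictions are tested on
the log2 fold-change distributions of the bound-target gene set against
all other expressed genes (two-sample KS), then cross-tabulated gene by
gene (concordance Venn).
"""

from cernakit import (
    SimConfig,
    concordance_venn,
    cpm_filter,
    default_design,
    differential_expression,
    ecdf_shift_test,
    generate_counts,
    generate_transcriptome,
    size_factors_median_of_ratios,
)

config = SimConfig(seed=1)
txome, _, truth = generate_transcriptome(config)
cm, _ = generate_counts(txome, truth, default_design(config), config)

cmf = cpm_filter(cm)  # drop genes below 2 mean CPM
sf = size_factors_median_of_ratios(cmf.counts)
st = "aCD3aCD28"
de_scr = differential_expression(
    cmf,
    cmf.sample_ids(genotype="WT", stimulation=st),
    cmf.sample_ids(genotype="scr", stimulation=st),
    label="WT_vs_scr",
    size_factors=sf,
)
de_ko = differential_expression(
    cmf,
    cmf.sample_ids(genotype="fl", stimulation=st),
    cmf.sample_ids(genotype="ko", stimulation=st),
    label="fl_vs_ko",
    size_factors=sf,
)

targets = truth.target_gene_ids
for label, de, expect in (("WT vs scr", de_scr, "targets lower in scr"),
                          ("fl vs ko", de_ko, "targets higher in ko")):
    ks = ecdf_shift_test(de, targets)
    arrow = "+" if ks.direction > 0 else "-"
    print(f"{label}: KS D = {ks.statistic:.3f}, p = {ks.p_value:.2g}, "
          f"target shift direction {arrow} ({expect})")

venn = concordance_venn(de_scr, de_ko, targets)
pct = venn.percentages()
print(f"\nof {venn.n_targets} bound targets: "
      f"{venn.n_down_in_scr} down in scr ({pct['down_in_scr']:.0f}%), "
      f"{venn.n_up_in_ko} up in ko ({pct['up_in_ko']:.0f}%), "
      f"{venn.n_both} both ({pct['both']:.0f}%), union {pct['union']:.0f}%")
# A large 'both' cell is the gene-level signature of one miRNA family
# driving reciprocal expression changes in the two genotypes.
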