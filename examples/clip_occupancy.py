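"""Rank Argonaute CLIP occupancy across annotations and call binding peaks.

Integrates wild-type CLIP reads over lncRNA and 3'UTR annotations, ranks
lncRNAs by total occupancy, calls peaks with the zero-truncated
negative-binomial bin model, and measures how the sponge's site-level
binding collapses in the sponge-mutant (scr) genotype.
"""

from cernakit import (
    SimConfig,
    annotation_read_totals,
    call_peaks,
    class_median_ratio,
    generate_clip_reads,
    generate_transcriptome,
    rank_by_occupancy,
    site_coverage_fold_change,
)
from cernakit.intervals import GenomicInterval
from cernakit.occupancy import peak_density_percentiles

config = SimConfig(seed=1)
txome, sequences, truth = generate_transcriptome(config)
reads = {g: generate_clip_reads(txome, truth, g, config) for g in ("WT", "scr", "ko")}

totals = annotation_read_totals(reads["WT"], txome)
ranked = rank_by_occupancy(totals, "lncRNA")
top = ranked.iloc[0]
print(f"top-occupied lncRNA: {top.annotation_id} "
      f"({top.total_reads} reads; planted sponge is {truth.sponge_id})")
ratio = class_median_ratio(totals, "lncRNA", "three_prime_UTR")
print(f"median 3'UTR has {ratio:.2f}x the reads of the median lncRNA")

lnc_peaks, model, _ = call_peaks(reads["WT"], txome.by_class("lncRNA"))
utr_peaks, _, _ = call_peaks(reads["WT"], txome.by_class("three_prime_UTR"))
print(f"background model: mean {model.mean:.2f}, dispersion {model.dispersion:.2g} "
      f"({model.method}); {len(lnc_peaks)} lncRNA peaks, {len(utr_peaks)} UTR peaks")

sponge_peaks = [p for p in lnc_peaks if p.region_id == truth.sponge_id]
top_peak = max(sponge_peaks, key=lambda p: p.density)
pct = peak_density_percentiles([top_peak], utr_peaks)
print(f"sponge top peak: {top_peak.reads_in_peak} reads, density "
      f"{top_peak.density:.1f}/nt -> {pct.loc[0, 'density_percentile']:.1f}th "
      f"percentile among UTR peaks")

# site-level genotype comparison, normalized within the sponge transcript
srow = truth.sites[truth.sites.gene_id == truth.sponge_id].iloc[0]
site = GenomicInterval(srow.contig, int(srow.start), int(srow.end))
sponge_iv = txome.get("lncRNA", truth.sponge_id).interval
for genotype in ("scr", "ko"):
    fc = site_coverage_fold_change(site, reads[genotype], reads["WT"], sponge_iv)
    print(f"sponge-site occupancy fold change {genotype}/WT: {fc.value:.3f}"
          f"{' (site reads = 0)' if fc.value == 0 else ''}")
# A fold change near 0 in scr reproduces the hallmark of a sequence-specific
# sponge site: binding lost only where the site was mutated.
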