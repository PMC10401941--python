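"""Generate a small synthetic sponge-circuit fixture and inspect its truth.

Builds a transcriptome where one lncRNA ("the sponge") carries a single
miR-15/16 8mer site, 50 mRNA 3'UTRs carry planted target sites, and
genotype-specific CLIP read sets plus RNA-seq counts embed the circuit
effects.  Files are written as GFF3/FASTA/BED/TSV so every downstream
stage can be run from disk.
"""

import tempfile
from pathlib import Path

from cernakit import SimConfig, simulate_all, write_fixture

config = SimConfig(
    n_mrna=250,
    n_lncrna=8,
    n_target_genes=50,
    sites_per_control_family=25,
    module_size=12,
    seed=1,
)
txome, sequences, readsets, counts, truth = simulate_all(config)

outdir = Path(tempfile.mkdtemp(prefix="cernakit_fixture_"))
manifest = write_fixture(txome, sequences, readsets, counts, truth, outdir, config)

print(f"fixture written to {outdir}")
print(f"sponge lncRNA: {truth.sponge_id}; focal family: {truth.focal_family}")
print(f"planted sites: {len(truth.sites)} "
      f"({sum(truth.sites.family_id == truth.focal_family)} focal)")
for genotype, rs in readsets.items():
    print(f"  {genotype:>3} CLIP reads: {rs.total_reads}")
print(f"count matrix: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")
# The scr genotype loses the sponge site but gains occupancy at mRNA target
# sites; the ko genotype loses all focal-family site reads.
sponge_site = truth.sites[truth.sites.gene_id == truth.sponge_id].iloc[0]
print("planted sponge-site mean reads by genotype:",
      truth.site_enrichment[sponge_site.site_id])
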