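"""Run every stage from one config and print the assembled circuit report.

Equivalent to ``cernakit all --outdir <dir> --seed 1`` on the command
line: simulate -> CLIP occupancy -> seed statistic -> expression ->
report.json, fully determined by (config, seed).
"""

import tempfile

from cernakit import PipelineConfig, SimConfig, run_pipeline

with tempfile.TemporaryDirectory(prefix="cernakit_pipeline_") as outdir:
    config = PipelineConfig(outdir=outdir, seed=1, simulate=SimConfig())
    report = run_pipeline(config)

occ, seed_stats, expr = (
    report["occupancy"], report["seed_stats"], report["expression"],
)
print(f"top lncRNA by occupancy: {occ['top_lncrna']} "
      f"(planted sponge rank {occ['truth_sponge_rank']})")
site = occ["sponge_site"]
print(f"nominated focal family: {site['family']} ({site['match_type']} site in "
      f"the top peak; WT peak called: {site['peak_called_wt']}, "
      f"ko: {site['peak_called_ko']})")
scr = seed_stats["wt_vs_scr"]
print(f"site occupancy WT -> scr: {100 * scr['mean_fraction_a']:.1f}% -> "
      f"{100 * scr['mean_fraction_b']:.1f}% of UTR binding "
      f"(p = {scr['p_value']:.2g} over {scr['n_sites']} sites)")
print(f"expression: KS p {expr['ks_wt_vs_scr']['p_value']:.2g} (targets down in "
      f"scr), {expr['ks_fl_vs_ko']['p_value']:.2g} (targets up in ko); "
      f"{expr['venn']['percentages']['both']:.0f}% of targets concordant in both")
print(f"costim set: {expr['costim_set_size']} genes; cluster split at k=2 "
      f"follows stimulation: see report['expression']['clustering']")
# Together these four lines are the circuit evidence chain: a dominant,
# genotype-specific sponge site; redistribution of miRNA binding; reciprocal
# target expression shifts; and a costimulation program downstream.
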