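"""End-to-end orchestration: CLIP occupancy -> seed statistic -> expression.

A single :class:`PipelineConfig` (optionally loaded from YAML) drives every
stage with one master seed; outputs are per-stage TSV/BED files plus one
machine-readable ``report.json`` whose content is a pure function of
(config, seed) — rerunning a config byte-identically reproduces it.

The discovery logic mirrors the comparative study design: the top-occupied
lncRNA is the sponge candidate; its largest binding peak is scanned for
canonical seed sites to nominate the focal miRNA family; site-level binding
shifts, target-set expression shifts, concordance and gene-set clustering
then assemble the circuit evidence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    CountMatrix,
    ClusterResult,
    cluster_samples,
    concordance_venn,
    cpm_filter,
    differential_expression,
    ecdf_shift_test,
    linkage_to_newick,
    size_factors_median_of_ratios,
    threshold_gene_set,
)
from .intervals import AnnotationSet, GenomicInterval, ReadSet
from .io import (
    read_bed_readset,
    read_counts_tsv,
    read_fasta,
    read_gff,
    read_sample_table,
    write_bed,
    write_tsv,
)
from .occupancy import (
    annotation_read_totals,
    call_peaks,
    class_median_ratio,
    peak_density_percentiles,
    peaks_to_bed_rows,
    rank_by_occupancy,
    site_coverage_fold_change,
)
from .seeds import (
    SeedFamily,
    build_site_table,
    control_family_screen,
    find_seed_sites,
    paired_occupancy_test,
    site_occupancy_fractions,
    supported_sites,
)
from .simulate import (
    GENOTYPES_CLIP,
    SimConfig,
    default_design,
    generate_clip_reads,
    generate_counts,
    generate_transcriptome,
    write_fixture,
)

logger = logging.getLogger(__name__)

STAGE_EXIT_CODES = {
    "config": 2,
    "data": 3,
    "clip": 4,
    "seed": 5,
    "expression": 6,
    "report": 7,
}

REQUIRED_INPUT_KEYS = (
    "annotations",
    "sequences",
    "reads_WT",
    "reads_scr",
    "reads_ko",
    "counts",
    "samples",
    "families",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class PipelineConfig:
    """One structured config for the whole analysis.

    Exactly one of ``simulate`` (a :class:`SimConfig`) or ``inputs`` (a
    mapping of input-file paths) must be given.
    """

    outdir: str
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict[str, str] | None = None
    bin_size: int = 30
    alpha: float = 0.05
    epsilon: float = 1e-3
    min_overlap_site: int = 8
    min_mean_cpm: float = 2.0
    lfc_min: float = 1.5
    padj_max: float = 0.001
    pseudocount: float = 0.5
    k_clusters: int = 2
    occupancy_pair: tuple[str, str] = ("WT", "scr")
    ko_genotype: str = "ko"
    expression_stimulation: str = "aCD3aCD28"
    stim_contrast_genotype: str = "WT"
    cluster_genotypes: tuple[str, ...] = ("WT", "scr")

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise PipelineError(
                "config", "exactly one of 'simulate' or 'inputs' must be set"
            )
        if self.inputs is not None:
            for key in REQUIRED_INPUT_KEYS:
                if key not in self.inputs:
                    raise PipelineError("config", f"missing input path field {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise PipelineError(
                        "config", f"input path for {key!r} does not exist: {self.inputs[key]}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "utr_len_range" in sim:
                sim["utr_len_range"] = tuple(sim["utr_len_range"])
            if "lnc_len_range" in sim:
                sim["lnc_len_range"] = tuple(sim["lnc_len_range"])
            sim = SimConfig(**sim)
        for key in ("occupancy_pair", "cluster_genotypes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)

    def to_canonical_json(self) -> str:
        d: dict[str, Any] = dataclasses.asdict(self)
        d.pop("outdir", None)  # a location, not an analysis parameter
        return json.dumps(d, sort_keys=True, default=str)


@dataclass
class PipelineData:
    txome: AnnotationSet
    sequences: dict[str, str]
    readsets: dict[str, ReadSet]
    counts: CountMatrix
    families: list[SeedFamily]
    truth_sponge_id: str | None = None
    truth_focal_family: str | None = None


def load_or_simulate(config: PipelineConfig) -> PipelineData:
    """Stage "data": simulate the fixture (and write it) or load real inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            txome, sequences, truth = generate_transcriptome(sim)
            readsets = {
                g: generate_clip_reads(txome, truth, g, sim) for g in GENOTYPES_CLIP
            }
            cm, truth = generate_counts(txome, truth, default_design(sim), sim)
            write_fixture(
                txome, sequences, readsets, cm, truth, outdir / "fixture", sim
            )
            return PipelineData(
                txome=txome,
                sequences=sequences,
                readsets=readsets,
                counts=cm,
                families=truth.families,
                truth_sponge_id=truth.sponge_id,
                truth_focal_family=truth.focal_family,
            )
        inputs = config.inputs or {}
        txome = read_gff(inputs["annotations"])
        sequences = read_fasta(inputs["sequences"])
        readsets = {
            g: read_bed_readset(inputs[f"reads_{g}"], genotype=g)
            for g in GENOTYPES_CLIP
        }
        counts = read_counts_tsv(inputs["counts"])
        samples = read_sample_table(inputs["samples"])
        fam_df = pd.read_csv(inputs["families"], sep="\t", dtype=str)
        families = [
            SeedFamily(r.family_id, r.seed7) for r in fam_df.itertuples(index=False)
        ]
        return PipelineData(
            txome=txome,
            sequences=sequences,
            readsets=readsets,
            counts=CountMatrix(counts, samples),
            families=families,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("data", str(exc)) from exc


def stage_clip(config: PipelineConfig, data: PipelineData) -> dict:
    """Occupancy integration, lncRNA ranking, peak calling, sponge-site shifts."""
    outdir = Path(config.outdir)
    try:
        wt = data.readsets[config.occupancy_pair[0]]
        mut = data.readsets[config.occupancy_pair[1]]
        ko = data.readsets[config.ko_genotype]

        totals = annotation_read_totals(wt, data.txome)
        write_tsv(totals, outdir / "occupancy_totals_WT.tsv")
        ranked = rank_by_occupancy(totals, "lncRNA")
        write_tsv(ranked, outdir / "lncrna_ranking_WT.tsv")
        top_lncrna = str(ranked.iloc[0]["annotation_id"])
        sponge_rank = None
        if data.truth_sponge_id is not None:
            row = ranked[ranked["annotation_id"] == data.truth_sponge_id]
            sponge_rank = int(row["rank_within_class"].iloc[0]) if len(row) else None
        median_ratio = class_median_ratio(totals, "lncRNA", "three_prime_UTR")

        lnc_regions = data.txome.by_class("lncRNA")
        utr_regions = data.txome.by_class("three_prime_UTR")
        lnc_peaks, model, _ = call_peaks(
            wt, lnc_regions, bin_size=config.bin_size, alpha=config.alpha
        )
        utr_peaks, _, _ = call_peaks(
            wt, utr_regions, bin_size=config.bin_size, alpha=config.alpha
        )
        write_bed(peaks_to_bed_rows(lnc_peaks + utr_peaks), outdir / "peaks_WT.bed")

        sponge = data.txome.get("lncRNA", top_lncrna)
        sponge_peaks = [p for p in lnc_peaks if p.region_id == top_lncrna]
        report: dict[str, Any] = {
            "top_lncrna": top_lncrna,
            "truth_sponge_rank": sponge_rank,
            "lncrna_to_utr_median_ratio": float(median_ratio),
            "n_lncrna_peaks": len(lnc_peaks),
            "n_utr_peaks": len(utr_peaks),
            "background_model": {
                "mean": model.mean,
                "dispersion": model.dispersion,
                "method": model.method,
            },
        }
        if not sponge_peaks:
            report["sponge_top_peak"] = None
            report["sponge_site"] = None
            return report

        top_peak = max(sponge_peaks, key=lambda p: p.density)
        pct = peak_density_percentiles([top_peak], utr_peaks) if utr_peaks else None
        report["sponge_top_peak"] = {
            "interval": [top_peak.interval.start, top_peak.interval.end],
            "reads": top_peak.reads_in_peak,
            "density": top_peak.density,
            "density_percentile_vs_utr_peaks": (
                float(pct["density_percentile"].iloc[0]) if pct is not None else None
            ),
        }

        # nominate the focal family: a canonical seed site overlapping the top
        # peak (a site may straddle a bin boundary, so containment is too
        # strict)
        seq = data.sequences.get(top_lncrna)
        site_hit = None
        if seq is not None:
            for fam in data.families:
                for s, e, mtype in find_seed_sites(seq, fam):
                    gs, ge = sponge.interval.start + s, sponge.interval.start + e
                    if gs < top_peak.interval.end and ge > top_peak.interval.start:
                        site_hit = (fam, gs, ge, mtype)
                        break
                if site_hit:
                    break
        if site_hit is None:
            report["sponge_site"] = None
            return report
        fam, gs, ge, mtype = site_hit
        site_iv = GenomicInterval(sponge.interval.contig, gs, ge, name="sponge_site")
        fc_scr = site_coverage_fold_change(site_iv, mut, wt, sponge.interval)
        fc_ko = site_coverage_fold_change(site_iv, ko, wt, sponge.interval)
        ko_peaks, _, _ = call_peaks(
            ko, lnc_regions, bin_size=config.bin_size, alpha=config.alpha
        )
        covers = lambda p: (  # noqa: E731
            p.region_id == top_lncrna
            and p.interval.start < ge
            and gs < p.interval.end
        )
        report["sponge_site"] = {
            "family": fam.family_id,
            "match_type": mtype,
            "interval": [gs, ge],
            "fold_change_scr_vs_wt": fc_scr.value,
            "fold_change_ko_vs_wt": fc_ko.value,
            "peak_called_wt": any(covers(p) for p in sponge_peaks),
            "peak_called_ko": any(covers(p) for p in ko_peaks),
        }
        return report
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("clip", str(exc)) from exc


def stage_seed(
    config: PipelineConfig, data: PipelineData, focal_family_id: str
) -> tuple[dict, list[str]]:
    """Supported sites, occupancy fractions, paired tests, control screen."""
    outdir = Path(config.outdir)
    try:
        utr_ids = {r.id for r in data.txome.by_class("three_prime_UTR")}
        utr_seqs = {k: v for k, v in data.sequences.items() if k in utr_ids}
        sites = build_site_table(utr_seqs, data.txome, data.families)
        sites_by_family = {
            fid: sub.reset_index(drop=True) for fid, sub in sites.groupby("family_id")
        }
        focal_sites = sites_by_family.get(focal_family_id)
        if focal_sites is None or focal_sites.empty:
            raise ValueError(f"no predicted sites for focal family {focal_family_id!r}")

        pair = config.occupancy_pair
        supported = supported_sites(
            focal_sites, data.readsets, pair, min_overlap=config.min_overlap_site
        )
        write_tsv(supported, outdir / "supported_sites.tsv")
        target_genes = sorted(supported["gene_id"].unique())

        frac = {
            g: site_occupancy_fractions(
                data.readsets[g], supported, data.txome,
                min_overlap=config.min_overlap_site, epsilon=config.epsilon,
            )
            for g in (pair[0], pair[1], config.ko_genotype)
        }
        all_frac = pd.concat(frac.values(), ignore_index=True)
        write_tsv(all_frac, outdir / "occupancy_fractions.tsv")

        def _paired(a: str, b: str) -> dict:
            ra, rb = frac[a], frac[b]
            ok = ra["defined"].to_numpy() & rb["defined"].to_numpy()
            res = paired_occupancy_test(ra.loc[ok], rb.loc[ok], epsilon=config.epsilon)
            return {
                "genotypes": [a, b],
                "n_sites": res.n_sites,
                "mean_fraction_a": res.mean_fraction_a,
                "mean_fraction_b": res.mean_fraction_b,
                "percent_change": res.percent_change,
                "t_statistic": res.t_statistic,
                "p_value": res.p_value,
            }

        screen = control_family_screen(
            data.families,
            data.readsets,
            sites_by_family,
            pair,
            data.txome,
            min_overlap=config.min_overlap_site,
            epsilon=config.epsilon,
        )
        write_tsv(screen, outdir / "family_screen.tsv")
        report = {
            "focal_family": focal_family_id,
            "n_predicted_sites": int(len(focal_sites)),
            "n_supported_sites": int(supported.attrs["n_sites"]),
            "n_supported_genes": int(supported.attrs["n_genes"]),
            "wt_vs_scr": _paired(pair[0], pair[1]),
            "wt_vs_ko": _paired(pair[0], config.ko_genotype),
            "family_screen": json.loads(
                screen.replace({np.nan: None}).to_json(orient="records")
            ),
        }
        return report, target_genes
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("seed", str(exc)) from exc


def stage_expression(
    config: PipelineConfig, data: PipelineData, target_genes: list[str]
) -> dict:
    """CPM filter, DE contrasts, target-set KS, concordance, clustering."""
    outdir = Path(config.outdir)
    try:
        cm = cpm_filter(data.counts, config.min_mean_cpm)
        sf = size_factors_median_of_ratios(cm.counts)
        st = config.expression_stimulation

        de_scr = differential_expression(
            cm,
            cm.sample_ids(genotype=config.occupancy_pair[0], stimulation=st),
            cm.sample_ids(genotype=config.occupancy_pair[1], stimulation=st),
            label="WT_vs_scr",
            pseudocount=config.pseudocount,
            size_factors=sf,
        )
        de_ko = differential_expression(
            cm,
            cm.sample_ids(genotype="fl", stimulation=st),
            cm.sample_ids(genotype=config.ko_genotype, stimulation=st),
            label="fl_vs_ko",
            pseudocount=config.pseudocount,
            size_factors=sf,
        )
        write_tsv(de_scr.reset_index(), outdir / "de_WT_vs_scr.tsv")
        write_tsv(de_ko.reset_index(), outdir / "de_fl_vs_ko.tsv")

        ks_scr = ecdf_shift_test(de_scr, target_genes)
        ks_ko = ecdf_shift_test(de_ko, target_genes)
        venn = concordance_venn(de_scr, de_ko, target_genes)

        g = config.stim_contrast_genotype
        de_stim = differential_expression(
            cm,
            cm.sample_ids(genotype=g, stimulation="aCD3aCD28"),
            cm.sample_ids(genotype=g, stimulation="aCD3"),
            label="aCD3aCD28_vs_aCD3",
            pseudocount=config.pseudocount,
            size_factors=sf,
        )
        write_tsv(de_stim.reset_index(), outdir / "de_stim.tsv")
        costim = threshold_gene_set(
            de_stim, config.lfc_min, config.padj_max, set_id="costim_responsive"
        )
        with open(outdir / "costim_gene_set.txt", "w", newline="\n") as fh:
            for gene in costim.genes:
                fh.write(gene + "\n")

        clustering = None
        if len(costim.genes) >= 2:
            norm = np.log2(cm.counts / sf + config.pseudocount)
            keep_samples = [
                s
                for s in norm.columns
                if cm.samples.set_index("sample_id").loc[s, "genotype"]
                in config.cluster_genotypes
            ]
            cl: ClusterResult = cluster_samples(
                norm[keep_samples], costim.genes, k=config.k_clusters
            )
            write_tsv(
                cl.labels.rename_axis("sample_id").reset_index(),
                outdir / "cluster_labels.tsv",
            )
            with open(outdir / "cluster_tree.nwk", "w", newline="\n") as fh:
                fh.write(linkage_to_newick(cl.linkage, cl.sample_ids) + "\n")
            clustering = {
                "k": config.k_clusters,
                "labels": {s: int(v) for s, v in cl.labels.items()},
                "leaf_order": cl.leaf_order,
                "n_genes_used": len(costim.genes) - len(cl.dropped_genes),
            }

        return {
            "n_genes_tested": int(len(cm.counts)),
            "n_genes_removed_cpm": int(cm.counts.attrs.get("n_removed", 0)),
            "ks_wt_vs_scr": dataclasses.asdict(ks_scr),
            "ks_fl_vs_ko": dataclasses.asdict(ks_ko),
            "venn": {
                "n_targets": venn.n_targets,
                "n_down_in_scr": venn.n_down_in_scr,
                "n_up_in_ko": venn.n_up_in_ko,
                "n_both": venn.n_both,
                "n_neither": venn.n_neither,
                "n_union": venn.n_union,
                "percentages": venn.percentages(),
            },
            "costim_set_size": len(costim.genes),
            "clustering": clustering,
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expression", str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write ``report.json``; returns the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "package": f"cernakit {__version__}",
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.to_canonical_json().encode()
            ).hexdigest(),
        }
    }
    t0 = time.perf_counter()
    data = load_or_simulate(config)
    logger.info("stage data: %.2fs, %d reads (WT)", time.perf_counter() - t0,
                data.readsets["WT"].total_reads)

    t0 = time.perf_counter()
    clip = stage_clip(config, data)
    report["occupancy"] = clip
    logger.info("stage clip: %.2fs", time.perf_counter() - t0)

    focal = None
    if clip.get("sponge_site"):
        focal = clip["sponge_site"]["family"]
    elif data.truth_focal_family:
        focal = data.truth_focal_family
    if focal is None:
        raise PipelineError("seed", "no focal family could be nominated from the data")

    t0 = time.perf_counter()
    seed_report, target_genes = stage_seed(config, data, focal)
    report["seed_stats"] = seed_report
    logger.info("stage seed: %.2fs, %d target genes", time.perf_counter() - t0,
                len(target_genes))

    t0 = time.perf_counter()
    report["expression"] = stage_expression(config, data, target_genes)
    logger.info("stage expression: %.2fs", time.perf_counter() - t0)

    text = json.dumps(report, sort_keys=True, indent=2)
    with open(outdir / "report.json", "w", newline="\n") as fh:
        fh.write(text + "\n")
    return report
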