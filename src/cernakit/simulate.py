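"""Synthetic transcriptome, CLIP read sets and RNA-seq counts with planted truth.

The generator emulates the comparative design of a sponge-circuit study:

* one synthetic contig carrying mRNA genes (each with a 3'UTR) and lncRNAs,
  with one lncRNA designated the *sponge* carrying a single focal-family
  8mer seed site;
* genotype-specific CLIP read sets — wild type (``WT``), a sponge-site
  point mutant (``scr``) that loses the sponge site and gains occupancy at
  the focal family's mRNA sites, and a miRNA-family knockout (``ko``) that
  loses occupancy at all focal sites;
* negative-binomial RNA-seq count matrices with planted target repression/
  derepression and a planted costimulation-responsive gene module.

Every random sequence is rejection-sampled to be free of canonical seed
sites for every configured family, so the planted site table is the exact
ground truth.  All outputs are pure functions of (config, seed): random
streams for each (stage, genotype) are derived from the master seed via a
SHA-256 keyed spawn, so adding a genotype never perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .intervals import Annotation, AnnotationSet, GenomicInterval, ReadSet
from .io import write_bed, write_fasta, write_gff, write_tsv
from .seeds import SITE_COLUMNS, SeedFamily, find_seed_sites

GENOTYPES_CLIP = ("WT", "scr", "ko")
GENOTYPES_RNA = ("WT", "scr", "fl", "ko")
STIMULATIONS = ("aCD3", "aCD3aCD28")

#: Focal family first, then the highly expressed control families screened
#: for specificity (seed = miRNA positions 2-8).
DEFAULT_FAMILIES = (
    ("miR-15/16", "AGCAGCA"),
    ("miR-101", "ACAGUAC"),
    ("let-7", "GAGGUAG"),
    ("miR-21", "AGCUUAU"),
    ("miR-142-3p", "GUAGUGU"),
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic circuit.

    Defaults are the conditions the downstream recovery checks run under:
    a 2000-gene transcriptome in which 10% of genes are focal-family
    targets (200 sites with 10 extra wild-type reads each), a 1.5-fold
    occupancy gain in the sponge mutant, complete loss in the knockout,
    half-log2 planted de/repression of target genes with 6 replicates, and
    a strongly costimulation-responsive 40-gene module.  The minority
    target fraction matters: median-of-ratios normalization assumes most
    genes are unchanged.
    """

    n_mrna: int = 2000
    n_lncrna: int = 20
    utr_len_range: tuple[int, int] = (200, 500)
    n_target_genes: int = 200
    n_families: int = 5
    sponge_site_strength: float = 500.0
    background_rate: float = 50.0  # reads per kb of transcript
    site_enrichment_wt: float = 10.0
    scr_gain: float = 1.5
    ko_loss: float = 0.0
    de_effect_scr: float = 0.5
    de_effect_ko: float = 0.5
    module_size: int = 40
    module_effect: float = 2.0
    nb_dispersion: float = 0.05
    n_replicates: int = 6
    seed: int = 0
    read_length: int = 30
    sites_per_control_family: int = 100
    lnc_len_range: tuple[int, int] = (1000, 3000)
    cds_len: int = 500
    contig: str = "synth1"
    gap: int = 200
    base_mean_log: float = 5.0  # log-scale mean of gene base expression
    base_mean_sigma: float = 1.0
    library_size_sigma: float = 0.15
    module_attenuation: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "n_mrna", "n_lncrna", "n_target_genes", "n_families",
            "module_size", "n_replicates",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.utr_len_range[0] < 30:
            raise ConfigurationError("utr_len_range minimum must be >= 30 nt")
        if self.utr_len_range[0] > self.utr_len_range[1]:
            raise ConfigurationError("utr_len_range must be (min, max) with min <= max")
        if self.scr_gain < 1:
            raise ConfigurationError("scr_gain must be >= 1")
        if not 0 <= self.ko_loss <= 1:
            raise ConfigurationError("ko_loss must be in [0, 1]")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be >= 0")
        if self.sponge_site_strength < 0:
            raise ConfigurationError("sponge_site_strength must be >= 0")
        if self.site_enrichment_wt < 0:
            raise ConfigurationError("site_enrichment_wt must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.n_target_genes > self.n_mrna:
            raise ConfigurationError("n_target_genes cannot exceed n_mrna")
        if self.n_families > 1 and self.sites_per_control_family > self.n_mrna:
            raise ConfigurationError("sites_per_control_family cannot exceed n_mrna")


def rng_for(seed: int, *labels: object) -> np.random.Generator:
    """Independent RNG stream for (seed, labels) via a SHA-256 keyed spawn."""
    digest = hashlib.sha256("|".join(str(x) for x in labels).encode()).digest()
    key = (
        int.from_bytes(digest[:4], "little"),
        int.from_bytes(digest[4:8], "little"),
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def default_families(config: SimConfig) -> list[SeedFamily]:
    fams = [SeedFamily(fid, seed7) for fid, seed7 in DEFAULT_FAMILIES[: config.n_families]]
    if config.n_families > len(DEFAULT_FAMILIES):
        rng = rng_for(config.seed, "families")
        cores = {f.site_core6 for f in fams}
        while len(fams) < config.n_families:
            seed7 = "".join(rng.choice(list("ACGU"), 7))
            fam = SeedFamily(f"ctrl-{len(fams)}", seed7)
            if fam.site_core6 not in cores:
                cores.add(fam.site_core6)
                fams.append(fam)
    return fams


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated circuit, for parameter-recovery checks."""

    sponge_id: str
    focal_family: str
    target_gene_ids: list[str]
    module_gene_ids: list[str]
    families: list[SeedFamily]
    sites: pd.DataFrame  # planted SiteTable (SITE_COLUMNS)
    site_enrichment: dict[str, dict[str, float]]  # site_id -> genotype -> mean reads
    gene_log2fc: dict[str, dict[str, float]]  # contrast -> gene_id -> planted lfc
    overlap_target_module: list[str] = field(default_factory=list)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _scrub(seq: np.ndarray, cores: Sequence[str], rng: np.random.Generator,
           protected: list[tuple[int, int]] | None = None, max_iter: int = 20000) -> np.ndarray:
    """Resample 6-nt windows until no forbidden core remains outside protected spans."""
    protected = protected or []
    s = seq.tobytes().decode()
    for _ in range(max_iter):
        hit = None
        for core in cores:
            pos = s.find(core)
            while pos != -1:
                if not any(ps - 5 <= pos < pe for ps, pe in protected):
                    hit = pos
                    break
                pos = s.find(core, pos + 1)
            if hit is not None:
                break
        if hit is None:
            return np.frombuffer(s.encode(), dtype="S1").copy()
        window = _random_seq(rng, 6)
        s = s[:hit] + window.tobytes().decode() + s[hit + 6:]
    raise ConfigurationError("could not scrub forbidden seed cores from sequence")


def _plant_site(seq_arr: np.ndarray, pos: int, family: SeedFamily) -> np.ndarray:
    """Write the family's 8mer site (7mer-m8 core + A) at ``pos``."""
    site = family.site_core + "A"
    out = seq_arr.copy()
    out[pos : pos + 8] = np.frombuffer(site.encode(), dtype="S1")
    return out


def _build_sequence(
    rng: np.random.Generator,
    length: int,
    families: Sequence[SeedFamily],
    plants: list[tuple[int, SeedFamily]],
    owner: str,
    max_attempts: int = 100,
) -> str:
    """Random sequence of ``length`` whose canonical sites are exactly ``plants``."""
    cores = [f.site_core6 for f in families]
    expected = sorted((pos, pos + 8, "8mer", fam.family_id) for pos, fam in plants)
    for _ in range(max_attempts):
        seq = _random_seq(rng, length)
        seq = _scrub(seq, cores, rng)
        for pos, fam in plants:
            seq = _plant_site(seq, pos, fam)
        s = seq.tobytes().decode()
        found = sorted(
            (st, en, mt, f.family_id)
            for f in families
            for st, en, mt in find_seed_sites(s, f)
        )
        if found == expected:
            return s
    raise ConfigurationError(
        f"could not place requested seed sites in {owner} (length {length})"
    )


def _choose_positions(
    rng: np.random.Generator, length: int, n_sites: int, margin: int = 2
) -> list[int]:
    """Non-overlapping 8mer start positions, >= margin from the ends."""
    lo, hi = margin, length - 8 - margin
    if hi < lo:
        return []
    for _ in range(1000):
        pos = sorted(int(p) for p in rng.integers(lo, hi + 1, size=n_sites))
        if all(b - a >= 10 for a, b in zip(pos, pos[1:])):
            return pos
    return []


def generate_transcriptome(
    config: SimConfig,
) -> tuple[AnnotationSet, dict[str, str], SyntheticTruth]:
    """Lay out the synthetic genome and plant all seed sites.

    Deterministic in (config, seed).  Raises :class:`ConfigurationError`
    naming the offending gene when a requested site cannot be placed.
    """
    rng = rng_for(config.seed, "txome")
    families = default_families(config)
    focal = families[0]
    controls = families[1:]

    # --- layout
    records: list[Annotation] = []
    utr_iv: dict[str, GenomicInterval] = {}
    pos = 0
    gene_ids = [f"gene{i:04d}" for i in range(config.n_mrna)]
    utr_lens = rng.integers(
        config.utr_len_range[0], config.utr_len_range[1] + 1, size=config.n_mrna
    )
    for gid, ulen in zip(gene_ids, utr_lens):
        gstart, gend = pos, pos + config.cds_len + int(ulen)
        records.append(
            Annotation(GenomicInterval(config.contig, gstart, gend, "+", gid), "gene", gid)
        )
        records.append(
            Annotation(
                GenomicInterval(config.contig, gstart, gstart + config.cds_len, "+", f"{gid}.cds"),
                "CDS",
                f"{gid}.cds",
                parent=gid,
            )
        )
        uid = f"{gid}.utr"
        iv = GenomicInterval(config.contig, gstart + config.cds_len, gend, "+", uid)
        records.append(Annotation(iv, "three_prime_UTR", uid, parent=gid))
        utr_iv[uid] = iv
        pos = gend + config.gap

    lnc_ids = [f"lnc{i:03d}" for i in range(config.n_lncrna)]
    lnc_lens = rng.integers(
        config.lnc_len_range[0], config.lnc_len_range[1] + 1, size=config.n_lncrna
    )
    lnc_ivs: dict[str, GenomicInterval] = {}
    for lid, llen in zip(lnc_ids, lnc_lens):
        iv = GenomicInterval(config.contig, pos, pos + int(llen), "+", lid)
        records.append(Annotation(iv, "lncRNA", lid))
        lnc_ivs[lid] = iv
        pos = iv.end + config.gap

    txome = AnnotationSet(records)
    sponge_id = lnc_ids[0]

    # --- roles
    target_idx = sorted(rng.choice(config.n_mrna, config.n_target_genes, replace=False))
    target_genes = [gene_ids[i] for i in target_idx]
    non_target = [g for g in gene_ids if g not in set(target_genes)]
    if config.module_size <= len(non_target):
        module_idx = sorted(rng.choice(len(non_target), config.module_size, replace=False))
        module_genes = [non_target[i] for i in module_idx]
    else:  # unavoidable overlap with targets; recorded in truth
        module_idx = sorted(rng.choice(config.n_mrna, config.module_size, replace=False))
        module_genes = [gene_ids[i] for i in module_idx]
    overlap = sorted(set(target_genes) & set(module_genes))

    # --- site plan: which family sites go in which UTR
    plants_by_utr: dict[str, list[tuple[int, SeedFamily]]] = {u: [] for u in utr_iv}
    plan_counts: dict[str, list[str]] = {u: [] for u in utr_iv}
    for gid in target_genes:
        plan_counts[f"{gid}.utr"].append(focal.family_id)
    fam_by_id = {f.family_id: f for f in families}
    for fam in controls:
        hosts = rng.choice(config.n_mrna, config.sites_per_control_family, replace=False)
        for i in sorted(int(h) for h in hosts):
            plan_counts[f"{gene_ids[i]}.utr"].append(fam.family_id)
    for uid, fam_list in plan_counts.items():
        if not fam_list:
            continue
        length = utr_iv[uid].length
        positions = _choose_positions(rng, length, len(fam_list))
        if len(positions) < len(fam_list):
            raise ConfigurationError(
                f"UTR {uid} (length {length}) too short for {len(fam_list)} seed sites"
            )
        plants_by_utr[uid] = [
            (p, fam_by_id[f]) for p, f in zip(positions, fam_list)
        ]

    # --- sequences
    sequences: dict[str, str] = {}
    site_rows: list[dict] = []
    for uid, iv in utr_iv.items():
        seq = _build_sequence(rng, iv.length, families, plants_by_utr[uid], owner=uid)
        sequences[uid] = seq
        gid = uid[: -len(".utr")]
        for p, fam in plants_by_utr[uid]:
            site_rows.append(
                {
                    "site_id": f"{fam.family_id}|{uid}|{p}",
                    "gene_id": gid,
                    "utr_id": uid,
                    "contig": iv.contig,
                    "start": iv.start + p,
                    "end": iv.start + p + 8,
                    "utr_start": p,
                    "utr_end": p + 8,
                    "family_id": fam.family_id,
                    "match_type": "8mer",
                }
            )
    sponge_site_row: dict | None = None
    for lid, iv in lnc_ivs.items():
        if lid == sponge_id:
            p = int(rng.integers(iv.length // 3, 2 * iv.length // 3))
            seq = _build_sequence(rng, iv.length, families, [(p, focal)], owner=lid)
            sponge_site_row = {
                "site_id": f"{focal.family_id}|{lid}|{p}",
                "gene_id": lid,
                "utr_id": lid,
                "contig": iv.contig,
                "start": iv.start + p,
                "end": iv.start + p + 8,
                "utr_start": p,
                "utr_end": p + 8,
                "family_id": focal.family_id,
                "match_type": "8mer",
            }
        else:
            seq = _build_sequence(rng, iv.length, families, [], owner=lid)
        sequences[lid] = seq
    assert sponge_site_row is not None
    site_rows.append(sponge_site_row)
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)

    # --- planted CLIP enrichment per genotype
    enrichment: dict[str, dict[str, float]] = {}
    for row in sites.itertuples(index=False):
        if row.site_id == sponge_site_row["site_id"]:
            means = {
                "WT": config.sponge_site_strength,
                "scr": 0.0,
                "ko": config.sponge_site_strength * config.ko_loss,
            }
        elif row.family_id == focal.family_id:
            means = {
                "WT": config.site_enrichment_wt,
                "scr": config.site_enrichment_wt * config.scr_gain,
                "ko": config.site_enrichment_wt * config.ko_loss,
            }
        else:
            means = {g: config.site_enrichment_wt for g in GENOTYPES_CLIP}
        enrichment[row.site_id] = means

    # --- planted expression effects
    gene_log2fc = {
        "WT_vs_scr": {g: config.de_effect_scr for g in target_genes},
        "fl_vs_ko": {g: -config.de_effect_ko for g in target_genes},
        "aCD3aCD28_vs_aCD3": {g: config.module_effect for g in module_genes},
    }

    truth = SyntheticTruth(
        sponge_id=sponge_id,
        focal_family=focal.family_id,
        target_gene_ids=target_genes,
        module_gene_ids=module_genes,
        families=families,
        sites=sites,
        site_enrichment=enrichment,
        gene_log2fc=gene_log2fc,
        overlap_target_module=overlap,
    )
    return txome, sequences, truth


def generate_clip_reads(
    txome: AnnotationSet,
    truth: SyntheticTruth,
    genotype: str,
    config: SimConfig,
) -> ReadSet:
    """Genotype-specific CLIP reads: Poisson background + Poisson site pileups.

    Background reads start uniformly within each transcript at
    ``background_rate`` per kb; site reads start uniformly in
    ``[site_start - read_length + 8, site_start]`` so each one covers the
    full 8mer.  Deterministic in (config.seed, genotype).
    """
    if genotype not in GENOTYPES_CLIP:
        raise ValueError(f"unknown genotype {genotype!r}; one of {GENOTYPES_CLIP}")
    rng = rng_for(config.seed, "clip", genotype)
    L = config.read_length
    starts: list[np.ndarray] = []

    transcripts = txome.by_class("gene") + txome.by_class("lncRNA")
    for rec in transcripts:
        iv = rec.interval
        lam = config.background_rate * iv.length / 1000.0
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n:
            hi = max(iv.start + 1, iv.end - L + 1)
            starts.append(rng.integers(iv.start, hi, size=n))

    for row in truth.sites.itertuples(index=False):
        mean = truth.site_enrichment[row.site_id][genotype]
        n = int(rng.poisson(mean)) if mean > 0 else 0
        if n:
            lo = int(row.start) - L + 8
            starts.append(rng.integers(max(lo, 0), int(row.start) + 1, size=n))

    if starts:
        all_starts = np.concatenate(starts)
    else:
        all_starts = np.empty(0, dtype=np.int64)
    return ReadSet.from_arrays(
        config.contig,
        all_starts,
        all_starts + L,
        library_id=f"AHC_{genotype}",
        genotype=genotype,
    )


def default_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for g in GENOTYPES_RNA:
        for st in STIMULATIONS:
            for r in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_{st}_r{r}",
                        "genotype": g,
                        "stimulation": st,
                        "replicate": str(r),
                    }
                )
    return pd.DataFrame(rows)


def generate_counts(
    txome: AnnotationSet,
    truth: SyntheticTruth,
    design: pd.DataFrame,
    config: SimConfig,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial counts with the planted expression effects.

    Gene base means are log-normal; target genes are repressed 2^-de_effect_scr
    in ``scr`` samples and derepressed 2^+de_effect_ko in ``ko`` samples;
    module genes gain 2^module_effect under costimulation (optionally
    attenuated per genotype); per-sample library-size factors are log-normal.
    """
    bad_g = set(design["genotype"]) - set(GENOTYPES_RNA)
    bad_s = set(design["stimulation"]) - set(STIMULATIONS)
    if bad_g:
        raise ValueError(f"unknown genotype labels in design: {sorted(bad_g)}")
    if bad_s:
        raise ValueError(f"unknown stimulation labels in design: {sorted(bad_s)}")
    rng = rng_for(config.seed, "rnaseq")
    genes = [r.id for r in txome.by_class("gene")] + [
        r.id for r in txome.by_class("lncRNA")
    ]
    n_genes = len(genes)
    base = rng.lognormal(config.base_mean_log, config.base_mean_sigma, size=n_genes)
    is_target = np.isin(genes, truth.target_gene_ids)
    is_module = np.isin(genes, truth.module_gene_ids)
    attenuation = dict(config.module_attenuation)
    r_nb = 1.0 / config.nb_dispersion

    counts = np.zeros((n_genes, len(design)), dtype=np.int64)
    for j, sample in enumerate(design.itertuples(index=False)):
        mult = np.ones(n_genes)
        if sample.genotype == "scr":
            mult[is_target] *= 2.0 ** (-config.de_effect_scr)
        elif sample.genotype == "ko":
            mult[is_target] *= 2.0 ** (config.de_effect_ko)
        if sample.stimulation == "aCD3aCD28":
            eff = config.module_effect * attenuation.get(sample.genotype, 1.0)
            mult[is_module] *= 2.0 ** eff
        depth = rng.lognormal(0.0, config.library_size_sigma)
        mu = base * mult * depth
        p_nb = r_nb / (r_nb + mu)
        counts[:, j] = rng.negative_binomial(r_nb, p_nb)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                     columns=design["sample_id"].tolist()),
        design.copy(),
    )
    return cm, truth


def write_fixture(
    txome: AnnotationSet,
    sequences: Mapping[str, str],
    readsets: Mapping[str, ReadSet],
    cm: CountMatrix,
    truth: SyntheticTruth,
    directory: str | Path,
    config: SimConfig,
) -> dict[str, str]:
    """Write the full fixture as plain-text files; returns the manifest.

    Emits GFF3 annotations, FASTA sequences, one BED6 per genotype, counts
    and metadata TSVs, truth TSVs and a flat key=value manifest recording
    the seed, so a rerun reproduces identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    write_gff(txome, directory / "annotations.gff3")
    paths["annotations"] = "annotations.gff3"
    write_fasta(sequences, directory / "sequences.fa")
    paths["sequences"] = "sequences.fa"
    for genotype, rs in readsets.items():
        name = f"reads_{genotype}.bed"
        write_bed(rs, directory / name)
        paths[f"reads_{genotype}"] = name
    write_tsv(cm.counts.reset_index(), directory / "counts.tsv")
    paths["counts"] = "counts.tsv"
    write_tsv(cm.samples, directory / "samples.tsv")
    paths["samples"] = "samples.tsv"

    write_tsv(truth.sites, directory / "truth_sites.tsv")
    paths["truth_sites"] = "truth_sites.tsv"

    rows = []
    rows.append({"gene_id": truth.sponge_id, "role": "sponge",
                 "log2fc_scr": 0.0, "log2fc_ko": 0.0, "log2fc_module": 0.0})
    for g in truth.target_gene_ids:
        rows.append({
            "gene_id": g, "role": "target",
            "log2fc_scr": truth.gene_log2fc["WT_vs_scr"][g],
            "log2fc_ko": truth.gene_log2fc["fl_vs_ko"][g],
            "log2fc_module": truth.gene_log2fc["aCD3aCD28_vs_aCD3"].get(g, 0.0),
        })
    for g in truth.module_gene_ids:
        if g in set(truth.target_gene_ids):
            continue  # already emitted with its module effect above
        rows.append({
            "gene_id": g, "role": "module",
            "log2fc_scr": 0.0, "log2fc_ko": 0.0,
            "log2fc_module": truth.gene_log2fc["aCD3aCD28_vs_aCD3"][g],
        })
    write_tsv(pd.DataFrame(rows), directory / "truth_genes.tsv")
    paths["truth_genes"] = "truth_genes.tsv"

    fam_df = pd.DataFrame(
        [{"family_id": f.family_id, "seed7": f.seed7} for f in truth.families]
    )
    write_tsv(fam_df, directory / "families.tsv")
    paths["families"] = "families.tsv"

    manifest = {"seed": str(config.seed), "sponge_id": truth.sponge_id,
                "focal_family": truth.focal_family}
    manifest.update({f"path_{k}": v for k, v in sorted(paths.items())})
    with open(directory / "manifest.txt", "w", newline="\n") as fh:
        for k in sorted(manifest):
            fh.write(f"{k}={manifest[k]}\n")
    return manifest


def simulate_all(
    config: SimConfig,
) -> tuple[AnnotationSet, dict[str, str], dict[str, ReadSet], CountMatrix, SyntheticTruth]:
    """One-call generation of the complete synthetic study."""
    txome, sequences, truth = generate_transcriptome(config)
    readsets = {
        g: generate_clip_reads(txome, truth, g, config) for g in GENOTYPES_CLIP
    }
    cm, truth = generate_counts(txome, truth, default_design(config), config)
    return txome, sequences, readsets, cm, truth
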