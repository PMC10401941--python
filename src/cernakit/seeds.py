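"""miRNA seed-site discovery and the per-3'UTR occupancy-fraction statistic.

The central quantity is the *occupancy fraction*: CLIP reads overlapping a
predicted seed site divided by all CLIP reads in that site's 3'UTR.  The
per-UTR denominator makes the statistic library-size free, so genotypes can
be compared site-by-site without depth normalization.  Fractions are logit
transformed (with clamping) and compared between genotypes by a paired t
test over sites; control miRNA families run through the identical chain as
a specificity screen.

Canonical site classes follow the standard TargetScan definitions: the
7mer-m8 is the reverse complement of miRNA positions 2-8, the 8mer adds an
A opposite position 1, the 7mer-A1 is the 6mer (positions 2-7 match) plus
that A.  When one locus satisfies several definitions only the strongest
class is reported (8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import AnnotationSet, GenomicInterval, ReadSet, count_overlaps
from .expression import bh_adjust

logger = logging.getLogger(__name__)

MATCH_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp_dna(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


@dataclass(frozen=True)
class SeedFamily:
    """A miRNA family identified by its seed (miRNA positions 2-8, 5'->3')."""

    family_id: str
    seed7: str

    def __post_init__(self) -> None:
        if len(self.seed7) != 7:
            raise ValueError(f"seed7 must be exactly 7 nt, got {self.seed7!r}")
        if set(self.seed7) - set("ACGU"):
            raise ValueError(f"seed7 must be RNA over ACGU, got {self.seed7!r}")

    @property
    def site_core(self) -> str:
        """DNA reverse complement of positions 2-8 (the 7mer-m8 site)."""
        return _revcomp_dna(self.seed7.replace("U", "T"))

    @property
    def site_core6(self) -> str:
        """DNA reverse complement of positions 2-7 (the 6mer site).

        Every canonical site class contains this 6mer, so a sequence free of
        it carries no canonical site of the family at all.
        """
        return self.site_core[1:]


def find_seed_sites(sequence: str, family: SeedFamily) -> list[tuple[int, int, str]]:
    """Canonical seed matches in ``sequence`` as (start, end, match_type).

    Coordinates are 0-based half-open within the sequence.  T and U are
    equivalent.  Each 6mer-core locus is reported once with its best class.
    """
    seq = sequence.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    core6 = family.site_core6
    m8_char = family.site_core[0]
    sites: list[tuple[int, int, str]] = []
    pos = seq.find(core6)
    while pos != -1:
        has_m8 = pos >= 1 and seq[pos - 1] == m8_char
        has_a1 = pos + 6 < len(seq) and seq[pos + 6] == "A"
        if has_m8 and has_a1:
            sites.append((pos - 1, pos + 7, "8mer"))
        elif has_m8:
            sites.append((pos - 1, pos + 6, "7mer-m8"))
        elif has_a1:
            sites.append((pos, pos + 7, "7mer-A1"))
        else:
            sites.append((pos, pos + 6, "6mer"))
        pos = seq.find(core6, pos + 1)
    return sites


SITE_COLUMNS = [
    "site_id",
    "gene_id",
    "utr_id",
    "contig",
    "start",
    "end",
    "utr_start",
    "utr_end",
    "family_id",
    "match_type",
]


def build_site_table(
    utr_sequences: Mapping[str, str],
    utr_annotations: AnnotationSet,
    families: Sequence[SeedFamily],
    utr_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Scan every UTR sequence for every family; one row per (site, family).

    ``start``/``end`` are genomic (UTR offset applied); ``utr_start``/
    ``utr_end`` are within-UTR.  UTRs are assumed colinear with their
    sequence (plus strand), as produced by the synthetic-data generator.
    """
    rows = []
    for utr_id, seq in utr_sequences.items():
        try:
            utr = utr_annotations.get("three_prime_UTR", utr_id)
        except KeyError:
            utr = utr_annotations.get("lncRNA", utr_id)
        gene_id = utr_to_gene.get(utr_id, utr.parent or utr_id) if utr_to_gene else (
            utr.parent or utr_id
        )
        for family in families:
            for s, e, mtype in find_seed_sites(seq, family):
                rows.append(
                    {
                        "site_id": f"{family.family_id}|{utr_id}|{s}",
                        "gene_id": gene_id,
                        "utr_id": utr_id,
                        "contig": utr.interval.contig,
                        "start": utr.interval.start + s,
                        "end": utr.interval.start + e,
                        "utr_start": s,
                        "utr_end": e,
                        "family_id": family.family_id,
                        "match_type": mtype,
                    }
                )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def _site_min_overlap(site_len: int, min_overlap: int) -> int:
    # a 6/7-nt site cannot host an 8-nt overlap; cap at the site length
    return max(1, min(min_overlap, site_len))


def supported_sites(
    sites: pd.DataFrame,
    reads_by_genotype: Mapping[str, ReadSet],
    required: tuple[str, str],
    min_overlap: int = 8,
) -> pd.DataFrame:
    """Sites with >=1 read (full-site overlap by default) in both genotypes.

    Mirrors the definition of an experimentally supported predicted site:
    at least one CLIP read at the site in each of the two compared
    genotypes.  Returns the retained subset (attrs carry n_sites and
    n_genes).
    """
    for g in required:
        if g not in reads_by_genotype:
            raise KeyError(f"required genotype {g!r} not in reads_by_genotype")
    keep = np.ones(len(sites), dtype=bool)
    for g in required:
        reads = reads_by_genotype[g]
        for i, row in enumerate(sites.itertuples(index=False)):
            if not keep[i]:
                continue
            site_iv = GenomicInterval(row.contig, int(row.start), int(row.end))
            m = _site_min_overlap(site_iv.length, min_overlap)
            if count_overlaps(reads, site_iv, min_overlap=m) < 1:
                keep[i] = False
    out = sites.loc[keep].reset_index(drop=True)
    out.attrs["n_sites"] = len(out)
    out.attrs["n_genes"] = out["gene_id"].nunique() if len(out) else 0
    return out


def logit(fraction: float, epsilon: float = 1e-3) -> float:
    """ln(f'/(1-f')) with f' clamped into [epsilon, 1-epsilon]."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    f = min(max(fraction, epsilon), 1.0 - epsilon)
    return math.log(f / (1.0 - f))


OCCUPANCY_COLUMNS = [
    "site_id",
    "genotype",
    "site_reads",
    "utr_reads",
    "fraction",
    "logit_fraction",
    "defined",
]


def site_occupancy_fractions(
    reads: ReadSet,
    sites: pd.DataFrame,
    utrs: AnnotationSet,
    min_overlap: int = 8,
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """Per-site occupancy fractions: reads at site / reads in the site's UTR.

    Multiple sites in one UTR share the denominator.  Sites whose UTR has
    zero reads are flagged undefined (fraction NaN) and the count logged;
    downstream tests drop them.
    """
    utr_counts: dict[str, int] = {}
    rows = []
    n_undef = 0
    for row in sites.itertuples(index=False):
        if row.utr_id not in utr_counts:
            try:
                utr = utrs.get("three_prime_UTR", row.utr_id)
            except KeyError:
                utr = utrs.get("lncRNA", row.utr_id)
            utr_counts[row.utr_id] = count_overlaps(reads, utr.interval, min_overlap=1)
        n_utr = utr_counts[row.utr_id]
        site_iv = GenomicInterval(row.contig, int(row.start), int(row.end))
        m = _site_min_overlap(site_iv.length, min_overlap)
        n_site = count_overlaps(reads, site_iv, min_overlap=m)
        if n_utr > 0:
            frac = n_site / n_utr
            rows.append(
                {
                    "site_id": row.site_id,
                    "genotype": reads.genotype,
                    "site_reads": n_site,
                    "utr_reads": n_utr,
                    "fraction": frac,
                    "logit_fraction": logit(frac, epsilon),
                    "defined": True,
                }
            )
        else:
            n_undef += 1
            rows.append(
                {
                    "site_id": row.site_id,
                    "genotype": reads.genotype,
                    "site_reads": n_site,
                    "utr_reads": 0,
                    "fraction": np.nan,
                    "logit_fraction": np.nan,
                    "defined": False,
                }
            )
    if n_undef:
        logger.warning(
            "%d of %d sites have zero-read UTRs in genotype %r (fraction undefined)",
            n_undef,
            len(sites),
            reads.genotype,
        )
    return pd.DataFrame(rows, columns=OCCUPANCY_COLUMNS)


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t test of logit occupancy fractions between two genotypes."""

    n_sites: int
    mean_fraction_a: float
    mean_fraction_b: float
    percent_change: float
    t_statistic: float
    p_value: float
    df: int
    epsilon: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"paired t over {self.n_sites} sites: mean fraction "
            f"{self.mean_fraction_a:.4f} -> {self.mean_fraction_b:.4f} "
            f"({self.percent_change:+.1f}%), t={self.t_statistic:.3f}, "
            f"p={self.p_value:.3g}"
        )


def paired_occupancy_test(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    epsilon: float = 1e-3,
) -> PairedTestResult:
    """Two-sided paired t test on logit-fraction differences (B - A).

    Records must match 1:1 by site_id.  Summary means and percent_change
    are on the raw-fraction scale; the test is on the logit scale.  If the
    differences have zero variance the p-value is 1 when every difference
    is zero and 0 otherwise (degenerate-but-unambiguous cases).
    """
    a = records_a.set_index("site_id")
    b = records_b.set_index("site_id")
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise ValueError(
            f"unmatched site ids: only in A {only_a[:5]}...; only in B {only_b[:5]}..."
        )
    b = b.loc[a.index]
    n = len(a)
    if n < 2:
        raise ValueError(f"paired test requires >= 2 matched sites, got {n}")
    la = a["logit_fraction"].to_numpy(float)
    lb = b["logit_fraction"].to_numpy(float)
    d = lb - la
    mean_a = float(a["fraction"].mean())
    mean_b = float(b["fraction"].mean())
    pct = 100.0 * (mean_b - mean_a) / mean_a if mean_a != 0 else math.inf
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if np.all(d == 0.0):
            return PairedTestResult(n, mean_a, mean_b, pct, 0.0, 1.0, n - 1, epsilon)
        t = math.inf if d[0] > 0 else -math.inf
        return PairedTestResult(n, mean_a, mean_b, pct, t, 0.0, n - 1, epsilon)
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTestResult(n, mean_a, mean_b, pct, t, p, n - 1, epsilon)


def control_family_screen(
    families: Sequence[SeedFamily],
    reads_by_genotype: Mapping[str, ReadSet],
    sites_by_family: Mapping[str, pd.DataFrame],
    pair: tuple[str, str],
    utrs: AnnotationSet,
    min_overlap: int = 8,
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """Run the full supported-sites -> fractions -> paired-test chain per family.

    Returns one row per family with BH-adjusted p-values across families.
    Families with fewer than 2 supported, defined, matched sites are flagged
    untestable (p NaN, excluded from the adjustment).
    """
    if not families:
        raise ValueError("at least one family is required")
    rows = []
    for family in families:
        sites = sites_by_family.get(family.family_id, pd.DataFrame(columns=SITE_COLUMNS))
        supported = (
            supported_sites(sites, reads_by_genotype, pair, min_overlap=min_overlap)
            if len(sites)
            else sites
        )
        row: dict = {
            "family_id": family.family_id,
            "n_sites": len(supported),
            "n_genes": supported["gene_id"].nunique() if len(supported) else 0,
        }
        if len(supported) < 2:
            row.update(
                testable=False, t_statistic=np.nan, p_value=np.nan,
                percent_change=np.nan, mean_fraction_a=np.nan, mean_fraction_b=np.nan,
            )
            rows.append(row)
            continue
        rec_a = site_occupancy_fractions(
            reads_by_genotype[pair[0]], supported, utrs, min_overlap, epsilon
        )
        rec_b = site_occupancy_fractions(
            reads_by_genotype[pair[1]], supported, utrs, min_overlap, epsilon
        )
        ok = rec_a["defined"].to_numpy() & rec_b["defined"].to_numpy()
        rec_a, rec_b = rec_a.loc[ok], rec_b.loc[ok]
        if len(rec_a) < 2:
            row.update(
                testable=False, t_statistic=np.nan, p_value=np.nan,
                percent_change=np.nan, mean_fraction_a=np.nan, mean_fraction_b=np.nan,
            )
            rows.append(row)
            continue
        res = paired_occupancy_test(rec_a, rec_b, epsilon=epsilon)
        row.update(
            testable=True,
            n_sites=res.n_sites,
            t_statistic=res.t_statistic,
            p_value=res.p_value,
            percent_change=res.percent_change,
            mean_fraction_a=res.mean_fraction_a,
            mean_fraction_b=res.mean_fraction_b,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p_value"])
    return table
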