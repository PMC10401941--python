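"""Readers and writers for the plain-text formats the pipeline touches.

BED6 and counts/metadata TSVs are parsed directly (the contracts here —
parse errors carrying line numbers, strict coordinate validation — are part
of the pipeline's interface).  FASTA goes through Biopython.  GFF3 input is
1-based inclusive and is converted to the internal 0-based half-open
convention at this boundary; writers invert the conversion exactly.

All writers emit tab-delimited, LF-terminated text.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Annotation, AnnotationSet, GenomicInterval, ReadSet

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record in an input file; message carries path and line."""


# GFF3 type column -> internal feature class.  Unknown types map to "other"
# with a logged warning (they are kept, not dropped).
GFF_TYPE_MAP = {
    "gene": "gene",
    "lncRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
    "three_prime_UTR": "three_prime_UTR",
    "3UTR": "three_prime_UTR",
    "exon": "exon",
    "intron": "intron",
    "CDS": "CDS",
    "repeat": "repeat",
    "repeat_region": "repeat",
}

# Internal feature class -> GFF3 type column on output.
CLASS_TO_GFF_TYPE = {
    "gene": "gene",
    "lncRNA": "lnc_RNA",
    "three_prime_UTR": "three_prime_UTR",
    "exon": "exon",
    "intron": "intron",
    "CDS": "CDS",
    "repeat": "repeat_region",
    "other": "sequence_feature",
}


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3/BED6 file into intervals (0-based half-open, as BED)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate {fields[1]!r}/{fields[2]!r}"
                ) from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(contig, start, end, strand, name, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def read_bed_readset(
    path: str | Path, library_id: str = "", genotype: str = ""
) -> ReadSet:
    return ReadSet(read_bed(path), library_id=library_id, genotype=genotype)


def write_bed(intervals: Iterable[GenomicInterval] | ReadSet, path: str | Path) -> None:
    if isinstance(intervals, ReadSet):
        intervals = intervals.intervals()
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF3

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def read_gff(path: str | Path) -> AnnotationSet:
    """Parse GFF3 into an :class:`AnnotationSet` (internal 0-based half-open)."""
    path = Path(path)
    records: list[Annotation] = []
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            contig, _source, ftype, start_s, end_s, score_s, strand, _phase, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate {start_s!r}/{end_s!r}"
                ) from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: invalid GFF range {start1}..{end1}")
            feature_class = GFF_TYPE_MAP.get(ftype)
            if feature_class is None:
                logger.warning(
                    "%s:%d: unknown feature type %r classified as 'other'",
                    path,
                    lineno,
                    ftype,
                )
                feature_class = "other"
            attrs = _parse_gff_attributes(attr_s)
            fid = attrs.get("ID")
            if not fid:
                n_anon += 1
                fid = f"{feature_class}_{n_anon}"
            score = 0.0 if score_s in (".", "") else float(score_s)
            if strand not in ("+", "-", "."):
                strand = "."
            records.append(
                Annotation(
                    interval=GenomicInterval(
                        contig, start1 - 1, end1, strand, fid, score
                    ),
                    feature_class=feature_class,
                    id=fid,
                    parent=attrs.get("Parent", ""),
                )
            )
    return AnnotationSet(records)


def write_gff(annotations: AnnotationSet, path: str | Path, source: str = "cernakit") -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotations:
            iv = rec.interval
            attrs = f"ID={rec.id}"
            if rec.parent:
                attrs += f";Parent={rec.parent}"
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        source,
                        CLASS_TO_GFF_TYPE[rec.feature_class],
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Counts and sample metadata

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample count matrix; first column gene_id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{path}: non-numeric entries in count matrix")
    if np.any(values < 0):
        raise ParseError(f"{path}: negative counts are not allowed")
    if not np.allclose(values, np.round(values)):
        raise ParseError(f"{path}: non-integer counts are not allowed")
    return df.astype(np.int64)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Sample metadata with at least sample_id, genotype, stimulation columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "stimulation"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups}")
    return df


def check_samples_match(counts: pd.DataFrame, samples: pd.DataFrame) -> None:
    """Counts columns and metadata sample ids must match exactly."""
    cols = set(counts.columns)
    ids = set(samples["sample_id"])
    only_counts = sorted(cols - ids)
    only_meta = sorted(ids - cols)
    if only_counts or only_meta:
        raise ValueError(
            "sample mismatch between counts and metadata: "
            f"only in counts {only_counts}; only in metadata {only_meta}"
        )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
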