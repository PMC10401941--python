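"""Genomic interval containers and the interval algebra the pipeline is built on.

Coordinates are uniformly 0-based, half-open (``[start, end)``), BED-style.
GFF3 input/output converts at the boundary (see :mod:`cernakit.io`).

The three primitives here — interval subtraction, overlap counting and
per-base coverage — are the counting backbone for every occupancy statistic
downstream, so they are implemented directly on numpy arrays and checked
against per-base brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: Feature classes an :class:`AnnotationSet` recognizes.  "gene" is carried
#: in addition to the spec classes so transcript spans (used as normalizers
#: and background regions) keep their identity.
FEATURE_CLASSES = (
    "gene",
    "lncRNA",
    "three_prime_UTR",
    "exon",
    "intron",
    "CDS",
    "repeat",
    "other",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, named interval on a contig; 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be a nonempty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Annotation:
    """A classed genomic feature (one row of an annotation file)."""

    interval: GenomicInterval
    feature_class: str
    id: str
    parent: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"unknown feature_class {self.feature_class!r}; one of {FEATURE_CLASSES}"
            )
        if not self.id:
            raise ValueError("annotation id must be nonempty")


class AnnotationSet:
    """A collection of classed features with unique ids within each class."""

    def __init__(self, records: Iterable[Annotation]):
        self.records: list[Annotation] = list(records)
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.feature_class, rec.id)
            if key in seen:
                raise ValueError(
                    f"duplicate annotation id {rec.id!r} within class {rec.feature_class!r}"
                )
            seen.add(key)
        self._by_id = {(r.feature_class, r.id): r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.records)

    def classes(self) -> list[str]:
        return sorted({r.feature_class for r in self.records})

    def by_class(self, feature_class: str) -> list[Annotation]:
        return [r for r in self.records if r.feature_class == feature_class]

    def get(self, feature_class: str, id: str) -> Annotation:
        try:
            return self._by_id[(feature_class, id)]
        except KeyError:
            raise KeyError(f"no {feature_class!r} annotation with id {id!r}") from None

    def children_of(self, parent_id: str) -> list[Annotation]:
        return [r for r in self.records if r.parent == parent_id]


class ReadSet:
    """Aligned CLIP read intervals for one library/genotype.

    Reads are held column-wise (numpy arrays per contig) because occupancy
    counting touches every read for every one of thousands of sites.
    """

    def __init__(
        self,
        reads: Sequence[GenomicInterval] | pd.DataFrame,
        library_id: str = "",
        genotype: str = "",
    ):
        if isinstance(reads, pd.DataFrame):
            df = reads.reset_index(drop=True)
        else:
            df = pd.DataFrame(
                {
                    "contig": [r.contig for r in reads],
                    "start": np.asarray([r.start for r in reads], dtype=np.int64),
                    "end": np.asarray([r.end for r in reads], dtype=np.int64),
                    "name": [r.name for r in reads],
                    "score": [r.score for r in reads],
                    "strand": [r.strand for r in reads],
                }
            )
        for col, default in (
            ("name", ""),
            ("score", 1.0),
            ("strand", "."),
        ):
            if col not in df.columns:
                df[col] = default
        self.df = df
        self.library_id = library_id
        self.genotype = genotype
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._sorted_cache: dict[str, tuple[np.ndarray, int | None]] = {}

    @classmethod
    def from_arrays(
        cls,
        contig: str,
        starts: np.ndarray,
        ends: np.ndarray,
        library_id: str = "",
        genotype: str = "",
    ) -> "ReadSet":
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have the same shape")
        if np.any(starts >= ends):
            raise ValueError("all reads require start < end")
        df = pd.DataFrame(
            {
                "contig": contig,
                "start": starts,
                "end": ends,
                "name": [f"r{i}" for i in range(len(starts))],
                "score": 1.0,
                "strand": ".",
            }
        )
        return cls(df, library_id=library_id, genotype=genotype)

    @property
    def total_reads(self) -> int:
        return len(self.df)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(
                row.contig, int(row.start), int(row.end), row.strand, row.name, row.score
            )
            for row in self.df.itertuples(index=False)
        ]

    def arrays(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of the reads on ``contig`` (cached)."""
        if contig not in self._cache:
            sub = self.df[self.df["contig"] == contig]
            self._cache[contig] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
            )
        return self._cache[contig]

    def sorted_starts(self, contig: str) -> tuple[np.ndarray, int | None]:
        """(sorted read starts, fixed read length or None) for ``contig``.

        When every read on the contig has the same length, overlap counting
        reduces to two binary searches on the sorted starts; the fixed
        length enables that fast path.
        """
        if contig not in self._sorted_cache:
            starts, ends = self.arrays(contig)
            lengths = ends - starts
            fixed = int(lengths[0]) if lengths.size and np.all(lengths == lengths[0]) else None
            self._sorted_cache[contig] = (np.sort(starts), fixed)
        return self._sorted_cache[contig]


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals: sorted, non-overlapping, per contig."""
    out: list[GenomicInterval] = []
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(contig, cur_s, cur_e))
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Parts of each a-interval not covered by any b-interval.

    The b set is merged first; each a record is emitted as its surviving
    sub-intervals in coordinate order, preserving the a record's strand and
    name.  Empty ``b`` returns ``a`` unchanged (as new records).
    """
    merged_b: dict[str, list[tuple[int, int]]] = {}
    for iv in merge_intervals(b) if b else []:
        merged_b.setdefault(iv.contig, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in a:
        cuts = merged_b.get(iv.contig, [])
        pos = iv.start
        for bs, be in cuts:
            if be <= pos or bs >= iv.end:
                continue
            if bs > pos:
                out.append(
                    GenomicInterval(iv.contig, pos, bs, iv.strand, iv.name, iv.score)
                )
            pos = max(pos, be)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(
                GenomicInterval(iv.contig, pos, iv.end, iv.strand, iv.name, iv.score)
            )
    return out


def count_overlaps(
    reads: ReadSet,
    target: GenomicInterval,
    min_overlap: int = 1,
    same_strand: bool = False,
) -> int:
    """Number of reads whose intersection with ``target`` is >= ``min_overlap`` nt.

    Strand is ignored unless ``same_strand`` is set (CLIP reads are counted
    over annotations without a strand requirement by default).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    starts, ends = reads.arrays(target.contig)
    if starts.size == 0:
        return 0
    if not same_strand:
        sorted_starts, fixed_len = reads.sorted_starts(target.contig)
        if fixed_len is not None:
            # overlap >= m needs m <= read length and m <= target length;
            # then it holds iff start in [target.start + m - L, target.end - m]
            if min_overlap > fixed_len or min_overlap > target.length:
                return 0
            lo = target.start + min_overlap - fixed_len
            hi = target.end - min_overlap
            return int(
                np.searchsorted(sorted_starts, hi, side="right")
                - np.searchsorted(sorted_starts, lo, side="left")
            )
    ov = np.minimum(ends, target.end) - np.maximum(starts, target.start)
    hit = ov >= min_overlap
    if same_strand:
        sub = reads.df[reads.df["contig"] == target.contig]
        hit &= (sub["strand"].to_numpy() == target.strand)
    return int(np.count_nonzero(hit))


def count_overlaps_many(
    reads: ReadSet,
    targets: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> np.ndarray:
    """Vector of :func:`count_overlaps` over many targets."""
    out = np.zeros(len(targets), dtype=np.int64)
    for i, t in enumerate(targets):
        out[i] = count_overlaps(reads, t, min_overlap=min_overlap)
    return out


def count_overlaps_union(
    reads: ReadSet,
    pieces: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> int:
    """Reads overlapping *any* of ``pieces`` by >= min_overlap nt, counted once."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    hits: dict[str, np.ndarray] = {}
    for p in pieces:
        starts, ends = reads.arrays(p.contig)
        if starts.size == 0:
            continue
        ov = np.minimum(ends, p.end) - np.maximum(starts, p.start)
        h = ov >= min_overlap
        if p.contig in hits:
            hits[p.contig] |= h
        else:
            hits[p.contig] = h
    return int(sum(np.count_nonzero(h) for h in hits.values()))


def coverage_track(reads: ReadSet, region: GenomicInterval) -> np.ndarray:
    """Per-base read depth over ``region``.

    ``vector[i]`` is the number of reads covering ``region.start + i``;
    the vector sums to the total per-read overlap length with the region.
    """
    n = region.length
    diff = np.zeros(n + 1, dtype=np.int64)
    starts, ends = reads.arrays(region.contig)
    if starts.size:
        s = np.clip(starts - region.start, 0, n)
        e = np.clip(ends - region.start, 0, n)
        keep = s < e
        np.add.at(diff, s[keep], 1)
        np.add.at(diff, e[keep], -1)
    return np.cumsum(diff[:-1])
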