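"""Genomic data model shared by the whole pipeline.

Coordinates are 0-based, half-open everywhere. Tags are single-end reads
reduced to their 5' position and strand; a library is the deduplicated set
of tags for one biological replicate. Distances to a TSS are signed and
strand-relative: negative means upstream of the gene's direction of
transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAG_COLUMNS = ["chrom", "pos5", "strand"]


class GenomeIndex:
    """Chromosome name -> length (bp) lookup; validates coordinates."""

    def __init__(self, chrom_lengths: Mapping[str, int]):
        lengths = dict(chrom_lengths)
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chrom_lengths: dict[str, int] = lengths

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def __len__(self) -> int:
        return len(self.chrom_lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self.chrom_lengths == other.chrom_lengths

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def chroms(self) -> list[str]:
        return sorted(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def validate_positions(self, chrom: np.ndarray, pos: np.ndarray) -> None:
        """Raise ValueError naming the first out-of-range record."""
        for c in pd.unique(np.asarray(chrom)):
            if c not in self.chrom_lengths:
                i = int(np.argmax(np.asarray(chrom) == c))
                raise ValueError(f"record {i}: unknown chromosome {c!r}")
        lengths = pd.Series(chrom).map(self.chrom_lengths).to_numpy()
        bad = (pos < 0) | (pos >= lengths)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"record {i}: position {int(pos[i])} outside [0, {int(lengths[i])}) "
                f"on {chrom[i]!r}"
            )


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class TagLibrary:
    """Deduplicated stranded 5'-end read positions for one replicate.

    ``tags`` is a DataFrame with columns chrom (str), pos5 (int), strand
    ('+'/'-'). ``n_tags`` always equals ``len(tags)``.
    """

    tags: pd.DataFrame
    replicate_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.tags = self.tags.reset_index(drop=True)[TAG_COLUMNS]

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def sorted(self) -> "TagLibrary":
        out = self.tags.sort_values(TAG_COLUMNS, kind="mergesort").reset_index(drop=True)
        return TagLibrary(out, self.replicate_id, self.condition)

    def tag_multiset(self) -> "pd.Series":
        """Counts per distinct (chrom, pos5, strand) triple."""
        return self.tags.groupby(TAG_COLUMNS, sort=True).size()


def make_tags(chrom: Sequence[str], pos5: Sequence[int], strand: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": np.asarray(chrom, dtype=object),
         "pos5": np.asarray(pos5, dtype=np.int64),
         "strand": np.asarray(strand, dtype=object)}
    )


def dedupe_tags(
    raw_tags: pd.DataFrame,
    genome: GenomeIndex | None = None,
    replicate_id: str = "",
    condition: str = "",
) -> TagLibrary:
    """Collapse redundant reads: one tag per distinct (chrom, pos5, strand).

    Redundant reads — PCR duplicates mapping to the same 5' position on the
    same strand — are discarded within each replicate before any pooling.
    """
    df = raw_tags[TAG_COLUMNS]
    if genome is not None and len(df):
        genome.validate_positions(df["chrom"].to_numpy(), df["pos5"].to_numpy())
    out = df.drop_duplicates().sort_values(TAG_COLUMNS, kind="mergesort")
    return TagLibrary(out.reset_index(drop=True), replicate_id, condition)


def pool_libraries(libs: Sequence[TagLibrary], label: str = "pool") -> TagLibrary:
    """Multiset union of replicate libraries (no cross-replicate dedup).

    Tags shared between replicates are retained once per contributing
    replicate, so the pooled ``n_tags`` is the sum of the inputs.
    """
    if not libs:
        raise ValueError("cannot pool zero libraries")
    conditions = {lib.condition for lib in libs}
    if len(conditions) > 1:
        raise ValueError(f"refusing to pool libraries from mixed conditions {sorted(conditions)}")
    tags = pd.concat([lib.tags for lib in libs], ignore_index=True)
    return TagLibrary(tags, replicate_id=label, condition=libs[0].condition)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Minimal sorted disjoint cover of the union of the inputs."""
    by_key = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[Interval] = []
    for iv in by_key:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(Interval(iv.chrom, iv.start, iv.end))
    return out


@dataclass
class OverlapStats:
    a_only: int
    b_only: int
    shared: int
    frac_a_in_b: float
    frac_b_in_a: float


def _interval_arrays(intervals: Sequence[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        out[chrom] = (np.array([iv.start for iv in ivs]), np.array([iv.end for iv in ivs]))
    return out

def overlaps_any(queries: Sequence[Interval], subjects: Sequence[Interval]) -> np.ndarray:
    """Boolean per query: does it overlap (>=1 bp) any subject interval?"""
    idx = _interval_arrays(subjects)
    hits = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        if q.chrom not in idx:
            continue
        starts, ends = idx[q.chrom]
        # overlap iff subject.start < q.end and subject.end > q.start
        j = np.searchsorted(starts, q.end, side="left")
        hits[i] = bool((ends[:j] > q.start).any())
    return hits


def overlap_stats(set_a: Sequence[Interval], set_b: Sequence[Interval]) -> OverlapStats:
    """Shared = >=1 bp overlap with any interval of the other set."""
    a_in_b = overlaps_any(set_a, set_b)
    b_in_a = overlaps_any(set_b, set_a)
    shared = int(a_in_b.sum())
    return OverlapStats(
        a_only=len(set_a) - shared,
        b_only=len(set_b) - int(b_in_a.sum()),
        shared=shared,
        frac_a_in_b=float(a_in_b.mean()) if len(set_a) else 0.0,
        frac_b_in_a=float(b_in_a.mean()) if len(set_b) else 0.0,
    )


@dataclass
class GeneModel:
    """One transcript of one gene; all coordinates 0-based half-open.

    ``tss`` is the coordinate of the first transcribed base (txStart on +,
    txEnd-1 on -); ``tes`` the last. ``cds_start``/``cds_end`` are genomic
    bounds of the coding region, or None for non-coding transcripts.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[Interval] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def signed_distance(self, pos: int) -> int:
        """Signed strand-relative distance from the TSS (negative = upstream)."""
        d = pos - self.tss
        return d if self.strand == "+" else -d

    def introns(self) -> list[Interval]:
        """Introns in genomic order (not transcription order)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(self.chrom, a.end, b.start))
        return out

    def first_intron(self) -> Interval | None:
        """First intron in transcription order."""
        introns = self.introns()
        if not introns:
            return None
        return introns[0] if self.strand == "+" else introns[-1]


class Transcriptome:
    """Gene models plus a per-chromosome sorted-TSS index for nearest queries."""

    def __init__(self, genes: Sequence[GeneModel], genome: GenomeIndex | None = None):
        self.genes: list[GeneModel] = list(genes)
        if genome is not None:
            for g in self.genes:
                if g.chrom not in genome:
                    raise ValueError(f"gene {g.gene_symbol} on unknown chromosome {g.chrom!r}")
        self._tss_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for i, g in enumerate(self.genes):
            by_chrom.setdefault(g.chrom, []).append((g.tss, i))
        self._tss_sign: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            idx = np.array([i for _, i in pairs], dtype=np.int64)
            self._tss_index[chrom] = (
                np.array([p for p, _ in pairs], dtype=np.int64),
                idx,
            )
            self._tss_sign[chrom] = np.array(
                [1 if self.genes[i].strand == "+" else -1 for i in idx], dtype=np.int64
            )

    def __len__(self) -> int:
        return len(self.genes)

    def nearest_tss(self, chrom: str, pos: int) -> tuple[GeneModel | None, int]:
        """Nearest-TSS gene and its signed strand-relative distance.

        Ties (equidistant TSSs) break toward the gene earlier in coordinate
        order, which is the lower TSS position here.
        """
        if chrom not in self._tss_index:
            return None, 0
        tss, idx = self._tss_index[chrom]
        j = int(np.searchsorted(tss, pos))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(tss):
                d = abs(int(tss[k]) - pos)
                if best is None or d < best[0]:
                    best = (d, k)
        if best is None:
            return None, 0
        gene = self.genes[int(idx[best[1]])]
        return gene, gene.signed_distance(pos)

    def nearest_tss_distances(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorised signed nearest-TSS distances (0 where no TSS on chrom)."""
        out = np.zeros(len(pos), dtype=np.int64)
        for c in pd.unique(np.asarray(chrom)):
            mask = np.asarray(chrom) == c
            if c not in self._tss_index:
                continue
            tss, idx = self._tss_index[c]
            p = np.asarray(pos)[mask]
            j = np.searchsorted(tss, p)
            left = np.clip(j - 1, 0, len(tss) - 1)
            right = np.clip(j, 0, len(tss) - 1)
            dl = np.abs(tss[left] - p)
            dr = np.abs(tss[right] - p)
            pick = np.where(dl <= dr, left, right)
            out[mask] = (p - tss[pick]) * self._tss_sign[c][pick]
        return out
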