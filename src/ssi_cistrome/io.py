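"""Readers and writers for the plain-text formats the pipeline touches.

tagAlign/BED6, chrom.sizes, refFlat-style gene tables, FASTA (via pyfaidx),
JASPAR-style position count matrices, generic BED3+ region sets, and the
TSV conventions used by every stage (header row, floats rendered with six
significant digits, rows ordered by chrom/start/end).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .core import GeneModel, GenomeIndex, Interval, TagLibrary, dedupe_tags, make_tags

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


# -- chrom.sizes ------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeIndex:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeIndex(dict(zip(df["chrom"], df["length"].astype(int))))


def write_chrom_sizes(genome: GenomeIndex, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f"{chrom}\t{genome.length(chrom)}\n")


# -- tagAlign / BED6 --------------------------------------------------------

def read_tagalign(
    path,
    genome: GenomeIndex | None = None,
    replicate_id: str = "",
    condition: str = "",
    dedupe: bool = True,
) -> TagLibrary:
    """Read a tagAlign/BED6 file into a (deduplicated) tag library.

    The 5' position of a + read is its start; of a - read, end-1.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"], dtype={0: str, 5: str},
    )
    pos5 = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    tags = make_tags(df["chrom"], pos5, df["strand"])
    if dedupe:
        return dedupe_tags(tags, genome, replicate_id, condition)
    lib = TagLibrary(tags, replicate_id, condition)
    if genome is not None and lib.n_tags:
        genome.validate_positions(tags["chrom"].to_numpy(), tags["pos5"].to_numpy())
    return lib


def write_tagalign(lib: TagLibrary, path, read_bp: int = 36) -> None:
    """Write tags as fixed-width tagAlign records (score 1000, name 'N')."""
    t = lib.sorted().tags
    start = np.where(t["strand"] == "+", t["pos5"], t["pos5"] - read_bp + 1)
    start = np.maximum(start, 0)
    end = np.where(t["strand"] == "+", t["pos5"] + read_bp, t["pos5"] + 1)
    out = pd.DataFrame({
        "chrom": t["chrom"], "start": start.astype(int), "end": end.astype(int),
        "name": "N", "score": 1000, "strand": t["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# -- generic BED region sets ------------------------------------------------

def read_bed_intervals(path, genome: GenomeIndex | None = None) -> list[Interval]:
    """Read BED3+ intervals; unknown chromosomes are skipped with a warning."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out: list[Interval] = []
    skipped = 0
    for chrom, start, end in zip(df[0].astype(str), df[1].astype(int), df[2].astype(int)):
        if genome is not None and chrom not in genome:
            skipped += 1
            continue
        out.append(Interval(chrom, start, end))
    if skipped:
        logger.warning("skipped %d records on chromosomes absent from the genome index", skipped)
    return out


def write_peaks_bed(peaks, path) -> None:
    """BED6+: chrom, start, end, id, RPM height x1000 as integer score, '.'."""
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for i, p in enumerate(rows):
            iv = p.interval
            score = int(round(p.height_rpm * 1000))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i + 1}\t{score}\t.\n")


def read_peaks_bed(path):
    """Read a peak BED back into a PeakSet (summit = interval midpoint)."""
    from .peaks import Peak, PeakSet

    df = pd.read_csv(path, sep="\t", header=None)
    peaks = []
    for _, row in df.iterrows():
        iv = Interval(str(row[0]), int(row[1]), int(row[2]))
        height = float(row[4]) / 1000.0 if len(row) > 4 else 0.0
        peaks.append(Peak(interval=iv, summit=iv.center, height_rpm=height))
    return PeakSet(peaks=peaks, source=str(path))


# -- refFlat-style gene tables ----------------------------------------------

REFFLAT_COLUMNS = [
    "gene_symbol", "transcript_id", "chrom", "strand", "tx_start", "tx_end",
    "cds_start", "cds_end", "exon_count", "exon_starts", "exon_ends",
]


def read_gene_table(path, one_based: bool = False) -> list[GeneModel]:
    """Read a refFlat-like table (UCSC column order, 0-based half-open).

    ``one_based=True`` converts tables using 1-based inclusive starts.
    A transcript with cds_start == cds_end is treated as non-coding.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=REFFLAT_COLUMNS, comment="#")
    shift = 1 if one_based else 0
    genes = []
    for _, row in df.iterrows():
        starts = [int(s) - shift for s in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(s) for s in str(row.exon_ends).rstrip(",").split(",")]
        exons = [Interval(row.chrom, s, e) for s, e in zip(starts, ends)]
        cds_start, cds_end = int(row.cds_start) - shift, int(row.cds_end)
        coding = cds_start < cds_end
        genes.append(GeneModel(
            gene_symbol=str(row.gene_symbol), transcript_id=str(row.transcript_id),
            chrom=str(row.chrom), strand=str(row.strand),
            tx_start=int(row.tx_start) - shift, tx_end=int(row.tx_end),
            exons=exons,
            cds_start=cds_start if coding else None,
            cds_end=cds_end if coding else None,
        ))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.transcript_id)):
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            cs = g.cds_start if g.cds_start is not None else g.tx_end
            ce = g.cds_end if g.cds_end is not None else g.tx_end
            fh.write("\t".join(map(str, [
                g.gene_symbol, g.transcript_id, g.chrom, g.strand,
                g.tx_start, g.tx_end, cs, ce, len(g.exons), starts, ends,
            ])) + "\n")


# -- FASTA ------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def open_fasta(path) -> Fasta:
    return Fasta(str(path), sequence_always_upper=True)


# -- JASPAR-style position count matrices -----------------------------------

def read_jaspar_pcm(path):
    """Read a JASPAR-style text matrix (4 rows A/C/G/T) into a PWM."""
    from .motifs import PWM

    name = "motif"
    counts: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            base, rest = line[0], line[1:]
            rest = rest.replace("[", " ").replace("]", " ")
            counts[base.upper()] = [float(x) for x in rest.split()]
    mat = np.array([counts[b] for b in "ACGT"])
    return PWM(name=name, counts=mat)


def write_jaspar_pcm(pwm, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, base in enumerate("ACGT"):
            vals = " ".join(FLOAT_FMT % v for v in pwm.counts[i])
            fh.write(f"{base} [ {vals} ]\n")


# -- DE gene tables ----------------------------------------------------------

DE_COLUMNS = ["gene", "log2fc", "direction", "measured"]


def read_de_table(path) -> pd.DataFrame:
    """TSV with header: gene, log2fc, direction {up,down,none}, measured {0,1}."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    df = df[DE_COLUMNS].copy()
    df["measured"] = df["measured"].astype(int)
    return df


def write_de_table(df: pd.DataFrame, path) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# -- TSV convention ----------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    """Stage-output convention: header row, 6-significant-digit floats."""
    out = df
    if {"chrom", "start", "end"} <= set(df.columns):
        out = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
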