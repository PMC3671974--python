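"""CRE classification, PWM scanning, TATA-promoter calling, TSS-distance
matched background sampling, and positional motif histograms.

The cAMP-response element (CRE) is the palindromic octamer TGACGTCA; its
half-sites are the pentamers TGACG / CGTCA. A binding site is classified
from the 100 bp of sequence centred on its peak center: "Full CRE" if any
octamer lies within Hamming distance 1 of the consensus, otherwise
"Half CRE" if either pentamer occurs exactly, otherwise "Non-CRE".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeIndex, Interval, Transcriptome

logger = logging.getLogger(__name__)

CRE_OCTAMER = "TGACGTCA"
CRE_HALF_SITES = ("TGACG", "CGTCA")  # closed under reverse complement
CRE_WINDOW_BP = 100

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MotifClass(str, Enum):
    FULL_CRE = "FULL_CRE"
    HALF_CRE = "HALF_CRE"
    NON_CRE = "NON_CRE"


def _min_hamming_to_octamer(window: str, octamer: str = CRE_OCTAMER) -> int:
    """Minimum mismatch count of any k-mer in ``window`` vs the octamer.

    N never matches, i.e. counts as a mismatch.
    """
    k = len(octamer)
    best = k
    for i in range(len(window) - k + 1):
        sub = window[i:i + k]
        d = sum(1 for a, b in zip(sub, octamer) if a != b or a == "N")
        if d < best:
            best = d
    return best


def classify_cre(sequence: str, half_sites: tuple[str, ...] = CRE_HALF_SITES) -> MotifClass:
    """Classify a peak-center window as FULL_CRE / HALF_CRE / NON_CRE.

    FULL takes precedence over HALF. ``half_sites=('TGACG',)`` gives the
    strict forward-pentamer reading.
    """
    seq = sequence.upper()
    if len(seq) < len(CRE_OCTAMER):
        logger.warning("window shorter than the CRE octamer: NON_CRE")
        return MotifClass.NON_CRE
    if _min_hamming_to_octamer(seq) <= 1:
        return MotifClass.FULL_CRE
    for half in half_sites:
        if half in seq:
            return MotifClass.HALF_CRE
    return MotifClass.NON_CRE


# -- position weight matrices ------------------------------------------------

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    """Position count matrix with derived log-odds scores.

    Log-odds per cell: log2((count + pseudocount) / column_total / background),
    uniform background 0.25, pseudocount 0.5 per count cell. N scores -inf
    (windows containing N are skipped).
    """

    name: str
    counts: np.ndarray  # 4 x width, rows A/C/G/T
    pseudocount: float = 0.5
    background: float = 0.25
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be 4 x width")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("a position has zero total count")
        padded = self.counts + self.pseudocount
        probs = padded / padded.sum(axis=0, keepdims=True)
        self.log_odds = np.log2(probs / self.background)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def score(self, kmer: str) -> float:
        """Log-odds of one k-mer (forward strand); -inf if it contains N."""
        s = 0.0
        for j, base in enumerate(kmer.upper()):
            i = _BASE_INDEX.get(base)
            if i is None:
                return float("-inf")
            s += self.log_odds[i, j]
        return s


@dataclass
class MotifHit:
    chrom: str
    start: int  # forward-strand coordinate of the matched window
    strand: str
    score: float
    motif: str


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold: float,
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands; return hits with score >= threshold, by position."""
    seq = sequence.upper()
    w = pwm.width
    if w > len(seq):
        raise ValueError("PWM wider than sequence")
    idx = np.full(len(seq), -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    n_win = len(seq) - w + 1
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    # reverse-complement scores via the complemented, reversed matrix
    lo_rc = pwm.log_odds[::-1, ::-1]
    for j in range(w):
        col = idx[j:j + n_win]
        bad = col < 0
        valid &= ~bad
        safe = np.where(bad, 0, col)
        fwd += pwm.log_odds[safe, j]
        rev += lo_rc[safe, j]
    hits = []
    for i in range(n_win):
        if not valid[i]:
            continue
        if fwd[i] >= threshold:
            hits.append(MotifHit(chrom, offset + i, "+", float(fwd[i]), pwm.name))
        if rev[i] >= threshold:
            hits.append(MotifHit(chrom, offset + i, "-", float(rev[i]), pwm.name))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def tata_pwm(sharpness: int = 93) -> PWM:
    """Synthetic TATA-box count matrix (consensus TATAAAAG, width 8).

    A consensus-built stand-in matrix, not a database-derived one: each
    column gives ``sharpness`` counts (of 99) to the consensus base and
    splits the rest evenly. With the default pseudocount, only k-mers within
    one mismatch of the consensus reach the conventional score threshold 6.
    """
    consensus = "TATAAAAG"
    rest = (99 - sharpness) / 3.0
    counts = np.full((4, len(consensus)), rest)
    for j, base in enumerate(consensus):
        counts[_BASE_INDEX[base], j] = sharpness
    return PWM(name="TATA-box-synthetic", counts=counts)


def classify_tata(
    gene,
    fasta,
    pwm: PWM,
    threshold: float = 6.0,
    window_bp: int = 250,
    genome: GenomeIndex | None = None,
) -> bool:
    """Is there a PWM hit with score >= threshold within ±window_bp of the TSS?

    The hit's start coordinate must lie in [tss - window_bp, tss + window_bp];
    windows truncated at chromosome edges are scanned as-is.
    """
    tss = gene.tss
    chrom_len = genome.length(gene.chrom) if genome is not None else None
    lo = max(tss - window_bp, 0)
    hi = tss + window_bp + pwm.width
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    seq = str(fasta[gene.chrom][lo:hi])
    if len(seq) < pwm.width:
        return False
    hits = scan_pwm(seq, pwm, threshold, chrom=gene.chrom, offset=lo)
    return any(lo <= h.start <= tss + window_bp for h in hits)


# -- matched background sampling ---------------------------------------------

# signed TSS-distance bin edges (bp), mirroring the annotation windows
TSS_DISTANCE_BIN_EDGES = [-np.inf, -50_000, -10_000, -2_000, -200, 0,
                          200, 2_000, 10_000, 50_000, np.inf]


def tss_distance_bin(distance: np.ndarray) -> np.ndarray:
    return np.digitize(distance, TSS_DISTANCE_BIN_EDGES[1:-1], right=False)


def sample_matched_background(
    foreground: list[Interval],
    transcriptome: Transcriptome,
    genome: GenomeIndex,
    n_per_site: int = 1,
    seed: int = 0,
) -> list[Interval]:
    """Background intervals with the foreground's nearest-TSS distance profile.

    Every genomic base is binned by its signed nearest-TSS distance
    (log-spaced bins per side); each foreground site draws ``n_per_site``
    background centers from its own bin, excluding foreground intervals.
    Deterministic under ``seed``. Suited to desk-scale genomes (the per-base
    distance array is materialised per chromosome).
    """
    if not foreground:
        raise ValueError("empty foreground")
    rng = np.random.default_rng(seed)
    width = max(len(iv) for iv in foreground)

    # per-bin pools of candidate (chrom, pos) centers
    pools: dict[int, list[tuple[str, np.ndarray]]] = {}
    fg_by_chrom: dict[str, list[Interval]] = {}
    for iv in foreground:
        fg_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in genome.chroms():
        positions = np.arange(genome.length(chrom), dtype=np.int64)
        dist = transcriptome.nearest_tss_distances(
            np.full(len(positions), chrom, dtype=object), positions
        )
        allowed = np.ones(len(positions), dtype=bool)
        for iv in fg_by_chrom.get(chrom, []):
            allowed[iv.start:iv.end] = False
        bins = tss_distance_bin(dist)
        for b in np.unique(bins):
            mask = (bins == b) & allowed
            if mask.any():
                pools.setdefault(int(b), []).append((chrom, positions[mask]))

    fg_dist = np.array([
        transcriptome.nearest_tss(iv.chrom, iv.center)[1] for iv in foreground
    ])
    fg_bins = tss_distance_bin(fg_dist)
    available = sorted(pools)
    out: list[Interval] = []
    for b in fg_bins:
        target = int(b)
        if target not in pools:
            nearest = min(available, key=lambda x: abs(x - target))
            logger.warning("no candidates in TSS-distance bin %d; using bin %d", target, nearest)
            target = nearest
        chroms = pools[target]
        sizes = np.array([len(p) for _, p in chroms])
        for _ in range(n_per_site):
            ci = rng.choice(len(chroms), p=sizes / sizes.sum())
            chrom, pos = chroms[ci]
            center = int(pos[rng.integers(len(pos))])
            half = width // 2
            lo = max(center - half, 0)
            hi = min(lo + width, genome.length(chrom))
            lo = max(hi - width, 0)
            out.append(Interval(chrom, lo, hi))
    return out


# -- positional histograms ---------------------------------------------------

@dataclass
class PositionalHistogram:
    bin_centers: np.ndarray
    frequencies: np.ndarray  # motif occurrences per site per bin
    bin_bp: int = 10


def positional_histogram(
    peaks,
    fasta,
    matcher,
    flank_bp: int = 250,
    bin_bp: int = 10,
    genome: GenomeIndex | None = None,
) -> PositionalHistogram:
    """Motif occurrence frequency per offset bin relative to peak centers.

    ``matcher(sequence) -> list of match start offsets`` (0-based within the
    given sequence); offsets are recorded relative to the peak center and
    averaged over peaks.
    """
    edges = np.arange(-flank_bp, flank_bp + bin_bp, bin_bp)
    counts = np.zeros(len(edges) - 1)
    n = 0
    for p in peaks:
        center = p.interval.center if hasattr(p, "interval") else p.center
        chrom = p.interval.chrom if hasattr(p, "interval") else p.chrom
        lo = max(center - flank_bp, 0)
        hi = center + flank_bp
        if genome is not None:
            hi = min(hi, genome.length(chrom))
        seq = str(fasta[chrom][lo:hi])
        offs = np.array([lo + m - center for m in matcher(seq)], dtype=float)
        if len(offs):
            counts += np.histogram(offs, bins=edges)[0]
        n += 1
    freq = counts / n if n else counts
    return PositionalHistogram((edges[:-1] + edges[1:]) / 2.0, freq, bin_bp)


def exact_matcher(motif: str, both_strands: bool = True):
    """Matcher factory: start offsets of exact occurrences of ``motif``."""
    rc = revcomp(motif)
    def match(seq: str) -> list[int]:
        seq = seq.upper()
        out = []
        for i in range(len(seq) - len(motif) + 1):
            sub = seq[i:i + len(motif)]
            if sub == motif or (both_strands and sub == rc):
                out.append(i)
        return out
    return match


def pwm_matcher(pwm: PWM, threshold: float):
    def match(seq: str) -> list[int]:
        return [h.start for h in scan_pwm(seq, pwm, threshold)]
    return match


def motif_rate_by_group(
    site_groups: dict[str, list[Interval]],
    fasta,
    matcher,
    window_bp: int = 250,
    reference_group: str = "NO_CHANGE",
    genome: GenomeIndex | None = None,
) -> pd.DataFrame:
    """Fraction of each group's sites with >=1 match within ±window_bp of
    center, plus a two-sided Fisher exact test of each group vs the reference.
    """
    hits_by_group: dict[str, tuple[int, int]] = {}
    for group, sites in site_groups.items():
        if not sites:
            continue
        n_hit = 0
        for iv in sites:
            lo = max(iv.center - window_bp, 0)
            hi = iv.center + window_bp
            if genome is not None:
                hi = min(hi, genome.length(iv.chrom))
            if matcher(str(fasta[iv.chrom][lo:hi])):
                n_hit += 1
        hits_by_group[group] = (n_hit, len(sites))
    rows = []
    ref = hits_by_group.get(reference_group)
    for group, (n_hit, n) in sorted(hits_by_group.items()):
        row = {"group": group, "n_sites": n, "n_with_motif": n_hit, "rate": n_hit / n}
        if ref is not None and group != reference_group:
            table = [[n_hit, n - n_hit], [ref[0], ref[1] - ref[0]]]
            row["fisher_p_vs_reference"] = float(stats.fisher_exact(table)[1])
        else:
            row["fisher_p_vs_reference"] = 1.0 if group == reference_group else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
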