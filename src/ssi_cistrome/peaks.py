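"""Window-based peak calling and the single-sample-independence (SSI) filter.

The caller slides fixed-width windows along each chromosome, counts
fragment-extended tags per window, scores each window against a Poisson
background (the larger of the global and a local expectation), corrects
across windows with Benjamini-Hochberg, and merges significant windows
into variable-width peaks.

The SSI filter is the reproducibility test: a peak called on the pool of
all replicates is kept only if a matching peak is also called in every
pool that omits one replicate. Peaks that vanish when a single replicate
is excluded depend on that replicate alone and are discarded as likely
artifacts. The filter consumes plain peak sets, so calls from any external
caller can be substituted for the built-in one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeIndex, Interval, TagLibrary, merge_intervals, pool_libraries

logger = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    window_bp: int = 200
    step_bp: int = 50
    fragment_bp: int = 108
    fdr: float = 0.05
    local_bg_bp: int = 10_000
    min_tags: int = 4

    def __post_init__(self):
        if not (0 < self.step_bp <= self.window_bp):
            raise ValueError("need 0 < step_bp <= window_bp")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")


@dataclass
class Peak:
    interval: Interval
    summit: int
    height_rpm: float
    pvalue: float | None = None
    qvalue: float | None = None

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside peak interval")
        if self.height_rpm < 0:
            raise ValueError("negative height")


@dataclass
class PeakSet:
    peaks: list[Peak]
    source: str = ""
    caller_config: CallerConfig | None = None

    def __post_init__(self):
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    def merged(self) -> "PeakSet":
        """Collapse overlapping peaks (keeps the higher summit per cluster)."""
        out: list[Peak] = []
        for p in self.peaks:
            if out and out[-1].interval.overlaps(p.interval):
                prev = out[-1]
                keep = prev if prev.height_rpm >= p.height_rpm else p
                iv = Interval(
                    prev.interval.chrom,
                    prev.interval.start,
                    max(prev.interval.end, p.interval.end),
                )
                out[-1] = Peak(iv, keep.summit, keep.height_rpm, keep.pvalue, keep.qvalue)
            else:
                out.append(p)
        return PeakSet(out, self.source, self.caller_config)


def fragment_starts(lib: TagLibrary, fragment_bp: int) -> dict[str, np.ndarray]:
    """Per-chromosome sorted fragment start positions.

    A + tag extends to [pos5, pos5+L); a - tag to [pos5-L+1, pos5+1).
    All fragments have length ``fragment_bp``, so starts fully determine them.
    """
    t = lib.tags
    starts = np.where(t["strand"].to_numpy() == "+", t["pos5"], t["pos5"] - fragment_bp + 1)
    out = {}
    for chrom, grp in pd.DataFrame({"chrom": t["chrom"], "s": starts}).groupby("chrom", sort=True):
        out[str(chrom)] = np.sort(grp["s"].to_numpy())
    return out


def pileup(frag_starts: np.ndarray, fragment_bp: int, region: Interval) -> np.ndarray:
    """Per-base fragment depth inside ``region`` (brute array, clipped)."""
    lo = np.searchsorted(frag_starts, region.start - fragment_bp, side="right")
    hi = np.searchsorted(frag_starts, region.end, side="left")
    depth = np.zeros(len(region) + 1, dtype=np.int64)
    s = np.clip(frag_starts[lo:hi] - region.start, 0, len(region))
    e = np.clip(frag_starts[lo:hi] + fragment_bp - region.start, 0, len(region))
    np.add.at(depth, s, 1)
    np.add.at(depth, e, -1)
    return np.cumsum(depth[:-1])


def bh_adjust(pvalues: np.ndarray, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (qvalues, significance flags at ``q``)."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    m = len(p)
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return qvals, qvals <= q


def call_peaks(pool: TagLibrary, genome: GenomeIndex, config: CallerConfig | None = None) -> PeakSet:
    """Call peaks on a pooled library against a Poisson background."""
    config = config or CallerConfig()
    if len(genome) == 0:
        raise ValueError("empty genome index")
    if pool.n_tags == 0:
        logger.warning("zero-tag pool %r: returning empty peak set", pool.replicate_id)
        return PeakSet([], source=pool.replicate_id, caller_config=config)

    frags = fragment_starts(pool, config.fragment_bp)
    eff_span = config.window_bp + config.fragment_bp
    lam_global = pool.n_tags / genome.total_bp * eff_span

    window_rows = []  # (chrom, w_start, w_end, count, pvalue)
    for chrom in genome.chroms():
        clen = genome.length(chrom)
        fs = frags.get(chrom, np.empty(0, dtype=np.int64))
        w_starts = np.arange(0, clen, config.step_bp, dtype=np.int64)
        w_ends = np.minimum(w_starts + config.window_bp, clen)
        # fragment overlaps window iff its start lies in (w_start - L, w_end)
        counts = (
            np.searchsorted(fs, w_ends, side="left")
            - np.searchsorted(fs, w_starts - config.fragment_bp, side="right")
        )
        keep = counts >= config.min_tags
        if not keep.any():
            continue
        half = config.local_bg_bp // 2
        centers = (w_starts[keep] + w_ends[keep]) // 2
        lo = np.maximum(centers - half, 0)
        hi = np.minimum(centers + half, clen)
        local_counts = (
            np.searchsorted(fs, hi, side="left") - np.searchsorted(fs, lo, side="right")
        )
        # exclude the window's own fragments from the local expectation
        local_out = np.maximum(local_counts - counts[keep], 0)
        span_out = np.maximum((hi - lo) - eff_span, eff_span)
        lam_local = local_out / span_out * eff_span
        lam = np.maximum(lam_global, lam_local)
        pvals = stats.poisson.sf(counts[keep] - 1, lam)
        for ws, we, k, p in zip(w_starts[keep], w_ends[keep], counts[keep], pvals):
            window_rows.append((chrom, int(ws), int(we), int(k), float(p)))

    if not window_rows:
        return PeakSet([], source=pool.replicate_id, caller_config=config)

    pvals = np.array([r[4] for r in window_rows])
    qvals, sig = bh_adjust(pvals, q=config.fdr)

    peaks: list[Peak] = []
    sig_rows = [(r, q) for r, q, s in zip(window_rows, qvals, sig) if s]
    # merge overlapping significant windows into variable-width peaks
    clusters: list[list[tuple]] = []
    for row, q in sorted(sig_rows, key=lambda rq: (rq[0][0], rq[0][1])):
        if clusters and clusters[-1][-1][0][0] == row[0] and row[1] <= clusters[-1][-1][0][2]:
            clusters[-1].append((row, q))
        else:
            clusters.append([(row, q)])
    for cluster in clusters:
        chrom = cluster[0][0][0]
        start = cluster[0][0][1]
        end = max(r[0][2] for r in cluster)
        region = Interval(chrom, start, end)
        depth = pileup(frags.get(chrom, np.empty(0, dtype=np.int64)), config.fragment_bp, region)
        summit_off = int(np.argmax(depth))  # argmax is leftmost on ties
        height = float(depth[summit_off]) * 1e6 / pool.n_tags
        peaks.append(Peak(
            interval=region,
            summit=start + summit_off,
            height_rpm=height,
            pvalue=min(r[0][4] for r in cluster),
            qvalue=min(r[1] for r in cluster),
        ))
    return PeakSet(peaks, source=pool.replicate_id, caller_config=config)


def make_loo_pools(replicates: list[TagLibrary]) -> list[tuple[str, TagLibrary]]:
    """All leave-one-out pools: one per replicate, excluding that replicate."""
    if len(replicates) < 2:
        raise ValueError("SSI needs at least 2 replicates")
    out = []
    for i, excl in enumerate(replicates):
        rest = [lib for j, lib in enumerate(replicates) if j != i]
        pool = pool_libraries(rest, label=f"loo_minus_{excl.replicate_id}")
        out.append((excl.replicate_id, pool))
    return out


@dataclass
class SsiResult:
    retained: PeakSet
    removed: PeakSet
    removal_by_replicate: dict[str, int]       # failing-pool tally (multi counted per pool)
    sole_removal_by_replicate: dict[str, int]  # peaks whose ONLY failing pool excludes r
    match_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _matches(peak: Peak, other: PeakSet, match_rule: str, summit_dist_bp: int) -> bool:
    iv = peak.interval
    for o in other.peaks:
        if o.interval.chrom != iv.chrom:
            continue
        if match_rule == "overlap":
            if o.interval.start < iv.end and iv.start < o.interval.end:
                return True
        elif match_rule == "summit":
            if abs(o.summit - peak.summit) <= summit_dist_bp:
                return True
        else:
            raise ValueError(f"unknown match rule {match_rule!r}")
    return False


def ssi_filter(
    full_peaks: PeakSet,
    loo_peaksets: list[tuple[str, PeakSet]],
    match_rule: str = "overlap",
    summit_dist_bp: int = 100,
) -> SsiResult:
    """Retain a full-pool peak iff it matches a peak in EVERY leave-one-out set.

    ``loo_peaksets`` pairs each peak set with the replicate its pool excluded.
    The default match rule is >=1 bp interval overlap; ``match_rule='summit'``
    instead requires a summit within ``summit_dist_bp``.
    """
    if not loo_peaksets:
        raise ValueError("SSI filter needs at least one leave-one-out peak set")
    for _, ps in loo_peaksets:
        if (
            ps.caller_config is not None
            and full_peaks.caller_config is not None
            and ps.caller_config != full_peaks.caller_config
        ):
            logger.warning("leave-one-out peak set %r used a different caller config", ps.source)

    full = full_peaks.merged()
    loo = [(rid, ps.merged()) for rid, ps in loo_peaksets]

    retained, removed, rows = [], [], []
    removal = {rid: 0 for rid, _ in loo}
    sole = {rid: 0 for rid, _ in loo}
    for i, peak in enumerate(full.peaks):
        flags = {rid: _matches(peak, ps, match_rule, summit_dist_bp) for rid, ps in loo}
        failing = [rid for rid, ok in flags.items() if not ok]
        if failing:
            removed.append(peak)
            for rid in failing:
                removal[rid] += 1
            if len(failing) == 1:
                sole[failing[0]] += 1
        else:
            retained.append(peak)
        rows.append({
            "peak_id": f"peak_{i + 1}",
            "chrom": peak.interval.chrom,
            "start": peak.interval.start,
            "end": peak.interval.end,
            "retained": int(not failing),
            **{f"match_minus_{rid}": int(flags[rid]) for rid, _ in loo},
            "attributed_replicates": ",".join(failing),
        })
    return SsiResult(
        retained=PeakSet(retained, full.source + ":ssi_retained", full.caller_config),
        removed=PeakSet(removed, full.source + ":ssi_removed", full.caller_config),
        removal_by_replicate=removal,
        sole_removal_by_replicate=sole,
        match_table=pd.DataFrame(rows),
    )


@dataclass
class VennSummary:
    a_only: int
    b_only: int
    shared: int
    percent_overlap_union: float  # shared / (a_only + b_only + shared), merged regions
    frac_a_in_b: float
    frac_b_in_a: float


def compare_peak_sets(set_a: PeakSet, set_b: PeakSet) -> VennSummary:
    """Venn comparison of two peak sets by >=1 bp overlap.

    Counts are over the merged union regions (each labelled by which sets
    contributed); per-set shared fractions are also reported, since a Venn
    percentage depends on the chosen denominator.
    """
    union = merge_intervals(set_a.intervals() + set_b.intervals())
    from .core import overlaps_any

    in_a = overlaps_any(union, set_a.intervals())
    in_b = overlaps_any(union, set_b.intervals())
    shared = int((in_a & in_b).sum())
    a_only = int((in_a & ~in_b).sum())
    b_only = int((in_b & ~in_a).sum())
    total = max(a_only + b_only + shared, 1)
    frac_a = (
        float(overlaps_any(set_a.intervals(), set_b.intervals()).mean()) if len(set_a) else 0.0
    )
    frac_b = (
        float(overlaps_any(set_b.intervals(), set_a.intervals()).mean()) if len(set_b) else 0.0
    )
    return VennSummary(a_only, b_only, shared, 100.0 * shared / total, frac_a, frac_b)
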