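"""Consolidated binding regions, per-replicate quantification, and the
differential-binding test.

Peak calls from the two conditions are union-merged into one region set, and
every region is then quantified in every replicate of both conditions —
peak height (maximum fragment-depth inside the region, normalised to reads
per million) and raw overlapping tag count. Quantification depends only on
the tags, never on which condition produced the call: the absence of a call
in one condition is not evidence of differential binding.

Differential binding is tested per region with an exact two-sided binomial
test on pooled counts, conditioned on the total: under the null the fasted
share of a region's tags follows Binomial(n, N_f/(N_f+N_r)) with N the
summed library sizes. This is a self-contained stand-in for a negative-
binomial count model and is anti-conservative under biological
overdispersion; an optional moment-based inflation factor shrinks the
effective counts to compensate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval, TagLibrary, merge_intervals, overlaps_any
from .peaks import PeakSet, bh_adjust, fragment_starts, pileup

logger = logging.getLogger(__name__)

DEFAULT_HEIGHT_THRESHOLD_RPM = 0.35
DEFAULT_FRAGMENT_BP = 108
LOG2_PSEUDOCOUNT_RPM = 0.01


def region_height(region: Interval, lib: TagLibrary, fragment_bp: int = DEFAULT_FRAGMENT_BP,
                  _frags: np.ndarray | None = None) -> float:
    """Max fragment-stack depth inside ``region``, in reads per million."""
    if fragment_bp <= 0:
        raise ValueError("fragment_bp must be positive")
    if lib.n_tags == 0:
        logger.warning("empty library %r: height 0", lib.replicate_id)
        return 0.0
    fs = _frags if _frags is not None else fragment_starts(lib, fragment_bp).get(
        region.chrom, np.empty(0, dtype=np.int64)
    )
    depth = pileup(fs, fragment_bp, region)
    return float(depth.max()) * 1e6 / lib.n_tags


def count_tags(region: Interval, lib: TagLibrary, fragment_bp: int = DEFAULT_FRAGMENT_BP,
               _frags: np.ndarray | None = None) -> int:
    """Number of tags whose extended fragment overlaps ``region`` by >=1 bp."""
    fs = _frags if _frags is not None else fragment_starts(lib, fragment_bp).get(
        region.chrom, np.empty(0, dtype=np.int64)
    )
    lo = np.searchsorted(fs, region.start - fragment_bp, side="right")
    hi = np.searchsorted(fs, region.end, side="left")
    return int(hi - lo)


@dataclass
class ConsolidatedRegion:
    interval: Interval
    origin: str  # 'fasted-only' | 'refed-only' | 'both'
    heights_rpm: dict[tuple[str, str], float] = field(default_factory=dict)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    mean_rpm: dict[str, float] = field(default_factory=dict)
    sem_rpm: dict[str, float] = field(default_factory=dict)
    log2_ratio: float = 0.0
    avg_height: float = 0.0
    quartile: int | None = None


def _condition_stats(region: ConsolidatedRegion, conditions: tuple[str, str]) -> None:
    for cond in conditions:
        vals = np.array([v for (c, _), v in region.heights_rpm.items() if c == cond])
        region.mean_rpm[cond] = float(vals.mean()) if len(vals) else 0.0
        region.sem_rpm[cond] = (
            float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        )
    eps = LOG2_PSEUDOCOUNT_RPM
    region.log2_ratio = float(np.log2(
        (region.mean_rpm[conditions[0]] + eps) / (region.mean_rpm[conditions[1]] + eps)
    ))
    region.avg_height = 0.5 * (region.mean_rpm[conditions[0]] + region.mean_rpm[conditions[1]])


def merge_condition_peaks(
    fasted: PeakSet,
    refed: PeakSet,
    libs: list[TagLibrary],
    height_threshold: float = DEFAULT_HEIGHT_THRESHOLD_RPM,
    fragment_bp: int = DEFAULT_FRAGMENT_BP,
    conditions: tuple[str, str] = ("fasted", "refed"),
) -> list[ConsolidatedRegion]:
    """Union-merge the two call sets and quantify every region everywhere.

    Regions whose average height (mean of the two condition means) does not
    exceed ``height_threshold`` are dropped. ``origin`` records which call
    set(s) contributed, for diagnosing call-set asymmetry vs real asymmetry.
    """
    union = merge_intervals(fasted.intervals() + refed.intervals())
    if not union:
        return []
    in_f = overlaps_any(union, fasted.intervals())
    in_r = overlaps_any(union, refed.intervals())

    frag_cache = {
        (lib.condition, lib.replicate_id): fragment_starts(lib, fragment_bp) for lib in libs
    }
    regions: list[ConsolidatedRegion] = []
    for iv, f, r in zip(union, in_f, in_r):
        origin = "both" if (f and r) else (f"{conditions[0]}-only" if f else f"{conditions[1]}-only")
        reg = ConsolidatedRegion(interval=iv, origin=origin)
        for lib in libs:
            key = (lib.condition, lib.replicate_id)
            fs = frag_cache[key].get(iv.chrom, np.empty(0, dtype=np.int64))
            reg.heights_rpm[key] = region_height(iv, lib, fragment_bp, _frags=fs)
            reg.counts[key] = count_tags(iv, lib, fragment_bp, _frags=fs)
        _condition_stats(reg, conditions)
        if reg.avg_height > height_threshold:
            regions.append(reg)
    return regions


def differential_test(
    counts_fasted: np.ndarray,
    counts_refed: np.ndarray,
    libsizes_fasted: np.ndarray,
    libsizes_refed: np.ndarray,
    dispersion_inflation: float = 1.0,
) -> float:
    """Exact two-sided binomial test on pooled per-condition counts.

    ``dispersion_inflation`` >= 1 divides all counts before testing, a
    quasi-likelihood-style correction for overdispersion.
    """
    x_f = int(round(np.sum(counts_fasted) / dispersion_inflation))
    x_r = int(round(np.sum(counts_refed) / dispersion_inflation))
    if x_f + x_r == 0:
        logger.warning("all-zero counts: p-value 1")
        return 1.0
    n_f, n_r = float(np.sum(libsizes_fasted)), float(np.sum(libsizes_refed))
    return float(stats.binomtest(x_f, x_f + x_r, n_f / (n_f + n_r)).pvalue)


def estimate_dispersion_inflation(
    counts_fasted: np.ndarray, counts_refed: np.ndarray
) -> float:
    """Method-of-moments inflation: mean of per-condition variance/mean ratios.

    ``counts_*`` are (regions x replicates) matrices. Returns max(1, phi).
    """
    phis = []
    for mat in (np.atleast_2d(counts_fasted), np.atleast_2d(counts_refed)):
        if mat.shape[1] < 2:
            continue
        m = mat.mean(axis=1)
        v = mat.var(axis=1, ddof=1)
        ok = m > 0
        if ok.any():
            phis.append(float(np.median(v[ok] / m[ok])))
    return max(1.0, float(np.mean(phis))) if phis else 1.0


@dataclass
class DifferentialResult:
    pvalues: np.ndarray
    qvalues: np.ndarray
    significant: np.ndarray
    fdr: float


def differential_binding(
    regions: list[ConsolidatedRegion],
    libs: list[TagLibrary],
    fdr: float = 0.10,
    dispersion_inflation: float = 1.0,
    conditions: tuple[str, str] = ("fasted", "refed"),
) -> DifferentialResult:
    """Per-region differential test + BH correction at ``fdr``."""
    sizes = {c: np.array([lib.n_tags for lib in libs if lib.condition == c]) for c in conditions}
    pvals = np.empty(len(regions))
    for i, reg in enumerate(regions):
        cf = np.array([v for (c, _), v in reg.counts.items() if c == conditions[0]])
        cr = np.array([v for (c, _), v in reg.counts.items() if c == conditions[1]])
        pvals[i] = differential_test(
            cf, cr, sizes[conditions[0]], sizes[conditions[1]], dispersion_inflation
        )
    qvals, sig = bh_adjust(pvals, q=fdr)
    return DifferentialResult(pvals, qvals, sig, fdr)


def assign_quartiles(regions: list[ConsolidatedRegion]) -> list[int]:
    """Quartile (1..4, low to high avg_height) per region.

    Rank-based: ties broken by genomic coordinate, so every quartile size is
    within 1 of n/4 even for degenerate height distributions.
    """
    n = len(regions)
    if n < 4:
        logger.warning("fewer than 4 regions: single stratum")
        for r in regions:
            r.quartile = 1
        return [1] * n
    order = sorted(
        range(n),
        key=lambda i: (
            regions[i].avg_height,
            regions[i].interval.chrom,
            regions[i].interval.start,
            regions[i].interval.end,
        ),
    )
    labels = [0] * n
    for rank, i in enumerate(order):
        labels[i] = rank * 4 // n + 1
    for r, q in zip(regions, labels):
        r.quartile = q
    return labels


def group_height_summary(
    regions: list[ConsolidatedRegion], groups: list[str]
) -> pd.DataFrame:
    """Five-number summaries of avg_height and log2 ratio per group label."""
    if len(groups) != len(regions):
        raise ValueError("one group label per region required")
    df = pd.DataFrame({
        "group": groups,
        "avg_height": [r.avg_height for r in regions],
        "log2_ratio": [r.log2_ratio for r in regions],
    })
    rows = []
    for g, sub in df.groupby("group", sort=True):
        row = {"group": g, "n": len(sub)}
        for col in ("avg_height", "log2_ratio"):
            q = np.percentile(sub[col], [0, 25, 50, 75, 100])
            row.update({
                f"{col}_min": q[0], f"{col}_q1": q[1], f"{col}_median": q[2],
                f"{col}_q3": q[3], f"{col}_max": q[4],
            })
        rows.append(row)
    return pd.DataFrame(rows)


def regions_to_frame(
    regions: list[ConsolidatedRegion], conditions: tuple[str, str] = ("fasted", "refed")
) -> pd.DataFrame:
    """Flatten regions into the stage-output table (one row per region)."""
    rows = []
    for i, r in enumerate(regions):
        row = {
            "chrom": r.interval.chrom, "start": r.interval.start, "end": r.interval.end,
            "id": f"region_{i + 1}", "origin": r.origin,
        }
        for (cond, rep), h in sorted(r.heights_rpm.items()):
            row[f"height_{cond}_{rep}"] = h
        for (cond, rep), c in sorted(r.counts.items()):
            row[f"count_{cond}_{rep}"] = c
        for cond in conditions:
            row[f"mean_rpm_{cond}"] = r.mean_rpm.get(cond, 0.0)
            row[f"sem_rpm_{cond}"] = r.sem_rpm.get(cond, 0.0)
        row["log2_ratio"] = r.log2_ratio
        row["avg_height"] = r.avg_height
        row["quartile"] = r.quartile if r.quartile is not None else 0
        rows.append(row)
    return pd.DataFrame(rows)
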