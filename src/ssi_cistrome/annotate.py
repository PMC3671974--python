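"""TSS-relative annotation of binding sites, target-gene mapping, regulation
groups from a differential-expression table, enrichment statistics, and
average signal profiles around site groups.

Feature classes follow the standard promoter-centric scheme: a site whose
center lies 2 kb upstream to 200 bp downstream of any TSS (strand-relative)
is a promoter site; remaining sites are classified against 5'UTRs (beyond
+200 bp), coding exons, 3'UTRs and introns; everything else is intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeIndex, Interval, TagLibrary, Transcriptome
from .quantify import DEFAULT_FRAGMENT_BP, region_height
from .peaks import fragment_starts, pileup

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM_BP = 2_000
PROMOTER_DOWNSTREAM_BP = 200
INTERGENIC_TSS_WINDOW_BP = 50_000
TARGET_UPSTREAM_BP = 10_000


class FeatureClass(str, Enum):
    PROMOTER = "PROMOTER"
    FIVE_UTR = "FIVE_UTR"
    EXON_CDS = "EXON_CDS"
    INTRON = "INTRON"
    THREE_UTR = "THREE_UTR"
    INTERGENIC = "INTERGENIC"


@dataclass
class SiteAnnotation:
    feature: FeatureClass
    first_intron: bool = False
    within_50kb_tss: bool = False


def _in_five_utr(gene, pos: int) -> bool:
    if gene.cds_start is None:
        return False
    lo, hi = (gene.tx_start, gene.cds_start) if gene.strand == "+" else (gene.cds_end, gene.tx_end)
    if not (lo <= pos < hi):
        return False
    return any(e.start <= pos < e.end for e in gene.exons)


def _in_three_utr(gene, pos: int) -> bool:
    if gene.cds_start is None:
        return False
    lo, hi = (gene.cds_end, gene.tx_end) if gene.strand == "+" else (gene.tx_start, gene.cds_start)
    if not (lo <= pos < hi):
        return False
    return any(e.start <= pos < e.end for e in gene.exons)


def _in_cds_exon(gene, pos: int) -> bool:
    if gene.cds_start is None:
        return False
    if not (gene.cds_start <= pos < gene.cds_end):
        return False
    return any(e.start <= pos < e.end for e in gene.exons)


def _containing_intron(gene, pos: int):
    for i, intron in enumerate(gene.introns()):
        if intron.start <= pos < intron.end:
            fi = gene.first_intron()
            return True, fi is not None and intron == fi
    return False, False


def classify_site(
    chrom: str,
    center: int,
    transcriptome: Transcriptome,
    priority: str = "exon_first",
) -> SiteAnnotation:
    """Feature class for one site center.

    ``priority='exon_first'`` ranks PROMOTER > FIVE_UTR > EXON_CDS >
    THREE_UTR > INTRON, so exonic overlap of one transcript beats intronic
    overlap of another; ``priority='intron_first'`` uses the literal
    intron-before-exon ordering instead.
    """
    if len(transcriptome) == 0:
        raise ValueError("empty transcriptome")
    genes = [g for g in transcriptome.genes if g.chrom == chrom]
    in_promoter = in_5utr = in_cds = in_3utr = False
    in_intron = in_first_intron = False
    for g in genes:
        d = g.signed_distance(center)
        if -PROMOTER_UPSTREAM_BP <= d <= PROMOTER_DOWNSTREAM_BP:
            in_promoter = True
        if g.tx_start <= center < g.tx_end:
            if d > PROMOTER_DOWNSTREAM_BP and _in_five_utr(g, center):
                in_5utr = True
            if _in_cds_exon(g, center):
                in_cds = True
            if _in_three_utr(g, center):
                in_3utr = True
            hit, first = _containing_intron(g, center)
            in_intron |= hit
            in_first_intron |= first

    if priority == "exon_first":
        ranked = [
            (in_promoter, FeatureClass.PROMOTER), (in_5utr, FeatureClass.FIVE_UTR),
            (in_cds, FeatureClass.EXON_CDS), (in_3utr, FeatureClass.THREE_UTR),
            (in_intron, FeatureClass.INTRON),
        ]
    elif priority == "intron_first":
        ranked = [
            (in_promoter, FeatureClass.PROMOTER), (in_intron, FeatureClass.INTRON),
            (in_cds, FeatureClass.EXON_CDS), (in_5utr, FeatureClass.FIVE_UTR),
            (in_3utr, FeatureClass.THREE_UTR),
        ]
    else:
        raise ValueError(f"unknown priority mode {priority!r}")
    for flag, feat in ranked:
        if flag:
            return SiteAnnotation(
                feature=feat, first_intron=(feat == FeatureClass.INTRON and in_first_intron)
            )
    _, dist = transcriptome.nearest_tss(chrom, center)
    gene, _ = transcriptome.nearest_tss(chrom, center)
    within = gene is not None and abs(dist) <= INTERGENIC_TSS_WINDOW_BP
    return SiteAnnotation(feature=FeatureClass.INTERGENIC, within_50kb_tss=within)


def classify_site_regulatory(chrom: str, center: int, transcriptome: Transcriptome) -> str:
    """Independent scheme: proximal / distal promoter, intronic, exonic, other."""
    genes = [g for g in transcriptome.genes if g.chrom == chrom]
    proximal = distal = intronic = exonic = False
    for g in genes:
        d = g.signed_distance(center)
        if -PROMOTER_UPSTREAM_BP <= d <= PROMOTER_DOWNSTREAM_BP:
            proximal = True
        elif -TARGET_UPSTREAM_BP <= d < -PROMOTER_UPSTREAM_BP:
            distal = True
        if g.tx_start <= center < g.tx_end:
            if any(e.start <= center < e.end for e in g.exons):
                exonic = True
            elif _containing_intron(g, center)[0]:
                intronic = True
    for flag, name in [(proximal, "proximal"), (distal, "distal"),
                       (intronic, "intronic"), (exonic, "exonic")]:
        if flag:
            return name
    return "other"


def tss_distance_profile(
    sites: list[Interval], transcriptome: Transcriptome,
    flank_bp: int = 50_000, bin_bp: int = 500,
) -> pd.DataFrame:
    """Histogram of signed strand-relative nearest-TSS distances."""
    dists = [transcriptome.nearest_tss(iv.chrom, iv.center)[1] for iv in sites]
    edges = np.arange(-flank_bp, flank_bp + bin_bp, bin_bp)
    counts, _ = np.histogram(np.clip(dists, -flank_bp, flank_bp - 1), bins=edges)
    return pd.DataFrame({
        "bin_center": (edges[:-1] + edges[1:]) / 2.0,
        "frequency": counts / max(len(sites), 1),
    })


# -- target-gene mapping -----------------------------------------------------

def map_targets(
    sites: list[Interval],
    transcriptome: Transcriptome,
    upstream_bp: int = TARGET_UPSTREAM_BP,
) -> pd.DataFrame:
    """Bipartite site-gene links: site center within ``upstream_bp`` upstream
    of a TSS or anywhere in the gene body (strand-relative).

    Returns a frame with columns site_index, gene_symbol; one site may link
    several genes and vice versa.
    """
    rows = []
    for i, iv in enumerate(sites):
        center = iv.center
        linked = set()
        for g in transcriptome.genes:
            if g.chrom != iv.chrom:
                continue
            d = g.signed_distance(center)
            in_body = g.tx_start <= center < g.tx_end
            if in_body or -upstream_bp <= d < 0:
                linked.add(g.gene_symbol)
        for sym in sorted(linked):
            rows.append({"site_index": i, "gene_symbol": sym})
    return pd.DataFrame(rows, columns=["site_index", "gene_symbol"])


def sites_per_gene(links: pd.DataFrame, all_genes: list[str]) -> pd.Series:
    counts = links.groupby("gene_symbol")["site_index"].nunique() if len(links) else pd.Series(dtype=int)
    return counts.reindex(sorted(set(all_genes)), fill_value=0).astype(int)


# -- regulation groups --------------------------------------------------------

class RegulationGroup(str, Enum):
    INDUCED = "INDUCED"
    REPRESSED = "REPRESSED"
    NO_CHANGE = "NO_CHANGE"
    UNASSIGNED = "UNASSIGNED"


def assign_regulation_groups(
    n_sites: int,
    links: pd.DataFrame,
    de_table: pd.DataFrame,
) -> tuple[list[RegulationGroup], dict]:
    """Partition sites by the expression response of their linked genes.

    Precedence for multi-gene sites: INDUCED > REPRESSED > NO_CHANGE;
    sites with no link, or links only to unmeasured genes, are UNASSIGNED.
    Returns (groups, diagnostics) where diagnostics counts up/down conflicts
    and links to genes absent from the DE table.
    """
    direction = dict(zip(de_table["gene"], de_table["direction"]))
    measured = dict(zip(de_table["gene"], de_table["measured"].astype(bool)))
    groups: list[RegulationGroup] = []
    diagnostics = {"conflicts_up_down": 0, "links_to_unknown_genes": 0}
    linked = {i: [] for i in range(n_sites)}
    for _, row in links.iterrows():
        linked[int(row.site_index)].append(row.gene_symbol)
    for i in range(n_sites):
        has_up = has_down = has_measured = False
        for sym in linked[i]:
            if sym not in direction:
                diagnostics["links_to_unknown_genes"] += 1
                continue
            if measured.get(sym, False):
                has_measured = True
            if direction[sym] == "up":
                has_up = True
            elif direction[sym] == "down":
                has_down = True
        if has_up and has_down:
            diagnostics["conflicts_up_down"] += 1
        if has_up:
            groups.append(RegulationGroup.INDUCED)
        elif has_down:
            groups.append(RegulationGroup.REPRESSED)
        elif has_measured:
            groups.append(RegulationGroup.NO_CHANGE)
        else:
            groups.append(RegulationGroup.UNASSIGNED)
    return groups, diagnostics


# -- enrichment ----------------------------------------------------------------

@dataclass
class EnrichmentResult:
    table: np.ndarray
    odds_ratio: float
    pvalue: float


def fisher_exact(table) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    Two-sided by summing hypergeometric probabilities no larger than the
    observed table's; odds ratio ad/bc (inf at zero off-diagonal margins).
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    (a, b), (c, d) = arr
    odds = np.inf if b * c == 0 else a * d / (b * c)
    if a * d == 0 and b * c == 0:
        odds = np.nan
    p = float(stats.fisher_exact(arr)[1])
    return EnrichmentResult(arr, float(odds), p)


def gene_level_enrichment(
    de_table: pd.DataFrame,
    gene_site_counts: pd.Series,
) -> pd.DataFrame:
    """Per-category percentages of genes with 1 / 2 / 3+ sites, with a Fisher
    test of bound-vs-unbound in each DE category against all measured genes.
    """
    measured = de_table[de_table["measured"] == 1]
    cats = {
        "up": measured.loc[measured["direction"] == "up", "gene"],
        "down": measured.loc[measured["direction"] == "down", "gene"],
        "regulated": measured.loc[measured["direction"].isin(["up", "down"]), "gene"],
        "all": measured["gene"],
    }
    counts_all = gene_site_counts.reindex(cats["all"], fill_value=0)
    bound_all, n_all = int((counts_all >= 1).sum()), len(counts_all)
    rows = []
    for cat, genes in cats.items():
        if len(genes) == 0:
            continue
        counts = gene_site_counts.reindex(genes, fill_value=0)
        n = len(counts)
        row = {
            "category": cat, "n_genes": n,
            "pct_1_site": 100.0 * (counts == 1).mean(),
            "pct_2_sites": 100.0 * (counts == 2).mean(),
            "pct_3plus_sites": 100.0 * (counts >= 3).mean(),
            "pct_bound": 100.0 * (counts >= 1).mean(),
        }
        if cat != "all":
            bound = int((counts >= 1).sum())
            other_bound = bound_all - bound
            other_n = n_all - n
            res = fisher_exact([[bound, n - bound], [other_bound, other_n - other_bound]])
            row["fisher_p_vs_all"] = res.pvalue
        else:
            row["fisher_p_vs_all"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def crosstab_tata_creb(
    genes: list[str],
    tata_flags: dict[str, bool],
    bound_flags: dict[str, bool],
    de_table: pd.DataFrame,
) -> pd.DataFrame:
    """Four groups (bound x TATA) with induced/repressed percentages and a
    Fisher test of each group's regulation rate against the unbound/TATA-less
    reference group.
    """
    direction = dict(zip(de_table["gene"], de_table["direction"]))
    measured = set(de_table.loc[de_table["measured"] == 1, "gene"])
    frame = pd.DataFrame({
        "gene": [g for g in genes if g in measured],
    })
    frame["bound"] = frame["gene"].map(lambda g: bool(bound_flags.get(g, False)))
    frame["tata"] = frame["gene"].map(lambda g: bool(tata_flags.get(g, False)))
    frame["dir"] = frame["gene"].map(lambda g: direction.get(g, "none"))
    ref = frame[(~frame["bound"]) & (~frame["tata"])]
    rows = []
    for bound in (False, True):
        for tata in (False, True):
            sub = frame[(frame["bound"] == bound) & (frame["tata"] == tata)]
            if len(sub) == 0:
                continue
            row = {
                "group": f"CREB{'+' if bound else '-'}/TATA{'+' if tata else '-'}",
                "n_genes": len(sub),
                "pct_induced": 100.0 * (sub["dir"] == "up").mean(),
                "pct_repressed": 100.0 * (sub["dir"] == "down").mean(),
            }
            for direction_name, key in (("up", "fisher_p_induced"), ("down", "fisher_p_repressed")):
                if bound or tata:
                    if len(ref) == 0:
                        row[key] = float("nan")
                        continue
                    de_g = int((sub["dir"] == direction_name).sum())
                    de_r = int((ref["dir"] == direction_name).sum())
                    res = fisher_exact([
                        [de_g, len(sub) - de_g], [de_r, len(ref) - de_r]
                    ])
                    row[key] = res.pvalue
                else:
                    row[key] = 1.0
            rows.append(row)
    return pd.DataFrame(rows)


# -- average profiles ----------------------------------------------------------

@dataclass
class ProfileMatrix:
    group: str
    offsets: np.ndarray       # bin centers relative to anchor center (bp)
    mean_rpm: np.ndarray      # mean fragment depth per bin, RPM-scaled
    n_anchors: int


def average_profile(
    anchor_groups: dict[str, list[Interval]],
    libs: list[TagLibrary],
    genome: GenomeIndex,
    flank_bp: int = 2_000,
    bin_bp: int = 25,
    fragment_bp: int = DEFAULT_FRAGMENT_BP,
) -> dict[str, ProfileMatrix]:
    """RPM fragment-depth profile around anchor centers, averaged per group.

    Anchors whose window is truncated by a chromosome edge contribute only
    to the bins they cover (per-bin denominators).
    """
    pool_tags = sum(lib.n_tags for lib in libs)
    frags: dict[str, np.ndarray] = {}
    for lib in libs:
        for chrom, fs in fragment_starts(lib, fragment_bp).items():
            frags[chrom] = np.sort(np.concatenate([frags.get(chrom, np.empty(0, dtype=np.int64)), fs]))
    n_bins = (2 * flank_bp) // bin_bp
    offsets = -flank_bp + bin_bp * (np.arange(n_bins) + 0.5)
    out = {}
    for group, anchors in anchor_groups.items():
        total = np.zeros(n_bins)
        denom = np.zeros(n_bins)
        for iv in anchors:
            center = iv.center
            lo, hi = center - flank_bp, center + flank_bp
            clo, chi = max(lo, 0), min(hi, genome.length(iv.chrom))
            if chi <= clo:
                continue
            depth = pileup(
                frags.get(iv.chrom, np.empty(0, dtype=np.int64)),
                fragment_bp, Interval(iv.chrom, clo, chi),
            )
            full = np.zeros(2 * flank_bp)
            cover = np.zeros(2 * flank_bp, dtype=bool)
            full[clo - lo:chi - lo] = depth
            cover[clo - lo:chi - lo] = True
            binned = full[: n_bins * bin_bp].reshape(n_bins, bin_bp)
            covered = cover[: n_bins * bin_bp].reshape(n_bins, bin_bp).all(axis=1)
            total[covered] += binned.mean(axis=1)[covered]
            denom[covered] += 1
        mean = np.divide(total, denom, out=np.zeros(n_bins), where=denom > 0)
        scale = 1e6 / pool_tags if pool_tags else 0.0
        out[group] = ProfileMatrix(group, offsets, mean * scale, len(anchors))
    return out


def secondary_heights(
    anchors: list[Interval],
    libs: list[TagLibrary],
    fragment_bp: int = DEFAULT_FRAGMENT_BP,
) -> np.ndarray:
    """Per-anchor peak height (RPM) of a secondary factor's pooled signal,
    computed exactly as the primary factor's region heights are.
    """
    from .core import pool_libraries
    pool = pool_libraries(libs, label="secondary_pool") if len(libs) > 1 else libs[0]
    frags = fragment_starts(pool, fragment_bp)
    return np.array([
        region_height(iv, pool, fragment_bp,
                      _frags=frags.get(iv.chrom, np.empty(0, dtype=np.int64)))
        for iv in anchors
    ])
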