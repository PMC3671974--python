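"""Seeded generator of a complete synthetic two-condition ChIP-seq study.

Emulates the statistical structure the pipeline assumes: a small random
genome; a transcriptome with a configurable fraction of TATA-containing
promoters; five biological replicates per condition of deduplicated tag
libraries with constitutively bound sites carrying a weak global condition
effect (median 1.3-fold by default); replicate-specific artifact sites whose
tags come from exactly one replicate (the case the SSI filter exists to
remove); CRE motif content planted per site; a differential-expression
table with planted site-gene associations; and a secondary transcription
factor whose binding concentrates at sites linked to induced genes.

Everything emitted is a pure function of (config, seed), and every planted
object is recorded in a TruthSet recoverable from the emitted files alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GeneModel, GenomeIndex, Interval, TagLibrary, Transcriptome, make_tags
from .motifs import CRE_OCTAMER, MotifClass, classify_cre, revcomp, tata_pwm

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# minimum gap between transcription units; exceeds the 10 kb upstream
# target-window reach plus the 2 kb promoter span, so planted site-gene
# links are unambiguous
TARGET_GAP_MIN_BP = 13_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the design the pipeline targets: 5+5 replicates, 200
    constitutively bound sites with a median 1.3-fold condition effect, 20
    single-replicate artifacts, ~20% TATA promoters, DE calls at |FC|>=1.5,
    108 bp fragments, and 60%-vs-33% bound-gene rates for regulated vs all
    genes.
    """

    n_chroms: int = 2
    chrom_bp: int = 1_000_000
    n_genes: int = 180
    frac_tata: float = 0.20
    n_true_sites: int = 200
    n_artifact_sites: int = 20
    artifact_owners: list | None = None  # [(condition, replicate_id), ...] or round-robin
    n_replicates: int = 5
    enrichment_fold: float = 10.0
    global_fold_median: float = 1.3
    fold_sigma_log2: float = 0.25
    frac_de_genes: float = 0.40
    de_fold_min: float = 1.5
    frac_measured: float = 0.90
    frac_de_bound: float = 0.60
    frac_bg_bound: float = 0.33
    depth_per_replicate: int = 100_000
    fragment_bp: int = 108
    motif_mix: tuple = (0.5, 0.3, 0.2)  # fractions full / half / none
    min_site_spacing_bp: int = 1_000
    edge_margin_bp: int = 3_000
    secondary_depth: int = 100_000
    secondary_enrichment_fold: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for frac in (self.frac_tata, self.frac_de_genes, self.frac_measured,
                     self.frac_de_bound, self.frac_bg_bound, *self.motif_mix):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.motif_mix) - 1) > 1e-9:
            raise ValueError("motif_mix must sum to 1")
        if self.depth_per_replicate <= 0 or self.secondary_depth <= 0:
            raise ValueError("depths must be positive")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def replicate_ids(self) -> list[str]:
        return [f"rep{i + 1}" for i in range(self.n_replicates)]


@dataclass
class TruthSet:
    sites: pd.DataFrame   # site_id, chrom, center, kind, fold_log2, motif_class, owner_*, linked_gene
    genes: pd.DataFrame   # gene, chrom, strand, tss, tata_planted, de_direction, log2fc, measured, n_planted_sites


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: GenomeIndex
    sequences: dict[str, str]
    genes: list[GeneModel]
    transcriptome: Transcriptome
    libraries: list[TagLibrary]          # n_replicates per condition
    secondary_library: TagLibrary
    de_table: pd.DataFrame
    truth: TruthSet


# -- transcriptome layout -----------------------------------------------------

def simulate_transcriptome(config: SimulationConfig, rng: np.random.Generator
                           ) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place non-overlapping genes (2-8 exons) and choose the TATA subset.

    Genes are laid out as tail-facing (+,-) pairs separated by >=13 kb shared
    upstream gaps, so no gene's 10 kb-upstream target window reaches into a
    neighbouring transcription unit: a site planted at one gene links to that
    gene alone, keeping the planted bound-gene rates exact.
    Returns (gene models, per-gene truth frame).
    """
    def build_gene(chrom: str, pos: int, strand: str, n_placed: int) -> GeneModel:
        n_exons = int(rng.integers(2, 9))
        exon_lens = rng.integers(80, 300, size=n_exons)
        intron_lens = rng.integers(100, 800, size=n_exons - 1)
        exons, cursor = [], pos
        for i in range(n_exons):
            exons.append(Interval(chrom, cursor, cursor + int(exon_lens[i])))
            cursor += int(exon_lens[i])
            if i < n_exons - 1:
                cursor += int(intron_lens[i])
        cds_start = exons[0].start + int(rng.integers(10, max(exon_lens[0] - 10, 11)))
        cds_end = exons[-1].end - int(rng.integers(10, max(exon_lens[-1] - 10, 11)))
        return GeneModel(
            gene_symbol=f"gene{n_placed + 1}", transcript_id=f"tx{n_placed + 1}",
            chrom=chrom, strand=strand, tx_start=pos, tx_end=cursor, exons=exons,
            cds_start=cds_start, cds_end=max(cds_end, cds_start + 3),
        )

    genes: list[GeneModel] = []
    n_placed = 0
    for chrom in config.chrom_names:
        pos = config.edge_margin_bp + TARGET_GAP_MIN_BP
        limit = config.chrom_bp - config.edge_margin_bp
        while n_placed < config.n_genes:
            g_plus = build_gene(chrom, pos, "+", n_placed)
            inner = int(rng.integers(800, 1500))
            g_minus = build_gene(chrom, g_plus.tx_end + inner, "-", n_placed + 1)
            gap = int(rng.integers(TARGET_GAP_MIN_BP, TARGET_GAP_MIN_BP + 3000))
            if g_minus.tx_end + gap >= limit:
                break
            genes.extend([g_plus, g_minus][: config.n_genes - n_placed])
            n_placed = len(genes)
            pos = g_minus.tx_end + gap
    if n_placed < config.n_genes:
        raise ValueError(
            f"genome capacity exceeded: placed {n_placed} of {config.n_genes} genes"
        )
    tata = rng.random(len(genes)) < config.frac_tata
    frame = pd.DataFrame({
        "gene": [g.gene_symbol for g in genes],
        "chrom": [g.chrom for g in genes],
        "strand": [g.strand for g in genes],
        "tss": [g.tss for g in genes],
        "tata_planted": tata.astype(int),
    })
    return genes, frame


# -- differential expression and site placement -------------------------------

def _choose_de(config: SimulationConfig, rng, gene_frame: pd.DataFrame) -> pd.DataFrame:
    n = len(gene_frame)
    de = rng.random(n) < config.frac_de_genes
    up = rng.random(n) < 0.5
    direction = np.where(de, np.where(up, "up", "down"), "none")
    mag = np.log2(config.de_fold_min) + rng.exponential(0.5, size=n)
    null_fc = rng.normal(0.0, 0.3, size=n)
    null_fc = np.clip(null_fc, -np.log2(config.de_fold_min) * 0.95,
                      np.log2(config.de_fold_min) * 0.95)
    log2fc = np.where(de, np.where(up, mag, -mag), null_fc)
    measured = rng.random(n) < config.frac_measured
    out = gene_frame.copy()
    out["de_direction"] = direction
    out["log2fc"] = log2fc
    out["measured"] = measured.astype(int)
    # an unmeasured gene cannot carry a DE call
    out.loc[out["measured"] == 0, "de_direction"] = "none"
    return out


def _site_ok(center: int, chrom: str, placed: dict[str, list[int]],
             config: SimulationConfig, chrom_len: int) -> bool:
    if not (config.edge_margin_bp <= center < chrom_len - config.edge_margin_bp):
        return False
    return all(abs(center - c) >= config.min_site_spacing_bp for c in placed.get(chrom, []))


def simulate_sites(config: SimulationConfig, rng, genes: list[GeneModel],
                   gene_frame: pd.DataFrame) -> pd.DataFrame:
    """Plant true binding sites: per-gene Bernoulli placement at the
    configured bound rates (DE genes vs others), then intergenic sites
    appended up to ``n_true_sites``, then single-replicate artifact sites.
    """
    placed: dict[str, list[int]] = {}
    rows = []
    de_dirs = dict(zip(gene_frame["gene"], gene_frame["de_direction"]))
    owners_cycle = config.artifact_owners or [
        (cond, rep)
        for rep in config.replicate_ids
        for cond in ("fasted", "refed")
    ]

    def add_site(chrom, center, kind, linked_gene="", owner=("", "")):
        placed.setdefault(chrom, []).append(center)
        rows.append({
            "site_id": f"site{len(rows) + 1}", "chrom": chrom, "center": center,
            "kind": kind, "linked_gene": linked_gene,
            "owner_condition": owner[0], "owner_replicate": owner[1],
        })

    for g in genes:
        is_de = de_dirs[g.gene_symbol] in ("up", "down")
        p_bound = config.frac_de_bound if is_de else config.frac_bg_bound
        if rng.random() >= p_bound:
            continue
        n_sites = 1 + rng.poisson(0.35)
        for _ in range(n_sites):
            for _attempt in range(50):
                if rng.random() < 0.7:  # proximal promoter, else gene body
                    d = int(rng.integers(-2000, 201))
                else:
                    d = int(rng.integers(0, g.tx_end - g.tx_start))
                center = g.tss + d if g.strand == "+" else g.tss - d
                if _site_ok(center, g.chrom, placed, config, config.chrom_bp):
                    add_site(g.chrom, center, "true", linked_gene=g.gene_symbol)
                    break

    # intergenic top-up: outside every gene's target window
    windows: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        lo = g.tx_start - (10_000 if g.strand == "+" else 0)
        hi = g.tx_end + (10_000 if g.strand == "-" else 0)
        windows.setdefault(g.chrom, []).append((lo, hi))
    n_true = sum(1 for r in rows if r["kind"] == "true")
    attempts = 0
    while n_true < config.n_true_sites and attempts < 100_000:
        attempts += 1
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        center = int(rng.integers(config.edge_margin_bp,
                                  config.chrom_bp - config.edge_margin_bp))
        if any(lo <= center < hi for lo, hi in windows.get(chrom, [])):
            continue
        if _site_ok(center, chrom, placed, config, config.chrom_bp):
            add_site(chrom, center, "true")
            n_true += 1

    for i in range(config.n_artifact_sites):
        owner = owners_cycle[i % len(owners_cycle)]
        for _attempt in range(100_000):
            chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
            center = int(rng.integers(config.edge_margin_bp,
                                      config.chrom_bp - config.edge_margin_bp))
            if _site_ok(center, chrom, placed, config, config.chrom_bp):
                add_site(chrom, center, "artifact", owner=owner)
                break

    sites = pd.DataFrame(rows)
    is_true = sites["kind"] == "true"
    fold = np.zeros(len(sites))
    fold[is_true.to_numpy()] = rng.normal(
        np.log2(config.global_fold_median), config.fold_sigma_log2, size=int(is_true.sum())
    )
    sites["fold_log2"] = fold
    mix = np.asarray(config.motif_mix)
    classes = np.array([MotifClass.FULL_CRE.value, MotifClass.HALF_CRE.value,
                        MotifClass.NON_CRE.value], dtype=object)
    motif = np.full(len(sites), MotifClass.NON_CRE.value, dtype=object)
    motif[is_true.to_numpy()] = rng.choice(classes, size=int(is_true.sum()), p=mix)
    sites["motif_class"] = motif
    return sites


# -- genome sequence ----------------------------------------------------------

def _random_bases(rng, n: int) -> bytes:
    return _BASES[rng.integers(0, 4, size=n)].tobytes()


def _plant_cre_window(rng, target: MotifClass, width: int = 100) -> bytes:
    """A random window whose CRE classification equals ``target`` exactly.

    Rejection-resamples until the classifier agrees, so planted motif
    content is exact rather than approximate (chance half-CRE matches are
    common in uniform sequence).
    """
    for _ in range(200):
        window = bytearray(_random_bases(rng, width))
        if target == MotifClass.FULL_CRE:
            octamer = list(CRE_OCTAMER)
            if rng.random() < 0.5:  # single-mismatch variant
                i = int(rng.integers(8))
                octamer[i] = rng.choice([b for b in "ACGT" if b != octamer[i]])
            off = int(rng.integers(width - 8 + 1))
            window[off:off + 8] = "".join(octamer).encode()
        elif target == MotifClass.HALF_CRE:
            half = "TGACG" if rng.random() < 0.5 else "CGTCA"
            off = int(rng.integers(width - 5 + 1))
            window[off:off + 5] = half.encode()
        if classify_cre(window.decode()) == target:
            return bytes(window)
    raise RuntimeError("failed to construct a window of the requested CRE class")


def simulate_genome(config: SimulationConfig, rng, genes: list[GeneModel],
                    gene_frame: pd.DataFrame, sites: pd.DataFrame
                    ) -> tuple[dict[str, str], GenomeIndex]:
    """Uniform random sequence with CRE windows planted at true-site centers
    and the TATA consensus planted 25-35 bp upstream of flagged TSSs."""
    seqs = {c: bytearray(_random_bases(rng, config.chrom_bp)) for c in config.chrom_names}
    for _, site in sites.iterrows():
        if site["kind"] != "true":
            continue
        window = _plant_cre_window(rng, MotifClass(site["motif_class"]))
        c = int(site["center"])
        seqs[site["chrom"]][c - 50:c + 50] = window
    consensus = tata_pwm().consensus
    tata_lookup = dict(zip(gene_frame["gene"], gene_frame["tata_planted"]))
    for g in genes:
        if not tata_lookup[g.gene_symbol]:
            continue
        d = int(rng.integers(25, 36))  # motif start, bp upstream of TSS
        motif = consensus if g.strand == "+" else revcomp(consensus)
        if g.strand == "+":
            start = g.tss - d - len(consensus) + 1
        else:
            start = g.tss + d
        seqs[g.chrom][start:start + len(consensus)] = motif.encode()
    genome = GenomeIndex({c: config.chrom_bp for c in config.chrom_names})
    return {c: s.decode() for c, s in seqs.items()}, genome


# -- tag libraries ------------------------------------------------------------

def _encode(chrom_idx, pos, strand_bit, chrom_bp):
    return ((chrom_idx.astype(np.int64) * chrom_bp + pos) << 1) | strand_bit


def _decode(codes, chrom_names, chrom_bp):
    strand = np.where(codes & 1, "-", "+")
    rest = codes >> 1
    chrom_idx = rest // chrom_bp
    pos = rest % chrom_bp
    return np.array(chrom_names, dtype=object)[chrom_idx], pos, strand


def _site_tag_codes(rng, chrom_idx: int, center: int, n: int,
                    fragment_bp: int, chrom_bp: int) -> np.ndarray:
    """Draw up to ``n`` distinct site tags: + 5' ends uniform on
    [center-L, center), mirrored on -, sampled without replacement."""
    n_slots = 2 * fragment_bp
    n = min(n, n_slots)
    slots = rng.choice(n_slots, size=n, replace=False)
    plus = slots < fragment_bp
    pos = np.where(plus, center - fragment_bp + slots, center + slots - fragment_bp)
    strand_bit = (~plus).astype(np.int64)
    return _encode(np.full(n, chrom_idx), pos.astype(np.int64), strand_bit, chrom_bp)


def _background_codes(rng, n: int, existing: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Exactly ``n`` uniform background tags distinct from each other and
    from ``existing`` (top-up redraw after deduplication)."""
    existing_sorted = np.sort(existing)
    out: list[np.ndarray] = []
    have = 0
    while have < n:
        m = int((n - have) * 1.05) + 16
        chrom_idx = rng.integers(0, config.n_chroms, size=m)
        pos = rng.integers(0, config.chrom_bp, size=m)
        strand_bit = rng.integers(0, 2, size=m)
        codes = np.unique(_encode(chrom_idx, pos, strand_bit, config.chrom_bp))
        idx = np.searchsorted(existing_sorted, codes)
        idx = np.clip(idx, 0, len(existing_sorted) - 1) if len(existing_sorted) else idx
        fresh = codes if not len(existing_sorted) else codes[existing_sorted[idx] != codes]
        for prev in out:
            fresh = np.setdiff1d(fresh, prev, assume_unique=True)
        take = fresh[: n - have]
        out.append(take)
        have += len(take)
    return np.concatenate(out)


def simulate_chip_replicates(config: SimulationConfig, rng, sites: pd.DataFrame
                             ) -> list[TagLibrary]:
    """Five fasted + five re-fed deduplicated tag libraries.

    Per true site and replicate, tag numbers are Poisson with rate
    enrichment_fold x background-density x fragment length, scaled by the
    site's condition fold (split symmetrically between conditions so the
    fasted/re-fed ratio equals the fold). Artifact sites contribute tags
    only in their owning (condition, replicate), at a rate equivalent to a
    fully replicated site, and nothing anywhere else. Background tags top
    each library up to exactly ``depth_per_replicate``.
    """
    bg_rate = config.depth_per_replicate / (config.n_chroms * config.chrom_bp)
    lam_site = config.enrichment_fold * bg_rate * config.fragment_bp
    # one replicate supplies what all replicates together would at a true site
    lam_artifact = lam_site * config.n_replicates
    chrom_index = {c: i for i, c in enumerate(config.chrom_names)}
    libs = []
    for cond in ("fasted", "refed"):
        for rep in config.replicate_ids:
            codes = []
            for _, site in sites.iterrows():
                ci = chrom_index[site["chrom"]]
                if site["kind"] == "true":
                    mult = 2.0 ** (site["fold_log2"] / 2.0)
                    lam = lam_site * (mult if cond == "fasted" else 1.0 / mult)
                    n = rng.poisson(lam)
                elif (site["owner_condition"], site["owner_replicate"]) == (cond, rep):
                    n = rng.poisson(lam_artifact)
                else:
                    continue
                if n:
                    codes.append(_site_tag_codes(
                        rng, ci, int(site["center"]), int(n),
                        config.fragment_bp, config.chrom_bp,
                    ))
            site_codes = np.unique(np.concatenate(codes)) if codes else np.empty(0, np.int64)
            n_bg = config.depth_per_replicate - len(site_codes)
            if n_bg < 0:
                raise ValueError("site tags exceed configured depth")
            bg = _background_codes(rng, n_bg, site_codes, config)
            all_codes = np.sort(np.concatenate([site_codes, bg]))
            chrom, pos, strand = _decode(all_codes, config.chrom_names, config.chrom_bp)
            libs.append(TagLibrary(make_tags(chrom, pos, strand),
                                   replicate_id=rep, condition=cond))
    return libs


def simulate_secondary_factor(config: SimulationConfig, rng, sites: pd.DataFrame,
                              gene_frame: pd.DataFrame) -> TagLibrary:
    """A co-localising factor bound only at sites linked to induced genes."""
    de_dirs = dict(zip(gene_frame["gene"], gene_frame["de_direction"]))
    bg_rate = config.secondary_depth / (config.n_chroms * config.chrom_bp)
    lam = (config.secondary_enrichment_fold * bg_rate * config.fragment_bp
           * config.n_replicates)
    chrom_index = {c: i for i, c in enumerate(config.chrom_names)}
    codes = []
    for _, site in sites.iterrows():
        if site["kind"] != "true" or de_dirs.get(site["linked_gene"], "none") != "up":
            continue
        n = rng.poisson(lam)
        if n:
            codes.append(_site_tag_codes(
                rng, chrom_index[site["chrom"]], int(site["center"]), int(n),
                config.fragment_bp, config.chrom_bp,
            ))
    site_codes = np.unique(np.concatenate(codes)) if codes else np.empty(0, np.int64)
    n_bg = config.secondary_depth - len(site_codes)
    bg = _background_codes(rng, n_bg, site_codes, config)
    all_codes = np.sort(np.concatenate([site_codes, bg]))
    chrom, pos, strand = _decode(all_codes, config.chrom_names, config.chrom_bp)
    return TagLibrary(make_tags(chrom, pos, strand),
                      replicate_id="secondary", condition="secondary")


def simulate_de_table(gene_frame: pd.DataFrame) -> pd.DataFrame:
    """The consumed DE product: gene, log2fc, direction, measured."""
    return pd.DataFrame({
        "gene": gene_frame["gene"],
        "log2fc": gene_frame["log2fc"],
        "direction": gene_frame["de_direction"],
        "measured": gene_frame["measured"].astype(int),
    })


def simulate_study(config: SimulationConfig | None = None, seed: int | None = None
                   ) -> SimulationResult:
    """One-shot generator of the full synthetic study."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    genes, gene_frame = simulate_transcriptome(config, rng)
    gene_frame = _choose_de(config, rng, gene_frame)
    sites = simulate_sites(config, rng, genes, gene_frame)
    sequences, genome = simulate_genome(config, rng, genes, gene_frame, sites)
    libraries = simulate_chip_replicates(config, rng, sites)
    secondary = simulate_secondary_factor(config, rng, sites, gene_frame)
    de_table = simulate_de_table(gene_frame)
    n_planted = sites[sites["kind"] == "true"].groupby("linked_gene").size()
    gene_frame = gene_frame.copy()
    gene_frame["n_planted_sites"] = gene_frame["gene"].map(n_planted).fillna(0).astype(int)
    truth = TruthSet(sites=sites, genes=gene_frame)
    return SimulationResult(
        config=config, genome=genome, sequences=sequences, genes=genes,
        transcriptome=Transcriptome(genes, genome), libraries=libraries,
        secondary_library=secondary, de_table=de_table, truth=truth,
    )


def write_study(result: SimulationResult, outdir) -> dict[str, str]:
    """Emit the study as standard-format files; returns {name: path}."""
    from . import io as sio

    out = sio.ensure_dir(outdir)
    paths = {}
    sio.write_fasta(result.sequences, out / "genome.fa")
    paths["genome"] = str(out / "genome.fa")
    sio.write_chrom_sizes(result.genome, out / "chrom.sizes")
    paths["chrom_sizes"] = str(out / "chrom.sizes")
    sio.write_gene_table(result.genes, out / "genes.refflat")
    paths["genes"] = str(out / "genes.refflat")
    for lib in result.libraries:
        name = f"{lib.condition}_{lib.replicate_id}.tagAlign"
        sio.write_tagalign(lib, out / name)
        paths[name] = str(out / name)
    sio.write_tagalign(result.secondary_library, out / "secondary.tagAlign")
    paths["secondary"] = str(out / "secondary.tagAlign")
    sio.write_de_table(result.de_table, out / "de_genes.tsv")
    paths["de_table"] = str(out / "de_genes.tsv")
    truth_dir = sio.ensure_dir(out / "truth")
    result.truth.sites.to_csv(truth_dir / "sites.tsv", sep="\t", index=False)
    result.truth.genes.to_csv(truth_dir / "genes.tsv", sep="\t", index=False)
    paths["truth_sites"] = str(truth_dir / "sites.tsv")
    paths["truth_genes"] = str(truth_dir / "genes.tsv")
    return paths
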