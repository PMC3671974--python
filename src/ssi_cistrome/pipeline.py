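"""One-shot pipeline: simulate (or load) -> call peaks (full + leave-one-out)
-> SSI filter -> consolidate & quantify -> differential test -> motif and
TATA classification -> genomic annotation -> expression integration ->
co-localisation profiles.

Every stage writes deterministic text outputs under the run directory and
records them, with SHA-256 checksums, in a JSON manifest; a rerun with the
same configuration and seed reproduces every byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .annotate import (RegulationGroup, assign_regulation_groups, average_profile,
                       classify_site, crosstab_tata_creb, gene_level_enrichment,
                       map_targets, sites_per_gene, tss_distance_profile)
from .core import Interval, Transcriptome, pool_libraries
from .motifs import classify_cre, classify_tata, tata_pwm
from .peaks import CallerConfig, call_peaks, compare_peak_sets, make_loo_pools, ssi_filter
from .quantify import (DEFAULT_HEIGHT_THRESHOLD_RPM, assign_quartiles,
                       differential_binding, group_height_summary,
                       merge_condition_peaks, regions_to_frame)
from .simulate import SimulationConfig, simulate_study, write_study

logger = logging.getLogger(__name__)

CONDITIONS = ("fasted", "refed")


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_run"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # read a previously written study instead of simulating
    caller: CallerConfig = field(default_factory=CallerConfig)
    height_threshold_rpm: float = DEFAULT_HEIGHT_THRESHOLD_RPM
    differential_fdr: float = 0.10
    match_rule: str = "overlap"
    feature_priority: str = "exon_first"
    cre_window_bp: int = 100
    tata_score_min: float = 6.0
    tata_window_bp: int = 250
    profile_flank_bp: int = 2_000
    profile_bin_bp: int = 25

    def validate(self) -> None:
        if not 0 < self.differential_fdr < 1:
            raise ValueError("differential_fdr must be in (0, 1)")
        if self.height_threshold_rpm < 0:
            raise ValueError("height threshold must be non-negative")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input directory {self.input_dir!r} does not exist")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.stages: list[dict] = []

    def record(self, stage: str, params: dict, outputs: dict[str, str], note: str = ""):
        entry = {
            "stage": stage,
            "params": params,
            "outputs": {
                name: {"path": str(Path(p).relative_to(self.outdir)), "sha256": _sha256(p)}
                for name, p in outputs.items()
            },
        }
        if note:
            entry["note"] = note
        self.stages.append(entry)
        logger.info("stage %s complete (%d outputs)", stage, len(outputs))

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _load_study(input_dir: Path, sim: SimulationConfig):
    """Read a study previously emitted by write_study (or hand-assembled)."""
    genome = sio.read_chrom_sizes(input_dir / "chrom.sizes")
    genes = sio.read_gene_table(input_dir / "genes.refflat")
    libs = []
    for cond in CONDITIONS:
        for path in sorted(input_dir.glob(f"{cond}_rep*.tagAlign")):
            rep = path.stem.split("_", 1)[1]
            libs.append(sio.read_tagalign(path, genome, replicate_id=rep, condition=cond))
    secondary_path = input_dir / "secondary.tagAlign"
    secondary = (
        sio.read_tagalign(secondary_path, genome, replicate_id="secondary",
                          condition="secondary")
        if secondary_path.exists() else None
    )
    de_path = input_dir / "de_genes.tsv"
    de_table = sio.read_de_table(de_path) if de_path.exists() else None
    fasta = sio.open_fasta(input_dir / "genome.fa")
    return genome, genes, libs, secondary, de_table, fasta


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    config.validate()
    outdir = sio.ensure_dir(config.outdir)
    manifest = _Manifest(outdir)
    logger.info("pipeline start: seed=%d fdr=%g height_threshold=%g RPM",
                config.seed, config.differential_fdr, config.height_threshold_rpm)

    # -- stage 1: simulate (or load) ----------------------------------------
    if config.input_dir is None:
        study = simulate_study(config.sim, seed=config.seed)
        sim_dir = outdir / "sim"
        paths = write_study(study, sim_dir)
        manifest.record("simulate", {"seed": config.seed,
                                     "n_true_sites": config.sim.n_true_sites,
                                     "n_artifact_sites": config.sim.n_artifact_sites},
                        {k: v for k, v in paths.items()})
        genome, genes, libs = study.genome, study.genes, study.libraries
        secondary, de_table = study.secondary_library, study.de_table
        fasta = study.sequences  # dict of str supports [chrom][lo:hi]
    else:
        genome, genes, libs, secondary, de_table, fasta = _load_study(
            Path(config.input_dir), config.sim
        )
        manifest.record("simulate", {"input_dir": config.input_dir}, {},
                        note="inputs loaded from disk; generation skipped")
    transcriptome = Transcriptome(genes, genome)

    # -- stage 2: peak calling (full pool + leave-one-out pools) ------------
    peak_outputs = {}
    full_sets, loo_sets = {}, {}
    for cond in CONDITIONS:
        reps = [lib for lib in libs if lib.condition == cond]
        full_pool = pool_libraries(reps, label=f"{cond}_pool")
        full_sets[cond] = call_peaks(full_pool, genome, config.caller)
        path = outdir / f"peaks_{cond}_full.bed"
        sio.write_peaks_bed(full_sets[cond].peaks, path)
        peak_outputs[f"{cond}_full"] = str(path)
        loo_sets[cond] = []
        for excluded, pool in make_loo_pools(reps):
            ps = call_peaks(pool, genome, config.caller)
            loo_sets[cond].append((excluded, ps))
            path = outdir / f"peaks_{cond}_minus_{excluded}.bed"
            sio.write_peaks_bed(ps.peaks, path)
            peak_outputs[f"{cond}_minus_{excluded}"] = str(path)
    manifest.record("callpeaks", {"fdr": config.caller.fdr,
                                  "fragment_bp": config.caller.fragment_bp,
                                  "window_bp": config.caller.window_bp}, peak_outputs)

    # -- stage 3: SSI filter -------------------------------------------------
    ssi_outputs = {}
    retained = {}
    for cond in CONDITIONS:
        res = ssi_filter(full_sets[cond], loo_sets[cond], match_rule=config.match_rule)
        retained[cond] = res.retained
        bed = outdir / f"peaks_{cond}_ssi.bed"
        sio.write_peaks_bed(res.retained.peaks, bed)
        report = outdir / f"ssi_report_{cond}.tsv"
        sio.write_tsv(res.match_table, report)
        ssi_outputs[f"{cond}_retained"] = str(bed)
        ssi_outputs[f"{cond}_report"] = str(report)
        logger.info("SSI %s: %d/%d peaks retained", cond, len(res.retained), len(res.retained) + len(res.removed))
    venn = compare_peak_sets(retained[CONDITIONS[0]], retained[CONDITIONS[1]])
    venn_path = outdir / "venn_summary.tsv"
    sio.write_tsv(pd.DataFrame([{
        "a_only": venn.a_only, "b_only": venn.b_only, "shared": venn.shared,
        "percent_overlap_union": venn.percent_overlap_union,
        "frac_fasted_in_refed": venn.frac_a_in_b, "frac_refed_in_fasted": venn.frac_b_in_a,
    }]), venn_path)
    ssi_outputs["venn"] = str(venn_path)
    manifest.record("ssi", {"match_rule": config.match_rule}, ssi_outputs)

    # -- stage 4: consolidate and quantify -----------------------------------
    regions = merge_condition_peaks(
        retained[CONDITIONS[0]], retained[CONDITIONS[1]], libs,
        height_threshold=config.height_threshold_rpm,
        fragment_bp=config.caller.fragment_bp,
    )
    assign_quartiles(regions)
    regions_frame = regions_to_frame(regions)
    regions_path = outdir / "regions.tsv"
    sio.write_tsv(regions_frame, regions_path)
    manifest.record("quantify", {"height_threshold_rpm": config.height_threshold_rpm},
                    {"regions": str(regions_path)})

    # -- stage 5: differential binding ---------------------------------------
    diff = differential_binding(regions, libs, fdr=config.differential_fdr)
    diff_frame = pd.DataFrame({
        "chrom": [r.interval.chrom for r in regions],
        "start": [r.interval.start for r in regions],
        "end": [r.interval.end for r in regions],
        "id": regions_frame["id"],
        "pvalue": diff.pvalues, "qvalue": diff.qvalues,
        "significant": diff.significant.astype(int),
    })
    diff_path = outdir / "differential.tsv"
    sio.write_tsv(diff_frame, diff_path)
    manifest.record("diff", {"fdr": config.differential_fdr},
                    {"differential": str(diff_path)})

    # -- stage 6: motif + TATA classification --------------------------------
    half = config.cre_window_bp // 2
    cre_classes = []
    for r in regions:
        c = r.interval.center
        seq = str(fasta[r.interval.chrom][max(c - half, 0):c + half])
        cre_classes.append(classify_cre(seq).value)
    motif_frame = regions_frame[["chrom", "start", "end", "id"]].copy()
    motif_frame["cre_class"] = cre_classes
    motif_path = outdir / "motif_classes.tsv"
    sio.write_tsv(motif_frame, motif_path)
    summary_path = outdir / "motif_group_summary.tsv"
    sio.write_tsv(group_height_summary(regions, cre_classes), summary_path)
    pwm = tata_pwm()
    tata_flags = {
        g.gene_symbol: classify_tata(g, fasta, pwm, threshold=config.tata_score_min,
                                     window_bp=config.tata_window_bp, genome=genome)
        for g in genes
    }
    tata_frame = pd.DataFrame(sorted(tata_flags.items()), columns=["gene", "tata"])
    tata_frame["tata"] = tata_frame["tata"].astype(int)
    tata_path = outdir / "tata_flags.tsv"
    sio.write_tsv(tata_frame, tata_path)
    manifest.record("motifs", {"cre_window_bp": config.cre_window_bp,
                               "tata_score_min": config.tata_score_min,
                               "tata_window_bp": config.tata_window_bp},
                    {"cre_classes": str(motif_path), "group_summary": str(summary_path),
                     "tata_flags": str(tata_path)})

    # -- stage 7: genomic annotation -----------------------------------------
    site_intervals = [r.interval for r in regions]
    annotations = [
        classify_site(iv.chrom, iv.center, transcriptome, priority=config.feature_priority)
        for iv in site_intervals
    ]
    ann_frame = regions_frame[["chrom", "start", "end", "id"]].copy()
    ann_frame["feature"] = [a.feature.value for a in annotations]
    ann_frame["first_intron"] = [int(a.first_intron) for a in annotations]
    ann_frame["within_50kb_tss"] = [int(a.within_50kb_tss) for a in annotations]
    ann_path = outdir / "annotated.tsv"
    sio.write_tsv(ann_frame, ann_path)
    tss_prof = tss_distance_profile(site_intervals, transcriptome)
    tss_path = outdir / "tss_distance_profile.tsv"
    sio.write_tsv(tss_prof, tss_path)
    manifest.record("annotate", {"feature_priority": config.feature_priority},
                    {"annotated": str(ann_path), "tss_profile": str(tss_path)})

    # -- stage 8: expression integration -------------------------------------
    groups = [RegulationGroup.UNASSIGNED] * len(regions)
    if de_table is None:
        manifest.record("integrate", {}, {},
                        note="DE table missing: integration skipped")
        logger.warning("no DE table: integrate stage skipped")
    else:
        links = map_targets(site_intervals, transcriptome)
        groups, diagnostics = assign_regulation_groups(len(site_intervals), links, de_table)
        groups_frame = regions_frame[["chrom", "start", "end", "id"]].copy()
        groups_frame["regulation_group"] = [g.value for g in groups]
        groups_path = outdir / "groups.tsv"
        sio.write_tsv(groups_frame, groups_path)
        counts = sites_per_gene(links, list(de_table["gene"]))
        enr = gene_level_enrichment(de_table, counts)
        enr_path = outdir / "enrichment.tsv"
        sio.write_tsv(enr, enr_path)
        bound_flags = {g: c >= 1 for g, c in counts.items()}
        cross = crosstab_tata_creb(list(de_table["gene"]), tata_flags, bound_flags, de_table)
        cross_path = outdir / "tata_creb_crosstab.tsv"
        sio.write_tsv(cross, cross_path)
        manifest.record("integrate", {"diagnostics": diagnostics},
                        {"groups": str(groups_path), "enrichment": str(enr_path),
                         "crosstab": str(cross_path)})

    # -- stage 9: co-localisation profiles ------------------------------------
    anchor_groups: dict[str, list[Interval]] = {}
    for iv, g in zip(site_intervals, groups):
        anchor_groups.setdefault(g.value, []).append(iv)
    if secondary is not None and anchor_groups:
        profiles = average_profile(anchor_groups, [secondary], genome,
                                   flank_bp=config.profile_flank_bp,
                                   bin_bp=config.profile_bin_bp,
                                   fragment_bp=config.caller.fragment_bp)
        rows = []
        for name, prof in sorted(profiles.items()):
            for off, val in zip(prof.offsets, prof.mean_rpm):
                rows.append({"group": name, "offset_bp": off, "mean_rpm": val,
                             "n_anchors": prof.n_anchors})
        prof_path = outdir / "profiles.tsv"
        sio.write_tsv(pd.DataFrame(rows), prof_path)
        manifest.record("profile", {"flank_bp": config.profile_flank_bp,
                                    "bin_bp": config.profile_bin_bp},
                        {"profiles": str(prof_path)})
    else:
        manifest.record("profile", {}, {}, note="no secondary signal: profiles skipped")

    manifest_path = manifest.write()
    logger.info("pipeline complete: %s", manifest_path)
    return {"stages": manifest.stages, "manifest_path": str(manifest_path)}


def write_report(manifest: dict, outdir) -> str:
    """Plain-text digest of a completed run, read back from stage outputs
    (no recomputation)."""
    outdir = Path(outdir)
    lines = ["run summary", "==========="]
    for stage in manifest["stages"]:
        lines.append(f"\n[{stage['stage']}]")
        if stage.get("note"):
            lines.append(f"  note: {stage['note']}")
        for name, info in sorted(stage["outputs"].items()):
            path = outdir / info["path"]
            lines.append(f"  {name}: {info['path']}")
            if path.suffix == ".tsv":
                df = sio.read_tsv(path)
                lines.append(f"    rows: {len(df)}")
                if stage["stage"] == "diff" and "significant" in df.columns:
                    lines.append(f"    significant regions: {int(df['significant'].sum())}")
                if stage["stage"] == "integrate" and "regulation_group" in df.columns:
                    for g, n in df["regulation_group"].value_counts().sort_index().items():
                        lines.append(f"    {g}: {n}")
            elif path.suffix == ".bed":
                with open(path) as fh:
                    lines.append(f"    peaks: {sum(1 for _ in fh)}")
    text = "\n".join(lines) + "\n"
    report_path = outdir / "report.txt"
    with open(report_path, "w") as fh:
        fh.write(text)
    return str(report_path)
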