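"""Integrating a binding-site map with differential gene expression.

Sites are linked to target genes (center within 10 kb upstream of a TSS or
anywhere in the gene body), partitioned into regulation groups by their
linked genes' expression response (induced / repressed / no change /
unassigned), and tested for gene-level enrichment: the fraction of
regulated genes with at least one site versus all measured genes. A
secondary transcription factor that the generator co-localises only at
sites of induced genes shows up as profile enrichment restricted to the
INDUCED anchor group.
"""

from ssi_cistrome import (SimulationConfig, assign_regulation_groups,
                          average_profile, gene_level_enrichment, map_targets,
                          simulate_study)
from ssi_cistrome.annotate import sites_per_gene
from ssi_cistrome.core import Interval

study = simulate_study(SimulationConfig(), seed=7)

sites = study.truth.sites.query("kind == 'true'")
ivs = [Interval(s.chrom, s.center - 100, s.center + 100) for s in sites.itertuples()]
links = map_targets(ivs, study.transcriptome)
groups, diagnostics = assign_regulation_groups(len(ivs), links, study.de_table)

counts = {g.value: 0 for g in set(groups)}
for g in groups:
    counts[g.value] += 1
print(f"regulation groups over {len(ivs)} sites: {counts}")
print(f"up/down link conflicts (resolved INDUCED-first): "
      f"{diagnostics['conflicts_up_down']}")

per_gene = sites_per_gene(links, list(study.de_table["gene"]))
enr = gene_level_enrichment(study.de_table, per_gene).set_index("category")
print(f"\nbound-gene rates: regulated {enr.loc['regulated', 'pct_bound']:.0f}% "
      f"vs all measured {enr.loc['all', 'pct_bound']:.0f}% "
      f"(Fisher p = {enr.loc['regulated', 'fisher_p_vs_all']:.2g})")

anchors = {}
for iv, g in zip(ivs, groups):
    anchors.setdefault(g.value, []).append(iv)
profiles = average_profile(anchors, [study.secondary_library], study.genome,
                           flank_bp=2_000, bin_bp=25)
print("\nsecondary-factor signal at anchor centers (RPM, max of central bins):")
for name, prof in sorted(profiles.items()):
    central = prof.mean_rpm[len(prof.mean_rpm) // 2 - 2:len(prof.mean_rpm) // 2 + 2]
    print(f"  {name:10s} {central.max():8.1f}  (n={prof.n_anchors})")
# The INDUCED group's central enrichment, absent from the other groups,
# reproduces the planted co-localisation of the secondary factor at sites
# of induced genes.
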