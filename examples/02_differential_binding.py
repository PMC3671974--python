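"""Quantitative differential-binding analysis across two conditions.

Peak calls from the two conditions are union-merged into one region set and
every region is quantified in every replicate of both conditions (maximum
fragment-stack height in reads per million, and raw overlapping tag
counts). The point of quantifying call-set-independently: a region called
in only one condition usually shows comparable signal in the other — a
missing peak CALL is not evidence of differential BINDING. Differential
regions are then found with an exact binomial test on pooled counts at 10%
FDR (Benjamini-Hochberg).
"""

import numpy as np

from ssi_cistrome import (SimulationConfig, assign_quartiles, call_peaks,
                          differential_binding, make_loo_pools,
                          merge_condition_peaks, pool_libraries,
                          simulate_study, ssi_filter)

study = simulate_study(SimulationConfig(
    n_chroms=2, chrom_bp=300_000, n_genes=24, n_true_sites=60,
    n_artifact_sites=8, depth_per_replicate=30_000, secondary_depth=30_000,
), seed=7)

retained = {}
for cond in ("fasted", "refed"):
    reps = [lib for lib in study.libraries if lib.condition == cond]
    full = call_peaks(pool_libraries(reps), study.genome)
    loo = [(rid, call_peaks(p, study.genome)) for rid, p in make_loo_pools(reps)]
    retained[cond] = ssi_filter(full, loo).retained

regions = merge_condition_peaks(retained["fasted"], retained["refed"],
                                study.libraries, height_threshold=0.35)
assign_quartiles(regions)
diff = differential_binding(regions, study.libraries, fdr=0.10)

ratios = np.array([r.log2_ratio for r in regions])
print(f"consolidated regions (avg height > 0.35 RPM): {len(regions)}")
print(f"origin breakdown: "
      f"{ {o: sum(r.origin == o for r in regions) for o in ('both', 'fasted-only', 'refed-only')} }")
print(f"median fasted/re-fed fold: {2 ** np.median(ratios):.3f} "
      f"(generator planted median {study.config.global_fold_median})")
print(f"regions significant at 10% FDR: {int(diff.significant.sum())}")
# The recovered median fold tracks the weak global condition effect the
# generator planted; the significant set reflects that every site carries
# some real (if small) planted fold at this sequencing depth.
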