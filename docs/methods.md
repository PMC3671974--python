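# Methods

This note records the models, parameter choices and numerical conventions
behind `ssi_cistrome`, and what the synthetic-data validation does and
does not establish.

## Coordinates and tags

All coordinates are 0-based half-open (BED-native); gene tables using
1-based inclusive starts are converted on read. A sequencing read is
reduced to a *tag*: its 5′-end position and strand. Redundant reads
(identical chromosome, 5′ position and strand — presumed PCR duplicates)
are discarded **within** each replicate before any pooling; pooling across
replicates is a multiset union, so the same position contributed by two
replicates counts twice. Distances to a TSS are signed and
strand-relative, negative upstream; nearest-TSS ties break toward the
lower-coordinate gene.

## Peak caller

The built-in caller slides `window_bp` = 200 windows in `step_bp` = 50
steps. Tags are extended to `fragment_bp` = 108 (the average sonication
fragment length assumed throughout) in their strand direction; a window's
count is the number of fragments overlapping it by ≥ 1 bp. Windows with
fewer than `min_tags` = 4 fragments are not tested. Each tested window
gets a Poisson upper-tail p-value against λ = max(global, local)
expectation, where the global expectation is genome-wide fragment density
times the effective span (window + fragment length) and the local
expectation is the density in ±5 kb around the window, excluding the
window's own fragments (a defence against broad enriched domains and
copy-number-like background variation). Benjamini–Hochberg is applied
across tested windows at `fdr` = 0.05; overlapping significant windows
merge into variable-width peaks. The summit is the leftmost position of
maximal fragment depth (leftmost on ties, for determinism); peak height is
that maximal depth × 10⁶ / library size (RPM). The caller is a
well-defined, exactly testable stand-in for production callers: its
window-level BH correction is *not* an empirical peak-level FDR, and it
performs no input-chromatin subtraction beyond the local background. The
SSI filter deliberately takes peak sets, not tag data, so calls from any
external caller can be filtered the same way.

## The SSI filter

Given the full-pool peak set and the n leave-one-out peak sets of one
condition, a peak is retained iff it matches ≥ 1 peak in *every*
leave-one-out set. "Matches" defaults to ≥ 1 bp interval overlap — the
weakest defensible similarity rule; a summit-distance rule
(`match_rule="summit"`, default 100 bp) is available and is monotone:
tightening the allowed distance never grows the retained set. Peaks within
a set are merged if overlapping before filtering, so matching is between
disjoint intervals. Removal accounting reports two tallies per replicate:
peaks whose *only* failing pool excludes that replicate (sole
attributions), and a per-failing-pool count in which a peak failing
several pools contributes to each.

## Consolidation, quantification, differential testing

The two conditions' SSI-filtered sets are union-merged; each merged
region records its origin (both / one condition only). Every region is
quantified in every replicate of both conditions: height = max per-base
fragment depth inside the region (RPM), count = tags whose fragment
overlaps the region by ≥ 1 bp (fragment overlap, not 5′-end containment,
to stay consistent with heights). Regions with average height — the
unweighted mean of the two condition means — at or below 0.35 RPM are
dropped; the threshold reflects an empirical reproducibility cutoff for
this kind of data and is configurable. The per-region log2 condition
ratio uses a pseudocount of ε = 0.01 RPM in numerator and denominator so
zero-height regions stay finite. Quartiles by average height are assigned
rank-based (stable sort, coordinate-order tie-break), guaranteeing sizes
within 1 of n/4 even for degenerate height distributions.

Differential binding per region is an exact two-sided binomial test:
conditional on the total pooled count n = x_f + x_r, x_f ~ Binomial(n,
N_f/(N_f+N_r)) under the null, with N the summed library sizes; two-sided
by summing outcome probabilities ≤ the observed one. This is a
self-contained, exactly testable substitute for a negative-binomial count
model and is **anti-conservative under biological overdispersion**: with
replicate-to-replicate variability beyond Poisson, its p-values are too
small. An optional method-of-moments inflation factor
(`estimate_dispersion_inflation`, median per-region variance/mean ratio)
divides the pooled counts as a quasi-likelihood-style correction; it is
off by default and flagged in output metadata. BH correction at 10% FDR
yields the significant set.

## Motifs

CRE classification scans the 100 bp window centred on the peak center
(extraction is exactly [center−50, center+50); motifs must be fully
contained): Full CRE if any octamer is within Hamming distance 1 of
TGACGTCA (N counts as a mismatch, so a single N still permits a Full
call); else Half CRE if TGACG or CGTCA occurs exactly (the pair is closed
under reverse complement, making the classifier strand-symmetric; a
strict forward-only pentamer option exists); else Non-CRE. Exactly 25 of
the 65,536 octamers are Full (1 exact + 8×3 single mismatches).

PWM scanning uses per-cell pseudocount 0.5 and uniform background 0.25;
scores are summed log2 odds, both strands scanned, N-containing windows
skipped. The TATA matrix shipped with the package is a *synthetic*
consensus-built count matrix (width 8, consensus TATAAAAG, 93% consensus
weight per column), not a database matrix; with the conventional score
threshold 6, k-mers within one mismatch of the consensus score as hits. A
gene is TATA-containing if a hit's start lies within ±250 bp of its TSS.
Note that in uniform-random DNA this admits a substantial chance hit rate
(≈ 25/4⁸ per position over a 500 bp double-stranded window, i.e. roughly a
third of promoters); real promoter sequence composition differs, and
recovery tests therefore use a background-corrected estimator
(planted fraction = (call rate − background rate)/(1 − background rate),
with the background rate measured on a generator run that plants nothing).

Matched background sampling bins every genomic base by signed nearest-TSS
distance (per-side bins 0–200 bp, 200 bp–2 kb, 2–10 kb, 10–50 kb, >50 kb,
mirroring the annotation windows) and draws each foreground site's
backgrounds from its own bin, excluding foreground intervals;
deterministic under a seed. The per-base distance array is materialised
per chromosome, which suits desk-scale genomes (tens of Mb), not full
mammalian ones. No GC/CpG matching is attempted.

## Annotation and integration

Feature classes are assigned by center position with priority PROMOTER
(−2 kb…+200 bp strand-relative of any TSS) > 5′UTR (beyond +200 bp) >
coding exon > 3′UTR > intron > intergenic; the choice that exonic overlap
of one transcript beats intronic overlap of another is deliberate
(biological sensibility), and a literal intron-first ordering is available
(`priority="intron_first"`). First-intron status is evaluated in
transcription order. Intergenic sites record whether the nearest TSS is
within 50 kb. A second, independent scheme (proximal −2 kb…+200 bp /
distal −10 kb…−2 kb / intronic / exonic) is exposed as
`classify_site_regulatory`.

Target mapping links a site to every gene whose strand-relative window
[TSS − 10 kb, gene end] contains the site center. Regulation groups per
site follow the precedence INDUCED > REPRESSED > NO_CHANGE over the
linked genes' DE flags (conflicts counted and reported); sites with no
links, or links only to unmeasured genes, are UNASSIGNED. Gene-level
enrichment compares bound/unbound in each DE category (up, down, their
union "regulated") against all measured genes by two-sided Fisher exact
test; the TATA×binding cross-tab tests each of the four bound×TATA groups
against the unbound/TATA-less reference. Average profiles are RPM-scaled
fragment-depth means in 25 bp bins over ±2 kb around anchor centers;
anchors truncated by a chromosome edge contribute only to the bins they
cover. Secondary-factor heights at primary sites reuse the same
`region_height` computation as the primary factor.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: 5 + 5
replicate libraries of 100,000 deduplicated tags each over a 2 × 1 Mb
genome; 200 constitutively bound sites; 20 artifact sites, each owned by
one (condition, replicate) in round-robin; per-site condition folds
log-normal with median 1.3 and σ = 0.25 in log2 (the literature reports
only a median for such weak global effects), split symmetrically between
conditions so the fasted/re-fed rate ratio equals the fold; fragment
length 108 bp; a DE table with |log2FC| ≥ log2(1.5) for called genes; 20%
TATA promoters; CRE content mixed 50/30/20 Full/Half/None.

Design choices worth noting:

- **Site tag model.** Fragment 5′ ends are uniform on [center−L, center)
  for + tags and mirrored for −, so every site fragment covers the center
  and the expected summit is the center — simple and analytically
  checkable. Site rates are Poisson with mean `enrichment_fold` ×
  background density × fragment length (default fold 10); artifact sites
  get one replicate's worth of the full-pool rate (n× that), and zero
  tags elsewhere — the cleanest construction exercising the SSI
  contract. Positions are sampled without replacement within a site's
  2L fragment-start slots and background tags are topped up after
  deduplication, so emitted libraries are duplicate-free and hit the
  configured depth exactly.
- **Gene layout.** Genes (2–8 exons) are placed as tail-facing (+,−)
  pairs separated by ≥ 13 kb shared upstream gaps, so no gene's 10 kb
  target window reaches a neighbouring transcription unit and a planted
  site links to exactly its intended gene. The defaults (180 genes, 40%
  DE) are sized so the planted 60%-vs-33% bound-gene contrast is
  statistically resolvable (Fisher p < 0.01) at this genome scale; real
  arrays have far lower DE fractions but proportionally more genes.
- **Planted motif windows** are rejection-resampled until the CRE
  classifier agrees with the intended class — in uniform-random sequence,
  chance half-site matches are otherwise common — so planted class
  fractions are exact, not approximate.
- **Secondary factor.** One extra library places enriched tags only at
  sites linked to up-regulated genes, plus uniform background,
  reproducing the co-localisation structure the integration stage is
  meant to detect.

What the generator does **not** emulate: real base composition and CpG
structure, mappability and repeat artifacts, copy-number variation,
fragment-length dispersion, or biological replicate overdispersion in
counts. Passing tests therefore demonstrate the correctness of the
computations and the recoverability of planted structure under the stated
noise model — not calibration on real chromatin.

## Problem sizes and determinism

Validation runs use the default study (2 Mb genome, 10 × 100k tags,
~220 peaks per condition), 2,000-region null/spiked simulations for the
differential test, exhaustive octamer enumeration (4⁸), exhaustive Fisher
enumeration to table total 24 plus 1,000 sampled larger tables, and two
full pipeline runs for checksum determinism. Every artifact of a pipeline
run is a pure function of (config, seed); stage outputs are written with
six-significant-digit floats and deterministic row order, and the manifest
records SHA-256 checksums so reruns can be compared byte-for-byte.

## Known limitations

- The binomial differential test overstates significance under
  overdispersion (see above); with the generator's Poisson replicates and
  genuinely planted per-site folds, a large fraction of regions is
  correctly — but unrealistically, by real-data standards — significant.
- The caller's window-level BH is not an empirical peak-level FDR.
- The synthetic TATA matrix's score scale is conventional, not matched to
  any production scanner's; the threshold 6 is kept for interface
  fidelity and the background hit rate in uniform DNA is high.
- Matched background sampling materialises per-base arrays; use on full
  mammalian genomes would need a streaming implementation.
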