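"""Feature classification, target mapping, regulation groups, enrichment
statistics, and average profiles."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ssi_cistrome.annotate import (FeatureClass, RegulationGroup,
                                   assign_regulation_groups, average_profile,
                                   classify_site, classify_site_regulatory,
                                   crosstab_tata_creb, fisher_exact,
                                   gene_level_enrichment, map_targets,
                                   secondary_heights, sites_per_gene,
                                   tss_distance_profile)
from ssi_cistrome.core import GenomeIndex, Interval, TagLibrary, make_tags
from ssi_cistrome.quantify import region_height


class TestClassifySite:
    # toy_transcriptome: geneA (+) tx 20000-26000 (TSS 20000, 5'UTR to 20500,
    # introns [21000,22000) and [23000,25000), 3'UTR from 25500);
    # geneB (-) tx 60000-66000 (TSS 65999).

    def test_upstream_promoter(self, toy_transcriptome):
        assert classify_site("chr1", 19_500, toy_transcriptome).feature \
            == FeatureClass.PROMOTER

    def test_minus_strand_promoter_is_strand_relative(self, toy_transcriptome):
        # 500 bp upstream of geneB's TSS lies at higher coordinates
        assert classify_site("chr1", 66_499, toy_transcriptome).feature \
            == FeatureClass.PROMOTER
        # 500 bp on the wrong side (inside the gene) is beyond +200
        assert classify_site("chr1", 65_499, toy_transcriptome).feature \
            != FeatureClass.PROMOTER

    def test_five_utr_beyond_promoter_window(self, toy_transcriptome):
        # geneA exon1 positions 20000-21000, CDS starts 20500: 5'UTR is
        # 20000-20500, all within +200 of TSS here; use geneB whose 5'UTR
        # (65600-66000, minus strand) extends beyond +200 from TSS 65999
        ann = classify_site("chr1", 65_700, toy_transcriptome)
        assert ann.feature == FeatureClass.FIVE_UTR

    def test_first_intron_flag(self, toy_transcriptome):
        ann = classify_site("chr1", 21_500, toy_transcriptome)
        assert ann.feature == FeatureClass.INTRON and ann.first_intron
        ann2 = classify_site("chr1", 24_000, toy_transcriptome)
        assert ann2.feature == FeatureClass.INTRON and not ann2.first_intron

    def test_minus_strand_first_intron_is_transcription_order(self):
        from ssi_cistrome.core import GeneModel, Transcriptome
        g = GeneModel("g", "t", "chr1", "-", 1_000, 9_000,
                      exons=[Interval("chr1", 1_000, 2_000),
                             Interval("chr1", 4_000, 5_000),
                             Interval("chr1", 8_000, 9_000)])
        tr = Transcriptome([g])
        assert classify_site("chr1", 6_000, tr).first_intron       # intron nearest TSS
        assert not classify_site("chr1", 3_000, tr).first_intron

    def test_cds_exon(self, toy_transcriptome):
        assert classify_site("chr1", 22_500, toy_transcriptome).feature \
            == FeatureClass.EXON_CDS

    def test_three_utr(self, toy_transcriptome):
        assert classify_site("chr1", 25_700, toy_transcriptome).feature \
            == FeatureClass.THREE_UTR

    def test_distant_intergenic(self, toy_transcriptome):
        ann = classify_site("chr1", 95_000, toy_transcriptome)
        assert ann.feature == FeatureClass.INTERGENIC
        assert ann.within_50kb_tss  # 29 kb from geneB's TSS
        far = classify_site("chr1", 45_000, toy_transcriptome)
        assert far.feature == FeatureClass.INTERGENIC and far.within_50kb_tss

    def test_partition_every_site_gets_one_class(self, toy_transcriptome):
        rng = np.random.default_rng(50)
        sites = rng.integers(0, 100_000, 300)
        feats = [classify_site("chr1", int(p), toy_transcriptome).feature
                 for p in sites]
        counts = pd.Series([f.value for f in feats]).value_counts()
        assert counts.sum() == 300

    def test_regulatory_scheme_distal_window(self, toy_transcriptome):
        assert classify_site_regulatory("chr1", 15_000, toy_transcriptome) == "distal"
        assert classify_site_regulatory("chr1", 19_500, toy_transcriptome) == "proximal"


class TestTssDistanceProfile:
    def test_sites_at_tss_spike_at_zero(self, toy_transcriptome):
        sites = [Interval("chr1", 19_950, 20_050)] * 5
        prof = tss_distance_profile(sites, toy_transcriptome, flank_bp=5_000, bin_bp=500)
        freqs = prof.set_index("bin_center")["frequency"]
        assert freqs[250.0] == 1.0  # distance 0 falls in the [0, 500) bin
        assert freqs.drop(250.0).sum() == 0.0

    def test_symmetric_offsets_symmetric_histogram(self, toy_transcriptome):
        sites = [Interval("chr1", 20_000 + d - 50, 20_000 + d + 50) for d in (-1_000, 1_000)]
        prof = tss_distance_profile(sites, toy_transcriptome, flank_bp=2_000, bin_bp=500)
        freqs = prof.set_index("bin_center")["frequency"]
        assert freqs[-750.0] == freqs[1_250.0] == 0.5  # [-1000,-500) and [1000,1500)

    def test_matches_linear_scan_oracle(self, toy_transcriptome):
        rng = np.random.default_rng(51)
        sites = [Interval("chr1", int(p), int(p) + 100)
                 for p in rng.integers(0, 99_000, 200)]
        prof = tss_distance_profile(sites, toy_transcriptome, flank_bp=50_000, bin_bp=1_000)
        dists = []
        for iv in sites:
            c = iv.center
            best = min(
                ((abs(c - g.tss), g) for g in toy_transcriptome.genes), key=lambda x: x[0]
            )[1]
            dists.append(best.signed_distance(c))
        expected = np.histogram(np.clip(dists, -50_000, 49_999),
                                bins=np.arange(-50_000, 51_000, 1_000))[0] / 200
        np.testing.assert_allclose(prof["frequency"], expected)


class TestMapTargets:
    def test_upstream_boundary(self, toy_transcriptome):
        just_in = [Interval("chr1", 20_000 - 9_999 - 50, 20_000 - 9_999 + 50)]
        links = map_targets(just_in, toy_transcriptome)
        assert list(links["gene_symbol"]) == ["geneA"]
        just_out = [Interval("chr1", 20_000 - 10_001 - 50, 20_000 - 10_001 + 50)]
        assert len(map_targets(just_out, toy_transcriptome)) == 0

    def test_gene_body_linked(self, toy_transcriptome):
        links = map_targets([Interval("chr1", 24_000, 24_100)], toy_transcriptome)
        assert list(links["gene_symbol"]) == ["geneA"]

    def test_matches_all_pairs_oracle(self, toy_transcriptome):
        rng = np.random.default_rng(52)
        sites = [Interval("chr1", int(p), int(p) + 100)
                 for p in rng.integers(0, 99_000, 300)]
        links = map_targets(sites, toy_transcriptome)
        got = set(map(tuple, links.itertuples(index=False)))
        expected = set()
        for i, iv in enumerate(sites):
            for g in toy_transcriptome.genes:
                d = g.signed_distance(iv.center)
                if (g.tx_start <= iv.center < g.tx_end) or (-10_000 <= d < 0):
                    expected.add((i, g.gene_symbol))
        assert got == expected

    def test_bipartite_double_count(self, toy_transcriptome):
        rng = np.random.default_rng(53)
        sites = [Interval("chr1", int(p), int(p) + 100)
                 for p in rng.integers(0, 99_000, 200)]
        links = map_targets(sites, toy_transcriptome)
        per_gene = sites_per_gene(links, [g.gene_symbol for g in toy_transcriptome.genes])
        assert per_gene.sum() == links.groupby("site_index")["gene_symbol"].nunique().sum()


class TestRegulationGroups:
    def _de(self):
        return pd.DataFrame({
            "gene": ["up1", "down1", "flat1", "flat2"],
            "log2fc": [1.0, -1.0, 0.1, 0.0],
            "direction": ["up", "down", "none", "none"],
            "measured": [1, 1, 1, 0],
        })

    def test_examples_and_precedence(self):
        links = pd.DataFrame({
            "site_index": [0, 1, 2, 2, 3, 5],
            "gene_symbol": ["up1", "down1", "up1", "down1", "flat1", "flat2"],
        })
        groups, diag = assign_regulation_groups(6, links, self._de())
        assert groups == [
            RegulationGroup.INDUCED, RegulationGroup.REPRESSED,
            RegulationGroup.INDUCED,       # up beats down
            RegulationGroup.NO_CHANGE,
            RegulationGroup.UNASSIGNED,    # no links
            RegulationGroup.UNASSIGNED,    # linked gene unmeasured
        ]
        assert diag["conflicts_up_down"] == 1

    def test_partition_matches_rule_oracle(self):
        rng = np.random.default_rng(54)
        de = self._de()
        n = 100
        rows = []
        for i in range(n):
            for g in rng.choice(de["gene"], size=rng.integers(0, 3), replace=False):
                rows.append({"site_index": i, "gene_symbol": g})
        links = pd.DataFrame(rows, columns=["site_index", "gene_symbol"])
        groups, _ = assign_regulation_groups(n, links, de)
        assert len(groups) == n
        by_site = links.groupby("site_index")["gene_symbol"].apply(set).to_dict()
        for i in range(n):
            syms = by_site.get(i, set())
            if "up1" in syms:
                expected = RegulationGroup.INDUCED
            elif "down1" in syms:
                expected = RegulationGroup.REPRESSED
            elif "flat1" in syms:
                expected = RegulationGroup.NO_CHANGE
            else:
                expected = RegulationGroup.UNASSIGNED
            assert groups[i] == expected


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    observed = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= observed * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_homogeneous_table(self):
        res = fisher_exact([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0) and res.pvalue == pytest.approx(1.0)

    def test_diagonal_table_exact_value(self):
        res = fisher_exact([[5, 0], [0, 5]])
        assert res.pvalue == pytest.approx(2 / comb(10, 5))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])

    def test_thousand_random_tables_match_enumeration(self):
        rng = np.random.default_rng(55)
        for _ in range(1_000):
            a, b, c, d = rng.integers(0, 50, 4)
            if a + b + c + d == 0:
                continue
            res = fisher_exact([[a, b], [c, d]])
            assert res.pvalue == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-12)


class TestGeneLevelEnrichment:
    def test_every_gene_bound_once(self):
        de = pd.DataFrame({
            "gene": [f"g{i}" for i in range(10)],
            "log2fc": [1.0] * 5 + [0.0] * 5,
            "direction": ["up"] * 5 + ["none"] * 5,
            "measured": [1] * 10,
        })
        counts = pd.Series(1, index=de["gene"])
        table = gene_level_enrichment(de, counts).set_index("category")
        assert (table["pct_1_site"] == 100.0).all()
        assert (table["pct_bound"] == 100.0).all()

    def test_percentages_match_counting_oracle(self):
        rng = np.random.default_rng(56)
        genes = [f"g{i}" for i in range(200)]
        de = pd.DataFrame({
            "gene": genes,
            "log2fc": rng.normal(size=200),
            "direction": rng.choice(["up", "down", "none"], 200, p=[0.2, 0.2, 0.6]),
            "measured": rng.choice([0, 1], 200, p=[0.1, 0.9]),
        })
        counts = pd.Series(rng.poisson(0.8, 200), index=genes)
        table = gene_level_enrichment(de, counts).set_index("category")
        up = de[(de.direction == "up") & (de.measured == 1)]["gene"]
        expected = 100.0 * (counts.reindex(up) >= 3).mean()
        assert table.loc["up", "pct_3plus_sites"] == pytest.approx(expected)


class TestCrosstab:
    def _setup(self, rng, interaction=False):
        genes = [f"g{i}" for i in range(400)]
        bound = {g: rng.random() < 0.5 for g in genes}
        tata = {g: rng.random() < 0.3 for g in genes}
        p_up = np.array([
            0.4 if (interaction and bound[g] and tata[g]) else 0.05 for g in genes
        ])
        direction = np.where(rng.random(400) < p_up, "up", "none")
        de = pd.DataFrame({"gene": genes, "log2fc": np.where(direction == "up", 1.0, 0.0),
                           "direction": direction, "measured": 1})
        return genes, tata, bound, de

    def test_uniform_rates_no_enrichment(self):
        rng = np.random.default_rng(57)
        genes, tata, bound, de = self._setup(rng, interaction=False)
        table = crosstab_tata_creb(genes, tata, bound, de)
        assert (table["fisher_p_induced"] > 0.05).all()

    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(58)
        genes, tata, bound, de = self._setup(rng, interaction=True)
        table = crosstab_tata_creb(genes, tata, bound, de).set_index("group")
        assert table.loc["CREB+/TATA+", "fisher_p_induced"] < 1e-5
        assert table.loc["CREB+/TATA+", "pct_induced"] > \
            table.loc["CREB-/TATA-", "pct_induced"]

    def test_cell_percentages_match_crosstab_oracle(self):
        rng = np.random.default_rng(59)
        genes, tata, bound, de = self._setup(rng, interaction=True)
        table = crosstab_tata_creb(genes, tata, bound, de).set_index("group")
        sel = [g for g in genes if bound[g] and tata[g]]
        dirs = dict(zip(de["gene"], de["direction"]))
        expected = 100.0 * np.mean([dirs[g] == "up" for g in sel])
        assert table.loc["CREB+/TATA+", "pct_induced"] == pytest.approx(expected)


class TestAverageProfile:
    def _library(self, rng, centers, n_per_center, depth, span=100_000):
        frames = [make_tags(["chr1"] * n_per_center,
                            c - rng.integers(0, 108, n_per_center),
                            ["+"] * n_per_center) for c in centers]
        n_bg = depth - n_per_center * len(centers)
        frames.append(make_tags(["chr1"] * n_bg, rng.integers(0, span, n_bg),
                                rng.choice(["+", "-"], n_bg)))
        return TagLibrary(pd.concat(frames), "sec", "secondary")

    def test_single_anchor_equals_pileup_oracle(self):
        rng = np.random.default_rng(60)
        genome = GenomeIndex({"chr1": 100_000})
        lib = self._library(rng, [50_000], 80, 2_000)
        anchor = Interval("chr1", 49_900, 50_100)
        profiles = average_profile({"g": [anchor]}, [lib], genome,
                                   flank_bp=500, bin_bp=25)
        prof = profiles["g"]
        from ssi_cistrome.peaks import fragment_starts, pileup
        frags = fragment_starts(lib, 108)["chr1"]
        depth = pileup(frags, 108, Interval("chr1", 49_500, 50_500))
        expected = depth.reshape(40, 25).mean(axis=1) * 1e6 / lib.n_tags
        np.testing.assert_allclose(prof.mean_rpm, expected)

    def test_zero_signal_all_zero(self):
        genome = GenomeIndex({"chr1": 10_000})
        lib = TagLibrary(make_tags([], [], []), "sec", "secondary")
        profiles = average_profile({"g": [Interval("chr1", 5_000, 5_100)]},
                                   [lib], genome, flank_bp=200, bin_bp=20)
        assert (profiles["g"].mean_rpm == 0).all()

    def test_linearity_of_pooled_signal(self):
        rng = np.random.default_rng(61)
        genome = GenomeIndex({"chr1": 100_000})
        lib_a = self._library(rng, [30_000], 50, 1_000)
        lib_b = self._library(rng, [30_000], 20, 3_000)
        anchors = {"g": [Interval("chr1", 29_900, 30_100)]}
        pooled = average_profile(anchors, [lib_a, lib_b], genome,
                                 flank_bp=400, bin_bp=20)["g"].mean_rpm
        prof_a = average_profile(anchors, [lib_a], genome,
                                 flank_bp=400, bin_bp=20)["g"].mean_rpm
        prof_b = average_profile(anchors, [lib_b], genome,
                                 flank_bp=400, bin_bp=20)["g"].mean_rpm
        na, nb = lib_a.n_tags, lib_b.n_tags
        combo = (prof_a * na + prof_b * nb) / (na + nb)
        np.testing.assert_allclose(pooled, combo, rtol=1e-9)

    def test_secondary_heights_use_region_height(self):
        rng = np.random.default_rng(62)
        lib = self._library(rng, [40_000], 60, 2_000)
        anchors = [Interval("chr1", 39_900, 40_100), Interval("chr1", 10_000, 10_200)]
        hs = secondary_heights(anchors, [lib])
        assert hs[0] == pytest.approx(region_height(anchors[0], lib))
        assert hs[0] > hs[1]
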