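"""TF cis-variant discovery, TF-gene pairing, STFCRE ranking, trans groups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ttwas.genomics_io import IntervalSet, SummaryStatsTable
from ttwas.regulatory_prioritization import (
    TFGeneMap,
    TFCisVariantSet,
    build_trans_groups,
    discover_tf_gene_pairs,
    find_tf_cis_variants,
    prioritize_stfcre_variants,
)
from ttwas.synthetic_cohort import SimulationConfig, simulate_annotations


@pytest.fixture()
def tf_setup():
    gene_table = pd.DataFrame(
        [("FOXA1", "chr14", 100_000, 140_000, "+")],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    candidates = pd.DataFrame(
        {
            "variant_id": ["v_eqtl", "v_outside", "v_prom", "v_link", "v_ia", "v_none"],
            "chrom": ["chr14"] * 6,
            "pos": [50_000, 60_000, 101_500, 70_000, 80_000, 90_000],
        }
    )
    regions = {
        "dhs": IntervalSet([("chr14", 49_000, 51_000, ""), ("chr14", 69_000, 81_000, ""),
                            ("chr14", 89_000, 91_000, "")]),
        "enhancer": IntervalSet([]),
        "promoter": IntervalSet([("chr14", 98_000, 102_000, "FOXA1")]),
    }
    eqtl = pd.DataFrame(
        {
            "tf": ["FOXA1", "FOXA1", "FOXA1"],
            "variant_id": ["v_eqtl", "v_outside", "v_prom"],
            "pvalue": [0.01, 0.001, 0.3],
        }
    )
    links = pd.DataFrame([("FOXA1", "chr14", 69_500, 70_500)],
                         columns=["tf", "chrom", "start", "end"])
    interactions = pd.DataFrame(
        [("chr14", 79_500, 80_500, "chr14", 99_000, 101_000)],
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
    )
    return gene_table, candidates, regions, eqtl, links, interactions


class TestFindTfCisVariants:
    def test_evidence_rules(self, tf_setup):
        gene_table, candidates, regions, eqtl, links, interactions = tf_setup
        out = find_tf_cis_variants("FOXA1", gene_table, candidates, [eqtl], regions,
                                   links, interactions)
        assert set(out.variants) == {"v_eqtl", "v_prom", "v_link", "v_ia"}
        assert out.evidence["v_eqtl"] == {"eqtl"}
        # significant eQTL but outside all regulatory regions -> dropped
        assert "v_outside" not in out.variants
        # in the promoter (TSS + 1,500) with non-significant eQTL -> kept
        assert out.evidence["v_prom"] == {"promoter"}
        assert out.evidence["v_link"] == {"enhancer_link"}
        assert out.evidence["v_ia"] == {"chromatin_interaction"}
        # in a DHS but with no link to the TF -> dropped
        assert "v_none" not in out.variants

    def test_missing_tf_errors(self, tf_setup):
        gene_table, candidates, regions, eqtl, *_ = tf_setup
        with pytest.raises(KeyError, match="GATA3"):
            find_tf_cis_variants("GATA3", gene_table, candidates, [eqtl], regions)

    def test_monotone_in_link_table(self, tf_setup):
        """Enlarging the enhancer-link table never removes a variant."""
        gene_table, candidates, regions, eqtl, links, interactions = tf_setup
        small = find_tf_cis_variants("FOXA1", gene_table, candidates, [eqtl], regions,
                                     links.iloc[:0], interactions)
        big = find_tf_cis_variants("FOXA1", gene_table, candidates, [eqtl], regions,
                                   links, interactions)
        assert set(small.variants) <= set(big.variants)


class TestDiscoverTfGenePairs:
    def _genes(self, strand="+"):
        return pd.DataFrame(
            [("g1", "chr1", 100_000, 150_000, strand)],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )

    def test_peak_inside_window_paired(self):
        peaks = {"TF_A": IntervalSet([("chr1", 119_000, 119_500, "TF_A")])}
        out = discover_tf_gene_pairs(peaks, self._genes())
        assert out.pairs == {("TF_A", "g1")}

    def test_peak_outside_window_not_paired(self):
        peaks = {"TF_A": IntervalSet([("chr1", 120_100, 120_200, "TF_A")])}
        assert discover_tf_gene_pairs(peaks, self._genes()).pairs == set()

    def test_minus_strand_uses_transcript_end(self):
        # TSS of a minus-strand gene is the end coordinate (150,000)
        peaks = {"TF_A": IntervalSet([("chr1", 165_000, 165_400, "TF_A")])}
        assert discover_tf_gene_pairs(peaks, self._genes("-")).pairs == {("TF_A", "g1")}
        assert discover_tf_gene_pairs(peaks, self._genes("+")).pairs == set()

    def test_missing_strand_errors(self):
        genes = self._genes().drop(columns=["strand"])
        with pytest.raises(ValueError, match="strand"):
            discover_tf_gene_pairs({}, genes)

    def test_recovers_planted_assignments_exactly(self):
        cfg = SimulationConfig(n_genes=4, n_trans_regions=5, variants_per_region=10)
        ann = simulate_annotations(cfg, seed=7)
        out = discover_tf_gene_pairs(ann.tf_peaks, ann.gene_table)
        recovered = {(tf, g) for tf, g in out.pairs if g.startswith("gene")}
        assert recovered == ann.planted_tf_genes


def _null_gwas(n_variants, seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_variants)
    return SummaryStatsTable(
        pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n_variants)],
                "chrom": "chr1",
                "pos": np.arange(1, n_variants + 1),
                "effect_allele": "G",
                "other_allele": "A",
                "beta": z * 0.01,
                "se": 0.01,
            }
        )
    )


class TestPrioritizeStfcre:
    def test_inflated_binding_set_flagged(self):
        rng = np.random.default_rng(1)
        n = 5_000
        member = np.zeros(n, bool)
        member[:500] = True
        chi2 = np.where(member, rng.chisquare(2, n), rng.chisquare(1, n))
        z = np.sqrt(chi2) * rng.choice([-1, 1], n)
        gwas = SummaryStatsTable(
            pd.DataFrame(
                {
                    "variant_id": [f"v{i}" for i in range(n)],
                    "chrom": "chr1", "pos": np.arange(1, n + 1),
                    "effect_allele": "G", "other_allele": "A",
                    "beta": z * 0.01, "se": 0.01,
                }
            )
        )
        binding = pd.DataFrame({"TFX": member}, index=gwas.table.index)
        ranked, assoc = prioritize_stfcre_variants(gwas, binding, target_count=100)
        assert assoc.loc["TFX", "pvalue"] < 0.05
        assert len(ranked) == 100

    def test_null_flag_rate_near_alpha(self):
        gwas = _null_gwas(2_000, seed=2)
        rng = np.random.default_rng(3)
        binding = pd.DataFrame(
            rng.random((2_000, 1_000)) < 0.1,
            index=gwas.table.index,
            columns=[f"T{i}" for i in range(1_000)],
        )
        _, assoc = prioritize_stfcre_variants(gwas, binding)
        rate = (assoc["pvalue"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 1_000)
        assert abs(rate - 0.05) < 3 * se

    def test_truncation_deterministic(self):
        gwas = _null_gwas(100, seed=4)
        rng = np.random.default_rng(5)
        binding = pd.DataFrame(
            rng.random((100, 5)) < 0.5, index=gwas.table.index,
            columns=[f"T{i}" for i in range(5)],
        )
        a, _ = prioritize_stfcre_variants(gwas, binding, target_count=10, alpha=1.1)
        b, _ = prioritize_stfcre_variants(gwas, binding, target_count=10, alpha=1.1)
        assert a == b and len(a) == 10

    def test_no_tf_passing_returns_empty(self, caplog):
        import logging

        gwas = _null_gwas(50, seed=6)
        binding = pd.DataFrame({"T0": [True] * 25 + [False] * 25}, index=gwas.table.index)
        with caplog.at_level(logging.WARNING):
            ranked, _ = prioritize_stfcre_variants(gwas, binding, alpha=1e-12)
        assert ranked == []
        assert "no TF passed" in caplog.text


class TestBuildTransGroups:
    def _positions(self):
        rows = []
        for t in range(3):
            for i in range(50):
                rows.append((f"t{t}_v{i}", f"chr{t + 5}", 1_000_000 + i))
        rows.append(("near_v", "chr1", 5_500_000))  # 0.5 Mb from the gene body
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])

    def _map(self, tfs):
        m = TFGeneMap()
        for tf in tfs:
            m.pairs.add((tf, "g1"))
        return m

    def test_three_full_groups(self):
        sets = {f"TF{t}": TFCisVariantSet(f"TF{t}", [f"t{t}_v{i}" for i in range(50)])
                for t in range(3)}
        groups = build_trans_groups("g1", ("chr1", 5_000_000, 5_010_000),
                                    self._map(sets), sets, self._positions())
        assert [g.tf for g in groups] == ["TF0", "TF1", "TF2"]
        assert sum(len(g.variants) for g in groups) == 150

    def test_variant_within_1mb_removed(self):
        sets = {"TF0": TFCisVariantSet("TF0", ["t0_v0", "near_v"])}
        groups = build_trans_groups("g1", ("chr1", 5_000_000, 5_010_000),
                                    self._map(sets), sets, self._positions())
        assert groups[0].variants == ["t0_v0"]

    def test_all_near_group_dropped(self):
        sets = {"TF0": TFCisVariantSet("TF0", ["near_v"]),
                "TF1": TFCisVariantSet("TF1", ["t1_v0"])}
        groups = build_trans_groups("g1", ("chr1", 5_000_000, 5_010_000),
                                    self._map(sets), sets, self._positions())
        assert [g.tf for g in groups] == ["TF1"]
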