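"""Interval annotation, enrichment ratios, matched-loci permutation test."""

import numpy as np
import pandas as pd
import pytest

import helpdmr as h
from helpdmr.annotate import dhs_enrichment_test, matched_random_loci

from conftest import brute_force_overlap


def _iv(chrom, start, end, name="x"):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end], "name": [name]})


class TestRefseqCategories:
    def test_interval_inside_single_exon_gene_is_exon(self, toy_genes):
        # GB spans [40000,45000) as one exon; cds [41000,44000)
        out = h.assign_refseq_categories(_iv("chr1", 42_000, 42_300), toy_genes)
        assert out["category"].iloc[0] == "exon"

    def test_promoter_beats_first_exon(self, toy_genes):
        # GA '+' TSS 10000: promoter window [9000,10500); first exon [10000,11000)
        out = h.assign_refseq_categories(_iv("chr1", 9_900, 10_200), toy_genes)
        assert out["category"].iloc[0] == "promoter"

    def test_intron_and_intergenic(self, toy_genes):
        assert (
            h.assign_refseq_categories(_iv("chr1", 15_000, 15_200), toy_genes)["category"].iloc[0]
            == "intron"
        )
        assert (
            h.assign_refseq_categories(_iv("chr1", 300_000, 300_400), toy_genes)["category"].iloc[0]
            == "intergenic"
        )

    def test_utr_requires_coding_bounds(self, toy_genes):
        # within GA first exon, upstream of cdsStart -> 5' UTR
        out = h.assign_refseq_categories(_iv("chr1", 10_050, 10_080), toy_genes)
        assert out["category"].iloc[0] in ("promoter", "five_prime_utr")
        noncoding = toy_genes.assign(cdsStart=toy_genes["txStart"], cdsEnd=toy_genes["txStart"])
        out2 = h.assign_refseq_categories(_iv("chr1", 10_450, 10_480), noncoding)
        assert out2["category"].iloc[0] != "five_prime_utr"

    def test_nearest_gene_tie_breaks_lexicographically(self):
        genes = pd.DataFrame(
            {
                "gene": ["ZZZ", "AAA"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "+"],
                "txStart": [1_000, 9_000],
                "txEnd": [2_000, 10_000],
                "exonStarts": ["1000", "9000"],
                "exonEnds": ["2000", "10000"],
                "cdsStart": [1_000, 9_000],
                "cdsEnd": [2_000, 10_000],
            }
        )
        # midpoint 5000: equidistant (4000) from both TSSs
        out = h.assign_refseq_categories(_iv("chr1", 4_900, 5_100), genes)
        assert out["nearest_gene"].iloc[0] == "AAA"

    def test_every_interval_gets_exactly_one_category(self, small_data):
        frags = small_data.fragment_map.fragments.rename(columns={"fragment_id": "name"})
        out = h.assign_refseq_categories(
            frags[["name", "chrom", "start", "end"]], small_data.tracks.genes
        )
        assert len(out) == len(frags)
        assert out["category"].isin(h.CATEGORY_PRIORITY).all()


class TestEnrichmentRatios:
    def test_hand_computed_fractions(self):
        bg = pd.Series(["promoter"] * 20 + ["intron"] * 80)
        dmr = pd.Series(["promoter"] * 1 + ["intron"] * 9)
        out = h.refseq_enrichment_ratios(dmr, bg).set_index("category")
        assert out.loc["promoter", "enrichment_ratio"] == pytest.approx(0.5)
        assert out.loc["intron", "enrichment_ratio"] == pytest.approx(0.9 / 0.8)

    def test_self_comparison_is_unity(self):
        cats = pd.Series(["promoter", "exon", "intron", "intron", "tts"])
        out = h.refseq_enrichment_ratios(cats, cats)
        present = out[out["n_background"] > 0]
        assert (present["enrichment_ratio"] == 1.0).all()

    def test_absent_background_category_is_missing(self):
        out = h.refseq_enrichment_ratios(
            pd.Series(["promoter"]), pd.Series(["intron"])
        ).set_index("category")
        assert np.isnan(out.loc["promoter", "enrichment_ratio"])

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(20)
        cats = pd.Series(rng.choice(list(h.CATEGORY_PRIORITY), 500))
        out = h.refseq_enrichment_ratios(cats, cats)
        assert out["dmr_fraction"].sum() == pytest.approx(1.0)
        assert out["background_fraction"].sum() == pytest.approx(1.0)


class TestChromatinStateOverlap:
    def test_one_bp_overlap_counts_half_open_does_not(self):
        states = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [199, 250], "end": [250, 400],
             "state": ["E5_Enhancer", "E10_Quiescent"]}
        )
        hit, _ = h.chromatin_state_overlap(_iv("chr1", 100, 200), states)
        assert hit["state"].tolist() == ["E5_Enhancer"]
        assert hit["overlap_bp"].iloc[0] == 1
        miss, _ = h.chromatin_state_overlap(_iv("chr1", 100, 199), states)
        assert miss.empty

    def test_multi_state_spanning_dmr_counted_per_state(self):
        states = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 150], "end": [150, 300],
             "state": ["E1_TssActive", "E5_Enhancer"]}
        )
        hit, dist = h.chromatin_state_overlap(_iv("chr1", 100, 200), states)
        assert sorted(hit["state"]) == ["E1_TssActive", "E5_Enhancer"]
        assert dist["n"].sum() == 2

    def test_agrees_with_brute_force_on_random_intervals(self, small_data):
        rng = np.random.default_rng(21)
        genome = dict(zip(small_data.fragment_map.genome["chrom"],
                          small_data.fragment_map.genome["length"]))
        chroms = list(genome)
        q = pd.DataFrame(
            {
                "chrom": rng.choice(chroms, 200),
                "start": rng.integers(0, 50_000, 200),
            }
        )
        q["end"] = q["start"] + rng.integers(1, 2_000, 200)
        q["name"] = [f"q{i}" for i in range(200)]
        states = small_data.tracks.states
        assignments, _ = h.chromatin_state_overlap(q, states)
        got = set(zip(assignments["name"], assignments["state"]))
        expected = set()
        for iv in q.itertuples(index=False):
            for s in states.itertuples(index=False):
                if iv.chrom == s.chrom and min(iv.end, s.end) - max(iv.start, s.start) >= 1:
                    expected.add((iv.name, s.state))
        assert got == expected


class TestCountOverlapping:
    @pytest.mark.parametrize("min_overlap", [1, 25])
    def test_matches_brute_force(self, min_overlap):
        rng = np.random.default_rng(22)
        n, m = 150, 60
        q = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], n), "start": rng.integers(0, 10_000, n)}
        )
        q["end"] = q["start"] + rng.integers(1, 300, n)
        s = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], m), "start": rng.integers(0, 10_000, m)}
        )
        s["end"] = s["start"] + rng.integers(1, 300, m)
        got = h.count_overlapping(q, s, min_overlap).to_numpy()
        np.testing.assert_array_equal(got, brute_force_overlap(q, s, min_overlap))


class TestMatchedRandomLoci:
    def test_empty_request(self):
        assert len(matched_random_loci(0, 443, {"chr1": 10_000}, 0)) == 0

    def test_geometry_audit(self):
        genome = {"chr1": 2_000_000, "chr2": 1_000_000}
        loci = matched_random_loci(4751, 443, genome, 7)
        assert len(loci) == 4751
        assert ((loci["end"] - loci["start"]) == 443).all()
        for chrom, g in loci.groupby("chrom"):
            assert (g["start"] >= 0).all()
            assert (g["end"] <= genome[chrom]).all()
        # chromosomes sampled roughly proportional to length (2:1)
        frac = (loci["chrom"] == "chr1").mean()
        assert abs(frac - 2 / 3) < 3 * np.sqrt((2 / 3) * (1 / 3) / 4751)

    def test_short_chromosome_excluded(self):
        loci = matched_random_loci(50, 443, {"chr1": 100_000, "tiny": 100}, 1)
        assert (loci["chrom"] == "chr1").all()

    def test_seed_reproducibility(self):
        genome = {"chr1": 100_000}
        a = matched_random_loci(100, 443, genome, 5)
        b = matched_random_loci(100, 443, genome, 5)
        pd.testing.assert_frame_equal(a, b)


class TestDhsEnrichment:
    def test_saturated_cover_gives_p_one(self):
        genome = {"chr1": 10_000}
        dmrs = pd.DataFrame(
            {"chrom": ["chr1"] * 5, "start": [0, 2000, 4000, 6000, 8000],
             "end": [400, 2400, 4400, 6400, 8400]}
        )
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        res = dhs_enrichment_test(dmrs, peaks, genome, n_permutations=49, seed=0)
        assert res.observed == 5
        assert res.p_value == 1.0

    def test_empirical_p_bounds_and_determinism(self, small_data):
        frags = small_data.fragment_map.fragments
        dmr_ids = small_data.truth.fragments.query("direction != 'null'")["fragment_id"]
        dmrs = frags[frags["fragment_id"].isin(dmr_ids)]
        genome = dict(zip(small_data.fragment_map.genome["chrom"],
                          small_data.fragment_map.genome["length"]))
        res1 = dhs_enrichment_test(dmrs, small_data.tracks.dhs, genome, 99, seed=3)
        res2 = dhs_enrichment_test(dmrs, small_data.tracks.dhs, genome, 99, seed=3)
        assert 1 / 100 <= res1.p_value <= 1.0
        np.testing.assert_array_equal(res1.null_counts, res2.null_counts)
        assert res1.p_value == res2.p_value
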