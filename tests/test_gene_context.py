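import numpy as np
import pandas as pd
import pytest

from polyte.gene_context import (
    closest_flanking_te,
    module_enrichment,
    promoter_enrichment,
    promoter_intervals,
    promoter_te_copies,
    triplet_flank_conservation,
)


def _gene(gene_id, chrom, start, end, strand="+"):
    return {
        "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
        "strand": strand, "subgenome": chrom[-1],
    }


def _te(copy_id, chrom, start, end, family="DTT_famc1"):
    return {
        "copy_id": copy_id, "chrom": chrom, "start": start, "end": end,
        "strand": "+", "family": family, "subfamily": None, "superfamily": family[:3],
    }


class TestClosestFlanking:
    def test_distances_on_both_sides(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 10_000, 13_000)])
        tes = pd.DataFrame(
            [_te("t1", "c1A", 7_000, 7_500), _te("t2", "c1A", 13_200, 14_000)]
        )
        out = closest_flanking_te(genes, tes).iloc[0]
        assert (out["up_copy"], out["up_dist"]) == ("t1", 2_500)
        assert (out["down_copy"], out["down_dist"]) == ("t2", 200)

    def test_overlap_gives_zero_distance(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 10_000, 13_000)])
        tes = pd.DataFrame([_te("t1", "c1A", 9_500, 10_500)])
        out = closest_flanking_te(genes, tes).iloc[0]
        assert out["up_dist"] == 0

    def test_no_te_on_chromosome(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 10_000, 13_000)])
        tes = pd.DataFrame([_te("t1", "c9D", 0, 100)])
        out = closest_flanking_te(genes, tes).iloc[0]
        assert out["up_copy"] is None and out["down_copy"] is None

    def test_minus_strand_swaps_sides(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 10_000, 13_000, strand="-")])
        tes = pd.DataFrame(
            [_te("t1", "c1A", 7_000, 7_500), _te("t2", "c1A", 13_200, 14_000)]
        )
        out = closest_flanking_te(genes, tes).iloc[0]
        assert out["up_copy"] == "t2" and out["down_copy"] == "t1"

    def test_agrees_with_brute_force(self, rng):
        chrom = "c1A"
        genes = pd.DataFrame(
            [_gene(f"g{i}", chrom, int(s), int(s) + 500)
             for i, s in enumerate(sorted(rng.choice(200_000, 30, replace=False)))]
        )
        tes = pd.DataFrame(
            [_te(f"t{i}", chrom, int(s), int(s) + int(rng.integers(50, 400)))
             for i, s in enumerate(sorted(rng.choice(210_000, 400, replace=False)))]
        )
        out = closest_flanking_te(genes, tes)
        for g in genes.itertuples(index=False):
            left = tes[tes["start"] < g.start]
            right = tes[tes["end"] > g.end]
            exp_up = (
                left.sort_values(["end", "start", "copy_id"]).iloc[-1]["copy_id"]
                if len(left) else None
            )
            exp_down = (
                right.sort_values(["start", "end", "copy_id"]).iloc[0]["copy_id"]
                if len(right) else None
            )
            row = out[out["gene_id"] == g.gene_id].iloc[0]
            assert row["up_copy"] == exp_up
            assert row["down_copy"] == exp_down


class TestPromoterCopies:
    def test_te_inside_promoter_counted(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 10_000, 13_000)])
        tes = pd.DataFrame([_te("t1", "c1A", 8_500, 9_000)])
        assert len(promoter_te_copies(genes, tes)) == 1

    def test_one_bp_overlap_counted(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 10_000, 13_000)])
        tes = pd.DataFrame([_te("t1", "c1A", 7_700, 8_001)])
        assert len(promoter_te_copies(genes, tes)) == 1

    def test_te_inside_gene_body_not_counted(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 10_000, 13_000)])
        tes = pd.DataFrame([_te("t1", "c1A", 11_000, 11_500)])
        assert promoter_te_copies(genes, tes).empty

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 10_000, 13_000, strand="-")])
        prom = promoter_intervals(genes).iloc[0]
        assert (prom["start"], prom["end"]) == (13_000, 15_000)

    def test_truncated_at_chromosome_start(self):
        genes = pd.DataFrame([_gene("g1", "c1A", 500, 2_000)])
        prom = promoter_intervals(genes).iloc[0]
        assert (prom["start"], prom["end"]) == (0, 500)


class TestPromoterEnrichment:
    def _tables(self, n_prom, n_bg):
        """Synthetic copy tables with given per-family promoter/background counts."""
        prom_rows, genome_rows = [], []
        i = 0
        for fam, (np_, nb) in {**n_prom}.items():
            for _ in range(np_):
                prom_rows.append({"gene_id": "g", "copy_id": f"c{i}", "family": fam,
                                  "chrom": "c1A"})
                genome_rows.append(_te(f"c{i}", "c1A", 10 * i, 10 * i + 5, fam))
                i += 1
            for _ in range(nb):
                genome_rows.append(_te(f"c{i}", "c1A", 10 * i, 10 * i + 5, fam))
                i += 1
        return pd.DataFrame(prom_rows), pd.DataFrame(genome_rows)

    def test_fourfold_enrichment_is_log2_two(self):
        # promoters: fam1 10%, genome-wide 2.5%
        prom, genome = self._tables({"DTT_famc1": (10, 15), "DTC_famc1": (90, 885)}, {})
        out = promoter_enrichment(prom, genome, min_copies=10)
        row = out[out["family"] == "DTT_famc1"].iloc[0]
        assert row["pct_fg"] == pytest.approx(10.0)
        assert row["pct_bg"] == pytest.approx(2.5)
        assert row["log2_ratio"] == pytest.approx(2.0)

    def test_equal_percentages_zero_ratio(self):
        prom, genome = self._tables({"DTT_famc1": (10, 90), "DTC_famc1": (90, 810)}, {})
        out = promoter_enrichment(prom, genome, min_copies=10)
        assert out["log2_ratio"].abs().max() == pytest.approx(0.0)

    def test_rare_families_dropped(self):
        prom, genome = self._tables({"DTT_famc1": (10, 15), "DTC_famc1": (90, 885)}, {})
        out = promoter_enrichment(prom, genome, min_copies=500)
        assert set(out["family"]) == {"DTC_famc1"}

    def test_percentages_sum_to_100(self):
        prom, genome = self._tables(
            {"DTT_famc1": (10, 40), "DTC_famc1": (20, 130), "RSX_famc1": (5, 45)}, {}
        )
        out = promoter_enrichment(prom, genome, min_copies=1)
        assert out["pct_bg"].sum() == pytest.approx(100.0)
        assert out["pct_fg"].sum() == pytest.approx(100.0)


class TestModuleEnrichment:
    def _upstream(self, assignments):
        return pd.DataFrame(
            [{"gene_id": g, "family": f} for g, f in assignments.items()]
        )

    def test_small_module_skipped(self):
        up = self._upstream({f"g{i}": "DTT_famc1" for i in range(1000)})
        modules = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(1000)],
             "module_id": ["M1"] * 800 + ["M2"] * 200}
        )
        out = module_enrichment(up, modules, min_module_genes=1000)
        assert out.empty

    def test_background_matching_module_has_zero_ratios(self):
        genes = {f"g{i}": ("DTT_famc1" if i % 2 else "DTC_famc1") for i in range(2000)}
        up = self._upstream(genes)
        modules = pd.DataFrame(
            {"gene_id": list(genes), "module_id": ["M1" if i < 1000 else "M2"
                                                   for i in range(2000)]}
        )
        out = module_enrichment(up, modules, min_module_genes=500)
        assert out["log2_ratio"].abs().max() < 0.1

    def test_unknown_gene_errors(self):
        up = self._upstream({"g1": "DTT_famc1"})
        modules = pd.DataFrame({"gene_id": ["ghost"], "module_id": ["M1"]})
        with pytest.raises(Exception):
            module_enrichment(up, modules, min_module_genes=1)


class TestTripletConservation:
    def _flanks(self, fams):
        return pd.DataFrame(
            [{"gene_id": g, "up_copy": "c", "up_family": f, "up_dist": 100,
              "down_copy": None, "down_family": None, "down_dist": None}
             for g, f in fams.items()]
        )

    def test_categories(self):
        triplets = pd.DataFrame(
            [{"group_id": "T1", "gene_A": "a1", "gene_B": "b1", "gene_D": "d1"},
             {"group_id": "T2", "gene_A": "a2", "gene_B": "b2", "gene_D": "d2"},
             {"group_id": "T3", "gene_A": "a3", "gene_B": "b3", "gene_D": "d3"}]
        )
        flanks = self._flanks({
            "a1": "f1", "b1": "f1", "d1": "f1",
            "a2": "f1", "b2": "f2", "d2": "f3",
            "a3": "f1", "b3": "f1", "d3": "f2",
        })
        out, summary = triplet_flank_conservation(triplets, flanks)
        by_id = dict(zip(out["group_id"], out["category"]))
        assert by_id == {"T1": "all_same", "T2": "all_different", "T3": "two_same"}
        assert summary["all_same"] == pytest.approx(1 / 3)

    def test_incomplete_and_rejected(self):
        triplets = pd.DataFrame(
            [{"group_id": "T1", "gene_A": "a1", "gene_B": "b1", "gene_D": "d1"},
             {"group_id": "T2", "gene_A": "a2", "gene_B": "a2", "gene_D": "d2"}]
        )
        flanks = self._flanks({"a1": "f1", "b1": "f1"})  # d1 missing
        out, summary = triplet_flank_conservation(triplets, flanks)
        cats = dict(zip(out["group_id"], out["category"]))
        assert cats["T1"] == "incomplete"
        assert cats["T2"] == "rejected_not_1_1_1"
        assert summary["n_complete"] == 0
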