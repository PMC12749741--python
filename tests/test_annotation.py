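"""Context enrichment, promoter mapping, gene-set tests and biomarker staging."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from crcmeth.annotation import (
    context_enrichment,
    evaluate_biomarkers,
    geneset_enrichment,
    load_biomarker_panel,
    map_promoter_genes,
    promoter_universe,
    read_gmt,
    stage_from_fractions,
)
from crcmeth.core import BetaMatrix, ProbeAnnotation


def _annotation(contexts, genes=None, regions=None):
    n = len(contexts)
    genes = genes or [[f"G{i}"] for i in range(n)]
    regions = regions or [["Body"]] * n
    frame = pd.DataFrame(
        {
            "chr": ["chr1"] * n,
            "pos": np.arange(1, n + 1),
            "island_context": contexts,
            "gene_symbols": genes,
            "region_groups": regions,
        },
        index=[f"cg{i:05d}" for i in range(n)],
    )
    return ProbeAnnotation(frame)


def _hypergeom_p_oracle(k, N, K, n):
    """Upper-tail hypergeometric by explicit summation."""
    return sum(
        comb(K, x) * comb(N - K, n - x) / comb(N, n)
        for x in range(k, min(K, n) + 1)
    )


def _fisher_p_oracle(a, b, c, d):
    """Two-sided Fisher exact p by enumerating the hypergeometric support."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)
        )

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestContextEnrichment:
    def test_odds_ratio_arithmetic(self):
        # a=10 island DMCs, b=90, c=20, d=880 -> OR = (10*880)/(90*20)
        contexts = (
            ["Island"] * 30 + ["OpenSea"] * 970
        )  # 30 island probes, 10 of them DMCs
        ann = _annotation(contexts)
        dmcs = [f"cg{i:05d}" for i in range(10)] + [
            f"cg{i:05d}" for i in range(30, 120)
        ]
        out = context_enrichment(dmcs, ann.probe_ids, ann, "gain")
        row = out.set_index("island_context").loc["Island"]
        assert (row["a"], row["b"], row["c"], row["d"]) == (10, 90, 20, 880)
        assert row["odds_ratio"] == pytest.approx(4.888888, rel=1e-6)
        assert row["p"] == pytest.approx(
            _fisher_p_oracle(10, 90, 20, 880), rel=1e-6
        )

    def test_haldane_correction_on_zero_cell(self):
        contexts = ["Island"] * 10 + ["OpenSea"] * 90
        ann = _annotation(contexts)
        dmcs = [f"cg{i:05d}" for i in range(10, 30)]  # no island DMC
        out = context_enrichment(dmcs, ann.probe_ids, ann, "loss")
        row = out.set_index("island_context").loc["Island"]
        assert row["a"] == 0
        assert np.isfinite(row["odds_ratio"]) and row["odds_ratio"] < 1

    def test_counts_sum_to_universe(self):
        contexts = ["Island", "N_Shore", "S_Shelf", "OpenSea"] * 25
        ann = _annotation(contexts)
        dmcs = [f"cg{i:05d}" for i in range(0, 40)]
        out = context_enrichment(dmcs, ann.probe_ids, ann, "gain")
        assert (out[["a", "b", "c", "d"]].sum(axis=1) == 100).all()

    def test_absent_context_row_p_one(self):
        contexts = ["Island"] * 50
        ann = _annotation(contexts)
        out = context_enrichment([], ann.probe_ids, ann, "gain")
        row = out.set_index("island_context").loc["OpenSea"]
        assert row["p"] == 1.0 and row["a"] == 0

    def test_merge_shores_and_shelves(self):
        contexts = ["N_Shore", "S_Shore", "N_Shelf", "S_Shelf"] * 10
        ann = _annotation(contexts)
        out = context_enrichment([], ann.probe_ids, ann, "gain", merge_shores_shelves=True)
        assert set(out["island_context"]) == {"Island", "Shore", "Shelf", "OpenSea"}

    def test_planted_island_bias_detected(self, default_synthetic):
        """The generator plants island/shore-enriched gains; the Fisher test
        finds them."""
        bm, ann, _, truth = default_synthetic
        gains = truth.probes.index[truth.probes["direction"] == "gain"]
        out = context_enrichment(gains, bm.probe_ids, ann, "gain")
        row = out.set_index("island_context").loc["Island"]
        assert row["odds_ratio"] > 1
        assert row["q"] < 0.05

    def test_fisher_matches_enumeration_on_small_margins(self):
        """Sweep of 2x2 tables with total n <= 30 against the enumeration
        oracle."""
        from scipy.stats import fisher_exact

        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            if a + b + c + d == 0 or a + b + c + d > 30:
                continue
            p_scipy = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert p_scipy == pytest.approx(
                _fisher_p_oracle(a, b, c, d), abs=1e-9
            ), (a, b, c, d)


class TestPromoterMapping:
    def test_promoter_regions_only(self):
        ann = _annotation(
            ["Island", "Island"],
            genes=[["GENE1"], ["GENE2"]],
            regions=[["TSS200"], ["Body"]],
        )
        genes, table = map_promoter_genes(ann.probe_ids, ann)
        assert genes == {"GENE1"}
        assert list(table["region_group"]) == ["TSS200"]

    def test_multi_gene_probe(self):
        ann = _annotation(
            ["Island"],
            genes=[["GENE1", "GENE2"]],
            regions=[["TSS1500", "TSS1500"]],
        )
        genes, _ = map_promoter_genes(ann.probe_ids, ann)
        assert genes == {"GENE1", "GENE2"}

    def test_empty_probe_set(self):
        ann = _annotation(["Island"], regions=[["TSS200"]])
        genes, table = map_promoter_genes([], ann)
        assert genes == set() and table.empty

    def test_universe_covers_all_promoter_genes(self):
        ann = _annotation(
            ["Island"] * 3,
            genes=[["A"], ["B"], ["C"]],
            regions=[["TSS200"], ["1stExon"], ["3UTR"]],
        )
        assert promoter_universe(ann) == {"A", "B"}


class TestGenesetEnrichment:
    def test_hypergeometric_oracle(self):
        # universe 100, set 10, hits 20, overlap 5
        universe = {f"g{i}" for i in range(100)}
        geneset = {f"g{i}" for i in range(10)}
        hits = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 65)}
        out = geneset_enrichment(hits, universe, {"s": geneset})
        expected = _hypergeom_p_oracle(5, 100, 10, 20)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.0254, abs=2e-4)

    def test_zero_overlap_near_one(self):
        universe = {f"g{i}" for i in range(100)}
        out = geneset_enrichment(
            {"g0", "g1"}, universe, {"s": {"g98", "g99"}}
        )
        assert out["p"].iloc[0] > 0.9

    def test_degenerate_all_equal(self):
        universe = {"a", "b", "c"}
        out = geneset_enrichment(universe, universe, {"s": universe})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="zzz"):
            geneset_enrichment({"zzz"}, {"a"}, {"s": {"a"}})

    def test_monotone_in_overlap(self):
        universe = {f"g{i}" for i in range(60)}
        geneset = {f"g{i}" for i in range(20)}
        prev = 1.1
        for k in range(0, 15):
            hits = {f"g{i}" for i in range(k)} | {
                f"g{i}" for i in range(20, 35 - k)
            }
            p = geneset_enrichment(hits, universe, {"s": geneset})["p"].iloc[0]
            assert p <= prev + 1e-12
            prev = p

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET1\tdesc\tA\tB\tC\nSET2\tdesc\tB\tD\n")
        sets = read_gmt(path)
        assert sets == {"SET1": {"A", "B", "C"}, "SET2": {"B", "D"}}


class TestBiomarkers:
    def test_packaged_panel_loads(self):
        panel = load_biomarker_panel()
        assert {"gene", "probe_id", "region_group", "specimen"} <= set(panel.columns)
        assert "SEPT9" in set(panel["gene"])
        assert (
            panel.loc[panel["gene"] == "SEPT9", "probe_id"].iloc[0] == "cg17300544"
        )
        assert len(panel) == 35

    @pytest.mark.parametrize(
        "fracs,expected",
        [
            ({"NONTUMOR": 0.0, "LGA": 0.1, "HGA": 0.9, "ADK": 1.0}, "high_grade_onset"),
            ({"NONTUMOR": 0.0, "LGA": 0.0, "HGA": 0.2, "ADK": 0.1}, "non_informative"),
            ({"NONTUMOR": 1.0, "LGA": 1.0, "HGA": 1.0, "ADK": 1.0}, "early"),
            ({"NONTUMOR": 0.0, "LGA": 0.1, "HGA": 0.3, "ADK": 0.9}, "carcinoma_onset"),
            ({"NONTUMOR": 0.0, "LGA": 0.5, "HGA": 0.5, "ADK": 0.5}, "early"),
        ],
    )
    def test_stage_rule(self, fracs, expected):
        assert stage_from_fractions(fracs) == expected

    def test_evaluate_on_constructed_matrix(self):
        # two panel probes: one methylated from HGA on, one never
        values = pd.DataFrame(
            {
                "N1": [0.05, 0.05],
                "N2": [0.05, 0.05],
                "L1": [0.1, 0.05],
                "L2": [0.1, 0.05],
                "H1": [0.7, 0.05],
                "H2": [0.8, 0.05],
                "A1": [0.9, 0.05],
                "A2": [0.9, 0.05],
            },
            index=["cg17300544", "cg20276585"],
        )
        groups = pd.Series(
            ["NONTUMOR"] * 2 + ["LGA"] * 2 + ["HGA"] * 2 + ["ADK"] * 2,
            index=values.columns,
        )
        bm = BetaMatrix(values=values, groups=groups)
        panel = pd.DataFrame(
            {
                "gene": ["SEPT9", "BMP3"],
                "probe_id": ["cg17300544", "cg20276585"],
                "region_group": ["TSS200", "TSS200"],
            }
        )
        out = evaluate_biomarkers(bm, panel, cutoff=0.3).set_index("gene")
        assert out.loc["SEPT9", "stage"] == "high_grade_onset"
        assert out.loc["BMP3", "stage"] == "non_informative"

    def test_absent_probe_warns_and_emits_missing_row(self):
        values = pd.DataFrame({"A1": [0.9], "A2": [0.8]}, index=["cg17300544"])
        groups = pd.Series(["ADK", "ADK"], index=values.columns)
        bm = BetaMatrix(values=values, groups=groups)
        panel = pd.DataFrame(
            {"gene": ["SEPT9", "BMP3"], "probe_id": ["cg17300544", "cg20276585"]}
        )
        with pytest.warns(UserWarning, match="cg20276585"):
            out = evaluate_biomarkers(bm, panel)
        assert out.set_index("gene").loc["BMP3", "stage"] == "missing"

    def test_no_panel_probe_present_raises(self):
        values = pd.DataFrame({"A1": [0.9], "A2": [0.8]}, index=["cgXXXX"])
        groups = pd.Series(["ADK", "ADK"], index=values.columns)
        bm = BetaMatrix(values=values, groups=groups)
        with pytest.raises(ValueError):
            evaluate_biomarkers(bm)
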