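"""Data model, table IO, evidence classes, and network statistics."""

import itertools

import numpy as np
import pytest

from cytgrn.grn_model import (CytokineGRN, SchemaError, activity_fraction,
                              build_grns, classify_evidence,
                              degree_rank_coverage, read_interaction_table,
                              species_overlap, write_interaction_table)
from cytgrn.synthetic_data import generate_grn

from conftest import make_record


class TestClassifyEvidence:
    def test_exhaustive_truth_table(self):
        """High evidence requires functional plus a binding read-out, over
        all 7 non-empty assay subsets."""
        cats = ["binding_in_vitro", "chip", "functional"]
        for r in range(1, 4):
            for subset in itertools.combinations(cats, r):
                s = set(subset)
                expected = ("high" if "functional" in s
                            and s & {"chip", "binding_in_vitro"} else "low")
                assert classify_evidence(s) == expected

    @pytest.mark.parametrize("assays,level", [
        ({"functional", "chip"}, "high"),
        ({"binding_in_vitro"}, "low"),
        ({"chip", "binding_in_vitro"}, "low"),  # no functional assay
    ])
    def test_stated_examples(self, assays, level):
        assert classify_evidence(assays) == level

    def test_empty_assays_rejected(self):
        with pytest.raises(ValueError):
            classify_evidence(set())


class TestReadInteractionTable:
    def test_duplicate_rows_merge(self, tmp_path):
        """Two reports of the same PDI merge; assays and articles union."""
        path = tmp_path / "t.tsv"
        path.write_text(
            "TF\tCytokine\tSpecies\tAssay\tActivity\tPMID\n"
            "RELA\tIL6\thuman\tchip\tactivating\t111\n"
            "rela \til6\thuman\tluciferase\t\t222\n")
        records = read_interaction_table(path)
        assert len(records) == 1
        (r,) = records
        assert r.assay_categories == {"chip", "functional"}
        assert set(r.article_ids) == {"111", "222"}
        assert r.regulatory_activity == "activating"
        assert r.evidence_level == "high"

    def test_blank_symbol_rejected(self, tmp_path, caplog):
        path = tmp_path / "t.tsv"
        path.write_text("TF\tCytokine\tSpecies\tAssay\tActivity\tPMID\n"
                        "\tIL6\thuman\tchip\t\t1\n"
                        "RELA\tTNF\thuman\temsa\t\t2\n")
        with caplog.at_level("WARNING"):
            records = read_interaction_table(path)
        assert len(records) == 1
        assert records[0].tf_symbol == "RELA"
        assert "rejected" in caplog.text

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("TF\tCytokine\tAssay\n")
        with pytest.raises(SchemaError, match="Species"):
            read_interaction_table(path)

    def test_conflicting_activities_become_bifunctional(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("TF\tCytokine\tSpecies\tAssay\tActivity\tPMID\n"
                        "A\tIL6\thuman\tchip\tactivating\t1\n"
                        "A\tIL6\thuman\tchip\trepressing\t2\n")
        (r,) = read_interaction_table(path)
        assert r.regulatory_activity == "bifunctional"

    def test_round_trip_identity(self, tmp_path):
        grn = generate_grn(n_tfs=10, n_cytokines=12, seed=4)
        out = tmp_path / "written.tsv"
        write_interaction_table(grn.records, out)
        back = read_interaction_table(out)
        assert sorted((r.tf_symbol, r.cytokine_symbol, r.species,
                       tuple(sorted(r.assay_categories)),
                       r.regulatory_activity, r.article_ids)
                      for r in back) == \
               sorted((r.tf_symbol, r.cytokine_symbol, r.species,
                       tuple(sorted(r.assay_categories)),
                       r.regulatory_activity, r.article_ids)
                      for r in grn.records)


class TestDegreeRankCoverage:
    def test_strict_exceedance(self, toy_grn):
        """A alone covers exactly 50%, so two of four TFs are needed."""
        assert degree_rank_coverage(toy_grn, "tf", 0.5) == pytest.approx(0.5)

    def test_single_tf(self):
        grn = CytokineGRN("human", [make_record("A", "IL6")])
        assert degree_rank_coverage(grn, "tf", 0.5) == 1.0

    def test_against_bruteforce_oracle(self):
        """Sweep coverage on random networks against cumulative sums; k is
        non-decreasing in the coverage level."""
        rng = np.random.default_rng(7)
        for trial in range(10):
            grn = generate_grn(n_tfs=12, n_cytokines=15,
                               seed=int(rng.integers(2**31)))
            deg = sorted(grn.tf_degree.items(), key=lambda kv: (-kv[1], kv[0]))
            n, total = len(deg), grn.n_edges
            last_k = 0
            for coverage in np.linspace(0.05, 0.95, 19):
                cum, k_oracle = 0, n
                for k, (_, d) in enumerate(deg, start=1):
                    cum += d
                    if cum > coverage * total:
                        k_oracle = k
                        break
                frac = degree_rank_coverage(grn, "tf", float(coverage))
                assert frac == pytest.approx(k_oracle / n)
                assert k_oracle >= last_k
                last_k = k_oracle

    def test_bad_inputs(self, toy_grn):
        with pytest.raises(ValueError):
            degree_rank_coverage(toy_grn, "tf", 0.0)
        with pytest.raises(ValueError):
            degree_rank_coverage(CytokineGRN.from_edges("human", []), "tf", 0.5)


class TestSpeciesOverlap:
    def test_identical_networks(self, toy_grn):
        ov = species_overlap(toy_grn, toy_grn)
        assert ov.frac_specific_a == 0.0 and ov.frac_specific_b == 0.0

    def test_disjoint_networks(self, toy_grn):
        other = CytokineGRN.from_edges("mouse", [("Z", "IL33"), ("W", "IL2")])
        ov = species_overlap(toy_grn, other)
        assert ov.frac_specific_a == 1.0 and ov.frac_specific_b == 1.0

    def test_ortholog_map_translates(self, toy_grn):
        # mouse-style pair maps onto the human IL6 edge through the map
        mouse = CytokineGRN.from_edges("mouse", [("A", "IL6M"), ("B", "CXCL1")])
        ov = species_overlap(toy_grn, mouse, ortholog_map={"IL6M": "IL6"})
        assert ("A", "IL6") in ov.shared_pairs
        assert ov.frac_specific_b == pytest.approx(0.5)

    def test_shared_set_symmetric(self, toy_grn):
        mouse = CytokineGRN.from_edges("mouse",
                                       [("A", "IL6"), ("Q", "IL13")])
        ab = species_overlap(toy_grn, mouse)
        ba = species_overlap(mouse, toy_grn)
        assert ab.shared_pairs == ba.shared_pairs


class TestActivityFraction:
    def test_unknown_excluded_from_denominator(self):
        records = ([make_record("A", f"C{i}", activity="activating",
                                pmids=(str(i),)) for i in range(3)]
                   + [make_record("B", "C9", activity="repressing")]
                   + [make_record("D", f"C{i}", activity="unknown",
                                  pmids=(str(i),)) for i in range(6)])
        grn = CytokineGRN("human", records)
        assert activity_fraction(grn, "activating") == pytest.approx(0.75)

    def test_all_unknown_errors(self):
        grn = CytokineGRN("human", [make_record("A", "IL6")])
        with pytest.raises(ValueError, match="annotated"):
            activity_fraction(grn, "activating")

    def test_all_activating(self):
        grn = CytokineGRN("human",
                          [make_record("A", "IL6", activity="activating")])
        assert activity_fraction(grn, "activating") == 1.0


def test_build_grns_splits_by_species():
    records = [make_record("A", "IL6"), make_record("A", "IL6", species="mouse")]
    grns = build_grns(records)
    assert set(grns) == {"human", "mouse"}
    assert grns["human"].n_edges == 1


def test_degree_sum_invariant(toy_grn):
    assert (sum(toy_grn.tf_degree.values())
            == sum(toy_grn.cytokine_degree.values())
            == toy_grn.n_edges)
    assert min(toy_grn.tf_degree.values()) >= 1
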