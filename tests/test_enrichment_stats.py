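"""Proportion/Fisher tests, BH adjustment, and the association summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from cytgrn.enrichment_stats import (ContingencyTable2x2, bh_adjust,
                                     celltype_enrichment,
                                     connectivity_phenotype, cofactor_usage,
                                     disease_enrichment, drug_targetability,
                                     family_comparison, fisher_exact,
                                     proportion_test)
from cytgrn.grn_model import CytokineGRN
from cytgrn.synthetic_data import generate_grn

from conftest import make_record


def hypergeom_fisher_oracle(a, b, c, d, sided):
    """Exact p by enumerating the hypergeometric support with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {x: (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)
             for x in support}
    if sided == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    cutoff = probs[a] * (1 + 1e-9)
    return sum(p for p in probs.values() if p <= cutoff)


class TestProportionTest:
    def test_hand_computed_pooled_z(self):
        z, p = proportion_test(8, 10, 2, 10)
        assert z == pytest.approx(0.6 / math.sqrt(0.05), abs=1e-3)  # 2.683
        assert p == pytest.approx(0.0073, abs=2e-4)

    def test_equal_proportions(self):
        z, p = proportion_test(5, 10, 5, 10)
        assert z == 0.0 and p == 1.0

    def test_extreme_split(self):
        z, p = proportion_test(10, 10, 0, 10)
        assert z == pytest.approx(4.472, abs=1e-3)
        assert p < 1e-4

    def test_degenerate_pooled_proportion(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, p = proportion_test(0, 10, 0, 10)
        assert (z, p) == (0.0, 1.0)

    @given(st.integers(0, 20), st.integers(1, 20),
           st.integers(0, 20), st.integers(1, 20))
    @settings(max_examples=60, deadline=None)
    def test_p_matches_normal_tail_of_z(self, x1, n1, x2, n2):
        x1, x2 = min(x1, n1), min(x2, n2)
        if (x1 + x2) in (0, n1 + n2):
            return
        z, p = proportion_test(x1, n1, x2, n2)
        assert p == pytest.approx(2 * scipy.stats.norm.sf(abs(z)), abs=1e-12)


class TestFisherExact:
    def test_enumeration_example(self):
        or_, p = fisher_exact(ContingencyTable2x2(3, 1, 1, 3), sided="two")
        assert or_ == 9.0
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_least_extreme_greater(self):
        _, p = fisher_exact(ContingencyTable2x2(0, 5, 5, 0), sided="greater")
        assert p == pytest.approx(1.0)

    def test_infinite_odds_ratio(self):
        or_, _ = fisher_exact(ContingencyTable2x2(3, 0, 0, 3), sided="two")
        assert or_ == float("inf")

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @given(st.integers(0, 8), st.integers(0, 8),
           st.integers(0, 8), st.integers(0, 8),
           st.sampled_from(["two", "greater"]))
    @settings(max_examples=120, deadline=None)
    def test_matches_hypergeometric_oracle(self, a, b, c, d, sided):
        """Exact p equals full hypergeometric enumeration on all tables
        with n <= 32."""
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        _, p = fisher_exact(ContingencyTable2x2(a, b, c, d), sided)
        assert p == pytest.approx(hypergeom_fisher_oracle(a, b, c, d, sided),
                                  rel=1e-9, abs=1e-12)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.8])
        assert list(adj) == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_single_and_ties(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert list(bh_adjust([0.2, 0.2, 0.2])) == pytest.approx([0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_dominates_raw(self, pvals):
        adj = bh_adjust(sorted(pvals))
        assert all(a >= p for a, p in zip(adj, sorted(pvals)))
        assert list(adj) == sorted(adj)  # monotone on sorted input
        assert (adj <= 1.0 + 1e-12).all()


class TestCelltypeEnrichment:
    def test_dominant_tf_is_significant(self):
        """A TF whose six targets are the only Th17 cytokines, against
        other TFs' 20 targets outside it, clears FDR 0.1."""
        th17 = [f"TH{i}" for i in range(6)]
        other = [f"C{i}" for i in range(20)]
        records = [make_record("HIT", c, pmids=(c,)) for c in th17]
        for i, c in enumerate(other):
            records.append(make_record(f"T{i % 5}", c, pmids=(c,)))
        grn = CytokineGRN("human", records)
        celltypes = {c: {"Th17"} for c in th17}
        celltypes.update({c: set() for c in other})
        results = celltype_enrichment(grn, celltypes, fdr=0.1)
        hit = [r for r in results if r.unit == ("HIT", "Th17")]
        assert hit and hit[0].significant

    def test_null_false_positive_rate_controlled(self):
        """Uniform random cell-type assignment keeps the significant
        fraction at or below the FDR plus sampling error, over 200
        replicates."""
        rng = np.random.default_rng(42)
        n_sig = n_tests = 0
        for _ in range(200):
            grn = generate_grn(n_tfs=8, n_cytokines=12,
                               seed=int(rng.integers(2**31)))
            celltypes = {c: {ct for ct in ("ctA", "ctB")
                             if rng.random() < 0.4}
                         for c in grn.cytokines}
            results = celltype_enrichment(grn, celltypes, fdr=0.1)
            n_sig += sum(r.significant for r in results)
            n_tests += len(results)
        assert n_tests > 500
        assert n_sig / n_tests <= 0.1 + 0.03

    def test_empty_annotation_warns(self, toy_grn, caplog):
        with caplog.at_level("WARNING"):
            results = celltype_enrichment(
                toy_grn, {c: set() for c in toy_grn.cytokines})
        assert results == [] and "empty" in caplog.text


class TestDiseaseEnrichment:
    def test_perfect_overlap_significant(self):
        """A TF hitting all five upregulated cytokines of a disease and
        none of the other 95 is significant."""
        universe = {f"C{i}" for i in range(100)}
        up = {f"C{i}" for i in range(5)}
        records = [make_record("TF1", c, pmids=(c,)) for c in up]
        records += [make_record("TF2", c, pmids=(c,)) for c in
                    ["C50", "C51", "C52"]]
        grn = CytokineGRN("human", records)
        results = disease_enrichment(grn, {"dis": up}, universe, fdr=0.1)
        by_unit = {r.unit: r for r in results}
        assert by_unit[("TF1", "dis")].significant
        assert by_unit[("TF1", "dis")].statistic == float("inf")

    def test_disjoint_targets_not_significant(self):
        universe = {f"C{i}" for i in range(20)}
        records = [make_record("TF1", "C10"), make_record("TF1", "C11",
                                                          pmids=("2",))]
        grn = CytokineGRN("human", records)
        results = disease_enrichment(grn, {"dis": {"C0", "C1"}}, universe)
        (r,) = results
        assert r.statistic == 0.0 and not r.significant

    def test_label_permutation_controls_fdr(self):
        """Random disease sets drawn independently of the network keep the
        significant fraction near or below the nominal FDR."""
        rng = np.random.default_rng(17)
        n_sig = n_tests = 0
        for _ in range(100):
            grn = generate_grn(n_tfs=8, n_cytokines=20,
                               seed=int(rng.integers(2**31)))
            universe = set(f"CYT{i:03d}" for i in range(1, 21))
            sets = {f"d{j}": set(rng.choice(sorted(universe), size=5,
                                            replace=False))
                    for j in range(3)}
            results = disease_enrichment(grn, sets, universe, fdr=0.1)
            n_sig += sum(r.significant for r in results)
            n_tests += len(results)
        assert n_sig / n_tests <= 0.1 + 0.03

    def test_empty_disease_set_skipped(self, toy_grn, caplog):
        with caplog.at_level("WARNING"):
            results = disease_enrichment(toy_grn, {"dis": set()},
                                         toy_grn.cytokines)
        assert results == [] and "skipping" in caplog.text


class TestFamilyComparison:
    def test_identical_networks_on_diagonal(self, toy_grn):
        ref = dict(toy_grn.tf_degree)
        groups = {tf: f"fam_{tf}" for tf in toy_grn.tfs}
        df, r = family_comparison(toy_grn, ref, groups)
        assert np.allclose(df["pct_grn"], df["pct_reference"])
        assert r == pytest.approx(1.0)

    def test_halved_family_above_diagonal(self, toy_grn):
        ref = dict(toy_grn.tf_degree)
        ref["A"] = ref["A"] // 2  # family A under-represented in reference
        groups = {tf: f"fam_{tf}" for tf in toy_grn.tfs}
        df, _ = family_comparison(toy_grn, ref, groups)
        row = df[df["group"] == "fam_A"].iloc[0]
        assert row["pct_grn"] > row["pct_reference"]

    def test_zero_pdi_group_retained(self, toy_grn):
        ref = dict(toy_grn.tf_degree)
        groups = {tf: "famX" for tf in toy_grn.tfs}
        groups["GHOST"] = "famGhost"
        df, _ = family_comparison(toy_grn, ref, groups)
        ghost = df[df["group"] == "famGhost"].iloc[0]
        assert ghost["pct_grn"] == 0.0 and ghost["pct_reference"] == 0.0

    def test_empty_reference_errors(self, toy_grn):
        with pytest.raises(ValueError):
            family_comparison(toy_grn, {}, {"A": "f"})


class TestConnectivityPhenotype:
    def test_all_flagged(self, toy_grn):
        df = connectivity_phenotype(toy_grn, {tf: True for tf in toy_grn.tfs})
        assert (df["fraction_flagged"] == 1.0).all()

    def test_monotone_with_planted_flags(self):
        """Flag probability increasing in degree yields higher flagged
        fractions in higher-degree bins."""
        grn = generate_grn(n_tfs=150, n_cytokines=60, seed=21)
        rng = np.random.default_rng(21)
        flags = {tf: bool(rng.random() < min(0.95, 0.1 * d))
                 for tf, d in grn.tf_degree.items()}
        df = connectivity_phenotype(grn, flags).set_index("bin")
        lo = df.loc["1", "fraction_flagged"]
        hi = df.loc[[b for b in (">=10", "5-9") if b in df.index][0],
                    "fraction_flagged"]
        assert hi > lo

    def test_degree_zero_bin_from_universe(self, toy_grn):
        df = connectivity_phenotype(toy_grn, {"GHOST": True},
                                    tf_universe=["GHOST"])
        assert df.set_index("bin").loc["0", "fraction_flagged"] == 1.0


class TestCofactorAndDrugs:
    def test_cofactor_counts(self, toy_grn):
        counts, fractions = cofactor_usage(
            toy_grn, [("A", "EP300"), ("B", "EP300"), ("C", "NCOA1")],
            tf_class={"A": "PSA", "B": "PSA", "C": "TS"})
        il6 = counts[(counts["cytokine"] == "IL6")
                     & (counts["cofactor"] == "EP300")]
        assert il6["n_tfs"].iloc[0] == 2  # A and B both bind IL6
        psa_only = fractions[fractions["cofactor"] == "EP300"].iloc[0]
        assert psa_only["frac_psa"] == 1.0

    def test_drug_grouping_and_double_counting(self, toy_grn, caplog):
        tf_drugs = [("A", "d1", "activator"),   # grouped as agonist
                    ("A", "d2", "inhibitor"),   # and as antagonist
                    ("B", "d3", "antagonist"),
                    ("C", "d4", "modulator")]   # unknown -> other
        with caplog.at_level("WARNING"):
            df = drug_targetability(toy_grn, tf_drugs).set_index("cytokine")
        assert df.loc["IL6", "n_agonist_tfs"] == 1     # A
        assert df.loc["IL6", "n_antagonist_tfs"] == 2  # A and B
        assert df.loc["IFNG", "n_agonist_tfs"] == 0
        assert "modulator" in caplog.text
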