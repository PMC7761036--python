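"""Assignment table, three-pass allocation, composition estimation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycolinker import (
    FractionLabel,
    LinkageCode,
    LinkageProfile,
    SchemaError,
    ValidationError,
    allocate_linkages,
    compare_fractions,
    default_assignment_table,
    estimate_composition,
    estimate_from_profile,
    load_assignment_table,
)
from glycolinker.assignments import REPORT_ORDER

from _oracle import oracle_allocate
from conftest import EDTA, KOH4, VOCABULARY, random_profile_means

L = LinkageCode.parse


class TestAssignmentTable:
    def test_default_5_araf_maps_only_to_arabinan(self, table):
        assert table.candidates(L("5-Araf"), None) == ["AB"]

    def test_default_t_fucp_maps_to_agII_and_xg(self, table):
        assert table.candidates(L("t-Fucp"), None) == ["AG-II/ET", "XG"]

    def test_default_3_glcp_maps_to_callose(self, table):
        assert table.candidates(L("3-Glcp"), None) == ["CA"]

    def test_cellulose_suppressed_in_chelator_and_alkali_fractions(self, table):
        assert "CE" in table.candidates(L("4-Glcp"), None)
        assert "CE" not in table.candidates(L("4-Glcp"), "EDTA+Na2CO3")
        assert "CE" not in table.candidates(L("4-Glcp"), "4M KOH")
        assert "CE" in table.candidates(L("4-Glcp"), "Residue")

    def test_config_removing_callose(self, tmp_path):
        cfg = tmp_path / "table.yaml"
        cfg.write_text("classes:\n  CA: []\n")
        table = load_assignment_table(cfg)
        assert "CA" not in table.classes
        assert table.candidates(L("3-Glcp"), None) == []
        profile = LinkageProfile.from_means({"3-Glcp": 4.0, "4-Xylp": 96.0})
        comp = estimate_from_profile(profile, table)
        assert comp.values["UA"] == pytest.approx(4.0)

    def test_unknown_tokens_rejected(self, tmp_path):
        cfg = tmp_path / "table.yaml"
        cfg.write_text("classes:\n  XYZ: [4-Glcp]\n")
        with pytest.raises(SchemaError, match="XYZ"):
            load_assignment_table(cfg)
        cfg.write_text("classes:\n  CA: [9-Qlcp]\n")
        with pytest.raises(ValidationError):
            load_assignment_table(cfg)

    def test_rule_constants_configurable(self, tmp_path):
        cfg = tmp_path / "table.yaml"
        cfg.write_text("rules:\n  glc_man_ratio: 0.5\n")
        table = load_assignment_table(cfg)
        assert table.rules["glc_man_ratio"] == 0.5
        assert table.rules["xg_unbranched_ratio"] == pytest.approx(1 / 3)


class TestAllocation:
    def test_galA_without_rhamnose_goes_to_hg(self, table):
        profile = LinkageProfile.from_means({"4-GalAp": 100.0})
        comp = estimate_from_profile(profile, table)
        assert comp.values["RG-I"] == 0.0
        assert comp.values["HG"] == pytest.approx(100.0)

    def test_galA_split_by_rhamnose_backbone(self, table):
        profile = LinkageProfile.from_means(
            {"2-Rhap": 10.0, "2,4-Rhap": 5.0, "4-GalAp": 40.0, "t-GalAp": 2.0,
             "5-Araf": 43.0}
        )
        comp = estimate_from_profile(profile, table)
        # RG-I backbone takes GalA up to the rhamnose sum (15), rest is HG
        assert comp.values["RG-I"] == pytest.approx(30.0)
        assert comp.values["HG"] == pytest.approx(27.0)
        assert comp.values["AB"] == pytest.approx(43.0)

    def test_glc_partition_whole_wall(self, table):
        profile = LinkageProfile.from_means(
            {"4-Glcp": 10.0, "4,6-Glcp": 9.0, "t-Xylp": 6.0, "2-Xylp": 3.0,
             "5-Araf": 72.0}
        )
        matrix = allocate_linkages(profile, table)
        assert matrix.frame.at["4-Glcp", "XG"] == pytest.approx(3.0)  # 9/3
        assert matrix.frame.at["4-Glcp", "CE"] == pytest.approx(7.0)

    def test_glc_partition_cellulose_suppressed(self, table):
        profile = LinkageProfile.from_means(
            {"4-Glcp": 10.0, "4,6-Glcp": 9.0, "t-Xylp": 6.0, "2-Xylp": 3.0,
             "5-Araf": 72.0},
            fraction=EDTA,
        )
        matrix = allocate_linkages(profile, table)
        assert matrix.frame.at["4-Glcp", "CE"] == 0.0
        assert matrix.frame.at["4-Glcp", "XG"] == pytest.approx(10.0)

    def test_unmapped_linkage_goes_to_ua(self, table):
        profile = LinkageProfile.from_means({"2-Glcp": 4.0, "4-Xylp": 96.0})
        comp = estimate_from_profile(profile, table)
        assert comp.values["UA"] == pytest.approx(4.0)

    def test_zero_demand_terminal_falls_to_first_class(self, table):
        # no branch points anywhere: t-Araf goes to AB (first row)
        profile = LinkageProfile.from_means({"t-Araf": 100.0})
        comp = estimate_from_profile(profile, table)
        assert comp.values["AB"] == pytest.approx(100.0)

    def test_terminal_split_proportional_to_demand(self, table):
        # AB demand 2,5-Araf = 10; AG-I demand 4,6-Galp = 5 -> 2:1 split
        profile = LinkageProfile.from_means(
            {"t-Araf": 30.0, "2,5-Araf": 10.0, "4,6-Galp": 5.0, "4-Xylp": 55.0}
        )
        matrix = allocate_linkages(profile, table)
        assert matrix.frame.at["t-Araf", "AB"] == pytest.approx(20.0)
        assert matrix.frame.at["t-Araf", "AG-I"] == pytest.approx(10.0)

    def test_monotone_in_rhamnose(self, table):
        """More Rha backbone weakly raises RG-I and weakly lowers HG."""
        prev_rg, prev_hg = -1.0, 101.0
        for rha in (0.0, 5.0, 10.0, 20.0, 30.0):
            profile = LinkageProfile.from_means(
                {"2-Rhap": rha, "4-GalAp": 40.0, "4-Xylp": 60.0 - rha}
            )
            comp = estimate_from_profile(profile, table)
            assert comp.values["RG-I"] >= prev_rg
            assert comp.values["HG"] <= prev_hg
            prev_rg, prev_hg = comp.values["RG-I"], comp.values["HG"]

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_row_conservation_on_random_profiles(self, seed, table):
        rng = np.random.default_rng(seed)
        means = random_profile_means(rng, max_linkages=10)
        profile = LinkageProfile.from_means(means)
        matrix = allocate_linkages(profile, table)
        for lk, amount in means.items():
            assert matrix.frame.loc[lk].sum() == pytest.approx(amount, abs=1e-9)
        assert (matrix.frame.to_numpy() >= -1e-12).all()

    def test_composition_sums_to_profile_total(self, table):
        rng = np.random.default_rng(3)
        profile = LinkageProfile.from_means(random_profile_means(rng, 8))
        comp = estimate_from_profile(profile, table)
        assert comp.total == pytest.approx(100.0, abs=1e-9)


class TestOracleAgreement:
    def test_brute_force_agreement_spot(self, table):
        rng = np.random.default_rng(99)
        for _ in range(50):
            means = random_profile_means(rng, 6)
            fraction = rng.choice([None, "EDTA+Na2CO3", "4M KOH", "Residue"])
            label = FractionLabel("linkage-series", fraction) if fraction else None
            profile = LinkageProfile.from_means(means, fraction=label)
            matrix = allocate_linkages(profile, table)
            expected = oracle_allocate(means, fraction, table)
            for lk, per_class in expected.items():
                for cls, amount in per_class.items():
                    assert matrix.frame.at[lk, cls] == pytest.approx(amount, abs=1e-9), (
                        lk, cls, fraction)


class TestCompareFractions:
    def test_single_composition_shape_and_order(self, table):
        comp = estimate_from_profile(LinkageProfile.from_means({"4-GalAp": 100.0}), table)
        report = compare_fractions([comp])
        assert list(report["class"]) == list(REPORT_ORDER)
        assert report.loc[report["class"] == "HG", "molar_percent"].item() == 100.0

    def test_two_fractions_give_22_rows(self, table):
        a = estimate_from_profile(
            LinkageProfile.from_means({"4-GalAp": 100.0}, fraction=EDTA), table)
        b = estimate_from_profile(
            LinkageProfile.from_means({"4-Xylp": 100.0}, fraction=KOH4), table)
        report = compare_fractions([a, b])
        assert len(report) == 22

    def test_duplicate_fraction_labels_rejected(self, table):
        comp = estimate_from_profile(LinkageProfile.from_means({"4-GalAp": 100.0}), table)
        with pytest.raises(ValidationError, match="duplicate"):
            compare_fractions([comp, comp])

    def test_pectin_vs_residue_enrichment_ordering(self, table):
        """Synthetic pectin-enriched vs residue fractions: pectins dominate the
        chelator pool, cellulose dominates the residue."""
        from glycolinker import generate_fractionation

        profiles, _, _ = generate_fractionation()
        pectin = estimate_from_profile(profiles["EDTA+Na2CO3"], table)
        residue = estimate_from_profile(profiles["Residue"], table)
        pectin_sum = pectin.values["RG-I"] + pectin.values["HG"]
        residue_sum = residue.values["RG-I"] + residue.values["HG"]
        assert pectin_sum > residue_sum
        assert residue.values["CE"] > pectin.values["CE"]
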