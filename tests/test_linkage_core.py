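"""Linkage nomenclature, peak tables, spectral matching, molar% profiles."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycolinker import (
    FormatError,
    FractionLabel,
    LibraryEntry,
    LinkageCode,
    LinkageProfile,
    PeakRecord,
    ValidationError,
    aggregate_replicates,
    assign_peaks,
    compute_molar_composition,
    compute_yields,
    cosine_similarity,
    match_spectrum,
    parse_peak_table,
    write_peak_table,
)
from glycolinker.peaks import load_library

from conftest import VOCABULARY, EDTA


class TestLinkageCode:
    @pytest.mark.parametrize("text", ["t-Araf", "5-Araf", "2,5-Araf", "2,3,5-Araf",
                                      "4-GalAp", "t-GlcAp", "3,4,6-Galp", "4-Glcp"])
    def test_parse_render_roundtrip(self, text):
        assert str(LinkageCode.parse(text)) == text

    def test_vocabulary_roundtrips(self):
        for text in VOCABULARY:
            assert str(LinkageCode.parse(text)) == text

    def test_positions_are_canonicalised(self):
        # order of positions in the input does not matter
        assert LinkageCode("Ara", "f", frozenset({5, 2})) == LinkageCode.parse("2,5-Araf")

    def test_uronic_origin_flag(self):
        assert LinkageCode.parse("4-GalAp").uronic_origin
        assert LinkageCode.parse("t-GlcAp").uronic_origin
        assert not LinkageCode.parse("4-Glcp").uronic_origin

    @pytest.mark.parametrize("bad", ["4-Qlcp", "x-Galp", "7-Glcp", "Galp", "4-Gal"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValidationError):
            LinkageCode.parse(bad)

    def test_fraction_label_scheme_membership(self):
        FractionLabel("linkage-series", "EDTA+Na2CO3")
        with pytest.raises(ValidationError):
            FractionLabel("linkage-series", "AO")


class TestPeakTable:
    def test_read_back_areas(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text(
            "peak_id,rt_min,area\np1,10.0,2\np2,11.0,3\np3,12.0,5\n"
        )
        records = parse_peak_table(p)
        assert [r.area for r in records] == [2, 3, 5]
        assert [r.peak_id for r in records] == ["p1", "p2", "p3"]

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("peak_id,rt_min,area\n")
        assert parse_peak_table(p) == []

    def test_negative_area_cites_row(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("peak_id,rt_min,area\np1,10.0,-1\n")
        with pytest.raises(ValidationError, match="row 1"):
            parse_peak_table(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("peak_id,rt_min\np1,10.0\n")
        with pytest.raises(FormatError, match="area"):
            parse_peak_table(p)

    def test_roundtrip_with_spectra_and_linkages(self, tmp_path):
        records = [
            PeakRecord("p1", 10.0, 2.5, spectrum=[(100.0, 1.0), (200.0, 0.5)],
                       assigned_linkage=LinkageCode.parse("4-Glcp")),
            PeakRecord("p2", 11.0, 3.0),
        ]
        p = tmp_path / "peaks.csv"
        write_peak_table(records, p)
        back = parse_peak_table(p)
        assert back[0].spectrum == records[0].spectrum
        assert back[0].assigned_linkage == records[0].assigned_linkage
        assert back[1].spectrum is None

    def test_unsorted_spectrum_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            PeakRecord("p", 1.0, 1.0, spectrum=[(200.0, 1.0), (100.0, 1.0)])


LIB = [
    LibraryEntry(LinkageCode.parse("4-Glcp"), ((118.0, 100.0), (233.0, 45.0))),
    LibraryEntry(LinkageCode.parse("4-Xylp"), ((117.0, 80.0), (189.0, 60.0))),
]


class TestSpectrumMatching:
    def test_self_match_ranks_first_with_unit_similarity(self):
        for entry in LIB:
            ranked = match_spectrum(list(entry.spectrum), LIB)
            assert ranked[0][0] == entry.linkage
            assert ranked[0][1] == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        sim = cosine_similarity([(500.0, 1.0)], list(LIB[0].spectrum))
        assert sim == 0.0

    def test_hand_computed_cosine(self):
        # (1*0.5 + 0.5*1) / (sqrt(1.25) * sqrt(1.25)) = 0.8
        sim = cosine_similarity([(100.0, 1.0), (200.0, 0.5)],
                                [(100.0, 0.5), (200.0, 1.0)])
        assert sim == pytest.approx(0.8)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            match_spectrum([], LIB)
        with pytest.raises(ValidationError):
            match_spectrum([(100.0, 1.0)], [])

    def test_assignment_gates_on_threshold_and_rt(self):
        lib = [
            LibraryEntry(LinkageCode.parse("4-Glcp"), ((118.0, 100.0),),
                         retention_time=20.0, retention_window=0.5),
        ]
        inside = PeakRecord("a", 20.2, 1.0, spectrum=[(118.0, 90.0)])
        outside = PeakRecord("b", 25.0, 1.0, spectrum=[(118.0, 90.0)])
        got = assign_peaks([inside, outside], lib)
        assert got[0].assigned_linkage == LinkageCode.parse("4-Glcp")
        assert got[1].assigned_linkage is None

    def test_matchms_cross_check(self):
        """The similarity agrees with matchms CosineGreedy on spectra whose
        peak separations make the greedy pairing unambiguous."""
        matchms = pytest.importorskip("matchms")
        import numpy as np
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(7)
        for _ in range(20):
            q_mz = np.sort(rng.choice(np.arange(60, 400, 2.0), 8, replace=False))
            r_mz = np.sort(rng.choice(np.arange(60, 400, 2.0), 8, replace=False))
            q_int = rng.random(8) + 0.1
            r_int = rng.random(8) + 0.1
            ours = cosine_similarity(list(zip(q_mz, q_int)), list(zip(r_mz, r_int)),
                                     mz_tolerance=0.5)
            score = CosineGreedy(tolerance=0.5).pair(
                matchms.Spectrum(mz=q_mz, intensities=q_int,
                                 metadata={"precursor_mz": 1.0}, metadata_harmonization=False),
                matchms.Spectrum(mz=r_mz, intensities=r_int,
                                 metadata={"precursor_mz": 1.0}, metadata_harmonization=False),
            )
            assert ours == pytest.approx(float(score["score"]), abs=1e-9)

    def test_msp_and_json_libraries_agree(self, tmp_path):
        msp = tmp_path / "lib.msp"
        msp.write_text(
            "NAME: 4-Glcp\nRT: 21.4\nRTWIN: 0.3\nNum Peaks: 2\n118 100\n233 45\n\n"
            "NAME: t-Araf\nNum Peaks: 1\n101 99\n"
        )
        js = tmp_path / "lib.json"
        js.write_text(
            '[{"linkage": "4-Glcp", "spectrum": [[118, 100], [233, 45]],'
            ' "rt": 21.4, "rt_window": 0.3},'
            ' {"linkage": "t-Araf", "spectrum": [[101, 99]]}]'
        )
        assert load_library(msp) == load_library(js)


class TestMolarComposition:
    def _peaks(self, spec):  # spec: list of (linkage, area)
        return [
            PeakRecord(f"p{i}", 10.0 + i, area,
                       assigned_linkage=LinkageCode.parse(lk))
            for i, (lk, area) in enumerate(spec)
        ]

    def test_single_peak_is_100(self):
        prof = compute_molar_composition(self._peaks([("4-Glcp", 7.0)]))
        assert prof.entries[LinkageCode.parse("4-Glcp")].mean == pytest.approx(100.0)

    def test_equal_areas_split_evenly(self):
        prof = compute_molar_composition(self._peaks([("4-Glcp", 3.0), ("4-Xylp", 3.0)]))
        assert all(s.mean == pytest.approx(50.0) for s in prof.entries.values())

    def test_response_factor_normalization(self):
        # areas 2, 3, 5 with factors 1, 1, 2 -> adjusted 2, 3, 2.5 over 7.5
        prof = compute_molar_composition(
            self._peaks([("t-Araf", 2.0), ("4-Xylp", 3.0), ("4-Glcp", 5.0)]),
            response_factors={LinkageCode.parse("4-Glcp"): 2.0},
        )
        means = {str(lk): s.mean for lk, s in prof.entries.items()}
        assert means["t-Araf"] == pytest.approx(100 * 2 / 7.5)
        assert means["4-Xylp"] == pytest.approx(100 * 3 / 7.5)
        assert means["4-Glcp"] == pytest.approx(100 * 2.5 / 7.5)

    def test_same_linkage_peaks_are_summed(self):
        prof = compute_molar_composition(
            self._peaks([("4-Glcp", 2.0), ("4-Glcp", 3.0), ("4-Xylp", 5.0)])
        )
        assert prof.entries[LinkageCode.parse("4-Glcp")].mean == pytest.approx(50.0)

    def test_unassigned_peaks_listed(self):
        peaks = self._peaks([("4-Glcp", 1.0)]) + [PeakRecord("stray", 9.0, 1.0)]
        with pytest.raises(ValidationError, match="stray"):
            compute_molar_composition(peaks)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        areas=st.lists(st.floats(0.01, 1e6), min_size=1, max_size=12),
        scale=st.floats(1e-3, 1e3),
    )
    def test_normalization_and_scale_invariance(self, areas, scale):
        """Output sums to 100 and is invariant to rescaling all areas."""
        linkages = [VOCABULARY[i % len(VOCABULARY)] for i in range(len(areas))]
        base = compute_molar_composition(self._peaks(list(zip(linkages, areas))))
        scaled = compute_molar_composition(
            self._peaks([(lk, a * scale) for lk, a in zip(linkages, areas)])
        )
        assert base.total_check == pytest.approx(100.0, abs=1e-9)
        for lk, stat in base.entries.items():
            assert scaled.entries[lk].mean == pytest.approx(stat.mean, rel=1e-9)


class TestAggregateReplicates:
    def _profile(self, means):
        return LinkageProfile.from_means(means, fraction=EDTA)

    def test_identical_replicates_have_zero_sd(self):
        prof = self._profile({"4-Glcp": 60.0, "4-GalAp": 40.0})
        agg = aggregate_replicates([prof, prof, prof])
        for stat in agg.entries.values():
            assert stat.sd == 0.0
            assert stat.n == 3

    def test_hand_computed_sample_sd(self):
        reps = [self._profile({"4-Glcp": v, "4-GalAp": 100 - v}) for v in (10, 12, 14)]
        agg = aggregate_replicates(reps)
        stat = agg.entries[LinkageCode.parse("4-Glcp")]
        assert stat.mean == pytest.approx(12.0)
        assert stat.sd == pytest.approx(2.0)

    def test_absent_linkage_counts_as_zero(self):
        reps = [
            self._profile({"3-Glcp": 3.0, "4-Glcp": 97.0}),
            self._profile({"3-Glcp": 3.0, "4-Glcp": 97.0}),
            self._profile({"4-Glcp": 100.0}),
        ]
        agg = aggregate_replicates(reps)
        stat = agg.entries[LinkageCode.parse("3-Glcp")]
        assert stat.mean == pytest.approx(2.0)
        assert stat.sd == pytest.approx(math.sqrt(3.0))

    def test_mixed_fractions_rejected(self):
        a = LinkageProfile.from_means({"4-Glcp": 100.0}, fraction=EDTA)
        b = LinkageProfile.from_means({"4-Glcp": 100.0})
        with pytest.raises(ValidationError, match="fraction"):
            aggregate_replicates([a, b])


class TestYields:
    def test_full_recovery_is_100(self):
        ledger = compute_yields(50.0, {EDTA: 50.0})
        assert ledger.yields[EDTA] == pytest.approx(100.0)
        assert not ledger.over_recovery

    def test_pretreated_fraction_yields(self):
        """Yield bookkeeping for a 100 mg borodeuteride-pretreated wall whose
        three fractions weigh 32.1, 29.0 and 38.9 mg."""
        from conftest import KOH4, RESIDUE

        ledger = compute_yields(100.0, {EDTA: 32.1, KOH4: 29.0, RESIDUE: 38.9})
        assert ledger.yields[EDTA] == pytest.approx(32.1)
        assert ledger.yields[KOH4] == pytest.approx(29.0)
        assert ledger.yields[RESIDUE] == pytest.approx(38.9)
        assert ledger.total_yield == pytest.approx(100.0)
        assert not ledger.over_recovery

    def test_over_recovery_flagged(self):
        from conftest import KOH4

        ledger = compute_yields(100.0, {EDTA: 60.0, KOH4: 60.0})
        assert ledger.over_recovery

    def test_nonpositive_starting_mass_rejected(self):
        with pytest.raises(ValidationError):
            compute_yields(0.0, {EDTA: 1.0})
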