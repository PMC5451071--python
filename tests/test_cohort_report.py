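import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcellassay import (
    AlleleFrequencyTable,
    HLAGenotype,
    ReadoutKind,
    build_report,
    cohort_hla_path,
    donor_frequencies,
    hla_allele_frequencies,
    immunogenicity_plot_table,
    magnitude_table,
    population_correlation,
    read_allele_frequencies,
    read_hla_table,
    responder_frequency,
    synthetic_reference_path,
)
from tcellassay.response_stats import DonorCompoundCall, ReadoutSummary


def make_call(donor, compound, si_by_readout, pos_by_readout):
    summaries = tuple(
        ReadoutSummary(
            donor_id=donor,
            compound=compound,
            readout=ro,
            si=si_by_readout[ro],
            p_value=0.01 if pos_by_readout[ro] else 0.5,
            n_treated=6,
            n_baseline=6,
            positive=pos_by_readout[ro],
        )
        for ro in ReadoutKind
    )
    return DonorCompoundCall(donor, compound, summaries, any(pos_by_readout.values()))


def flat_calls(n_donors, compound, si=1.0, positive=False):
    si_map = {ro: si for ro in ReadoutKind}
    pos_map = {ro: positive for ro in ReadoutKind}
    return [make_call(f"d{i}", compound, si_map, pos_map) for i in range(n_donors)]


class TestMagnitudeTable:
    def test_unit_si_everywhere(self):
        table = magnitude_table(flat_calls(5, "X"))
        assert np.allclose(table.loc["X"], 1.0)

    def test_null_cohort_means_near_one(self, calibration_run):
        # non-responder (donor, compound) groups have no planted signal, so
        # their mean SI sits near 1 for the proliferation readouts
        _, _, truth, calls = calibration_run
        null_pairs = {
            (r.donor_id, r.compound)
            for r in truth.donors.itertuples()
            if not r.is_responder
        }
        sis = [
            s.si
            for c in calls
            if (c.donor_id, c.compound) in null_pairs
            for s in c.readouts
            if s.readout.is_proliferation
        ]
        assert np.mean(sis) == pytest.approx(1.0, abs=0.1)

    def test_controls_dominate_bp_means(self, calibration_run):
        _, _, _, calls = calibration_run
        table = magnitude_table(calls)
        bps = ["infliximab", "rituximab", "adalimumab", "natalizumab"]
        for readout in table.columns:
            top = min(table.loc["KLH", readout], table.loc["CMV", readout])
            assert all(table.loc[bp, readout] < top for bp in bps)


class TestImmunogenicityPlot:
    def test_zero_responders_has_absent_ordinate(self):
        table = immunogenicity_plot_table(flat_calls(4, "X"))
        row = table.set_index("compound").loc["X"]
        assert row["pct_responders"] == 0.0
        assert math.isnan(row["mean_si_responders"])

    def test_single_responder_single_positive_readout(self):
        si = {ReadoutKind.PROLIF_D6: 4.0, ReadoutKind.PROLIF_D8: 1.0, ReadoutKind.ELISPOT: 1.0}
        pos = {ReadoutKind.PROLIF_D6: True, ReadoutKind.PROLIF_D8: False, ReadoutKind.ELISPOT: False}
        calls = [make_call("d0", "X", si, pos)] + flat_calls(4, "X")[1:]
        table = immunogenicity_plot_table(calls).set_index("compound")
        assert table.loc["X", "pct_responders"] == 25.0
        assert table.loc["X", "mean_si_responders"] == pytest.approx(4.0)

    def test_all_readouts_mode_includes_negative_readouts(self):
        si = {ReadoutKind.PROLIF_D6: 4.0, ReadoutKind.PROLIF_D8: 1.0, ReadoutKind.ELISPOT: 1.0}
        pos = {ReadoutKind.PROLIF_D6: True, ReadoutKind.PROLIF_D8: False, ReadoutKind.ELISPOT: False}
        calls = [make_call("d0", "X", si, pos)]
        table = immunogenicity_plot_table(calls, responder_si="all_readouts")
        assert table["mean_si_responders"].iloc[0] == pytest.approx(2.0)

    def test_reference_cohort_ordering(self, calibration_run):
        _, _, _, calls = calibration_run
        table = immunogenicity_plot_table(calls).set_index("compound")
        pct = table["pct_responders"]
        assert pct["natalizumab"] > pct["rituximab"] > pct["adalimumab"] > pct["infliximab"]
        assert [pct[c] for c in ("natalizumab", "rituximab", "adalimumab", "infliximab")] == [
            26.9,
            19.2,
            7.7,
            3.8,
        ]


# hand-tallied DRB1 chromosome counts of the bundled 26-donor typing table
# (single-allele donor 17 counted homozygous: 52 chromosomes in total)
DRB1_HAND_TALLY = {
    "*01:01": 5, "*01:02": 1, "*03:01": 5, "*04:01": 4, "*04:04": 7,
    "*04:07": 1, "*07:01": 6, "*10:01": 1, "*11:01": 2, "*12:01": 1,
    "*13:01": 3, "*13:02": 5, "*14:01": 3, "*15:01": 8,
}


class TestHLAFrequencies:
    def test_two_identical_heterozygotes(self):
        genotypes = [
            HLAGenotype("a", "DRB1", "*01:01", "*02:01"),
            HLAGenotype("b", "DRB1", "*01:01", "*02:01"),
        ]
        table = hla_allele_frequencies(genotypes, "DRB1")
        assert table.frequencies == {"*01:01": 0.5, "*02:01": 0.5}

    def test_homozygote_conventions_for_single_allele(self):
        genotypes = [HLAGenotype("17", "DRB1", "*15:01")] + [
            HLAGenotype(str(i), "DRB1", "*01:01", "*02:01") for i in range(3)
        ]
        hom = hla_allele_frequencies(genotypes, "DRB1", "homozygous")
        single = hla_allele_frequencies(genotypes, "DRB1", "single")
        assert hom.frequencies["*15:01"] == pytest.approx(2 / 8)
        assert single.frequencies["*15:01"] == pytest.approx(1 / 7)

    def test_bundled_table_matches_hand_tally(self):
        genotypes = read_hla_table(cohort_hla_path())
        table = hla_allele_frequencies(genotypes, "DRB1", "homozygous")
        total = sum(DRB1_HAND_TALLY.values())
        assert total == 52
        expected = {a: n / total for a, n in DRB1_HAND_TALLY.items()}
        assert set(table.frequencies) == set(expected)
        for allele, freq in expected.items():
            assert table.frequencies[allele] == pytest.approx(freq, abs=1e-12)

    def test_unknown_convention_errors(self):
        with pytest.raises(ValueError, match="convention"):
            hla_allele_frequencies(
                [HLAGenotype("a", "DRB1", "*01:01", "*02:01")], "DRB1", "carrier"
            )


class TestPopulationCorrelation:
    def test_identical_tables_give_r_one(self):
        t = AlleleFrequencyTable("DRB1", {"*01:01": 0.2, "*02:01": 0.3, "*03:01": 0.5})
        cmp = population_correlation(t, t)
        assert cmp.pearson_r == pytest.approx(1.0)

    def test_reference_value(self):
        # frozen oracle: R cor.test on (0.5, 0.5, 0) vs (0.1, 0.9, 0)
        cohort = AlleleFrequencyTable("DRB1", {"*01:01": 0.5, "*02:01": 0.5})
        reference = AlleleFrequencyTable("DRB1", {"*01:01": 0.1, "*02:01": 0.9, "*03:01": 0.0})
        cmp = population_correlation(cohort, reference)
        assert cmp.pearson_r == pytest.approx(0.585205735981, rel=1e-9)
        assert cmp.p_value == pytest.approx(0.602027, rel=1e-4)

    def test_relabelling_invariance(self):
        cohort = AlleleFrequencyTable("DRB1", {"*01:01": 0.5, "*02:01": 0.3, "*03:01": 0.2})
        reference = AlleleFrequencyTable("DRB1", {"*01:01": 0.1, "*02:01": 0.6, "*03:01": 0.3})
        relabel = {"*01:01": "*09:01", "*02:01": "*08:01", "*03:01": "*07:01"}
        r1 = population_correlation(cohort, reference).pearson_r
        r2 = population_correlation(
            AlleleFrequencyTable("DRB1", {relabel[a]: f for a, f in cohort.frequencies.items()}),
            AlleleFrequencyTable("DRB1", {relabel[a]: f for a, f in reference.frequencies.items()}),
        ).pearson_r
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_symmetry(self):
        a = AlleleFrequencyTable("DRB1", {"*01:01": 0.5, "*02:01": 0.3, "*03:01": 0.2})
        b = AlleleFrequencyTable("DRB1", {"*01:01": 0.2, "*02:01": 0.2, "*04:01": 0.6})
        assert population_correlation(a, b).pearson_r == pytest.approx(
            population_correlation(b, a).pearson_r, rel=1e-12
        )

    @given(c=st.floats(min_value=0.05, max_value=1.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        a = AlleleFrequencyTable("DRB1", {"*01:01": 0.5, "*02:01": 0.3, "*03:01": 0.2})
        b = AlleleFrequencyTable("DRB1", {"*01:01": 0.1, "*02:01": 0.6, "*03:01": 0.3})
        r = population_correlation(a, b).pearson_r
        scaled = population_correlation(
            AlleleFrequencyTable("DRB1", {k: c * v for k, v in a.frequencies.items()}),
            AlleleFrequencyTable("DRB1", {k: c * v for k, v in b.frequencies.items()}),
        ).pearson_r
        assert scaled == pytest.approx(r, rel=1e-9)

    def test_zero_variance_flagged(self):
        flat = AlleleFrequencyTable("DRB1", {"*01:01": 0.25, "*02:01": 0.25, "*03:01": 0.25})
        other = AlleleFrequencyTable("DRB1", {"*01:01": 0.7, "*02:01": 0.2, "*03:01": 0.1})
        cmp = population_correlation(flat, other)
        assert cmp.pearson_r is None
        assert "zero_variance" in cmp.flags

    def test_cohort_vs_synthetic_reference_runs(self):
        genotypes = read_hla_table(cohort_hla_path())
        cohort = hla_allele_frequencies(genotypes, "DRB1")
        reference = read_allele_frequencies(synthetic_reference_path(), "DRB1")
        cmp = population_correlation(cohort, reference)
        assert -1.0 <= cmp.pearson_r <= 1.0


class TestBuildReport:
    def test_pct_matches_responder_frequency(self, calibration_run):
        _, wells, _, calls = calibration_run
        report = build_report(calls, donor_frequencies(wells))
        by_compound = {c["compound"]: c for c in report["compounds"]}
        for compound in by_compound:
            assert by_compound[compound]["pct_responders"] == responder_frequency(
                calls, compound
            )

    def test_hla_section_optional(self, calibration_run):
        _, _, _, calls = calibration_run
        assert "hla" not in build_report(calls)
        genotypes = read_hla_table(cohort_hla_path())
        cmp = population_correlation(
            hla_allele_frequencies(genotypes, "DRB1"),
            read_allele_frequencies(synthetic_reference_path(), "DRB1"),
        )
        assert "hla" in build_report(calls, hla_comparison=cmp)

    def test_report_is_deterministic_and_serialisable(self, calibration_run):
        _, wells, _, calls = calibration_run
        r1 = build_report(calls, donor_frequencies(wells))
        r2 = build_report(calls, donor_frequencies(wells))
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_adding_nonresponder_lowers_pct(self):
        calls = flat_calls(3, "X", si=5.0, positive=True)
        before = build_report(calls)["compounds"][0]
        extended = calls + [flat_calls(5, "X")[4]]
        after = build_report(extended)["compounds"][0]
        assert after["pct_responders"] < before["pct_responders"]
        assert after["mean_si_responders"] == before["mean_si_responders"]
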