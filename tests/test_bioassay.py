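"""Concentration-response evaluation and equivalence arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edascreen import bioassay as ba
from edascreen.errors import FitDomainError, UndefinedPotencyError, UnitError
from edascreen.fixtures import gen_crc


class TestEnrichment:
    @pytest.mark.parametrize(
        "ef,df,expected",
        [(0.513, 0.01, 5.13e-3), (1.0, 1.0, 1.0), (1.23, 0.01, 1.23e-2)],
    )
    def test_ref_product(self, ef, df, expected):
        assert ba.relative_enrichment_factor(ef, df) == pytest.approx(expected)
        assert ba.EnrichmentSpec(ef, df).ref == pytest.approx(expected)

    @pytest.mark.parametrize("ef,df", [(0.0, 1.0), (1.0, -0.1), (-1.0, 1.0)])
    def test_nonpositive_rejected(self, ef, df):
        with pytest.raises(ValueError):
            ba.relative_enrichment_factor(ef, df)


class TestFitPotency:
    def test_forced_slope(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0])
        series = ba.DoseResponseSeries("s", conc, 2.0 * conc, "uM")
        summary = ba.fit_potency(series)
        assert summary.ec10 == pytest.approx(5.0)
        assert summary.slope == pytest.approx(2.0)
        assert summary.fit_diagnostics == pytest.approx(1.0)

    def test_ten_percent_at_unit_concentration(self):
        conc = np.array([0.125, 0.25, 0.5, 1.0])
        series = ba.DoseResponseSeries("s", conc, 10.0 * conc, "uM")
        assert ba.fit_potency(series).ec10 == pytest.approx(1.0)

    def test_noisy_recovery_within_ten_percent(self):
        series = gen_crc(0.8, noise_sd=1.0, n_levels=11, seed=11)
        assert ba.fit_potency(series).ec10 == pytest.approx(0.8, rel=0.10)

    def test_recovery_median_error_under_ten_percent(self):
        """Over 200 simulated series with 1% effect noise the median
        absolute relative EC10 error stays below 10%."""
        errors = []
        for i in range(200):
            series = gen_crc(0.8, noise_sd=1.0, n_levels=11, seed=1000 + i)
            ec10 = ba.fit_potency(series).ec10
            errors.append(abs(ec10 - 0.8) / 0.8)
        assert np.median(errors) < 0.10

    def test_no_points_in_linear_range(self):
        conc = np.array([1.0, 2.0, 3.0, 4.0])
        series = ba.DoseResponseSeries("s", conc, np.full(4, 90.0), "uM")
        with pytest.raises(FitDomainError):
            ba.fit_potency(series)

    def test_negative_slope_flags_inactive(self):
        conc = np.array([1.0, 2.0, 3.0, 4.0])
        series = ba.DoseResponseSeries("s", conc, np.array([1.0, -1.0, -2.0, -4.0]), "uM")
        summary = ba.fit_potency(series)
        assert summary.inactive and summary.ec10 is None

    def test_too_few_levels(self):
        series = ba.DoseResponseSeries("s", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "uM")
        with pytest.raises(FitDomainError):
            ba.fit_potency(series)

    def test_cytotoxicity_gives_sr(self):
        series = gen_crc(1.0, noise_sd=0.0, seed=0, cytotox_onset=50.0)
        summary = ba.fit_potency(series)
        assert summary.sr == pytest.approx(50.0, rel=0.05)

    def test_sr_missing_without_cytotoxicity(self):
        series = gen_crc(1.0, noise_sd=0.0, seed=0)
        summary = ba.fit_potency(series)
        assert summary.ic10 is None and summary.sr is None
        assert "no cytotoxicity observed" in summary.notes

    def test_loglogistic_model_on_full_curve(self):
        conc = np.geomspace(0.01, 100.0, 11)
        effect = 100.0 / (1.0 + (1.0 / conc))  # EC50=1, hill 1 -> EC10 = 1/9
        series = ba.DoseResponseSeries("s", conc, effect, "uM")
        summary = ba.fit_potency(series, model="loglogistic")
        assert summary.ec10 == pytest.approx(1.0 / 9.0, rel=1e-3)

    def test_sr_equals_ratio_of_fitted_values(self):
        series = gen_crc(1.0, noise_sd=0.5, seed=3, cytotox_onset=20.0)
        summary = ba.fit_potency(series)
        assert summary.sr == pytest.approx(
            ba.specificity_ratio(summary.ic10, summary.ec10)
        )


class TestSpecificityRatio:
    @pytest.mark.parametrize("ic10,ec10,expected", [(5.0, 5.0, 1.0), (50.0, 5.0, 10.0)])
    def test_ratio(self, ic10, ec10, expected):
        assert ba.specificity_ratio(ic10, ec10) == expected

    def test_missing_ic10_annotated(self):
        notes = []
        assert ba.specificity_ratio(None, 5.0, notes=notes) is None
        assert "no cytotoxicity observed" in notes

    def test_missing_ec10_undefined(self):
        with pytest.raises(UndefinedPotencyError):
            ba.specificity_ratio(5.0, None)


class TestEquivalence:
    def test_beq_dimensional_anchor(self):
        # 2.67 ug/L over 1e-3 g/mL (= 1 g/L) -> 2.67 ug/g
        assert ba.bap_eq_bio(2.67, 1e-3, "ug/L", "g/mL") == pytest.approx(2.67)

    def test_beq_unity_and_proportionality(self):
        assert ba.bap_eq_bio(2.0, 2.0, "ug/L", "g/L") == pytest.approx(1.0)
        assert ba.bap_eq_bio(2.67, 0.5e-3, "ug/L", "g/mL") == pytest.approx(
            2 * ba.bap_eq_bio(2.67, 1e-3, "ug/L", "g/mL")
        )

    def test_beq_unit_mismatch(self):
        with pytest.raises(UnitError):
            ba.bap_eq_bio(2.67, 1.0, "uM", "g/L")
        with pytest.raises(UnitError):
            ba.bap_eq_bio(2.67, 1.0, "ug/L", "uM")

    def test_tcdd_conversion(self):
        assert ba.tcdd_to_bap_eq(3.0, 5.0, 5.0) == pytest.approx(3.0)
        assert ba.tcdd_to_bap_eq(2.0, 10.0, 1.0) == pytest.approx(20.0)

    def test_tcdd_round_trip_with_rep(self):
        x, e_bap, e_tcdd = 7.0, 2.5, 0.5
        forward = ba.tcdd_to_bap_eq(x, e_bap, e_tcdd)
        assert forward / ba.rep(e_bap, e_tcdd, "ug/L", "ug/L") == pytest.approx(x)

    def test_rep_identity_and_scaling(self):
        assert ba.rep(108.0, 108.0) == 1.0
        assert ba.rep(1.0, 10.0) == pytest.approx(0.1)

    def test_rep_ratio_bjf_vs_bbf(self):
        """REP 5.3 vs 2.2 makes one isomer 2.4x more potent (2 s.f.)."""
        ec10_bap = 108.0
        ec10_bjf = ec10_bap / 5.3
        ec10_bbf = ec10_bap / 2.2
        ratio = ba.rep(ec10_bbf, ec10_bjf)
        assert float(f"{ratio:.2g}") == pytest.approx(2.4)

    def test_rep_unit_mismatch(self):
        with pytest.raises(UnitError):
            ba.rep(1.0, 1.0, "uM", "ug/L")


class TestChemicalLedger:
    @pytest.mark.parametrize(
        "ledger,expected",
        [([(1.0, 2.0)], 2.0), ([(1.0, 2.0), (0.5, 4.0)], 4.0), ([], 0.0)],
    )
    def test_sum(self, ledger, expected):
        assert ba.bap_eq_chem(ledger) == pytest.approx(expected)

    def test_negative_concentration(self):
        with pytest.raises(ValueError):
            ba.bap_eq_chem([(1.0, -2.0)])

    def test_censoring_policies(self):
        ledger = [(1.0, 2.0), (2.0, 0.0, True, 0.5)]
        assert ba.bap_eq_chem(ledger) == pytest.approx(2.0)
        assert ba.bap_eq_chem(ledger, censored_policy="half_mdl") == pytest.approx(2.5)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 10.0, allow_nan=False),
                st.floats(0.0, 10.0, allow_nan=False),
            ),
            max_size=12,
        ),
        st.integers(0, 12),
    )
    @settings(max_examples=50, deadline=None)
    def test_additive_over_partitions(self, ledger, split):
        split = min(split, len(ledger))
        whole = ba.bap_eq_chem(ledger)
        parts = ba.bap_eq_chem(ledger[:split]) + ba.bap_eq_chem(ledger[split:])
        assert whole == pytest.approx(parts, abs=1e-9)


class TestContribution:
    def test_fractions(self):
        assert ba.contribution(3.0, 3.0) == pytest.approx(100.0)
        assert ba.contribution(1.0, 4.0) == pytest.approx(25.0)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            ba.contribution(1.0, 0.0)

    def test_split_ledger_contributions_sum(self):
        ledger = [(1.0, 2.0), (0.5, 4.0), (2.0, 1.0)]
        beq_bio = 12.0
        whole = ba.contribution(ba.bap_eq_chem(ledger), beq_bio)
        halves = sum(
            ba.contribution(ba.bap_eq_chem(part), beq_bio)
            for part in (ledger[:2], ledger[2:])
        )
        assert whole == pytest.approx(halves)


class TestBenchmarks:
    def test_unit_identity(self):
        assert ba.ebt_sediment(0.0, 1.0) == pytest.approx(1e-3)

    def test_koc_transfer_three_sig_figs(self):
        assert ba.ebt_sediment(4.82, 0.248) == pytest.approx(16.4, abs=0.05)

    def test_linear_in_water_value(self):
        assert ba.ebt_sediment(3.0, 0.4) == pytest.approx(2 * ba.ebt_sediment(3.0, 0.2))

    def test_benchmark_dataclass(self):
        bench = ba.SedimentBenchmark(4.82, 0.248)
        assert bench.ebt_sediment == pytest.approx(16.4, abs=0.05)

    def test_distribution_ratio(self):
        assert ba.d_sed_w(5.0, 5.0) == (1.0, 0.0)
        ratio, log = ba.d_sed_w(1e4, 1.0)
        assert ratio == pytest.approx(1e4) and log == pytest.approx(4.0)

    def test_distribution_scale_invariance(self):
        assert ba.d_sed_w(3.0 * 2.0, 3.0 * 0.5).ratio == pytest.approx(
            ba.d_sed_w(2.0, 0.5).ratio
        )

    def test_toc_normalization_round_trip(self):
        assert ba.toc_normalize(5.0, 1.0) == 5.0
        assert ba.toc_normalize(5.0, 0.05) == pytest.approx(100.0)
        assert ba.toc_normalize(5.0, 0.05) * 0.05 == pytest.approx(5.0)
        with pytest.raises(ValueError):
            ba.toc_normalize(5.0, 0.0)


class TestConcentrationAddition:
    def test_single_component(self):
        assert ba.ca_mixture_ec10([(1.0, 3.7)]) == pytest.approx(3.7)

    def test_closed_form_pair(self):
        assert ba.ca_mixture_ec10([(0.5, 1.0), (0.5, 3.0)]) == pytest.approx(1.5)

    def test_equipotent_design_matches_direct_summation(self):
        ec10s = [0.5, 1.0, 2.0, 4.0]
        total = sum(ec10s)
        mixture = [(e / total, e) for e in ec10s]
        expected = 1.0 / sum(p / e for p, e in mixture)  # direct summation
        assert ba.ca_mixture_ec10(mixture) == pytest.approx(expected)
        # equipotent design: each term p/EC10 is 1/total, n of them
        assert expected == pytest.approx(total / len(ec10s))

    def test_permutation_invariance(self):
        mix = [(0.2, 1.0), (0.3, 5.0), (0.5, 0.7)]
        assert ba.ca_mixture_ec10(mix) == pytest.approx(ba.ca_mixture_ec10(mix[::-1]))

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            ba.ca_mixture_ec10([(0.5, 1.0), (0.4, 2.0)])

    def test_missing_component_potency(self):
        with pytest.raises(UndefinedPotencyError):
            ba.ca_mixture_ec10([(0.5, 1.0), (0.5, math.inf)])

    def test_mixture_spec_of_identical_compound(self):
        comp = ba.ChemicalPotency("x", "XKEY", 2.0, "uM")
        spec = ba.MixtureSpec([(comp, 0.5), (comp, 0.5)])
        assert ba.ca_mixture_ec10(spec) == pytest.approx(2.0)


class TestRecoveryAndLayout:
    def test_fractionation_recovery(self):
        assert ba.fractionation_recovery(1.0, 1.0) == pytest.approx(100.0)
        assert ba.fractionation_recovery(1.58, 1.0) == pytest.approx(158.0)

    def test_designed_fraction_count(self):
        assert ba.designed_fraction_count(24.0, 18.0) == 80

    def test_blank_policy(self):
        corrected, pct = ba.blank_corrected_beq(10.0, 0.5)
        assert corrected == 10.0 and pct == pytest.approx(5.0)
        corrected, pct = ba.blank_corrected_beq(10.0, 2.0)
        assert corrected == pytest.approx(8.0) and pct == pytest.approx(20.0)


class TestPlateIO:
    def test_round_trip_and_grouping(self, tmp_path):
        import pandas as pd

        rows = []
        for rep_id in (0, 1):
            for c in (1.0, 2.0, 4.0, 8.0):
                rows.append(
                    {
                        "sample_id": "S1",
                        "replicate": rep_id,
                        "concentration": c,
                        "unit": "g/L",
                        "effect_pct": 2.0 * c,
                        "cytotox_pct": 0.0,
                    }
                )
        path = tmp_path / "plate.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        series = ba.read_plate_csv(path)
        assert len(series) == 2
        assert {s.replicate_id for s in series} == {0, 1}
        assert ba.fit_potency(series[0]).ec10 == pytest.approx(5.0)

    def test_mixed_units_rejected(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "sample_id": ["S1"] * 4,
                "replicate": [0] * 4,
                "concentration": [1.0, 2.0, 3.0, 4.0],
                "unit": ["g/L", "g/L", "g/mL", "g/L"],
                "effect_pct": [1.0, 2.0, 3.0, 4.0],
            }
        )
        path = tmp_path / "plate.csv"
        df.to_csv(path, index=False)
        with pytest.raises(UnitError):
            ba.read_plate_csv(path)
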