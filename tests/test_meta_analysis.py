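"""Group summaries, regressions and the measured-vs-predicted validation."""

import dataclasses

import numpy as np
import pytest

from conftest import ols_oracle
from oxycap.errors import DomainError, NumericalError, UsageError
from oxycap.meta_analysis import (
    CapillaryDensityRecord,
    RegionRecord,
    StimulationRecord,
    capillary_density_fits,
    fit_linear,
    group_summary,
    normalize_by_species_mean,
    oef_summary,
    oef_table,
    predicted_vs_measured,
    stimulation_slope,
)
from oxycap.state_curve import ModelParams, cbf_prime_from_j_prime


class TestGroupSummary:
    @pytest.mark.parametrize(
        "values, mean_1dp, sd_1dp",
        [
            ([35.0, 33.0, 25.0, 22.0], 28.8, 6.2),  # mouse cortex tissue PO2
            ([37.0, 26.7, 29.0, 34.0, 25.0], 30.3, 5.0),  # rat
            ([23.1, 25.5, 26.9, 29.0, 33.0], 27.5, 3.7),  # human
        ],
    )
    def test_published_tissue_po2_summaries(self, values, mean_1dp, sd_1dp):
        stat = group_summary(values, "species")
        assert round(stat.mean, 1) == mean_1dp
        assert round(stat.sd, 1) == sd_1dp
        assert stat.n == len(values)

    def test_constant_group(self):
        stat = group_summary([5, 5, 5], "c")
        assert (stat.mean, stat.sd) == (5.0, 0.0)

    def test_singleton_has_no_sd(self):
        assert group_summary([3.0], "one").sd is None

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            group_summary([], "none")


def _region(species="rat", cbf=50.0, cmro2=None, o2=8.0, state="awake"):
    if cmro2 is None:
        cmro2 = 0.4 * cbf * o2
    return RegionRecord(
        species=species, region="r", tissue_class="gray",
        cbf=cbf, cmro2=cmro2, o2_content=o2, state=state,
    )


class TestOefTable:
    def test_consistent_record(self):
        df = oef_table([_region()])
        assert df["oef"].iloc[0] == pytest.approx(0.4)

    def test_zero_noise_identity_on_truth(self):
        records = [
            _region(species=s, cbf=c, cmro2=0.35 * c * 8.0)
            for s in ("rat", "mouse") for c in (30.0, 60.0, 90.0)
        ]
        summary = oef_summary(records)
        for stat in summary["by_species"]:
            assert stat.mean == pytest.approx(0.35, rel=1e-12)
        assert summary["grand"].mean == pytest.approx(0.35, rel=1e-12)

    def test_awake_only_filter(self):
        records = [_region(state="awake"), _region(state="anesthetized", cmro2=100.0)]
        all_in = oef_summary(records)["grand"]
        awake = oef_summary(records, awake_only=True)["grand"]
        assert all_in.n == 2 and awake.n == 1


class TestNormalizeBySpeciesMean:
    def test_two_record_species(self):
        records = [_region(cbf=1.0, o2=8.0), _region(cbf=3.0, o2=8.0)]
        df = normalize_by_species_mean(records)
        assert list(df["cbf_norm"]) == pytest.approx([0.5, 1.5])

    def test_species_means_are_one(self):
        records = [
            _region(species=s, cbf=c) for s in ("rat", "human") for c in (20.0, 50.0, 95.0)
        ]
        df = normalize_by_species_mean(records)
        means = df.groupby("species")[["cbf_norm", "cmro2_norm"]].mean()
        assert np.allclose(means.to_numpy(), 1.0, atol=1e-12)

    def test_idempotent(self):
        records = [_region(cbf=1.0), _region(cbf=3.0)]
        df1 = normalize_by_species_mean(records)
        df2 = df1.rename(columns={"cbf": "_cbf", "cmro2": "_cmro2"}).rename(
            columns={"cbf_norm": "cbf", "cmro2_norm": "cmro2"}
        )
        df3 = normalize_by_species_mean(df2[df1.columns.drop(["cbf_norm", "cmro2_norm"]).tolist()])
        assert np.allclose(df3["cbf_norm"], df1["cbf_norm"])


class TestFitLinear:
    def test_exact_origin_line(self):
        fit = fit_linear([1, 2, 3], [2, 4, 6], through_origin=True)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_exact_free_line(self):
        fit = fit_linear([0, 1, 2], [1, 3, 5])
        assert (fit.slope, fit.intercept, fit.r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_hand_computed_free_fit(self):
        fit = fit_linear([1, 2, 3], [2, 3, 5])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(1 / 3, abs=1e-9)
        assert fit.r2 == pytest.approx(0.9642857, abs=1e-4)

    @pytest.mark.parametrize("through_origin", [False, True])
    def test_matches_normal_equations_oracle(self, through_origin):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(4, 12)
            x = rng.uniform(-5, 5, n)
            y = 1.7 * x + rng.normal(0, 1, n)
            fit = fit_linear(x, y, through_origin=through_origin)
            slope, intercept, r2 = ols_oracle(x, y, through_origin=through_origin)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(NumericalError):
            fit_linear([2, 2, 2], [1, 2, 3])


def _stim(dcmro2, dcbf, condition="stimulation", species="human"):
    return StimulationRecord(
        species=species, frac_dcbf=dcbf, frac_dcmro2=dcmro2, condition=condition
    )


class TestStimulationSlope:
    def test_exact_slope_two(self):
        records = [_stim(x, 2 * x) for x in (0.05, 0.1, 0.2, 0.3)]
        assert stimulation_slope(records).slope == pytest.approx(2.0)

    def test_three_hand_points(self):
        records = [_stim(0.1, 0.2), _stim(0.2, 0.4), _stim(0.3, 0.6)]
        assert stimulation_slope(records).slope == pytest.approx(2.0)

    def test_seizure_excluded_by_default(self):
        records = [_stim(x, 2 * x) for x in (0.1, 0.2, 0.3)]
        outlier = _stim(0.9, 4.0, condition="seizure")
        base = stimulation_slope(records + [outlier])
        assert base.n == 3 and base.slope == pytest.approx(2.0)
        with_seizure = stimulation_slope(records + [outlier], include_seizure=True)
        assert with_seizure.n == 4 and with_seizure.slope > 2.0

    def test_sleep_points_never_enter(self):
        records = [_stim(x, 2 * x) for x in (0.1, 0.2)] + [
            _stim(-0.3, -0.3, condition="sleep")
        ]
        assert stimulation_slope(records).n == 2

    def test_model_curve_samples_land_in_meta_analytic_band(self, default_params):
        # noise-free fractional changes from the supply curve itself
        js = np.linspace(1.05, 1.4, 15)
        records = [
            _stim(j - 1.0, cbf_prime_from_j_prime(float(j), default_params) - 1.0)
            for j in js
        ]
        assert 2.0 <= stimulation_slope(records).slope <= 2.6


class TestPredictedVsMeasured:
    def test_exact_model_points(self, default_params):
        points = [
            (j, cbf_prime_from_j_prime(j, default_params))
            for j in (0.6, 0.9, 1.1, 1.2, 1.3, 1.4)
        ]
        fit = predicted_vs_measured(points, default_params)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_oef_biases_slope_down(self, default_params):
        # data generated at OEF_o = 0.4, fitted with 0.3: the low-extraction
        # model predicts more flow per flux, so measured-on-predicted < 1
        points = [
            (j, cbf_prime_from_j_prime(j, default_params))
            for j in np.linspace(1.05, 1.45, 12)
        ]
        low = dataclasses.replace(default_params, oef_o=0.3)
        fit = predicted_vs_measured(points, low, through_origin=True)
        assert fit.slope < 0.95


class TestCapillaryDensityFits:
    def test_exact_linear_table(self):
        records = [
            CapillaryDensityRecord(
                region=f"s{i}", capillary_density=d,
                cmr_glc=0.002 * d + 0.1, cbf=0.003 * d + 0.2,
            )
            for i, d in enumerate((300.0, 500.0, 700.0, 900.0))
        ]
        glc, cbf = capillary_density_fits(records)
        assert glc.slope == pytest.approx(0.002) and glc.r2 == pytest.approx(1.0)
        assert cbf.slope == pytest.approx(0.003) and cbf.r2 == pytest.approx(1.0)
        assert glc.p_slope < 1e-6

    def test_constant_density_rejected(self):
        records = [
            CapillaryDensityRecord(region=f"s{i}", capillary_density=500.0,
                                   cmr_glc=1.0, cbf=1.0)
            for i in range(4)
        ]
        with pytest.raises(NumericalError):
            capillary_density_fits(records)

    def test_too_few_records_rejected(self):
        records = [
            CapillaryDensityRecord(region="a", capillary_density=300.0, cmr_glc=1, cbf=1),
            CapillaryDensityRecord(region="b", capillary_density=600.0, cmr_glc=2, cbf=2),
        ]
        with pytest.raises(UsageError):
            capillary_density_fits(records)


class TestRecordValidation:
    def test_bad_tissue_class(self):
        with pytest.raises(DomainError):
            RegionRecord(species="rat", region="r", tissue_class="pink",
                         cbf=50.0, cmro2=100.0, o2_content=8.0)

    def test_bad_condition(self):
        with pytest.raises(DomainError):
            StimulationRecord(species="rat", frac_dcbf=0.2, frac_dcmro2=0.1,
                              condition="nap")

    def test_fractional_change_floor(self):
        with pytest.raises(DomainError):
            StimulationRecord(species="rat", frac_dcbf=-1.5, frac_dcmro2=0.1)
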