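import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyfi import hplc
from flyfi.hplc import CatecholamineQuant, Chromatogram, Peak
from flyfi.synth import (
    ChromatogramConfig,
    generate_chromatogram,
    generate_hplc_experiment,
)

QUIET = ChromatogramConfig(noise_sd=0.0, baseline_drift=0.0)


def label_standard(chrom):
    refs = [
        Peak(a, t, t - 1e-3, t + 1e-3, 0.0, 0.0)
        for a, t in chrom.metadata["retention_times"].items()
    ]
    return hplc.identify_peaks(hplc.detect_and_integrate(chrom), refs)


class TestChromatogramType:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Chromatogram(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Chromatogram(np.arange(3.0), np.zeros(4))


class TestDetectAndIntegrate:
    def test_triangle_area(self):
        # isoceles triangle, base 0.8 min, height 50, on zero baseline
        t = np.arange(0, 10, 1 / 300)
        s = np.clip(50.0 * (1.0 - np.abs(t - 5.0) / 0.4), 0.0, None)
        peaks = hplc.detect_and_integrate(Chromatogram(t, s))
        assert len(peaks) == 1
        assert peaks[0].area == pytest.approx(0.8 * 50.0 / 2.0, rel=0.005)

    @pytest.mark.parametrize("amount,sigma", [(1.0, 0.08), (0.2, 0.05), (3.0, 0.15)])
    def test_gaussian_area_within_1pct(self, amount, sigma):
        cfg = ChromatogramConfig(noise_sd=0.0, baseline_drift=0.0, sigma_min=sigma)
        chrom = generate_chromatogram({"DA": amount}, config=cfg)
        peaks = hplc.detect_and_integrate(chrom)
        assert len(peaks) == 1
        amplitude = cfg.response_factor * amount / (sigma * math.sqrt(2 * math.pi))
        assert peaks[0].area == pytest.approx(
            amplitude * sigma * math.sqrt(2 * math.pi), rel=0.01)

    def test_two_separated_peaks_ordered(self):
        chrom = generate_chromatogram({"DOPAC": 0.5, "HVA": 0.5}, config=QUIET)
        peaks = hplc.detect_and_integrate(chrom)
        assert [round(p.apex_time, 1) for p in peaks] == [3.5, 8.0]

    def test_flat_signal_empty(self):
        t = np.arange(0, 5, 1 / 300)
        assert hplc.detect_and_integrate(Chromatogram(t, np.full_like(t, 2.0))) == []

    def test_disjoint_sum_additivity(self):
        single = {
            a: hplc.detect_and_integrate(
                generate_chromatogram({a: 1.0}, config=QUIET))[0].area
            for a in ("DOPAC", "DA", "HVA")
        }
        combined = hplc.detect_and_integrate(
            generate_chromatogram({a: 1.0 for a in single}, config=QUIET))
        assert sum(p.area for p in combined) == pytest.approx(
            sum(single.values()), rel=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            hplc.detect_and_integrate(Chromatogram(np.arange(5.0), np.zeros(5)))


class TestIdentify:
    def test_exact_match(self):
        std = [Peak("DA", 5.0, 4.9, 5.1, 10.0, 1.0)]
        sample = [Peak(None, 5.0, 4.9, 5.1, 3.0, 1.0)]
        assert hplc.identify_peaks(sample, std)[0].analyte == "DA"

    def test_outside_tolerance_unassigned(self):
        std = [Peak("DA", 5.0, 4.9, 5.1, 10.0, 1.0)]
        sample = [Peak(None, 5.6, 5.5, 5.7, 3.0, 1.0)]
        assert hplc.identify_peaks(sample, std, tolerance_min=0.2)[0].analyte is None

    def test_tie_breaks_to_earlier_standard(self):
        std = [Peak("A", 4.9, 4.8, 5.0, 1.0, 1.0),
               Peak("B", 5.1, 5.0, 5.2, 1.0, 1.0)]
        sample = [Peak(None, 5.0, 4.9, 5.1, 1.0, 1.0)]
        assert hplc.identify_peaks(sample, std)[0].analyte == "A"

    def test_generator_defaults_all_assigned(self):
        runs = generate_hplc_experiment({"DA": 1.0, "DOPAC": 0.3, "HVA": 0.2}, seed=2)
        std = label_standard(runs["standard"])
        sample = hplc.identify_peaks(hplc.detect_and_integrate(runs["sample"]), std)
        assert {p.analyte for p in sample} == {"DA", "DOPAC", "HVA"}


class TestSpiking:
    def test_identity_not_confirmed(self):
        peaks = [Peak("DA", 5.0, 4.9, 5.1, 10.0, 1.0)]
        table = hplc.confirm_by_spiking(peaks, peaks, ["DA"])
        assert table.loc[0, "verdict"] == "not confirmed"

    def test_absent_label_not_found(self):
        peaks = [Peak("DA", 5.0, 4.9, 5.1, 10.0, 1.0)]
        table = hplc.confirm_by_spiking(peaks, peaks, ["HVA"])
        assert table.loc[0, "verdict"] == "not found"

    def test_generator_spike_confirms_all(self):
        runs = generate_hplc_experiment({"DA": 1.0, "DOPAC": 0.3, "HVA": 0.2}, seed=5)
        std = label_standard(runs["standard"])
        sample = hplc.identify_peaks(hplc.detect_and_integrate(runs["sample"]), std)
        spiked = hplc.identify_peaks(hplc.detect_and_integrate(runs["spiked"]), std)
        table = hplc.confirm_by_spiking(sample, spiked, ["DA", "DOPAC", "HVA"])
        assert (table["verdict"] == "confirmed").all()

    def test_spiked_areas_strictly_increase(self):
        runs = generate_hplc_experiment({"DA": 1.0, "DOPAC": 0.3, "HVA": 0.2}, seed=9)
        std = label_standard(runs["standard"])
        sample = {p.analyte: p.area for p in hplc.identify_peaks(
            hplc.detect_and_integrate(runs["sample"]), std)}
        spiked = {p.analyte: p.area for p in hplc.identify_peaks(
            hplc.detect_and_integrate(runs["spiked"]), std)}
        for analyte in ("DA", "DOPAC", "HVA"):
            assert spiked[analyte] > sample[analyte]


def worked_chain():
    return CatecholamineQuant(
        analyte="DA", c_std=200.0, a_std=5000.0, i_std=20.0,
        a_samp=2500.0, i_samp=50.0, n_heads=15, p_samp=1.0,
        extract_volume=300.0, dilution_factor=2.0)


class TestQuantifyChain:
    def test_v1_from_standard_inputs(self):
        q = hplc.quantify(worked_chain())
        assert q.v1 == pytest.approx(4.0)

    def test_equal_areas_v2_equals_v1(self):
        q = worked_chain()
        q.a_samp = q.a_std
        q = hplc.quantify(q)
        assert q.v2 == pytest.approx(q.v1)

    def test_hand_computed_chain(self):
        q = hplc.quantify(worked_chain())
        assert (q.v1, q.v2, q.v3, q.v4) == pytest.approx((4.0, 2.0, 50.0, 0.04))
        assert (q.v5, q.v6, q.v7, q.v8) == pytest.approx((12.0, 0.8, 0.4, 400.0))

    def test_chain_consistency_identity(self):
        q = hplc.quantify(worked_chain())
        assert q.v8 / 1000.0 * q.dilution_factor * q.n_heads == pytest.approx(q.v5)

    @given(scale=st.floats(min_value=0.01, max_value=100.0,
                           allow_nan=False, allow_infinity=False))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_sample_area(self, scale):
        q1 = hplc.quantify(worked_chain())
        q2 = worked_chain()
        q2.a_samp *= scale
        q2 = hplc.quantify(q2)
        for v in ("v2", "v4", "v5", "v6", "v7", "v8"):
            assert getattr(q2, v) == pytest.approx(scale * getattr(q1, v), rel=1e-9)

    def test_nonpositive_input_named(self):
        q = worked_chain()
        q.p_samp = 0.0
        with pytest.raises(ValueError, match="p_samp"):
            hplc.quantify(q)

    def test_fractional_heads_rejected(self):
        q = worked_chain()
        q.n_heads = 0
        with pytest.raises(ValueError, match="n_heads"):
            hplc.quantify(q)


class TestTurnover:
    def test_arithmetic(self):
        assert hplc.turnover_ratio(100.0, 20.0, 30.0) == pytest.approx(0.5)

    def test_zero_metabolites(self):
        assert hplc.turnover_ratio(10.0, 0.0, 0.0) == 0.0

    def test_monotone_in_da(self):
        ratios = [hplc.turnover_ratio(da, 20.0, 30.0) for da in (100.0, 50.0, 25.0)]
        assert ratios == sorted(ratios)

    def test_zero_da_rejected(self):
        with pytest.raises(ValueError, match="turnover undefined"):
            hplc.turnover_ratio(0.0, 1.0, 1.0)


def test_end_to_end_recovery_within_3pct():
    amounts = {"DA": 1.0, "DOPAC": 0.3, "HVA": 0.2}
    runs = generate_hplc_experiment(amounts, seed=5)
    std = label_standard(runs["standard"])
    sample = hplc.identify_peaks(hplc.detect_and_integrate(runs["sample"]), std)
    areas_std = {p.analyte: p.area for p in std}
    for p in sample:
        q = hplc.quantify(CatecholamineQuant(
            analyte=p.analyte, c_std=200.0, a_std=areas_std[p.analyte],
            i_std=20.0, a_samp=p.area, i_samp=50.0, n_heads=15, p_samp=1.0))
        v1 = 4.0
        expected_v8 = amounts[p.analyte] * v1 * (300.0 / 50.0) / 15 / 2 * 1000.0
        assert q.v8 == pytest.approx(expected_v8, rel=0.03)


def test_chromatogram_csv_round_trip(tmp_path):
    chrom = generate_chromatogram({"DA": 1.0}, seed=0)
    path = tmp_path / "chrom.csv"
    hplc.write_chromatogram_csv(chrom, path)
    back = hplc.read_chromatogram_csv(path)
    assert np.allclose(back.time, chrom.time)
    assert np.allclose(back.signal, chrom.signal)
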