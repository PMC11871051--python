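"""Detector model, difference distributions, region statistics, onsets."""

import numpy as np
import pytest

from tucei.frames import CoincidenceEvent, Histogram1D, cos_alpha_histogram
from tucei.scan import (
    DelayScanConfig,
    RegionBox,
    RegionSeries,
    default_regions,
    detect_onset,
    detector_model,
    difference_distribution,
    integrate_region,
    onset_order,
    region_series,
    scale_to_reference,
    smooth,
)


def series(name, values, errors=None, baseline=1.0, baseline_error=0.01):
    values = np.asarray(values, float)
    errors = np.full_like(values, 0.01) if errors is None else \
        np.asarray(errors, float)
    return RegionSeries(name, np.array([65.0, 130.0, 260.0, 1000.0]),
                        values, errors, baseline, baseline_error)


class TestDetectorModel:
    def test_zero_sigma_keeps_momenta(self, small_events):
        out = detector_model(small_events, sigma_p=0.0, seed=1)
        for a, b in zip(small_events, out):
            assert np.array_equal(a.p_s, b.p_s)
            lab, p = next(iter(b.protons.items()))
            assert np.array_equal(a.protons[lab], p)

    def test_threefold_coincidence_one_proton_each(self, small_events):
        out = detector_model(small_events, sigma_p=1.0, seed=2)
        for e in out:
            assert len(e.protons) == 1

    def test_all_four_protons_get_selected(self, small_events):
        out = detector_model(small_events, sigma_p=0.0, seed=3)
        labels = {next(iter(e.protons)) for e in out}
        assert labels == {"H9", "H10", "H11", "H12"}

    def test_measured_mode_strips_labels(self, small_events):
        out = detector_model(small_events, sigma_p=0.0, seed=4,
                             keep_labels=False)
        assert all(set(e.protons) == {"H"} for e in out)

    def test_smearing_broadens_cos_alpha(self, s0_events):
        sharp = cos_alpha_histogram(detector_model(s0_events, 0.0, seed=5))
        wide = cos_alpha_histogram(detector_model(s0_events, 15.0, seed=5))

        def variance(h):
            c = h.centers
            w = h.counts / h.counts.sum()
            mu = (c * w).sum()
            return ((c - mu) ** 2 * w).sum()

        assert variance(wide) > variance(sharp)

    def test_reproducible(self, small_events):
        a = detector_model(small_events, 2.0, seed=11)
        b = detector_model(small_events, 2.0, seed=11)
        for x, y in zip(a, b):
            assert np.array_equal(x.p_s, y.p_s)


class TestDifferenceDistribution:
    def test_identical_inputs_give_zero(self, small_events):
        h = cos_alpha_histogram(small_events)
        d = difference_distribution(h, h)
        assert np.all(d.counts == 0.0)

    def test_antisymmetry_under_swap(self, small_events):
        a = cos_alpha_histogram(small_events[:100])
        b = cos_alpha_histogram(small_events[100:])
        d1 = difference_distribution(a, b)
        d2 = difference_distribution(b, a)
        assert np.allclose(d1.counts, -d2.counts)
        assert np.allclose(d1.errors, d2.errors)

    def test_binning_mismatch_rejected(self, small_events):
        a = cos_alpha_histogram(small_events, bin_width=0.05)
        b = cos_alpha_histogram(small_events, bin_width=0.1)
        with pytest.raises(ValueError, match="binning"):
            difference_distribution(a, b)


class TestSmooth:
    def test_zero_width_is_identity(self, small_events):
        h = cos_alpha_histogram(small_events)
        s = smooth(h, 0.0)
        assert np.array_equal(s.counts, h.counts)

    def test_integral_preserved(self, small_events):
        h = cos_alpha_histogram(small_events)
        s = smooth(h, 0.08)
        assert s.counts.sum() == pytest.approx(h.counts.sum(), rel=1e-12)

    def test_delta_input_recovers_kernel(self):
        edges = np.linspace(-1, 1, 41)
        counts = np.zeros(40)
        counts[20] = 100.0
        h = Histogram1D(edges, counts, np.sqrt(counts))
        s = smooth(h, 0.10)          # sigma = 2 bins
        c = s.centers
        mu = (c * s.counts).sum() / s.counts.sum()
        sd = np.sqrt(((c - mu) ** 2 * s.counts).sum() / s.counts.sum())
        assert sd == pytest.approx(0.10, rel=0.05)


class TestRegions:
    def test_full_range_box_gives_total(self, small_events):
        from tucei.frames import angular_map
        h = angular_map(small_events, normalize=True)
        box = RegionBox("all", (-180.0, 180.0), (-1.0, 1.0))
        v, e = integrate_region(h, box)
        assert v == pytest.approx(1.0, rel=1e-12)

    def test_partition_additivity(self, small_events):
        from tucei.frames import angular_map
        h = angular_map(small_events)
        lower = RegionBox("lo", (-180.0, 180.0), (-1.0, 0.0))
        upper = RegionBox("hi", (-180.0, 180.0),
                          (np.nextafter(0.0, 1), 1.0))
        v1, _ = integrate_region(h, lower)
        v2, _ = integrate_region(h, upper)
        assert v1 + v2 == pytest.approx(h.total, rel=1e-12)

    def test_wrap_aware_phi_interval(self, small_events):
        from tucei.frames import angular_map
        h = angular_map(small_events)
        wrap = RegionBox("wrap", (150.0, -150.0), (-1.0, 1.0))
        left = RegionBox("l", (150.0, 180.0), (-1.0, 1.0))
        right = RegionBox("r", (-180.0, -150.0), (-1.0, 1.0))
        vw, _ = integrate_region(h, wrap)
        vl, _ = integrate_region(h, left)
        vr, _ = integrate_region(h, right)
        assert vw == pytest.approx(vl + vr, rel=1e-12)

    def test_empty_box_warns_and_returns_zero(self, small_events):
        from tucei.frames import angular_map
        h = angular_map(small_events, costheta_bins=4)
        box = RegionBox("thin", (0.0, 1.0), (-0.01, 0.01))
        with pytest.warns(UserWarning, match="no bins"):
            v, e = integrate_region(h, box)
        assert (v, e) == (0.0, 0.0)

    def test_costheta_bounds_validated(self):
        with pytest.raises(ValueError):
            RegionBox("bad", (0.0, 10.0), (-2.0, 0.5))

    def test_default_regions_are_disjoint(self, s0_events):
        from tucei.frames import angular_map
        h = angular_map(s0_events)
        regions = default_regions()
        masks = [box.mask(h) for box in regions.values()]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not np.any(masks[i] & masks[j])


class TestOnsets:
    def test_flat_series_has_no_onset(self):
        assert detect_onset(series("flat", [1.0, 1.0, 1.0, 1.0])) is None

    def test_departing_series_onset_at_first_departure(self):
        s = series("drop", [1.0, 0.8, 0.7, 0.7])
        assert detect_onset(s) == 130.0

    def test_rising_series_detected_too(self):
        s = series("rise", [1.0, 1.0, 1.3, 1.4])
        assert detect_onset(s) == 260.0

    def test_threshold_k_controls_sensitivity(self):
        s = series("weak", [0.97, 0.97, 0.97, 0.97])   # 2.1 sigma below
        assert detect_onset(s, k=2.0) == 65.0
        assert detect_onset(s, k=3.0) is None

    def test_order_and_ties(self):
        rep = onset_order([
            series("a", [0.5, 0.5, 0.5, 0.5]),
            series("b", [1.0, 0.5, 0.5, 0.5]),
            series("c", [1.0, 0.5, 0.5, 0.5]),
            series("d", [1.0, 1.0, 1.0, 1.0]),
        ])
        assert rep.onsets == {"a": 65.0, "b": 130.0, "c": 130.0, "d": None}
        assert rep.order == [("a",), ("b", "c")]
        assert rep.precedes("a", "b")
        assert rep.precedes("a", "d")
        assert not rep.precedes("b", "c")
        assert "no onset" in str(rep)

    def test_too_few_delays_rejected(self):
        s = RegionSeries("x", np.array([65.0]), np.array([1.0]),
                         np.array([0.1]), 1.0, 0.1)
        with pytest.raises(ValueError, match=">= 2"):
            detect_onset(s)


class TestScaleToReference:
    def test_identity_scaling(self):
        s = series("a", [1.0, 2.0, 3.0, 4.0])
        scaled, factor = scale_to_reference(s, s)
        assert factor == pytest.approx(1.0)

    def test_triple_series_gets_one_third(self):
        ref = series("ref", [1.0, 2.0, 3.0, 4.0])
        s = series("a", [3.0, 6.0, 9.0, 12.0])
        scaled, factor = scale_to_reference(s, ref)
        assert factor == pytest.approx(1.0 / 3.0)
        assert np.allclose(scaled.values, ref.values)
        assert np.allclose(scaled.errors, s.errors / 3.0)

    def test_matches_dense_grid_search(self):
        rng = np.random.default_rng(8)
        s = series("a", rng.uniform(0.5, 2.0, 4))
        ref = series("ref", rng.uniform(0.5, 2.0, 4))
        _, factor = scale_to_reference(s, ref)
        grid = np.linspace(0.01, 5.0, 200_001)
        loss = ((ref.values[None, :] - grid[:, None] * s.values[None, :])
                ** 2).sum(axis=1)
        assert factor == pytest.approx(grid[np.argmin(loss)], abs=1e-4)

    def test_zero_reference_rejected(self):
        s = series("a", [1.0, 2.0, 3.0, 4.0])
        ref = series("ref", [0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="all-zero"):
            scale_to_reference(s, ref)

    def test_mismatched_grid_rejected(self):
        s = series("a", [1.0, 2.0, 3.0, 4.0])
        ref = RegionSeries("r", np.array([1.0, 2.0]), np.ones(2),
                           np.ones(2), 1.0, 0.1)
        with pytest.raises(ValueError, match="delay grid"):
            scale_to_reference(s, ref)


class TestDelayScanConfig:
    def test_delays_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            DelayScanConfig(delays=(130.0, 65.0))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="excited_fraction"):
            DelayScanConfig(excited_fraction=1.5)

    def test_defaults_match_measured_delays(self):
        cfg = DelayScanConfig()
        assert cfg.delays == (65.0, 130.0, 260.0, 1000.0)
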