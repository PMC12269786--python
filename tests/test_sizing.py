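"""IPI measurement, the piecewise length conversion, and age/sex classing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cachalot as ca
from cachalot.sizing import (
    EQ_SWITCH_IPI_MS,
    IPIMeasurement,
    classify_individual,
    cluster_individuals,
    ipi_from_size,
    size_from_ipi,
    summarize_individual,
)


class TestSizeFromIpi:
    @pytest.mark.parametrize(
        "ipi_ms, expected_m, tol",
        [
            (1.90, 7.59, 0.005),   # the visually confirmed calf
            (2.90, 9.04, 0.005),   # immature / female boundary
            (5.00, 12.03, 0.005),  # female / adult-male boundary
            (3.85, 10.41, 0.005),  # the population median
            (4.250, 11.08, 0.005),  # first IPI on the linear branch
            (4.184, 10.89, 0.005),  # last IPI before the switch (quadratic)
            (7.80, 15.55, 0.005),  # largest animal in the study
        ],
    )
    def test_known_conversions(self, ipi_ms, expected_m, tol):
        assert size_from_ipi(ipi_ms) == pytest.approx(expected_m, abs=tol)

    def test_vectorised_matches_scalar(self):
        ipis = np.array([2.0, 4.0, 6.0])
        assert np.allclose(size_from_ipi(ipis), [size_from_ipi(v) for v in ipis])

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing(self, a, b):
        if a != b:
            lo, hi = sorted((a, b))
            assert size_from_ipi(lo) < size_from_ipi(hi)

    def test_branches_nearly_continuous_at_the_switch(self):
        # both branches stay within ~0.11 m of each other over the overlap
        # of their stated validity limits (the gap peaks at 4.184 ms)
        for ipi in np.linspace(4.184, 4.250, 30):
            quad = 4.833 + 1.453 * ipi - 0.001 * ipi**2
            lin = 1.258 * ipi + 5.736
            assert abs(quad - lin) < 0.11

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            size_from_ipi(0.0)


class TestIpiFromSize:
    @pytest.mark.parametrize("length_m, expected_ms", [(9.0, 2.874), (12.0, 4.979)])
    def test_known_inversions(self, length_m, expected_ms):
        assert ipi_from_size(length_m) == pytest.approx(expected_ms, abs=5e-4)

    @given(st.floats(5.6, 19.5))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, length_m):
        """Exact inversion everywhere except inside the small jump of the
        forward map at the equation switch, where the error stays < 0.1 m."""
        back = size_from_ipi(ipi_from_size(length_m))
        gap = (4.833 + 1.453 * 4.25 - 0.001 * 4.25**2, 1.258 * 4.25 + 5.736)
        if gap[0] <= length_m <= gap[1]:
            assert ipi_from_size(length_m) == EQ_SWITCH_IPI_MS
            assert back == pytest.approx(length_m, abs=0.1)
        else:
            assert back == pytest.approx(length_m, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ipi_from_size(3.0)
        with pytest.raises(ValueError):
            ipi_from_size(25.0)


class TestClassify:
    @pytest.mark.parametrize(
        "ipi_ms, label",
        [
            (2.5, "immature"),
            (2.89, "immature"),
            (2.9, "female_or_juvenile_male"),
            (3.85, "female_or_juvenile_male"),
            (5.0, "female_or_juvenile_male"),
            (5.01, "adult_male"),
            (7.8, "adult_male"),
        ],
    )
    def test_thresholds(self, ipi_ms, label):
        assert classify_individual(ipi_ms) == label

    def test_thresholds_map_to_9_and_12_metres(self):
        assert size_from_ipi(2.9) == pytest.approx(9.0, abs=0.05)
        assert size_from_ipi(5.0) == pytest.approx(12.0, abs=0.05)


class TestEstimateIpi:
    def test_envelope_on_noisy_click(self):
        spec = ca.ClickSpec(ipi_ms=4.0, snr_db=20.0)
        seg = ca.synth_click(spec, t0=0.01, seed=1)
        hp = ca.highpass(seg)
        (click,) = ca.detect_clicks(hp)
        m = ca.estimate_ipi_envelope(hp, click)
        assert m is not None and m.method == "envelope"
        assert m.ipi_ms == pytest.approx(4.0, abs=0.05)
        assert 0 < m.quality <= 1

    def test_sub_floor_ipi_is_measurable_but_rejected_downstream(self):
        """A 1.5 ms interval is measured; the 2 ms floor acts at averaging."""
        spec = ca.ClickSpec(ipi_ms=1.5, snr_db=np.inf)
        seg = ca.synth_click(spec, t0=0.01, seed=1)
        hp = ca.highpass(seg)
        (click,) = ca.detect_clicks(hp)
        m = ca.estimate_ipi_envelope(hp, click)
        assert m is not None and m.ipi_ms == pytest.approx(1.5, abs=0.05)
        assert summarize_individual([m] * 10) is None
        est = summarize_individual([m] * 10, calf_confirmed=True)
        assert est is not None and est.calf_confirmed

    def test_cepstrum_on_clean_click(self):
        spec = ca.ClickSpec(ipi_ms=5.5, snr_db=np.inf)
        seg = ca.synth_click(spec, t0=0.01, seed=1)
        hp = ca.highpass(seg)
        (click,) = ca.detect_clicks(hp)
        m = ca.estimate_ipi_cepstrum(hp, click)
        assert m is not None and m.method == "cepstrum"
        assert m.ipi_ms == pytest.approx(5.5, abs=0.05)

    def test_methods_agree_on_clean_clicks(self):
        """Envelope and cepstral measurements cross-validate to <= 0.1 ms."""
        for ipi in np.arange(2.25, 7.51, 0.75):
            seg = ca.synth_click(ca.ClickSpec(ipi_ms=float(ipi), snr_db=np.inf), t0=0.01, seed=1)
            hp = ca.highpass(seg)
            (click,) = ca.detect_clicks(hp)
            env = ca.estimate_ipi_envelope(hp, click)
            cep = ca.estimate_ipi_cepstrum(hp, click)
            assert env is not None and cep is not None
            assert abs(env.ipi_ms - cep.ipi_ms) <= 0.1

    def test_noise_window_yields_nothing(self, rng):
        noise = ca.AudioSegment(rng.normal(0.0, 0.1, 96_000), 96_000.0)
        fake = ca.ClickEvent(time_s=0.5, peak_amplitude=0.1, snr_db=10.0)
        assert ca.estimate_ipi_envelope(noise, fake) is None
        assert ca.estimate_ipi_cepstrum(noise, fake) is None


class TestSummarize:
    def test_mean_and_flags(self, rng):
        values = rng.normal(3.85, 0.05, 10)
        ms = [IPIMeasurement(v, "envelope", 0.5) for v in values]
        est = summarize_individual(ms)
        assert est.ipi_mean_ms == pytest.approx(values.mean())
        assert est.ipi_sd_ms == pytest.approx(values.std(ddof=1))
        assert est.flags == ()
        assert est.class_label == "female_or_juvenile_male"

    def test_floor_and_calf_override(self):
        ms = [IPIMeasurement(1.90, "envelope", 0.5)] * 10
        assert summarize_individual(ms) is None
        est = summarize_individual(ms, calf_confirmed=True)
        assert est.length_m == pytest.approx(7.59, abs=0.01)

    def test_warning_flags(self):
        short = [IPIMeasurement(3.0, "envelope", 0.5)] * 4
        assert "few_measurements" in summarize_individual(short).flags
        noisy = [IPIMeasurement(v, "envelope", 0.5) for v in (3.0, 3.6, 2.8, 3.9, 3.1) * 2]
        assert "high_sd" in summarize_individual(noisy).flags

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_individual([])


class TestClusterIndividuals:
    def _ms(self, values):
        return [IPIMeasurement(v, "envelope", 0.5) for v in values]

    def test_two_separated_animals(self, rng):
        ipis = np.concatenate([rng.normal(3.0, 0.03, 10), rng.normal(5.5, 0.03, 10)])
        groups = cluster_individuals(self._ms(ipis))
        assert len(groups) == 2

    def test_empty(self):
        assert cluster_individuals([]) == []

    def test_chaining_merges_evenly_spaced_values(self):
        groups = cluster_individuals(self._ms(np.arange(3.0, 3.51, 0.1)))
        assert len(groups) == 1


class TestParameterRecovery:
    def test_fifty_individuals_at_low_snr(self):
        """Lengths Uniform(7.6, 15.6) m at 10 dB SNR: mean absolute length
        error <= 0.15 m; class exact for animals >= 0.2 m from a boundary."""
        from cachalot.pipeline import estimate_individual_from_audio

        rng = np.random.default_rng(42)
        errors, class_ok = [], []
        for i in range(50):
            length = rng.uniform(7.6, 15.6)
            ipi = ipi_from_size(length)
            audio, _ = ca.synth_train(
                ca.TrainSpec("regular", 12, (0.5, 0.8)),
                ca.ClickSpec(ipi_ms=ipi, snr_db=10.0),
                seed=3000 + i,
            )
            est, _ = estimate_individual_from_audio(audio)
            assert est is not None
            errors.append(abs(est.length_m - length))
            if min(abs(length - 9.0), abs(length - 12.0)) >= 0.2:
                class_ok.append(est.class_label == classify_individual(ipi))
        assert np.mean(errors) <= 0.15
        assert all(class_ok)
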