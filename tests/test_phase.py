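"""Phase profiles, rhythmicity, classification and profile metrics."""

import numpy as np
import pandas as pd
import pytest

from crawlkit import phase, rhythm, synth
from crawlkit.phase import (
    PhaseProfile,
    autocorr_rhythmicity,
    classify_unit,
    epoch_profiles,
    phase_profile,
    profile_metrics,
)
from crawlkit.rhythm import Burst, RateCurve, compute_bff, segment_cycles


def make_profile(values, unit_id="u"):
    n = len(values)
    return PhaseProfile(unit_id, (np.arange(n) + 0.5) / n, np.asarray(values, float), 4)


def cycle_table(starts, dur=3.0, n=20):
    bursts = [Burst(s, s + dur, n) for s in starts]
    return segment_cycles(bursts, "start_to_start")


class TestAutocorrRhythmicity:
    def test_square_wave_is_rhythmic(self):
        T, dt = 10.0, 0.5
        t = np.arange(0, 4 * T, dt)
        v = (np.mod(t, T) < 3.0) * 20.0
        bff = RateCurve(np.arange(t.size + 1) * dt, v, dt)
        rr = autocorr_rhythmicity(bff, period=T)
        assert rr.is_rhythmic
        assert rr.n_qualifying_peaks >= 2
        assert rr.coefficients[0] == pytest.approx(1.0)

    def test_white_noise_rarely_rhythmic(self):
        T, dt = 10.0, 0.5
        n = int(4 * T / dt)
        hits = 0
        for seed in range(100):
            v = np.random.default_rng(seed).poisson(3, n) / dt
            bff = RateCurve(np.arange(n + 1) * dt, v, dt)
            if autocorr_rhythmicity(bff, period=T).is_rhythmic:
                hits += 1
        assert hits <= 5  # non-rhythmic in at least 95/100 seeds

    def test_subthreshold_peak_not_rhythmic(self):
        # sinusoid drowned in noise until the oracle — the direct Pearson
        # coefficient maximized over all candidate periodic lags (0.8-2.2 T)
        # — sits just below the 0.25 criterion
        T, dt = 10.0, 0.5
        n = int(4 * T / dt)
        t = np.arange(n) * dt
        rng = np.random.default_rng(12)

        def oracle(v):
            best = -1.0
            for k in range(int(0.8 * T / dt), int(2.2 * T / dt)):
                if n - k < 4:
                    break
                best = max(best, np.corrcoef(v[:-k], v[k:])[0, 1])
            return best

        for amp in np.linspace(1.0, 0.02, 80):
            v = amp * np.sin(2 * np.pi * t / T) + rng.standard_normal(n)
            r_oracle = oracle(v)
            if 0.05 < r_oracle < 0.21:
                bff = RateCurve(np.arange(n + 1) * dt, v - v.min(), dt)
                rr = autocorr_rhythmicity(bff, period=T)
                assert not rr.is_rhythmic
                return
        pytest.fail("could not construct a sub-threshold case")

    def test_constant_flagged_nonrhythmic(self):
        bff = RateCurve(np.arange(81) * 0.5, np.full(80, 5.0), 0.5)
        rr = autocorr_rhythmicity(bff, period=10.0)
        assert not rr.is_rhythmic
        assert rr.flag == "constant"


class TestPhaseProfile:
    def test_spikes_at_cycle_starts_fill_bin_zero(self):
        tab = cycle_table([0.0, 10.0, 20.0, 30.0, 40.0])
        spikes = np.array([0.01, 10.01, 20.01, 30.01])
        prof = phase_profile(spikes, tab, n_bins=50, n_cycles=4)
        assert prof.mean_bff[0] > 0
        assert np.all(prof.mean_bff[1:] == 0)

    def test_uniform_spikes_flat_profile(self):
        tab = cycle_table([0.0, 10.0, 20.0, 30.0, 40.0])
        rng = np.random.default_rng(8)
        spikes = np.sort(rng.uniform(0, 40, 4000))
        prof = phase_profile(spikes, tab, n_bins=20, n_cycles=4)
        expect = 4000 / 40  # 100 Hz overall
        # per-bin binomial error: ~200 spikes per bin
        assert np.all(np.abs(prof.mean_bff - expect) < 5 * np.sqrt(expect / (0.5 * 4)))

    def test_in_phase_unit_mass_inside_window(self, default_cycles):
        cycles, _ = default_cycles
        spec = synth.UnitSpec("in_phase", 20.0, 0.0, 0.0, 0.32)
        spikes, _ = synth.gen_unit_spikes(spec, cycles, seed=5)
        de3 = synth.UnitSpec("DE3", 20.0, 0.0, 0.0, 0.32)
        st, _ = synth.gen_unit_spikes(de3, cycles, seed=6)
        tab = segment_cycles(rhythm.detect_bursts(st), "start_to_start")
        prof = phase_profile(spikes, tab, n_bins=50, n_cycles=4)
        mass = prof.mean_bff[prof.phases < 0.32].sum() / prof.mean_bff.sum()
        assert mass >= 0.95

    def test_silent_unit_flagged(self):
        tab = cycle_table([0.0, 10.0, 20.0, 30.0, 40.0])
        prof = phase_profile(np.array([]), tab, n_bins=10, n_cycles=4)
        assert prof.flag == "silent"
        assert np.all(prof.mean_bff == 0)


class TestProfileMetrics:
    def test_rectangle_width(self):
        v = np.where(np.arange(50) < 16, 20.0, 0.0)
        max_bff, rel_hw, _ = profile_metrics(make_profile(v))
        assert max_bff == pytest.approx(20.0, rel=1e-3)
        assert rel_hw == pytest.approx(0.32, abs=0.005)

    def test_triangle_half_width(self):
        x = np.arange(50) / 50
        v = np.interp(x, [0, 0.2, 0.4], [0, 10, 0])
        _, rel_hw, _ = profile_metrics(make_profile(v), smooth_sigma_bins=0)
        assert rel_hw == pytest.approx(0.2, abs=0.01)

    def test_wrap_invariance(self):
        v = np.where(np.arange(50) < 16, 20.0, 0.0)
        _, hw0, _ = profile_metrics(make_profile(v))
        for roll in (10, 25, 42):
            _, hw, _ = profile_metrics(make_profile(np.roll(v, roll)))
            assert hw == pytest.approx(hw0, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            profile_metrics(make_profile(np.zeros(50)))


class TestClassifyUnit:
    def test_de3_own_profile_in_phase(self, default_cycles):
        cycles, _ = default_cycles
        de3 = synth.UnitSpec("DE3", 20.0, 0.0, 0.0, 0.32)
        st, _ = synth.gen_unit_spikes(de3, cycles, seed=1)
        tab = segment_cycles(rhythm.detect_bursts(st), "start_to_start")
        prof = phase_profile(st, tab, 50, 4, "DE3")
        assert classify_unit(prof, tab["duty"].mean()) == "in_phase"

    @pytest.mark.parametrize(
        "cls,window",
        [("anti_phase", (0.36, 1.0)), ("in_phase_early_onset", (0.9, 0.2))],
    )
    def test_synthetic_classes_recovered(self, default_cycles, cls, window):
        cycles, _ = default_cycles
        spec = synth.UnitSpec(cls, 15.0, 0.2, *window)
        spikes, _ = synth.gen_unit_spikes(spec, cycles, seed=9)
        de3 = synth.UnitSpec("DE3", 20.0, 0.0, 0.0, 0.32)
        st, _ = synth.gen_unit_spikes(de3, cycles, seed=10)
        tab = segment_cycles(rhythm.detect_bursts(st), "start_to_start")
        prof = phase_profile(spikes, tab, 50, 4, cls)
        assert classify_unit(prof, tab["duty"].mean()) == cls

    def test_rate_scaling_invariance(self):
        v = np.where((np.arange(50) >= 20) & (np.arange(50) < 45), 8.0, 0.1)
        lab1 = classify_unit(make_profile(v), 0.32)
        lab2 = classify_unit(make_profile(v * 7.3), 0.32)
        assert lab1 == lab2 == "anti_phase"

    def test_bimodal_profile_unclassified(self):
        v = np.zeros(50)
        v[5:10] = 10.0
        v[30:35] = 9.8  # second peak within 10% of the maximum
        assert classify_unit(make_profile(v), 0.32) == "unclassified"


class TestEpochProfiles:
    def _epoch_setup(self, test_gain=1.0, seed=0):
        osc = synth.OscillatorSpec(seed=seed, n_cycles=14, period_cv=0.05)
        cycles, _ = synth.gen_cycles(osc)
        de3 = synth.UnitSpec("DE3", 20.0, 0.0, 0.0, 0.32)
        st, _ = synth.gen_unit_spikes(de3, cycles, seed=seed + 50)
        tab = segment_cycles(rhythm.detect_bursts(st), "start_to_start")
        pulse = (float(cycles.bounds[5, 0]) + 0.1, float(cycles.bounds[9, 0]) - 0.1)
        tab = rhythm.assign_epochs(tab, pulse)
        spec = synth.UnitSpec("in_phase", 15.0, 0.2, 0.0, 0.32)
        base, _ = synth.gen_unit_spikes(spec, cycles, seed=seed + 80)
        if test_gain != 1.0:
            boost = synth.UnitSpec("in_phase", 15.0 * test_gain, 0.2, 0.0, 0.32)
            alt, _ = synth.gen_unit_spikes(boost, cycles, seed=seed + 81)
            in_test = (base >= pulse[0]) & (base <= pulse[1])
            alt_in = (alt >= pulse[0]) & (alt <= pulse[1])
            base = np.sort(np.concatenate([base[~in_test], alt[alt_in]]))
        return base, tab

    def test_stationary_unit_equal_max_bff(self):
        ratios = []
        for seed in range(6):
            spikes, tab = self._epoch_setup(seed=seed)
            profs = epoch_profiles(spikes, tab, n_bins=50)
            assert set(profs) == {"pre", "test", "post"}
            ratios.append(profs["test"].max_bff / profs["pre"].max_bff)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_programmed_test_epoch_gain_recovered(self):
        ratios = []
        for seed in range(6):
            spikes, tab = self._epoch_setup(test_gain=1.5, seed=seed)
            profs = epoch_profiles(spikes, tab, n_bins=50)
            ratios.append(profs["test"].max_bff / profs["pre"].max_bff)
        assert np.mean(ratios) == pytest.approx(1.5, abs=0.25)

    def test_missing_epoch_absent(self):
        spikes, tab = self._epoch_setup()
        tab = tab[tab["epoch"] != "post"]
        profs = epoch_profiles(spikes, tab, n_bins=50)
        assert "post" not in profs
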