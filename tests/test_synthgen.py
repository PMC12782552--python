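"""Generators: oscillator cycles, phase-tuned spikes, NS traces, kinematics."""

import numpy as np
import pytest

from crawlkit import synth
from crawlkit.synth import (
    KinematicSpec,
    NSSpec,
    OscillatorSpec,
    UnitSpec,
    gen_behavior,
    gen_cycles,
    gen_ns_trace,
    gen_unit_spikes,
    make_template,
    render_extracellular,
)


class TestGenCycles:
    def test_zero_jitter_exact_periods(self):
        cycles, _ = gen_cycles(OscillatorSpec(period_cv=0.0, n_cycles=7, seed=0))
        assert np.allclose(cycles.periods, 15.22)

    def test_default_mean_period_within_three_sem(self):
        spec = OscillatorSpec(n_cycles=20, seed=1)
        cycles, _ = gen_cycles(spec)
        sem = spec.period_cv * spec.period_mean / np.sqrt(spec.n_cycles)
        assert abs(cycles.periods.mean() - 15.22) < 3 * sem

    def test_contraction_duty_exact_per_cycle(self):
        cycles, _ = gen_cycles(OscillatorSpec(seed=3))
        duty = (cycles.contraction[:, 1] - cycles.contraction[:, 0]) / cycles.periods
        assert np.allclose(duty, 0.32)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            gen_cycles(OscillatorSpec(period_mean=-1.0))
        with pytest.raises(ValueError):
            gen_cycles(OscillatorSpec(contraction_duty=1.5))

    def test_bit_reproducible(self):
        a, _ = gen_cycles(OscillatorSpec(seed=11))
        b, _ = gen_cycles(OscillatorSpec(seed=11))
        assert np.array_equal(a.bounds, b.bounds)

    def test_cycles_contiguous(self, default_cycles):
        cycles, truth = default_cycles
        assert np.allclose(cycles.starts[1:], cycles.ends[:-1])
        truth.validate()


class TestGenUnitSpikes:
    def test_silent_unit(self, default_cycles):
        spec = UnitSpec(peak_rate=0.0, baseline_rate=0.0)
        times, _ = gen_unit_spikes(spec, default_cycles[0], seed=0)
        assert times.size == 0

    def test_de3_spikes_confined_to_contraction_window(self, default_cycles):
        cycles, _ = default_cycles
        spec = UnitSpec("DE3", 20.0, 0.0, 0.0, 0.32)
        times, _ = gen_unit_spikes(spec, cycles, seed=1)
        phase = cycles.phase_of(times)
        assert times.size > 100
        assert np.all(phase < 0.32)

    def test_poisson_count_statistics(self, default_cycles):
        cycles, _ = default_cycles
        spec = UnitSpec("DE3", 20.0, 0.0, 0.0, 0.32, refractory=0.001)
        window_time = np.sum(cycles.periods * 0.32)
        counts = [
            gen_unit_spikes(spec, cycles, seed=s)[0].size for s in range(30)
        ]
        expect = 20.0 * window_time
        # refractory dead time trims ~2% at 20 Hz x 1 ms
        assert abs(np.mean(counts) - expect) < 3 * np.sqrt(expect)

    def test_empty_tuning_window_rejected(self, default_cycles):
        spec = UnitSpec("in_phase", 10.0, 0.0, 0.4, 0.4)
        with pytest.raises(ValueError, match="empty tuning window"):
            gen_unit_spikes(spec, default_cycles[0], seed=0)

    def test_refractory_enforced(self, default_cycles):
        spec = UnitSpec("DE3", 50.0, 0.0, 0.0, 0.32, refractory=0.01)
        times, _ = gen_unit_spikes(spec, default_cycles[0], seed=2)
        assert np.all(np.diff(times) >= 0.01)

    def test_wrapped_window(self, default_cycles):
        cycles, _ = default_cycles
        spec = UnitSpec("in_phase_early_onset", 15.0, 0.0, 0.9, 0.2)
        times, _ = gen_unit_spikes(spec, cycles, seed=3)
        ph = cycles.phase_of(times)
        ph = ph[~np.isnan(ph)]
        assert np.all((ph >= 0.9) | (ph < 0.2))


class TestRenderExtracellular:
    def test_noiseless_is_exact_superposition(self):
        tpl = make_template(10.0, rate=10_000)
        times = np.array([0.05, 0.12, 0.30])
        trace, ledger = render_extracellular(
            [(times, tpl)], rate=10_000, noise_sd=0.0, duration=0.4
        )
        manual = np.zeros(trace.n)
        peak = int(np.argmax(np.abs(tpl)))
        for t in times:
            s = int(round(t * 10_000))
            manual[s - peak : s - peak + tpl.size] += tpl
        assert np.allclose(trace.values, manual)
        assert len(ledger) == 3

    def test_amplitude_ratio_preserved(self):
        t1 = make_template(10.0, rate=10_000)
        t2 = make_template(5.0, rate=10_000)
        trace, _ = render_extracellular(
            [(np.array([0.05]), t1), (np.array([0.25]), t2)],
            rate=10_000,
            noise_sd=0.0,
            duration=0.4,
        )
        a1 = np.max(np.abs(trace.values[:1500]))
        a2 = np.max(np.abs(trace.values[1500:]))
        assert a1 / a2 == pytest.approx(2.0, rel=1e-9)

    def test_noise_only_rms(self):
        trace, ledger = render_extracellular([], rate=10_000, noise_sd=2.0, duration=50.0)
        rms = np.sqrt(np.mean(trace.values**2))
        assert rms == pytest.approx(2.0, rel=0.01)
        assert len(ledger) == 0

    def test_ledger_covers_every_rendered_spike(self, std_episode):
        total = sum(len(v) for v in std_episode.spikes.values())
        # spikes too close to the trace edge may be skipped, never added
        assert 0 <= total - len(std_episode.ledger) <= 2


class TestGenNsTrace:
    def test_flat_when_quiet(self, default_cycles):
        spec = NSSpec(hyp_amplitude=0.0, noise_sd=0.0, drift=0.0)
        ns, _ = gen_ns_trace(spec, default_cycles[0], rate=200, seed=0)
        assert np.allclose(ns.values, spec.resting_vm)

    def test_trough_mode_minimum_is_programmed_depth(self, default_cycles):
        spec = NSSpec(hyp_amplitude=6.0, noise_sd=0.0, depth_reference="trough")
        ns, _ = gen_ns_trace(spec, default_cycles[0], rate=500, seed=0)
        cycles = default_cycles[0]
        for a, b in cycles.bounds:
            seg = ns.slice(a, b)
            assert seg.values.min() == pytest.approx(spec.resting_vm - 6.0, abs=0.05)

    def test_baseline_mode_measured_depth_is_programmed(self, default_cycles):
        from scipy.ndimage import gaussian_filter1d

        cycles = default_cycles[0]
        spec = NSSpec(hyp_amplitude=6.0, noise_sd=0.0)
        ns, truth = gen_ns_trace(spec, cycles, rate=500, seed=0)
        base = gaussian_filter1d(ns.values, 5.0 * 500, mode="reflect")
        for k, (a, b) in enumerate(cycles.contraction):
            i0, i1 = int(a * 500), int(b * 500)
            depth = base[i0] - ns.values[i0:i1].min()
            assert depth == pytest.approx(6.0, rel=0.02)
        assert np.allclose(truth.ns_depths, 6.0)

    def test_antiphase_coupling_with_de3_rate(self, default_cycles):
        cycles, _ = default_cycles
        spec = NSSpec(noise_sd=0.0)
        ns, _ = gen_ns_trace(spec, cycles, rate=100, seed=0)
        # smooth DE-3 rate curve built from the same contraction windows
        # (raised-cosine burst envelope, the generator's rate shape family)
        t = ns.times
        rate = np.zeros(t.size)
        for a, b in cycles.contraction:
            m = (t >= a) & (t < b)
            rate[m] = 0.5 * (1.0 - np.cos(2 * np.pi * (t[m] - a) / (b - a)))
        r = np.corrcoef(ns.values, rate)[0, 1]
        assert r < -0.9  # hyperpolarization is anti-phase to DE-3 activity


class TestGenBehavior:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            KinematicSpec(elong_frac=0.5, contr_frac=0.5, iso_pre_frac=0.2,
                          iso_post_frac=0.2).validate()

    def test_noiseless_max_at_programmed_junction(self):
        beh = gen_behavior(KinematicSpec(noise_sd=0.0, n_steps=3), seed=0)
        fps = beh.fps
        for s in beh.truth.steps:
            i0, i1 = int(s["t_start"] * fps), int(s["t_end"] * fps)
            imax = i0 + np.argmax(beh.section_lengths[i0:i1, 3])
            assert abs(imax / fps - s["max_length_time"]) <= 2 / fps

    def test_programmed_dynamic_duty_default(self):
        spec = KinematicSpec()
        assert spec.dynamic_duty_elong == pytest.approx(0.65)

    def test_n_steps_in_ground_truth(self):
        beh = gen_behavior(KinematicSpec(n_steps=5), seed=0)
        assert len(beh.truth.steps) == 5

    def test_bit_reproducible(self):
        a = gen_behavior(KinematicSpec(n_steps=2), seed=4)
        b = gen_behavior(KinematicSpec(n_steps=2), seed=4)
        assert np.array_equal(a.points, b.points)

    def test_dlc_roundtrip(self, tmp_path):
        from crawlkit import kinematics

        beh = gen_behavior(KinematicSpec(n_steps=2), seed=1)
        p = tmp_path / "track.csv"
        beh.to_dlc_csv(p)
        track = kinematics.load_pose(p, fps=beh.fps)
        assert np.allclose(track.points, beh.points)
        assert track.valid.all()

    def test_boundaries_inside_trace(self):
        beh = gen_behavior(KinematicSpec(n_steps=4), seed=2)
        span = beh.n_frames / beh.fps
        for s in beh.truth.steps:
            assert 0.0 <= s["t_start"] < s["t_end"] <= span + 1e-9
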