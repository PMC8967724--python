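"""dF/F transform, responsiveness, activation kinetics and marker rules."""

import numpy as np
import pytest

from vagalseq.activity import (
    DEFAULT_MARKER_RULES,
    StimulusWindow,
    activation_metrics,
    align_at_activation,
    classify_archetype,
    classify_subpopulation,
    delta_f_over_f,
    is_responsive,
    stretch_window,
)
from vagalseq.synthetic import SynthConfig, generate_trace_set

ONSET = 40
WINDOW = StimulusWindow("stim", ONSET, ONSET, ONSET + 30)

ALL_GENES = (
    "Trpa1", "Runx3", "Uts2b", "Gabra1", "Slit2", "Kcng1", "Piezo2", "Ddc",
    "Vip", "Trpv1", "Gpr65", "Chodl", "Glp1r", "Grm5", "Slc17a7", "P2ry1",
    "Tmc3", "Car8", "Nts", "Cckar", "Calca",
)


def panel(*positive):
    return {g: g in positive for g in ALL_GENES}


def scan_oracle(dff, start, stop, level=0.1):
    """Independent brute-force scan for peak/activation/duration."""
    peak_frame = start + max(range(stop - start), key=lambda k: dff[start + k])
    peak = dff[peak_frame]
    cut = level * peak
    act = peak_frame
    while act > 0 and dff[act - 1] >= cut:
        act -= 1
    post = peak_frame
    censored = False
    while dff[post] >= cut:
        if post == len(dff) - 1:
            censored = True
            break
        if dff[post + 1] < cut:
            break
        post += 1
    return peak, peak_frame, act, post - act + 1, censored


class TestDeltaFOverF:
    def test_constant_trace_all_zero(self):
        assert np.allclose(delta_f_over_f(np.full(100, 50.0), ONSET), 0.0)

    def test_forced_arithmetic(self):
        trace = np.full(100, 100.0)
        trace[60] = 250.0
        dff = delta_f_over_f(trace, ONSET)
        assert dff[60] == pytest.approx(1.5)

    def test_baseline_window_half_open(self):
        # frames onset-20 .. onset-11 are used; onset-10 is excluded
        trace = np.full(100, 100.0)
        trace[ONSET - 10] = 1e6  # just outside the baseline window
        assert delta_f_over_f(trace, ONSET)[0] == pytest.approx(0.0)
        trace2 = np.full(100, 100.0)
        trace2[ONSET - 11] = 200.0  # inside: baseline becomes 110
        assert delta_f_over_f(trace2, ONSET)[0] == pytest.approx(100 / 110 - 1)

    def test_scale_invariance(self, rng):
        trace = 100 + rng.uniform(size=120) * 50
        assert np.allclose(
            delta_f_over_f(trace, ONSET), delta_f_over_f(7.3 * trace, ONSET)
        )

    def test_early_onset_raises(self):
        with pytest.raises(ValueError):
            delta_f_over_f(np.ones(50), 10)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            delta_f_over_f(np.zeros(100), ONSET)


class TestIsResponsive:
    def dff_with_peak(self, value, frame):
        d = np.zeros(100)
        d[frame] = value
        return d

    def test_above_threshold_responsive(self):
        assert is_responsive(self.dff_with_peak(1.5, 50), WINDOW)

    def test_exactly_one_not_responsive(self):
        assert not is_responsive(self.dff_with_peak(1.0, 50), WINDOW)

    def test_peak_outside_window_not_responsive(self):
        assert not is_responsive(self.dff_with_peak(1.5, 5), WINDOW)

    def test_monotone_in_threshold(self, rng):
        for _ in range(50):
            d = rng.uniform(0, 2, size=100)
            r_low = is_responsive(d, WINDOW, threshold=0.5)
            r_high = is_responsive(d, WINDOW, threshold=1.5)
            assert r_low or not r_high


class TestActivationMetrics:
    def test_triangular_pulse_matches_scan_oracle(self):
        dff = np.zeros(100)
        for k in range(11):
            dff[ONSET - 10 + k] = k / 10
            dff[ONSET + 10 - k] = k / 10
        r = activation_metrics(dff, WINDOW)
        peak, pf, act, dur, cens = scan_oracle(dff, WINDOW.start, WINDOW.stop)
        assert (r.peak, r.peak_frame, r.activation_frame, r.activation_duration, r.censored) == (
            peak, pf, act, dur, cens
        )

    def test_rectangular_pulse_duration_equals_width(self):
        dff = np.zeros(100)
        dff[50:60] = 2.0
        r = activation_metrics(dff, WINDOW)
        assert r.activation_frame == 50
        assert r.activation_duration == 10
        assert not r.censored

    def test_monotone_rise_censored(self):
        dff = np.linspace(0, 3, 100)
        r = activation_metrics(dff, StimulusWindow("s", 40, 40, 100))
        assert r.censored
        assert r.activation_duration == 100 - r.activation_frame

    def test_activation_not_after_peak(self, rng):
        for _ in range(50):
            dff = rng.uniform(0, 2, size=100)
            r = activation_metrics(dff, WINDOW)
            assert r.activation_frame <= r.peak_frame

    def test_random_traces_match_scan_oracle(self, rng):
        for _ in range(300):
            dff = rng.uniform(-0.2, 2.5, size=120)
            r = activation_metrics(dff, WINDOW)
            peak, pf, act, dur, cens = scan_oracle(dff, WINDOW.start, WINDOW.stop)
            assert r.peak == pytest.approx(peak)
            assert (r.peak_frame, r.activation_frame, r.activation_duration, r.censored) == (
                pf, act, dur, cens
            )


class TestAlign:
    def pulse_trace(self, shift=0):
        trace = np.full(200, 100.0)
        trace[60 + shift:70 + shift] = 300.0
        return trace

    def test_identical_traces_identical_rows(self):
        w = stretch_window("s", 50, 100)
        dffs = [delta_f_over_f(self.pulse_trace(), 50)] * 3
        aligned = align_at_activation(dffs, w)
        assert np.array_equal(aligned[0], aligned[1], equal_nan=True)

    def test_shift_equivariance(self):
        w = stretch_window("s", 50, 110)
        d0 = delta_f_over_f(self.pulse_trace(0), 50)
        d5 = delta_f_over_f(self.pulse_trace(5), 50)
        aligned = align_at_activation([d0, d5], w, n_post=30)
        assert np.allclose(aligned[0], aligned[1])

    def test_column_zero_is_activation_value(self):
        w = stretch_window("s", 50, 110)
        dffs = [delta_f_over_f(self.pulse_trace(s), 50) for s in (0, 3, 7)]
        aligned = align_at_activation(dffs, w)
        for row, d in zip(aligned, dffs):
            r = activation_metrics(d, w)
            assert row[0] == d[r.activation_frame]

    def test_unresponsive_cell_rejected(self):
        w = stretch_window("s", 50, 100)
        flat = np.zeros(200)
        with pytest.raises(ValueError):
            align_at_activation([flat], w)


class TestMarkerRules:
    @pytest.mark.parametrize(
        "positive,expected",
        [
            (("Gpr65",), "F"),
            (("Gabra1",), "B"),
            ((), "X"),
            (("Runx3",), "A"),  # any-of rule with Tmc3 negative
            (("Slit2", "Ddc"), "C"),  # multiple hits, Trpv1-/P2ry1-
            (("Slit2",), "X"),  # a single hit is not "multiple"
            (("Tmc3",), "D"),
            (("Trpv1", "Trpa1"), "H"),
            (("Tmc3", "Car8", "Cckar"), "D"),  # D precedes I in evaluation order
            (("Trpv1", "Calca"), "J"),
            (("P2ry1", "Trpv1", "Calca"), "J"),  # J admits P2ry1+ cells
            (("P2ry1",), "L"),
            (("Trpv1", "Uts2b", "Vip"), "G"),
        ],
    )
    def test_rule_assignments(self, positive, expected):
        assert classify_subpopulation(panel(*positive)) == expected

    def test_first_match_wins(self):
        # Gpr65+ Gabra1+ hits B before F in the A->L order
        assert classify_subpopulation(panel("Gabra1", "Gpr65")) == "B"

    def test_unmeasured_gene_raises(self):
        with pytest.raises(KeyError):
            classify_subpopulation({"Gpr65": True})

    def test_rule_order_is_a_through_l(self):
        assert [r.name for r in DEFAULT_MARKER_RULES] == list("ABCDFGHIJKL")


class TestArchetypes:
    def test_nonresponder_flat_at_zero_noise(self):
        cfg = SynthConfig(
            n_trace_cells=20, trace_noise_sd=0.0, archetype_probs=(0, 0, 0, 1.0), seed=2
        )
        traces, _ = generate_trace_set(cfg)
        assert np.allclose(traces.f, cfg.baseline_f)

    def test_sustained_peak_equals_amplitude(self):
        cfg = SynthConfig(
            n_trace_cells=5, trace_noise_sd=0.0, archetype_probs=(1.0, 0, 0, 0),
            response_amplitude=2.0, seed=2,
        )
        traces, _ = generate_trace_set(cfg)
        w = traces.stimuli[0]
        for row in traces.f:
            dff = delta_f_over_f(row, w.onset)
            assert dff[w.start:w.stop].max() == pytest.approx(2.0)

    def test_recovery_at_low_noise_is_perfect(self):
        cfg = SynthConfig(n_trace_cells=100, trace_noise_sd=0.05, seed=9)
        traces, truth = generate_trace_set(cfg)
        for cid, row in zip(traces.cell_ids, traces.f):
            assert classify_archetype(row, traces.stimuli) == truth.archetypes[cid]
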