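"""Event and barrage detection on ΔF and somatic current traces."""

import numpy as np
import pytest

from dendrodomains import (
    Barrage,
    CurrentTrace,
    RoiTrace,
    associate_events,
    barrage_charge,
    detect_barrages,
    detect_events,
    estimate_noise,
    geometric_bins,
    zscore_amplitudes,
)
from dendrodomains.detection import TransmissionEvent


def make_trace(values, fr=10.0, roi="roi0", rec="r0"):
    values = np.asarray(values, dtype=float)
    return RoiTrace(roi, np.arange(len(values)) / fr, values, rec)


class TestEstimateNoise:
    def test_pure_gaussian(self):
        rng = np.random.default_rng(0)
        tr = make_trace(rng.normal(0, 1.0, 10_000))
        assert estimate_noise(tr) == pytest.approx(1.0, abs=0.05)

    def test_constant_trace_warns_zero(self):
        tr = make_trace(np.full(100, 3.0))
        with pytest.warns(UserWarning):
            assert estimate_noise(tr) == 0.0

    def test_robust_to_transients(self):
        # 5% of frames carry +10 transients; estimate must stay near 1
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, 10_000)
        idx = rng.choice(10_000, 500, replace=False)
        x[idx] += 10.0
        assert 0.9 <= estimate_noise(make_trace(x)) <= 1.2

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise(make_trace(np.zeros(10)))


class TestDetectEvents:
    def test_flat_trace(self):
        assert detect_events(make_trace(np.zeros(100)), noise=1.0) == []

    def test_square_transient(self):
        x = np.zeros(100)
        x[40:45] = 3.0  # 3σ for 5 frames
        evs = detect_events(make_trace(x), noise=1.0)
        assert len(evs) == 1
        assert evs[0].duration_frames == 5
        assert evs[0].onset == pytest.approx(4.0)
        assert evs[0].amplitude == pytest.approx(3.0)

    def test_single_frame_excursion_rejected(self):
        x = np.zeros(100)
        x[50] = 10.0
        assert detect_events(make_trace(x), noise=1.0) == []

    def test_subthreshold_rejected(self):
        x = np.zeros(100)
        x[40:45] = 1.5  # below 2σ
        assert detect_events(make_trace(x), noise=1.0) == []

    def test_accept_mask_vetoes_frames(self):
        x = np.zeros(100)
        x[40:45] = 3.0
        mask = np.ones(100, dtype=bool)
        mask[40:45] = False
        assert detect_events(make_trace(x), 1.0, accept_mask=mask) == []

    def test_disjoint_events(self):
        x = np.zeros(100)
        x[10:13] = 3.0
        x[50:54] = 4.0
        evs = detect_events(make_trace(x), noise=1.0)
        assert [e.duration_frames for e in evs] == [3, 4]
        ends = [e.onset + (e.duration_frames - 1) / 10.0 for e in evs]
        assert ends[0] < evs[1].onset  # disjoint in time


def current(values, fs=10_000.0, rec="r0"):
    values = np.asarray(values, dtype=float)
    return CurrentTrace(np.arange(len(values)) / fs, values, rec)


def two_deflections(gap_s, amp=-20.0, dur=0.5, fs=10_000.0, total=25.0):
    t = np.arange(0, total, 1 / fs)
    y = np.zeros_like(t)
    y[(t >= 5.0) & (t < 5.0 + dur)] = amp
    start2 = 5.0 + dur + gap_s
    y[(t >= start2) & (t < start2 + dur)] = amp
    return CurrentTrace(t, y)


class TestDetectBarrages:
    def test_separated_by_more_than_3s(self):
        assert len(detect_barrages(two_deflections(5.0))) == 2

    def test_merged_below_3s(self):
        assert len(detect_barrages(two_deflections(2.0))) == 1

    def test_below_10pA_ignored(self):
        assert detect_barrages(two_deflections(5.0, amp=-5.0)) == []

    def test_windows_ordered_and_gapped(self):
        bs = detect_barrages(two_deflections(4.0))
        assert bs[0].onset < bs[0].offset < bs[1].onset
        assert bs[1].onset - bs[0].offset >= 3.0

    def test_peak_recorded(self):
        (b,) = detect_barrages(two_deflections(2.0))
        assert b.peak_pA == pytest.approx(20.0, rel=0.15)


class TestBarrageCharge:
    def test_rectangular(self):
        tr = two_deflections(10.0)
        b = Barrage("b", "r0", 4.9, 5.7, 0.0, 20.0)
        # 20 pA for 0.5 s = 10 pC
        assert barrage_charge(tr, b, baseline=0.0) == pytest.approx(10.0, rel=0.02)

    def test_zero_deflection(self):
        tr = current(np.zeros(1000))
        b = Barrage("b", "r0", 0.01, 0.05, 0.0, 0.0)
        assert barrage_charge(tr, b, baseline=0.0) == pytest.approx(0.0, abs=1e-9)

    def test_triangular(self):
        fs = 10_000.0
        t = np.arange(0, 4.0, 1 / fs)
        y = np.where(np.abs(t - 2.0) <= 1.0, -10.0 * (1 - np.abs(t - 2.0)), 0.0)
        b = Barrage("b", "r0", 1.0, 3.0, 0.0, 10.0)
        # peak 10 pA, base 2 s triangle -> 10 pC
        q = barrage_charge(CurrentTrace(t, y), b, baseline=0.0)
        assert q == pytest.approx(10.0, rel=0.01)

    def test_additive_over_subwindows(self):
        tr = two_deflections(2.0)
        whole = Barrage("w", "r0", 4.0, 9.0, 0.0, 20.0)
        left = Barrage("l", "r0", 4.0, 6.0, 0.0, 20.0)
        right = Barrage("r", "r0", 6.0, 9.0, 0.0, 20.0)
        qw = barrage_charge(tr, whole, baseline=0.0)
        ql = barrage_charge(tr, left, baseline=0.0)
        qr = barrage_charge(tr, right, baseline=0.0)
        assert qw == pytest.approx(ql + qr, rel=1e-6)

    def test_window_outside_trace_rejected(self):
        tr = current(np.zeros(1000))
        with pytest.raises(ValueError):
            barrage_charge(tr, Barrage("b", "r0", -1.0, 0.05, 0.0, 0.0))


def ev(t, syn="s0", rec="r0"):
    return TransmissionEvent(syn, rec, t, 3, 1.0)


def bar(bid, on, off, rec="r0"):
    return Barrage(bid, rec, on, off, 1.0, 20.0)


class TestAssociateEvents:
    def test_inside_window_assigned(self):
        out = associate_events([ev(5.0)], [bar("b0", 4.0, 6.0)])
        assert out[0].barrage_id == "b0"

    def test_no_window_unassigned(self):
        out = associate_events([ev(20.0)], [bar("b0", 4.0, 6.0)])
        assert out[0].barrage_id is None

    def test_tolerance_edge(self):
        out = associate_events([ev(6.15)], [bar("b0", 4.0, 6.0)], tolerance=0.2)
        assert out[0].barrage_id == "b0"

    def test_equidistant_tie_goes_to_earlier_onset(self):
        # windows overlap the event with equal onset distance
        b1, b2 = bar("early", 4.0, 6.5), bar("late", 8.0, 9.0)
        out = associate_events([ev(6.0)], [b1, b2], tolerance=2.0)
        assert out[0].barrage_id == "early"

    def test_cross_recording_never_assigned(self):
        out = associate_events([ev(5.0, rec="r1")], [bar("b0", 4.0, 6.0, rec="r0")])
        assert out[0].barrage_id is None

    def test_event_count_conservation(self):
        events = [ev(t) for t in (4.5, 5.0, 5.5, 20.0)]
        barrages = [bar("b0", 4.0, 6.0), bar("b1", 19.0, 21.0)]
        out = associate_events(events, barrages)
        assigned = sum(1 for e in out if e.barrage_id is not None)
        assert assigned == sum(b.n_events for b in barrages) == 4


class TestZScore:
    def test_mean_zero_unit_sd(self):
        events = [
            TransmissionEvent("s0", "r0", float(t), 3, a)
            for t, a in enumerate([1.0, 2.0, 4.0, 8.0])
        ]
        out = zscore_amplitudes(events)
        z = np.array([e.z_amplitude for e in out])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_single_event_zero(self):
        (out,) = zscore_amplitudes([TransmissionEvent("s0", "r0", 0.0, 3, 5.0)])
        assert out.z_amplitude == 0.0

    def test_per_synapse_scaling_independent(self):
        events = [
            TransmissionEvent("a", "r0", 0.0, 3, 1.0),
            TransmissionEvent("a", "r0", 1.0, 3, 3.0),
            TransmissionEvent("b", "r0", 0.0, 3, 100.0),
            TransmissionEvent("b", "r0", 1.0, 3, 300.0),
        ]
        out = zscore_amplitudes(events)
        za = [e.z_amplitude for e in out if e.synapse_id == "a"]
        zb = [e.z_amplitude for e in out if e.synapse_id == "b"]
        assert za == pytest.approx(zb)


class TestGeometricBins:
    def test_powers_of_two(self):
        edges, _ = geometric_bins(np.arange(1, 101), factor=2.0, origin=1.0)
        assert edges.tolist() == [1, 2, 4, 8, 16, 32, 64, 128]

    def test_single_value(self):
        edges, means = geometric_bins([5.0], factor=2.0)
        assert len(edges) == 2 and edges[0] <= 5.0 < edges[1]
        assert means[0] == pytest.approx(5.0)

    def test_every_value_in_exactly_one_bin(self):
        rng = np.random.default_rng(4)
        v = rng.lognormal(2, 1, 500)
        edges, means = geometric_bins(v, factor=2.0)
        counts = np.histogram(v, edges)[0]
        assert counts.sum() == len(v)
        # per-bin means match brute force
        for k in range(len(edges) - 1):
            sel = (v >= edges[k]) & (v < edges[k + 1])
            if sel.any():
                assert means[k] == pytest.approx(v[sel].mean())

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            geometric_bins([1.0, 2.0], factor=1.0)
        with pytest.raises(ValueError):
            geometric_bins([0.0, 2.0])
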