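"""Ground-truth generator: determinism, designed statistical structure,
consistency between observables and truth."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from dendrodomains import (
    GeneratorConfig,
    compute_frequencies,
    detect_events,
    estimate_noise,
    generate_cohort,
    generate_experiment,
    preset,
    render_traces,
)
from dendrodomains.io import barrages_to_frame, events_to_frame


class TestDeterminism:
    def test_identical_seed_identical_tables(self):
        cfg = GeneratorConfig(seed=11)
        e1, t1 = generate_experiment(cfg, "a")
        e2, t2 = generate_experiment(cfg, "a")
        assert events_to_frame(t1.events).equals(events_to_frame(t2.events))
        assert barrages_to_frame(t1.barrages).equals(barrages_to_frame(t2.barrages))
        assert t1.high_release == t2.high_release
        assert t1.domain_membership == t2.domain_membership

    def test_different_seed_differs(self):
        e1, t1 = generate_experiment(GeneratorConfig(seed=1), "a")
        e2, t2 = generate_experiment(GeneratorConfig(seed=2), "a")
        assert len(t1.events) != len(t2.events) or t1.events[0].onset != t2.events[0].onset

    def test_render_deterministic(self):
        cfg = replace(GeneratorConfig(seed=5), n_recordings=1)
        exp, truth = generate_experiment(cfg, "a")
        r1, c1 = render_traces(exp, truth, cfg)
        r2, c2 = render_traces(exp, truth, cfg)
        assert np.array_equal(r1[0].values, r2[0].values)
        assert np.array_equal(c1["r0"].values, c2["r0"].values)


class TestDesignedStructure:
    def test_frequency_distribution_long_tailed(self):
        fs = []
        for k in range(4):
            exp, _ = generate_experiment(GeneratorConfig(seed=30 + k), f"d{k}")
            fs.extend(s.f for s in exp.synapses)
        assert stats.skew(fs) > 1.0

    def test_most_events_inside_barrages(self):
        exp, truth = generate_experiment(GeneratorConfig(seed=3), "d")
        frac = np.mean([ev.barrage_id is not None for ev in truth.events])
        assert frac >= 0.5

    def test_high_release_fraction_near_design(self):
        n = n_high = 0
        for k in range(5):
            _, truth = generate_experiment(GeneratorConfig(seed=60 + k), f"d{k}")
            n += len(truth.high_release)
            n_high += sum(truth.high_release.values())
        assert 0.15 <= n_high / n <= 0.25

    def test_truth_consistent_with_observables(self):
        exp, truth = generate_experiment(GeneratorConfig(seed=8), "d")
        ids = {s.synapse_id for s in exp.synapses}
        assert set(truth.high_release) == ids
        assert set(truth.domain_membership) == ids
        bids = {b.barrage_id for b in truth.barrages}
        for ev in truth.events:
            assert ev.barrage_id is None or ev.barrage_id in bids
        # per-barrage event counters match the event list
        counts = {}
        for ev in truth.events:
            if ev.barrage_id:
                counts[ev.barrage_id] = counts.get(ev.barrage_id, 0) + 1
        for b in truth.barrages:
            assert b.n_events == counts.get(b.barrage_id, 0)

    def test_barrage_gaps_at_least_3s(self):
        _, truth = generate_experiment(GeneratorConfig(seed=9), "d")
        by_rec = {}
        for b in truth.barrages:
            by_rec.setdefault(b.recording_id, []).append(b)
        for bs in by_rec.values():
            bs.sort(key=lambda b: b.onset)
            for a, b in zip(bs[:-1], bs[1:]):
                assert b.onset - a.offset >= 3.0 - 1e-9

    def test_positive_trend_injection_raises_mk(self):
        from dendrodomains.coactivity import trend_scores

        cfg = replace(
            GeneratorConfig(seed=13), trend_mode="positive", trend_fraction=1.0
        )
        exp, _ = generate_experiment(cfg, "d")
        compute_frequencies(exp)
        df = trend_scores(exp)
        assert df["mk_score"].mean() > 0

    def test_null_recruitment_no_domain_contrast(self):
        # no domain recruitment at all: in-domain firing is background-like,
        # so within- and other-domain co-activity coincide
        from dendrodomains import assign_domains, classify_high_activity, \
            filter_active
        from dendrodomains.coactivity import domain_coactivity_contrast

        diffs = []
        for k in range(4):
            cfg = replace(
                GeneratorConfig(seed=70 + k),
                p_domain_recruit=0.0,
                p_background_fire=0.1,
                trend_mode="none",
            )
            exp, _ = generate_experiment(cfg, f"d{k}")
            compute_frequencies(exp)
            exp.synapses = filter_active(exp.synapses)
            classify_high_activity([exp])
            ds = assign_domains(exp.tree, exp.synapses)
            out = domain_coactivity_contrast(exp, ds)
            if len(out["paired"]) >= 3:
                diffs.append(out["mean_within"] - out["mean_other"])
        assert abs(np.mean(diffs)) < 0.05

    def test_amplitudes_scale_with_barrage_size(self):
        _, truth = generate_experiment(GeneratorConfig(seed=21), "d")
        sizes, amps = [], []
        for ev in truth.events:
            if ev.barrage_id is not None:
                sizes.append(truth.barrage_size[ev.barrage_id])
                amps.append(ev.amplitude)
        r = stats.spearmanr(sizes, amps)
        assert r.statistic > 0.2 and r.pvalue < 0.01

    def test_zero_domain_density_uniform_placement(self):
        cfg = replace(
            GeneratorConfig(seed=14),
            domain_density_per_100um=0.0,
            background_density_per_100um=20.0,
            high_release_fraction=0.0,
            trend_mode="none",
        )
        exp, truth = generate_experiment(cfg, "d")
        assert all(m is None for m in truth.domain_membership.values())
        offs = np.array([s.position.offset for s in exp.synapses])
        ks = stats.kstest(offs / 150.0, "uniform")
        assert ks.pvalue > 0.01

    def test_infeasible_geometry_rejected(self):
        cfg = replace(
            GeneratorConfig(seed=1),
            dendrite_length_um=15.0,
            domain_extent_mean_um=40.0,
        )
        with pytest.raises(ValueError):
            generate_experiment(cfg, "d")

    def test_presets_differ_in_activity(self):
        young = [generate_experiment(preset("young", s), f"y{s}")[0] for s in range(3)]
        old = [generate_experiment(preset("old", s), f"o{s}")[0] for s in range(3)]
        fy = np.mean([s.f for e in young for s in e.synapses])
        fo = np.mean([s.f for e in old for s in e.synapses])
        assert fo > 1.5 * fy

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("adult")


class TestRendering:
    def test_noiseless_single_event_peak_at_onset(self):
        cfg = replace(
            GeneratorConfig(seed=2), n_recordings=1, trace_noise_sd=0.0
        )
        exp, truth = generate_experiment(cfg, "d")
        rois, _ = render_traces(exp, truth, cfg)
        # pick a trace with exactly one event
        for tr in rois:
            evs = [
                e for e in truth.events
                if e.synapse_id == tr.roi_id and e.recording_id == tr.recording_id
            ]
            if len(evs) == 1 and tr.values.max() > 0:
                rise_peak = tr.times[np.argmax(tr.values)]
                lag = rise_peak - evs[0].onset
                assert 0.0 <= lag <= 0.5  # kernel rise after onset
                return
        pytest.fail("no single-event trace found")

    def test_detection_recall_on_rendered_trace(self):
        cfg = replace(GeneratorConfig(seed=4), n_recordings=1)
        exp, truth = generate_experiment(cfg, "d")
        rois, _ = render_traces(exp, truth, cfg)
        tp = fn = 0
        for tr in rois:
            sigma = estimate_noise(tr)
            det = detect_events(tr, sigma)
            for ev in truth.events:
                if ev.synapse_id != tr.roi_id or ev.recording_id != tr.recording_id:
                    continue
                if ev.amplitude < 4 * cfg.trace_noise_sd:
                    continue
                ok = any(-0.3 <= d.onset - ev.onset <= 1.2 for d in det)
                tp += ok
                fn += not ok
        assert tp / (tp + fn) >= 0.9


def test_cohort_structure():
    cohort = generate_cohort(seed=2, n_per_group=2)
    assert len(cohort) == 4
    ages = sorted({e.age for e, _ in cohort})
    assert ages == [9, 12]
    assert len({e.dendrite_id for e, _ in cohort}) == 4
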