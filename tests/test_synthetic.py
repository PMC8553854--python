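import itertools

import numpy as np
import pytest

from erpstates import (
    EffectSpec,
    Timeline,
    TruthManifest,
    compute_gfp,
    cos_theta,
    default_envelope,
    make_templates,
    random_timeline,
    rotate_topography,
    simulate_dataset,
    simulate_epoch,
    time_axis,
)
from erpstates.synthetic import TemplateInfeasibleError


class TestMakeTemplates:
    def test_single_template_has_unit_gfp(self):
        ts = make_templates(1, 30, 60, seed=0)
        assert compute_gfp(ts.templates[0]) == pytest.approx(1.0, abs=1e-9)

    def test_two_channel_orthogonal_pair(self):
        ts = make_templates(2, 2, 90, seed=0)
        assert cos_theta(ts.templates[0], ts.templates[1]) == pytest.approx(0.0, abs=1e-12)
        for t in ts.templates:
            assert compute_gfp(t) == pytest.approx(1.0, abs=1e-9)

    def test_pairwise_separation_by_direct_dot_products(self):
        ts = make_templates(3, 30, 60, seed=1)
        for a, b in itertools.combinations(ts.templates, 2):
            assert abs(cos_theta(a, b)) <= 0.5 + 1e-12  # cos(60 deg)

    def test_deterministic_given_seed(self):
        a = make_templates(3, 30, 60, seed=5)
        b = make_templates(3, 30, 60, seed=5)
        np.testing.assert_array_equal(a.templates, b.templates)

    def test_infeasible_request_fails_explicitly(self):
        # a 2-channel space cannot hold 5 mutually near-orthogonal maps
        with pytest.raises(TemplateInfeasibleError):
            make_templates(5, 2, 89, seed=0, max_attempts=500)
        with pytest.raises(TemplateInfeasibleError):
            make_templates(3, 2, 90, seed=0)


class TestTimeline:
    def test_rejects_gap_overlap_and_repeats(self):
        with pytest.raises(ValueError):
            Timeline([(0, 100, "T1"), (120, 200, "T2")], (0, 200))
        with pytest.raises(ValueError):
            Timeline([(0, 100, "T1"), (100, 200, "T1")], (0, 200))
        with pytest.raises(ValueError):
            Timeline([(0, 100, "T1")], (0, 200))

    def test_random_timeline_durations_in_range(self):
        tl = random_timeline((0.0, 600.0), ["T1", "T2", "T3"], seed=11)
        assert tl.segments[0][0] == 0.0 and tl.segments[-1][1] == 600.0
        for s0, s1, _ in tl.segments:
            assert 60.0 <= s1 - s0 <= 120.0 + 60.0  # tail may absorb remainder
        for (_, _, a), (_, _, b) in zip(tl.segments, tl.segments[1:]):
            assert a != b


class TestSimulateEpoch:
    def test_noiseless_columns_match_segment_templates(self, timeline):
        ts = make_templates(4, 30, 45, seed=3)
        t = time_axis(timeline.window)
        epoch = simulate_epoch(timeline, ts, np.full(t.size, 5.0), 0.0, seed=0)
        seg_idx = timeline.segment_index_per_timepoint(t)
        for i in range(t.size):
            tmpl = ts[timeline.segments[seg_idx[i]][2]]
            assert cos_theta(epoch[:, i], tmpl) == pytest.approx(1.0, abs=1e-12)

    def test_zero_envelope_leaves_pure_noise(self, timeline):
        ts = make_templates(4, 30, 45, seed=3)
        t = time_axis(timeline.window)
        epoch = simulate_epoch(timeline, ts, np.zeros(t.size), 3.0, seed=1)
        sds = epoch.std(axis=1)
        assert np.all(np.abs(sds - 3.0) < 0.6)  # ~150 samples per channel

    def test_high_snr_columns_stay_aligned(self, timeline):
        # envelope 10, noise 1: Monte-Carlo cos(column, template) averages >= 0.95
        ts = make_templates(4, 30, 45, seed=3)
        t = time_axis(timeline.window)
        epoch = simulate_epoch(timeline, ts, np.full(t.size, 10.0), 1.0, seed=2)
        seg_idx = timeline.segment_index_per_timepoint(t)
        cs = [
            cos_theta(epoch[:, i], ts[timeline.segments[seg_idx[i]][2]])
            for i in range(t.size)
        ]
        assert np.mean(cs) >= 0.95

    def test_envelope_length_mismatch_fails(self, timeline):
        ts = make_templates(4, 30, 45, seed=3)
        with pytest.raises(ValueError, match="envelope"):
            simulate_epoch(timeline, ts, np.ones(10), 1.0, seed=0)

    def test_unknown_template_id_named_in_error(self):
        ts = make_templates(2, 8, 45, seed=0)
        tl = Timeline([(0.0, 100.0, "T1"), (100.0, 200.0, "T9")], (0.0, 200.0))
        t = time_axis(tl.window)
        with pytest.raises(KeyError, match="T9"):
            simulate_epoch(tl, ts, np.ones(t.size), 0.0, seed=0)


class TestSimulateDataset:
    def test_shape_contract(self, timeline):
        man = TruthManifest(
            template_set=make_templates(4, 30, 45, seed=3),
            timeline=timeline,
            n_subjects=2,
            n_epochs_per_condition=5,
            seed=1,
        )
        sets = simulate_dataset(man)
        assert len(sets) == 4  # 2 subjects x 2 conditions
        for es in sets:
            assert es.data.shape == (5, 30, 150)

    def test_bit_identical_for_identical_manifests(self, small_manifest):
        a = simulate_dataset(small_manifest)
        b = simulate_dataset(small_manifest)
        for x, y in zip(a, b):
            assert (x.subject_id, x.condition) == (y.subject_id, y.condition)
            np.testing.assert_array_equal(x.data, y.data)

    def test_effect_angle_realized_exactly_in_noiseless_means(self, noiseless_manifest):
        sets = simulate_dataset(noiseless_manifest)
        t = noiseless_manifest.time_ms
        tl = noiseless_manifest.timeline
        mean = {
            c: np.mean([es.data.mean(axis=0) for es in sets if es.condition == c], axis=0)
            for c in ("A", "B")
        }
        for i, (s0, s1, _) in enumerate(tl.segments):
            mask = (t >= s0) & (t < s1)
            c = cos_theta(mean["A"][:, mask].mean(axis=1), mean["B"][:, mask].mean(axis=1))
            expected = 60.0 if i in noiseless_manifest.effect_spec.affected_segments else 0.0
            assert np.degrees(np.arccos(np.clip(c, -1, 1))) == pytest.approx(
                expected, abs=1e-6
            )

    def test_amplitude_ratio_scales_affected_segment(self, timeline):
        man = TruthManifest(
            template_set=make_templates(4, 30, 45, seed=3),
            timeline=timeline,
            effect_spec=EffectSpec(affected_segments=(1,), angle_deg=0.0, amplitude_ratio=2.0),
            n_subjects=1,
            n_epochs_per_condition=1,
            noise_sd=0.0,
            subject_sd=0.0,
            seed=0,
        )
        sets = simulate_dataset(man)
        t = man.time_ms
        a = next(es for es in sets if es.condition == "A").data[0]
        b = next(es for es in sets if es.condition == "B").data[0]
        s0, s1, _ = timeline.segments[1]
        inside = (t >= s0) & (t < s1)
        np.testing.assert_allclose(b[:, inside], 2.0 * a[:, inside], atol=1e-12)
        np.testing.assert_allclose(b[:, ~inside], a[:, ~inside], atol=1e-12)

    def test_manifest_validation(self, timeline):
        ts = make_templates(4, 30, 45, seed=3)
        with pytest.raises(ValueError):
            TruthManifest(ts, timeline, n_subjects=0)
        with pytest.raises(ValueError):
            TruthManifest(ts, timeline, noise_sd=-1.0)
        with pytest.raises(ValueError):
            TruthManifest(ts, timeline, effect_spec=EffectSpec((99,), 10.0))

    def test_optional_spatially_correlated_noise(self, timeline):
        cov = 4.0 * (0.5 * np.eye(8) + 0.5)  # uniform 0.5 correlation, sd 2
        man = TruthManifest(
            template_set=make_templates(4, 8, 45, seed=3),
            timeline=timeline,
            n_subjects=1,
            n_epochs_per_condition=30,
            noise_sd=0.0,
            subject_sd=0.0,
            envelope=np.zeros(150),  # pure noise: sample covariance visible
            noise_cov=cov,
            seed=6,
        )
        sets = simulate_dataset(man)
        noise = sets[0].data.reshape(-1, 8, 150).transpose(0, 2, 1).reshape(-1, 8)
        sample_cov = np.cov(noise.T)
        assert np.abs(sample_cov - cov).max() < 0.4  # 4500 samples

    def test_manifest_json_roundtrip(self, small_manifest):
        again = TruthManifest.from_json(small_manifest.to_json())
        np.testing.assert_array_equal(
            again.template_set.templates, small_manifest.template_set.templates
        )
        assert again.timeline.segments == small_manifest.timeline.segments
        sets_a = simulate_dataset(small_manifest)
        sets_b = simulate_dataset(again)
        np.testing.assert_array_equal(sets_a[0].data, sets_b[0].data)


def test_rotate_topography_controls_the_angle_exactly(rng):
    v = rng.standard_normal(30)
    for angle in (0.0, 15.0, 60.0, 90.0, 180.0):
        w = rotate_topography(v, angle, np.random.default_rng(4))
        realized = np.degrees(np.arccos(np.clip(cos_theta(v, w), -1, 1)))
        assert realized == pytest.approx(angle, abs=1e-9)
        assert np.linalg.norm(w) == pytest.approx(np.linalg.norm(v), rel=1e-12)


def test_default_envelope_positive_over_both_windows():
    for window in ((0.0, 600.0), (600.0, 2000.0)):
        env = default_envelope(time_axis(window))
        assert np.all(env > 0)
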