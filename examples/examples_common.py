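"""Shared demo study for the example scripts: 8 subjects, 2 conditions,
a 60-degree topographic effect confined to segment 3."""

from erpstates import EffectSpec, Timeline, TruthManifest, make_templates


def demo_manifest() -> TruthManifest:
    return TruthManifest(
        template_set=make_templates(4, 30, 45, seed=3),
        timeline=Timeline.from_durations(
            [80, 100, 120, 100, 100, 100], ["T1", "T2", "T3", "T4", "T1", "T3"]
        ),
        effect_spec=EffectSpec(affected_segments=(2,), angle_deg=60.0),
        n_subjects=8,
        n_epochs_per_condition=10,
        noise_sd=10.0,
        subject_sd=0.1,
        seed=7,
    )
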