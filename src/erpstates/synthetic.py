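"""Synthetic epoched EEG with known microstate structure.

The generator emulates a task ERP study: a fixed sequence of quasi-stable
scalp topographies (templates) spans the post-stimulus window, each epoch is
the template sequence scaled by a GFP envelope plus channel noise, and a
second condition may perturb the template of selected segments by a
controlled angle. Because the templates, the timeline and the injected
effect are all known, every downstream stage (clustering, segmentation,
TANOVA, post-hoc tests) can be validated against ground truth.

Defaults mirror a 107-participant picture-viewing design: 30 channels
sampled at 250 Hz over a 0-600 ms window, 16 retained epochs per
subject x condition cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .erp import DEFAULT_MONTAGE, EpochSet, compute_gfp

#: Sampling step of the 250 Hz analysis grid, in ms.
SAMPLE_STEP_MS = 4.0

#: Primary analysis window (half-open, ms post-stimulus): 150 samples.
DEFAULT_WINDOW_MS = (0.0, 600.0)

#: Exploratory late window (half-open, ms): 350 samples.
LATE_WINDOW_MS = (600.0, 2000.0)


class TemplateInfeasibleError(ValueError):
    """Requested more mutually separated templates than the space admits."""


def time_axis(window_ms: tuple[float, float], step_ms: float = SAMPLE_STEP_MS) -> np.ndarray:
    """Sample times of a half-open window [t0, t1) on the regular grid."""
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    n = int(round((t1 - t0) / step_ms))
    return t0 + step_ms * np.arange(n)


@dataclass
class TemplateSet:
    """Unit-GFP channel-space topographies with a minimum pairwise angle."""

    templates: np.ndarray  # (n_templates, n_channels)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2:
            raise ValueError("templates must be (n_templates, n_channels)")
        if len(self.labels) != self.templates.shape[0]:
            raise ValueError("one label per template required")

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown template id {label!r}") from None
        return self.templates[i]


@dataclass
class Timeline:
    """Contiguous, non-overlapping template segments covering a window.

    Each segment is (start_ms, end_ms, template_id), half-open in time.
    Adjacent segments must use distinct templates, otherwise they would be
    one longer segment.
    """

    segments: list[tuple[float, float, str]]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("timeline needs at least one segment")
        t0, t1 = self.window
        if self.segments[0][0] != t0 or self.segments[-1][1] != t1:
            raise ValueError("segments must cover the window exactly")
        for (a0, a1, ida), (b0, b1, idb) in zip(self.segments, self.segments[1:]):
            if a1 != b0:
                raise ValueError("segments must be contiguous and non-overlapping")
            if ida == idb:
                raise ValueError("adjacent segments must use distinct templates")
        for s0, s1, _ in self.segments:
            if s1 <= s0:
                raise ValueError("segment end must exceed segment start")

    @classmethod
    def from_durations(
        cls,
        durations_ms: Sequence[float],
        template_ids: Sequence[str],
        t0_ms: float = 0.0,
    ) -> "Timeline":
        if len(durations_ms) != len(template_ids):
            raise ValueError("need one template id per duration")
        segs, t = [], t0_ms
        for d, tid in zip(durations_ms, template_ids):
            segs.append((t, t + d, tid))
            t += d
        return cls(segments=segs, window=(t0_ms, t))

    def segment_index_per_timepoint(self, time_ms: np.ndarray) -> np.ndarray:
        """Map each sample to the index of the segment containing it."""
        idx = np.full(len(time_ms), -1, dtype=int)
        for i, (s0, s1, _) in enumerate(self.segments):
            idx[(time_ms >= s0) & (time_ms < s1)] = i
        if np.any(idx < 0):
            raise ValueError("time axis extends beyond the timeline window")
        return idx


@dataclass
class EffectSpec:
    """Topographic perturbation of condition B relative to condition A.

    In each affected segment the template is rotated by angle_deg within the
    plane it spans with a seeded orthogonal direction, so the cosine between
    the A and B topographies equals cos(angle_deg) exactly. amplitude_ratio
    additionally scales the GFP envelope in those segments.
    """

    affected_segments: tuple[int, ...] = ()
    angle_deg: float = 0.0
    amplitude_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError("angle_deg must lie in [0, 180]")
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be positive")


def default_envelope(time_ms: np.ndarray) -> np.ndarray:
    """A plausible ERP GFP waveform (microvolts): early peaks, late sustained.

    Sum of Gaussian components over a 2 uV floor; peak ~10 uV near 180 ms.
    """
    t = np.asarray(time_ms, dtype=float)
    bumps = (
        (100.0, 30.0, 6.0),
        (180.0, 40.0, 8.0),
        (300.0, 60.0, 7.0),
        (450.0, 90.0, 5.0),
        (900.0, 300.0, 4.0),
    )
    env = 2.0 * np.ones_like(t)
    for mu, sd, amp in bumps:
        env = env + amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return env


@dataclass
class TruthManifest:
    """Everything needed to regenerate a dataset bit-for-bit.

    noise_sd is the per-channel, per-timepoint Gaussian noise SD in uV;
    subject_sd scales per-subject topographic jitter of the templates.
    """

    template_set: TemplateSet
    timeline: Timeline
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    n_subjects: int = 107
    n_epochs_per_condition: int = 16
    noise_sd: float = 15.0
    subject_sd: float = 0.2
    envelope: np.ndarray | None = None
    condition_labels: tuple[str, str] = ("A", "B")
    montage: tuple[str, ...] | None = None
    noise_cov: np.ndarray | None = None  # optional channel covariance (uV^2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_epochs_per_condition < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be >= 0")
        n_seg = len(self.timeline.segments)
        for i in self.effect_spec.affected_segments:
            if not 0 <= i < n_seg:
                raise ValueError(f"affected segment index {i} out of range")
        for _, _, tid in self.timeline.segments:
            if tid not in self.template_set.labels:
                raise ValueError(f"timeline references unknown template id {tid!r}")
        if self.montage is None:
            n_ch = self.template_set.n_channels
            if n_ch == len(DEFAULT_MONTAGE):
                self.montage = DEFAULT_MONTAGE
            else:
                self.montage = tuple(f"ch{i + 1}" for i in range(n_ch))
        t = self.time_ms
        if self.envelope is None:
            self.envelope = default_envelope(t)
        else:
            self.envelope = np.asarray(self.envelope, dtype=float)
            if self.envelope.shape != t.shape:
                raise ValueError("envelope length must match the time axis")
        if self.noise_cov is not None:
            self.noise_cov = np.asarray(self.noise_cov, dtype=float)
            n_ch = self.template_set.n_channels
            if self.noise_cov.shape != (n_ch, n_ch):
                raise ValueError("noise_cov must be (n_channels, n_channels)")
            if not np.allclose(self.noise_cov, self.noise_cov.T):
                raise ValueError("noise_cov must be symmetric")

    @property
    def time_ms(self) -> np.ndarray:
        return time_axis(self.timeline.window)

    def to_json(self) -> str:
        d = {
            "templates": self.template_set.templates.tolist(),
            "template_labels": list(self.template_set.labels),
            "segments": [list(s) for s in self.timeline.segments],
            "window": list(self.timeline.window),
            "effect": asdict(self.effect_spec),
            "n_subjects": self.n_subjects,
            "n_epochs_per_condition": self.n_epochs_per_condition,
            "noise_sd": self.noise_sd,
            "subject_sd": self.subject_sd,
            "envelope": np.asarray(self.envelope).tolist(),
            "condition_labels": list(self.condition_labels),
            "montage": list(self.montage),
            "noise_cov": None if self.noise_cov is None else self.noise_cov.tolist(),
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        eff = d["effect"]
        return cls(
            template_set=TemplateSet(
                np.asarray(d["templates"], dtype=float),
                tuple(d["template_labels"]),
            ),
            timeline=Timeline(
                [tuple(s) for s in d["segments"]], tuple(d["window"])
            ),
            effect_spec=EffectSpec(
                tuple(eff["affected_segments"]), eff["angle_deg"], eff["amplitude_ratio"]
            ),
            n_subjects=d["n_subjects"],
            n_epochs_per_condition=d["n_epochs_per_condition"],
            noise_sd=d["noise_sd"],
            subject_sd=d["subject_sd"],
            envelope=np.asarray(d["envelope"], dtype=float),
            condition_labels=tuple(d["condition_labels"]),
            montage=tuple(d["montage"]),
            noise_cov=(
                None
                if d.get("noise_cov") is None
                else np.asarray(d["noise_cov"], dtype=float)
            ),
            seed=d["seed"],
        )


def _unit_gfp(v: np.ndarray) -> np.ndarray:
    g = compute_gfp(v)
    if g <= 1e-12:
        raise ValueError("cannot GFP-normalize a flat topography")
    return v / g


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def make_templates(
    n_templates: int,
    n_channels: int,
    min_angle_deg: float,
    seed: int,
    max_attempts: int = 2000,
) -> TemplateSet:
    """Draw unit-GFP topographies with pairwise angular separation.

    Candidates are Gaussian draws, GFP-normalized, accepted only if the
    absolute cosine with every accepted template stays at or below
    cos(min_angle_deg). At exactly 90 degrees (where rejection sampling has
    measure zero) candidates are Gram-Schmidt-orthogonalized instead.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if not 0 < min_angle_deg <= 90:
        raise ValueError("min_angle_deg must lie in (0, 90]")
    if min_angle_deg == 90 and n_templates > n_channels:
        raise TemplateInfeasibleError(
            f"cannot place {n_templates} mutually orthogonal templates "
            f"in {n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    cos_max = np.cos(np.deg2rad(min_angle_deg))
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_templates:
        if attempts >= max_attempts:
            raise TemplateInfeasibleError(
                f"could not place {n_templates} templates at >= "
                f"{min_angle_deg} deg separation in {n_channels} channels "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        cand = rng.standard_normal(n_channels)
        if min_angle_deg == 90:
            for t in accepted:
                cand = cand - (cand @ t) / (t @ t) * t
            if np.linalg.norm(cand) < 1e-9:
                continue
        try:
            cand = _unit_gfp(cand)
        except ValueError:
            continue
        if all(abs(_cos(cand, t)) <= cos_max + 1e-12 for t in accepted):
            accepted.append(cand)
    return TemplateSet(
        templates=np.array(accepted),
        labels=tuple(f"T{i + 1}" for i in range(n_templates)),
    )


def rotate_topography(
    topo: np.ndarray,
    angle_deg: float,
    direction: np.ndarray | np.random.Generator,
) -> np.ndarray:
    """Rotate a topography by angle_deg toward an orthogonalized direction.

    ``direction`` is either a raw vector (its component along the
    topography is projected out) or a Generator from which one is drawn.
    The rotation happens in the plane spanned by the topography and the
    resulting orthogonal unit vector, so cos(angle between input and
    output) == cos(angle_deg) exactly and the Euclidean norm is preserved.
    """
    topo = np.asarray(topo, dtype=float)
    if angle_deg == 0.0:
        return topo.copy()
    if isinstance(direction, np.random.Generator):
        z = direction.standard_normal(topo.size)
    else:
        z = np.asarray(direction, dtype=float)
    u = z - (z @ topo) / (topo @ topo) * topo
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise ValueError("degenerate orthogonal direction")
    u = u / nu
    a = np.deg2rad(angle_deg)
    return np.cos(a) * topo + np.sin(a) * np.linalg.norm(topo) * u


def simulate_epoch(
    timeline: Timeline,
    templates: TemplateSet,
    envelope: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Render one epoch: envelope-scaled segment templates plus channel noise.

    Returns a (channels, timepoints) matrix in uV. At each timepoint t in
    segment s the expected topography is envelope[t] * template(s); noise is
    iid Gaussian per channel and timepoint with SD noise_sd.
    """
    t_ms = time_axis(timeline.window)
    envelope = np.asarray(envelope, dtype=float)
    if envelope.shape != t_ms.shape:
        raise ValueError(
            f"envelope has {envelope.size} samples but the window implies {t_ms.size}"
        )
    seg_idx = timeline.segment_index_per_timepoint(t_ms)
    seg_topos = np.array([templates[tid] for _, _, tid in timeline.segments])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = seg_topos[seg_idx].T * envelope[np.newaxis, :]
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return clean


def _subject_segment_topographies(
    manifest: TruthManifest,
    rng: np.random.Generator,
    effect_directions: dict[int, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment topographies for conditions A and B of one subject.

    Draws the subject's template jitter, then rotates the jittered template
    of each affected segment for condition B. The rotation direction is a
    dataset-level draw (shared across subjects, re-orthogonalized against
    each subject's jittered template) so the angle between the noiseless
    condition-mean topographies equals angle_deg exactly. Returns
    (topos_A, topos_B, envelope_scale_B).
    """
    ts, tl, eff = manifest.template_set, manifest.timeline, manifest.effect_spec
    jittered = {}
    for label, base in zip(ts.labels, ts.templates):
        if manifest.subject_sd > 0:
            jittered[label] = _unit_gfp(
                base + manifest.subject_sd * rng.standard_normal(base.size)
            )
        else:
            jittered[label] = base.copy()
    topos_a = np.array([jittered[tid] for _, _, tid in tl.segments])
    topos_b = topos_a.copy()
    scale_b = np.ones(len(tl.segments))
    for i in eff.affected_segments:
        topos_b[i] = rotate_topography(
            topos_a[i], eff.angle_deg, effect_directions[i]
        )
        scale_b[i] = eff.amplitude_ratio
    return topos_a, topos_b, scale_b


def simulate_dataset(manifest: TruthManifest) -> list[EpochSet]:
    """Generate one EpochSet per subject x condition, ground truth known.

    Condition B differs from A only in the affected segments, where the
    subject's segment topography is rotated by the specified angle (and its
    envelope optionally rescaled). Bit-identical output for identical
    manifests, including the seed.
    """
    t_ms = manifest.time_ms
    seg_idx = manifest.timeline.segment_index_per_timepoint(t_ms)
    env = np.asarray(manifest.envelope, dtype=float)
    ss = np.random.SeedSequence(manifest.seed)
    children = ss.spawn(manifest.n_subjects + 1)
    # dataset-level rotation directions, one per affected segment
    effect_rng = np.random.default_rng(children[-1])
    effect_directions = {
        i: effect_rng.standard_normal(manifest.template_set.n_channels)
        for i in manifest.effect_spec.affected_segments
    }
    out: list[EpochSet] = []
    for s, child in enumerate(children[: manifest.n_subjects]):
        rng = np.random.default_rng(child)
        topos_a, topos_b, scale_b = _subject_segment_topographies(
            manifest, rng, effect_directions
        )
        subject_id = f"S{s + 1:03d}"
        for cond, topos, scale in (
            (manifest.condition_labels[0], topos_a, np.ones(len(scale_b))),
            (manifest.condition_labels[1], topos_b, scale_b),
        ):
            clean = topos[seg_idx].T * (env * scale[seg_idx])[np.newaxis, :]
            shape = (manifest.n_epochs_per_condition,) + clean.shape
            if manifest.noise_cov is not None:
                # spatially correlated noise: Cholesky-color iid draws
                chol = np.linalg.cholesky(manifest.noise_cov)
                z = rng.standard_normal(
                    (manifest.n_epochs_per_condition, shape[2], shape[1])
                )
                noise = np.einsum("cd,etd->ect", chol, z)
            elif manifest.noise_sd > 0:
                noise = rng.normal(0.0, manifest.noise_sd, size=shape)
            else:
                noise = np.zeros(shape)
            out.append(
                EpochSet(
                    subject_id=subject_id,
                    condition=cond,
                    data=clean[np.newaxis] + noise,
                    time_ms=t_ms,
                    montage=manifest.montage,
                    sampling_rate_hz=1000.0 / SAMPLE_STEP_MS,
                )
            )
    return out


def random_timeline(
    window_ms: tuple[float, float],
    template_ids: Sequence[str],
    seed: int,
    min_dur_ms: float = 60.0,
    max_dur_ms: float = 120.0,
    step_ms: float = SAMPLE_STEP_MS,
) -> Timeline:
    """Random contiguous timeline with durations in [min_dur, max_dur].

    Durations are drawn uniformly on the sampling grid (default keeps them
    inside the conventional 60-120 ms microstate range); template ids cycle
    with random starting order so adjacent segments always differ. The final
    segment absorbs the remainder of the window.
    """
    if len(template_ids) < 2:
        raise ValueError("need >= 2 template ids for adjacent segments to differ")
    rng = np.random.default_rng(seed)
    t0, t1 = window_ms
    choices = np.arange(
        round(min_dur_ms / step_ms), round(max_dur_ms / step_ms) + 1
    ) * step_ms
    segs: list[tuple[float, float, str]] = []
    t = t0
    prev = None
    while t < t1:
        d = float(rng.choice(choices))
        end = min(t + d, t1)
        if t1 - end < min_dur_ms:  # absorb a too-short tail
            end = t1
        options = [tid for tid in template_ids if tid != prev]
        tid = str(options[rng.integers(len(options))])
        segs.append((t, end, tid))
        prev = tid
        t = end
    return Timeline(segments=segs, window=(t0, t1))
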