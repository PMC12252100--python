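"""Seeded synthetic single-lead ECG beats for the five AAMI classes.

Beat morphology is the standard synthetic-ECG idealization: a sum of five
Gaussian deflections (P, Q, R, S, T) on a flat baseline, contaminated with
the three noise sources that dominate ambulatory recordings — baseline
wander (slow sinusoid), power-line interference (50/60 Hz sinusoid) and
additive white noise.  Class identities are encoded as parameter offsets
from the normal template, scaled by a single `separability` knob:

* S — earlier, flattened P wave and a shortened preceding RR interval;
* V — widened, lower R deflection, absent P, inverted T (wide-QRS ectopy);
* F — the midpoint of the N and V templates (fusion morphology);
* Q — flat P plus a narrow pacing-spike artifact ahead of the QRS.

At separability 0 all five templates coincide (downstream classifiers must
sit at chance); large values saturate against physiological clamps but stay
monotonically more separable.  This is artifact-grade realism: good enough
to exercise every pipeline stage, not a dynamical heart model.

Default per-class proportions mirror the imbalanced training distribution
this package targets (54,171 / 1,807 / 4,348 / 483 / 4,858 for N/S/V/F/Q);
`table1_counts(scale)` produces proportionally shrunk versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import CLASSES, BeatDataset

#: imbalanced training-distribution class counts (N, S, V, F, Q)
TRAIN_COUNTS: dict[str, int] = {"N": 54171, "S": 1807, "V": 4348, "F": 483, "Q": 4858}

#: representative MIT-BIH annotation symbol emitted per AAMI class
CLASS_TO_MITBIH_SYMBOL = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "/"}

WAVE_NAMES = ("P", "Q", "R", "S", "T")


def table1_counts(scale: float = 1.0, minimum: int = 2) -> dict[str, int]:
    """The default class counts scaled by `scale` (each class >= minimum)."""
    return {c: max(int(round(n * scale)), minimum) for c, n in TRAIN_COUNTS.items()}


@dataclass
class BeatTemplate:
    """Five (amplitude mV, centre sample, width samples) Gaussian deflections
    plus the RR-interval statistics of the class."""

    aami_class: str
    wave_params: tuple[tuple[float, float, float], ...]  # P, Q, R, S, T
    rr_mean: float = 360.0          # samples
    rr_jitter_sd: float = 10.0      # samples

    def __post_init__(self):
        if self.aami_class not in CLASSES:
            raise ValueError(f"aami_class must be one of {CLASSES}, got {self.aami_class!r}")
        if len(self.wave_params) != 5:
            raise ValueError("wave_params must hold exactly five (amp, centre, width) triples")
        centres = [w[1] for w in self.wave_params]
        if not all(a < b for a, b in zip(centres, centres[1:])):
            raise ValueError(f"wave centres must be strictly increasing P<Q<R<S<T, got {centres}")
        if any(w[2] <= 0 for w in self.wave_params):
            raise ValueError("wave widths must be positive")
        if self.wave_params[2][0] <= 0:
            raise ValueError("R amplitude must be positive")


@dataclass
class NoiseSpec:
    baseline_amp: float = 0.1       # mV
    baseline_freq: float = 0.3      # Hz
    powerline_amp: float = 0.03     # mV
    powerline_freq: float = 50.0    # Hz, mains frequency
    white_sd: float = 0.05          # mV

    def __post_init__(self):
        if min(self.baseline_amp, self.powerline_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.powerline_freq not in (50, 60):
            raise ValueError(f"powerline_freq must be 50 or 60 Hz, got {self.powerline_freq}")

    @staticmethod
    def silent() -> "NoiseSpec":
        return NoiseSpec(0.0, 0.3, 0.0, 50, 0.0)


@dataclass
class SynthDatasetSpec:
    counts_per_class: dict[str, int] = field(default_factory=lambda: dict(TRAIN_COUNTS))
    fs: float = 360.0
    segment_len: int = 300
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.counts_per_class.values()):
            raise ValueError("class counts must be >= 0")
        unknown = set(self.counts_per_class) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in counts_per_class: {sorted(unknown)}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")


# --------------------------------------------------------------------------
# templates
# --------------------------------------------------------------------------

# normal-beat deflections with the R peak at the window centre (sample 150
# of a 300-sample window at 360 Hz)
_N_WAVES = {
    "P": (0.15, 100.0, 10.0),
    "Q": (-0.12, 140.0, 4.0),
    "R": (1.2, 150.0, 5.0),
    "S": (-0.25, 160.0, 4.0),
    "T": (0.35, 215.0, 18.0),
}

# per-class parameter offsets, applied as N + separability * delta
_DELTAS = {
    "S": {"P": (-0.10, -15.0, 0.0), "T": (-0.05, 0.0, 0.0)},
    "V": {"P": (-0.15, 0.0, 0.0), "R": (-0.4, 0.0, 8.0),
          "S": (0.15, 0.0, 2.0), "T": (-0.55, 0.0, 4.0)},
    "Q": {"P": (-0.15, 0.0, 0.0), "Q": (0.92, 0.0, -2.2)},
}
_DELTAS["F"] = {w: tuple(0.5 * d for d in ds) for w, ds in _DELTAS["V"].items()}

_RR_DELTA = {"S": -60.0}  # shortened preceding RR for supraventricular beats


def default_template(aami_class: str, separability: float = 1.0,
                     segment_len: int = 300) -> BeatTemplate:
    """Class template: normal-beat parameters plus separability-scaled offsets,
    clamped to stay physiologically ordered and inside the window."""
    if aami_class not in CLASSES:
        raise ValueError(f"unknown AAMI class {aami_class!r}")
    scale = segment_len / 300.0
    waves = []
    for name in WAVE_NAMES:
        amp, centre, width = _N_WAVES[name]
        d_amp, d_c, d_w = _DELTAS.get(aami_class, {}).get(name, (0.0, 0.0, 0.0))
        amp = amp + separability * d_amp
        centre = (centre + separability * d_c) * scale
        width = max((width + separability * d_w) * scale, 1.0)
        if name == "P":
            amp = max(amp, 0.0)
            centre = max(centre, 5.0 * scale)
        if name == "R":
            amp = max(amp, 0.2)
        if name == "T":
            amp = float(np.clip(amp, -0.6, 0.6))
        waves.append((amp, centre, width))
    rr = 360.0 * scale + separability * _RR_DELTA.get(aami_class, 0.0) * scale
    rr = max(rr, 0.6 * segment_len)
    return BeatTemplate(aami_class, tuple(waves), rr_mean=rr, rr_jitter_sd=10.0 * scale)


def default_templates(separability: float = 1.0, segment_len: int = 300) -> list[BeatTemplate]:
    return [default_template(c, separability, segment_len) for c in CLASSES]


# --------------------------------------------------------------------------
# beat / record / dataset generation
# --------------------------------------------------------------------------


def clean_beat(template: BeatTemplate, segment_len: int = 300) -> np.ndarray:
    """Noise-free beat: the sum of the five Gaussian deflections (mV)."""
    t = np.arange(segment_len, dtype=np.float64)
    out = np.zeros(segment_len)
    for name, (amp, centre, width) in zip(WAVE_NAMES, template.wave_params):
        if not (0 <= centre < segment_len):
            raise ValueError(
                f"wave {name} centre {centre} lies outside the window [0, {segment_len})"
            )
        out += amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
    return out


def make_beat(template: BeatTemplate, noise: NoiseSpec, seed: int,
              segment_len: int = 300, fs: float = 360.0) -> np.ndarray:
    """One raw beat (mV): Gaussian deflections + baseline-wander and
    power-line sinusoids (random phase) + white noise.  Deterministic in
    (template, noise, seed)."""
    rng = np.random.default_rng(seed)
    out = clean_beat(template, segment_len)
    t = np.arange(segment_len, dtype=np.float64) / fs
    phase_b, phase_p = rng.uniform(0, 2 * np.pi, 2)
    out = out + noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t + phase_b)
    out = out + noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_freq * t + phase_p)
    out = out + rng.normal(0.0, noise.white_sd, segment_len) if noise.white_sd > 0 else out
    return out


def make_record(spec: SynthDatasetSpec, templates: list[BeatTemplate],
                noise: NoiseSpec | None = None
                ) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Concatenate beats into an annotated record.

    Beats cycle through the class sequence implied by `spec.counts_per_class`
    (shuffled with the spec seed); RR intervals are jittered with a normal
    truncated at +-3 s.d.  Every annotation's sample index coincides with the
    R-deflection centre of the emitted beat; symbols use the MIT-BIH beat
    code inventory.
    """
    if not templates:
        raise ValueError("at least one beat template is required")
    by_class = {t.aami_class: t for t in templates}
    for tmpl in templates:
        if tmpl.rr_mean <= spec.segment_len / 2:
            raise ValueError(
                f"rr_mean {tmpl.rr_mean} of class {tmpl.aami_class} must exceed "
                f"segment_len/2 = {spec.segment_len / 2}"
            )
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(spec.seed)
    order = [c for c in CLASSES for _ in range(spec.counts_per_class.get(c, 0))
             if c in by_class]
    rng.shuffle(order)
    if not order:
        raise ValueError("counts_per_class requests zero beats for the given templates")

    half = spec.segment_len // 2
    r_centre = None
    r_indices = []
    for cls in order:
        tmpl = by_class[cls]
        if r_centre is None:
            r_centre = int(round(tmpl.rr_mean / 2))
        else:
            jit = rng.normal(0.0, tmpl.rr_jitter_sd) if tmpl.rr_jitter_sd > 0 else 0.0
            jit = float(np.clip(jit, -3 * tmpl.rr_jitter_sd, 3 * tmpl.rr_jitter_sd))
            r_centre = r_centre + max(int(round(tmpl.rr_mean + jit)), 1)
        r_indices.append(r_centre)

    length = r_indices[-1] + int(round(by_class[order[-1]].rr_mean / 2)) + 1
    signal = np.zeros(length)
    annotations = []
    for cls, r in zip(order, r_indices):
        beat_seed = int(rng.integers(0, 2**31 - 1))
        beat = make_beat(by_class[cls], noise, beat_seed, spec.segment_len, spec.fs)
        lo = r - half
        a, b = max(lo, 0), min(lo + spec.segment_len, length)
        signal[a:b] += beat[a - lo : b - lo]
        annotations.append((r, CLASS_TO_MITBIH_SYMBOL[cls]))
    return signal, annotations


def make_dataset(spec: SynthDatasetSpec, noise: NoiseSpec | None = None,
                 normalize: bool = True) -> BeatDataset:
    """Seeded dataset of isolated beat segments with exact per-class counts.

    With `normalize` each segment is min-max rescaled to [0, 1] (the form the
    network consumes); otherwise raw mV values are kept.
    """
    total = sum(spec.counts_per_class.values())
    if total == 0:
        raise ValueError("counts_per_class requests zero beats in total")
    noise = NoiseSpec() if noise is None else noise
    root = np.random.SeedSequence(spec.seed)
    feats, labels = [], []
    for cls, child in zip(CLASSES, root.spawn(len(CLASSES))):
        count = spec.counts_per_class.get(cls, 0)
        if count == 0:
            continue
        tmpl = default_template(cls, spec.separability, spec.segment_len)
        seeds = child.generate_state(count) % (2**31 - 1)
        for s in seeds:
            beat = make_beat(tmpl, noise, int(s), spec.segment_len, spec.fs)
            if normalize:
                span = beat.max() - beat.min()
                beat = (beat - beat.min()) / span if span > 0 else np.zeros_like(beat)
            feats.append(beat)
            labels.append(cls)
    X = np.stack(feats)
    y = np.array(labels)
    # deterministic shuffle so classes are interleaved
    perm = np.random.default_rng(spec.seed).permutation(len(y))
    return BeatDataset(X[perm], y[perm],
                       record_id=np.full(len(y), "synthetic", dtype="<U32"))
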