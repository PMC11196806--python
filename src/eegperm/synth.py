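"""Synthetic resting-state EEG with controllable band power and coherence.

Each channel is a sum over the six analysis bands of band-limited Gaussian
oscillations.  A band's component on channel *c* mixes one band-wide common
source ``s_b`` with a channel-private source ``p_bc``::

    x_bc = g_b * s_b + (1 - g_b) * p_bc

where ``g_b`` is the band's ``shared_source_gain``: 0 gives independent
channels, 1 gives perfectly coherent ones.  Sources are white noise passed
through the same Kaiser band-pass design used for preprocessing, and each
mixed component is analytically rescaled (by the kernel energy and the
mixture variance ``g² + (1−g)²``) so the expected relative power per band
matches ``band_weights``.  A small white-noise floor is added on top.

Study-level generation draws two groups of subjects; the treated group's
post-intervention recordings apply a multiplicative band-power effect
(default: delta and theta down, beta2 up) and a coherence-gain increase,
mirroring the direction of change the pipeline is designed to detect.
Subject-to-subject variation is log-normal multiplicative jitter on the
band weights, shared between a subject's pre and post sessions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .io import Recording, write_recording
from .montage import CHANNELS_62, default_montage
from .preprocess import FilterSpec, design_bandpass
from .spectral import DEFAULT_BANDS, Band

__all__ = [
    "SynthConfig",
    "Artifact",
    "StudyDataset",
    "generate_recording",
    "inject_artifacts",
    "generate_study",
    "null_power_maps",
]

#: Typical resting relative-power profile (delta-dominant, clear alpha).
DEFAULT_BAND_WEIGHTS: dict[str, float] = {
    "delta": 0.25,
    "theta": 0.20,
    "alpha1": 0.15,
    "alpha2": 0.10,
    "beta1": 0.15,
    "beta2": 0.10,
}

#: Post-intervention multiplicative power change in the treated group.
DEFAULT_EFFECT: dict[str, float] = {"delta": 0.7, "theta": 0.7, "beta2": 1.3}


@dataclass
class SynthConfig:
    """Generator settings; defaults reproduce the study's recording geometry
    (62 channels, 2048 Hz, 2 minutes per session)."""

    n_channels: int = 62
    fs: float = 2048.0
    duration: float = 120.0
    band_weights: dict = field(default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS))
    shared_source_gain: float | dict = 0.3
    effect: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT))
    coherence_effect: float = 0.3  # added to shared gain post-intervention
    noise_floor: float = 1.5  # µV RMS of the broadband floor
    rms: float = 12.0  # µV RMS of the oscillatory part
    subject_sigma: float = 0.1  # log-normal jitter of band weights
    bands: tuple[Band, ...] = DEFAULT_BANDS
    transition_bw: float = 1.0
    labels: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        names = {b.name for b in self.bands}
        for k, v in self.band_weights.items():
            if k not in names:
                raise ValueError(f"band_weights names unknown band {k!r}")
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"band_weights[{k!r}] must be nonnegative")
        for g in self._gains().values():
            if not 0 <= g <= 1:
                raise ValueError("shared_source_gain must lie in [0, 1]")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        lo = sorted(self.bands, key=lambda b: b.low)
        for a, b in zip(lo, lo[1:]):
            if b.low < a.high:
                raise ValueError(f"bands {a.name}/{b.name} overlap")
        if self.labels is not None and len(self.labels) != self.n_channels:
            raise ValueError("labels length must equal n_channels")

    def _gains(self) -> dict[str, float]:
        if isinstance(self.shared_source_gain, dict):
            return {b.name: float(self.shared_source_gain.get(b.name, 0.0))
                    for b in self.bands}
        return {b.name: float(self.shared_source_gain) for b in self.bands}

    def channel_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return tuple(self.labels)
        if self.n_channels == len(CHANNELS_62):
            return CHANNELS_62
        return tuple(f"ch{i:02d}" for i in range(self.n_channels))


def _band_kernel(band: Band, fs: float, transition_bw: float) -> np.ndarray:
    spec = FilterSpec(
        low_cut=band.low, high_cut=band.high, transition_bw=transition_bw
    )
    return design_bandpass(fs, spec)


def generate_recording(
    config: SynthConfig,
    seed: int | np.random.SeedSequence | None = None,
    *,
    weight_scale: dict | None = None,
    gain_offset: float = 0.0,
) -> Recording:
    """Draw one recording from the generator.

    ``weight_scale`` multiplies selected bands' power targets (values may be
    scalars or per-channel arrays) and ``gain_offset`` shifts every band's
    shared-source gain — both are the hooks through which study-level
    effects and subject jitter enter.  Identical config and seed give
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(config.duration * config.fs))
    n_ch = config.n_channels
    gains = config._gains()

    weights = {}
    for b in config.bands:
        w = np.asarray(config.band_weights.get(b.name, 0.0), dtype=float)
        if weight_scale and b.name in weight_scale:
            w = w * np.asarray(weight_scale[b.name], dtype=float)
        weights[b.name] = np.broadcast_to(w, (n_ch,)).copy()

    total = np.sum([w for w in weights.values()], axis=0)
    if np.any(total <= 0):
        raise ValueError("at least one band weight must be positive on every channel")

    data = np.zeros((n_ch, n))
    for b in config.bands:
        w = weights[b.name] / total  # normalized relative-power target
        if not np.any(w > 0):
            continue
        g = min(1.0, max(0.0, gains[b.name] + gain_offset))
        kernel = _band_kernel(b, config.fs, config.transition_bw)
        noise = rng.standard_normal((n_ch + 1, n))
        filtered = _sig.fftconvolve(noise, kernel[None, :], mode="same", axes=-1)
        # Analytic calibration: unit-variance white noise through the kernel
        # has variance ||h||²; the g/(1-g) mixture has variance g²+(1-g)².
        filtered /= np.linalg.norm(kernel)
        common, private = filtered[0], filtered[1:]
        # The common source projects with a channel-dependent polarity: a
        # spatially uniform projection would be cancelled exactly by the
        # average reference downstream, whereas real sources reach the
        # electrodes with varying topographies.  Unit-magnitude signs keep
        # the pairwise coherence and the power calibration unchanged.
        proj = rng.choice([-1.0, 1.0], size=n_ch)
        mix = g * proj[:, None] * common[None, :] + (1.0 - g) * private
        mix /= np.sqrt(g * g + (1.0 - g) ** 2)
        data += np.sqrt(w)[:, None] * mix * config.rms
    if config.noise_floor > 0:
        data += config.noise_floor * rng.standard_normal((n_ch, n))

    labels = config.channel_labels()
    coords = None
    if labels == CHANNELS_62:
        coords = default_montage().coords
    return Recording(data=data, fs=config.fs, labels=labels, coords=coords)


# ---------------------------------------------------------------------------
# artifacts


@dataclass(frozen=True)
class Artifact:
    """One injected artifact: a spike, a sustained step, or an oscillatory
    burst whose peak-to-peak amplitude is ``amplitude``."""

    kind: str  # spike | step | burst
    channel: str
    onset: float  # seconds
    amplitude: float  # µV (peak for spike/step, peak-to-peak for burst)
    duration: float = 0.0  # seconds; 0 = single sample (spike) / to end (step)
    frequency: float = 10.0  # Hz, bursts only

    def validate(self, rec: Recording) -> None:
        if self.kind not in ("spike", "step", "burst"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("artifact amplitude must be nonnegative")
        if not 0 <= self.onset < rec.duration:
            raise ValueError(
                f"artifact onset {self.onset} s outside recording "
                f"(0–{rec.duration} s)"
            )
        if self.channel not in rec.labels:
            raise ValueError(f"unknown channel {self.channel!r}")


def inject_artifacts(
    rec: Recording, artifacts: list[Artifact]
) -> tuple[Recording, list[dict]]:
    """Add the requested artifacts; untouched samples are unchanged.

    Returns the modified copy and a ground-truth log with sample positions.
    """
    data = rec.data.copy()
    log: list[dict] = []
    for art in artifacts:
        art.validate(rec)
        ch = rec.labels.index(art.channel)
        i0 = int(round(art.onset * rec.fs))
        if art.kind == "spike":
            n_s = max(1, int(round(art.duration * rec.fs)))
            i1 = min(i0 + n_s, rec.n_samples)
            data[ch, i0:i1] += art.amplitude
        elif art.kind == "step":
            i1 = (
                rec.n_samples
                if art.duration == 0
                else min(i0 + int(round(art.duration * rec.fs)), rec.n_samples)
            )
            data[ch, i0:i1] += art.amplitude
        else:  # burst
            n_s = max(1, int(round(art.duration * rec.fs)))
            i1 = min(i0 + n_s, rec.n_samples)
            t = np.arange(i1 - i0) / rec.fs
            data[ch, i0:i1] += (art.amplitude / 2.0) * np.sin(
                2 * np.pi * art.frequency * t
            )
        log.append(
            {
                "kind": art.kind,
                "channel": art.channel,
                "start_sample": i0,
                "end_sample": i1,
                "amplitude": art.amplitude,
            }
        )
    return replace(rec, data=data), log


# ---------------------------------------------------------------------------
# study-level generation


@dataclass
class StudyDataset:
    """Two groups of subjects, each with a pre and a post recording."""

    groups: dict  # group name -> {subject id -> {"pre": Recording, "post": Recording}}
    config: SynthConfig
    ground_truth: dict = field(default_factory=dict)

    def subjects(self, group: str) -> list[str]:
        return list(self.groups[group])

    def recordings(self):
        for group, subs in self.groups.items():
            for sid, conds in subs.items():
                for cond, rec in conds.items():
                    yield group, sid, cond, rec

    @property
    def n_recordings(self) -> int:
        return sum(1 for _ in self.recordings())

    def save(self, out_dir, format: str = "raw-matrix") -> Path:
        """Write one file per subject/condition plus the ground truth JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = ".edf" if format == "edf" else ".f32"
        for group, sid, cond, rec in self.recordings():
            write_recording(rec, out_dir / f"{group}_{sid}_{cond}{ext}", format)
        (out_dir / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2)
        )
        return out_dir


def generate_study(
    config: SynthConfig, n_per_group: int = 13, seed: int | None = None
) -> StudyDataset:
    """Simulate a two-group pre/post study.

    Control subjects' pre and post sessions come from identical parameters;
    treated ("chiropractic") subjects' post sessions apply ``config.effect``
    to the band-power targets and ``config.coherence_effect`` to the
    shared-source gain.  Per-subject log-normal jitter on band weights is
    shared between a subject's sessions.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    config.validate()
    entropy = config.seed if seed is None else seed
    root = (
        entropy
        if isinstance(entropy, np.random.SeedSequence)
        else np.random.SeedSequence(entropy)
    )
    groups: dict = {}
    truth: dict = {
        "effect": config.effect,
        "coherence_effect": config.coherence_effect,
        "band_weights": {k: float(np.mean(v)) for k, v in config.band_weights.items()},
        "subjects": {},
    }
    for group in ("control", "chiropractic"):
        groups[group] = {}
        for i in range(n_per_group):
            sid = f"{group[:4]}{i + 1:02d}"
            ss_jitter, ss_pre, ss_post = root.spawn(3)
            jitter_rng = np.random.default_rng(ss_jitter)
            jitter = {
                b.name: float(
                    np.exp(jitter_rng.normal(0.0, config.subject_sigma))
                )
                for b in config.bands
            }
            pre = generate_recording(config, ss_pre, weight_scale=jitter)
            post_scale = dict(jitter)
            gain_offset = 0.0
            if group == "chiropractic":
                for band, mult in config.effect.items():
                    post_scale[band] = post_scale.get(band, 1.0) * mult
                gain_offset = config.coherence_effect
            post = generate_recording(
                config, ss_post, weight_scale=post_scale, gain_offset=gain_offset
            )
            pre.meta.update(group=group, subject=sid, condition="pre")
            post.meta.update(group=group, subject=sid, condition="post")
            groups[group][sid] = {"pre": pre, "post": post}
            truth["subjects"][sid] = {"group": group, "jitter": jitter}
    return StudyDataset(groups=groups, config=config, ground_truth=truth)


# ---------------------------------------------------------------------------
# fast subject-level null maps (for permutation-test calibration)


def null_power_maps(
    n_subjects: int,
    coords: np.ndarray,
    rng: np.random.Generator,
    base: float = 0.2,
    sigma: float = 0.03,
    length_scale: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw exchangeable pre/post subject-level relative-power maps.

    Channel noise is spatially correlated with a squared-exponential kernel
    over electrode coordinates (length scale in unit-sphere chord units), so
    the null reflects the smooth topographies real band power exhibits.
    Pre and post maps are i.i.d. — the null hypothesis of no intervention
    effect.  Returns two (n_subjects x n_channels) arrays.
    """
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2.0 * length_scale**2))
    cov += 1e-8 * np.eye(len(coords))
    chol = np.linalg.cholesky(cov)

    def draw() -> np.ndarray:
        z = rng.standard_normal((n_subjects, len(coords)))
        return base + sigma * z @ chol.T

    return draw(), draw()
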