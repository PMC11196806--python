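"""Signal conditioning and artifact-based epoch rejection.

Conditioning order: zero-phase FIR band-pass (Kaiser window, 0.5–40 Hz,
1 Hz transition) → integer-factor decimation (anti-aliasing guaranteed by
the 40 Hz cutoff) → common average reference.

Epoch rejection applies four amplitude criteria per channel; an epoch is
discarded as soon as any channel violates any criterion:

1. absolute voltage above 100 µV;
2. peak-to-peak range above 150 µV in a 200 ms window slid in 100 ms steps;
3. step-function response above 100 µV — the absolute difference between the
   means of the two halves of a 200 ms window slid in 50 ms steps, which
   targets the quasi-step deflections of saccades and blinks;
4. a jump of more than 50 µV between two consecutive samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import Recording

__all__ = [
    "FilterSpec",
    "RejectionThresholds",
    "EpochSet",
    "design_bandpass",
    "condition",
    "segment",
    "reject_epochs",
]

#: Kaiser shape parameter equivalent to 60 dB of stopband attenuation.
KAISER_BETA_60DB = 5.653


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design parameters (defaults follow the study pipeline)."""

    low_cut: float = 0.5
    high_cut: float = 40.0
    transition_bw: float = 1.0
    kaiser_beta: float = KAISER_BETA_60DB
    order: int | None = None  # taps − 1; derived from the design relation if None

    def validate(self, fs: float) -> None:
        if not 0 < self.low_cut < self.high_cut < fs / 2:
            raise ValueError(
                f"need 0 < low_cut < high_cut < fs/2, got "
                f"({self.low_cut}, {self.high_cut}) at fs={fs}"
            )
        if self.transition_bw <= 0:
            raise ValueError("transition_bw must be positive")
        if self.order is not None and (self.order < 2 or self.order % 2):
            raise ValueError("order must be even and >= 2")


def design_bandpass(fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Design the linear-phase Kaiser-window band-pass kernel.

    The number of taps comes from the Kaiser order-estimation relation for
    the requested attenuation and transition width (rounded up to an even
    order, i.e. an odd, type-I symmetric tap count) unless ``spec.order``
    pins it explicitly.
    """
    spec.validate(fs)
    atten_db = spec.kaiser_beta / 0.1102 + 8.7  # invert the Kaiser relation

    def _design(nt: int) -> np.ndarray:
        return signal.firwin(
            nt,
            [spec.low_cut, spec.high_cut],
            window=("kaiser", spec.kaiser_beta),
            pass_zero=False,
            fs=fs,
        )

    if spec.order is not None:
        numtaps = spec.order + 1
        min_taps, _ = signal.kaiserord(30.0, spec.transition_bw / (fs / 2))
        if numtaps < min_taps:
            raise ValueError(
                f"order {spec.order} too small for a {spec.transition_bw} Hz "
                f"transition at fs={fs}"
            )
        return _design(numtaps)

    numtaps, _ = signal.kaiserord(atten_db, spec.transition_bw / (fs / 2))
    if numtaps % 2 == 0:
        numtaps += 1
    # The band-pass kernel is a difference of two low-pass designs, so the
    # residual at DC depends on how the edge ripples phase-align for the
    # exact length; nudge the tap count until DC leakage meets the design
    # attenuation.
    target = 10.0 ** (-atten_db / 20.0)
    kernel = _design(numtaps)
    for _ in range(200):
        if abs(kernel.sum()) <= target:
            break
        numtaps += 2
        kernel = _design(numtaps)
    return kernel


def _filter_zero_phase(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR kernel with its group delay compensated.

    Edges are handled by reflect-padding half a kernel length so the output
    has the input's length with no phase shift anywhere (the kernel is
    linear-phase, so 'same'-mode convolution after centring is exact).
    """
    half = (len(kernel) - 1) // 2
    padded = np.pad(data, [(0, 0), (half, half)], mode="reflect")
    out = signal.fftconvolve(padded, kernel[None, :], mode="valid", axes=-1)
    return out


def condition(
    rec: Recording,
    spec: FilterSpec = FilterSpec(),
    target_fs: float | None = 512.0,
) -> Recording:
    """Band-pass filter, decimate and average-reference a recording."""
    kernel = design_bandpass(rec.fs, spec)
    data = _filter_zero_phase(rec.data, kernel)
    fs = rec.fs
    if target_fs is not None and target_fs != fs:
        factor = fs / target_fs
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                f"target_fs {target_fs} must divide fs {fs} evenly"
            )
        data = data[:, :: int(round(factor))]
        fs = target_fs
    data = data - data.mean(axis=0, keepdims=True)  # average reference
    return replace(rec, data=data, fs=fs)


@dataclass
class EpochSet:
    """Fixed-length segments of one recording plus a rejection report."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    labels: tuple[str, ...]
    epoch_len: float
    source: dict = field(default_factory=dict)  # subject / condition ids
    kept_mask: np.ndarray | None = None
    rejection_report: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.epochs), dtype=bool)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def kept(self) -> np.ndarray:
        return self.epochs[self.kept_mask]

    def report_table(self):
        import pandas as pd

        return pd.DataFrame(
            self.rejection_report,
            columns=["epoch_index", "kept", "criteria_fired", "worst_channel"],
        )


def segment(rec: Recording, epoch_len: float = 5.0, source: dict | None = None) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    A trailing partial window is discarded; an input shorter than one epoch
    yields an empty set with a warning.
    """
    n_per = epoch_len * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_len times fs must be an integer sample count")
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        warnings.warn(
            f"recording shorter ({rec.duration:.1f} s) than one epoch "
            f"({epoch_len} s); zero epochs",
            stacklevel=2,
        )
        epochs = np.empty((0, rec.n_channels, n_per))
    else:
        epochs = (
            rec.data[:, : n_epochs * n_per]
            .reshape(rec.n_channels, n_epochs, n_per)
            .transpose(1, 0, 2)
            .copy()
        )
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        labels=rec.labels,
        epoch_len=epoch_len,
        source=dict(source or rec.meta),
    )


@dataclass(frozen=True)
class RejectionThresholds:
    """Amplitude thresholds (µV) and window geometry of the four criteria."""

    absolute: float = 100.0
    peak_to_peak: float = 150.0
    p2p_window: float = 0.2
    p2p_step: float = 0.1
    step_response: float = 100.0
    step_window: float = 0.2
    step_step: float = 0.05
    sample_diff: float = 50.0

    def validate(self) -> None:
        for name in ("absolute", "peak_to_peak", "step_response", "sample_diff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def _sliding_starts(n: int, win: int, step: int) -> np.ndarray:
    """Start indices of step-strided windows, always including the last
    fully-contained window so the epoch tail is never unexamined."""
    if n < win:
        return np.empty(0, dtype=int)
    starts = np.arange(0, n - win + 1, step)
    if starts[-1] != n - win:
        starts = np.append(starts, n - win)
    return starts


def _criteria_fired(epoch: np.ndarray, fs: float, thr: RejectionThresholds):
    """Evaluate all four criteria on one (channels x samples) epoch.

    Returns (sorted criterion indices, index of the worst channel) — worst
    meaning the channel with the largest absolute excursion among violators.
    """
    fired: set[int] = set()
    offenders = np.zeros(epoch.shape[0])

    over = np.abs(epoch) > thr.absolute
    if over.any():
        fired.add(1)
        offenders = np.maximum(offenders, np.abs(epoch).max(axis=1))

    win = int(round(thr.p2p_window * fs))
    step = max(1, int(round(thr.p2p_step * fs)))
    starts = _sliding_starts(epoch.shape[1], win, step)
    if starts.size:
        views = epoch[:, starts[:, None] + np.arange(win)[None, :]]
        p2p = views.max(axis=2) - views.min(axis=2)  # (channels, windows)
        if (p2p > thr.peak_to_peak).any():
            fired.add(2)
            offenders = np.maximum(offenders, p2p.max(axis=1))

    win = int(round(thr.step_window * fs))
    step = max(1, int(round(thr.step_step * fs)))
    half = win // 2
    starts = _sliding_starts(epoch.shape[1], win, step)
    if starts.size and half:
        views = epoch[:, starts[:, None] + np.arange(win)[None, :]]
        step_stat = np.abs(
            views[:, :, half:].mean(axis=2) - views[:, :, :half].mean(axis=2)
        )
        if (step_stat > thr.step_response).any():
            fired.add(3)
            offenders = np.maximum(offenders, step_stat.max(axis=1))

    jumps = np.abs(np.diff(epoch, axis=1))
    if jumps.size and (jumps > thr.sample_diff).any():
        fired.add(4)
        offenders = np.maximum(offenders, jumps.max(axis=1))

    worst = int(np.argmax(offenders)) if fired else -1
    return sorted(fired), worst


def reject_epochs(
    epochs: EpochSet, thresholds: RejectionThresholds = RejectionThresholds()
) -> EpochSet:
    """Mark epochs violating any criterion on any channel as rejected.

    The returned set shares the epoch array; ``kept_mask`` and the
    per-epoch ``rejection_report`` (criteria fired, worst channel) are
    recomputed from scratch.
    """
    thresholds.validate()
    kept = np.ones(epochs.n_epochs, dtype=bool)
    report = []
    for i, ep in enumerate(epochs.epochs):
        fired, worst = _criteria_fired(ep, epochs.fs, thresholds)
        ok = not fired
        kept[i] = ok
        report.append(
            (
                i,
                ok,
                ",".join(f"C{c}" for c in fired),
                epochs.labels[worst] if not ok else "",
            )
        )
    return EpochSet(
        epochs=epochs.epochs,
        fs=epochs.fs,
        labels=epochs.labels,
        epoch_len=epochs.epoch_len,
        source=epochs.source,
        kept_mask=kept,
        rejection_report=report,
    )
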