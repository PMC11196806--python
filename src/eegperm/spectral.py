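"""Hann-taper power spectra and relative band power.

The six analysis bands partition 0.5–35 Hz: delta 0.5–4, theta 4–8,
alpha1 8–11, alpha2 11–14, beta1 14–25 and beta2 25–35 Hz.  Relative power
normalizes each band's integrated PSD by the total over the analyzed
0.5–40 Hz range (the filtered band), so the six values sum to at most 1.
Band edges are half-open, ``low <= f < high``: a bin landing exactly on a
shared edge counts once, toward the upper band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EpochSet

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "BAND_NAMES",
    "power_spectrum",
    "relative_band_power",
    "band_power_table",
    "prepost_difference_features",
]


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha1", 8.0, 11.0),
    Band("alpha2", 11.0, 14.0),
    Band("beta1", 14.0, 25.0),
    Band("beta2", 25.0, 35.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)

#: Denominator range for relative power: the conditioned pass-band.
TOTAL_RANGE: tuple[float, float] = (0.5, 40.0)


def validate_bands(bands) -> tuple[Band, ...]:
    bands = tuple(bands)
    for b in bands:
        if not b.low < b.high:
            raise ValueError(f"band {b.name}: low must be below high")
    for a, b in zip(bands, bands[1:]):
        if b.low < a.high:
            raise ValueError(f"bands {a.name} and {b.name} overlap")
    if bands[0].low < TOTAL_RANGE[0] or bands[-1].high > TOTAL_RANGE[1]:
        raise ValueError(f"bands must lie within {TOTAL_RANGE} Hz")
    return bands


def power_spectrum(epoch: np.ndarray, fs: float):
    """One-sided Hann-tapered periodogram of a (channels x samples) epoch.

    Returns ``(freqs, psd)`` scaled as a density: the trapezoid integral of
    ``psd`` over frequency equals the tapered signal's mean power (Hann
    window normalization included).  Epochs must span at least 2 s so the
    frequency resolution resolves the 0.5 Hz delta edge.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[-1] == 0:
        raise ValueError("empty epoch")
    if epoch.shape[-1] / fs < 2.0:
        raise ValueError(
            "epoch shorter than 2 s: frequency resolution too coarse for the "
            "0.5 Hz delta band edge"
        )
    freqs, psd = signal.periodogram(
        epoch, fs=fs, window="hann", detrend=False, scaling="density", axis=-1
    )
    return freqs, psd


def relative_band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands=DEFAULT_BANDS,
    total_range: tuple[float, float] = TOTAL_RANGE,
) -> np.ndarray:
    """Relative power per band: band PSD mass over total mass in 0.5–40 Hz.

    Bin assignment is half-open (``low <= f < high``).  Input ``psd`` may be
    (channels x freqs) or a single spectrum; output has a trailing band axis.
    """
    bands = validate_bands(bands)
    psd = np.atleast_2d(np.asarray(psd, dtype=float))
    if freqs[-1] < total_range[1]:
        raise ValueError(
            f"spectrum must cover {total_range} Hz; reaches only {freqs[-1]:.2f}"
        )
    total_mask = (freqs >= total_range[0]) & (freqs < total_range[1])
    denom = psd[..., total_mask].sum(axis=-1)
    if np.any(denom <= 0):
        raise ValueError("zero total power in the analysis range (flat signal?)")
    out = np.empty(psd.shape[:-1] + (len(bands),))
    for j, b in enumerate(bands):
        mask = (freqs >= b.low) & (freqs < b.high)
        out[..., j] = psd[..., mask].sum(axis=-1) / denom
    return out


def band_power_table(epochs: EpochSet, bands=DEFAULT_BANDS) -> np.ndarray:
    """Relative band power of every kept epoch: (kept_epochs x channels x bands)."""
    kept = epochs.kept
    if kept.shape[0] == 0:
        return np.empty((0, len(epochs.labels), len(tuple(bands))))
    freqs, psd = power_spectrum(
        kept.reshape(-1, kept.shape[-1]), epochs.fs
    )
    rel = relative_band_power(freqs, psd, bands)
    return rel.reshape(kept.shape[0], kept.shape[1], -1)


def prepost_difference_features(
    pre_tables: dict,
    post_tables: dict,
    band: str,
    group: str,
    labels,
    bands=DEFAULT_BANDS,
) -> pd.DataFrame:
    """Post-minus-pre relative power per channel, one row per paired epoch.

    ``pre_tables``/``post_tables`` map subject id → (epochs x channels x
    bands) relative-power array for that subject's pre/post recording.
    Epochs are paired by index (k-th kept pre with k-th kept post) and
    truncated to the shorter list; a subject with zero paired epochs is
    dropped with a warning.  Output columns: group, subject, epoch, then one
    column per channel label.
    """
    band_names = [b.name for b in validate_bands(bands)]
    if band not in band_names:
        raise KeyError(f"unknown band {band!r}; have {band_names}")
    bidx = band_names.index(band)
    labels = list(labels)
    rows = []
    for subject in pre_tables:
        if subject not in post_tables:
            warnings.warn(f"subject {subject}: no post recording, dropped", stacklevel=2)
            continue
        pre = pre_tables[subject]
        post = post_tables[subject]
        n = min(pre.shape[0], post.shape[0])
        if n == 0:
            warnings.warn(
                f"subject {subject}: zero paired epochs after rejection, dropped",
                stacklevel=2,
            )
            continue
        diff = post[:n, :, bidx] - pre[:n, :, bidx]
        for k in range(n):
            rows.append([group, subject, k, *diff[k]])
    return pd.DataFrame(rows, columns=["group", "subject", "epoch", *labels])
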