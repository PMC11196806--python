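"""Region-pair magnitude-squared coherence and rank-based group comparisons.

Magnitude-squared coherence (MSC) between two channels is
``|S_xy|² / (S_xx S_yy)`` from Hann-windowed Welch averaged periodograms.
A single segment gives MSC ≡ 1 identically, so each 5 s epoch is subdivided
into 1 s segments with 50% overlap (9 averaging segments) before the
cross-spectra are averaged.

Scalp-level coherence between two of the seven regions is the mean MSC over
all cross-region channel pairs, band-averaged, one value per 5 s epoch.
Pairs whose regions lie in opposite hemispheres are inter-hemispheric; all
other pairs — including those involving the shared occipital region — count
as intra-hemispheric.

Group comparisons use the two-sided Wilcoxon rank-sum test on per-subject
mean pre→post coherence changes (exact null for small samples without ties,
normal approximation with tie correction otherwise), with
Benjamini–Hochberg adjusted p-values reported alongside the raw ones.
A paired signed-rank variant for within-group pre-vs-post contrasts is
also provided.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .montage import REGIONS, Montage
from .preprocess import EpochSet
from .spectral import DEFAULT_BANDS, validate_bands

__all__ = [
    "WilcoxonResult",
    "msc",
    "msc_matrix",
    "region_pairs",
    "pair_type",
    "region_pair_coherence",
    "subject_mean_coherence",
    "compare_coherence_change",
    "coherence_change_table",
    "paired_signed_rank",
]


def _check_segments(n_samples: int, fs: float, seg_len: float, overlap: float):
    nper = int(round(seg_len * fs))
    step = max(1, int(round(nper * (1.0 - overlap))))
    n_seg = 1 + (n_samples - nper) // step if n_samples >= nper else 0
    if n_seg < 2:
        raise ValueError(
            f"only {n_seg} averaging segment(s): the MSC of a single segment "
            "is identically 1; shorten seg_len or lengthen the signal"
        )
    return nper, step, n_seg


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    seg_len: float = 1.0,
    overlap: float = 0.5,
):
    """Welch magnitude-squared coherence of two signals.

    Returns ``(freqs, coherence)`` with coherence in [0, 1] at every bin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nper, step, _ = _check_segments(x.shape[-1], fs, seg_len, overlap)
    freqs, coh = signal.coherence(
        x, y, fs=fs, window="hann", nperseg=nper, noverlap=nper - step,
        detrend=False,
    )
    return freqs, np.clip(coh, 0.0, 1.0)


def msc_matrix(
    epoch: np.ndarray,
    fs: float,
    seg_len: float = 1.0,
    overlap: float = 0.5,
):
    """All-channel-pair MSC of one (channels x samples) epoch in one pass.

    Computes the Hann-windowed segment FFTs once and forms the full
    cross-spectral matrix by outer products, which is algebraically the
    pairwise Welch estimate.  Returns ``(freqs, msc)`` with msc of shape
    (channels, channels, freqs).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n_ch, n = epoch.shape
    nper, step, n_seg = _check_segments(n, fs, seg_len, overlap)
    win = signal.get_window("hann", nper)
    starts = np.arange(n_seg) * step
    segs = epoch[:, starts[:, None] + np.arange(nper)[None, :]]  # (ch, seg, nper)
    spec = np.fft.rfft(segs * win[None, None, :], axis=-1)  # (ch, seg, freq)
    csd = np.einsum("isf,jsf->ijf", spec, spec.conj()) / n_seg
    auto = np.einsum("iif->if", csd).real
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(csd) ** 2 / denom
    out[~np.isfinite(out)] = 0.0
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, np.clip(out.real, 0.0, 1.0)


def region_pairs() -> list[tuple[str, str]]:
    """The 21 unordered pairs of the seven scalp regions."""
    return list(itertools.combinations(REGIONS, 2))


def pair_type(region_a: str, region_b: str) -> str:
    """'inter-hemispheric' iff the two regions lie in opposite hemispheres."""
    ha = region_a.rsplit("_", 1)[-1] if "_" in region_a else None
    hb = region_b.rsplit("_", 1)[-1] if "_" in region_b else None
    if ha and hb and ha != hb:
        return "inter-hemispheric"
    return "intra-hemispheric"


def region_pair_coherence(
    epochs: EpochSet,
    montage: Montage,
    bands=DEFAULT_BANDS,
    seg_len: float = 1.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Mean cross-region MSC per 5 s epoch, region pair and band.

    Output columns: epoch, region_pair, pair_type, band, coherence.
    """
    bands = validate_bands(bands)
    region_idx = {}
    for r in REGIONS:
        chans = montage.channels_in(r)
        if not chans:
            raise ValueError(f"region {r} has no channels in this montage")
        region_idx[r] = np.array([epochs.labels.index(c) for c in chans])
    rows = []
    kept_idx = np.flatnonzero(epochs.kept_mask)
    for k, ep_i in enumerate(kept_idx):
        freqs, m = msc_matrix(epochs.epochs[ep_i], epochs.fs, seg_len, overlap)
        band_masks = [(freqs >= b.low) & (freqs < b.high) for b in bands]
        for ra, rb in region_pairs():
            ia, ib = region_idx[ra], region_idx[rb]
            block = m[np.ix_(ia, ib)]  # (|a|, |b|, freqs)
            ptype = pair_type(ra, rb)
            for b, mask in zip(bands, band_masks):
                rows.append(
                    (
                        k,
                        f"{ra}-{rb}",
                        ptype,
                        b.name,
                        float(block[:, :, mask].mean()),
                    )
                )
    return pd.DataFrame(
        rows, columns=["epoch", "region_pair", "pair_type", "band", "coherence"]
    )


def subject_mean_coherence(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the epoch axis: mean coherence per region pair and band."""
    return (
        table.groupby(["region_pair", "pair_type", "band"], as_index=False)[
            "coherence"
        ].mean()
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of the first sample
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def compare_coherence_change(
    group_a: np.ndarray, group_b: np.ndarray
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test on per-subject values.

    Uses the exact null when the combined sample is small (≤ 25) and
    tie-free, the tie-corrected normal approximation otherwise.  The
    reported statistic is the rank sum W of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 subjects per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        w = len(a) * (len(a) + 1) / 2 + len(a) * len(b) / 2
        return WilcoxonResult(w, 1.0, float(np.median(a)), float(np.median(b)),
                              len(a), len(b))
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U1 -> rank sum
    return WilcoxonResult(
        statistic=w,
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
    )


def paired_signed_rank(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for within-group pre vs post."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    d = post - pre
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    res = stats.wilcoxon(post, pre, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def coherence_change_table(
    changes_a: pd.DataFrame, changes_b: pd.DataFrame
) -> pd.DataFrame:
    """Rank-sum comparison of per-subject Δcoherence for every pair × band.

    Inputs carry one row per (subject, region_pair, band) with a ``delta``
    column (mean post − mean pre coherence).  Output columns: region_pair,
    pair_type, band, median_a, median_b, statistic, p_raw, p_adjusted
    (Benjamini–Hochberg over all pair × band cells).
    """
    rows = []
    keys = ["region_pair", "pair_type", "band"]
    grouped_a = changes_a.groupby(keys)
    grouped_b = changes_b.groupby(keys)
    for key, ga in grouped_a:
        if key not in grouped_b.groups:
            continue
        gb = grouped_b.get_group(key)
        res = compare_coherence_change(ga["delta"].values, gb["delta"].values)
        rows.append((*key, res.median_a, res.median_b, res.statistic, res.p_value))
    out = pd.DataFrame(
        rows,
        columns=[*keys, "median_a", "median_b", "statistic", "p_raw"],
    )
    if len(out):
        out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = []
    return out
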