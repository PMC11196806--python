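"""SVM separation of control vs treated pre/post power-change features.

The feature of one 5 s epoch is the per-channel post-minus-pre relative
power difference in one band.  Evaluation repeats a random 70/30 split 20
times; splits are made at the SUBJECT level — every epoch of a subject
stays on one side — because epochs of the same subject are strongly
correlated and epoch-level splitting would leak identity information into
the test set.  (An epoch-level mode exists for quantifying exactly that
inflation.)  Features are standardized with training-set statistics only;
the classifier is a soft-margin RBF support vector machine with C = 1 and
the inverse-feature-count ('scale') kernel width.  Accuracy is
(tp + tn) / (tp + fp + tn + fn) · 100, averaged over runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["AccuracyResult", "evaluate_band", "per_channel_accuracy"]

_META_COLS = ("group", "subject", "epoch")


@dataclass
class AccuracyResult:
    band: str
    channel_subset: tuple[str, ...]  # all feature channels used
    accuracies: list  # one percentage per run
    confusions: list  # per run dict tp/tn/fp/fn over test epochs
    mean_accuracy: float = field(init=False)
    sd_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracies, dtype=float)
        self.mean_accuracy = float(acc.mean())
        self.sd_accuracy = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "channels": list(self.channel_subset),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "accuracies": list(map(float, self.accuracies)),
            "confusions": self.confusions,
        }


def _feature_channels(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c not in _META_COLS]


def _split_subjects(
    subjects: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[set, set]:
    n_train = int(round(train_frac * len(subjects)))
    n_train = min(max(n_train, 2), len(subjects) - 2)
    perm = rng.permutation(subjects)
    return set(perm[:n_train]), set(perm[n_train:])


def evaluate_band(
    features_control: pd.DataFrame,
    features_treated: pd.DataFrame,
    band: str = "",
    train_frac: float = 0.7,
    n_runs: int = 20,
    seed: int | np.random.Generator | None = None,
    channels: list[str] | None = None,
    split_level: str = "subject",
) -> AccuracyResult:
    """Repeated random-split SVM evaluation of one band's features.

    ``features_*`` are tables with group/subject/epoch columns followed by
    one column per channel (the output of
    :func:`eegperm.spectral.prepost_difference_features`).  ``channels``
    restricts the feature set (e.g. to a single channel for topographic
    accuracy maps).
    """
    if split_level not in ("subject", "epoch"):
        raise ValueError("split_level must be 'subject' or 'epoch'")
    all_channels = _feature_channels(features_control)
    if _feature_channels(features_treated) != all_channels:
        raise ValueError("the two feature tables have different channel columns")
    use = list(channels) if channels is not None else all_channels
    missing = [c for c in use if c not in all_channels]
    if missing:
        raise KeyError(f"channels absent from features: {missing}")

    x0 = features_control[use].to_numpy(dtype=float)
    x1 = features_treated[use].to_numpy(dtype=float)
    s0 = features_control["subject"].to_numpy()
    s1 = features_treated["subject"].to_numpy()
    subj0, subj1 = np.unique(s0), np.unique(s1)
    if min(len(subj0), len(subj1)) < 4:
        raise ValueError("need >= 4 subjects per group for a 70/30 subject split")

    rng = np.random.default_rng(seed)
    accuracies, confusions = [], []
    for _ in range(n_runs):
        for attempt in range(10):
            if split_level == "subject":
                tr0, te0 = _split_subjects(subj0, train_frac, rng)
                tr1, te1 = _split_subjects(subj1, train_frac, rng)
                tr_mask0, te_mask0 = np.isin(s0, list(tr0)), np.isin(s0, list(te0))
                tr_mask1, te_mask1 = np.isin(s1, list(tr1)), np.isin(s1, list(te1))
            else:
                tr_mask0 = rng.random(len(x0)) < train_frac
                te_mask0 = ~tr_mask0
                tr_mask1 = rng.random(len(x1)) < train_frac
                te_mask1 = ~tr_mask1
            if tr_mask0.any() and tr_mask1.any() and te_mask0.any() and te_mask1.any():
                break
            warnings.warn("a class was absent from a split; resampling", stacklevel=2)
        else:
            raise RuntimeError("could not draw a split with both classes present")

        x_train = np.vstack([x0[tr_mask0], x1[tr_mask1]])
        y_train = np.concatenate(
            [np.zeros(tr_mask0.sum()), np.ones(tr_mask1.sum())]
        )
        x_test = np.vstack([x0[te_mask0], x1[te_mask1]])
        y_test = np.concatenate(
            [np.zeros(te_mask0.sum()), np.ones(te_mask1.sum())]
        )
        scaler = StandardScaler().fit(x_train)
        clf = SVC(C=1.0, kernel="rbf", gamma="scale")
        clf.fit(scaler.transform(x_train), y_train)
        y_hat = clf.predict(scaler.transform(x_test))
        tp = int(np.sum((y_hat == 1) & (y_test == 1)))
        tn = int(np.sum((y_hat == 0) & (y_test == 0)))
        fp = int(np.sum((y_hat == 1) & (y_test == 0)))
        fn = int(np.sum((y_hat == 0) & (y_test == 1)))
        accuracies.append(100.0 * (tp + tn) / (tp + fp + tn + fn))
        confusions.append({"tp": tp, "tn": tn, "fp": fp, "fn": fn})
    return AccuracyResult(
        band=band, channel_subset=tuple(use), accuracies=accuracies,
        confusions=confusions,
    )


def per_channel_accuracy(
    features_control: pd.DataFrame,
    features_treated: pd.DataFrame,
    band: str = "",
    train_frac: float = 0.7,
    n_runs: int = 20,
    seed: int | np.random.Generator | None = None,
    split_level: str = "subject",
) -> pd.Series:
    """Single-channel SVM accuracy per channel (topographic accuracy map).

    Runs the full repeated-split protocol once per channel with that
    channel's difference feature alone; returns a Series indexed by channel
    label, ordered as the feature table's channel columns.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for ch in _feature_channels(features_control):
        res = evaluate_band(
            features_control,
            features_treated,
            band=band,
            train_frac=train_frac,
            n_runs=n_runs,
            seed=rng,
            channels=[ch],
            split_level=split_level,
        )
        out[ch] = res.mean_accuracy
    return pd.Series(out, name=f"accuracy_{band}" if band else "accuracy")
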