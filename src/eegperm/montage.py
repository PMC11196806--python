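"""62-channel 10-10 montage: coordinates, scalp regions, hemispheres.

Region scheme follows the seven-area coherence layout used for region-pair
connectivity: left/right frontal, left/right parietal, left/right temporal
and a single shared occipital area.  Hemisphere is read off the electrode
name (odd digit = left, even = right, trailing ``z`` = midline); midline
electrodes outside the occipital strip belong to no lateralized region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNELS_62",
    "REGIONS",
    "Montage",
    "assign_regions",
    "default_montage",
    "hemisphere_of_label",
    "region_of_label",
]

#: Default 62-electrode subset of the extended 10-20 (10-10) system.
#: AFz is reserved as the ground electrode and therefore absent.
CHANNELS_62: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

REGIONS: tuple[str, ...] = (
    "frontal_L", "frontal_R",
    "parietal_L", "parietal_R",
    "temporal_L", "temporal_R",
    "occipital",
)

# Longest-match first: FT before F and T, Fp/AF before F, CP/PO before P, ...
_PREFIX_AREA = (
    ("Fp", "frontal"),
    ("AF", "frontal"),
    ("FC", "frontal"),
    ("FT", "temporal"),
    ("TP", "temporal"),
    ("CP", "parietal"),
    ("PO", "occipital"),
    ("F", "frontal"),
    ("C", "parietal"),
    ("P", "parietal"),
    ("T", "temporal"),
    ("O", "occipital"),
)

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+|z)$")


def _parse_label(label: str) -> tuple[str, str]:
    """Split a 10-10 label into (prefix, suffix); suffix is digits or 'z'."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"channel label {label!r} does not follow 10-10 naming")
    return m.group(1), m.group(2)


def hemisphere_of_label(label: str) -> str:
    """Return 'L', 'R' or 'midline' from the electrode-name suffix."""
    _, suffix = _parse_label(label)
    if suffix.lower() == "z":
        return "midline"
    return "L" if int(suffix) % 2 == 1 else "R"


def region_of_label(label: str) -> str | None:
    """Map an electrode label to one of the seven scalp regions.

    Returns ``None`` for midline electrodes outside the occipital strip
    (they belong to neither hemisphere and so to no lateralized region).
    """
    prefix, _ = _parse_label(label)
    area = None
    for pfx, a in _PREFIX_AREA:
        if prefix.lower() == pfx.lower():
            area = a
            break
    if area is None:
        raise ValueError(f"channel label {label!r}: unknown 10-10 prefix {prefix!r}")
    hemi = hemisphere_of_label(label)
    if area == "occipital":
        return "occipital"
    if hemi == "midline":
        return None
    return f"{area}_{hemi}"


@dataclass
class Montage:
    """Electrode labels with unit-sphere coordinates and region bookkeeping."""

    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 3) on the unit head sphere
    region_of: dict[str, str | None] = field(default_factory=dict)
    hemisphere_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (n_labels, 3)")
        if not self.region_of:
            self.region_of = {lb: region_of_label(lb) for lb in self.labels}
        if not self.hemisphere_of:
            self.hemisphere_of = {lb: hemisphere_of_label(lb) for lb in self.labels}

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def channels_in(self, region: str) -> list[str]:
        return [lb for lb in self.labels if self.region_of[lb] == region]

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def to_table(self):
        """Montage as a tidy table (label, x, y, z, region, hemisphere)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "label": self.labels,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "region": [self.region_of[lb] or "" for lb in self.labels],
                "hemisphere": [self.hemisphere_of[lb] for lb in self.labels],
            }
        )


def _template_positions(labels: tuple[str, ...]) -> np.ndarray:
    """Unit-sphere positions for 10-10 labels from MNE's standard template."""
    import mne

    mne.set_log_level("ERROR")
    std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    missing = [lb for lb in labels if lb not in pos]
    if missing:
        raise KeyError(f"labels absent from the 10-05 template: {missing}")
    xyz = np.array([pos[lb] for lb in labels], dtype=float)
    # The template is head-centred in metres; project radially onto the unit
    # sphere (about the head origin) so inter-electrode distances are
    # scale-free without distorting the cap geometry.
    norms = np.linalg.norm(xyz, axis=1, keepdims=True)
    return xyz / norms


def assign_regions(labels) -> Montage:
    """Build a :class:`Montage` (coordinates + regions) for the given labels.

    Labels must follow 10-10 naming; unknown prefixes raise ``ValueError``
    listing the offending label.  Every one of the seven regions must end up
    non-empty.
    """
    labels = tuple(labels)
    coords = _template_positions(labels)
    m = Montage(labels=labels, coords=coords)
    empty = [r for r in REGIONS if not m.channels_in(r)]
    if empty:
        raise ValueError(f"regions with no channels: {empty}")
    return m


def default_montage() -> Montage:
    """The study's 62-channel montage with template coordinates."""
    return assign_regions(CHANNELS_62)
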