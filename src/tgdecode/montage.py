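"""Electrode montage and scalp-network handling.

The study montage is the 28-scalp-channel subset of the international 10-5
system used by the simultaneous EEG-NIRS recordings this package emulates
(reference TP9 and ground TP10 carry no signal and are excluded).  Channels
are grouped into three anterior-to-posterior networks — frontal, central,
parietal/occipital — whose three pairwise unions give six networks in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 28 scalp channels, in recording order.
CHANNELS_28 = (
    "Fp1", "Fp2", "AFF5h", "AFF6h", "AFz", "F1", "F2",
    "FC1", "FC2", "FC5", "FC6", "Cz", "C3", "C4", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "Pz", "P3", "P4", "P7", "P8",
    "POz", "O1", "O2",
)

#: Default network assignment by 10-5 name prefix (anterior -> posterior).
DEFAULT_GROUPS = {
    "frontal": ("Fp1", "Fp2", "AFF5h", "AFF6h", "AFz", "F1", "F2"),
    "central": ("FC1", "FC2", "FC5", "FC6", "Cz", "C3", "C4", "T7", "T8"),
    "parietal_occipital": (
        "CP1", "CP2", "CP5", "CP6", "Pz", "P3", "P4", "P7", "P8",
        "POz", "O1", "O2",
    ),
}

NETWORK_NAMES = (
    "frontal",
    "central",
    "parietal_occipital",
    "frontal-central",
    "frontal-parietal_occipital",
    "central-parietal_occipital",
)


@dataclass
class Montage:
    """Electrode names with 3-D head-frame positions in millimeters."""

    channels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3) mm
    groups: dict[str, str] = field(default_factory=dict)  # channel -> group

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.channels), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names in montage")

    def position_of(self, channel: str) -> np.ndarray:
        return self.positions[self.channels.index(channel)]

    def projected_2d(self) -> np.ndarray:
        """Azimuthal equidistant projection of the 3-D positions.

        Positions are re-centred on their centroid, then each electrode is
        mapped to (theta*cos(phi), theta*sin(phi)) where theta is the polar
        angle from the vertex (+z) and phi the azimuth; the result is scaled
        by the mean head radius so units stay comparable to millimeters.
        """
        p = self.positions - self.positions.mean(axis=0)
        r = np.linalg.norm(p, axis=1)
        if np.any(r == 0):
            raise ValueError("electrode at projection center")
        theta = np.arccos(np.clip(p[:, 2] / r, -1.0, 1.0))
        phi = np.arctan2(p[:, 1], p[:, 0])
        scale = r.mean()
        return scale * np.column_stack([theta * np.cos(phi),
                                        theta * np.sin(phi)])


def default_montage() -> Montage:
    """The 28-channel 10-5 montage with standard template positions."""
    import mne  # deferred: slow import, only needed for the default

    for name in ("colin27_1005", "standard_1005"):
        try:
            std = mne.channels.make_standard_montage(name)
            break
        except ValueError:  # pragma: no cover - depends on mne version
            continue
    ch_pos = std.get_positions()["ch_pos"]
    pos_mm = np.array([ch_pos[ch] for ch in CHANNELS_28]) * 1000.0
    groups = {ch: g for g, chans in DEFAULT_GROUPS.items() for ch in chans}
    return Montage(CHANNELS_28, pos_mm, groups)


def read_montage_tsv(path) -> Montage:
    """Read a montage from a TSV file with columns ``name x y z group``."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "x", "y", "z", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage TSV must have columns {sorted(required)}")
    return Montage(
        tuple(df["name"]),
        df[["x", "y", "z"]].to_numpy(dtype=float),
        dict(zip(df["name"], df["group"])),
    )


def write_montage_tsv(montage: Montage, path) -> None:
    df = pd.DataFrame(
        {
            "name": montage.channels,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
            "group": [montage.groups.get(ch, "") for ch in montage.channels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


class NetworkMap:
    """Three disjoint base electrode groups plus their pairwise unions."""

    def __init__(self, groups: dict[str, tuple[str, ...]] | None = None):
        groups = dict(groups or DEFAULT_GROUPS)
        expected = {"frontal", "central", "parietal_occipital"}
        if set(groups) != expected:
            raise ValueError(f"base groups must be exactly {sorted(expected)}")
        sets = {k: tuple(v) for k, v in groups.items()}
        all_ch = [ch for v in sets.values() for ch in v]
        if len(all_ch) != len(set(all_ch)):
            raise ValueError("base network groups must be disjoint")
        self._base = sets
        self._networks = dict(sets)
        for a, b in (
            ("frontal", "central"),
            ("frontal", "parietal_occipital"),
            ("central", "parietal_occipital"),
        ):
            self._networks[f"{a}-{b}"] = sets[a] + sets[b]

    @property
    def names(self) -> tuple[str, ...]:
        return NETWORK_NAMES

    @property
    def base_groups(self) -> dict[str, tuple[str, ...]]:
        return dict(self._base)

    def channels(self, network: str) -> tuple[str, ...]:
        if network not in self._networks:
            raise KeyError(
                f"unknown network {network!r}; valid names: "
                f"{', '.join(self._networks)}"
            )
        return self._networks[network]

    def all_channels(self) -> tuple[str, ...]:
        return tuple(ch for g in self._base.values() for ch in g)

    @classmethod
    def from_montage(cls, montage: Montage) -> "NetworkMap":
        groups: dict[str, list[str]] = {
            "frontal": [], "central": [], "parietal_occipital": []}
        for ch in montage.channels:
            g = montage.groups.get(ch)
            if g not in groups:
                raise ValueError(f"channel {ch!r} has unknown group {g!r}")
            groups[g].append(ch)
        return cls({k: tuple(v) for k, v in groups.items()})
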