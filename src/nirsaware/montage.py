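"""Optode montage description for a continuous-wave fNIRS recording.

The montage carries the channel list (source-detector pairs), the
source-detector separations that enter the modified Beer-Lambert law, the
index of the single short-separation channel used for superficial-signal
regression, and the two laser wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "default_montage"]


@dataclass
class Montage:
    """Geometry and wiring of an fNIRS cap.

    Parameters
    ----------
    source_labels, detector_labels
        Optode names (10-20 positions for the default cap).
    channel_pairs
        One ``(source_index, detector_index)`` per channel (0-based into the
        label lists).
    distances_cm
        Source-detector separation per channel, in cm.
    short_channel_index
        Index into ``channel_pairs`` of the single short-separation
        (scalp-only) channel.
    wavelengths_nm
        The two laser wavelengths; must be distinct.
    """

    source_labels: list[str]
    detector_labels: list[str]
    channel_pairs: list[tuple[int, int]]
    distances_cm: np.ndarray
    short_channel_index: int
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        self.distances_cm = np.asarray(self.distances_cm, dtype=float)
        if len(self.channel_pairs) == 0:
            raise ValueError("montage must define at least one channel")
        if len(self.distances_cm) != len(self.channel_pairs):
            raise ValueError("distances_cm must match channel_pairs in length")
        if np.any(self.distances_cm <= 0):
            raise ValueError("all source-detector distances must be positive")
        if not 0 <= self.short_channel_index < len(self.channel_pairs):
            raise ValueError("short_channel_index out of range")
        if float(self.wavelengths_nm[0]) == float(self.wavelengths_nm[1]):
            raise ValueError("wavelengths must be distinct")
        for s, d in self.channel_pairs:
            if not (0 <= s < len(self.source_labels)):
                raise ValueError(f"source index {s} out of range")
            if not (0 <= d < len(self.detector_labels)):
                raise ValueError(f"detector index {d} out of range")

    @property
    def n_channels(self) -> int:
        return len(self.channel_pairs)

    @property
    def long_indices(self) -> np.ndarray:
        """Indices of the normal-separation (cortical) channels."""
        return np.array(
            [i for i in range(self.n_channels) if i != self.short_channel_index]
        )

    @property
    def n_long(self) -> int:
        return self.n_channels - 1

    def channel_names(self) -> list[str]:
        return [
            f"S{s + 1}-D{d + 1}" for s, d in self.channel_pairs
        ]

    def drop_short(self) -> "Montage":
        """Montage restricted to the long channels (after short-channel
        regression the short channel no longer exists).

        The resulting montage has no genuine short channel; index 0 is kept
        as a placeholder and ``has_short`` is False.
        """
        keep = self.long_indices
        m = Montage(
            source_labels=self.source_labels,
            detector_labels=self.detector_labels,
            channel_pairs=[self.channel_pairs[i] for i in keep],
            distances_cm=self.distances_cm[keep],
            short_channel_index=0,
            wavelengths_nm=self.wavelengths_nm,
        )
        m._has_short = False
        return m

    _has_short: bool = field(default=True, repr=False)

    @property
    def has_short(self) -> bool:
        return self._has_short

    def to_dict(self) -> dict:
        return {
            "source_labels": list(self.source_labels),
            "detector_labels": list(self.detector_labels),
            "channel_pairs": [list(p) for p in self.channel_pairs],
            "distances_cm": self.distances_cm.tolist(),
            "short_channel_index": int(self.short_channel_index),
            "wavelengths_nm": [float(w) for w in self.wavelengths_nm],
            "has_short": bool(self._has_short),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        m = cls(
            source_labels=list(d["source_labels"]),
            detector_labels=list(d["detector_labels"]),
            channel_pairs=[tuple(p) for p in d["channel_pairs"]],
            distances_cm=np.asarray(d["distances_cm"], dtype=float),
            short_channel_index=int(d["short_channel_index"]),
            wavelengths_nm=tuple(d["wavelengths_nm"]),
        )
        m._has_short = bool(d.get("has_short", True))
        return m


# Default left-hemisphere fronto-parietal cap: nine sources on FC5, C3, CP5,
# P3, FC1, Cz, CP1, Pz and between Cz/FCz; eight detectors on F5, C5, FC3,
# CP3, FCz, C1, CPz, P1.  S9-D5 is the 1-cm short-separation channel; all
# other pairs are 3-cm cortical channels.
_SOURCES = ["FC5", "C3", "CP5", "P3", "FC1", "Cz", "CP1", "Pz", "Sh"]
_DETECTORS = ["F5", "C5", "FC3", "CP3", "FCz", "C1", "CPz", "P1"]
_LONG_PAIRS = [
    (0, 0), (0, 1), (0, 2),          # FC5 -> F5, C5, FC3
    (1, 1), (1, 2), (1, 3), (1, 5),  # C3  -> C5, FC3, CP3, C1
    (2, 1), (2, 3),                  # CP5 -> C5, CP3
    (3, 3), (3, 7),                  # P3  -> CP3, P1
    (4, 2), (4, 4), (4, 5),          # FC1 -> FC3, FCz, C1
    (5, 5), (5, 6),                  # Cz  -> C1, CPz
    (6, 3), (6, 5), (6, 6), (6, 7),  # CP1 -> CP3, C1, CPz, P1
    (7, 6), (7, 7),                  # Pz  -> CPz, P1
]


def default_montage() -> Montage:
    """The 9-source / 8-detector left-hemisphere cap with one short channel.

    22 long channels at 3 cm plus one short channel (S9-D5) at 1 cm.
    """
    pairs = list(_LONG_PAIRS) + [(8, 4)]
    distances = np.array([3.0] * len(_LONG_PAIRS) + [1.0])
    return Montage(
        source_labels=list(_SOURCES),
        detector_labels=list(_DETECTORS),
        channel_pairs=pairs,
        distances_cm=distances,
        short_channel_index=len(pairs) - 1,
    )
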