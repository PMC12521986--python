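"""SNIRF input/output and the in-memory raw-recording container.

Recordings are exchanged as SNIRF (HDF5) files holding the raw two-wavelength
intensities, plus a tab-separated event table (columns ``onset``,
``duration``, ``trial_type``) and a JSON sidecar with montage metadata and,
for simulated data, the generator ground truth.  Events are stored both in
the SNIRF stimulus groups and in the sidecar TSV; on conflict the TSV wins
(with a logged warning), since event files are routinely corrected by hand.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "read_snirf",
    "write_snirf",
    "read_events_tsv",
    "write_events_tsv",
    "SnirfFormatError",
    "MissingEventsError",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type"]


class SnirfFormatError(IOError):
    """The file does not follow the expected SNIRF layout."""


class MissingEventsError(ValueError):
    """No stimulus information found in file or sidecar."""


@dataclass
class RawRecording:
    """Raw two-wavelength intensity recording.

    Parameters
    ----------
    intensities
        Array of shape ``(n_channels, 2, n_samples)`` in arbitrary units;
        strictly positive.  Axis 1 follows ``montage.wavelengths_nm``.
    sampling_rate
        In Hz.
    montage
        Channel geometry.
    events
        DataFrame with columns ``onset`` (s), ``duration`` (s),
        ``trial_type``.
    annotations
        Free-form metadata (serialized to the JSON sidecar).
    """

    intensities: np.ndarray
    sampling_rate: float
    montage: Montage
    events: pd.DataFrame
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.shape[1] != 2:
            raise ValueError(
                "intensities must have shape (n_channels, 2, n_samples), got "
                f"{self.intensities.shape}"
            )
        if self.intensities.shape[0] != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(self.intensities > 0):
            raise ValueError("raw intensities must be strictly positive")
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        if len(self.events):
            last = float(self.events["onset"].max())
            if last > self.duration_s:
                raise ValueError(
                    f"event onset {last:.1f}s beyond recording end "
                    f"{self.duration_s:.1f}s"
                )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"event file {path} missing columns {sorted(missing)}")
    return ev[EVENT_COLUMNS]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _events_path(path: Path) -> Path:
    return path.with_suffix(".events.tsv")


def write_snirf(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as SNIRF plus events TSV and JSON sidecar.

    The SNIRF file stores intensities as ``dataTimeSeries`` (time x
    measurement) with one measurementList entry per channel/wavelength, the
    probe geometry, and one stimulus group per trial type.  The round trip
    through :func:`read_snirf` is lossless on all modeled fields.
    """
    path = Path(path)
    m = rec.montage
    n_ch, _, n_t = rec.intensities.shape
    # measurement order: channel-major, wavelength-minor
    data = np.empty((n_t, n_ch * 2))
    for c in range(n_ch):
        for w in range(2):
            data[:, c * 2 + w] = rec.intensities[c, w]

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=rec.times)
        for c in range(n_ch):
            s, d = m.channel_pairs[c]
            for w in range(2):
                ml = d1.create_group(f"measurementList{c * 2 + w + 1}")
                ml.create_dataset("sourceIndex", data=s + 1)
                ml.create_dataset("detectorIndex", data=d + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(m.wavelengths_nm))
        probe.create_dataset(
            "sourceLabels", data=np.array(m.source_labels, dtype=object),
            dtype=h5py.string_dtype(),
        )
        probe.create_dataset(
            "detectorLabels", data=np.array(m.detector_labels, dtype=object),
            dtype=h5py.string_dtype(),
        )
        # nominal optode coordinates (cm); schematic layout, separations are
        # authoritative in the sidecar
        probe.create_dataset("sourcePos3D", data=_schematic_positions(len(m.source_labels), 0.0))
        probe.create_dataset("detectorPos3D", data=_schematic_positions(len(m.detector_labels), 1.5))
        for k, ttype in enumerate(sorted(rec.events["trial_type"].unique())):
            sub = rec.events[rec.events["trial_type"] == ttype]
            stim = nirs.create_group(f"stim{k + 1}")
            stim.create_dataset("name", data=str(ttype))
            stim_data = np.column_stack(
                [sub["onset"].to_numpy(float), sub["duration"].to_numpy(float),
                 np.ones(len(sub))]
            )
            stim.create_dataset("data", data=stim_data)
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("SubjectID", data=str(
            rec.annotations.get("subject_id", "sim")))
        meta.create_dataset("MeasurementDate", data="2000-01-01")
        meta.create_dataset("MeasurementTime", data="00:00:00")

    write_events_tsv(rec.events, _events_path(path))
    sidecar = {
        "montage": m.to_dict(),
        "sampling_rate": float(rec.sampling_rate),
        "annotations": rec.annotations,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _schematic_positions(n: int, y: float) -> np.ndarray:
    # evenly spaced schematic coordinates; not used for distance computation
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * 3.0
    pos[:, 1] = y
    return pos


def read_snirf(path: str | Path) -> RawRecording:
    """Read a SNIRF file (with its sidecars) into a :class:`RawRecording`.

    Events are taken from the ``.events.tsv`` sidecar when present; the
    in-file stimulus groups are the fallback.  When both exist and disagree a
    warning is logged and the TSV wins.
    """
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            nirs = f["nirs"]
            d1 = nirs["data1"]
            data = np.asarray(d1["dataTimeSeries"])
            time = np.asarray(d1["time"])
            probe = nirs["probe"]
            wavelengths = tuple(float(w) for w in np.asarray(probe["wavelengths"]))
            ml_names = sorted(
                (k for k in d1 if k.startswith("measurementList")),
                key=lambda k: int(k[len("measurementList"):]),
            )
            meas = []
            for k in ml_names:
                g = d1[k]
                meas.append(
                    (int(np.asarray(g["sourceIndex"])),
                     int(np.asarray(g["detectorIndex"])),
                     int(np.asarray(g["wavelengthIndex"])))
                )
            stim_events = []
            for k in sorted(k for k in nirs if k.startswith("stim")):
                g = nirs[k]
                name = _decode(g["name"][()])
                arr = np.atleast_2d(np.asarray(g["data"]))
                for row in arr:
                    stim_events.append((float(row[0]), float(row[1]), name))
            source_labels = [_decode(x) for x in np.asarray(probe["sourceLabels"])] \
                if "sourceLabels" in probe else None
            detector_labels = [_decode(x) for x in np.asarray(probe["detectorLabels"])] \
                if "detectorLabels" in probe else None
    except (KeyError, OSError) as exc:
        raise SnirfFormatError(f"{path}: not a readable SNIRF file ({exc})") from exc

    if len(time) >= 2:
        fs = 1.0 / float(np.median(np.diff(time)))
    else:
        fs = 0.0

    sidecar_file = _sidecar_path(path)
    montage = None
    annotations: dict = {}
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        montage = Montage.from_dict(sidecar["montage"])
        fs = float(sidecar.get("sampling_rate", fs))
        annotations = sidecar.get("annotations", {})
    else:
        montage = _montage_from_measurements(
            meas, wavelengths, source_labels, detector_labels
        )

    # channel-major ordering from the measurement list
    pair_order: list[tuple[int, int]] = []
    for s, d, _w in meas:
        if (s - 1, d - 1) not in pair_order:
            pair_order.append((s - 1, d - 1))
    n_ch = len(pair_order)
    if data.shape[1] != len(meas):
        raise SnirfFormatError(
            f"{path}: dataTimeSeries has {data.shape[1]} columns but "
            f"{len(meas)} measurementList entries"
        )
    intensities = np.empty((n_ch, 2, data.shape[0]))
    for col, (s, d, w) in enumerate(meas):
        c = pair_order.index((s - 1, d - 1))
        intensities[c, w - 1] = data[:, col]

    events_file = _events_path(path)
    file_events = pd.DataFrame(stim_events, columns=EVENT_COLUMNS).sort_values(
        "onset", ignore_index=True
    )
    if events_file.exists():
        events = read_events_tsv(events_file).sort_values("onset", ignore_index=True)
        if len(file_events) and not _events_equal(events, file_events):
            logger.warning(
                "%s: stimulus groups disagree with %s; using the TSV",
                path, events_file,
            )
    elif len(file_events):
        events = file_events
    else:
        raise MissingEventsError(
            f"{path}: no stimulus groups in file and no {events_file}"
        )

    if np.any(intensities <= 0):
        raise ValueError(f"{path}: non-positive raw intensities")
    return RawRecording(
        intensities=intensities,
        sampling_rate=fs,
        montage=montage,
        events=events,
        annotations=annotations,
    )


def _decode(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def _events_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if len(a) != len(b):
        return False
    return (
        np.allclose(a["onset"], b["onset"])
        and np.allclose(a["duration"], b["duration"])
        and (a["trial_type"].to_numpy() == b["trial_type"].to_numpy()).all()
    )


def _montage_from_measurements(meas, wavelengths, source_labels, detector_labels):
    pairs: list[tuple[int, int]] = []
    for s, d, _w in meas:
        if (s - 1, d - 1) not in pairs:
            pairs.append((s - 1, d - 1))
    n_src = max(p[0] for p in pairs) + 1
    n_det = max(p[1] for p in pairs) + 1
    warnings.warn(
        "no montage sidecar found; assuming 3-cm separations and no short "
        "channel metadata",
        stacklevel=2,
    )
    m = Montage(
        source_labels=source_labels or [f"S{i + 1}" for i in range(n_src)],
        detector_labels=detector_labels or [f"D{i + 1}" for i in range(n_det)],
        channel_pairs=pairs,
        distances_cm=np.full(len(pairs), 3.0),
        short_channel_index=0,
        wavelengths_nm=wavelengths,
    )
    m._has_short = False
    return m
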