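"""Epoch containers and on-disk formats.

The canonical container is an HDF5 file with datasets ``/signals``
(channels x samples, float64), ``/fs`` (scalar Hz) and per-channel metadata
arrays (``/labels``, ``/electrode``, ``/hemisphere``, ``/focal``,
``/resected``).  EDF is supported for interchange: reading goes through MNE;
a minimal plain-EDF (16-bit) writer is provided for export, since the signals
here are synthetic and do not require EDF+ annotations.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EpochRecording",
    "read_epoch",
    "write_epoch_hdf5",
    "read_epoch_hdf5",
    "write_epoch_edf",
    "read_epoch_edf",
]

_METADATA_COLUMNS = ("label", "electrode", "hemisphere", "focal", "resected")

_LABEL_RE = re.compile(r"^(?P<electrode>[A-Za-z]+)(?P<side>[LR])(?P<contact>\d{2})$")


@dataclass
class EpochRecording:
    """A multichannel recording epoch with per-channel metadata.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Raw signal block, one row per channel.
    sampling_rate : float
        Sampling rate in Hz.
    metadata : pandas.DataFrame
        One row per channel with columns ``label`` (e.g. ``"HiR01"``),
        ``electrode`` (e.g. ``"HiR"``), ``hemisphere`` (``"L"``/``"R"``),
        ``focal`` (bool, channel lies in the hemisphere of seizure onset) and
        ``resected`` (bool).
    provenance : dict
        Free-form provenance (patient id, seizure index, "preictal" tag ...).
    """

    signals: np.ndarray
    sampling_rate: float
    metadata: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D channels x samples array")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        missing = [c for c in _METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if len(self.metadata) != self.n_channels:
            raise ValueError(
                f"metadata has {len(self.metadata)} rows for "
                f"{self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def labels(self) -> list[str]:
        return list(self.metadata["label"])


def parse_channel_label(label: str) -> tuple[str, str, int]:
    """Split a label like ``"HiR03"`` into (electrode base, side, contact)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse channel label {label!r}")
    return m.group("electrode"), m.group("side"), int(m.group("contact"))


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_epoch_hdf5(epoch: EpochRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=epoch.signals)
        f.create_dataset("fs", data=float(epoch.sampling_rate))
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset("labels", data=list(epoch.metadata["label"]), dtype=str_dt)
        f.create_dataset(
            "electrode", data=list(epoch.metadata["electrode"]), dtype=str_dt
        )
        f.create_dataset(
            "hemisphere", data=list(epoch.metadata["hemisphere"]), dtype=str_dt
        )
        f.create_dataset("focal", data=np.asarray(epoch.metadata["focal"], bool))
        f.create_dataset("resected", data=np.asarray(epoch.metadata["resected"], bool))
        f.attrs["provenance"] = json.dumps(epoch.provenance)


def read_epoch_hdf5(path) -> EpochRecording:
    with h5py.File(path, "r") as f:
        signals = f["signals"][()]
        fs = float(f["fs"][()])
        meta = pd.DataFrame(
            {
                "label": [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]],
                "electrode": [s.decode() if isinstance(s, bytes) else s for s in f["electrode"][()]],
                "hemisphere": [s.decode() if isinstance(s, bytes) else s for s in f["hemisphere"][()]],
                "focal": f["focal"][()].astype(bool),
                "resected": f["resected"][()].astype(bool),
            }
        )
        prov = json.loads(f.attrs.get("provenance", "{}"))
    return EpochRecording(signals, fs, meta, prov)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_epoch_edf(epoch: EpochRecording, path) -> None:
    """Write a plain EDF (16-bit) file.

    Minimal writer: one data record per second, all channels at the epoch
    sampling rate, physical range spanning each channel's data.  Values are
    quantized to 16 bits, so round-trips are exact only to the quantization
    step (range / 65534).
    """
    fs = epoch.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = epoch.n_channels
    n_rec, rem = divmod(epoch.n_samples, fs)
    if rem:
        raise ValueError("EDF export requires a whole number of 1 s records")

    phys_min = epoch.signals.min(axis=1)
    phys_max = epoch.signals.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig_min, dig_max = -32767, 32767
    scale = (dig_max - dig_min) / span
    digital = np.round(
        (epoch.signals - phys_min[:, None]) * scale[:, None] + dig_min
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id (anonymous)
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration (s)
            pad(str(n_ch), 4),
        ]
    )
    labels = [pad(lab, 16) for lab in epoch.metadata["label"]]
    fields = [
        b"".join(labels),
        b"".join(pad("iEEG", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_min),
        b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_max),
        b"".join(pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(str(fs), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as f:
        f.write(header)
        for blob in fields:
            f.write(blob)
        for r in range(n_rec):
            f.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_epoch_edf(path, metadata: pd.DataFrame | None = None) -> EpochRecording:
    """Read an EDF file via MNE, optionally attaching channel metadata.

    Without an explicit metadata table, hemisphere/electrode fields are parsed
    from channel labels of the ``AmR01`` form; focal/resected flags default to
    False.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signals = raw.get_data() * 1e6  # MNE converts uV to V on read
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    if metadata is None:
        rows = []
        for lab in labels:
            electrode, side, _ = parse_channel_label(lab)
            rows.append(
                {
                    "label": lab,
                    "electrode": f"{electrode}{side}",
                    "hemisphere": side,
                    "focal": False,
                    "resected": False,
                }
            )
        metadata = pd.DataFrame(rows)
    else:
        metadata = align_metadata(labels, metadata)
    return EpochRecording(signals, fs, metadata, {"source": str(path)})


def align_metadata(labels: list[str], metadata: pd.DataFrame) -> pd.DataFrame:
    """Match a metadata table to recorded channels by label, in signal order."""
    missing = [c for c in _METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    table = metadata.set_index("label", drop=False)
    unmatched = [lab for lab in labels if lab not in table.index]
    if unmatched:
        raise ValueError(f"channels without metadata: {unmatched}")
    return table.loc[labels].reset_index(drop=True)


def read_epoch(path, metadata_path=None) -> EpochRecording:
    """Read an epoch from HDF5 or EDF, with optional external metadata.

    ``metadata_path`` may point at a CSV or JSON table with columns
    ``label, electrode, hemisphere, focal, resected``.
    """
    path = str(path)
    metadata = None
    if metadata_path is not None:
        mp = str(metadata_path)
        if mp.endswith(".json"):
            metadata = pd.read_json(mp)
        else:
            metadata = pd.read_csv(mp)
    if path.endswith((".h5", ".hdf5")):
        epoch = read_epoch_hdf5(path)
        if metadata is not None:
            epoch.metadata = align_metadata(epoch.labels, metadata)
        return epoch
    if path.endswith(".edf"):
        return read_epoch_edf(path, metadata)
    raise ValueError(f"unrecognized epoch format: {path}")
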