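"""Reading and writing multichannel EEG recordings.

Two on-disk formats are supported: plain ASCII sample matrices
(tab-separated, one column per channel, header row of electrode labels)
and EDF/EDF+. EDF files are read through MNE; writing uses a small
built-in EDF writer (16-bit integer encoding, one data record per
second) because no dedicated EDF-writing library is part of the stack.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .montage import normalize_label


@dataclass
class EEGRecording:
    """A channels x samples EEG matrix with sampling rate and labels.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in samples per second.
    labels : list of str
        Electrode names (canonical 10-20 spelling), one per row.
    """

    samples: np.ndarray
    rate: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.rate

    def pick(self, labels: list[str]) -> "EEGRecording":
        """Return a copy restricted to ``labels`` in the given order."""
        idx = [self.labels.index(l) for l in labels]
        return EEGRecording(self.samples[idx].copy(), self.rate, list(labels))


def write_ascii(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a tab-separated matrix, channels as columns."""
    header = "\t".join(rec.labels)
    np.savetxt(path, rec.samples.T, delimiter="\t", header=header, comments="",
               fmt="%.6f")


def read_ascii(path: str | Path, rate: float = 500.0) -> EEGRecording:
    """Read a tab-separated sample matrix with a header row of labels.

    The ASCII format carries no rate metadata; ``rate`` supplies it
    (default 500 samples/s, the acquisition rate of the target setting).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    labels = [normalize_label(l) for l in header.split("\t")]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate electrode labels in {path}")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] != len(labels):
        raise ValueError("column count does not match header labels")
    return EEGRecording(data.T, rate, labels)


# ---------------------------------------------------------------------------
# EDF

_EDF_HEADER = struct.Struct("<8s80s80s8s8s8s44s8s8s4s")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit), one data record per second.

    A trailing partial second is dropped (EDF records have fixed length).
    Physical scaling is chosen per channel from the data range.
    """
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per record (1 s records)
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels
    data = rec.samples[:, : n_rec * spr]

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    flat = pmax <= pmin
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768.0, 32767.0
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    now = datetime(2000, 1, 1)
    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate X X X X", 80),
        pad(now.strftime("%d.%m.%y"), 8),
        pad(now.strftime("%H.%M.%S"), 8),
        pad(str(256 + ns * 256), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])

    def col(values: list[str], width: int) -> bytes:
        return b"".join(pad(v, width) for v in values)

    header += col([f"EEG {l}" for l in rec.labels], 16)       # labels
    header += col(["AgAgCl electrode"] * ns, 80)              # transducer
    header += col(["uV"] * ns, 8)                             # physical dim
    header += col([f"{v:.1f}" for v in pmin], 8)              # physical min
    header += col([f"{v:.1f}" for v in pmax], 8)              # physical max
    header += col([f"{dmin:.0f}"] * ns, 8)                    # digital min
    header += col([f"{dmax:.0f}"] * ns, 8)                    # digital max
    header += col([""] * ns, 80)                              # prefiltering
    header += col([str(spr)] * ns, 8)                         # samples/record
    header += col([""] * ns, 32)                              # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file through MNE and normalize the channel labels."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [normalize_label(ch) for ch in raw.ch_names]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate electrode labels in {path}")
    # MNE converts EEG channels to volts; the package works in microvolts.
    return EEGRecording(raw.get_data() * 1e6, float(raw.info["sfreq"]), labels)


def read_recording(path: str | Path, format: str | None = None,
                   rate: float = 500.0) -> EEGRecording:
    """Read a recording from ``path``.

    ``format`` is ``"edf"`` or ``"ascii"``; if omitted it is inferred from
    the file suffix. ``rate`` applies to ASCII input only.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "ascii"
    if format == "edf":
        return read_edf(path)
    if format == "ascii":
        return read_ascii(path, rate=rate)
    raise ValueError(f"unsupported recording format: {format!r}")
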