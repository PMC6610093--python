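"""Phase lag index (PLI) functional connectivity.

The PLI between two signals is the absolute mean sign of their wrapped
instantaneous phase differences, obtained from the analytic signal
(Hilbert transform). It ranges from 0 (symmetric phase differences, or
consistent zero lag) to 1 (a fixed-sign lag on every sample), and by
construction discounts zero-lag coupling such as volume conduction:
sign(0) contributes 0, so identical signals score exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochSet


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band PLI matrix over electrodes.

    Entries live in [0, 1] with a zero diagonal.
    """

    values: np.ndarray
    labels: list[str]
    band: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectivity diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLI values must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal at each sample, in (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    if np.all(x == 0):
        raise ValueError("phase of the all-zero series is undefined")
    return np.angle(hilbert(x))


def pli_from_phases(phi_x: np.ndarray, phi_y: np.ndarray,
                    trim: int = 0) -> float:
    """PLI from two instantaneous-phase series.

    Phase differences are wrapped to (-pi, pi] before taking signs, so
    the sign reflects lead/lag direction rather than unwrapped drift.
    ``trim`` drops that many samples at each end (Hilbert edge effects);
    0 by default since analysis epochs are long.
    """
    phi_x = np.asarray(phi_x, dtype=float)
    phi_y = np.asarray(phi_y, dtype=float)
    if phi_x.shape != phi_y.shape:
        raise ValueError("phase series length mismatch")
    dphi = np.angle(np.exp(1j * (phi_x - phi_y)))
    if trim:
        dphi = dphi[trim:-trim]
    return float(abs(np.mean(np.sign(dphi))))


def pli_pair(x: np.ndarray, y: np.ndarray, trim: int = 0) -> float:
    """PLI between two equal-length time series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("time series length mismatch")
    return pli_from_phases(instantaneous_phase(x), instantaneous_phase(y),
                           trim=trim)


def pli_matrix(epoch: np.ndarray, labels: list[str],
               band: str | None = None, trim: int = 0) -> ConnectivityMatrix:
    """PLI over every unordered channel pair of one epoch.

    ``epoch`` is channels x samples. All analytic phases are computed in
    one vectorised Hilbert pass.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 channels")
    zero_rows = np.flatnonzero(np.all(epoch == 0, axis=1))
    if zero_rows.size:
        bad = ", ".join(labels[i] for i in zero_rows)
        raise ValueError(f"phase undefined for all-zero channel(s): {bad}")
    phases = np.angle(hilbert(epoch, axis=1))
    n = epoch.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        dphi = np.angle(np.exp(1j * (phases[i, None, :] - phases[i + 1 :, :])))
        if trim:
            dphi = dphi[:, trim:-trim]
        values[i, i + 1 :] = np.abs(np.mean(np.sign(dphi), axis=1))
    values += values.T
    return ConnectivityMatrix(values, list(labels), band=band)


def average_matrices(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of PLI matrices with identical labels."""
    if not mats:
        raise ValueError("cannot average an empty list of matrices")
    first = mats[0]
    for m in mats[1:]:
        if m.labels != first.labels:
            raise ValueError("matrices carry different electrode labels")
    mean = np.mean([m.values for m in mats], axis=0)
    return ConnectivityMatrix(mean, list(first.labels), band=first.band)


def global_pli(mat: ConnectivityMatrix) -> float:
    """Grand mean PLI: average of the strict upper triangle."""
    if mat.n < 2:
        raise ValueError("global PLI needs >= 2 channels")
    iu = np.triu_indices(mat.n, k=1)
    return float(mat.values[iu].mean())


def epochs_pli(epochs: EpochSet, trim: int = 0) -> list[ConnectivityMatrix]:
    """Per-epoch PLI matrices for an epoch set."""
    return [pli_matrix(e, epochs.labels, band=epochs.band, trim=trim)
            for e in epochs.data]
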