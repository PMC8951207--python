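"""Instantaneous phase and the phase lag index (PLI).

The PLI between two signals is ``|< sign(sin(phase_j - phase_k)) >|``: the
absolute mean, over time, of the sign of the sine of their phase difference.
It measures the *asymmetry* of the phase-difference distribution, so coupling
at exactly zero (or pi) lag -- the signature of volume conduction -- does not
contribute.  Values lie in [0, 1]; 1 means a fixed nonzero lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .preprocess import Band, EpochSet

__all__ = ["PhaseEpochs", "PLIMatrix", "instantaneous_phase", "pli_pair", "pli_matrix"]


@dataclass(frozen=True)
class PhaseEpochs:
    """Analytic-signal phases, radians in (-pi, pi], shape (n_epochs, channels, samples)."""

    phases: np.ndarray
    fs: float
    band: Band | None = None

    def __post_init__(self):
        ph = np.asarray(self.phases, dtype=np.float64)
        if ph.ndim != 3:
            raise ValueError("phases must be 3-D (n_epochs, channels, samples)")
        object.__setattr__(self, "phases", ph)


@dataclass(frozen=True)
class PLIMatrix:
    """Symmetric channel x channel PLI matrix with zero diagonal, entries in [0, 1]."""

    values: np.ndarray
    labels: tuple[str, ...]
    band: Band | None = None
    n_epochs_used: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLI matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("PLI matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("PLI matrix diagonal must be zero")
        if v.min(initial=0.0) < -1e-12 or v.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("PLI values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))


def instantaneous_phase(epochs: EpochSet) -> PhaseEpochs:
    """Phase of the analytic (Hilbert) signal, per channel and sample.

    Input should be narrowband for the analytic phase to be meaningful.
    All-zero channels (phase undefined) are flagged with a warning.
    """
    data = epochs.epochs
    if data.size == 0:
        raise ValueError("no epochs to compute phases from")
    flat = np.abs(data).max(axis=2) == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} all-zero channel-epochs: analytic phase undefined there",
            stacklevel=2,
        )
    return PhaseEpochs(np.angle(hilbert(data, axis=2)), epochs.fs, epochs.band)


def pli_pair(phase_j: np.ndarray, phase_k: np.ndarray) -> float:
    """PLI of two equal-length phase series; sin exactly 0 contributes 0."""
    phase_j = np.asarray(phase_j, dtype=np.float64)
    phase_k = np.asarray(phase_k, dtype=np.float64)
    if phase_j.shape != phase_k.shape:
        raise ValueError("phase series must have equal length")
    if phase_j.size == 0:
        raise ValueError("empty phase series")
    return float(np.abs(np.mean(np.sign(np.sin(phase_j - phase_k)))))


def _epoch_pli(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLI for one epoch of phases (channels x samples).

    Uses sign(sin(a-b)) = sign(sin a cos b - cos a sin b) to avoid forming the
    channel x channel x time phase-difference tensor twice.
    """
    s, c = np.sin(phases), np.cos(phases)
    cross = s[:, None, :] * c[None, :, :] - c[:, None, :] * s[None, :, :]
    return np.abs(np.mean(np.sign(cross), axis=2))


def pli_matrix(
    epochs: EpochSet,
    *,
    channels: Sequence[str] | None = None,
    edge_trim: float = 0.1,
) -> PLIMatrix:
    """PLI matrix of an epoch set: per-epoch PLI averaged across epochs.

    Parameters
    ----------
    channels
        If given, the epochs are restricted to these labels (in this order);
        missing labels raise.  Used by the pipeline to enforce the canonical
        20-electrode node set.
    edge_trim
        Fraction of samples discarded at each epoch edge before the PLI, to
        suppress Hilbert end transients.
    """
    if epochs.n_epochs < 1:
        raise ValueError("PLI requires at least one retained epoch")
    labels = tuple(epochs.montage.labels)
    data = epochs
    if channels is not None:
        missing = [ch for ch in channels if ch not in labels]
        if missing:
            raise ValueError(f"missing canonical channels: {missing}")
        idx = [epochs.montage.index(ch) for ch in channels]
        sub = epochs.montage.subset(channels)
        data = EpochSet(
            epochs.epochs[:, idx, :], epochs.fs, sub, band=epochs.band,
            kept_mask=epochs.kept_mask, provenance=epochs.provenance,
        )
        labels = tuple(channels)
    phases = instantaneous_phase(data).phases
    trim = int(edge_trim * phases.shape[2])
    if trim:
        phases = phases[:, :, trim:phases.shape[2] - trim]
    mats = np.stack([_epoch_pli(p) for p in phases])
    values = mats.mean(axis=0)
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)
    return PLIMatrix(values, labels, band=data.band, n_epochs_used=data.n_epochs)
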