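"""Preprocessing of continuous EEG into band-limited, spatially filtered epochs.

The pipeline order mirrors standard resting-state practice: zero-phase FIR
band-pass (0.5-45 Hz) with a 50 Hz notch, narrowband filtering into the
analysis band, segmentation into non-overlapping 2-s epochs, average-reference
re-referencing, anti-aliased downsampling to 512 Hz, +/-80 uV amplitude-based
epoch rejection, and a Hjorth nearest-neighbour surface Laplacian.  Every
:class:`EpochSet` carries a provenance trail of the steps applied to it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .montage import Montage, default_montage

__all__ = [
    "Band", "DEFAULT_BANDS", "Recording", "EpochSet",
    "bandpass", "notch", "segment", "rereference_average",
    "downsample", "reject_amplitude", "laplacian", "preprocess_recording",
]


@dataclass(frozen=True)
class Band:
    """A named frequency interval in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"invalid band {self.name}: {self.f_low}-{self.f_high} Hz")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def width(self) -> float:
        return self.f_high - self.f_low


#: Standard clinical split of the 0.5-45 Hz range into seven bands.
DEFAULT_BANDS: dict[str, Band] = {
    b.name: b
    for b in (
        Band("delta", 0.5, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha1", 8.0, 10.0),
        Band("alpha2", 10.0, 13.0),
        Band("beta1", 13.0, 20.0),
        Band("beta2", 20.0, 30.0),
        Band("gamma", 30.0, 45.0),
    )
}


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel signal in microvolts.

    ``data`` has shape ``(n_channels, n_samples)`` with rows ordered as
    ``montage.labels``.
    """

    data: np.ndarray
    fs: float
    montage: Montage

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {data.shape[0]} rows but montage has {self.montage.n_channels} labels"
            )
        if not np.isfinite(data).all():
            raise ValueError("recording data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class EpochSet:
    """Fixed-length epochs: array of shape (n_epochs, n_channels, n_samples).

    ``kept_mask`` records, over the originally segmented epochs, which ones
    survived rejection.  ``provenance`` lists the processing steps applied.
    """

    epochs: np.ndarray
    fs: float
    montage: Montage
    band: Band | None = None
    kept_mask: np.ndarray | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        ep = np.asarray(self.epochs, dtype=np.float64)
        if ep.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, channels, samples)")
        if ep.shape[1] != self.montage.n_channels:
            raise ValueError("epoch channel count does not match montage")
        mask = self.kept_mask
        if mask is None:
            mask = np.ones(ep.shape[0], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if int(mask.sum()) != ep.shape[0]:
            raise ValueError("kept_mask must have exactly n_epochs True entries")
        object.__setattr__(self, "epochs", ep)
        object.__setattr__(self, "kept_mask", mask)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]

    def with_step(self, step: str, **changes) -> "EpochSet":
        return replace(self, provenance=self.provenance + (step,), **changes)


# ----------------------------------------------------------------------------
# FIR filtering helpers
# ----------------------------------------------------------------------------

def _fir_kernel(fs: float, f_low: float | None, f_high: float | None,
                transition: float, pass_zero) -> np.ndarray:
    """Linear-phase Hamming FIR kernel; odd length for an integer group delay."""
    numtaps = int(math.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # force odd
    edges = [f for f in (f_low, f_high) if f is not None]
    return sps.firwin(numtaps, edges, pass_zero=pass_zero, window="hamming", fs=fs)


def _zero_phase_filter(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with exact group-delay compensation.

    Reflect-padding keeps the edges usable; the convolution runs in the
    frequency domain so long kernels (narrow transitions) stay cheap.
    """
    ntaps = kernel.size
    half = ntaps // 2
    n = data.shape[-1]
    pad = min(half, n - 1)
    padded = np.concatenate(
        [data[..., 1:pad + 1][..., ::-1], data, data[..., -pad - 1:-1][..., ::-1]], axis=-1
    )
    out = sps.fftconvolve(padded, kernel[np.newaxis, :], mode="same", axes=-1)
    return np.ascontiguousarray(out[..., pad:pad + n])


def bandpass(recording: Recording, f_low: float, f_high: float) -> Recording:
    """Zero-phase FIR band-pass filter.

    The transition width is 25% of the lower band edge (floored at 0.4 Hz so
    kernels stay shorter than typical recordings); stop-band attenuation of the
    Hamming design is ~53 dB.
    """
    nyq = recording.fs / 2.0
    if not (0 < f_low < f_high < nyq):
        raise ValueError(f"band {f_low}-{f_high} Hz outside (0, Nyquist={nyq}) range")
    transition = max(0.4, 0.25 * f_low)
    kernel = _fir_kernel(recording.fs, f_low, f_high, transition, pass_zero=False)
    if kernel.size >= recording.n_samples:
        raise ValueError(
            f"recording too short ({recording.n_samples} samples) for a "
            f"{kernel.size}-tap filter at band {f_low}-{f_high} Hz"
        )
    return replace(recording, data=_zero_phase_filter(recording.data, kernel))


def notch(recording: Recording, freq: float = 50.0, width: float = 4.0) -> Recording:
    """Zero-phase FIR band-stop (notch) filter centred on `freq`."""
    nyq = recording.fs / 2.0
    lo, hi = freq - width / 2.0, freq + width / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"notch {lo}-{hi} Hz outside (0, Nyquist={nyq}) range")
    kernel = _fir_kernel(recording.fs, lo, hi, transition=1.0, pass_zero=True)
    return replace(recording, data=_zero_phase_filter(recording.data, kernel))


# ----------------------------------------------------------------------------
# Epoching and spatial operations
# ----------------------------------------------------------------------------

def segment(recording: Recording, epoch_len_s: float = 2.0, band: Band | None = None) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing partial segment is dropped.  Raises if the recording is
    shorter than one epoch.
    """
    spe = int(round(epoch_len_s * recording.fs))
    if recording.n_samples < spe:
        raise ValueError(
            f"recording of {recording.duration_s:.3f} s is shorter than one "
            f"{epoch_len_s} s epoch"
        )
    n_epochs = recording.n_samples // spe
    ep = recording.data[:, : n_epochs * spe].reshape(recording.montage.n_channels, n_epochs, spe)
    ep = np.ascontiguousarray(np.swapaxes(ep, 0, 1))
    return EpochSet(
        ep, recording.fs, recording.montage, band=band,
        kept_mask=np.ones(n_epochs, dtype=bool),
        provenance=(f"segment({epoch_len_s}s)",),
    )


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous average over channels (idempotent)."""
    if epochs.montage.n_channels < 2:
        raise ValueError("average reference requires at least two channels")
    data = epochs.epochs - epochs.epochs.mean(axis=1, keepdims=True)
    return epochs.with_step("rereference_average", epochs=data)


def downsample(obj: Recording | EpochSet, target_fs: float = 512.0):
    """Anti-aliased downsampling (polyphase resampling) to `target_fs`."""
    if target_fs > obj.fs:
        raise ValueError(f"cannot upsample from {obj.fs} to {target_fs} Hz")
    if target_fs == obj.fs:
        return obj
    frac = Fraction(target_fs / obj.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if isinstance(obj, Recording):
        data = sps.resample_poly(obj.data, up, down, axis=-1)
        return replace(obj, data=data, fs=target_fs)
    data = sps.resample_poly(obj.epochs, up, down, axis=-1)
    return obj.with_step(f"downsample({target_fs}Hz)", epochs=data, fs=target_fs)


def reject_amplitude(epochs: EpochSet, limit_uv: float = 80.0) -> EpochSet:
    """Drop epochs whose absolute amplitude exceeds `limit_uv` on any channel."""
    if limit_uv <= 0:
        raise ValueError("rejection limit must be positive")
    ok = np.abs(epochs.epochs).max(axis=(1, 2)) <= limit_uv
    mask = epochs.kept_mask.copy()
    mask[np.flatnonzero(mask)] = ok
    if not ok.any():
        warnings.warn("amplitude rejection removed every epoch", stacklevel=2)
    return epochs.with_step(
        f"reject_amplitude({limit_uv}uV)", epochs=epochs.epochs[ok], kept_mask=mask
    )


def laplacian(epochs: EpochSet, montage: Montage | None = None) -> EpochSet:
    """Hjorth nearest-neighbour surface Laplacian.

    Each channel is replaced by itself minus the mean of its montage
    neighbours, attenuating spatially common (volume-conducted) activity.
    """
    montage = montage or epochs.montage
    n = montage.n_channels
    op = np.eye(n)
    for i, lab in enumerate(montage.labels):
        ns = montage.neighbors[lab]
        if not ns:
            raise ValueError(f"channel {lab} has no neighbors; Laplacian undefined")
        for other in ns:
            op[i, montage.index(other)] -= 1.0 / len(ns)
    data = np.einsum("ij,ejs->eis", op, epochs.epochs)
    return epochs.with_step("laplacian", epochs=data)


def preprocess_recording(
    recording: Recording,
    band: Band,
    *,
    broadband: tuple[float, float] = (0.5, 45.0),
    notch_freq: float | None = 50.0,
    epoch_len_s: float = 2.0,
    target_fs: float = 512.0,
    reject_uv: float | None = 80.0,
    apply_laplacian: bool = True,
) -> EpochSet:
    """Full preprocessing chain for one analysis band.

    Order: broadband filter + notch -> narrowband filter -> segment ->
    average reference -> downsample -> amplitude rejection -> Laplacian.
    """
    rec = bandpass(recording, *broadband)
    if notch_freq is not None and notch_freq < recording.fs / 2.0 - 2.0:
        rec = notch(rec, notch_freq)
    rec = bandpass(rec, band.f_low, band.f_high)
    epochs = segment(rec, epoch_len_s, band=band)
    epochs = rereference_average(epochs)
    epochs = downsample(epochs, target_fs)
    if reject_uv is not None and math.isfinite(reject_uv):
        epochs = reject_amplitude(epochs, reject_uv)
    if apply_laplacian:
        epochs = laplacian(epochs)
    return epochs
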