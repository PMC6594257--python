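"""Welch spectra, relative power, band summaries, and the cross-spectral matrix.

Spectra follow the acquisition convention of the study design they serve:
Hann-windowed Welch averaging with 512-sample blocks, which at a 512 Hz
sampling rate gives exactly 1.0 Hz bins.  Power is reported as *relative*
power — each channel's spectrum normalized to unit sum over the 1–256 Hz
analysis range — so electrode-impedance and gain differences between
animals cancel.

Frequency-band conventions: summed band powers use half-open intervals
[lo, hi) so adjacent bands (4–6, 6–8 Hz) partition without double counting;
the theta center of mass uses the inclusive band [lo, hi] (the midpoint of a
flat spectrum over 4–12 Hz is then exactly 8 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import EpochSet

__all__ = [
    "PowerSpectrum",
    "RelativePowerSpectrum",
    "SpectralMatrix",
    "welch_psd",
    "relative_power",
    "band_power",
    "theta_center_of_mass",
    "cross_spectral_matrix",
]


@dataclass
class PowerSpectrum:
    """Welch power spectral density per channel.

    ``power`` has shape (n_freqs, n_channels) in µV²/Hz; ``freqs`` is the
    uniform grid with step fs/nperseg.
    """

    freqs: np.ndarray
    power: np.ndarray
    channels: list[str]
    fs: float
    nperseg: int
    n_blocks_averaged: int

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


@dataclass
class RelativePowerSpectrum:
    """Per-channel power as a fraction of total power over ``norm_band``."""

    freqs: np.ndarray
    relpower: np.ndarray
    channels: list[str]
    norm_band: tuple[float, float]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


@dataclass
class SpectralMatrix:
    """Auto/cross-spectra between all channel pairs.

    ``S`` has shape (n_freqs, n_channels, n_channels); Hermitian at every
    frequency with real non-negative diagonal.
    """

    freqs: np.ndarray
    S: np.ndarray
    channels: list[str]
    fs: float
    nperseg: int
    n_blocks_averaged: int

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


def _welch_params(epochs: EpochSet, nperseg: int, overlap_frac: float):
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    if epochs.epoch_len < nperseg:
        raise ValueError(
            f"epoch length {epochs.epoch_len} shorter than nperseg={nperseg}"
        )
    noverlap = int(round(nperseg * overlap_frac))
    step = nperseg - noverlap
    blocks_per_epoch = (epochs.epoch_len - nperseg) // step + 1
    return noverlap, blocks_per_epoch


def welch_psd(
    epochs: EpochSet,
    nperseg: int = 512,
    window: str = "hann",
    overlap_frac: float = 0.5,
) -> PowerSpectrum:
    """Welch PSD averaged over all blocks of all epochs.

    The frequency step is fs/nperseg (1.0 Hz for fs=512, nperseg=512).
    """
    noverlap, bpe = _welch_params(epochs, nperseg, overlap_frac)
    freqs, psd = sps.welch(
        epochs.epochs,
        fs=epochs.fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        axis=1,
        detrend=False,
    )
    power = psd.mean(axis=0)  # (n_freqs, n_channels): equal-length epochs
    return PowerSpectrum(
        freqs, power, list(epochs.channels), epochs.fs, nperseg,
        bpe * epochs.n_epochs,
    )


def _band_mask(freqs: np.ndarray, lo: float, hi: float, inclusive: bool = False):
    if inclusive:
        return (freqs >= lo) & (freqs <= hi + 1e-12)
    return (freqs >= lo) & (freqs < hi - 1e-12)


def relative_power(
    ps: PowerSpectrum, norm_band: tuple[float, float] = (1.0, 256.0)
) -> RelativePowerSpectrum:
    """Normalize each channel's spectrum to unit sum over ``norm_band``.

    The normalization band follows the same half-open [lo, hi) convention as
    ``band_power``, so a band covering the whole normalization range sums to
    exactly 1.
    """
    lo, hi = norm_band
    mask = _band_mask(ps.freqs, lo, hi)
    if not mask.any():
        raise ValueError(f"norm_band {norm_band} outside the frequency grid")
    total = ps.power[mask].sum(axis=0)
    if np.any(total <= 0):
        bad = [ps.channels[i] for i in np.where(total <= 0)[0]]
        raise ValueError(f"zero total power in channels {bad}")
    rel = ps.power / total
    return RelativePowerSpectrum(ps.freqs, rel, list(ps.channels), (lo, hi))


def band_power(rel: RelativePowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Summed relative power over [lo, hi) per channel."""
    lo, hi = band
    mask = _band_mask(rel.freqs, lo, hi)
    if not mask.any():
        raise ValueError(f"band {band} selects no frequency bins")
    return rel.relpower[mask].sum(axis=0)


def theta_center_of_mass(
    ps: PowerSpectrum, band: tuple[float, float] = (4.0, 12.0)
) -> np.ndarray:
    """Power-weighted mean frequency Σ f·P(f) / Σ P(f) over [lo, hi], per channel.

    A leftward shift of the theta peak moves this center of mass down even
    when total theta power is unchanged.
    """
    lo, hi = band
    mask = _band_mask(ps.freqs, lo, hi, inclusive=True)
    if not mask.any():
        raise ValueError(f"band {band} selects no frequency bins")
    p = ps.power[mask]
    f = ps.freqs[mask]
    total = p.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("zero power in the theta band")
    return (f[:, None] * p).sum(axis=0) / total


def cross_spectral_matrix(
    epochs: EpochSet,
    nperseg: int = 512,
    window: str = "hann",
    overlap_frac: float = 0.5,
) -> SpectralMatrix:
    """Full matrix of Welch auto- and cross-spectra.

    Averaging at least two blocks is required: the coherence of a single
    block is identically 1 regardless of the data.
    """
    if len(epochs.channels) < 2:
        raise ValueError("cross-spectral matrix needs at least 2 channels")
    noverlap, bpe = _welch_params(epochs, nperseg, overlap_frac)
    n_blocks = bpe * epochs.n_epochs
    if n_blocks < 2:
        raise ValueError(
            "only one Welch block available: coherence of a single block is "
            "identically 1; use longer recordings or more epochs"
        )
    x = np.transpose(epochs.epochs, (0, 2, 1))  # (n_epochs, n_ch, n_samp)
    freqs, Pxy = sps.csd(
        x[:, :, None, :],
        x[:, None, :, :],
        fs=epochs.fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        axis=-1,
        detrend=False,
    )
    S = Pxy.mean(axis=0)                    # (n_ch, n_ch, n_freqs)
    S = np.moveaxis(S, -1, 0)               # (n_freqs, n_ch, n_ch)
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))  # enforce exact Hermitianity
    return SpectralMatrix(
        freqs, S, list(epochs.channels), epochs.fs, nperseg, n_blocks
    )
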