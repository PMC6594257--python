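"""Theta–gamma phase-amplitude coupling: modulation index and comodulograms.

The modulation index (MI) used here is the normalized mean-vector length

    MI = |⟨A_H(t) · exp(i·φ_L(t))⟩| / ⟨A_H(t)⟩ ,

where φ_L is the instantaneous phase of the slow (theta) band and A_H the
instantaneous amplitude envelope of the fast (gamma) band, both via the
Hilbert transform of narrowband-filtered signals.  Normalizing by the mean
envelope makes MI dimensionless in [0, 1] and invariant to electrode gain,
so values are comparable across channels and animals.  For a sinusoidally
modulated envelope A(t) ∝ (1 + m·cos φ) the population value is exactly m/2.

A comodulogram evaluates MI over a grid of (phase frequency f_L × amplitude
frequency f_H); phase and amplitude may come from the same electrode
(intrasite) or from two different electrodes (intersite).  The phase band is
f_L ± 1 Hz; the amplitude band is f_H ± max(5, f_L + 2) Hz — wide enough to
pass the modulation sidebands at f_H ± f_L, without which coupling is
invisible by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import AnalyticSeries, analytic, analytic_bank_complex
from .signal_io import EpochSet, MultichannelRecording

__all__ = [
    "Comodulogram",
    "PhaseAmplitudeCurve",
    "PacPhaseShift",
    "default_phase_grid",
    "default_amp_grid",
    "amp_halfwidth",
    "modulation_index",
    "comodulogram",
    "comodulogram_epochs",
    "mean_pac",
    "phase_amplitude_curve",
    "pac_phase_shift",
]

PHASE_HALFWIDTH = 1.0  # Hz, band half-width around each f_L


def default_phase_grid() -> np.ndarray:
    """Phase frequencies f_L: 2–12 Hz in steps of 2 Hz."""
    return np.arange(2.0, 12.0 + 1e-9, 2.0)


def default_amp_grid() -> np.ndarray:
    """Amplitude frequencies f_H: 10–200 Hz in steps of 5 Hz."""
    return np.arange(10.0, 200.0 + 1e-9, 5.0)


def amp_halfwidth(f_L: float) -> float:
    """Amplitude-band half-width: max(5, f_L + 2) Hz (passes sidebands)."""
    return max(5.0, f_L + 2.0)


@dataclass
class Comodulogram:
    """MI over a (phase-frequency × amplitude-frequency) grid.

    ``mi[i, j]`` is the modulation index at (phase_freqs[i], amp_freqs[j]).
    """

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray
    phase_channel: str
    amp_channel: str

    def __post_init__(self) -> None:
        if self.mi.shape != (len(self.phase_freqs), len(self.amp_freqs)):
            raise ValueError("mi shape inconsistent with grids")

    def argmax_cell(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.mi), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


@dataclass
class PhaseAmplitudeCurve:
    """Mean fast-band envelope per slow-band phase bin over [−π, π)."""

    bin_centers: np.ndarray
    mean_amp: np.ndarray
    n_per_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


@dataclass
class PacPhaseShift:
    """Preferred coupling phase: circular mean of the phase-amplitude curve.

    ``resultant_length`` near 0 marks a flat curve whose angle carries no
    information (``reliable`` is False then).
    """

    angle: float
    resultant_length: float
    reliable: bool = True


def modulation_index(
    phase_series: AnalyticSeries,
    amp_series: AnalyticSeries,
    valid: np.ndarray | None = None,
) -> float:
    """Normalized mean-vector-length MI of a (phase, amplitude) series pair.

    Transient-guard samples of either series are excluded; ``valid`` can
    additionally mask samples (e.g. artifact stretches) out of the average.
    """
    if phase_series.n_samples != amp_series.n_samples:
        raise ValueError(
            f"series length mismatch: {phase_series.n_samples} vs "
            f"{amp_series.n_samples}"
        )
    guard = max(phase_series.guard, amp_series.guard)
    n = phase_series.n_samples
    if 2 * guard >= n:
        raise ValueError("transient guards leave no valid samples")
    sl = slice(guard, n - guard)
    amp = amp_series.amplitude[sl]
    ph = phase_series.phase[sl]
    if valid is not None:
        keep = np.asarray(valid, bool)[sl]
        if not keep.any():
            raise ValueError("valid mask leaves no samples")
        amp = amp[keep]
        ph = ph[keep]
    mean_amp = amp.mean()
    if mean_amp <= 0:
        raise ValueError("zero amplitude envelope")
    z = np.mean(amp * np.exp(1j * ph))
    return float(abs(z) / mean_amp)


def _comodulogram_signals(
    phase_sig: np.ndarray,
    amp_sig: np.ndarray,
    fs: float,
    phase_grid: np.ndarray,
    amp_grid: np.ndarray,
    phase_halfwidth: float,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    # works on the complex analytic signals directly: e^{iφ} = z/|z| and
    # A = |z|, so MI per cell is |Σ u·A| / Σ A over guarded valid samples
    mi = np.zeros((len(phase_grid), len(amp_grid)))
    n = phase_sig.shape[0]
    vmask = None if valid is None else np.asarray(valid, float)
    phase_bands = [
        (f_L - phase_halfwidth, f_L + phase_halfwidth) for f_L in phase_grid
    ]
    phase_u = []
    for z, guard in analytic_bank_complex(phase_sig, fs, phase_bands):
        mag = np.abs(z)
        u = np.where(mag > 0, z / np.where(mag > 0, mag, 1.0), 0.0)
        phase_u.append((u, guard))
    # amplitude bands depend on (f_L, f_H); deduplicate before extraction
    cell_bands = {}
    for f_L in phase_grid:
        hw = amp_halfwidth(f_L)
        for f_H in amp_grid:
            # low-f_H corner cells: keep the band's lower edge positive
            hw_j = min(hw, f_H - 0.5)
            cell_bands[(f_H - hw_j, f_H + hw_j)] = None
    amp_bands = list(cell_bands)
    amp_env = {}
    for band, (z, guard) in zip(
        amp_bands, analytic_bank_complex(amp_sig, fs, amp_bands)
    ):
        a = np.abs(z)
        if vmask is not None:
            a = a * vmask
        amp_env[band] = (a, guard)
    for i, f_L in enumerate(phase_grid):
        hw = amp_halfwidth(f_L)
        u, g_ph = phase_u[i]
        for j, f_H in enumerate(amp_grid):
            hw_j = min(hw, f_H - 0.5)
            a, g_am = amp_env[(f_H - hw_j, f_H + hw_j)]
            g = max(g_ph, g_am)
            if 2 * g >= n:
                raise ValueError("transient guards leave no valid samples")
            sl = slice(g, n - g)
            denom = a[sl].sum()
            if denom <= 0:
                raise ValueError("zero amplitude envelope")
            mi[i, j] = abs(np.dot(u[sl], a[sl])) / denom
    return mi


def comodulogram(
    rec: MultichannelRecording,
    phase_channel: str,
    amp_channel: str,
    phase_grid: np.ndarray | None = None,
    amp_grid: np.ndarray | None = None,
    phase_halfwidth: float = PHASE_HALFWIDTH,
    valid: np.ndarray | None = None,
) -> Comodulogram:
    """MI grid for one (phase-source, amplitude-source) channel pair,
    computed over the whole (continuous) recording.

    ``phase_channel == amp_channel`` gives the intrasite comodulogram;
    distinct channels give the intersite one.  ``valid`` masks samples
    (e.g. artifact stretches) out of the MI average without breaking the
    filtering continuity.
    """
    phase_grid = default_phase_grid() if phase_grid is None else np.asarray(phase_grid, float)
    amp_grid = default_amp_grid() if amp_grid is None else np.asarray(amp_grid, float)
    nyq = rec.fs / 2
    if (phase_grid + phase_halfwidth).max() >= nyq:
        raise ValueError("phase grid extends beyond Nyquist")
    if max(f + amp_halfwidth(phase_grid.max()) for f in amp_grid) >= nyq:
        raise ValueError("amplitude grid (plus band half-width) extends beyond Nyquist")
    if np.any(np.diff(phase_grid) <= 0) or np.any(np.diff(amp_grid) <= 0):
        raise ValueError("grids must be sorted ascending")
    mi = _comodulogram_signals(
        rec.get_channel(phase_channel),
        rec.get_channel(amp_channel),
        rec.fs,
        phase_grid,
        amp_grid,
        phase_halfwidth,
        valid,
    )
    return Comodulogram(phase_grid, amp_grid, mi, phase_channel, amp_channel)


def comodulogram_epochs(
    epochs: EpochSet,
    phase_channel: str,
    amp_channel: str,
    phase_grid: np.ndarray | None = None,
    amp_grid: np.ndarray | None = None,
    phase_halfwidth: float = PHASE_HALFWIDTH,
) -> Comodulogram:
    """Per-epoch comodulograms averaged across epochs.

    The per-epoch estimate respects epoch boundaries (no phase continuity is
    assumed across artifact gaps); the average over epochs is the session
    value used as the unit of analysis per animal.
    """
    phase_grid = default_phase_grid() if phase_grid is None else np.asarray(phase_grid, float)
    amp_grid = default_amp_grid() if amp_grid is None else np.asarray(amp_grid, float)
    pi = epochs.channel_index(phase_channel)
    ai = epochs.channel_index(amp_channel)
    acc = np.zeros((len(phase_grid), len(amp_grid)))
    for e in range(epochs.n_epochs):
        acc += _comodulogram_signals(
            epochs.epochs[e, :, pi],
            epochs.epochs[e, :, ai],
            epochs.fs,
            phase_grid,
            amp_grid,
            phase_halfwidth,
        )
    return Comodulogram(
        phase_grid, amp_grid, acc / epochs.n_epochs, phase_channel, amp_channel
    )


def mean_pac(
    c: Comodulogram,
    phase_window: tuple[float, float],
    amp_window: tuple[float, float],
) -> float:
    """Unweighted mean MI over grid cells whose center lies in both windows.

    Window bounds are closed, so the theta–gamma window 3.5–12.5 × 32–100 Hz
    on the default grid selects phase cells {4, 6, 8, 10, 12} and amplitude
    cells {35, 40, ..., 100}.
    """
    pmask = (c.phase_freqs >= phase_window[0]) & (c.phase_freqs <= phase_window[1])
    amask = (c.amp_freqs >= amp_window[0]) & (c.amp_freqs <= amp_window[1])
    if not pmask.any() or not amask.any():
        raise ValueError(
            f"windows {phase_window} × {amp_window} select no grid cells"
        )
    return float(c.mi[np.ix_(pmask, amask)].mean())


def phase_amplitude_curve(
    phase_series: AnalyticSeries,
    amp_series: AnalyticSeries,
    n_bins: int = 6,
    valid: np.ndarray | None = None,
) -> PhaseAmplitudeCurve:
    """Mean fast-band envelope in equal-width phase bins over [−π, π).

    Six bins of width 2π/6 ≈ 1.05 rad approximate "radian-wide" bins while
    tiling the circle exactly.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 phase bins")
    if phase_series.n_samples != amp_series.n_samples:
        raise ValueError("series length mismatch")
    guard = max(phase_series.guard, amp_series.guard)
    sl = slice(guard, phase_series.n_samples - guard)
    phase = phase_series.phase[sl]
    amp = amp_series.amplitude[sl]
    if valid is not None:
        keep = np.asarray(valid, bool)[sl]
        phase = phase[keep]
        amp = amp[keep]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    n_per_bin = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    mean_amp = np.full(n_bins, np.nan)
    nz = n_per_bin > 0
    mean_amp[nz] = sums[nz] / n_per_bin[nz]
    if (~nz).any() and phase.size >= 100 * n_bins:
        warnings.warn(
            f"{(~nz).sum()} empty phase bins despite {phase.size} samples",
            stacklevel=2,
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PhaseAmplitudeCurve(centers, mean_amp, n_per_bin)


def pac_phase_shift(curve: PhaseAmplitudeCurve) -> PacPhaseShift:
    """Circular mean direction of the phase-amplitude curve.

    The angle is where the envelope peaks along the slow-wave cycle; the
    resultant length measures how concentrated the curve is (0 = flat).
    """
    ok = np.isfinite(curve.mean_amp)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-empty phase bins")
    amp = curve.mean_amp[ok]
    if np.all(amp <= 0):
        raise ValueError("all-zero phase-amplitude curve")
    vec = np.sum(amp * np.exp(1j * curve.bin_centers[ok]))
    total = amp.sum()
    r = float(abs(vec) / total)
    angle = float(np.angle(vec))
    return PacPhaseShift(angle, r, reliable=r > 1e-3)
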