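"""Coherence, partial coherence, network efficiency, and directed coherence.

All measures derive from the cross-spectral matrix S(f) or from a fitted
multivariate autoregressive (MVAR) model:

* magnitude-squared coherence  Coh_AB(f) = |S_AB|² / (S_AA·S_BB) ∈ [0, 1];
* partial coherence  |M_AB| / √(M_AA·M_BB), with M_XY the minor of S(f)
  after deleting row X and column Y — coherence that survives after the
  linear influence of every other recorded channel is removed;
* global efficiency Eglob: electrodes form a graph weighted by band-mean
  coherence; with edge distance 1/weight, Eglob is the mean inverse
  shortest-path distance over all electrode pairs (1 = fully synchronous
  network, 0 = disconnected);
* generalized ("extended") partial directed coherence from the MVAR
  coefficients: the noise-variance-weighted, column-normalized magnitude of
  Ā(f) = I − Σ_k A_k e^{−2πifk/fs}, measuring directed influence j→i per
  frequency while excluding paths through the other modelled channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .signal_io import EpochSet
from .spectral import SpectralMatrix, _band_mask

__all__ = [
    "CoherenceFunction",
    "CoherenceGraph",
    "MVARModel",
    "DirectedCoherence",
    "coherence",
    "coherence_matrix",
    "coherence_graph",
    "global_efficiency",
    "partial_coherence",
    "fit_mvar",
    "extended_pdc",
    "band_mean_pdc",
]


@dataclass
class CoherenceFunction:
    """Frequency-resolved coherence (or partial coherence) of a channel pair."""

    freqs: np.ndarray
    coh: np.ndarray
    pair: tuple[str, str]
    kind: str = "coherence"  # or 'partial'


@dataclass
class CoherenceGraph:
    """Electrode graph weighted by band-mean coherence (symmetric, diag 1)."""

    nodes: list[str]
    weights: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape inconsistent with nodes")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        self.weights = w


@dataclass
class MVARModel:
    """Stable MVAR(p): x(t) = Σ_k A_k x(t−k) + ε(t), ε ~ N(0, Sigma)."""

    coeffs: np.ndarray        # (p, n, n)
    sigma: np.ndarray         # (n, n) innovation covariance
    fs: float
    channels: list[str]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion_spectral_radius(self) -> float:
        p, n, _ = self.coeffs.shape
        top = np.concatenate(list(self.coeffs.transpose(0, 1, 2)), axis=1)
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = top.reshape(n, n * p)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self) -> bool:
        return self.companion_spectral_radius() < 1.0


@dataclass
class DirectedCoherence:
    """Generalized PDC: ``pdc[f, i, j]`` is the strength of j→i at freqs[f]."""

    freqs: np.ndarray
    pdc: np.ndarray           # (n_freqs, n, n)
    channels: list[str]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


# ---------------------------------------------------------------------------
# Coherence family
# ---------------------------------------------------------------------------

def coherence(S: SpectralMatrix, a: str, b: str) -> CoherenceFunction:
    """Magnitude-squared coherence |S_AB|²/(S_AA·S_BB) per frequency."""
    ia, ib = S.channel_index(a), S.channel_index(b)
    saa = S.S[:, ia, ia].real
    sbb = S.S[:, ib, ib].real
    bad = (saa <= 0) | (sbb <= 0)
    if bad.any():
        raise ValueError(
            f"zero autospectrum at f={S.freqs[bad][0]:.3g} Hz for pair ({a},{b})"
        )
    coh = np.abs(S.S[:, ia, ib]) ** 2 / (saa * sbb)
    return CoherenceFunction(S.freqs, np.clip(coh, 0.0, 1.0), (a, b))


def coherence_matrix(S: SpectralMatrix) -> np.ndarray:
    """All-pairs magnitude-squared coherence, shape (n_freqs, n, n)."""
    d = np.einsum("fii->fi", S.S).real
    denom = d[:, :, None] * d[:, None, :]
    if np.any(denom <= 0):
        raise ValueError("zero autospectrum in coherence matrix")
    return np.clip(np.abs(S.S) ** 2 / denom, 0.0, 1.0)


def coherence_graph(S: SpectralMatrix, band: tuple[float, float]) -> CoherenceGraph:
    """Graph of band-mean coherence weights over [lo, hi)."""
    mask = _band_mask(S.freqs, *band)
    if not mask.any():
        raise ValueError(f"band {band} selects no frequency bins")
    cm = coherence_matrix(S)[mask].mean(axis=0)
    np.fill_diagonal(cm, 1.0)
    cm = 0.5 * (cm + cm.T)
    return CoherenceGraph(list(S.channels), cm, band)


def global_efficiency(g: CoherenceGraph) -> float:
    """Mean inverse shortest-path distance over unordered electrode pairs.

    Edge distance is 1/weight (∞ for zero weight), so stronger coherence
    shortens paths and raises Eglob toward 1.
    """
    n = len(g.nodes)
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    w = np.asarray(g.weights, float)
    if np.any(w < 0):
        raise ValueError("negative edge weight")
    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(dist, 0.0)
    D = dijkstra(dist, directed=False)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D[iu]) & (D[iu] > 0), 1.0 / D[iu], 0.0)
    return float(inv.mean())


def partial_coherence(S: SpectralMatrix, a: str, b: str) -> CoherenceFunction:
    """Partial coherence |M_AB|/√(M_AA·M_BB) from minors of S(f).

    Frequencies where S(f) is numerically singular (condition number above
    1e10) are masked with NaN and reported in a warning.
    """
    ia, ib = S.channel_index(a), S.channel_index(b)
    n_f, n, _ = S.S.shape
    if n < 2:
        raise ValueError("partial coherence needs at least 2 channels")

    def minor(mat: np.ndarray, row: int, col: int) -> np.ndarray:
        keep_r = [i for i in range(n) if i != row]
        keep_c = [j for j in range(n) if j != col]
        sub = mat[:, keep_r][:, :, keep_c]
        return np.linalg.det(sub)

    cond = np.linalg.cond(S.S)
    ill = cond > 1e10
    m_ab = minor(S.S, ia, ib)
    m_aa = minor(S.S, ia, ia).real
    m_bb = minor(S.S, ib, ib).real
    denom = np.sqrt(np.clip(m_aa, 0.0, None) * np.clip(m_bb, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = np.abs(m_ab) / denom
    pc = np.where(denom > 0, pc, np.nan)
    if ill.any():
        pc = np.where(ill, np.nan, pc)
        warnings.warn(
            f"partial coherence masked at {int(ill.sum())} ill-conditioned "
            f"frequencies (cond > 1e10)",
            stacklevel=2,
        )
    return CoherenceFunction(
        S.freqs, np.clip(pc, 0.0, 1.0), (a, b), kind="partial"
    )


# ---------------------------------------------------------------------------
# MVAR and directed coherence
# ---------------------------------------------------------------------------

def _mvar_lstsq(epochs: np.ndarray, p: int):
    """Stacked least-squares MVAR(p) fit over epochs (n_e, n_s, n_ch)."""
    n_e, n_s, n_ch = epochs.shape
    rows = n_e * (n_s - p)
    X = np.empty((rows, n_ch * p))
    Y = np.empty((rows, n_ch))
    r = 0
    for e in range(n_e):
        seg = epochs[e]
        t = np.arange(p, n_s)
        Y[r : r + len(t)] = seg[t]
        for k in range(1, p + 1):
            X[r : r + len(t), (k - 1) * n_ch : k * n_ch] = seg[t - k]
        r += len(t)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    dof = max(rows - n_ch * p, 1)
    sigma = resid.T @ resid / dof
    A = B.T.reshape(n_ch, p, n_ch).transpose(1, 0, 2)  # (p, n, n), A_k = lag k
    return A, sigma, rows


def fit_mvar(epochs: EpochSet, max_order: int = 20) -> MVARModel:
    """Fit an MVAR model by multi-epoch least squares; order by BIC.

    Each epoch contributes its own lagged design block, so no artificial
    continuity is assumed across epoch boundaries.
    """
    data = epochs.epochs
    n_e, n_s, n_ch = data.shape
    if n_s <= max_order * 2:
        raise ValueError("epochs too short for the requested MVAR order")
    # remove per-epoch channel means: MVAR assumes zero-mean signals
    data = data - data.mean(axis=1, keepdims=True)
    best = None
    for p in range(1, max_order + 1):
        A, sigma, rows = _mvar_lstsq(data, p)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        bic = logdet + (n_ch * n_ch * p) * np.log(rows) / rows
        if best is None or bic < best[0]:
            best = (bic, p, A, sigma)
    if best is None:
        raise ValueError("MVAR fit failed: singular innovation covariance")
    _, p, A, sigma = best
    model = MVARModel(A, sigma, epochs.fs, list(epochs.channels))
    if not model.is_stable():
        raise ValueError(
            f"fitted MVAR({p}) is unstable (spectral radius "
            f"{model.companion_spectral_radius():.3f} ≥ 1); detrend the data "
            "or reduce max_order"
        )
    return model


def extended_pdc(
    m: MVARModel, freqs: np.ndarray | None = None, weighted: bool = True
) -> DirectedCoherence:
    """Generalized (noise-variance-weighted) partial directed coherence.

    pdc[i, j](f) = (|Ā_ij(f)|/σ_i) / sqrt(Σ_k |Ā_kj(f)|²/σ_k²), with
    Ā(f) = I − Σ_k A_k e^{−2πifk/fs}.  ``weighted=False`` gives the classic
    unweighted PDC for sensitivity analysis.
    """
    if not m.is_stable():
        raise ValueError("MVAR model is unstable")
    if freqs is None:
        freqs = np.arange(0.0, m.fs / 2 + 1e-9, 1.0)
    freqs = np.asarray(freqs, float)
    p, n, _ = m.coeffs.shape
    sig_d = np.diag(m.sigma).copy()
    if np.any(sig_d <= 0):
        raise ValueError("singular innovation covariance")
    w_i = 1.0 / np.sqrt(sig_d) if weighted else np.ones(n)
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / m.fs)  # (f, p)
    Abar = np.eye(n)[None, :, :] - np.einsum("fk,kij->fij", phase, m.coeffs)
    num = w_i[None, :, None] * np.abs(Abar)          # (f, n, n)
    denom = np.sqrt(np.sum(num**2, axis=1, keepdims=True))  # per source column
    pdc = num / denom
    return DirectedCoherence(freqs, pdc, list(m.channels))


def band_mean_pdc(
    d: DirectedCoherence, band: tuple[float, float], source: str, sink: str
) -> float:
    """Mean PDC (source → sink) over the half-open band [lo, hi)."""
    mask = _band_mask(d.freqs, *band)
    if not mask.any():
        raise ValueError(f"band {band} selects no frequency bins")
    i = d.channel_index(sink)
    j = d.channel_index(source)
    return float(d.pdc[mask, i, j].mean())
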