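"""Synthetic LFP/EEG cohorts with known ground truth.

The generator emulates vigilance-wake hippocampal/cortical field potentials
from the six-electrode montage (FL, FR, CA1L, CA1R, CA3L, CA3R) at 512 Hz:

* a 1/f "pink" background per channel;
* a hippocampal theta oscillator (peak near 7.5 Hz) whose phase performs a
  slow random walk, giving the peak a realistic few-Hz width (wake rodent
  theta wanders over roughly 6–9 Hz); channels share one theta drive with
  small per-channel phase jitter, so theta is coherent across sites without
  being identical;
* theta-phase-modulated gamma: a broadband bump centered near 52 Hz
  (random-walk carrier phase) whose envelope is (1 + m·cos θ), so the
  normalized modulation index is exactly m/2 and the coupling spreads over
  the amplitude-frequency axis of the comodulogram as in vivo;
* shared broadband components per electrode pair (tunable coherence);
* lagged gamma coupling between CA1R and CA1L (asymmetric directed flow);
* 50 Hz line interference so the notch stage is exercised end to end.

A two-group cohort reproduces the contrast structure of a unilateral
tau-seeding experiment: the treated ("k18") group has a leftward theta-peak
shift (7.0 vs 7.5 Hz in CA1), halved CA1R coupling depth (m 0.14 vs 0.24,
i.e. MI ≈ 0.07 vs 0.12), a weaker CA1L–CA1R shared gain, and weaker
CA1R→CA1L lagged gamma coupling.  Every draw is deterministic given
(config, seed); per-animal lognormal multipliers (σ = 0.15) on coupling
depth, shared gains, and theta power emulate between-animal variability
and persist across weeks for the same animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.signal import lfilter as sps_lfilter

from .signal_io import MultichannelRecording

__all__ = [
    "GroupParams",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "CHANNELS",
    "gen_background",
    "gen_pac_channel",
    "gen_coupled_pair",
    "gen_mvar_network",
    "gen_cohort",
    "write_cohort",
]

CHANNELS = ["FL", "FR", "CA1L", "CA1R", "CA3L", "CA3R"]


def _pair(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass
class GroupParams:
    """Per-group generative parameters."""

    theta_peak: dict = field(default_factory=dict)       # channel -> Hz
    pac_depth: dict = field(default_factory=dict)        # channel -> m in [0,1]
    gamma_center: float = 52.0                           # Hz
    shared_gains: dict = field(default_factory=dict)     # unordered pair -> gain
    directed: dict = field(default_factory=dict)         # (src, dst) -> coeff

    def validate(self) -> None:
        for ch, m in self.pac_depth.items():
            if not 0 <= m <= 1:
                raise ValueError(f"pac_depth[{ch}]={m} outside [0, 1]")
        for p, g in self.shared_gains.items():
            if not np.isfinite(g) or g < 0:
                raise ValueError(f"shared gain {p}={g} invalid")
        for p, c in self.directed.items():
            if not np.isfinite(c) or abs(c) >= 1:
                raise ValueError(f"directed coupling {p}={c} must satisfy |c| < 1")


def _buffer_params() -> GroupParams:
    return GroupParams(
        theta_peak={c: 7.5 for c in CHANNELS},
        pac_depth={
            "FL": 0.16, "FR": 0.16,
            "CA1L": 0.24, "CA1R": 0.24,
            "CA3L": 0.20, "CA3R": 0.20,
        },
        gamma_center=52.0,
        shared_gains={
            _pair("CA1L", "CA1R"): 1.0,
            _pair("FL", "FR"): 0.5,
            _pair("CA3L", "CA3R"): 0.5,
            _pair("CA1L", "CA3L"): 0.4,
            _pair("CA1R", "CA3R"): 0.4,
        },
        directed={("CA1R", "CA1L"): 0.3, ("CA1L", "CA1R"): 0.3},
    )


def _k18_params() -> GroupParams:
    p = _buffer_params()
    p.theta_peak["CA1L"] = 7.0
    p.theta_peak["CA1R"] = 7.0
    p.pac_depth["CA1R"] = 0.14
    p.shared_gains[_pair("CA1L", "CA1R")] = 0.6
    p.directed[("CA1R", "CA1L")] = 0.12
    return p


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic two-group cohort.

    Group sizes follow the study design (7 buffer vs 8 treated animals);
    sessions default to 5 minutes — long enough for every estimator to
    converge at 512 Hz while keeping a full cohort tractable on one CPU.
    """

    n_buffer: int = 7
    n_k18: int = 8
    weeks: tuple = (1, 10, 20)
    fs: float = 512.0
    duration_s: float = 300.0
    theta_amp: float = 2.0            # slow-wave amplitude (pre-gain units)
    gamma_amp: float = 1.0
    background_rms: float = 0.4       # 1/f floor relative to oscillators
    noise_exponent: float = 1.0       # 1/f^exponent background slope
    line_freq: float = 50.0
    line_amp: float = 0.04            # sine amplitude ≈ 10% of background RMS
    theta_linewidth: float = 2.5      # Hz, FWHM of the theta peak
    gamma_linewidth: float = 12.0     # Hz, FWHM of the (broadband) gamma bump
    phase_jitter_sd: float = 0.4      # rad, per-channel theta phase jitter
    directed_lag: int = 2             # samples
    animal_sigma: float = 0.15        # lognormal sd of per-animal multipliers
    output_gain_uv: float = 40.0      # scales the unitless mix to microvolts
    seed: int = 0
    buffer: GroupParams = field(default_factory=_buffer_params)
    k18: GroupParams = field(default_factory=_k18_params)

    def validate(self) -> None:
        if self.n_buffer < 2 or self.n_k18 < 2:
            raise ValueError("each group needs at least 2 animals")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        top = max(
            max(self.buffer.theta_peak.values()),
            max(self.k18.theta_peak.values()),
            self.buffer.gamma_center,
            self.k18.gamma_center,
            self.line_freq,
        )
        if self.fs <= 2 * top:
            raise ValueError(f"fs={self.fs} too low for content up to {top} Hz")
        if not 0 <= self.noise_exponent <= 2:
            raise ValueError("noise_exponent must be in [0, 2]")
        self.buffer.validate()
        self.k18.validate()

    def group_params(self, group: str) -> GroupParams:
        if group == "buffer":
            return self.buffer
        if group == "k18":
            return self.k18
        raise KeyError(group)

    def null(self) -> "CohortConfig":
        """Copy with all group effects removed (k18 ≡ buffer)."""
        cfg = replace(self, buffer=_buffer_params(), k18=_buffer_params())
        return cfg


@dataclass
class GroundTruth:
    """Design-level truth behind a generated cohort.

    Keys are ``(animal, channel)`` / ``(animal, pair)`` / ``(animal,
    (src, dst))``; values include the per-animal lognormal multipliers, so
    ``mi[(animal, ch)]`` is exactly the population MI of that channel.
    """

    theta_peak: dict = field(default_factory=dict)
    mi: dict = field(default_factory=dict)
    shared_gain: dict = field(default_factory=dict)
    directed: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        def flat(d: dict) -> dict:
            out = {}
            for k, v in d.items():
                animal, rest = k
                if isinstance(rest, tuple):
                    rest = "-".join(rest)
                out[f"{animal}/{rest}"] = float(v)
            return out

        return {
            "theta_peak": flat(self.theta_peak),
            "mi": flat(self.mi),
            "shared_gain": flat(self.shared_gain),
            "directed": flat(self.directed),
        }


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_background(fs: float, duration: float, exponent: float, seed) -> np.ndarray:
    """Unit-variance Gaussian noise with power spectrum ∝ 1/f^exponent."""
    if not 0 <= exponent <= 2:
        raise ValueError("exponent must be in [0, 2]")
    rng = _rng(seed)
    n = int(round(fs * duration))
    white = rng.standard_normal(n)
    if exponent == 0:
        return (white - white.mean()) / white.std()
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2)
    x = np.fft.irfft(spec * shape, n)
    return (x - x.mean()) / x.std()


def gen_pac_channel(
    fs: float,
    duration: float,
    f_theta: float,
    f_gamma: float,
    m: float,
    snr: float = 4.0,
    seed=0,
    theta_amp: float = 2.0,
    gamma_amp: float = 1.0,
    noise_exponent: float = 1.0,
) -> np.ndarray:
    """Theta + theta-phase-modulated gamma + 1/f background.

    ``s(t) = A_θ·cos(2πf_θt+φ₀) + (1 + m·cos(2πf_θt+φ₀))·A_γ·cos(2πf_γt+ψ)
    + background``, with the background scaled so the oscillatory RMS is
    ``snr`` times the background RMS.  Population normalized MI is m/2.
    """
    if not 0 <= m <= 1:
        raise ValueError(f"modulation depth m={m} outside [0, 1]")
    if f_gamma <= 2 * f_theta:
        raise ValueError("need f_gamma > 2·f_theta")
    rng = _rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    phi0 = rng.uniform(0, 2 * np.pi)
    psi = rng.uniform(0, 2 * np.pi)
    theta_phase = 2 * np.pi * f_theta * t + phi0
    osc = theta_amp * np.cos(theta_phase)
    osc = osc + (1 + m * np.cos(theta_phase)) * gamma_amp * np.cos(
        2 * np.pi * f_gamma * t + psi
    )
    bg = gen_background(fs, duration, noise_exponent, rng)
    osc_rms = np.sqrt(np.mean(osc**2))
    return osc + bg * (osc_rms / snr)


def gen_coupled_pair(
    fs: float, duration: float, shared_gain: float, seed=0
) -> np.ndarray:
    """Two channels x = g·s + n₁, y = g·s + n₂ (s, n₁, n₂ unit white).

    True magnitude-squared coherence is (g²/(g²+1))² at every frequency.
    """
    if shared_gain < 0:
        raise ValueError("shared_gain must be ≥ 0")
    rng = _rng(seed)
    n = int(round(fs * duration))
    s = rng.standard_normal(n)
    x = shared_gain * s + rng.standard_normal(n)
    y = shared_gain * s + rng.standard_normal(n)
    return np.column_stack([x, y])


def gen_mvar_network(
    coeffs: np.ndarray, sigma: np.ndarray, fs: float, duration: float, seed=0
) -> np.ndarray:
    """Simulate a stable MVAR process; burn-in (≥10× order) is discarded."""
    from .connectivity import MVARModel

    coeffs = np.asarray(coeffs, float)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise ValueError("coeffs must have shape (p, n, n)")
    p, nch, _ = coeffs.shape
    sigma = np.asarray(sigma, float)
    model = MVARModel(coeffs, sigma, fs, [f"x{i}" for i in range(nch)])
    rho = model.companion_spectral_radius()
    if rho >= 1:
        raise ValueError(f"unstable MVAR coefficients (spectral radius {rho:.3f})")
    rng = _rng(seed)
    n = int(round(fs * duration))
    burn = max(10 * p, 500)
    L = np.linalg.cholesky(sigma)
    eps = rng.standard_normal((n + burn, nch)) @ L.T
    x = np.zeros((n + burn, nch))
    for t in range(p, n + burn):
        acc = eps[t].copy()
        for k in range(1, p + 1):
            acc += coeffs[k - 1] @ x[t - k]
        x[t] = acc
    return x[burn:]


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _animal_ids(cfg: CohortConfig) -> list[tuple[str, str]]:
    out = [("buffer", f"buffer{i+1:02d}") for i in range(cfg.n_buffer)]
    out += [("k18", f"k18{i+1:02d}") for i in range(cfg.n_k18)]
    return out


def _animal_traits(cfg: CohortConfig, animal_index: int) -> dict:
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % (2**31), 7919, animal_index])
    )
    s = cfg.animal_sigma
    draw = lambda: float(rng.lognormal(mean=-0.5 * s * s, sigma=s))
    return {"pac": draw(), "theta": draw(), "gain": draw(), "directed": draw()}


@dataclass
class Cohort:
    """Lazily generated two-group cohort with its ground truth.

    Sessions are synthesized on demand — ``session(animal, week)`` is
    deterministic in (config.seed, animal, week) and independent of the
    order of calls.
    """

    config: CohortConfig
    ground_truth: GroundTruth
    animals: list  # [(group, animal_id), ...]

    def session(self, animal: str, week: int) -> MultichannelRecording:
        group = next(g for g, a in self.animals if a == animal)
        aidx = [a for _, a in self.animals].index(animal)
        return _gen_session(self.config, group, animal, aidx, week)

    def sessions(self):
        for group, animal in self.animals:
            for week in self.config.weeks:
                yield group, animal, week


def _gen_session(
    cfg: CohortConfig, group: str, animal: str, aidx: int, week: int
) -> MultichannelRecording:
    gp = cfg.group_params(group)
    traits = _animal_traits(cfg, aidx)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % (2**31), aidx, int(week)])
    )
    fs, dur = cfg.fs, cfg.duration_s
    n = int(round(fs * dur))
    t = np.arange(n) / fs

    # shared theta drive: random-walk phase gives a ~theta_linewidth peak
    sigma_rw = np.sqrt(2 * np.pi * cfg.theta_linewidth / fs)
    walk = np.cumsum(rng.standard_normal(n) * sigma_rw)
    phi0 = rng.uniform(0, 2 * np.pi)

    # per-channel phase jitter: slow OU process, sd = phase_jitter_sd
    lam = 1.0 / (0.2 * fs)  # ~200 ms correlation time
    ou_sd = cfg.phase_jitter_sd

    data = np.zeros((n, len(CHANNELS)))
    gamma_parts: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(CHANNELS):
        f_peak = gp.theta_peak[ch]
        incr = rng.standard_normal(n) * (ou_sd * np.sqrt(2 * lam))
        # AR(1) recursion jit[i] = (1-lam)·jit[i-1] + incr[i]
        jit = sps_lfilter([1.0], [1.0, -(1.0 - lam)], incr)
        theta_phase = 2 * np.pi * f_peak * t + phi0 + walk + jit
        a_theta = cfg.theta_amp * traits["theta"]
        x = a_theta * np.cos(theta_phase)
        m = min(gp.pac_depth[ch] * traits["pac"], 0.95)
        psi = rng.uniform(0, 2 * np.pi)
        # broadband gamma: random-walk phase gives a ~gamma_linewidth bump,
        # so coupling spreads over the amplitude-frequency axis as in vivo
        g_walk = np.cumsum(
            rng.standard_normal(n) * np.sqrt(2 * np.pi * cfg.gamma_linewidth / fs)
        )
        gam = (1 + m * np.cos(theta_phase)) * cfg.gamma_amp * np.cos(
            2 * np.pi * gp.gamma_center * t + psi + g_walk
        )
        gamma_parts[ch] = gam
        x = x + gam
        x = x + cfg.background_rms * gen_background(fs, dur, cfg.noise_exponent, rng)
        x = x + cfg.line_amp * np.sin(
            2 * np.pi * cfg.line_freq * t + rng.uniform(0, 2 * np.pi)
        )
        data[:, ci] = x

    # shared broadband components (coherence control)
    for (a, b), g in gp.shared_gains.items():
        if g <= 0:
            continue
        s = rng.standard_normal(n) * cfg.background_rms
        gg = g * traits["gain"]
        data[:, CHANNELS.index(a)] += gg * s
        data[:, CHANNELS.index(b)] += gg * s

    # lagged directed gamma coupling
    lag = cfg.directed_lag
    for (src, dst), c in gp.directed.items():
        if c == 0:
            continue
        cc = c * traits["directed"]
        shifted = np.roll(gamma_parts[src], lag)
        shifted[:lag] = 0.0
        data[:, CHANNELS.index(dst)] += cc * shifted

    data *= cfg.output_gain_uv
    return MultichannelRecording(
        data, fs, list(CHANNELS),
        {"animal": animal, "group": group, "week": week},
    )


def gen_cohort(cfg: CohortConfig | None = None) -> Cohort:
    """Build a lazily evaluated cohort and its ground truth."""
    cfg = CohortConfig() if cfg is None else cfg
    cfg.validate()
    animals = _animal_ids(cfg)
    gt = GroundTruth()
    for aidx, (group, animal) in enumerate(animals):
        gp = cfg.group_params(group)
        traits = _animal_traits(cfg, aidx)
        for ch in CHANNELS:
            gt.theta_peak[(animal, ch)] = gp.theta_peak[ch]
            m = min(gp.pac_depth[ch] * traits["pac"], 0.95)
            gt.mi[(animal, ch)] = m / 2.0
        for pair, g in gp.shared_gains.items():
            gt.shared_gain[(animal, pair)] = g * traits["gain"]
        for dpair, c in gp.directed.items():
            gt.directed[(animal, dpair)] = c * traits["directed"]
    return Cohort(cfg, gt, animals)


def write_cohort(cohort: Cohort, out_dir, format: str = "delimited") -> None:
    """Materialize a cohort as ``<out>/<group>/<animal>/week<k>.{csv,edf}``
    plus ``ground_truth.json``."""
    import json
    from pathlib import Path

    from .signal_io import write_recording

    out = Path(out_dir)
    suffix = ".edf" if format == "edf" else ".csv"
    for group, animal, week in cohort.sessions():
        d = out / group / animal
        d.mkdir(parents=True, exist_ok=True)
        rec = cohort.session(animal, week)
        write_recording(rec, d / f"week{week}{suffix}", format=format)
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth.to_jsonable(), indent=1)
    )
    (out / "cohort_config.json").write_text(
        json.dumps(_config_jsonable(cohort.config), indent=1)
    )


def _config_jsonable(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    for grp in ("buffer", "k18"):
        for key in ("shared_gains", "directed"):
            d[grp][key] = {"-".join(k): v for k, v in d[grp][key].items()}
    d["weeks"] = list(cfg.weeks)
    return d
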