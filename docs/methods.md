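# Methods

`netdyn` analyzes continuous multichannel local-field-potential/EEG
recordings from a six-electrode rodent montage (frontal FL/FR, hippocampal
CA1L/CA1R and CA3L/CA3R, 512 Hz, microvolts) and compares two treatment
groups ("buffer" controls vs "k18" treated) week by week.  This note
documents the models, the estimator choices, the synthetic study design,
and what the tests do and do not establish.

## Preprocessing

Line interference is removed with a linear-phase FIR band-stop at 50 Hz
(2 Hz stopband).  All filters in the package are zero-phase: the
forward-backward magnitude response |H(f)|² of a Hamming-window FIR is
applied, either via `filtfilt` (`bandpass`) or spectrally on reflect-padded
data (`notch_filter`, `analytic`) — the two applications share the same
kernel and differ only inside the transient guard.

Band filters are designed from the transition width
`max(min(bandwidth, f_lo)/2, 0.5)` Hz, capped at 2 Hz, and the −6 dB
cutoffs are pushed half a transition width outside the nominal band.  The
cap matters for wide gamma bands: an amplitude band such as 55–75 Hz must
reject a strong oscillation sitting just below its lower edge, otherwise
carrier leakage manufactures spurious phase-amplitude coupling.  The cutoff
shift matters for narrow bands: the modulation sidebands at f_H ± f_L sit
near the band edges and must pass at unit gain for the modulation index to
be unbiased.

Filter transients: `analytic` flags three filter lengths at each edge
(capped at a quarter of the segment, so short epochs keep a usable core);
every statistic downstream excludes guarded samples.

Artifact handling substitutes an amplitude criterion for behavioural
vigilance scoring: an epoch (default 8 s, non-overlapping) is kept when
every channel stays below 1000 µV peak and swings more than 1 µV.  The
synthetic cohorts contain no sleep or movement artifacts, so this criterion
is exercised but rarely binding there.

## Spectra

Welch periodograms with 512-sample Hann blocks and 50% overlap give 1.0 Hz
bins at 512 Hz.  Power is reported as relative power — each channel
normalized to unit sum over 1–256 Hz — which cancels electrode gain and
impedance differences between animals.  Summed band powers (slow theta 4–6,
high theta 6–8, γ1 50–80 Hz) use half-open intervals [lo, hi) so adjacent
bands partition the axis; the normalization range follows the same
convention.  The theta center of mass Σf·P(f)/ΣP(f) is computed over the
inclusive band [4, 12] Hz (rodent hippocampal theta), so the center of a
flat spectrum is exactly 8 Hz; it moves with the peak position even when
total theta power is unchanged.

## Phase-amplitude coupling

The modulation index is the normalized mean vector length

    MI = |⟨A_H(t)·exp(i·φ_L(t))⟩| / ⟨A_H(t)⟩ ∈ [0, 1],

with φ_L the Hilbert phase of the slow band (f_L ± 1 Hz) and A_H the
Hilbert envelope of the fast band (f_H ± max(5, f_L + 2) Hz — wide enough
to pass the modulation sidebands, the standard PAC bandwidth requirement;
for low-f_H grid corners the lower band edge is clamped to 0.5 Hz).  For an
envelope A ∝ (1 + m·cos φ) the population value is exactly m/2.  The
envelope normalization makes MI invariant to channel gain and hence
comparable across animals and groups; group means of ~0.07–0.12 are on
this dimensionless scale.

Comodulograms evaluate MI over f_L ∈ 2–12 Hz (step 2) × f_H ∈ 10–200 Hz
(step 5); intersite variants draw phase and amplitude from different
electrodes.  The theta–gamma summary ("mean PAC") is the unweighted mean
over grid cells whose centers fall in 3.5–12.5 × 32–100 Hz (intrasite) or
3.5–11 × 32–100 Hz (intersite), window bounds closed.

MI is computed by default over the continuous notched session with artifact
epochs masked out of the time average ("session" mode).  The alternative —
estimating MI per 8-s epoch and averaging — carries an irreducible
small-sample bias: |mean of N noisy unit vectors| has expectation
~(π/4N)^½ even without coupling, about 0.05 per epoch at these bandwidths,
which swamps coupling differences of the size of interest and does not
decay with session length.  Session-level estimates converge as 1/√T and
reach the reported group levels; per-epoch averaging remains available
(`StudyConfig.pac_mode="epochs"`) for sensitivity analysis.  Null MI still
depends on the phase bandwidth: the f_L = 2 Hz row of a 60-s comodulogram
has only ~120 slow cycles and a null ceiling near 0.07, while rows at
f_L ≥ 4 Hz stay below 0.05.

The phase-binned amplitude curve sorts the fast-band envelope into six
equal phase bins over [−π, π) (≈1.05 rad wide — exact 1-radian bins cannot
tile the circle); its circular mean direction is the coupling phase shift,
flagged unreliable when the resultant length vanishes.

## Connectivity

From the Welch cross-spectral matrix S(f) (Hermitian, PSD by
construction):

* coherence: |S_AB|²/(S_AA·S_BB), magnitude-squared convention;
* partial coherence: |M_AB|/√(M_AA·M_BB) with M_XY the minor of S(f) after
  deleting row X, column Y — equivalently the magnitude of the normalized
  inverse-spectral-matrix entry; ill-conditioned frequencies (condition
  number > 1e10) are masked with a warning.  The amplitude (not squared)
  convention keeps the 2-channel case equal to √coherence;
* global efficiency: electrodes form a graph weighted by band-mean
  coherence; with edge distance 1/weight (∞ for zero weight), Eglob is the
  mean inverse Dijkstra distance over electrode pairs.  The distance is the
  *reciprocal* of coherence so that stronger coupling means a more
  efficient network — the direction all group predictions require;
* directed coherence: an MVAR model is fitted by multi-epoch stacked least
  squares (per-epoch mean removed; order selected by BIC up to 20 lags at
  512 Hz; stability enforced via the companion-matrix spectral radius), and
  the generalized ("extended") PDC is computed from
  Ā(f) = I − Σ_k A_k e^{−2πifk/fs}: pdc_ij(f) =
  (|Ā_ij|/σ_i) / √(Σ_k |Ā_kj|²/σ_k²).  The noise-variance weighting makes
  the measure scale-invariant per channel; the classic unweighted PDC is a
  flag away.  Band summaries (30–50, 50–100 Hz) are half-open means.

Default analysis bands: coherence/Eglob over 4–70 Hz (band-mean graph; a
per-frequency Eglob is also available).

## Group statistics

Linear metrics use the classic pooled-variance two-sample t-test, two-sided,
each week analyzed separately; no multiple-testing correction is applied
(matching the per-week, per-metric design), and the comparison table
records every test performed.  Summaries are means with 95% t confidence
intervals.  Coupling phase shifts use the circular mean and the
Watson–Williams F-test with the 1 + 3/(8κ̂) concentration correction
(κ̂ from the maximum-likelihood inversion of the mean resultant); samples
with pooled resultant < 0.45 violate the test's concentration assumption
and are flagged rather than rejected.  Both tests hold their nominal 5%
type-I error within ±1% in 10⁴-replicate null simulations.

## Synthetic cohort

The generator emulates the study design — 7 control vs 8 treated animals,
weekly sessions — with every metric's ground truth known by construction:

| ingredient | default | rationale |
|---|---|---|
| background | 1/f, unit variance, rms 0.4 | vigilance-wake LFP floor |
| theta | 7.5 Hz (controls), amplitude 2, FWHM 2.5 Hz | wake rodent theta wanders over ~6–9 Hz |
| gamma | 52 Hz bump, amplitude 1, FWHM 12 Hz | broadband mid-gamma; spreads coupling over the comodulogram as in vivo |
| coupling | envelope (1 + m·cos θ); m: CA1 0.24, CA3 0.20, frontal 0.16 | MI = m/2 → CA1 ≈ 0.12 |
| shared components | white, gain 1.0 (CA1L–CA1R), 0.4–0.5 elsewhere | coherence control; closed form (g²/(g²+1))² for the isolated pair |
| directed coupling | CA1R→CA1L and CA1L→CA1R lagged gamma, coefficient 0.3, lag 2 samples | asymmetric PDC ground truth; weak enough that cross-hemispheric gamma leakage does not mask local coupling |
| line noise | 50 Hz, amplitude 10% of background rms | exercises the notch end to end |
| treated-group effects | theta 7.0 Hz in CA1; CA1R m = 0.14; CA1L–CA1R gain 0.6; CA1R→CA1L coefficient 0.12 | the four contrast directions of the study |
| animal variability | lognormal multipliers, σ = 0.15, fixed per animal across weeks | between-animal pathology-load spread |

Sessions default to 5 minutes (all estimators converge well before that at
512 Hz); the scale to microvolts is a single output gain (40 µV).  Theta is
one random-walk-phase drive shared across channels with per-channel
Ornstein–Uhlenbeck phase jitter (sd 0.4 rad), so theta is coherent across
sites without being identical.  Every draw is determined by
(config, seed, animal, week) independently of evaluation order.

What the generator does *not* emulate: sleep/wake transitions, movement
artifacts, volume conduction with distance-dependent mixing, nonstationary
coupling, electrode drift, or any biophysics of the underlying circuits.
Passing tests therefore establish estimator correctness and the detectability
of designed contrasts under realistic stationary noise — not performance on
real recordings.

One generator consequence worth knowing: the shared theta drive's
Lorentzian tails are a broadband common component, so partial coherence
between any electrode pair has a floor (~0.4 at these settings) even where
no pair-specific coupling exists.  This mirrors a genuinely shared
oscillator and is why the partial-coherence discrimination test uses an
MVAR chain with known structure instead of the cohort.

## Problem sizes and reproducibility

The power analysis (detection of the CA1R mean-PAC contrast at p < 0.05
across 100 seeded cohort replicates) runs single-week cohorts with 180-s
sessions and restricts the comodulogram to the averaging window (which
leaves the window mean unchanged); 180 s is the shortest session at which
the session-level MI noise is clearly below the designed between-animal
spread, keeping the measured rate a property of the study design rather
than of estimator noise.  The null calibration (all effects zeroed) uses
120-s sessions.  `scripts/acceptance.py --seed N --out results.json`
recomputes all headline quantities from scratch; every random draw derives
from the given seed.

## Known limitations

* EDF support writes 16-bit EDF with 1-s records and integer sampling
  rates; reading requires `mne` (optional extra).  BioSemi 24-bit BDF is
  out of scope.
* The Watson–Williams concentration correction is only approximate for
  very small or very dispersed samples; results below the validity
  threshold are flagged, not suppressed.
* Partial coherence minors become ill-conditioned when channels are nearly
  collinear; masked frequencies propagate as NaN into band means
  (`nanmean`).
* MVAR order selection by BIC favors parsimony; strongly nonstationary
  epochs should be shortened or detrended before fitting.
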