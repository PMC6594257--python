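"""Study orchestration: preprocess → spectra → PAC → connectivity → statistics.

``run_study`` drives the whole analysis over animals × weeks and emits long
tables per metric plus a group-comparison table per (metric, week).  The
unit of analysis is the animal: per-epoch estimates are averaged within a
session, sessions are compared across groups week by week with two-sample
t-tests (Watson–Williams for the circular coupling phase).  Weeks are
analyzed independently; no longitudinal model is fitted.

A study is reproducible by construction: given the same cohort (on disk or
a seeded synthetic cohort) and the same configuration the output tables are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .signal_io import MultichannelRecording, read_recording, slice_epochs
from .preprocess import analytic, notch_filter, select_artifact_free
from .spectral import (
    band_power,
    cross_spectral_matrix,
    relative_power,
    theta_center_of_mass,
    welch_psd,
)
from .pac import (
    PhaseAmplitudeCurve,
    comodulogram_epochs,
    mean_pac,
    pac_phase_shift,
)
from .connectivity import (
    band_mean_pdc,
    coherence,
    coherence_graph,
    extended_pdc,
    fit_mvar,
    global_efficiency,
    partial_coherence,
)
from .group_stats import CircularSample, two_sample_t, watson_williams
from .synthgen import Cohort, CohortConfig, gen_cohort

__all__ = ["StudyConfig", "CohortResult", "run_study", "render_report", "load_cohort"]


@dataclass
class StudyConfig:
    """Configuration of one full study analysis.

    Band edges follow the analysis windows of the study design: slow/high
    theta 4–6/6–8 Hz, γ1 50–80 Hz, coherence and Eglob over 4–70 Hz, PDC
    summarized over 30–50 and 50–100 Hz, theta–gamma PAC averaged over
    3.5–12.5 × 32–100 Hz (intrasite) and 3.5–11 × 32–100 Hz (intersite).
    """

    weeks: tuple | None = None            # None: every week in the cohort
    epoch_len_s: float = 8.0
    epoch_step_s: float | None = None
    amp_thresh_uv: float = 1000.0
    flat_thresh_uv: float = 1.0
    notch_f0: float = 50.0
    notch_bw: float = 2.0
    nperseg: int = 512
    overlap_frac: float = 0.5
    norm_band: tuple = (1.0, 256.0)
    bands: dict = field(default_factory=lambda: {
        "theta_slow": (4.0, 6.0),
        "theta_high": (6.0, 8.0),
        "gamma1": (50.0, 80.0),
    })
    theta_com_band: tuple = (4.0, 12.0)
    coherence_band: tuple = (4.0, 70.0)
    coherence_detail_pairs: tuple = (("CA1L", "CA1R"),)
    pdc_bands: tuple = ((30.0, 50.0), (50.0, 100.0))
    pdc_pairs: tuple = (("CA1R", "CA1L"), ("CA1L", "CA1R"))
    mvar_max_order: int = 20
    pac_channels: tuple = ("CA1L", "CA1R", "FL", "FR")
    intersite_pairs: tuple = (("CA1L", "CA1R"), ("CA1R", "CA1L"))
    pac_phase_grid: tuple | None = None   # None: 2–12 Hz step 2
    pac_amp_grid: tuple | None = None     # None: 10–200 Hz step 5
    intrasite_window: tuple = ((3.5, 12.5), (32.0, 100.0))
    intersite_window: tuple = ((3.5, 11.0), (32.0, 100.0))
    curve_phase: tuple = (7.0, 1.0)       # (center, halfwidth) Hz for curves
    curve_amp: tuple = (52.0, 10.0)
    curve_n_bins: int = 6
    pac_mode: str = "session"             # 'session' (continuous) | 'epochs'
    metrics: tuple = ("spectra", "pac", "intersite_pac", "connectivity", "pdc")
    store_relpower: bool = True
    store_comodulograms: bool = True
    seed: int = 0

    def jsonable(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in d["bands"].items()}
        return d


@dataclass
class CohortResult:
    """Long metric tables plus the group-comparison table.

    ``tables`` maps metric family → DataFrame keyed by (group, animal,
    week, ...); ``comparisons`` holds one row per (metric, week) group
    test; ``exclusions`` logs every (animal, week, stage) that failed,
    with the reason.
    """

    tables: dict
    comparisons: pd.DataFrame
    exclusions: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        self.comparisons.to_csv(out / "group_comparisons.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


# ---------------------------------------------------------------------------
# Cohort resolution
# ---------------------------------------------------------------------------

class DiskCohort:
    """Cohort materialized as ``<dir>/<group>/<animal>/week<k>.{csv,edf}``."""

    def __init__(self, root) -> None:
        self.root = Path(root)
        if not self.root.is_dir():
            raise FileNotFoundError(self.root)
        self._index: dict[tuple[str, int], Path] = {}
        self.animals: list[tuple[str, str]] = []
        for group_dir in sorted(p for p in self.root.iterdir() if p.is_dir()):
            for animal_dir in sorted(p for p in group_dir.iterdir() if p.is_dir()):
                self.animals.append((group_dir.name, animal_dir.name))
                for f in sorted(animal_dir.glob("week*")):
                    week = int("".join(ch for ch in f.stem if ch.isdigit()))
                    self._index[(animal_dir.name, week)] = f
        if not self.animals:
            raise ValueError(f"no <group>/<animal> tree under {self.root}")

    @property
    def weeks(self) -> tuple:
        return tuple(sorted({w for (_, w) in self._index}))

    def sessions(self):
        for group, animal in self.animals:
            for week in self.weeks:
                if (animal, week) in self._index:
                    yield group, animal, week

    def session(self, animal: str, week: int) -> MultichannelRecording:
        rec = read_recording(self._index[(animal, week)])
        group = next(g for g, a in self.animals if a == animal)
        rec.meta.update({"animal": animal, "group": group, "week": week})
        return rec


def load_cohort(source) -> Cohort | DiskCohort:
    """Resolve a cohort source: directory path, CohortConfig, or Cohort."""
    if isinstance(source, (Cohort, DiskCohort)):
        return source
    if isinstance(source, CohortConfig):
        return gen_cohort(source)
    return DiskCohort(source)


def _cohort_weeks(cohort) -> tuple:
    if isinstance(cohort, DiskCohort):
        return cohort.weeks
    return tuple(cohort.config.weeks)


# ---------------------------------------------------------------------------
# Per-session analysis
# ---------------------------------------------------------------------------

def _epoch_sample_mask(rec, cfg: StudyConfig) -> np.ndarray:
    """Sample-level validity mask: True where an artifact-free epoch covers
    the sample (used by session-level PAC to skip artifact stretches)."""
    from .preprocess import artifact_free_mask

    epochs = slice_epochs(rec, cfg.epoch_len_s, cfg.epoch_step_s)
    keep = artifact_free_mask(epochs, cfg.amp_thresh_uv, cfg.flat_thresh_uv)
    if not keep.any():
        raise ValueError("empty selection: no artifact-free epochs")
    n_len = epochs.epoch_len
    step = n_len if cfg.epoch_step_s is None else int(round(cfg.epoch_step_s * rec.fs))
    valid = np.zeros(rec.n_samples, dtype=bool)
    for e in np.where(keep)[0]:
        valid[e * step : e * step + n_len] = True
    return valid


def _session_curve(rec, valid, channel: str, cfg: StudyConfig) -> PhaseAmplitudeCurve:
    """Phase-amplitude curve over the continuous session."""
    from .pac import phase_amplitude_curve

    x = rec.get_channel(channel)
    ph = analytic(x, rec.fs, *cfg.curve_phase)
    am = analytic(x, rec.fs, *cfg.curve_amp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return phase_amplitude_curve(ph, am, cfg.curve_n_bins, valid)


def _epochs_curve(epochs, channel: str, cfg: StudyConfig) -> PhaseAmplitudeCurve:
    """Phase-amplitude curve pooled over epochs (bin sums accumulate)."""
    from .pac import phase_amplitude_curve

    idx = epochs.channel_index(channel)
    n_bins = cfg.curve_n_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    centers = None
    for e in range(epochs.n_epochs):
        x = epochs.epochs[e, :, idx]
        ph = analytic(x, epochs.fs, *cfg.curve_phase)
        am = analytic(x, epochs.fs, *cfg.curve_amp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = phase_amplitude_curve(ph, am, n_bins)
        centers = curve.bin_centers
        ok = curve.n_per_bin > 0
        sums[ok] += curve.mean_amp[ok] * curve.n_per_bin[ok]
        counts += curve.n_per_bin
    mean_amp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PhaseAmplitudeCurve(centers, mean_amp, counts)


def _analyze_session(rec: MultichannelRecording, cfg: StudyConfig, rows: dict,
                     group: str, animal: str, week: int) -> None:
    base = {"group": group, "animal": animal, "week": week}
    if not ({"spectra", "connectivity", "pdc"} & set(cfg.metrics)):
        # PAC-only runs touch few channels; skip preprocessing the rest
        needed = []
        for ch in cfg.pac_channels if "pac" in cfg.metrics else ():
            needed.append(ch)
        if "intersite_pac" in cfg.metrics:
            for a, b in cfg.intersite_pairs:
                needed.extend([a, b])
        keep = [c for c in rec.channels if c in set(needed)]
        if keep:
            rec = rec.subset(keep)
    rec = notch_filter(rec, cfg.notch_f0, cfg.notch_bw)
    epochs = slice_epochs(rec, cfg.epoch_len_s, cfg.epoch_step_s)
    epochs = select_artifact_free(epochs, cfg.amp_thresh_uv, cfg.flat_thresh_uv)

    if "spectra" in cfg.metrics:
        ps = welch_psd(epochs, cfg.nperseg, "hann", cfg.overlap_frac)
        rel = relative_power(ps, cfg.norm_band)
        if cfg.store_relpower:
            for ci, ch in enumerate(rel.channels):
                for fi, f in enumerate(rel.freqs):
                    rows["relative_power"].append(
                        {**base, "channel": ch, "freq_hz": f,
                         "relpower": rel.relpower[fi, ci]}
                    )
        for name, band in cfg.bands.items():
            bp = band_power(rel, band)
            for ci, ch in enumerate(rel.channels):
                rows["band_power"].append(
                    {**base, "channel": ch, "band": name, "value": bp[ci]}
                )
        com = theta_center_of_mass(ps, cfg.theta_com_band)
        for ci, ch in enumerate(ps.channels):
            rows["theta_com"].append({**base, "channel": ch, "value": com[ci]})

    if "pac" in cfg.metrics or "intersite_pac" in cfg.metrics:
        if cfg.pac_mode == "session":
            pac_valid = _epoch_sample_mask(rec, cfg)

        def _pac_grid(phase_ch, amp_ch, pg, ag):
            if cfg.pac_mode == "session":
                from .pac import comodulogram

                return comodulogram(rec, phase_ch, amp_ch, pg, ag, valid=pac_valid)
            return comodulogram_epochs(epochs, phase_ch, amp_ch, pg, ag)

    if "pac" in cfg.metrics:
        pg = None if cfg.pac_phase_grid is None else np.asarray(cfg.pac_phase_grid)
        ag = None if cfg.pac_amp_grid is None else np.asarray(cfg.pac_amp_grid)
        for ch in cfg.pac_channels:
            c = _pac_grid(ch, ch, pg, ag)
            if cfg.store_comodulograms:
                for i, fL in enumerate(c.phase_freqs):
                    for j, fH in enumerate(c.amp_freqs):
                        rows["comodulogram"].append(
                            {**base, "phase_channel": ch, "amp_channel": ch,
                             "f_phase": fL, "f_amp": fH, "mi": c.mi[i, j]}
                        )
            rows["mean_pac"].append(
                {**base, "channel": ch,
                 "value": mean_pac(c, *cfg.intrasite_window)}
            )
            if cfg.pac_mode == "session":
                curve = _session_curve(rec, pac_valid, ch, cfg)
            else:
                curve = _epochs_curve(epochs, ch, cfg)
            shift = pac_phase_shift(curve)
            rows["pac_phase_shift"].append(
                {**base, "channel": ch, "value": shift.angle,
                 "resultant": shift.resultant_length}
            )
            for b, amp in zip(curve.bin_centers, curve.mean_amp):
                rows["phase_amplitude_curve"].append(
                    {**base, "channel": ch, "bin_center_rad": b, "mean_amp": amp}
                )

    if "intersite_pac" in cfg.metrics:
        pg = None if cfg.pac_phase_grid is None else np.asarray(cfg.pac_phase_grid)
        ag = None if cfg.pac_amp_grid is None else np.asarray(cfg.pac_amp_grid)
        for phase_ch, amp_ch in cfg.intersite_pairs:
            c = _pac_grid(phase_ch, amp_ch, pg, ag)
            rows["intersite_pac"].append(
                {**base, "phase_channel": phase_ch, "amp_channel": amp_ch,
                 "value": mean_pac(c, *cfg.intersite_window)}
            )

    if "connectivity" in cfg.metrics:
        S = cross_spectral_matrix(epochs, cfg.nperseg, "hann", cfg.overlap_frac)
        chans = S.channels
        for ai in range(len(chans)):
            for bi in range(ai + 1, len(chans)):
                a, b = chans[ai], chans[bi]
                coh = coherence(S, a, b)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pcoh = partial_coherence(S, a, b)
                mask = (coh.freqs >= cfg.coherence_band[0]) & (
                    coh.freqs < cfg.coherence_band[1]
                )
                rows["coherence"].append(
                    {**base, "pair": f"{a}-{b}", "value": coh.coh[mask].mean()}
                )
                rows["partial_coherence"].append(
                    {**base, "pair": f"{a}-{b}",
                     "value": float(np.nanmean(pcoh.coh[mask]))}
                )
                if (a, b) in cfg.coherence_detail_pairs or (
                    b, a
                ) in cfg.coherence_detail_pairs:
                    for fi in np.where(coh.freqs <= 100)[0]:
                        rows["coherence_spectrum"].append(
                            {**base, "pair": f"{a}-{b}",
                             "freq_hz": coh.freqs[fi],
                             "coherence": coh.coh[fi],
                             "partial_coherence": pcoh.coh[fi]}
                        )
        g = coherence_graph(S, cfg.coherence_band)
        rows["eglob"].append({**base, "value": global_efficiency(g)})

    if "pdc" in cfg.metrics:
        model = fit_mvar(epochs, cfg.mvar_max_order)
        d = extended_pdc(model)
        for src, dst in cfg.pdc_pairs:
            for band in cfg.pdc_bands:
                rows["pdc"].append(
                    {**base, "source": src, "sink": dst,
                     "band": f"{band[0]:g}-{band[1]:g}",
                     "value": band_mean_pdc(d, band, src, dst)}
                )
            i, j = d.channel_index(dst), d.channel_index(src)
            for fi in np.where(d.freqs <= 100)[0]:
                rows["pdc_spectrum"].append(
                    {**base, "source": src, "sink": dst,
                     "freq_hz": d.freqs[fi], "pdc": d.pdc[fi, i, j]}
                )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

_METRIC_KEYS = {
    "band_power": ["channel", "band"],
    "theta_com": ["channel"],
    "mean_pac": ["channel"],
    "intersite_pac": ["phase_channel", "amp_channel"],
    "coherence": ["pair"],
    "partial_coherence": ["pair"],
    "eglob": [],
    "pdc": ["source", "sink", "band"],
}


def _compare_groups(tables: dict) -> pd.DataFrame:
    out = []
    for name, keys in _METRIC_KEYS.items():
        df = tables.get(name)
        if df is None or df.empty:
            continue
        for gvals, sub in df.groupby(["week"] + keys) if keys else df.groupby("week"):
            if keys:
                week, *rest = gvals if isinstance(gvals, tuple) else (gvals,)
            else:
                week, rest = gvals, []
            a = sub.loc[sub["group"] == "buffer", "value"].to_numpy()
            b = sub.loc[sub["group"] == "k18", "value"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            label = "/".join([name] + [str(r) for r in rest])
            cmp_ = two_sample_t(a, b, metric=label)
            out.append(_cmp_row(cmp_, week))
    df = tables.get("pac_phase_shift")
    if df is not None and not df.empty:
        for (week, ch), sub in df.groupby(["week", "channel"]):
            a = sub.loc[sub["group"] == "buffer", "value"].to_numpy()
            b = sub.loc[sub["group"] == "k18", "value"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            cmp_ = watson_williams(
                CircularSample(a), CircularSample(b),
                metric=f"pac_phase_shift/{ch}",
            )
            out.append(_cmp_row(cmp_, week))
    cols = ["metric", "week", "mean_buffer", "mean_k18", "ci_lo_buffer",
            "ci_hi_buffer", "ci_lo_k18", "ci_hi_k18", "statistic",
            "statistic_name", "df", "p", "n_buffer", "n_k18",
            "significant", "stars", "notes"]
    frame = pd.DataFrame(out, columns=cols)
    return frame.sort_values(["metric", "week"]).reset_index(drop=True)


def _cmp_row(c, week) -> dict:
    return {
        "metric": c.metric, "week": week,
        "mean_buffer": c.mean_a, "mean_k18": c.mean_b,
        "ci_lo_buffer": c.ci95_a[0], "ci_hi_buffer": c.ci95_a[1],
        "ci_lo_k18": c.ci95_b[0], "ci_hi_k18": c.ci95_b[1],
        "statistic": c.statistic, "statistic_name": c.statistic_name,
        "df": c.df, "p": c.p, "n_buffer": c.n_a, "n_k18": c.n_b,
        "significant": c.significant, "stars": c.stars, "notes": c.notes,
    }


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

_TABLE_NAMES = [
    "relative_power", "band_power", "theta_com", "comodulogram", "mean_pac",
    "pac_phase_shift", "phase_amplitude_curve", "intersite_pac", "coherence",
    "partial_coherence", "coherence_spectrum", "eglob", "pdc", "pdc_spectrum",
]


def run_study(cfg: StudyConfig, cohort=None, out_dir=None) -> CohortResult:
    """Run the full analysis over a cohort.

    ``cohort`` may be a directory path, a ``CohortConfig`` (generated on the
    fly), or an in-memory ``Cohort``.  Stage failures exclude the animal
    from that metric only and are logged, never silently dropped.
    """
    if cohort is None:
        raise ValueError("run_study needs a cohort (path, CohortConfig, or Cohort)")
    cohort = load_cohort(cohort)
    weeks = tuple(cfg.weeks) if cfg.weeks is not None else _cohort_weeks(cohort)
    rows: dict = {name: [] for name in _TABLE_NAMES}
    exclusions = []
    n_sessions = 0
    for group, animal, week in cohort.sessions():
        if week not in weeks:
            continue
        n_sessions += 1
        try:
            rec = cohort.session(animal, week)
            _analyze_session(rec, cfg, rows, group, animal, week)
        except Exception as exc:  # noqa: BLE001 - logged, not swallowed
            exclusions.append(
                {"group": group, "animal": animal, "week": week,
                 "reason": f"{type(exc).__name__}: {exc}"}
            )
    tables = {
        name: pd.DataFrame(rws) for name, rws in rows.items() if rws
    }
    comparisons = _compare_groups(tables)
    cfg_json = json.dumps(cfg.jsonable(), sort_keys=True)
    manifest = {
        "netdyn_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg.jsonable(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_sessions": n_sessions,
        "n_excluded": len(exclusions),
        "weeks": list(weeks),
        "tables": {k: len(v) for k, v in tables.items()},
    }
    result = CohortResult(
        tables,
        comparisons,
        pd.DataFrame(exclusions, columns=["group", "animal", "week", "reason"]),
        manifest,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def render_report(res: CohortResult, out_dir) -> list:
    """Render figure-equivalent panels (spectra, comodulograms, coupling
    bars, connectivity) as PNG files; returns the paths written.

    Empty metric tables skip their panel with a notice rather than failing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    colors = {"buffer": "black", "k18": "green"}

    def _bar_panel(ax, df, title):
        groups = ["buffer", "k18"]
        means = [df.loc[df["group"] == g, "value"].mean() for g in groups]
        ax.bar(groups, means, color=[colors[g] for g in groups], alpha=0.7)
        ax.set_title(title, fontsize=8)

    rel = res.tables.get("relative_power")
    if rel is not None and not rel.empty:
        chans = [c for c in ("CA1L", "CA1R") if c in set(rel["channel"])]
        weeks = sorted(set(rel["week"]))
        if chans:
            fig, axes = plt.subplots(
                len(chans), len(weeks), squeeze=False,
                figsize=(3 * len(weeks), 2.5 * len(chans)),
            )
            for i, ch in enumerate(chans):
                for j, wk in enumerate(weeks):
                    ax = axes[i][j]
                    sub = rel[(rel["channel"] == ch) & (rel["week"] == wk)
                              & (rel["freq_hz"] <= 20) & (rel["freq_hz"] >= 1)]
                    for g, gsub in sub.groupby("group"):
                        m = gsub.groupby("freq_hz")["relpower"].mean()
                        ax.plot(m.index, m.values, color=colors.get(g, "gray"),
                                label=g)
                    ax.set_title(f"{ch} week {wk}", fontsize=8)
                    if i == 0 and j == 0:
                        ax.legend(fontsize=6)
            fig.suptitle("Relative power 1-20 Hz")
            p = out / "relative_power.png"
            fig.tight_layout()
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

    com = res.tables.get("comodulogram")
    if com is not None and not com.empty:
        weeks = sorted(set(com["week"]))
        chans = sorted(set(com["phase_channel"]))[:2]
        fig, axes = plt.subplots(
            len(chans), 2 * len(weeks), squeeze=False,
            figsize=(2.2 * 2 * len(weeks), 2.2 * len(chans)),
        )
        for i, ch in enumerate(chans):
            for j, wk in enumerate(weeks):
                for k, g in enumerate(("buffer", "k18")):
                    ax = axes[i][2 * j + k]
                    sub = com[(com["phase_channel"] == ch)
                              & (com["week"] == wk) & (com["group"] == g)]
                    if sub.empty:
                        ax.axis("off")
                        continue
                    grid = sub.groupby(["f_amp", "f_phase"])["mi"].mean().unstack()
                    ax.pcolormesh(grid.columns, grid.index, grid.values,
                                  shading="nearest", cmap="jet")
                    ax.set_title(f"{ch} wk{wk} {g}", fontsize=7)
        fig.suptitle("PAC comodulograms (phase 2-12 Hz × amplitude 10-200 Hz)")
        p = out / "comodulograms.png"
        fig.tight_layout()
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    bars = [
        ("mean_pac", "channel", "mean theta-gamma PAC"),
        ("eglob", None, "global coherence efficiency"),
        ("coherence", "pair", "band-mean coherence"),
        ("pdc", None, "band-mean extended PDC"),
    ]
    sig = res.comparisons
    panels = []
    for name, key, title in bars:
        df = res.tables.get(name)
        if df is None or df.empty:
            print(f"render_report: no data for panel {name!r}; skipped")
            continue
        panels.append((name, key, title, df))
    if panels:
        fig, axes = plt.subplots(1, len(panels), squeeze=False,
                                 figsize=(3 * len(panels), 2.8))
        for ax, (name, key, title, df) in zip(axes[0], panels):
            _bar_panel(ax, df, title)
            hit = sig[(sig["metric"].str.startswith(name)) & sig["significant"]]
            if not hit.empty:
                stars = hit.iloc[0]["stars"] or "*"
                ax.annotate(stars, xy=(0.5, 0.92), xycoords="axes fraction",
                            ha="center")
        p = out / "group_bars.png"
        fig.tight_layout()
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    if not written:
        print("render_report: empty result, no panels written")
    return written
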