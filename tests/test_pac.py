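"""Modulation index, comodulograms, phase-amplitude curves, phase shift."""

import numpy as np
import pytest

from netdyn import (
    MultichannelRecording,
    analytic,
    comodulogram,
    comodulogram_epochs,
    gen_pac_channel,
    mean_pac,
    modulation_index,
    pac_phase_shift,
    phase_amplitude_curve,
    slice_epochs,
)
from netdyn.pac import Comodulogram, PhaseAmplitudeCurve, default_amp_grid, default_phase_grid
from netdyn.preprocess import AnalyticSeries

from conftest import FS


def _series(phase, amplitude, guard=0):
    return AnalyticSeries(np.asarray(phase, float), np.asarray(amplitude, float),
                          8.0, 1.0, FS, guard)


def _mi_from_signal(x, f_theta=8.0, f_gamma=50.0):
    ph = analytic(x, FS, f_theta, 1.0)
    am = analytic(x, FS, f_gamma, f_theta + 2.0)
    return modulation_index(ph, am)


class TestModulationIndex:
    @pytest.mark.parametrize("m", [0.0, 0.2, 0.4, 0.6, 0.8])
    def test_recovers_half_modulation_depth(self, m):
        """Mean vector of (1+m·cosφ)·e^{iφ} has length m/2 (closed form)."""
        x = gen_pac_channel(FS, 60.0, 8.0, 50.0, m, seed=7)
        assert _mi_from_signal(x) == pytest.approx(m / 2, abs=0.02)

    def test_monotone_in_depth(self):
        mis = [_mi_from_signal(gen_pac_channel(FS, 60.0, 8.0, 50.0, m, seed=3))
               for m in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(mis) > 0)

    def test_uniform_phase_constant_envelope_is_zero(self):
        n = int(FS * 10)
        phase = np.angle(np.exp(1j * 2 * np.pi * 8 * np.arange(n) / FS))
        mi = modulation_index(_series(phase, np.ones(n)),
                              _series(phase, np.ones(n)))
        assert mi < 1e-3

    def test_independent_noise_near_zero(self, rng):
        x = rng.standard_normal(int(FS * 60))
        y = rng.standard_normal(int(FS * 60))
        ph = analytic(x, FS, 8.0, 1.0)
        am = analytic(y, FS, 50.0, 10.0)
        assert modulation_index(ph, am) < 0.05

    def test_amplitude_rescaling_invariance(self):
        x = gen_pac_channel(FS, 30.0, 8.0, 50.0, 0.5, seed=2)
        assert _mi_from_signal(10.0 * x) == pytest.approx(
            _mi_from_signal(x), rel=1e-9
        )

    def test_length_mismatch_rejected(self):
        a = _series(np.zeros(10), np.ones(10))
        b = _series(np.zeros(12), np.ones(12))
        with pytest.raises(ValueError, match="mismatch"):
            modulation_index(a, b)

    def test_zero_envelope_rejected(self):
        a = _series(np.zeros(10), np.ones(10))
        b = _series(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="zero amplitude"):
            modulation_index(a, b)

    def test_bounded_unit_interval(self, rng):
        for _ in range(5):
            ph = rng.uniform(-np.pi, np.pi, 2000)
            am = rng.random(2000) + 0.01
            mi = modulation_index(_series(ph, am), _series(ph, am))
            assert 0.0 <= mi <= 1.0


class TestComodulogram:
    def test_argmax_at_coupled_cell(self):
        x = gen_pac_channel(FS, 60.0, 8.0, 52.0, 0.6, seed=5)
        rec = MultichannelRecording(x[:, None], FS, ["c"])
        c = comodulogram(rec, "c", "c")
        fL, fH = c.argmax_cell()
        assert fL == 8.0
        assert fH in (50.0, 55.0)

    def test_white_noise_grid_near_zero(self):
        rng = np.random.default_rng(21)
        rec = MultichannelRecording(
            rng.standard_normal((int(FS * 60), 1)), FS, ["c"]
        )
        c = comodulogram(rec, "c", "c")
        # slow phase rows (f_L = 2 Hz) have few independent phase cycles at
        # 60 s, which lifts their null MI; the rest of the grid is tight
        assert c.mi[c.phase_freqs >= 4].max() < 0.05
        assert c.mi.max() < 0.1

    def test_default_grids_match_analysis_design(self):
        assert np.array_equal(default_phase_grid(), np.arange(2, 13, 2))
        assert np.array_equal(default_amp_grid(), np.arange(10, 201, 5))

    def test_intersite_equals_intrasite_for_same_channel(self):
        x = gen_pac_channel(FS, 20.0, 8.0, 52.0, 0.5, seed=1)
        rec = MultichannelRecording(
            np.column_stack([x, x]), FS, ["a", "b"]
        )
        pg = np.array([6.0, 8.0])
        ag = np.array([50.0, 55.0])
        c_ab = comodulogram(rec, "a", "b", pg, ag)
        c_aa = comodulogram(rec, "a", "a", pg, ag)
        assert np.allclose(c_ab.mi, c_aa.mi)

    def test_grid_beyond_nyquist_rejected(self):
        rec = MultichannelRecording(np.ones((4096, 1)), FS, ["c"])
        with pytest.raises(ValueError, match="Nyquist"):
            comodulogram(rec, "c", "c", np.array([8.0]), np.array([260.0]))

    def test_epoch_average_close_to_session_estimate(self):
        x = gen_pac_channel(FS, 64.0, 8.0, 50.0, 0.6, seed=9)
        rec = MultichannelRecording(x[:, None], FS, ["c"])
        pg, ag = np.array([8.0]), np.array([50.0])
        c_sess = comodulogram(rec, "c", "c", pg, ag)
        c_ep = comodulogram_epochs(slice_epochs(rec, 8.0), "c", "c", pg, ag)
        # per-epoch estimates are noisier/biased upward but track the session value
        assert c_ep.mi[0, 0] == pytest.approx(c_sess.mi[0, 0], abs=0.05)


class TestMeanPac:
    def _grid(self, mi_value=0.5):
        pg, ag = default_phase_grid(), default_amp_grid()
        return Comodulogram(pg, ag, np.full((len(pg), len(ag)), mi_value),
                            "c", "c")

    def test_constant_field(self):
        assert mean_pac(self._grid(0.3), (3.5, 12.5), (32, 100)) == pytest.approx(0.3)

    def test_singleton_window(self):
        c = self._grid(0.0)
        c.mi[2, 8] = 0.7  # cell (6 Hz, 50 Hz)
        assert mean_pac(c, (5.9, 6.1), (49, 51)) == pytest.approx(0.7)

    def test_window_cell_selection_matches_enumeration(self):
        c = self._grid(0.0)
        got = []
        for i, fL in enumerate(c.phase_freqs):
            for j, fH in enumerate(c.amp_freqs):
                if 3.5 <= fL <= 12.5 and 32 <= fH <= 100:
                    got.append((fL, fH))
                    c.mi[i, j] = 1.0
        expect_phase = {4.0, 6.0, 8.0, 10.0, 12.0}
        expect_amp = set(np.arange(35.0, 101.0, 5.0))
        assert {p for p, _ in got} == expect_phase
        assert {a for _, a in got} == expect_amp
        assert mean_pac(c, (3.5, 12.5), (32, 100)) == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            mean_pac(self._grid(), (2.5, 3.4), (32, 100))


class TestPhaseAmplitudeCurve:
    def _uniform_phase(self, n=60000, seed=0):
        return np.random.default_rng(seed).uniform(-np.pi, np.pi, n)

    def test_cosine_modulation_recovered(self):
        phase = self._uniform_phase()
        amp = 1 + 0.5 * np.cos(phase)
        curve = phase_amplitude_curve(_series(phase, amp), _series(phase, amp))
        expect = 1 + 0.5 * np.sinc(1 / 6) * np.cos(curve.bin_centers)
        # binned expectation of 1+0.5·cosφ: bin-mean of the closed form
        assert np.allclose(curve.mean_amp, expect, atol=0.01)
        # peak bin borders phase 0 (no bin is centered exactly there)
        assert abs(curve.bin_centers[np.argmax(curve.mean_amp)]) < 2 * np.pi / 6

    def test_constant_amplitude_flat(self):
        phase = self._uniform_phase(12000)
        curve = phase_amplitude_curve(_series(phase, np.ones_like(phase)),
                                      _series(phase, np.ones_like(phase)))
        assert np.ptp(curve.mean_amp) == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_amplitude(self):
        phase = self._uniform_phase(12000)
        amp = 1 + 0.3 * np.cos(phase - 1.0)
        c1 = phase_amplitude_curve(_series(phase, amp), _series(phase, amp))
        c2 = phase_amplitude_curve(_series(phase, 2 * amp), _series(phase, 2 * amp))
        assert np.allclose(c2.mean_amp, 2 * c1.mean_amp)

    def test_bins_partition_circle(self):
        phase = self._uniform_phase(6000)
        curve = phase_amplitude_curve(_series(phase, np.ones_like(phase)),
                                      _series(phase, np.ones_like(phase)), n_bins=18)
        assert curve.n_per_bin.sum() == 6000
        assert len(curve.bin_centers) == 18


class TestPacPhaseShift:
    def _curve(self, shift_rad, n_bins=18):
        centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins - np.pi
        return PhaseAmplitudeCurve(
            centers, 1 + 0.5 * np.cos(centers - shift_rad),
            np.full(n_bins, 100)
        )

    def test_zero_shift(self):
        s = pac_phase_shift(self._curve(0.0))
        assert s.angle == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_shift(self):
        s = pac_phase_shift(self._curve(np.pi / 2))
        assert s.angle == pytest.approx(np.pi / 2, abs=2 * np.pi / 18 / 2)

    def test_flat_curve_flagged_unreliable(self):
        n = 18
        centers = (np.arange(n) + 0.5) * 2 * np.pi / n - np.pi
        s = pac_phase_shift(PhaseAmplitudeCurve(centers, np.ones(n),
                                                np.full(n, 10)))
        assert s.resultant_length < 1e-6
        assert not s.reliable

    def test_all_zero_curve_rejected(self):
        n = 6
        centers = (np.arange(n) + 0.5) * 2 * np.pi / n - np.pi
        with pytest.raises(ValueError):
            pac_phase_shift(PhaseAmplitudeCurve(centers, np.zeros(n),
                                                np.full(n, 10)))


def test_mi_and_curve_depth_agree_in_rank():
    """Stronger phase-amplitude curves correspond to larger MI."""
    depths, ptp = [], []
    for m in (0.2, 0.4, 0.6, 0.8):
        x = gen_pac_channel(FS, 40.0, 8.0, 50.0, m, seed=4)
        ph = analytic(x, FS, 8.0, 1.0)
        am = analytic(x, FS, 50.0, 10.0)
        depths.append(modulation_index(ph, am))
        curve = phase_amplitude_curve(ph, am, n_bins=18)
        ptp.append(np.ptp(curve.mean_amp))
    assert np.all(np.diff(depths) > 0)
    assert np.all(np.diff(ptp) > 0)
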