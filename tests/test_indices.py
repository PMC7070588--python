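import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulescan import (AScan, GridGeometry, InclusionSpec, PhantomSpec,
                        PulseModel, compute_cia, compute_cis, gate_plate_echo,
                        index_table, make_pulse, pulse_waveform, select_reference,
                        simulate_scan, spectrum)
from conftest import make_echo


def _ramp(n=16):
    return np.sin(np.linspace(0.3, 7.0, n))


class TestCIA:
    def test_identical_signals_give_zero(self):
        a = make_echo(_ramp())
        assert compute_cia(a, a) == pytest.approx(0.0)

    def test_half_amplitude_gives_three_quarters(self):
        a = _ramp()
        assert compute_cia(make_echo(a), make_echo(0.5 * a)) == pytest.approx(0.75)

    def test_sign_flip_invariant(self):
        a = _ramp()
        assert compute_cia(make_echo(a), make_echo(-a)) == pytest.approx(0.0)

    def test_symmetric(self):
        a, b = make_echo(_ramp()), make_echo(0.3 * _ramp() + 0.1)
        assert compute_cia(a, b) == pytest.approx(compute_cia(b, a))

    def test_zero_signal_is_maximally_dissimilar(self):
        assert compute_cia(make_echo(_ramp()), make_echo(np.zeros(16))) == 1.0

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError, match="zero energy"):
            compute_cia(make_echo(np.zeros(16)), make_echo(_ramp()))

    @given(st.floats(min_value=0.01, max_value=1.0))
    @settings(derandomize=True, max_examples=30)
    def test_scaling_closed_form(self, alpha):
        # CIA(alpha * a, a) = 1 - alpha^2 for |alpha| <= 1
        a = _ramp()
        got = compute_cia(make_echo(alpha * a), make_echo(a))
        assert got == pytest.approx(1.0 - alpha ** 2, abs=1e-12)


class TestCIS:
    def test_proportional_signals_give_zero(self):
        a = _ramp()
        assert compute_cis(make_echo(3.0 * a), make_echo(a)) == pytest.approx(0.0)
        assert compute_cis(make_echo(-2.0 * a), make_echo(a)) == pytest.approx(0.0)

    def test_orthogonal_signals_give_one(self):
        assert compute_cis(make_echo([1.0, 0.0]), make_echo([0.0, 1.0])) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # 1 - 1^2 / (1 * 2) = 0.5
        assert compute_cis(make_echo([1.0, 0.0]), make_echo([1.0, 1.0])) == pytest.approx(0.5)

    def test_zero_energy_raises(self):
        with pytest.raises(ValueError, match="nonzero"):
            compute_cis(make_echo(_ramp()), make_echo(np.zeros(16)))

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=4, max_size=32),
           st.lists(st.floats(min_value=-100, max_value=100), min_size=4, max_size=32))
    @settings(derandomize=True, max_examples=60)
    def test_both_indices_bounded(self, xs, ys):
        n = min(len(xs), len(ys))
        a, b = make_echo(xs[:n]), make_echo(ys[:n])
        if a.energy > 0 and b.energy > 0:
            assert 0.0 <= compute_cia(a, b) <= 1.0
            assert 0.0 <= compute_cis(a, b) <= 1.0


def _ascan_with_echo(delay, amplitude=1.0, extra=None, n_t=2000, fs=200e6, noise=0.0,
                     seed=0):
    t = np.arange(n_t) / fs
    model = PulseModel(amplitude=amplitude)
    samples = pulse_waveform(model, t, t0=delay)
    if extra is not None:
        samples = samples + pulse_waveform(PulseModel(amplitude=extra[1]), t, t0=extra[0])
    if noise:
        samples = samples + np.random.default_rng(seed).normal(0, noise, n_t)
    return AScan(samples=samples, sampling_rate=fs, position=(0.0, 0.0),
                 index=(0, 0), echo_delay=delay, record_start=0.0)


class TestGating:
    def test_gate_centers_on_known_delay(self):
        fs = 200e6
        delay = 4.0e-6
        echo = gate_plate_echo(_ascan_with_echo(delay))
        assert echo.peak_time == pytest.approx(delay, abs=1.0 / fs)
        assert not echo.empty

    def test_gate_locks_on_dominant_echo(self):
        # a second echo 100x smaller must not attract the gate
        echo = gate_plate_echo(_ascan_with_echo(6.0e-6, extra=(2.0e-6, 0.01)))
        assert echo.peak_time == pytest.approx(6.0e-6, abs=5e-9)

    def test_pure_noise_is_flagged_empty(self):
        ascan = _ascan_with_echo(4e-6, amplitude=0.0, noise=0.05, seed=3)
        assert gate_plate_echo(ascan).empty


class TestReference:
    def test_homogeneous_grid_gives_zero_indices(self):
        phantom = PhantomSpec(name="h", length=20, width=12, thickness=15,
                              background_heterogeneity=0.0)
        geom = GridGeometry.from_extent(20, 12, 2.0)
        grid = simulate_scan(phantom, geom, noise_snr_db=np.inf, thickness_ripple=0.0)
        table = index_table(grid)
        assert table["classifiable"].all()
        assert table["cia"].abs().max() < 1e-9
        assert table["cis"].abs().max() < 1e-6

    def test_candidate_on_inclusion_is_rejected(self):
        # one candidate sits dead-centre on a strong inclusion; the
        # most-typical rule must pick a background candidate instead
        inc = InclusionSpec("c", "sphere", (3.0, 3.0, 7.5), (6.0,), 0.6)
        phantom = PhantomSpec(name="p", length=20, width=12, thickness=15,
                              inclusions=[inc], background_heterogeneity=0.0)
        geom = GridGeometry.from_extent(20, 12, 2.0)
        grid = simulate_scan(phantom, geom, noise_snr_db=np.inf, thickness_ripple=0.0)
        candidates = [(1, 1), (9, 0), (0, 5), (9, 5)]  # (1, 1) is at (3, 3) mm
        ref = select_reference(grid, candidates=candidates)
        assert ref.source_index != (1, 1)

    def test_no_usable_candidate_raises(self):
        phantom = PhantomSpec(name="h", length=10, width=10, thickness=15)
        geom = GridGeometry.from_extent(10, 10, 2.0)
        grid = simulate_scan(phantom, geom, noise_snr_db=np.inf, thickness_ripple=0.0)
        grid.waveforms[:] = 0.0
        with pytest.raises(ValueError, match="candidate"):
            select_reference(grid)


class TestSpectrumDiagnostics:
    def test_pure_tone_peaks_at_its_frequency(self):
        fs = 200e6
        t = np.arange(4096) / fs
        tone = np.sin(2 * np.pi * 16e6 * t)
        freqs, mags = spectrum(tone, fs)
        assert freqs[np.argmax(mags)] == pytest.approx(16e6, abs=freqs[1])

    def test_indices_shrink_with_increasing_snr(self):
        phantom = PhantomSpec(name="h", length=20, width=12, thickness=15,
                              background_heterogeneity=0.0)
        geom = GridGeometry.from_extent(20, 12, 2.0)
        means = []
        for snr in (20.0, 60.0):
            grid = simulate_scan(phantom, geom, noise_snr_db=snr, seed=5)
            table = index_table(grid)
            means.append((table["cia"].mean(), table["cis"].mean()))
        assert means[1][0] < means[0][0]
        assert means[1][1] < means[0][1]
        assert means[1][0] < 0.01 and means[1][1] < 0.01
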