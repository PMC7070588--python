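"""Synthetic dry-coupled pulse-echo A-scan generation.

The measurement being emulated is reflectometric: a needle probe (16 MHz
centre frequency, 0.25 fractional bandwidth at -6 dB, 2 mm active element)
is pressed onto the tissue at each point of a rectangular indentation grid
and the strong echo reflected by the stainless-steel plate under the sample
is recorded.  Inclusions stiffer than the background attenuate that plate
echo along the two-way path; at inclusion *edges* diffraction additionally
strips the high-frequency end of the spectrum, distorting the echo shape.
Those two effects - amplitude drop and edge-selective spectral loss - are
exactly what the CIA/CIS detection indices downstream respond to.

The model is deliberately phenomenological (no wave propagation): each
A-scan is a Gaussian-enveloped tone burst delayed by the local two-way
travel time, scaled by a beam-coverage attenuation factor, spectrally
re-weighted at inclusion edges, modulated by background heterogeneity and
bubble-defect dropouts, plus additive white noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .grid import GridGeometry
from .phantom import PhantomSpec

__all__ = [
    "SPEED_OF_SOUND_MM_PER_S",
    "BEAM_WIDTH_MM",
    "EDGE_LOSS_MAX_DB",
    "PulseModel",
    "AScan",
    "ScanGrid",
    "PathEffect",
    "make_pulse",
    "pulse_waveform",
    "path_attenuation",
    "simulate_scan",
]

logger = logging.getLogger(__name__)

#: speed of sound used for echo delays, mm/s (standard soft-tissue value)
SPEED_OF_SOUND_MM_PER_S = 1.54e6
#: beam footprint diameter, mm (the probe's active-element size)
BEAM_WIDTH_MM = 2.0
#: peak extra high-frequency loss at f0 for a half-covered beam, dB
EDGE_LOSS_MAX_DB = 12.0
#: exponent of the (f / f0)**p edge-loss law; > 2 makes the loss sharply
#: high-frequency selective, which is what distorts the echo shape
EDGE_LOSS_EXPONENT = 4.0
#: envelope-peak-to-median threshold below which a record is "no echo"
_BUBBLE_FACTOR_RANGE = (0.2, 0.8)


@dataclass(frozen=True)
class PulseModel:
    """Transmitted probe pulse: Gaussian-enveloped sinusoid.

    The -6 dB full width of the amplitude spectrum equals
    ``fractional_bandwidth_6db * center_frequency`` and the spectral peak
    sits at ``center_frequency``.
    """

    center_frequency: float = 16e6        # Hz
    fractional_bandwidth_6db: float = 0.25
    sampling_rate: float = 200e6          # Hz
    duration: float = 0.8e-6              # s, length of the synthesized burst
    amplitude: float = 1.0                # linear units

    def __post_init__(self) -> None:
        if not 0.0 < self.fractional_bandwidth_6db < 1.0:
            raise ValueError("fractional_bandwidth_6db must lie in (0, 1)")
        if self.sampling_rate < 8.0 * self.center_frequency:
            raise ValueError(
                f"sampling_rate {self.sampling_rate:g} Hz is too low: the Nyquist "
                f"margin requires at least 8 x center_frequency "
                f"({8 * self.center_frequency:g} Hz)")

    @property
    def sigma_f(self) -> float:
        """Std of the Gaussian amplitude spectrum, Hz."""
        # -6 dB (half-magnitude) full width = 2 * sigma_f * sqrt(2 ln 2)
        return (self.fractional_bandwidth_6db * self.center_frequency
                / (2.0 * np.sqrt(2.0 * np.log(2.0))))

    @property
    def sigma_t(self) -> float:
        """Std of the Gaussian time envelope, s."""
        return 1.0 / (2.0 * np.pi * self.sigma_f)


def pulse_waveform(model: PulseModel, t: np.ndarray, t0: float = 0.0) -> np.ndarray:
    """Evaluate the pulse centred at ``t0`` on an arbitrary time axis (s)."""
    tt = np.asarray(t, dtype=float) - t0
    env = np.exp(-tt ** 2 / (2.0 * model.sigma_t ** 2))
    return model.amplitude * env * np.cos(2.0 * np.pi * model.center_frequency * tt)


def make_pulse(model: PulseModel) -> np.ndarray:
    """Synthesize the transmitted pulse sampled at ``model.sampling_rate``."""
    n = int(round(model.duration * model.sampling_rate))
    t = (np.arange(n) - (n - 1) / 2.0) / model.sampling_rate
    return pulse_waveform(model, t)


# ---------------------------------------------------------------------------
# Beam-coverage attenuation
# ---------------------------------------------------------------------------

class PathEffect(NamedTuple):
    """Deterministic effect of the tissue column under one probe position."""

    amplitude_factor: float      # in [0, 1]
    highfreq_loss_db: float      # extra loss at f0; > 0 only at edges
    beam_coverage: float         # fraction of the footprint over inclusions


def _unit_disk_quadrature(n_per_axis: int = 16) -> np.ndarray:
    """Fixed symmetric quadrature points filling the unit disk, shape (m, 2)."""
    s = (np.arange(n_per_axis) + 0.5) / n_per_axis * 2.0 - 1.0
    u, v = np.meshgrid(s, s)
    keep = u ** 2 + v ** 2 < 1.0
    return np.column_stack([u[keep], v[keep]])


_DISK_POINTS = _unit_disk_quadrature()


def path_attenuation(phantom: PhantomSpec, position: tuple[float, float],
                     beam_width: float = BEAM_WIDTH_MM,
                     edge_loss_max_db: float = EDGE_LOSS_MAX_DB) -> PathEffect:
    """Amplitude factor and edge spectral loss for a probe position.

    The beam footprint is a disk of diameter ``beam_width`` centred on
    ``position``.  Coverage is evaluated on a fixed symmetric quadrature
    grid inside the disk, so the result is deterministic and supports any
    footprint shape.  ``amplitude_factor`` is ``1 - <contrast over the
    footprint>``; the extra high-frequency loss is nonzero only when the
    footprint straddles an inclusion boundary (partial coverage), peaking
    for a half-covered beam.
    """
    x, y = position
    r = beam_width / 2.0
    px = x + r * _DISK_POINTS[:, 0]
    py = y + r * _DISK_POINTS[:, 1]
    point_contrast = np.zeros(px.shape)
    covered = np.zeros(px.shape, dtype=bool)
    for inc in phantom.inclusions:
        inside = inc.contains_lateral(px, py)
        covered |= inside
        point_contrast = np.where(inside, np.maximum(point_contrast, inc.amplitude_contrast),
                                  point_contrast)
    f_cover = float(covered.mean())
    amplitude_factor = float(np.clip(1.0 - point_contrast.mean(), 0.0, 1.0))
    highfreq_loss_db = edge_loss_max_db * 4.0 * f_cover * (1.0 - f_cover)
    return PathEffect(amplitude_factor, highfreq_loss_db, f_cover)


# ---------------------------------------------------------------------------
# A-scan containers
# ---------------------------------------------------------------------------

@dataclass
class AScan:
    """One sampled plate-echo record at one grid point."""

    samples: np.ndarray
    sampling_rate: float
    position: tuple[float, float]       # (x, y) mm
    index: tuple[int, int]              # (i, j) grid indices, i along X
    echo_delay: float                   # two-way travel time to the plate, s
    record_start: float = 0.0           # time of sample 0 relative to excitation, s

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("A-scan samples must be finite")


@dataclass
class ScanGrid:
    """The full indentation matrix of A-scans.

    ``waveforms`` has shape ``(n_y, n_x, n_t)`` with rows along Y.
    """

    geometry: GridGeometry
    waveforms: np.ndarray
    sampling_rate: float
    record_start: float
    echo_delays: np.ndarray             # (n_y, n_x), s
    phantom_name: str = ""
    seed: int = 0
    pulse: PulseModel = field(default_factory=PulseModel)

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        self.echo_delays = np.asarray(self.echo_delays, dtype=float)
        ny, nx = self.geometry.n_y, self.geometry.n_x
        if self.waveforms.shape[:2] != (ny, nx):
            raise ValueError("waveform array does not match the grid geometry")
        if self.echo_delays.shape != (ny, nx):
            raise ValueError("echo-delay array does not match the grid geometry")

    @property
    def n_points(self) -> int:
        return self.geometry.n_points

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[2]

    def ascan(self, i: int, j: int) -> AScan:
        """A-scan at grid point ``(i, j)``; ``i`` along X, ``j`` along Y."""
        return AScan(
            samples=self.waveforms[j, i],
            sampling_rate=self.sampling_rate,
            position=(float(self.geometry.x_centers[i]), float(self.geometry.y_centers[j])),
            index=(i, j),
            echo_delay=float(self.echo_delays[j, i]),
            record_start=self.record_start,
        )

    def iter_ascans(self):
        for j in range(self.geometry.n_y):
            for i in range(self.geometry.n_x):
                yield self.ascan(i, j)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _place_bubbles(phantom: PhantomSpec) -> list[tuple[float, float, float]]:
    """Poisson-place bubble defects in each inclusion; (x, y, factor) each.

    Placement depends only on the phantom's own seed: bubbles are part of
    the object, not of an acquisition.
    """
    rng = np.random.default_rng(phantom.seed)
    bubbles: list[tuple[float, float, float]] = []
    for inc in phantom.inclusions:
        n = rng.poisson(inc.bubble_density * inc.volume_mm3())
        x0, x1, y0, y1 = inc.lateral_bounds()
        placed = 0
        while placed < n:
            bx = rng.uniform(x0, x1)
            by = rng.uniform(y0, y1)
            if inc.contains_lateral(bx, by):
                factor = rng.uniform(*_BUBBLE_FACTOR_RANGE)
                bubbles.append((bx, by, factor))
                placed += 1
            else:  # rejected draw still consumes randomness deterministically
                continue
    return bubbles


def _edge_reshape(wave: np.ndarray, sampling_rate: float, loss_db: float,
                  f0: float) -> np.ndarray:
    """Apply the high-frequency-selective edge loss in the spectral domain.

    The amplitude spectrum is multiplied by ``10**(-(loss_db/20) *
    (f/f0)**p)``: exactly ``loss_db`` dB at the centre frequency, sharply
    more above it, little below - the diffraction signature of an
    inclusion edge.
    """
    n = wave.size
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    weight = 10.0 ** (-(loss_db / 20.0) * (freqs / f0) ** EDGE_LOSS_EXPONENT)
    return np.fft.irfft(np.fft.rfft(wave) * weight, n=n)


def simulate_scan(phantom: PhantomSpec, geometry: GridGeometry,
                  pulse: PulseModel | None = None,
                  noise_snr_db: float = 30.0,
                  seed: int = 0,
                  record_duration: float = 10e-6,
                  beam_width: float = BEAM_WIDTH_MM,
                  thickness_ripple: float = 0.002,
                  edge_loss_max_db: float = EDGE_LOSS_MAX_DB) -> ScanGrid:
    """Synthesize one full grid acquisition over a phantom.

    Parameters
    ----------
    noise_snr_db
        Additive-white-noise SNR in dB relative to the *background* plate
        echo peak.  ``inf`` disables noise.  Non-positive values are
        accepted but logged as a warning.
    record_duration
        Length of each A-scan record, s.  The record window is gated around
        the expected plate echo (it starts 2 us before the nominal two-way
        travel time), not at the excitation instant.
    thickness_ripple
        Fractional amplitude of a smooth spatial variation of the sample
        thickness, giving each echo its own small delay.
    seed
        Fixes noise and heterogeneity jitter; the same (phantom, seed) pair
        reproduces every sample bit-identically.
    """
    pulse = pulse or PulseModel()
    x_min, x_max, y_min, y_max = geometry.extent
    tol = 1e-9
    if (x_min < -tol or x_max > phantom.length + tol
            or y_min < -tol or y_max > phantom.width + tol):
        raise ValueError("scan grid lies outside the phantom's lateral extent")
    if noise_snr_db <= 0:
        logger.warning("noise_snr_db = %.1f dB <= 0: echoes will be noise-dominated",
                       noise_snr_db)

    c = SPEED_OF_SOUND_MM_PER_S
    nominal_delay = 2.0 * phantom.thickness / c
    record_start = max(nominal_delay - 2e-6, 0.0)
    n_t = int(round(record_duration * pulse.sampling_rate))
    t_axis = record_start + np.arange(n_t) / pulse.sampling_rate

    rng = np.random.default_rng(seed)
    rng_jitter, rng_noise = rng.spawn(2)
    ny, nx = geometry.n_y, geometry.n_x
    jitter = np.clip(rng_jitter.normal(1.0, phantom.background_heterogeneity, (ny, nx)),
                     0.05, None)
    sigma = 0.0 if np.isinf(noise_snr_db) else pulse.amplitude / 10.0 ** (noise_snr_db / 20.0)

    bubbles = _place_bubbles(phantom)
    bubble_xy = np.array([(bx, by) for bx, by, _ in bubbles]).reshape(-1, 2)
    bubble_factor = np.array([f for _, _, f in bubbles])
    beam_r = beam_width / 2.0

    waveforms = np.empty((ny, nx, n_t))
    delays = np.empty((ny, nx))
    xs, ys = geometry.x_centers, geometry.y_centers
    for j in range(ny):
        for i in range(nx):
            x, y = xs[i], ys[j]
            local_thickness = phantom.thickness * (
                1.0 + thickness_ripple * np.sin(2.0 * np.pi * x / phantom.length)
                * np.cos(2.0 * np.pi * y / phantom.width))
            delay = 2.0 * local_thickness / c
            effect = path_attenuation(phantom, (x, y), beam_width, edge_loss_max_db)
            amp = effect.amplitude_factor * jitter[j, i]
            if bubble_factor.size:
                near = (np.hypot(bubble_xy[:, 0] - x, bubble_xy[:, 1] - y) < beam_r)
                if near.any():
                    amp *= float(np.prod(bubble_factor[near]))
            wave = amp * pulse_waveform(pulse, t_axis, t0=delay)
            if effect.highfreq_loss_db > 0.0:
                wave = _edge_reshape(wave, pulse.sampling_rate,
                                     effect.highfreq_loss_db, pulse.center_frequency)
            waveforms[j, i] = wave
            delays[j, i] = delay
    if sigma > 0.0:
        waveforms += rng_noise.normal(0.0, sigma, waveforms.shape)

    return ScanGrid(geometry=geometry, waveforms=waveforms,
                    sampling_rate=pulse.sampling_rate, record_start=record_start,
                    echo_delays=delays, phantom_name=phantom.name, seed=seed,
                    pulse=pulse)
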