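"""Synthetic scanning-conductivity experiments with known ground truth.

Emulates the bench protocol end to end: a pre-run background scan of the
boundary-free channel, then a series of unidirectional scans starting at
7 min on the electrophoresis clock, repeated every 2 min at 1.0 mm/s, over a
24 mm channel in which a trough-shaped boundary signature migrates at a
concentration-dependent velocity U = a*log10(C) + b.  A parameterized noise
model (additive white noise, optional polynomial baseline drift and rare
spikes) makes every downstream stage testable without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .forward import (
    BoundaryState,
    ChannelGeometry,
    ElectrodeWindow,
    ScanTrace,
    SpatialProfile,
    erf_conductivity,
    erf_conductivity_profile,
    scan_response,
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one synthetic calibration experiment.

    The schedule (first scan at 7 min, 2 min interval, 4 scans, 1.0 mm/s)
    matches the bench protocol.  The velocity law keeps the measured slope of
    0.272 mm/min per decade; the intercept and the boundary-formation offset
    ``x0_mm`` are chosen so that every calibration concentration yields an
    advancing boundary that stays inside the scannable window for the whole
    run (see the methods note).  Noise defaults to white with SD equal to 2%
    of the conductivity step sigma2 - sigma1; drift and spikes are off.
    """

    concentrations_mM: tuple[float, ...] = (0.2, 0.5, 1.0, 3.5, 10.0, 30.0, 50.0)
    slope_a: float = 0.272  # mm/min per decade of concentration
    intercept_b: float = 0.55  # mm/min
    x0_mm: float = 4.0  # boundary position at clock zero

    first_scan_clock_min: float = 7.0
    scan_interval_min: float = 2.0
    n_scans: int = 4
    scan_speed_mm_s: float = 1.0
    sample_rate_hz: float = 100.0

    sigma1: float = 0.08  # S/m, titrated zone behind the boundary
    sigma2: float = 0.10  # S/m, background electrolyte ahead
    D: float = 1.0e-9  # m^2/s effective boundary diffusion
    depletion_amp: float = 0.08  # S/m leading-edge dip depth
    depletion_width_mm: float = 1.0
    depletion_offset_mm: float = 0.5
    accumulation_amp: float = 0.0

    noise_sd: float = 0.0004  # S/m, white; 2% of (sigma2 - sigma1)
    drift_coeffs: tuple[float, ...] = ()  # polynomial in scan time t_s, low order first
    spike_prob: float = 0.0  # per-sample probability of an additive spike
    spike_amp: float = 0.0

    seed: int = 0

    channel: ChannelGeometry = field(default_factory=ChannelGeometry)
    window: ElectrodeWindow = field(default_factory=ElectrodeWindow)
    grid_dx_mm: float = 0.01
    #: render the boundary frozen at the scan-start clock (the stationary
    #: idealization) instead of letting it migrate during the 17.5 s scan
    freeze_boundary_during_scan: bool = False

    def __post_init__(self) -> None:
        if self.n_scans < 3:
            raise ConfigurationError("need at least 3 scans for a velocity fit")
        for c in self.concentrations_mM:
            u = self.velocity_mm_min(c)
            if abs(u) >= self.scan_speed_mm_s * 60.0:
                raise ConfigurationError(
                    f"boundary velocity {u:.3g} mm/min at {c} mM is not below the "
                    f"scan speed ({self.scan_speed_mm_s * 60:.3g} mm/min): the "
                    "detector could never catch up with the boundary"
                )

    def velocity_mm_min(self, conc_mM: float) -> float:
        if conc_mM <= 0:
            raise ConfigurationError("concentrations must be positive")
        return self.slope_a * np.log10(conc_mM) + self.intercept_b

    def scan_clocks_min(self) -> np.ndarray:
        return self.first_scan_clock_min + self.scan_interval_min * np.arange(
            self.n_scans
        )

    @property
    def x_scan_start_mm(self) -> float:
        """First detector-center position with the window inside the channel."""
        return self.window.support_mm / 2.0


@dataclass(frozen=True)
class GroundTruth:
    """True generating quantities for a synthetic experiment."""

    slope_a: float
    intercept_b: float
    x0_mm: float
    velocities_mm_min: dict[float, float]  # conc -> U
    positions_mm: dict[float, np.ndarray]  # conc -> boundary center per scan clock
    scan_clocks_min: np.ndarray


@dataclass
class SyntheticExperiment:
    baseline: ScanTrace
    traces: dict[float, list[ScanTrace]]  # conc -> one trace per scan
    truth: GroundTruth
    config: ExperimentConfig


def _apply_noise(trace: ScanTrace, config: ExperimentConfig, rng: np.random.Generator) -> ScanTrace:
    s = trace.signal.copy()
    if config.noise_sd > 0:
        s = s + rng.normal(0.0, config.noise_sd, s.size)
    if config.drift_coeffs:
        drift = np.polynomial.polynomial.polyval(trace.t_s, config.drift_coeffs)
        s = s + drift
    if config.spike_prob > 0 and config.spike_amp != 0:
        hits = rng.random(s.size) < config.spike_prob
        s = s + np.where(hits, rng.choice([-1.0, 1.0], s.size) * config.spike_amp, 0.0)
    return trace.with_signal(s)


def _flat_profile(config: ExperimentConfig) -> SpatialProfile:
    grid = config.channel.grid(config.grid_dx_mm)
    return SpatialProfile(
        x_mm=grid, sigma=np.full_like(grid, config.sigma2), time_min=0.0
    )


def _render_scan(
    config: ExperimentConfig,
    profile: SpatialProfile,
    clock_min: float,
) -> ScanTrace:
    return scan_response(
        profile,
        config.window,
        scan_speed_mm_s=config.scan_speed_mm_s,
        x_start_mm=config.x_scan_start_mm,
        sample_rate_hz=config.sample_rate_hz,
        scan_start_clock_min=clock_min,
    )


def _render_moving_boundary_scan(
    config: ExperimentConfig, state: BoundaryState, clock_min: float
) -> ScanTrace:
    """Render a scan with the boundary migrating while the detector moves.

    Each sample evaluates the analytic boundary conductivity at the
    electrophoresis clock of that sample, so a fix at scan time t maps
    consistently onto the boundary position at clock + t/60.
    """
    half = config.window.support_mm / 2.0
    x_start = config.x_scan_start_mm
    duration = (config.channel.length_mm - half - x_start) / config.scan_speed_mm_s
    n = int(np.floor(duration * config.sample_rate_hz)) + 1
    t = np.arange(n) / config.sample_rate_hz
    centers = x_start + config.scan_speed_mm_s * t
    offsets, w = config.window.weights(config.grid_dx_mm)
    tau = clock_min + t / 60.0
    sigma = erf_conductivity(
        centers[:, None] + offsets[None, :], tau[:, None], state
    )
    return ScanTrace(
        t_s=t,
        signal=sigma @ w,
        scan_speed_mm_s=config.scan_speed_mm_s,
        scan_start_clock_min=clock_min,
        x_start_mm=x_start,
    )


def generate_experiment(config: ExperimentConfig) -> SyntheticExperiment:
    """Generate the background scan, all timed scans and the ground truth.

    Each scan renders the analytic boundary profile frozen at its scan clock
    (the boundary is effectively stationary during one 17.5 s scan) through
    the electrode window, then adds seeded noise.  Noise streams are spawned
    deterministically from ``config.seed``, so identical configs give
    bit-identical outputs.
    """
    clocks = config.scan_clocks_min()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.concentrations_mM) * len(clocks))
    rngs = [np.random.default_rng(c) for c in children]

    baseline = _apply_noise(
        _render_scan(config, _flat_profile(config), clock_min=0.0), config, rngs[0]
    )

    traces: dict[float, list[ScanTrace]] = {}
    velocities: dict[float, float] = {}
    positions: dict[float, np.ndarray] = {}
    k = 1
    for conc in config.concentrations_mM:
        u = config.velocity_mm_min(conc)
        state = BoundaryState(
            sigma1=config.sigma1,
            sigma2=config.sigma2,
            U_mm_min=u,
            D=config.D,
            x0_mm=config.x0_mm,
            depletion_amp=config.depletion_amp,
            depletion_width_mm=config.depletion_width_mm,
            depletion_offset_mm=config.depletion_offset_mm,
            accumulation_amp=config.accumulation_amp,
        )
        series: list[ScanTrace] = []
        for clock in clocks:
            if config.freeze_boundary_during_scan:
                profile = erf_conductivity_profile(
                    config.channel.grid(config.grid_dx_mm), clock, state
                )
                clean = _render_scan(config, profile, clock)
            else:
                clean = _render_moving_boundary_scan(config, state, clock)
            series.append(_apply_noise(clean, config, rngs[k]))
            k += 1
        traces[conc] = series
        velocities[conc] = u
        positions[conc] = config.x0_mm + u * clocks
    truth = GroundTruth(
        slope_a=config.slope_a,
        intercept_b=config.intercept_b,
        x0_mm=config.x0_mm,
        velocities_mm_min=velocities,
        positions_mm=positions,
        scan_clocks_min=clocks,
    )
    return SyntheticExperiment(baseline=baseline, traces=traces, truth=truth, config=config)


def generate_negative_control(config: ExperimentConfig) -> list[ScanTrace]:
    """Boundary-free scan series (noise and drift only).

    Emulates incomplete reaction mixes: the channel holds only background
    electrolyte, so after baseline subtraction the downstream pipeline should
    find no valid boundary at any realistic quality threshold.
    """
    clocks = config.scan_clocks_min()
    # distinct stream domain so controls never share noise with the
    # experiment's baseline/traces generated from the same seed
    ss = np.random.SeedSequence(config.seed, spawn_key=(1,))
    children = ss.spawn(len(clocks))
    flat = _flat_profile(config)
    return [
        _apply_noise(
            _render_scan(config, flat, clock), config, np.random.default_rng(child)
        )
        for clock, child in zip(clocks, children)
    ]
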