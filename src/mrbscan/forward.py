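"""Forward model of a moving reaction boundary seen by a scanning conductivity detector.

The physical picture: an electrophoresis channel carries a migrating reaction
boundary between a low-conductivity zone (behind, where the colored cation CV+
has titrated the hydroxide) and the undisturbed background electrolyte (ahead).
A pair of contactless-conductivity electrodes is translated along the channel
at constant speed, so the spatial conductivity profile sigma_E(x) is read out
as a time-domain trace sigma_D(t) through a sliding-window response function f:

    sigma_D(t) = sum_k f(k) * sigma_E(x(t) + offset_k),   x(t) = x_start + v_scan * t

Interface units follow bench conventions: positions in mm, electrophoresis
time in min, boundary velocities in mm/min, scan speed in mm/s. Physics
(diffusion coefficients, mobilities, conductivities) is SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.special import erf

from .errors import ConfigurationError, DomainError

#: Faraday constant, C/mol.
FARADAY = 96485.33212

_MM = 1e-3  # mm -> m
_MIN = 60.0  # min -> s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelGeometry:
    """Separation-channel geometry.

    ``x = 0`` is the anode-side channel entrance; x increases toward the
    cathode, the direction the boundary normally migrates.
    """

    length_mm: float = 24.0
    width_um: float = 200.0
    depth_um: float = 100.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_um <= 0 or self.depth_um <= 0:
            raise DomainError("channel length, width and depth must all be positive")

    def grid(self, dx_mm: float = 0.01) -> np.ndarray:
        """Uniform spatial grid over the channel (default 10 um spacing)."""
        n = int(round(self.length_mm / dx_mm)) + 1
        return np.linspace(0.0, self.length_mm, n)


@dataclass(frozen=True)
class ElectrodeWindow:
    """Discretizable sliding-window response of the electrode pair.

    Shapes:

    ``unipolar_trapezoid``
        Non-negative, normalized to unit sum.  Sensitivity ramps up across
        the actuator electrode, is flat over the inter-electrode gap (where
        the conduction path the detector probes lies) and ramps down across
        the pick-up electrode.  Reproduces the single-trough signature of a
        boundary passage.
    ``bipolar_differential``
        Antiparallel pick-up: +1-normalized rectangle over the actuator
        footprint minus a 1-normalized rectangle over the pick-up footprint.
        Integrates to zero, so uniform conductivity gives zero signal.
    ``delta``
        Unit weight at a single grid point; the trace is then the profile
        resampled along the scan path.
    """

    actuator_width_mm: float = 2.5
    pickup_width_mm: float = 2.5
    gap_mm: float = 1.5
    cross_length_mm: float = 1.1
    shape: Literal["unipolar_trapezoid", "bipolar_differential", "delta"] = (
        "unipolar_trapezoid"
    )

    def __post_init__(self) -> None:
        if min(self.actuator_width_mm, self.pickup_width_mm, self.gap_mm) <= 0:
            raise DomainError("electrode widths and gap must be positive")

    @property
    def support_mm(self) -> float:
        """Spatial extent of the response (actuator + gap + pick-up)."""
        if self.shape == "delta":
            return 0.0
        return self.actuator_width_mm + self.gap_mm + self.pickup_width_mm

    def weights(self, dx_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Discretize the window on spacing ``dx_mm``.

        Returns ``(offsets_mm, w)`` with offsets centered on the electrode
        pair's midpoint.  Unipolar weights sum to exactly 1; bipolar weights
        sum to 0 with each lobe summing to +/-1.
        """
        if dx_mm <= 0:
            raise DomainError("dx_mm must be positive")
        if self.shape == "delta":
            return np.array([0.0]), np.array([1.0])
        half = self.support_mm / 2.0
        n = int(round(self.support_mm / dx_mm)) + 1
        offsets = np.linspace(-half, half, n)
        if self.shape == "unipolar_trapezoid":
            # piecewise-linear: 0 at the outer edges, 1 across the gap
            w = np.interp(
                offsets,
                [-half, -self.gap_mm / 2.0, self.gap_mm / 2.0, half],
                [0.0, 1.0, 1.0, 0.0],
            )
            w = w / w.sum()
        elif self.shape == "bipolar_differential":
            w = np.zeros_like(offsets)
            act = offsets <= -self.gap_mm / 2.0
            pick = offsets >= self.gap_mm / 2.0
            w[act] = 1.0 / act.sum()
            w[pick] = -1.0 / pick.sum()
        else:  # pragma: no cover - guarded by Literal
            raise ConfigurationError(f"unknown window shape {self.shape!r}")
        return offsets, w


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species with unit charge magnitude.

    mobility in m^2 V^-1 s^-1, diffusion coefficient in m^2 s^-1,
    reservoir concentrations in mol m^-3 (== mM).
    """

    name: str
    charge_sign: int
    mobility: float
    diffusion_coeff: float
    init_conc_left: float = 0.0
    init_conc_right: float = 0.0

    def __post_init__(self) -> None:
        if self.charge_sign not in (-1, 1):
            raise DomainError(f"charge_sign must be +/-1, got {self.charge_sign}")
        if self.mobility < 0:
            raise DomainError("mobility must be non-negative")
        if self.diffusion_coeff <= 0:
            raise DomainError("diffusion_coeff must be positive")
        if self.init_conc_left < 0 or self.init_conc_right < 0:
            raise DomainError("concentrations must be non-negative")


@dataclass(frozen=True)
class BoundaryState:
    """Parameters of the analytic (erf) moving-boundary model.

    sigma1 is the zone conductivity behind the boundary (anode side, the
    titrated CV+ zone), sigma2 the zone ahead of it; the boundary center is at
    ``x0_mm + U_mm_min * t`` on the electrophoresis clock.  The optional
    depletion dip / anion-accumulation bump are localized Gaussian
    perturbations centered slightly ahead of the boundary, emulating the
    low-conductivity leading edge the real titration develops.
    """

    sigma1: float
    sigma2: float
    U_mm_min: float
    D: float = 1.0e-9
    c0: float = 1.0
    x0_mm: float = 0.0
    depletion_amp: float = 0.0
    depletion_width_mm: float = 0.5
    depletion_offset_mm: float = 0.5
    accumulation_amp: float = 0.0
    accumulation_width_mm: float = 0.5
    accumulation_offset_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise DomainError("zone conductivities must be positive")
        if self.D <= 0:
            raise DomainError("diffusion coefficient must be positive")
        if self.depletion_amp < 0 or self.accumulation_amp < 0:
            raise DomainError("perturbation amplitudes must be non-negative")

    def center_mm(self, t_min: float) -> float:
        """Boundary center position at electrophoresis time ``t_min``."""
        return self.x0_mm + self.U_mm_min * t_min


@dataclass(frozen=True)
class SpatialProfile:
    """Conductivity sigma(x) on a uniform grid at one electrophoresis time."""

    x_mm: np.ndarray
    sigma: np.ndarray
    time_min: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x_mm, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "x_mm", x)
        object.__setattr__(self, "sigma", s)
        if x.ndim != 1 or x.size < 2:
            raise DomainError("profile grid must be a 1-D array with >= 2 points")
        dx = np.diff(x)
        if not np.all(dx > 0) or not np.allclose(dx, dx[0], rtol=1e-8, atol=1e-12):
            raise DomainError("profile grid must be strictly increasing and uniform")
        if s.shape != x.shape:
            raise DomainError("sigma and x must have the same shape")
        if not np.all(np.isfinite(s)):
            raise DomainError("sigma must be finite everywhere")

    @property
    def dx_mm(self) -> float:
        return float(self.x_mm[1] - self.x_mm[0])

    def interp(self, x_mm) -> np.ndarray:
        return np.interp(x_mm, self.x_mm, self.sigma)


@dataclass(frozen=True)
class ScanTrace:
    """Detector output for one unidirectional scan.

    ``t_s`` is seconds since scan start (uniform sampling); the detector
    center is at ``x_start_mm + scan_speed_mm_s * t``.  ``scan_start_clock_min``
    is the electrophoresis clock at scan start.
    """

    t_s: np.ndarray
    signal: np.ndarray
    scan_speed_mm_s: float
    scan_start_clock_min: float
    x_start_mm: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.size < 2:
            raise DomainError("trace must be a 1-D array with >= 2 samples")
        dt = np.diff(t)
        if not np.all(dt > 0) or not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise DomainError("trace time grid must be strictly increasing and uniform")
        if s.shape != t.shape:
            raise DomainError("signal and t must have the same shape")
        if self.scan_speed_mm_s <= 0:
            raise DomainError("scan_speed must be positive")

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    def positions_mm(self) -> np.ndarray:
        """Detector center position at each sample."""
        return self.x_start_mm + self.scan_speed_mm_s * self.t_s

    def with_signal(self, signal: np.ndarray) -> "ScanTrace":
        return replace(self, signal=np.asarray(signal, dtype=float))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def conductivity_from_species(
    species_concs: Mapping[str, float | np.ndarray],
    species: Sequence[IonSpecies],
) -> float | np.ndarray:
    """Solution conductivity from per-species concentrations (Kohlrausch law).

    sigma = F * sum_i mu_i * c_i over all (unit-charge) cations and anions,
    with c_i in mol m^-3 and mu_i in m^2 V^-1 s^-1; result in S/m.
    Species absent from ``species_concs`` contribute zero.
    """
    if len(species) == 0:
        raise ConfigurationError("species list must not be empty")
    total = 0.0
    for sp in species:
        c = np.asarray(species_concs.get(sp.name, 0.0), dtype=float)
        if np.any(c < 0):
            raise DomainError(f"negative concentration for species {sp.name!r}")
        total = total + sp.mobility * c
    out = FARADAY * total
    return float(out) if np.ndim(out) == 0 else out


def linear_boundary_profile(
    state: BoundaryState,
    x1_mm: float,
    x2_mm: float,
    grid_mm: np.ndarray,
) -> SpatialProfile:
    """Idealized sharp boundary: sigma1 behind x1, sigma2 past x2, linear between."""
    if x1_mm >= x2_mm:
        raise DomainError(f"x1 ({x1_mm}) must be < x2 ({x2_mm})")
    grid = np.asarray(grid_mm, dtype=float)
    sigma = np.interp(grid, [x1_mm, x2_mm], [state.sigma1, state.sigma2])
    return SpatialProfile(x_mm=grid, sigma=sigma, time_min=0.0)


def _erf_argument(x_mm, t_min: float, state: BoundaryState) -> np.ndarray:
    """(x - x_center) / (2 sqrt(D t)) with mm/min interface units mapped to SI."""
    x_m = (np.asarray(x_mm, dtype=float) - state.center_mm(t_min)) * _MM
    return x_m / (2.0 * np.sqrt(state.D * t_min * _MIN))


def erf_front_concentration(
    x_mm, t_min: float, state: BoundaryState
) -> float | np.ndarray:
    """Advected-diffused concentration front of the titrant cation.

    c(x, t) = c0 * (1 - erf((x - U t) / (2 sqrt(D t)))): tends to 2*c0 far
    behind the boundary and to 0 far ahead; equals c0 at the boundary center.
    """
    if t_min <= 0:
        raise DomainError("t must be positive")
    c = state.c0 * (1.0 - erf(_erf_argument(x_mm, t_min, state)))
    return float(c) if np.ndim(c) == 0 else c


def _gaussian_bump(x_mm: np.ndarray, center_mm: float, width_mm: float) -> np.ndarray:
    return np.exp(-0.5 * ((x_mm - center_mm) / width_mm) ** 2)


def erf_conductivity(x_mm, t_min, state: BoundaryState) -> np.ndarray:
    """Pointwise boundary conductivity; broadcasts over positions and times.

    Asymptote-consistent diffuse step

        sigma(x, t) = sigma1 + (sigma2 - sigma1)/2 * (1 + erf((x - x_c)/(2 sqrt(D t))))

    so sigma -> sigma1 far behind the boundary and -> sigma2 far ahead, with
    the midpoint (sigma1+sigma2)/2 at the boundary center x_c(t).  Nonzero
    ``depletion_amp`` subtracts a Gaussian dip just ahead of x_c (the
    low-conductivity leading edge); ``accumulation_amp`` adds a bump further
    ahead (local anion pile-up).
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t <= 0):
        raise DomainError("t must be positive")
    x = np.asarray(x_mm, dtype=float)
    z = _erf_argument(x, t, state)
    sigma = state.sigma1 + 0.5 * (state.sigma2 - state.sigma1) * (1.0 + erf(z))
    xc = state.center_mm(t)
    if state.depletion_amp > 0:
        sigma = sigma - state.depletion_amp * _gaussian_bump(
            x, xc + state.depletion_offset_mm, state.depletion_width_mm
        )
    if state.accumulation_amp > 0:
        sigma = sigma + state.accumulation_amp * _gaussian_bump(
            x, xc + state.accumulation_offset_mm, state.accumulation_width_mm
        )
    if np.any(sigma <= 0):
        raise DomainError(
            "perturbation amplitudes drive the conductivity non-positive"
        )
    return sigma


def erf_conductivity_profile(
    grid_mm: np.ndarray, t_min: float, state: BoundaryState
) -> SpatialProfile:
    """Diffuse boundary conductivity on a grid at one electrophoresis time.

    See :func:`erf_conductivity` for the model.
    """
    grid = np.asarray(grid_mm, dtype=float)
    return SpatialProfile(
        x_mm=grid, sigma=erf_conductivity(grid, t_min, state), time_min=float(t_min)
    )


def scan_response(
    profile: SpatialProfile,
    window: ElectrodeWindow,
    scan_speed_mm_s: float,
    x_start_mm: float,
    sample_rate_hz: float,
    duration_s: float | None = None,
    scan_start_clock_min: float | None = None,
) -> ScanTrace:
    """Render a detector trace by sliding the window response along the profile.

    The boundary is treated as stationary during one scan (the scan is fast
    compared with the boundary migration).  The detector center moves from
    ``x_start_mm`` at ``scan_speed_mm_s``; by default the scan ends when the
    window support would leave the profile's grid.
    """
    if scan_speed_mm_s <= 0:
        raise DomainError("scan_speed must be positive")
    if sample_rate_hz <= 0:
        raise DomainError("sample_rate must be positive")
    half = window.support_mm / 2.0
    x_lo, x_hi = float(profile.x_mm[0]), float(profile.x_mm[-1])
    if window.support_mm >= (x_hi - x_lo):
        raise ConfigurationError(
            f"window support ({window.support_mm} mm) does not fit in the "
            f"profile extent ({x_hi - x_lo} mm)"
        )
    if x_start_mm - half < x_lo - 1e-9:
        raise ConfigurationError(
            f"scan start {x_start_mm} mm puts the window edge before the channel"
        )
    max_duration = (x_hi - half - x_start_mm) / scan_speed_mm_s
    if duration_s is None:
        duration_s = max_duration
    elif duration_s > max_duration + 1e-9:
        raise ConfigurationError(
            "requested scan duration drives the window past the channel end"
        )
    n = int(np.floor(duration_s * sample_rate_hz)) + 1
    if n < 2:
        raise ConfigurationError("scan too short for the requested sample rate")
    t = np.arange(n) / sample_rate_hz
    centers = x_start_mm + scan_speed_mm_s * t
    offsets, w = window.weights(profile.dx_mm)
    # (n_samples, n_weights) sampling positions; profile covers them by construction
    samples = profile.interp(centers[:, None] + offsets[None, :])
    signal = samples @ w
    if scan_start_clock_min is None:
        scan_start_clock_min = profile.time_min
    return ScanTrace(
        t_s=t,
        signal=signal,
        scan_speed_mm_s=scan_speed_mm_s,
        scan_start_clock_min=scan_start_clock_min,
        x_start_mm=x_start_mm,
    )


# ---------------------------------------------------------------------------
# 1-D Nernst-Planck electromigration-diffusion-reaction simulator
# ---------------------------------------------------------------------------


@dataclass
class ElectromigrationResult:
    """Time series emitted by :func:`simulate_electromigration`."""

    times_min: np.ndarray
    profiles: list[SpatialProfile]
    concentrations: list[dict[str, np.ndarray]] = field(default_factory=list)


def simulate_electromigration(
    species: Sequence[IonSpecies],
    field_V_m: float,
    grid_mm: np.ndarray,
    dt_s: float,
    t_end_min: float,
    reaction: bool = False,
    reactants: tuple[str, str] = ("CV+", "OH-"),
    rate_constant: float | None = None,
    output_times_min: Sequence[float] | None = None,
    bc: Literal["fixed", "noflux"] = "fixed",
    interface_mm: float | None = None,
    initial_conc: Mapping[str, np.ndarray] | None = None,
) -> ElectromigrationResult:
    """Explicit finite-difference 1-D electromigration-diffusion(-reaction) solver.

    Each species is advected at ``charge_sign * mobility * E`` (upwind flux)
    and diffuses with its own coefficient; the update is written in
    conservative flux form, so with ``bc='noflux'`` total moles are conserved
    to round-off.  With ``reaction=True`` the two ``reactants`` annihilate
    stoichiometrically 1:1 each step — instantaneously (limiting species per
    cell) when ``rate_constant`` is None, else at ``k * cA * cB * dt`` capped
    by availability.  Initial condition per species is a step: left reservoir
    value for x < interface, right value beyond; entries in ``initial_conc``
    override the step with an explicit profile (e.g. a narrow pulse).
    ``bc='fixed'`` pins the end cells at the reservoir values.

    Stability is checked up front: advection number |v| dt/dx <= 1 and
    diffusion number D dt/dx^2 <= 0.5 for every species, else a
    :class:`ConfigurationError` names the violated bound.
    """
    if len(species) == 0:
        raise ConfigurationError("species list must not be empty")
    grid = np.asarray(grid_mm, dtype=float)
    dx_m = (grid[1] - grid[0]) * _MM
    if interface_mm is None:
        interface_mm = 0.5 * (grid[0] + grid[-1])
    for sp in species:
        v = sp.mobility * abs(field_V_m)
        cfl_adv = v * dt_s / dx_m
        cfl_diff = sp.diffusion_coeff * dt_s / dx_m**2
        if cfl_adv > 1.0:
            raise ConfigurationError(
                f"advection number {cfl_adv:.3f} > 1 for {sp.name!r}: "
                f"reduce dt below {dx_m / v:.3e} s or coarsen the grid"
            )
        if cfl_diff > 0.5:
            raise ConfigurationError(
                f"diffusion number {cfl_diff:.3f} > 0.5 for {sp.name!r}: "
                f"reduce dt below {0.5 * dx_m**2 / sp.diffusion_coeff:.3e} s"
            )
    if reaction:
        names = {sp.name for sp in species}
        for r in reactants:
            if r not in names:
                raise ConfigurationError(f"reactant {r!r} not in species list")

    conc = {}
    for sp in species:
        if initial_conc is not None and sp.name in initial_conc:
            c0 = np.asarray(initial_conc[sp.name], dtype=float).copy()
            if c0.shape != grid.shape:
                raise ConfigurationError(
                    f"initial_conc for {sp.name!r} does not match the grid shape"
                )
            if np.any(c0 < 0):
                raise DomainError(f"negative initial concentration for {sp.name!r}")
        else:
            c0 = np.where(grid < interface_mm, sp.init_conc_left, sp.init_conc_right).astype(float)
        conc[sp.name] = c0
    if output_times_min is None:
        output_times_min = [t_end_min]
    out_times = np.asarray(sorted(output_times_min), dtype=float)
    if np.any(out_times > t_end_min + 1e-12):
        raise ConfigurationError("output times must not exceed t_end")

    result = ElectromigrationResult(times_min=out_times, profiles=[])
    n_steps = int(round(t_end_min * _MIN / dt_s))
    out_steps = np.rint(out_times * _MIN / dt_s).astype(int)
    next_out = 0

    def emit(step: int) -> None:
        nonlocal next_out
        while next_out < len(out_steps) and out_steps[next_out] == step:
            sigma = conductivity_from_species(conc, species)
            t_min = step * dt_s / _MIN
            result.profiles.append(
                SpatialProfile(x_mm=grid, sigma=np.asarray(sigma), time_min=t_min)
            )
            result.concentrations.append({k: v.copy() for k, v in conc.items()})
            next_out += 1

    emit(0)
    for step in range(1, n_steps + 1):
        for sp in species:
            c = conc[sp.name]
            v = sp.charge_sign * sp.mobility * field_V_m  # signed, m/s
            # upwind advective flux at interior faces i+1/2
            if v >= 0:
                f_adv = v * c[:-1]
            else:
                f_adv = v * c[1:]
            f_diff = -sp.diffusion_coeff * np.diff(c) / dx_m
            flux = f_adv + f_diff  # faces between cells, no-flux at the ends
            c[1:-1] += dt_s / dx_m * (flux[:-1] - flux[1:])
            c[0] -= dt_s / dx_m * flux[0]
            c[-1] += dt_s / dx_m * flux[-1]
            if bc == "fixed":
                c[0] = sp.init_conc_left
                c[-1] = sp.init_conc_right
            np.clip(c, 0.0, None, out=c)
        if reaction:
            a, b = conc[reactants[0]], conc[reactants[1]]
            if rate_constant is None:
                consumed = np.minimum(a, b)
            else:
                consumed = np.minimum(rate_constant * a * b * dt_s, np.minimum(a, b))
            a -= consumed
            b -= consumed
        emit(step)
    return result


def boundary_midpoint_mm(profile: SpatialProfile, sigma1: float, sigma2: float) -> float:
    """Position where sigma crosses (sigma1+sigma2)/2, by linear interpolation.

    Assumes a single monotone-in-the-mean transition from sigma1 to sigma2.
    """
    target = 0.5 * (sigma1 + sigma2)
    s = profile.sigma
    lo, hi = (sigma1, sigma2) if sigma1 < sigma2 else (sigma2, sigma1)
    if not (lo < target < hi):  # pragma: no cover - defensive
        raise DomainError("midpoint target outside the zone conductivities")
    rising = s[1:] >= target
    idx = np.nonzero(rising & (s[:-1] < target))[0]
    if idx.size == 0:
        raise DomainError("profile never crosses the midpoint conductivity")
    i = int(idx[0])
    frac = (target - s[i]) / (s[i + 1] - s[i])
    return float(profile.x_mm[i] + frac * (profile.x_mm[i + 1] - profile.x_mm[i]))
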