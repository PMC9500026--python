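"""Electrolysis-driven micropump model.

An implantable drug-delivery pump generates O2/H2 gas by water electrolysis
(2 H2O -> O2 + 2 H2, so 3/4 mol of gas per mol of electrons, i.e. ndot =
3 i / (4 F)).  The gas pressurizes a chamber sealed by a flexible membrane;
membrane displacement expels drug from a micro-reservoir through a square
micro-channel into tissue.

Two solution paths are provided and cross-checked against each other:

* a dimensional ODE for the membrane-displaced volume ``V`` obtained by
  combining the rate form of the ideal gas law,

      d/dt [ P (V + V0) ] = ndot R T,

  with the quasi-static force balance across the membrane and channel,

      P = 32 mu L Vdot / a^4 + f(V) + P0,

  where ``f(V)`` is the membrane's pressure-volume law and the first term
  is the laminar resistance of a square duct;

* the closed-form nondimensional solution: the quasi-steady implicit
  relation  t* = (V* + V0*) G(V*) + V* P0*  plus an exponentially decaying
  start-up transient.  The nondimensional time is t* = t / tau with
  tau = 4 F E h R0^2 / (3 i R T), fixed by requiring the quasi-steady
  integral of the gas law to reduce to the implicit relation above.

Under pulse-width-modulated (PWM) drive the ODE switches the electrode
current exactly, while the closed form uses the duty-cycle-averaged
"effective current".  All quantities are SI unless noted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "CHAMBER_VOLUME",
    "FluidProperties",
    "ChannelGeometry",
    "MembraneSpec",
    "PumpSystem",
    "DriveWaveform",
    "DimensionlessGroups",
    "FlowProfile",
    "Phase",
    "ProtocolSchedule",
    "ProtocolResult",
    "MembraneTravelError",
    "ClosedFormRangeError",
    "gas_generation_rate",
    "effective_current",
    "membrane_pressure",
    "nondimensionalize",
    "solve_volume_closed_form",
    "flow_rate_closed_form",
    "closed_form_profile",
    "integrate_pump_ode",
    "max_flow_rate_vs_current",
    "simulate_protocol",
    "logic1_schedule",
    "logic2_schedule",
]

FARADAY = 96485.0  # C / mol
GAS_CONSTANT = 8.3144  # J / (mol K)

#: Pump chamber volume: cylinder, height 1 mm, diameter 2.45 mm.
CHAMBER_VOLUME = math.pi * (2.45e-3 / 2.0) ** 2 * 1.0e-3  # m^3 (~4.71 uL)


class MembraneTravelError(ValueError):
    """Requested membrane displacement exceeds the geometric travel limit."""


class ClosedFormRangeError(RuntimeError):
    """Closed-form root not bracketed inside the physical volume range."""


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid properties.

    The default dynamic viscosity is that of water at ~25 C.
    """

    viscosity: float = 0.89e-3  # Pa s

    def __post_init__(self) -> None:
        if self.viscosity < 0:
            raise ValueError("viscosity must be >= 0")


@dataclass(frozen=True)
class ChannelGeometry:
    """Square-cross-section delivery channel: side ``a`` and length ``L``."""

    side_a: float = 30e-6  # m
    length_L: float = 7e-3  # m

    def __post_init__(self) -> None:
        if self.side_a <= 0 or self.length_L <= 0:
            raise ValueError("channel dimensions must be positive")

    def resistance(self, viscosity: float) -> float:
        """Laminar resistance 32 mu L / a^4 of the square duct (Pa s / m^3)."""
        return 32.0 * viscosity * self.length_L / self.side_a**4


@dataclass(frozen=True)
class MembraneSpec:
    """Flexible pump membrane and its pressure-volume law f(V).

    ``law`` selects between:

    * ``linear`` - f(V) = 64 E h^3 V / (3 pi R0^6).  The coefficient is the
      one whose nondimensional form reproduces the 64 h^2/(3 pi R0^2) group
      in the closed-form solution.
    * ``spherical_cap`` - large-deflection clamped circular membrane: the
      displaced volume is a spherical cap of apex height w,
      V = pi w (3 R0^2 + w^2) / 6, with P = 8 E h w^3 / (3 (1 - nu) R0^4).
    * ``tabulated`` - monotone (volume, pressure) pairs, e.g. from a finite
      element characterization, interpolated shape-preservingly (PCHIP).

    ``max_volume`` is the geometric travel limit; ``None`` means unlimited
    (the reservoir volume then bounds travel in practice).
    """

    radius_R0: float = 1.2e-3  # m
    modulus_E: float = 4.0e6  # Pa
    thickness_h: float = 150e-6  # m
    law: str = "linear"
    table: tuple[tuple[float, float], ...] | None = None
    poisson_nu: float = 0.5
    max_volume: float | None = None

    def __post_init__(self) -> None:
        if min(self.radius_R0, self.modulus_E, self.thickness_h) <= 0:
            raise ValueError("membrane dimensions and modulus must be positive")
        if self.law not in ("linear", "spherical_cap", "tabulated"):
            raise ValueError(f"unknown membrane law {self.law!r}")
        if self.law == "tabulated":
            if self.table is None or len(self.table) < 2:
                raise ValueError("tabulated law needs >= 2 (volume, pressure) pairs")
            vols = [v for v, _ in self.table]
            prs = [p for _, p in self.table]
            if any(b <= a for a, b in zip(vols, vols[1:])) or any(
                b <= a for a, b in zip(prs, prs[1:])
            ):
                raise ValueError("tabulated law must be strictly increasing")

    @property
    def linear_coefficient(self) -> float:
        """Slope of the linear law, 64 E h^3 / (3 pi R0^6) (Pa / m^3)."""
        return (
            64.0
            * self.modulus_E
            * self.thickness_h**3
            / (3.0 * math.pi * self.radius_R0**6)
        )

    def _interp(self) -> PchipInterpolator:
        vols = np.array([v for v, _ in self.table])
        prs = np.array([p for _, p in self.table])
        if vols[0] > 0.0:  # anchor at the undeformed state
            vols = np.concatenate([[0.0], vols])
            prs = np.concatenate([[0.0], prs])
        return PchipInterpolator(vols, prs)

    def _cap_height(self, volume: float) -> float:
        # solve pi w (3 R0^2 + w^2) / 6 = V for w >= 0 (monotone cubic)
        if volume == 0.0:
            return 0.0
        hi = self.radius_R0
        while math.pi * hi * (3 * self.radius_R0**2 + hi**2) / 6.0 < volume:
            hi *= 2.0
        return brentq(
            lambda w: math.pi * w * (3 * self.radius_R0**2 + w**2) / 6.0 - volume,
            0.0,
            hi,
            xtol=1e-18,
            rtol=1e-14,
        )

    def pressure(self, volume: float) -> float:
        """Membrane deformation pressure f(V) >= 0 for displaced volume V."""
        if volume < 0:
            raise ValueError("volume must be >= 0")
        if self.max_volume is not None and volume > self.max_volume * (1 + 1e-12):
            raise MembraneTravelError(
                f"volume {volume:g} m^3 exceeds travel limit {self.max_volume:g} m^3"
            )
        if self.law == "linear":
            return self.linear_coefficient * volume
        if self.law == "spherical_cap":
            w = self._cap_height(volume)
            return (
                8.0
                * self.modulus_E
                * self.thickness_h
                * w**3
                / (3.0 * (1.0 - self.poisson_nu) * self.radius_R0**4)
            )
        interp = self._interp()
        vmax = interp.x[-1]
        if volume > vmax * (1 + 1e-12):
            raise MembraneTravelError(
                f"volume {volume:g} m^3 beyond tabulated range {vmax:g} m^3"
            )
        return float(interp(min(volume, vmax)))

    def dpressure_dvolume(self, volume: float) -> float:
        """df/dV (Pa / m^3)."""
        if self.law == "linear":
            return self.linear_coefficient
        if self.law == "spherical_cap":
            w = self._cap_height(volume)
            if w == 0.0:
                return 0.0
            dP_dw = (
                8.0 * self.modulus_E * self.thickness_h * 3.0 * w**2
                / (3.0 * (1.0 - self.poisson_nu) * self.radius_R0**4)
            )
            dV_dw = math.pi * (3.0 * self.radius_R0**2 + 3.0 * w**2) / 6.0
            return dP_dw / dV_dw
        return float(self._interp().derivative()(volume))


@dataclass(frozen=True)
class PumpSystem:
    """Complete pump description: fluid, channel, membrane and gas chamber."""

    fluid: FluidProperties = field(default_factory=FluidProperties)
    channel: ChannelGeometry = field(default_factory=ChannelGeometry)
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    #: initial gas volume in the chamber; default 5% of the chamber volume
    initial_gas_volume_V0: float = 0.05 * CHAMBER_VOLUME
    ambient_pressure_P0: float = 101.3e3  # Pa
    temperature_T: float = 300.0  # K
    reservoir_volume: float = 500e-12  # m^3 (500 nL)
    faraday_F: float = FARADAY
    gas_constant_R: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.initial_gas_volume_V0 <= 0:
            raise ValueError("initial gas volume must be positive")
        if self.reservoir_volume <= 0 or self.ambient_pressure_P0 <= 0:
            raise ValueError("reservoir volume and ambient pressure must be positive")

    @property
    def channel_resistance(self) -> float:
        """32 mu L / a^4 (Pa s / m^3)."""
        return self.channel.resistance(self.fluid.viscosity)

    @property
    def initial_moles(self) -> float:
        """Gas moles initially in the chamber at ambient pressure."""
        return (
            self.ambient_pressure_P0
            * self.initial_gas_volume_V0
            / (self.gas_constant_R * self.temperature_T)
        )


@dataclass(frozen=True)
class DriveWaveform:
    """PWM electrode drive: square pulses of ``peak_current`` at ``duty_cycle``."""

    period: float = 0.25  # s
    duty_cycle: float = 0.1  # fraction of the period the current is on
    peak_current: float = 1.0e-3  # A
    duration: float = 30.0  # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty cycle must be in [0, 1]")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.peak_current < 0:
            raise ValueError("peak current must be >= 0")

    def current(self, t: float) -> float:
        """Instantaneous current at time ``t`` (0 outside [0, duration])."""
        if t < 0 or t > self.duration:
            return 0.0
        if (t % self.period) < self.duty_cycle * self.period:
            return self.peak_current
        return 0.0

    def on_time(self, t: float) -> float:
        """Cumulative electrode-on time up to ``t`` (exact, closed form)."""
        t = min(max(t, 0.0), self.duration)
        on = self.duty_cycle * self.period
        k, rem = divmod(t, self.period)
        return k * on + min(rem, on)

    def charge(self, t: float) -> float:
        """Cumulative delivered charge up to ``t`` (C)."""
        return self.peak_current * self.on_time(t)


@dataclass(frozen=True)
class DimensionlessGroups:
    """Nondimensional groups of the closed-form pump solution.

    ``g_linear`` is the 64 h^2 / (3 pi R0^2) group that is the slope of
    G(V*) for the linear membrane law; it enters the transient term.
    ``time_scale`` is seconds per unit t*.
    """

    v0_star: float
    p0_star: float
    m_star: float
    g_linear: float
    time_scale: float
    system: PumpSystem
    current: float

    def G(self, v_star: float) -> float:
        """Nondimensional membrane law G(V*) = f(V* R0^3) R0 / (E h)."""
        m = self.system.membrane
        return (
            self.system.membrane.pressure(v_star * m.radius_R0**3)
            * m.radius_R0
            / (m.modulus_E * m.thickness_h)
        )

    @property
    def v_max_star(self) -> float:
        """Reservoir volume in units of R0^3 (physical travel bound)."""
        return self.system.reservoir_volume / self.system.membrane.radius_R0**3


@dataclass
class FlowProfile:
    """Time-resolved pump state: pressure, gas volume, flow and delivery."""

    time: np.ndarray  # s
    pressure: np.ndarray  # Pa
    gas_volume: np.ndarray  # m^3 (membrane-displaced volume V)
    flow_rate: np.ndarray  # m^3 / s
    delivered_volume: np.ndarray  # m^3, cumulative (monotone)

    @property
    def peak_flow_rate(self) -> float:
        return float(np.max(self.flow_rate)) if self.flow_rate.size else 0.0

    @property
    def total_delivered(self) -> float:
        return float(self.delivered_volume[-1]) if self.delivered_volume.size else 0.0

    def moles(self, system: PumpSystem) -> np.ndarray:
        """Gas moles implied by the recorded state, P (V + V0) / (R T)."""
        return (
            self.pressure
            * (self.gas_volume + system.initial_gas_volume_V0)
            / (system.gas_constant_R * system.temperature_T)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "pressure_pa": self.pressure,
                "gas_volume_m3": self.gas_volume,
                "flow_rate_m3s": self.flow_rate,
                "delivered_volume_m3": self.delivered_volume,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "peak_flow_rate_m3s": self.peak_flow_rate,
            "total_delivered_m3": self.total_delivered,
            "peak_pressure_pa": float(np.max(self.pressure)) if self.pressure.size else 0.0,
            "duration_s": float(self.time[-1]) if self.time.size else 0.0,
        }


# ---------------------------------------------------------------------------
# elementary operations


def gas_generation_rate(current: float, system: PumpSystem | None = None) -> float:
    """Electrolytic gas generation rate ndot = 3 i / (4 F) (mol/s).

    Water electrolysis yields one O2 and two H2 per four electrons.
    """
    if current < 0:
        raise ValueError("current must be >= 0")
    F = system.faraday_F if system is not None else FARADAY
    return 3.0 * current / (4.0 * F)


def effective_current(drive: DriveWaveform) -> float:
    """Duty-cycle-averaged PWM current, duty * peak (A)."""
    return drive.duty_cycle * drive.peak_current


def membrane_pressure(volume: float, membrane: MembraneSpec) -> float:
    """Membrane deformation pressure f(V) for displaced volume ``V``."""
    return membrane.pressure(volume)


def nondimensionalize(system: PumpSystem, current: float) -> DimensionlessGroups:
    """Nondimensional groups for constant (effective) drive ``current``.

    V0* = V0/R0^3, P0* = P0 R0/(E h),
    M*  = (24 mu L / a^4) (i R T R0^2) / (F h^2 E^2),
    and t = tau t* with tau = 4 F E h R0^2 / (3 i R T).
    """
    if current <= 0:
        raise ValueError("current must be positive to nondimensionalize")
    m = system.membrane
    R0, E, h = m.radius_R0, m.modulus_E, m.thickness_h
    v0_star = system.initial_gas_volume_V0 / R0**3
    p0_star = system.ambient_pressure_P0 * R0 / (E * h)
    m_star = (
        24.0
        * system.fluid.viscosity
        * system.channel.length_L
        / system.channel.side_a**4
        * current
        * system.gas_constant_R
        * system.temperature_T
        * R0**2
        / (system.faraday_F * h**2 * E**2)
    )
    g_linear = 64.0 * h**2 / (3.0 * math.pi * R0**2)
    ndot = gas_generation_rate(current, system)
    time_scale = E * h * R0**2 / (
        ndot * system.gas_constant_R * system.temperature_T
    )
    return DimensionlessGroups(
        v0_star=v0_star,
        p0_star=p0_star,
        m_star=m_star,
        g_linear=g_linear,
        time_scale=time_scale,
        system=system,
        current=current,
    )


def _v_sol_star(
    t_star: float, groups: DimensionlessGroups, clamp: bool = True
) -> float:
    """Quasi-steady branch: solve t* = (V*+V0*) G(V*) + V* P0* for V*.

    Once the reservoir travel limit is reached the membrane can move no
    further; with ``clamp`` (default) the solution saturates at V*_max,
    otherwise a :class:`ClosedFormRangeError` is raised with a diagnostic.
    """
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    if t_star == 0.0:
        return 0.0

    def resid(v):
        return (v + groups.v0_star) * groups.G(v) + v * groups.p0_star - t_star

    lo, hi = 0.0, groups.v_max_star
    if resid(hi) < 0.0:
        if clamp:
            return hi
        raise ClosedFormRangeError(
            f"t*={t_star:g} lies beyond the reservoir travel limit "
            f"(V*_max={hi:g}, t*_max={resid(hi) + t_star:g}); "
            "shorten the time grid or enlarge the reservoir"
        )
    return brentq(resid, lo, hi, rtol=1e-9)


def _transient(groups: DimensionlessGroups) -> tuple[float, float]:
    """Amplitude and decay rate (per unit t*) of the start-up transient."""
    lam = groups.g_linear + groups.p0_star / groups.v0_star
    amp = groups.m_star / (groups.v0_star * lam**2)
    rate = lam / groups.m_star
    return amp, rate


def solve_volume_closed_form(t_star, groups: DimensionlessGroups):
    """Nondimensional displaced volume V*(t*) from the closed-form solution.

    Quasi-steady implicit solution minus the exponentially decaying
    start-up transient.  Accepts scalar or array ``t_star``.
    """
    amp, rate = _transient(groups)
    t_arr = np.atleast_1d(np.asarray(t_star, dtype=float))
    out = np.empty_like(t_arr)
    for k, ts in enumerate(t_arr):
        v_sol = _v_sol_star(ts, groups)
        out[k] = v_sol - amp * (1.0 - math.exp(-rate * ts))
    return out if np.ndim(t_star) else float(out[0])


def flow_rate_closed_form(t_star, groups: DimensionlessGroups):
    """Nondimensional flow rate dV*/dt* of the closed-form solution.

    First term: derivative of the quasi-steady implicit relation,
    1 / [G(V*) + f'(V* R0^3)(V*+V0*) R0^4/(E h) + P0*], evaluated on the
    quasi-steady branch; second term: derivative of the transient.
    """
    m = groups.system.membrane
    R0, E, h = m.radius_R0, m.modulus_E, m.thickness_h
    amp, rate = _transient(groups)
    t_arr = np.atleast_1d(np.asarray(t_star, dtype=float))
    out = np.empty_like(t_arr)
    for k, ts in enumerate(t_arr):
        v_sol = _v_sol_star(ts, groups)
        if v_sol >= groups.v_max_star:
            out[k] = 0.0  # reservoir exhausted, membrane at full travel
            continue
        denom = (
            groups.G(v_sol)
            + m.dpressure_dvolume(v_sol * R0**3)
            * (v_sol + groups.v0_star)
            * R0**4
            / (E * h)
            + groups.p0_star
        )
        out[k] = 1.0 / denom - amp * rate * math.exp(-rate * ts)
    return out if np.ndim(t_star) else float(out[0])


def closed_form_profile(
    system: PumpSystem, current: float, time: np.ndarray
) -> FlowProfile:
    """Dimensional FlowProfile from the closed-form solution at constant
    (effective) ``current`` on the time grid ``time`` (s)."""
    groups = nondimensionalize(system, current)
    R0 = system.membrane.radius_R0
    t_star = np.asarray(time, dtype=float) / groups.time_scale
    v_star = np.array([solve_volume_closed_form(ts, groups) for ts in t_star])
    q_star = np.array([flow_rate_closed_form(ts, groups) for ts in t_star])
    volume = v_star * R0**3
    q = q_star * R0**3 / groups.time_scale
    pressure = (
        system.channel_resistance * q
        + np.array([system.membrane.pressure(max(v, 0.0)) for v in volume])
        + system.ambient_pressure_P0
    )
    delivered = np.concatenate(
        [[0.0], np.cumsum(np.diff(time) * 0.5 * (np.clip(q, 0, None)[1:] + np.clip(q, 0, None)[:-1]))]
    )
    return FlowProfile(
        time=np.asarray(time, dtype=float),
        pressure=pressure,
        gas_volume=np.clip(volume, 0.0, None),
        flow_rate=q,
        delivered_volume=delivered,
    )


# ---------------------------------------------------------------------------
# dimensional ODE integration


def _flow_from_pressure(dp: float, r_chan: float, valve) -> float:
    """Flow through channel (+ optional check valve) for driving pressure
    ``dp`` = P - f(V) - P0 across the series path."""
    if valve is None:
        return dp / r_chan
    if dp <= valve.cracking_pressure:
        if dp < -valve.reverse_rating:
            warnings.warn(
                "reverse pressure exceeds the valve's reverse rating; "
                "complete blocking is outside the characterized range",
                RuntimeWarning,
                stacklevel=3,
            )
        return 0.0
    return (dp - valve.cracking_pressure) / (r_chan + valve.open_resistance)


def _build_grid(edges: Sequence[float], max_step: float) -> np.ndarray:
    """Time grid containing all ``edges`` with spacing <= max_step."""
    pts = [float(edges[0])]
    for a, b in zip(edges, edges[1:]):
        if b <= a:
            continue
        n = max(1, int(math.ceil((b - a) / max_step)))
        pts.extend(np.linspace(a, b, n + 1)[1:].tolist())
    return np.asarray(pts)


def _integrate(
    system: PumpSystem,
    charge_fn: Callable[[float], float],
    switch_edges: Sequence[float],
    max_step: float,
    valve=None,
) -> FlowProfile:
    """Fixed-step RK4 on V with the gas moles known analytically from the
    cumulative charge; steps are aligned to PWM switching edges so the
    right-hand side is smooth inside each step."""
    n0 = system.initial_moles
    RT = system.gas_constant_R * system.temperature_T
    r_chan = system.channel_resistance
    V0 = system.initial_gas_volume_V0
    P0 = system.ambient_pressure_P0
    f = system.membrane.pressure
    res = system.reservoir_volume

    def moles(t: float) -> float:
        return n0 + 3.0 * charge_fn(t) / (4.0 * system.faraday_F)

    def rhs(t: float, v: float) -> float:
        v = min(max(v, 0.0), res)
        p = moles(t) * RT / (v + V0)
        q = _flow_from_pressure(p - f(v) - P0, r_chan, valve)
        if v >= res and q > 0.0:
            return 0.0  # membrane at full travel / reservoir exhausted
        return q

    grid = _build_grid(switch_edges, max_step)
    nsteps = grid.size
    volume = np.empty(nsteps)
    flow = np.empty(nsteps)
    pressure = np.empty(nsteps)
    v = 0.0
    for k, t in enumerate(grid):
        p = moles(t) * RT / (v + V0)
        q = _flow_from_pressure(p - f(v) - P0, r_chan, valve)
        if v >= res and q > 0.0:
            q = 0.0
        volume[k] = v
        pressure[k] = p
        flow[k] = q
        if k + 1 < nsteps:
            dt = grid[k + 1] - t
            k1 = rhs(t, v)
            k2 = rhs(t + dt / 2, v + dt / 2 * k1)
            k3 = rhs(t + dt / 2, v + dt / 2 * k2)
            k4 = rhs(t + dt, v + dt * k3)
            v = v + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            v = min(max(v, 0.0), res)

    qpos = np.clip(flow, 0.0, None)
    delivered = np.concatenate(
        [[0.0], np.cumsum(np.diff(grid) * 0.5 * (qpos[1:] + qpos[:-1]))]
    )
    delivered = np.minimum(delivered, res)  # reservoir bound (qpos >= 0 keeps it monotone)
    return FlowProfile(
        time=grid,
        pressure=pressure,
        gas_volume=volume,
        flow_rate=flow,
        delivered_volume=delivered,
    )


def integrate_pump_ode(
    system: PumpSystem,
    drive: DriveWaveform,
    dt: float | None = None,
    valve=None,
    t_end: float | None = None,
) -> FlowProfile:
    """Integrate the dimensional pump ODE under exact PWM switching.

    ``dt`` is the maximum step; it must resolve the PWM period with at
    least 20 steps.  Steps are additionally aligned to every on/off edge.
    """
    t_end = drive.duration if t_end is None else t_end
    if dt is None:
        dt = drive.period / 40.0
    if dt > drive.period / 20.0:
        raise ValueError("dt must resolve the PWM period (>= 20 steps/period)")

    edges = {0.0, t_end}
    if drive.peak_current > 0 and drive.duty_cycle > 0:
        t_on = drive.duty_cycle * drive.period
        k = 0
        while k * drive.period < t_end:
            edges.add(min(k * drive.period, t_end))
            edges.add(min(k * drive.period + t_on, t_end))
            k += 1
    return _integrate(system, drive.charge, sorted(edges), dt, valve=valve)


def max_flow_rate_vs_current(
    system: PumpSystem,
    currents: Sequence[float],
    duration: float = 30.0,
    dt: float | None = None,
    valve=None,
) -> np.ndarray:
    """Peak flow rate for each constant effective current (m^3/s).

    Each current is simulated with a continuous (100% duty) drive and the
    peak of the resulting flow-rate profile is reported, mirroring how a
    peak-flow-vs-current characteristic is read off temporal profiles.
    """
    currents = list(currents)
    if not currents:
        raise ValueError("currents list must not be empty")
    peaks = np.empty(len(currents))
    for k, i in enumerate(currents):
        if i <= 0:
            raise ValueError("currents must be positive")
        drv = DriveWaveform(
            period=duration, duty_cycle=1.0, peak_current=i, duration=duration
        )
        step = dt if dt is not None else duration / 3000.0
        prof = integrate_pump_ode(system, drv, dt=min(step, duration / 20.0), valve=valve)
        peaks[k] = prof.peak_flow_rate
    return peaks


# ---------------------------------------------------------------------------
# protocol scheduling


@dataclass(frozen=True)
class Phase:
    """One phase of a delivery/illumination protocol.

    ``channel`` is "pump" or "led"; ``frequency`` and ``duty_cycle`` give
    the PWM drive inside the phase; ``peak_current`` applies to pump
    phases only.  ``start`` of None means "immediately after the previous
    phase".
    """

    channel: str
    duration: float
    frequency: float = 4.0  # Hz
    duty_cycle: float = 0.4
    peak_current: float = 1.0e-3  # A (pump phases)
    start: float | None = None

    def __post_init__(self) -> None:
        if self.channel not in ("pump", "led"):
            raise ValueError("channel must be 'pump' or 'led'")
        if self.duration <= 0 or self.frequency <= 0:
            raise ValueError("duration and frequency must be positive")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty cycle must be in [0, 1]")


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered phases of PWM pump/LED drive with resolved start times."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        t = 0.0
        resolved = []
        for ph in self.phases:
            start = ph.start if ph.start is not None else t
            resolved.append(replace(ph, start=start))
            t = start + ph.duration
        object.__setattr__(self, "phases", tuple(resolved))
        for ch in ("pump", "led"):
            spans = sorted(
                (p.start, p.start + p.duration) for p in self.phases if p.channel == ch
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1 - 1e-12:
                    raise ValueError(f"overlapping {ch} phases in schedule")

    @property
    def total_duration(self) -> float:
        if not self.phases:
            return 0.0
        return max(p.start + p.duration for p in self.phases)

    def pump_phases(self) -> list[Phase]:
        return [p for p in self.phases if p.channel == "pump"]

    def led_epochs(self) -> list[Phase]:
        return [p for p in self.phases if p.channel == "led"]

    def charge(self, t: float) -> float:
        """Cumulative pump-electrode charge up to ``t`` (exact)."""
        total = 0.0
        for ph in self.pump_phases():
            rel = min(max(t - ph.start, 0.0), ph.duration)
            wave = DriveWaveform(
                period=1.0 / ph.frequency,
                duty_cycle=ph.duty_cycle,
                peak_current=ph.peak_current,
                duration=ph.duration,
            )
            total += wave.charge(rel)
        return total

    def switch_edges(self, t_end: float) -> list[float]:
        edges = {0.0, t_end}
        for ph in self.pump_phases():
            period = 1.0 / ph.frequency
            t_on = ph.duty_cycle * period
            k = 0
            while ph.start + k * period < min(ph.start + ph.duration, t_end):
                edges.add(min(ph.start + k * period, t_end))
                edges.add(min(ph.start + k * period + t_on, t_end))
                k += 1
            edges.add(min(ph.start + ph.duration, t_end))
        for ph in self.led_epochs():
            edges.add(min(ph.start, t_end))
            edges.add(min(ph.start + ph.duration, t_end))
        return sorted(edges)


@dataclass
class ProtocolResult:
    """Output of :func:`simulate_protocol`."""

    profile: FlowProfile
    schedule: ProtocolSchedule
    phase_delivered: list[float]  # m^3 per phase, in schedule order
    led_epochs: list[Phase]

    def summary(self) -> dict:
        return {
            **self.profile.summary(),
            "phase_delivered_m3": self.phase_delivered,
            "n_led_epochs": len(self.led_epochs),
        }


def simulate_protocol(
    system: PumpSystem,
    schedule: ProtocolSchedule,
    dt: float | None = None,
    valve=None,
    settle_time: float = 0.0,
) -> ProtocolResult:
    """Simulate a multi-phase protocol, preserving pump state across phases.

    The gas volume and pressure carry over between phases, so drug keeps
    flowing from residual pressure while the pump is off (e.g. during LED
    phases).  ``settle_time`` extends the simulation past the last phase to
    observe relaxation.  Returns the full profile, per-phase delivered
    volumes, and the LED epochs for downstream photolysis coupling.
    """
    if not schedule.phases:
        empty = np.array([])
        return ProtocolResult(
            FlowProfile(empty, empty, empty, empty, empty), schedule, [], []
        )
    t_end = schedule.total_duration + settle_time
    min_period = min(
        [1.0 / p.frequency for p in schedule.pump_phases()], default=t_end
    )
    if dt is None:
        dt = min_period / 40.0
    if schedule.pump_phases() and dt > min_period / 20.0:
        raise ValueError("dt must resolve the fastest PWM period (>= 20 steps)")
    profile = _integrate(
        system, schedule.charge, schedule.switch_edges(t_end), dt, valve=valve
    )
    delivered_at = lambda t: float(
        np.interp(t, profile.time, profile.delivered_volume)
    )
    phase_delivered = [
        delivered_at(p.start + p.duration) - delivered_at(p.start)
        for p in schedule.phases
    ]
    return ProtocolResult(profile, schedule, phase_delivered, schedule.led_epochs())


def logic1_schedule(peak_current: float = 1.0e-3) -> ProtocolSchedule:
    """Delivery-then-illumination logic: pump at 4 Hz, 40% duty for 120 s,
    followed by LED at 20 Hz for 240 s."""
    return ProtocolSchedule(
        (
            Phase("pump", duration=120.0, frequency=4.0, duty_cycle=0.4,
                  peak_current=peak_current),
            Phase("led", duration=240.0, frequency=20.0, duty_cycle=0.4),
        )
    )


def logic2_schedule(peak_current: float = 1.0e-3) -> ProtocolSchedule:
    """Interleaved logic: 8 cycles of 15 s pump + 30 s LED (same totals as
    the delivery-then-illumination logic: 120 s pump-on, 240 s LED-on)."""
    phases = []
    for _ in range(8):
        phases.append(
            Phase("pump", duration=15.0, frequency=4.0, duty_cycle=0.4,
                  peak_current=peak_current)
        )
        phases.append(Phase("led", duration=30.0, frequency=20.0, duty_cycle=0.4))
    return ProtocolSchedule(tuple(phases))
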