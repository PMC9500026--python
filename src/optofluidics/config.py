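"""YAML configuration loading for pump, valve, drive and schedule blocks.

All quantities carry explicit unit suffixes in their keys (SI base units),
e.g.::

    fluid:
      viscosity_pa_s: 0.89e-3
    channel:
      side_a_m: 30.0e-6
      length_l_m: 7.0e-3
    membrane:
      radius_r0_m: 1.2e-3
      modulus_e_pa: 4.0e6
      thickness_h_m: 150.0e-6
      law: linear
    pump:
      initial_gas_volume_v0_m3: 2.36e-10
      reservoir_volume_m3: 500.0e-12
    valve:
      cracking_pressure_pa: 7200.0
    drive:
      period_s: 0.25
      duty_cycle: 0.1
      peak_current_a: 1.0e-3
      duration_s: 30.0

Omitting the ``valve`` block disables the valve element.  A ``schedule``
block (list of phases with ``channel``, ``duration_s``, ``frequency_hz``,
``duty_cycle``, ``peak_current_a``) replaces ``drive`` for multi-phase
protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .pump import (
    ChannelGeometry,
    DriveWaveform,
    FluidProperties,
    MembraneSpec,
    Phase,
    ProtocolSchedule,
    PumpSystem,
)
from .valve import ValveSpec

__all__ = ["PumpConfig", "load_pump_config"]


@dataclass
class PumpConfig:
    system: PumpSystem
    drive: DriveWaveform | None
    schedule: ProtocolSchedule | None
    valve: ValveSpec | None


def _num(block: dict, key: str, default: float) -> float:
    """Numeric lookup tolerant of YAML exponents without a sign, which
    PyYAML hands back as strings (e.g. ``4.0e6``)."""
    value = block.get(key, default)
    return default if value is None else float(value)


def _membrane(block: dict) -> MembraneSpec:
    table = block.get("table")
    max_volume = block.get("max_volume_m3")
    return MembraneSpec(
        radius_R0=_num(block, "radius_r0_m", MembraneSpec.radius_R0),
        modulus_E=_num(block, "modulus_e_pa", MembraneSpec.modulus_E),
        thickness_h=_num(block, "thickness_h_m", MembraneSpec.thickness_h),
        law=block.get("law", "linear"),
        table=tuple((float(v), float(p)) for v, p in table) if table else None,
        max_volume=None if max_volume is None else float(max_volume),
    )


def load_pump_config(path) -> PumpConfig:
    """Read a pump configuration YAML into domain objects."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    fl = cfg.get("fluid", {})
    fluid = FluidProperties(
        viscosity=_num(fl, "viscosity_pa_s", FluidProperties.viscosity)
    )
    ch = cfg.get("channel", {})
    channel = ChannelGeometry(
        side_a=_num(ch, "side_a_m", ChannelGeometry.side_a),
        length_L=_num(ch, "length_l_m", ChannelGeometry.length_L),
    )
    membrane = _membrane(cfg.get("membrane", {}))
    pm = cfg.get("pump", {})
    system = PumpSystem(
        fluid=fluid,
        channel=channel,
        membrane=membrane,
        initial_gas_volume_V0=_num(
            pm, "initial_gas_volume_v0_m3", PumpSystem.initial_gas_volume_V0
        ),
        ambient_pressure_P0=_num(
            pm, "ambient_pressure_p0_pa", PumpSystem.ambient_pressure_P0
        ),
        temperature_T=_num(pm, "temperature_t_k", PumpSystem.temperature_T),
        reservoir_volume=_num(pm, "reservoir_volume_m3", PumpSystem.reservoir_volume),
    )
    drive = None
    if "drive" in cfg:
        d = cfg["drive"]
        drive = DriveWaveform(
            period=_num(d, "period_s", DriveWaveform.period),
            duty_cycle=_num(d, "duty_cycle", DriveWaveform.duty_cycle),
            peak_current=_num(d, "peak_current_a", DriveWaveform.peak_current),
            duration=_num(d, "duration_s", DriveWaveform.duration),
        )
    schedule = None
    if "schedule" in cfg:
        phases = []
        for p in cfg["schedule"]:
            start = p.get("start_s")
            phases.append(
                Phase(
                    channel=p["channel"],
                    duration=float(p["duration_s"]),
                    frequency=_num(p, "frequency_hz", 4.0),
                    duty_cycle=_num(p, "duty_cycle", 0.4),
                    peak_current=_num(p, "peak_current_a", 1.0e-3),
                    start=None if start is None else float(start),
                )
            )
        schedule = ProtocolSchedule(tuple(phases))
    valve = None
    if "valve" in cfg:
        v = cfg["valve"]
        valve = ValveSpec(
            cracking_pressure=_num(
                v, "cracking_pressure_pa", ValveSpec.cracking_pressure
            ),
            reverse_rating=_num(v, "reverse_rating_pa", ValveSpec.reverse_rating),
            open_resistance=_num(
                v, "open_resistance_pa_s_m3", ValveSpec.open_resistance
            ),
        )
    return PumpConfig(system=system, drive=drive, schedule=schedule, valve=valve)
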