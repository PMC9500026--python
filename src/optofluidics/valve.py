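"""Passive flapper check valve as an ideal rectifying series element.

The valve is a perforated elastic membrane clamped over a ring seat: forward
pressure deflects the flap and opens the perforation; reverse pressure
presses the flap onto the seat and blocks flow completely.  Measured
behavior is reduced to two pressures: a forward cracking (burst) pressure
below which no forward flow passes, and a reverse rating up to which
blocking is complete.  Opening is modeled as a sharp threshold with an
optional additional series resistance when open.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

__all__ = ["ValveSpec", "ValveState", "valve_state", "valve_flow"]


class ValveState(str, enum.Enum):
    OPEN = "open"
    CLOSED = "closed"
    BLOCKED_REVERSE = "blocked_reverse"


@dataclass(frozen=True)
class ValveSpec:
    """Check-valve parameters.

    ``cracking_pressure``: minimum forward pressure that initiates flow (Pa).
    ``reverse_rating``: reverse pressure up to which blocking is complete
    and therefore contractual (Pa); beyond it the element still blocks but
    emits a warning since that regime is uncharacterized.
    ``open_resistance``: extra series resistance once open (Pa s / m^3).
    """

    cracking_pressure: float = 7.2e3  # Pa
    reverse_rating: float = 45e3  # Pa
    open_resistance: float = 0.0  # Pa s / m^3

    def __post_init__(self) -> None:
        if self.cracking_pressure <= 0 or self.reverse_rating <= 0:
            raise ValueError("cracking pressure and reverse rating must be positive")
        if self.open_resistance < 0:
            raise ValueError("open resistance must be >= 0")


def valve_state(delta_p: float, valve: ValveSpec) -> ValveState:
    """State of the valve under pressure difference ``delta_p`` (forward > 0).

    open for delta_p >= cracking pressure; closed for 0 <= delta_p below it;
    blocked_reverse for delta_p < 0 (warning beyond the reverse rating).
    """
    if delta_p < 0:
        if -delta_p > valve.reverse_rating:
            warnings.warn(
                f"reverse pressure {-delta_p:g} Pa exceeds the characterized "
                f"reverse rating {valve.reverse_rating:g} Pa",
                RuntimeWarning,
                stacklevel=2,
            )
        return ValveState.BLOCKED_REVERSE
    if delta_p >= valve.cracking_pressure:
        return ValveState.OPEN
    return ValveState.CLOSED


def valve_flow(
    delta_p: float, valve: ValveSpec, upstream_conductance: float
) -> float:
    """Flow (m^3/s) through the valve in series with an upstream path of
    conductance ``upstream_conductance`` (m^3 / (Pa s)).

    Zero unless open; when open, the flow solves the series pressure
    balance, i.e. Q = (delta_p - cracking) / (1/conductance + open_resistance),
    so just above the threshold the flow equals the unvalved flow driven by
    the excess pressure.
    """
    if upstream_conductance <= 0:
        raise ValueError("upstream conductance must be positive")
    if valve_state(delta_p, valve) is not ValveState.OPEN:
        return 0.0
    return (delta_p - valve.cracking_pressure) / (
        1.0 / upstream_conductance + valve.open_resistance
    )
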