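"""Quantitative NMR and first-order photolysis kinetics.

Concentrations are obtained from 1H NMR peak integrals via an internal
standard (maleic acid) of known concentration: per-proton integrals are
proportional to concentration, so

    C_sample = C_ref * (I_sample / n_sample) / (I_ref / n_ref).

Photolysis of a caged compound (e.g. RuBi-glutamate releasing glutamate
under blue light) is modeled as first order in the caged species:
caged(t) = C0 exp(-k t) and released(t) = C0 (1 - exp(-k t)), with ``k``
in 1/min.  The same law couples light epochs of a delivery/illumination
protocol to the released-compound time course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "NmrPeak",
    "ReferenceStandard",
    "PhotolysisSeries",
    "PhotolysisFit",
    "reference_concentration",
    "concentration_from_integrals",
    "fit_first_order",
    "concentrations_from_table",
    "photolysis_series_from_table",
    "simulate_uncaging_protocol",
]


@dataclass(frozen=True)
class NmrPeak:
    """One assigned peak: label, chemical shift, integral, proton count."""

    assignment: str
    shift_ppm: float
    integral: float
    n_protons: int = 1

    def __post_init__(self) -> None:
        if self.integral < 0:
            raise ValueError("integral must be >= 0")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")

    @property
    def per_proton(self) -> float:
        return self.integral / self.n_protons


@dataclass(frozen=True)
class ReferenceStandard:
    """Internal standard: stock concentration and dilution volumes.

    Defaults follow a 20 mM maleic-acid stock, 2 ul spiked into a final
    0.6 ml NMR sample; maleic acid's vinylic singlet represents 2 protons.
    """

    name: str = "maleic acid"
    stock_mM: float = 20.0
    spike_volume_ul: float = 2.0
    final_volume_ul: float = 600.0
    n_protons: int = 2

    def __post_init__(self) -> None:
        if self.spike_volume_ul < 0:
            raise ValueError("spike volume must be >= 0")
        if self.final_volume_ul <= 0:
            raise ValueError("final volume must be positive")
        if self.final_volume_ul < self.spike_volume_ul:
            raise ValueError("final volume must be >= spike volume")


@dataclass
class PhotolysisSeries:
    """Concentration (or normalized-integral) time series of a photolysis
    experiment: caged and released species vs illumination time."""

    time_min: np.ndarray
    caged: np.ndarray
    released: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.caged = np.asarray(self.caged, dtype=float)
        if self.released is not None:
            self.released = np.asarray(self.released, dtype=float)
        if np.any(np.diff(self.time_min) < 0):
            raise ValueError("illumination durations must be nondecreasing")
        if np.any(self.caged < 0) or (
            self.released is not None and np.any(self.released < 0)
        ):
            raise ValueError("concentrations must be >= 0")


@dataclass
class PhotolysisFit:
    """First-order fit result: rate constant, amplitude, diagnostics."""

    k_per_min: float
    c0: float
    offset: float
    residuals: np.ndarray
    k_ci: tuple[float, float] | None = None

    def summary(self) -> dict:
        return {
            "k_per_min": self.k_per_min,
            "c0": self.c0,
            "offset": self.offset,
            "rss": float(np.sum(self.residuals**2)),
            "k_ci_low": None if self.k_ci is None else self.k_ci[0],
            "k_ci_high": None if self.k_ci is None else self.k_ci[1],
        }


def reference_concentration(std: ReferenceStandard) -> float:
    """Concentration of the internal standard in the final sample (mM)."""
    return std.stock_mM * std.spike_volume_ul / std.final_volume_ul


def concentration_from_integrals(
    sample: NmrPeak, ref: NmrPeak, ref_conc_mM: float
) -> float:
    """Sample concentration (mM) from per-proton integral ratio to the
    internal standard."""
    if ref.integral <= 0:
        raise ValueError("reference integral must be positive")
    return ref_conc_mM * sample.per_proton / ref.per_proton


def _model(t, c0, k, offset, released: bool):
    # closed system of total C0: caged (C0 - offset) at t=0, offset already
    # released (e.g. handling exposure), photolysis first order in caged
    if released:
        return offset + (c0 - offset) * (1.0 - np.exp(-k * t))
    return (c0 - offset) * np.exp(-k * t)


def fit_first_order(
    series: PhotolysisSeries,
    fit_offset: bool = False,
    bootstrap: int = 0,
    rng: np.random.Generator | int | None = None,
) -> PhotolysisFit:
    """Least-squares fit of the first-order photolysis law.

    Fits caged = (C0 - offset) exp(-k t) and, when present, released =
    offset + (C0 - offset)(1 - exp(-k t)) jointly with shared k and C0
    (caged + released = C0 at all times).
    ``fit_offset`` adds a released-at-t=0 offset (e.g. from ambient-light
    exposure during sample handling); it is off by default.  ``bootstrap``
    > 0 adds a residual-bootstrap 95% CI on k (seed-controlled via ``rng``).
    """
    t = series.time_min
    if len(t) < 3:
        raise ValueError("need at least 3 time points")

    y_parts = [series.caged]
    if series.released is not None:
        y_parts.append(series.released)
    y = np.concatenate(y_parts)

    def model(t_, c0, k, offset=0.0):
        parts = [_model(t_, c0, k, offset, released=False)]
        if series.released is not None:
            parts.append(_model(t_, c0, k, offset, released=True))
        return np.concatenate(parts)

    c0_guess = max(float(series.caged[0]), 1e-12)
    span = float(t[-1] - t[0]) or 1.0
    k_guess = 1.0 / span
    if fit_offset:
        p0 = [c0_guess, k_guess, 0.0]
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
    else:
        p0 = [c0_guess, k_guess]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
    popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    fitted = model(t, *popt)
    resid = y - fitted
    c0, k = float(popt[0]), float(popt[1])
    offset = float(popt[2]) if fit_offset else 0.0

    k_ci = None
    if bootstrap > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        ks = []
        for _ in range(bootstrap):
            y_star = fitted + gen.choice(resid, size=resid.size, replace=True)
            try:
                p_star, _ = curve_fit(
                    model, t, y_star, p0=popt, bounds=bounds, maxfev=20000
                )
                ks.append(p_star[1])
            except RuntimeError:
                continue
        if ks:
            k_ci = (float(np.percentile(ks, 2.5)), float(np.percentile(ks, 97.5)))
    return PhotolysisFit(k, c0, offset, resid, k_ci)


def concentrations_from_table(
    table: pd.DataFrame,
    ref_label: str = "ref",
    ref_conc_mM: float | None = None,
    standard: ReferenceStandard | None = None,
) -> pd.DataFrame:
    """Per-time-point concentrations from a tidy peak-integral table.

    ``table`` needs columns sample_id, time_min, peak_label, n_protons,
    integral.  Each sample's peaks are referenced to its own internal-
    standard peak (``ref_label``).  ``ref_conc_mM`` defaults to the
    concentration implied by ``standard`` (maleic-acid defaults).
    Returns a tidy table (sample_id, time_min, peak_label, conc_mM).
    """
    if ref_conc_mM is None:
        ref_conc_mM = reference_concentration(standard or ReferenceStandard())
    rows = []
    for sid, g in table.groupby("sample_id", sort=False):
        refs = g[g["peak_label"] == ref_label]
        if len(refs) != 1:
            raise ValueError(f"sample {sid!r} must have exactly one reference peak")
        ref_row = refs.iloc[0]
        ref = NmrPeak(ref_label, float(ref_row.get("ppm", 0.0)),
                      float(ref_row["integral"]), int(ref_row["n_protons"]))
        for _, r in g[g["peak_label"] != ref_label].iterrows():
            pk = NmrPeak(str(r["peak_label"]), float(r.get("ppm", 0.0)),
                         float(r["integral"]), int(r["n_protons"]))
            rows.append(
                {
                    "sample_id": sid,
                    "time_min": float(r["time_min"]),
                    "peak_label": pk.assignment,
                    "conc_mM": concentration_from_integrals(pk, ref, ref_conc_mM),
                }
            )
    return pd.DataFrame(rows)


def photolysis_series_from_table(
    concentrations: pd.DataFrame,
    caged_label: str = "c",
    released_label: str = "d",
) -> PhotolysisSeries:
    """Assemble a :class:`PhotolysisSeries` from a tidy concentration table."""
    caged = concentrations[concentrations["peak_label"] == caged_label]
    rel = concentrations[concentrations["peak_label"] == released_label]
    caged = caged.sort_values("time_min")
    rel = rel.sort_values("time_min")
    if len(caged) == 0:
        raise ValueError(f"no rows with caged label {caged_label!r}")
    released = rel["conc_mM"].to_numpy() if len(rel) else None
    return PhotolysisSeries(
        time_min=caged["time_min"].to_numpy(),
        caged=caged["conc_mM"].to_numpy(),
        released=released,
    )


def simulate_uncaging_protocol(
    schedule,
    k_per_min: float,
    phase_delivered,
    scale_by_led_duty: bool = True,
    n_output: int = 500,
    settle_time: float = 0.0,
) -> pd.DataFrame:
    """Released-compound time course under a delivery/illumination protocol.

    The caged pool grows at the delivery rate of each pump phase
    (``phase_delivered`` gives the volume or amount delivered per schedule
    phase, in schedule order) and converts to released compound at rate
    ``k_per_min`` only while an LED epoch is active.  With
    ``scale_by_led_duty`` the rate is scaled by the LED duty cycle (PWM
    illumination delivers proportionally less average optical power).

    Each interval between protocol events is integrated in closed form
    (linear source + exponential decay), so caged + released equals the
    cumulative delivered amount to machine precision.  Returns a table with
    columns t_s, caged, released, delivered_cum.
    """
    if k_per_min < 0:
        raise ValueError("k_per_min must be >= 0")
    k_per_s = k_per_min / 60.0
    phases = list(schedule.phases)
    if len(phase_delivered) != len(phases):
        raise ValueError("phase_delivered must match the number of phases")

    t_end = schedule.total_duration + settle_time
    events = {0.0, t_end}
    for ph in phases:
        events.add(ph.start)
        events.add(min(ph.start + ph.duration, t_end))
    # output sampling points merged with exact event boundaries
    events.update(np.linspace(0.0, t_end, max(n_output, 2)).tolist())
    grid = np.array(sorted(events))

    def delivery_rate(t: float) -> float:
        # amounts may be attached to LED phases too: residual pump pressure
        # keeps delivering after the electrodes switch off
        rate = 0.0
        for ph, amount in zip(phases, phase_delivered):
            if ph.start <= t < ph.start + ph.duration:
                rate += amount / ph.duration
        return rate

    def led_rate(t: float) -> float:
        for ph in phases:
            if ph.channel == "led" and ph.start <= t < ph.start + ph.duration:
                return k_per_s * (ph.duty_cycle if scale_by_led_duty else 1.0)
        return 0.0

    caged = 0.0
    released = 0.0
    delivered = 0.0
    rows = [(0.0, 0.0, 0.0, 0.0)]
    for a, b in zip(grid, grid[1:]):
        if b <= a:
            continue
        dt = b - a
        mid = 0.5 * (a + b)
        r = delivery_rate(mid)
        kk = led_rate(mid)
        delivered += r * dt
        if kk > 0.0:
            decay = math.exp(-kk * dt)
            new_caged = caged * decay + r * (1.0 - decay) / kk
        else:
            new_caged = caged + r * dt
        released = delivered - new_caged  # exact mass balance
        caged = new_caged
        rows.append((b, caged, released, delivered))
    return pd.DataFrame(rows, columns=["t_s", "caged", "released", "delivered_cum"])
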