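"""In vitro gas-production kinetics.

Converts vented headspace-pressure traces from a gas-production system
(one pressure sensor per incubation bottle, automatic release above a
gauge-pressure threshold) into cumulative gas curves, fits the monophasic
sigmoidal model

    G(t) = A / (1 + (B / t)^C)

and derives the kinetic summaries used in forage evaluation: the
asymptotic (maximum) gas production ``A`` (mL/g DM), the half-time ``B``
(h), the shape constant ``C``, and the time of maximum digestion rate
``t_RM = B (C - 1)^(1/C)`` (defined only for C > 1), plus in vitro dry
matter disappearance.

Pressure is converted to moles with the ideal gas law n = pV/(RT) and to
volume with the standard molar volume (22 400 mL/mol); vented gas is
added back to the running total so the cumulative curve is independent of
the venting schedule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateInputError,
    DomainError,
    InconsistentTraceError,
    InvalidConstantsError,
)

__all__ = [
    "IncubationConstants",
    "PressureTrace",
    "GasCurve",
    "MonophasicFit",
    "IncubationResult",
    "pressure_to_moles",
    "moles_to_ml",
    "psi_to_ml",
    "cumulative_gas",
    "blank_correct",
    "monophasic_G",
    "fit_monophasic",
    "t_rm",
    "dm_disappearance_invitro",
]


@dataclass(frozen=True)
class IncubationConstants:
    """Physical constants of one incubation run.

    Parameters
    ----------
    headspace_volume
        Gas headspace of the bottle in litres. Default 0.150 L
        (250 mL bottle minus 66 mL buffer and 34 mL inoculum; substrate
        volume neglected).
    temperature
        Incubation temperature in kelvin (39 degC = 312.15 K).
    gas_constant
        Ideal gas constant, L*kPa/(K*mol).
    molar_volume
        Volume of one mole of ideal gas at standard conditions, mL/mol.
    psi_to_kpa
        Unit conversion, kPa per psi. Readings are gauge pressure above
        ambient.
    vent_threshold
        Gauge pressure (psi) at which the head module releases gas.
    """

    headspace_volume: float = 0.150
    temperature: float = 312.15
    gas_constant: float = 8.314472
    molar_volume: float = 22400.0
    psi_to_kpa: float = 6.894757
    vent_threshold: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "headspace_volume",
            "temperature",
            "gas_constant",
            "molar_volume",
            "psi_to_kpa",
            "vent_threshold",
        ):
            if not getattr(self, name) > 0:
                raise InvalidConstantsError(f"{name} must be strictly positive")


@dataclass
class PressureTrace:
    """One bottle's time-stamped gauge-pressure readings.

    ``times`` are hours since the start of incubation; the first reading
    is at t=0 with pressure 0. ``vent_times``/``vent_psi`` record gas
    releases; a vent recorded at time t happens after the reading at t,
    resetting the gauge to zero for subsequent readings.
    """

    bottle_id: str
    substrate_mass: float  # g as-weighed
    dm_fraction: float
    times: np.ndarray  # h
    gauge_psi: np.ndarray
    vent_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    vent_psi: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_blank: bool = False
    final_ph: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gauge_psi = np.asarray(self.gauge_psi, dtype=float)
        self.vent_times = np.asarray(self.vent_times, dtype=float)
        self.vent_psi = np.asarray(self.vent_psi, dtype=float)
        if self.times.shape != self.gauge_psi.shape:
            raise DomainError("times and gauge_psi must have equal length")
        if self.vent_times.shape != self.vent_psi.shape:
            raise DomainError("vent_times and vent_psi must have equal length")

    @property
    def g_dm(self) -> float:
        """Grams of substrate dry matter in the bottle."""
        return self.substrate_mass * self.dm_fraction

    def validate(self) -> None:
        """Raise :class:`DomainError` on an invariant violation."""
        if self.times.size == 0:
            raise DomainError(f"{self.bottle_id}: empty trace")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError(f"{self.bottle_id}: times must be strictly increasing")
        if self.times[0] != 0 or self.gauge_psi[0] != 0:
            raise DomainError(f"{self.bottle_id}: trace must start at (t=0, p=0)")
        if not (0 <= self.dm_fraction <= 1):
            raise DomainError(f"{self.bottle_id}: dm_fraction outside [0, 1]")
        if not self.is_blank and self.g_dm <= 0:
            raise DomainError(f"{self.bottle_id}: non-blank bottle needs substrate DM > 0")


@dataclass
class GasCurve:
    """Cumulative gas production for one bottle.

    ``per_g_dm`` distinguishes substrate bottles (mL per g DM) from blank
    bottles, which stay on a per-bottle mL basis so blank correction can
    subtract volumes before normalization.
    """

    bottle_id: str
    times: np.ndarray
    cumulative_gas: np.ndarray
    per_g_dm: bool
    g_dm: Optional[float] = None
    blank_corrected: bool = False
    negative_flagged: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_gas = np.asarray(self.cumulative_gas, dtype=float)


@dataclass
class MonophasicFit:
    """Fitted monophasic model parameters with diagnostics.

    ``t_rm`` is None when C <= 1 (the curve has no interior inflection,
    so the digestion rate is maximal at t -> 0).
    """

    A: float
    B: float
    C: float
    t_rm: Optional[float]
    rss: float
    converged: bool
    n_points: int


@dataclass
class IncubationResult:
    """Per-bottle summary joining the kinetic fit with end-point assays."""

    bottle_id: str
    fit: MonophasicFit
    ddm: Optional[float] = None  # in vitro DM disappearance, percent
    final_ph: Optional[float] = None


# ---------------------------------------------------------------------------
# unit conversions


def pressure_to_moles(pressure_kpa, constants: IncubationConstants = IncubationConstants()):
    """Moles of gas in the headspace at the given gauge pressure (ideal gas law).

    n = p * V / (R * T). Linear in pressure; accepts scalars or arrays.
    """
    if constants.headspace_volume <= 0 or constants.temperature <= 0:
        raise InvalidConstantsError("headspace_volume and temperature must be positive")
    p = np.asarray(pressure_kpa, dtype=float)
    if np.any(p < 0):
        raise DomainError("pressure must be non-negative")
    n = p * constants.headspace_volume / (constants.gas_constant * constants.temperature)
    return float(n) if np.isscalar(pressure_kpa) else n


def moles_to_ml(n, constants: IncubationConstants = IncubationConstants()):
    """Volume (mL) of ``n`` moles of gas at standard conditions."""
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 0):
        raise DomainError("moles must be non-negative")
    out = arr * constants.molar_volume
    return float(out) if np.isscalar(n) else out


def psi_to_ml(psi, constants: IncubationConstants = IncubationConstants()):
    """Gauge pressure (psi) -> gas volume (mL) via kPa, moles and molar volume."""
    p = np.asarray(psi, dtype=float)
    if np.any(p < 0):
        raise DomainError("pressure must be non-negative")
    ml = moles_to_ml(pressure_to_moles(p * constants.psi_to_kpa, constants), constants)
    return float(ml) if np.isscalar(psi) else ml


# ---------------------------------------------------------------------------
# curve reconstruction


def cumulative_gas(
    trace: PressureTrace,
    constants: IncubationConstants = IncubationConstants(),
    *,
    drop_tolerance_psi: float = 0.1,
) -> GasCurve:
    """Reconstruct the cumulative gas curve from a vented pressure trace.

    At each reading the total produced gas equals the current gauge
    pressure plus every release recorded strictly before that reading
    (the instrument reads, then vents). Substrate bottles are normalized
    to mL per g DM; blanks are left in mL per bottle.

    A decrease in the reconstructed cumulative pressure larger than
    ``drop_tolerance_psi`` (default 0.1 psi, generous against sensor
    noise) raises :class:`InconsistentTraceError` — it means gas left the
    bottle without a recorded vent.
    """
    trace.validate()
    vented_before = np.zeros_like(trace.times)
    if trace.vent_times.size:
        order = np.argsort(trace.vent_times, kind="stable")
        vt = trace.vent_times[order]
        vp = np.cumsum(trace.vent_psi[order])
        idx = np.searchsorted(vt, trace.times, side="left")  # vents strictly before t
        vented_before = np.where(idx > 0, vp[np.maximum(idx - 1, 0)], 0.0)
    total_psi = trace.gauge_psi + vented_before
    drops = np.diff(total_psi)
    if np.any(drops < -drop_tolerance_psi):
        k = int(np.argmax(drops < -drop_tolerance_psi))
        raise InconsistentTraceError(
            f"{trace.bottle_id}: cumulative pressure drops by "
            f"{-drops[k]:.3f} psi at t={trace.times[k + 1]:.3f} h without a vent event"
        )
    ml = psi_to_ml(np.clip(total_psi, 0.0, None), constants)
    if trace.is_blank:
        return GasCurve(trace.bottle_id, trace.times, ml, per_g_dm=False, g_dm=None)
    g_dm = trace.g_dm
    if g_dm <= 0:
        raise DomainError(f"{trace.bottle_id}: substrate DM must be positive")
    return GasCurve(trace.bottle_id, trace.times, ml / g_dm, per_g_dm=True, g_dm=g_dm)


def blank_correct(curve: GasCurve, blanks: Sequence[GasCurve]) -> GasCurve:
    """Subtract the mean blank gas volume from a bottle's curve.

    Blank curves carry mL per bottle; they are linearly interpolated onto
    the target grid, averaged pointwise, and subtracted (divided by g DM
    first when the target curve is normalized). Negative corrected values
    are kept and flagged, never clamped. An empty blank list is a no-op
    with a warning.
    """
    if not blanks:
        warnings.warn("no blank bottles supplied; returning curve uncorrected", stacklevel=2)
        return curve
    stacked = np.vstack(
        [np.interp(curve.times, b.times, b.cumulative_gas) for b in blanks]
    )
    mean_blank_ml = stacked.mean(axis=0)
    correction = mean_blank_ml / curve.g_dm if curve.per_g_dm else mean_blank_ml
    corrected = curve.cumulative_gas - correction
    return replace(
        curve,
        cumulative_gas=corrected,
        blank_corrected=True,
        negative_flagged=bool(np.any(corrected < 0)),
    )


# ---------------------------------------------------------------------------
# monophasic model


def monophasic_G(t, A: float, B: float, C: float):
    """Monophasic cumulative gas model G(t) = A / (1 + (B/t)^C).

    G(0) = 0 by continuity, G(B) = A/2 exactly, G -> A as t -> inf.
    """
    if not (A > 0 and B > 0 and C > 0):
        raise DomainError("A, B and C must be strictly positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be non-negative")
    out = np.zeros_like(t_arr)
    pos = t_arr > 0
    out[pos] = A / (1.0 + (B / t_arr[pos]) ** C)
    return float(out) if np.isscalar(t) else out


def t_rm(B: float, C: float) -> Optional[float]:
    """Time of maximum digestion rate, B * (C - 1)^(1/C).

    Returns None for C <= 1: the model then has no interior inflection
    point and the rate is maximal at the origin.
    """
    if not B > 0:
        raise DomainError("B must be strictly positive")
    if not C > 0:
        raise DomainError("C must be strictly positive")
    if C <= 1:
        return None
    return B * (C - 1.0) ** (1.0 / C)


def fit_monophasic(
    curve: GasCurve,
    *,
    max_iter: int = 1000,
    tol: float = 1e-12,
    bounds_scale: float = 5.0,
) -> MonophasicFit:
    """Fit the monophasic model to a cumulative gas curve by least squares.

    Starting values: A0 = 1.1 * max(G); B0 = the interpolated time at
    which G crosses A0/2; C0 = 1.5. Bounds: A in (0, bounds_scale*max(G)],
    B in (0, 96] h, C in [0.1, 10]. Non-convergence is reported in the
    ``converged`` flag, never silently.
    """
    t = curve.times
    g = curve.cumulative_gas
    mask = np.isfinite(g) & (t >= 0)
    t, g = t[mask], g[mask]
    if np.count_nonzero(t > 0) < 6:
        raise DomainError("need at least 6 readings at t > 0 to fit")
    gmax = float(np.max(g))
    if gmax <= 0:
        raise DegenerateInputError(f"{curve.bottle_id}: curve carries no gas production")

    a0 = 1.1 * gmax
    half = a0 / 2.0
    # first crossing of the half-asymptote on the (possibly noisy) curve
    above = np.nonzero(g >= half)[0]
    if above.size and above[0] > 0:
        k = above[0]
        frac = (half - g[k - 1]) / (g[k] - g[k - 1])
        b0 = float(t[k - 1] + frac * (t[k] - t[k - 1]))
    else:
        b0 = float(t[-1] / 2.0)
    b0 = min(max(b0, 0.5), 96.0)
    x0 = np.array([a0, b0, 1.5])
    lo = np.array([1e-9, 1e-9, 0.1])
    hi = np.array([bounds_scale * gmax, 96.0, 10.0])
    x0 = np.clip(x0, lo, hi)

    def residuals(theta):
        A, B, C = theta
        with np.errstate(over="ignore"):
            return monophasic_G(t, A, B, C) - g

    result = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter,
    )
    A, B, C = (float(v) for v in result.x)
    return MonophasicFit(
        A=A,
        B=B,
        C=C,
        t_rm=t_rm(B, C),
        rss=float(np.sum(result.fun**2)),
        converged=bool(result.success),
        n_points=int(t.size),
    )


def dm_disappearance_invitro(feed_in: float, residue: float) -> float:
    """In vitro dry matter disappearance, percent of incubated DM.

    100 * (feed_in - residue) / feed_in, both in g DM. Values outside
    [0, 100] are returned as-is with a warning (weighing error or
    microbial accretion), never clamped.
    """
    if not feed_in > 0:
        raise DomainError("feed_in must be strictly positive")
    if residue < 0:
        raise DomainError("residue must be non-negative")
    d = 100.0 * (feed_in - residue) / feed_in
    if d < 0 or d > 100:
        warnings.warn(f"disappearance {d:.2f}% outside [0, 100]", stacklevel=2)
    return d
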