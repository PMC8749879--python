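"""Ballistic jump metrics from foot-mounted accelerometry.

A repeated-jump (Bosco) trial is a sequence of contact -> flight cycles.  An
accelerometer in free fall reads ~0 g of specific force and ~1 g during quiet
standing, so flight phases appear as sustained near-zero runs in the signal
magnitude.  From the detected contact time Tc and flight time Tf the four
classic flight-time parameters follow:

    h_max     = g * Tf^2 / 8                      (projectile kinematics)
    P_mean    = (m*g^2/Tc) * (Tf^2/4 + Tc*|Tc+Tf|/pi - Tc^2/4)
    RSI       = h_max / Tc
    stiffness = m*pi*(Tf+Tc) / (Tc^2 * ((Tf+Tc)/pi - Tc/4))

where m is body mass and g gravitational acceleration.  The stiffness formula
is the spring-mass model of hopping: the leg is an ideal spring loaded during
ground contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BodyParams",
    "JumpEvent",
    "BoscoResult",
    "ValidityBounds",
    "flight_height",
    "mean_power",
    "reactive_strength_index",
    "leg_stiffness",
    "detect_jump_events",
    "bosco_summary",
]

G_DEFAULT = 9.81


@dataclass(frozen=True)
class BodyParams:
    """Body mass and local gravitational acceleration."""

    mass_kg: float
    g_ms2: float = G_DEFAULT

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError(f"mass_kg must be positive, got {self.mass_kg}")
        if self.g_ms2 <= 0:
            raise ValueError(f"g_ms2 must be positive, got {self.g_ms2}")


@dataclass(frozen=True)
class JumpEvent:
    """One contact -> flight cycle, in seconds from the trace origin."""

    contact_start_s: float
    takeoff_s: float
    landing_s: float

    def __post_init__(self) -> None:
        if not (self.contact_start_s < self.takeoff_s < self.landing_s):
            raise ValueError(
                "event ordering violated: need contact_start < takeoff < landing, "
                f"got {self.contact_start_s}, {self.takeoff_s}, {self.landing_s}"
            )

    @property
    def tc_s(self) -> float:
        return self.takeoff_s - self.contact_start_s

    @property
    def tf_s(self) -> float:
        return self.landing_s - self.takeoff_s


@dataclass(frozen=True)
class ValidityBounds:
    """Physiological plausibility window for repeated vertical jumps.

    Pairs outside these bounds are treated as detection artifacts (stumbles,
    double contacts, missed landings) and excluded from trial aggregates.
    """

    tc_min_s: float = 0.10
    tc_max_s: float = 1.00
    tf_min_s: float = 0.20
    tf_max_s: float = 0.90

    def is_valid(self, tc_s: float, tf_s: float) -> bool:
        return (self.tc_min_s <= tc_s <= self.tc_max_s) and (
            self.tf_min_s <= tf_s <= self.tf_max_s
        )


@dataclass(frozen=True)
class BoscoResult:
    """Per-trial aggregate of the six repeated-jump parameters."""

    h_max_m: float
    mean_power_w: float
    rsi_ms: float
    stiffness_nm: float
    tc_s: float
    tf_s: float
    n_jumps: int


# ---------------------------------------------------------------------------
# Flight-time formulas
# ---------------------------------------------------------------------------

def flight_height(tf_s: float, g: float = G_DEFAULT) -> float:
    """Maximum centre-of-mass height from flight time: h = g*Tf^2/8."""
    if tf_s < 0:
        raise ValueError(f"flight time must be non-negative, got {tf_s}")
    if g <= 0:
        raise ValueError(f"g must be positive, got {g}")
    return g * tf_s * tf_s / 8.0


def mean_power(body: BodyParams, tc_s: float, tf_s: float) -> float:
    """Mean exerted power over a contact+flight cycle (W).

    P = (m*g^2/Tc) * (Tf^2/4 + Tc*|Tc+Tf|/pi - Tc^2/4).  The bracket has
    units of s^2 and the prefactor kg*m^2/s^5, so P is in watts.
    """
    if tc_s <= 0:
        raise ValueError(f"contact time must be positive, got {tc_s}")
    if tf_s < 0:
        raise ValueError(f"flight time must be non-negative, got {tf_s}")
    m, g = body.mass_kg, body.g_ms2
    bracket = tf_s * tf_s / 4.0 + tc_s * abs(tc_s + tf_s) / math.pi - tc_s * tc_s / 4.0
    return m * g * g / tc_s * bracket


def reactive_strength_index(h_max_m: float, tc_s: float) -> float:
    """RSI = jump height / ground contact time (m/s)."""
    if tc_s <= 0:
        raise ValueError(f"contact time must be positive, got {tc_s}")
    if h_max_m < 0:
        raise ValueError(f"height must be non-negative, got {h_max_m}")
    return h_max_m / tc_s


def leg_stiffness(body: BodyParams, tc_s: float, tf_s: float) -> float:
    """Spring-mass leg stiffness (N/m).

    K = m*pi*(Tf+Tc) / (Tc^2 * ((Tf+Tc)/pi - Tc/4)).  The denominator is
    positive whenever Tf > Tc*(pi/4 - 1); shorter flights make the spring
    model inconsistent and raise a domain error.
    """
    if tc_s <= 0:
        raise ValueError(f"contact time must be positive, got {tc_s}")
    if tf_s < 0:
        raise ValueError(f"flight time must be non-negative, got {tf_s}")
    m = body.mass_kg
    denom_core = (tf_s + tc_s) / math.pi - tc_s / 4.0
    if denom_core <= 0:
        raise ValueError(
            "spring-mass stiffness undefined: (Tf+Tc)/pi - Tc/4 = "
            f"{denom_core:.6g} <= 0 for Tc={tc_s}, Tf={tf_s} "
            f"(requires Tf > Tc*(pi/4 - 1) = {tc_s * (math.pi / 4 - 1):.4g} s)"
        )
    return m * math.pi * (tf_s + tc_s) / (tc_s * tc_s * denom_core)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where mask is True."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_jump_events(
    trace,
    flight_threshold_g: float = 0.3,
    min_flight_s: float = 0.08,
    min_contact_s: float = 0.05,
    onset_floor_g: float = 0.005,
    min_onset_s: float = 0.05,
) -> list[JumpEvent]:
    """Detect contact/flight cycles in a foot-mounted accelerometer trace.

    Flight phases are maximal runs where the specific-force magnitude stays
    below ``flight_threshold_g`` for at least ``min_flight_s``; contacts are
    the gaps between consecutive flights.  Gaps shorter than
    ``min_contact_s`` are treated as noise inside a single flight and merged.
    The first contact starts at movement onset: the first sustained
    (``min_onset_s``) departure of |a - 1 g| beyond 3x the quiet-standing
    noise level (floored at ``onset_floor_g``).

    Parameters
    ----------
    trace
        An object with ``fs_hz``, ``t0`` and ``samples`` (specific force, g),
        e.g. :class:`fatiguekit.synthetic.AccelTrace`.
    """
    if flight_threshold_g <= 0 or min_flight_s <= 0 or min_contact_s <= 0:
        raise ValueError("thresholds must be positive")
    a = np.abs(np.asarray(trace.samples, dtype=float))
    if a.size == 0:
        raise ValueError("empty trace")
    fs = float(trace.fs_hz)

    min_flight_n = max(1, int(round(min_flight_s * fs)))
    min_contact_n = max(1, int(round(min_contact_s * fs)))

    runs = [(s, e) for s, e in _true_runs(a < flight_threshold_g) if e - s >= min_flight_n]
    # a flight needs a landing: drop a run touching the end of the trace,
    # and a run touching the start (no preceding contact).
    runs = [(s, e) for s, e in runs if s > 0 and e < a.size]
    if not runs:
        return []

    # merge flights separated by implausibly short "contacts" (spikes)
    merged: list[tuple[int, int]] = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < min_contact_n:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))

    first_takeoff = merged[0][0]
    onset = _movement_onset(a, fs, first_takeoff, onset_floor_g, min_onset_s)

    events: list[JumpEvent] = []
    prev_landing = onset
    for s, e in merged:
        if prev_landing is not None and s - prev_landing >= min_contact_n:
            t0 = float(trace.t0)
            events.append(
                JumpEvent(
                    contact_start_s=t0 + prev_landing / fs,
                    takeoff_s=t0 + s / fs,
                    landing_s=t0 + e / fs,
                )
            )
        prev_landing = e
    return events


def _movement_onset(
    a: np.ndarray, fs: float, first_takeoff: int, floor_g: float, min_onset_s: float
):
    """First sustained departure from quiet standing before the first flight."""
    if first_takeoff <= 1:
        return None
    quiet_n = max(2, min(int(round(0.2 * fs)), first_takeoff // 2))
    noise_sd = float(np.std(a[:quiet_n]))
    thr = max(3.0 * noise_sd, floor_g)
    min_onset_n = max(1, int(round(min_onset_s * fs)))
    dev = np.abs(a[:first_takeoff] - 1.0) > thr
    for s, e in _true_runs(dev):
        if e - s >= min_onset_n or e == first_takeoff:
            return s
    return None


# ---------------------------------------------------------------------------
# Trial aggregation
# ---------------------------------------------------------------------------

def bosco_summary(
    events: Sequence[JumpEvent],
    body: BodyParams,
    validity: ValidityBounds = ValidityBounds(),
) -> BoscoResult:
    """Aggregate a repeated-jump trial into the six Bosco parameters.

    Per-jump (Tc, Tf) pairs outside the validity bounds are excluded; the
    trial-level Tc and Tf are means over the remaining jumps, and the four
    derived parameters are computed from that aggregate pair — which keeps
    the identity h_max = g*Tf^2/8 exactly true for the reported aggregates.
    """
    events = list(events)
    if not events:
        raise ValueError("no jump events to summarize")
    valid = [ev for ev in events if validity.is_valid(ev.tc_s, ev.tf_s)]
    if not valid:
        raise ValueError(
            f"all {len(events)} events removed by validity bounds "
            f"tc in [{validity.tc_min_s}, {validity.tc_max_s}] s, "
            f"tf in [{validity.tf_min_s}, {validity.tf_max_s}] s"
        )
    tc = float(np.mean([ev.tc_s for ev in valid]))
    tf = float(np.mean([ev.tf_s for ev in valid]))
    h = flight_height(tf, body.g_ms2)
    return BoscoResult(
        h_max_m=h,
        mean_power_w=mean_power(body, tc, tf),
        rsi_ms=reactive_strength_index(h, tc),
        stiffness_nm=leg_stiffness(body, tc, tf),
        tc_s=tc,
        tf_s=tf,
        n_jumps=len(valid),
    )
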