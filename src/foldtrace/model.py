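"""Compartmental model of CFTR biogenesis under metabolic labeling.

The immature, core-glycosylated ER form of CFTR (the SDS-PAGE "B band") is
synthesized at a constant rate and either matures into the complex-glycosylated
post-Golgi form (the "C band") or is degraded by ER-associated degradation.
Both pools turn over with first-order kinetics::

    dB/dt = s(t) - (k_mat + k_degB) * B
    dC/dt = k_mat * B - k_degC * C

Metabolic labeling (SILAC) splits synthesis between a heavy and a light
isotopolog according to a piecewise-constant label schedule, giving four pools
(B/C x heavy/light) that share the same rate constants.  The ER folding
efficiency of the model is phi = k_mat / (k_mat + k_degB): the probability
that a B molecule matures rather than being degraded.

The system is linear with piecewise-constant input, so it is solved exactly
with the matrix exponential of the augmented affine system; no numerical
time-stepping is involved.  Cumulative synthesis and cumulative degradation
are propagated alongside the pools so that mass balance can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

from .errors import ValidationError

LABELS = ("heavy", "light")

# State vector layout: per label, [B, C, D, S] where D is cumulative mass
# degraded (from either pool) and S cumulative labeled synthesis; heavy block
# first, then light, then the affine constant 1.
_NB, _NC, _ND, _NS = 0, 1, 2, 3
_BLOCK = 4
_DIM = 2 * _BLOCK + 1


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the four-pool biogenesis model.

    Parameters
    ----------
    synthesis_rate : float
        Constant synthesis flux into the B pool, arbitrary units per hour.
    k_mat : float
        First-order B -> C maturation rate, 1/h.
    k_deg_b : float
        First-order degradation rate of the B pool, 1/h.
    k_deg_c : float
        First-order degradation rate of the C pool, 1/h.
    pulse_duration : float
        Duration of the labeling pulse, hours.
    """

    synthesis_rate: float
    k_mat: float
    k_deg_b: float
    k_deg_c: float
    pulse_duration: float = 0.5

    def __post_init__(self) -> None:
        for name in ("synthesis_rate", "k_mat", "k_deg_b", "k_deg_c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if not np.isfinite(self.pulse_duration) or self.pulse_duration <= 0:
            raise ValidationError(
                f"pulse_duration must be > 0, got {self.pulse_duration!r}"
            )

    @property
    def turnover_b(self) -> float:
        """Total first-order exit rate of the B pool (k_mat + k_degB), 1/h."""
        return self.k_mat + self.k_deg_b

    @property
    def folding_efficiency(self) -> float:
        """phi = k_mat / (k_mat + k_degB); defined as 0 when both rates are 0."""
        if self.turnover_b == 0:
            return 0.0
        return self.k_mat / self.turnover_b

    def steady_state(self) -> tuple[float, float]:
        """Pre-pulse steady state (B, C) under fully unlabeled synthesis.

        The mature pool has no finite steady state when k_degC = 0; it is
        started empty in that case (see docs/methods.md).
        """
        if self.turnover_b <= 0:
            raise ValidationError(
                "steady-state initialization requires k_mat + k_deg_b > 0"
            )
        b = self.synthesis_rate / self.turnover_b
        c = self.k_mat * b / self.k_deg_c if self.k_deg_c > 0 else 0.0
        return b, c


@dataclass(frozen=True)
class Trajectory:
    """Exact pool time courses of the labeled biogenesis model.

    All arrays share the time grid; abundances are in the synthesis-rate
    units.  ``synthesized_*`` and ``degraded_*`` are cumulative from t=0.
    """

    times: np.ndarray
    b_heavy: np.ndarray
    b_light: np.ndarray
    c_heavy: np.ndarray
    c_light: np.ndarray
    degraded_heavy: np.ndarray
    degraded_light: np.ndarray
    synthesized_heavy: np.ndarray
    synthesized_light: np.ndarray
    initial_pools: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def pool(self, band: str, isotopolog: str) -> np.ndarray:
        return getattr(self, f"{band.lower()}_{isotopolog}")

    def mass_balance_error(self) -> float:
        """Max relative violation of synthesis = pools + degradation."""
        b0h, c0h, b0l, c0l = self.initial_pools
        err = 0.0
        for lab, init in (("heavy", b0h + c0h), ("light", b0l + c0l)):
            lhs = getattr(self, f"synthesized_{lab}") + init
            rhs = (
                self.pool("b", lab)
                + self.pool("c", lab)
                + getattr(self, f"degraded_{lab}")
            )
            scale = np.maximum(np.abs(lhs), 1.0)
            err = max(err, float(np.max(np.abs(lhs - rhs) / scale)))
        return err


@dataclass(frozen=True)
class Segment:
    """One piece of a piecewise-constant simulation: params + label from start."""

    start: float
    params: KineticParams
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")


def pulse_chase_schedule(pulse_duration: float) -> list[tuple[float, str]]:
    """Heavy pulse from t=0 for `pulse_duration` hours, then light chase."""
    return [(0.0, "heavy"), (float(pulse_duration), "light")]


def _affine_matrix(p: KineticParams, label: str) -> np.ndarray:
    a = p.turnover_b
    m = np.zeros((_DIM, _DIM))
    for block in range(2):
        o = block * _BLOCK
        m[o + _NB, o + _NB] = -a
        m[o + _NC, o + _NB] = p.k_mat
        m[o + _NC, o + _NC] = -p.k_deg_c
        m[o + _ND, o + _NB] = p.k_deg_b
        m[o + _ND, o + _NC] = p.k_deg_c
    o = 0 if label == "heavy" else _BLOCK
    m[o + _NB, _DIM - 1] = p.synthesis_rate
    m[o + _NS, _DIM - 1] = p.synthesis_rate
    return m


def _initial_state(
    params: KineticParams, initial: str
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    y = np.zeros(_DIM)
    y[-1] = 1.0
    if initial == "empty":
        pools = (0.0, 0.0, 0.0, 0.0)
    elif initial == "steady_state":
        b, c = params.steady_state()
        y[_BLOCK + _NB] = b
        y[_BLOCK + _NC] = c
        pools = (0.0, 0.0, b, c)
    else:
        raise ValidationError(
            f"initial must be 'steady_state' or 'empty', got {initial!r}"
        )
    return y, pools


def simulate_segments(
    segments: Sequence[Segment],
    times: Iterable[float],
    initial: str = "steady_state",
) -> Trajectory:
    """Propagate the model exactly through a list of (params, label) segments.

    ``segments`` must start at t=0 with strictly increasing start times; the
    pre-t=0 history is encoded by ``initial`` (steady state of the *first*
    segment's parameters under light synthesis, or empty pools).
    """
    segments = list(segments)
    if not segments or segments[0].start != 0.0:
        raise ValidationError("segments must be non-empty and start at t=0")
    starts = [s.start for s in segments]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValidationError("segment start times must be strictly increasing")
    t = np.asarray(list(times), dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValidationError("times must be sorted and >= 0")

    y, init_pools = _initial_state(segments[0].params, initial)
    bounds = starts[1:] + [np.inf]
    out = np.empty((t.size, _DIM))
    now = 0.0
    seg_i = 0
    for k, tk in enumerate(t):
        while tk > bounds[seg_i]:
            dt = bounds[seg_i] - now
            if dt > 0:
                y = expm(_affine_matrix(segments[seg_i].params, segments[seg_i].label) * dt) @ y
            now = bounds[seg_i]
            seg_i += 1
        dt = tk - now
        if dt > 0:
            y = expm(_affine_matrix(segments[seg_i].params, segments[seg_i].label) * dt) @ y
            now = tk
        out[k] = y

    h, l = out[:, :_BLOCK], out[:, _BLOCK : 2 * _BLOCK]
    return Trajectory(
        times=t,
        b_heavy=h[:, _NB].copy(),
        c_heavy=h[:, _NC].copy(),
        degraded_heavy=h[:, _ND].copy(),
        synthesized_heavy=h[:, _NS].copy(),
        b_light=l[:, _NB].copy(),
        c_light=l[:, _NC].copy(),
        degraded_light=l[:, _ND].copy(),
        synthesized_light=l[:, _NS].copy(),
        initial_pools=(0.0, 0.0, init_pools[2], init_pools[3]),
    )


def simulate_trajectory(
    params: KineticParams,
    label_schedule: Sequence[tuple[float, str]],
    times: Iterable[float],
    initial: str = "steady_state",
) -> Trajectory:
    """Exact four-pool trajectory for constant rates and a label schedule.

    ``label_schedule`` is a list of (start_time, label) switch points, e.g.
    ``[(0, "heavy"), (0.5, "light")]`` for a 30-min heavy pulse followed by a
    light chase.  Time zero is the start of the schedule; the pre-schedule
    history is the light-synthesis steady state unless ``initial='empty'``.
    """
    segments = [Segment(float(s), params, lab) for s, lab in label_schedule]
    return simulate_segments(segments, times, initial=initial)


def ode_rhs(t: float, y: np.ndarray, params: KineticParams, label: str) -> np.ndarray:
    """Right-hand side of the labeled system for use by numerical integrators.

    Exposed so that an independent step-size-controlled integrator can serve
    as an oracle for the matrix-exponential solution.
    """
    m = _affine_matrix(params, label)
    return (m @ np.append(y, 1.0))[: 2 * _BLOCK]
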