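"""Explicit-Euler integration of the delayed rate equations.

The scheme follows the model's reference numerical treatment: forward
Euler with a 1 ms step, delayed rates read from a circular buffer of
length tau/dt, zero initial conditions and zero delay history.  STIM
protocols are piecewise constant per cell.

With the default parameters alpha_m * dt <= 0.08, which keeps every
rate inside [0, r0_m] for all time (the update is a convex-combination
contraction toward a point inside the box).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .model import CellType, ModelParams, WeightSet, response

__all__ = ["SimConfig", "StimProtocol", "RateTrace", "simulate",
           "remove_connection"]


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    dt                : step, s (default 0.001).
    duration          : total simulated time, s (default 8.0).
    transient_discard : initial interval dropped by analysis routines, s.
    seed              : recorded for provenance; the integration itself
                        is deterministic.
    """

    dt: float = 0.001
    duration: float = 8.0
    transient_discard: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.transient_discard:
            raise ValueError("duration must be at least transient_discard")

    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def delay_steps(self, params: ModelParams) -> int:
        tau_s = params.tau_ms / 1000.0
        steps = tau_s / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"delay tau = {params.tau_ms} ms is not an integer multiple "
                f"of dt = {self.dt} s")
        return int(round(steps))


@dataclass(frozen=True)
class StimProtocol:
    """Piecewise-constant per-cell STIM (au).

    ``segments`` maps a CellType to an ordered list of
    (t_start, t_end, value) triples.  Cells without an entry receive 0.
    Segments are left-closed: a change takes effect at the first step
    whose time is >= t_start.
    """

    segments: dict = field(default_factory=dict)

    @classmethod
    def constant(cls, values: dict | None = None) -> "StimProtocol":
        """Constant STIM per cell for the whole run; values in au."""
        values = values or {}
        return cls({c: [(0.0, np.inf, float(v))]
                    for c, v in values.items() if v != 0.0})

    @classmethod
    def single_cell(cls, cell: CellType, value: float) -> "StimProtocol":
        return cls.constant({cell: value})

    def stim_array(self, config: SimConfig) -> np.ndarray:
        """(n_steps, 4) array of STIM values at each step time."""
        n = config.n_steps()
        t = np.arange(n) * config.dt
        out = np.zeros((n, 4))
        for cell, segs in self.segments.items():
            covered = np.zeros(n, dtype=bool)
            for (t0, t1, v) in segs:
                sel = (t >= t0) & (t < t1)
                if np.any(covered & sel):
                    raise ValueError(
                        f"overlapping STIM segments for {cell.name}")
                covered |= sel
                out[sel, cell.value] = v
        return out

    def to_dict(self) -> dict:
        return {c.name: [[t0, (None if np.isinf(t1) else t1), v]
                         for (t0, t1, v) in segs]
                for c, segs in self.segments.items()}


@dataclass(frozen=True)
class RateTrace:
    """Simulated population rates.

    times : (n+1,) sample times, s, uniformly spaced from 0.
    rates : (n+1, 4) firing rates, Hz, columns in CellType order.
    """

    times: np.ndarray
    rates: np.ndarray
    params_fingerprint: str = ""

    def cell(self, cell: CellType) -> np.ndarray:
        return self.rates[:, cell.value]

    @property
    def fs(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])

    def after(self, t0: float) -> "RateTrace":
        """Sub-trace with times >= t0 (transient trimming)."""
        keep = self.times >= t0 - 1e-12
        return RateTrace(self.times[keep], self.rates[keep],
                         self.params_fingerprint)

    def window(self, t0: float, t1: float) -> "RateTrace":
        keep = (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)
        return RateTrace(self.times[keep], self.rates[keep],
                         self.params_fingerprint)

    def to_csv(self, path) -> None:
        header = (f"# fingerprint={self.params_fingerprint}\n"
                  "time_s,r_PYR,r_BiC,r_CCK,r_PV")
        data = np.column_stack([self.times, self.rates])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.6f")


def _fingerprint(params: ModelParams, protocol: StimProtocol,
                 config: SimConfig) -> str:
    payload = json.dumps(
        {"params": params.to_dict(), "protocol": protocol.to_dict(),
         "config": [config.dt, config.duration, config.transient_discard]},
        sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate(params: ModelParams,
             protocol: StimProtocol | None = None,
             config: SimConfig | None = None) -> RateTrace:
    """Integrate the delayed system with explicit Euler.

    Initial state and the delay history on [-tau, 0) are all zero.  The
    returned trace includes the initial transient; analysis routines are
    responsible for trimming it.
    """
    protocol = protocol or StimProtocol()
    config = config or SimConfig()
    n = config.n_steps()
    d = config.delay_steps(params)

    alpha, r0, ie, beta = params.alpha, params.r0, params.ie, params.beta
    W = params.weights.as_matrix()
    base = params.stim_vector
    stim = protocol.stim_array(config) + base

    rates = np.zeros((n + 1, 4))
    adt = alpha * config.dt
    zeros4 = np.zeros(4)
    for i in range(n):
        delayed = rates[i - d] if i >= d else zeros4
        I = ie + W @ delayed + stim[i]
        target = r0 * response(I, beta)
        rates[i + 1] = rates[i] + adt * (target - rates[i])
        if not np.all(np.isfinite(rates[i + 1])):
            raise FloatingPointError(
                f"non-finite state at step {i + 1} (t = {(i + 1) * config.dt:.4f} s)")
    times = np.arange(n + 1) * config.dt
    return RateTrace(times, rates, _fingerprint(params, protocol, config))


def remove_connection(params: ModelParams, edge) -> ModelParams:
    """Copy of ``params`` with one mask edge's weight set to zero."""
    weights = params.weights.replace(edge, 0.0)
    return replace(params, weights=weights)
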