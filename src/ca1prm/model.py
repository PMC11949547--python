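"""Domain types and instantaneous dynamics of the four-population rate model.

The model describes the mean firing rates r_m(t) of four CA1 populations
m in (PYR, BiC, CCK, PV) by delayed differential equations

    dr_m/dt = alpha_m * ( -r_m + r0_m * f(I_m) ),

where f is a logistic response function with gain beta, and the total
drive I_m = ie_m + Itilde_m combines the cell's intrinsic excitability
with delayed synaptic input and external stimulation.  All synaptic
terms are evaluated at t - tau (a single lumped synaptic/axonal delay);
STIM terms are instantaneous.

Units: rates and rate constants in Hz; drives (ie, STIM, w*r products)
in dimensionless "au"; the delay in ms.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CellType", "CellParams", "ConnectivityMask", "WeightSet", "ModelParams",
    "DriveVector", "response", "inverse_response", "presynaptic_drive", "drift",
    "MASK_EDGES", "EXCITATORY_EDGES", "INHIBITORY_EDGES",
]


class CellType(enum.Enum):
    """The four modeled populations, in fixed state-vector order."""

    PYR = 0   # pyramidal cells
    BiC = 1   # bistratified cells
    CCK = 2   # CCK-expressing basket cells
    PV = 3    # PV-expressing basket cells

    @classmethod
    def from_name(cls, name: str) -> "CellType":
        try:
            return cls[name]
        except KeyError:
            raise ValueError(f"unknown cell type {name!r}; expected one of "
                             f"{[c.name for c in cls]}") from None


# Directed edges of the fixed connectivity mask, (source, target).
EXCITATORY_EDGES: tuple = (
    (CellType.PYR, CellType.PYR),
    (CellType.PYR, CellType.BiC),
    (CellType.PYR, CellType.PV),
)
INHIBITORY_EDGES: tuple = (
    (CellType.BiC, CellType.PYR),
    (CellType.PV, CellType.PYR),
    (CellType.CCK, CellType.CCK),
    (CellType.PV, CellType.CCK),
    (CellType.CCK, CellType.PV),
    (CellType.PV, CellType.PV),
)
MASK_EDGES: tuple = EXCITATORY_EDGES + INHIBITORY_EDGES


def edge_key(edge) -> str:
    """String key "SRC->TGT" for a mask edge."""
    src, tgt = edge
    return f"{src.name}->{tgt.name}"


def parse_edge(key: str):
    try:
        s, t = key.split("->")
        edge = (CellType.from_name(s), CellType.from_name(t))
    except (ValueError, KeyError):
        raise ValueError(f"malformed edge key {key!r}; expected 'SRC->TGT'")
    return edge


@dataclass(frozen=True)
class ConnectivityMask:
    """The nine directed connections of the circuit.

    Any (source, target) pair not listed does not exist in the model and
    its weight is identically zero.  The excitatory/inhibitory labels
    are structural and immutable.
    """

    excitatory: tuple = EXCITATORY_EDGES
    inhibitory: tuple = INHIBITORY_EDGES

    @property
    def edges(self) -> tuple:
        return self.excitatory + self.inhibitory

    def __contains__(self, edge) -> bool:
        return edge in self.edges

    def is_excitatory(self, edge) -> bool:
        return edge in self.excitatory


MASK = ConnectivityMask()


@dataclass(frozen=True)
class WeightSet:
    """Signed synaptic weights w_{n->m} on the mask edges.

    Inhibitory weights carry their sign (stored <= 0), so the synaptic
    drive is a plain sum of w * r terms.  Excitatory weights are >= 0.
    """

    w: dict

    def __post_init__(self):
        clean = {}
        for edge, value in self.w.items():
            if isinstance(edge, str):
                edge = parse_edge(edge)
            if edge not in MASK:
                raise ValueError(f"edge {edge_key(edge)} is not in the "
                                 "connectivity mask")
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"weight for {edge_key(edge)} is not finite")
            if MASK.is_excitatory(edge):
                if value < 0:
                    raise ValueError(f"excitatory edge {edge_key(edge)} has "
                                     f"negative weight {value}")
            elif value > 0:
                raise ValueError(f"inhibitory edge {edge_key(edge)} has "
                                 f"positive weight {value}")
            clean[edge] = value
        for edge in MASK.edges:
            clean.setdefault(edge, 0.0)
        object.__setattr__(self, "w", clean)

    def __getitem__(self, edge) -> float:
        if isinstance(edge, str):
            edge = parse_edge(edge)
        if edge not in MASK:
            raise KeyError(f"edge {edge_key(edge)} is not in the mask")
        return self.w[edge]

    def replace(self, edge, value: float) -> "WeightSet":
        if isinstance(edge, str):
            edge = parse_edge(edge)
        if edge not in MASK:
            raise ValueError(f"edge {edge_key(edge)} is not in the mask")
        new = dict(self.w)
        new[edge] = float(value)
        return WeightSet(new)

    def as_matrix(self) -> np.ndarray:
        """Dense 4x4 matrix W with W[target, source] = w_{source->target}."""
        W = np.zeros((4, 4))
        for (src, tgt), v in self.w.items():
            W[tgt.value, src.value] = v
        return W

    def as_vector(self) -> np.ndarray:
        """Length-9 vector in canonical mask-edge order."""
        return np.array([self.w[e] for e in MASK.edges])

    def to_dict(self) -> dict:
        return {edge_key(e): self.w[e] for e in MASK.edges}

    @classmethod
    def from_vector(cls, vec) -> "WeightSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (9,):
            raise ValueError("weight vector must have length 9")
        return cls(dict(zip(MASK.edges, vec)))

    @classmethod
    def zeros(cls) -> "WeightSet":
        return cls({})


@dataclass(frozen=True)
class CellParams:
    """Per-population parameters.

    alpha : membrane rate constant, Hz.
    r0    : maximal firing rate, Hz.
    ie    : intrinsic excitability, au (captures threshold / rheobase /
            input resistance differences between the cell types).
    beta  : response-function gain, au.  A single beta = 20 is used for
            all populations by default; the field is per-cell so that
            differential gains can be explored.
    """

    alpha: float
    r0: float
    ie: float
    beta: float = 20.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


#: Default per-population parameters of the CA1 circuit.
DEFAULT_CELL_PARAMS = {
    CellType.PYR: CellParams(alpha=40.0, r0=40.0, ie=0.03),
    CellType.BiC: CellParams(alpha=80.0, r0=100.0, ie=-1.45),
    CellType.CCK: CellParams(alpha=40.0, r0=60.0, ie=0.8),
    CellType.PV: CellParams(alpha=80.0, r0=100.0, ie=0.5),
}


@dataclass(frozen=True)
class ModelParams:
    """Complete parameterization of the four-population delayed system."""

    cells: dict = field(default_factory=lambda: dict(DEFAULT_CELL_PARAMS))
    weights: WeightSet = field(default_factory=WeightSet.zeros)
    tau_ms: float = 5.0
    baseline_stim: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.cells) != set(CellType):
            raise ValueError("cells must map every CellType to CellParams")
        if self.tau_ms < 0:
            raise ValueError("tau must be non-negative")
        stim = {c: float(self.baseline_stim.get(c, 0.0)) for c in CellType}
        object.__setattr__(self, "baseline_stim", stim)

    # -- convenience vectors in CellType order ---------------------------
    @property
    def alpha(self) -> np.ndarray:
        return np.array([self.cells[c].alpha for c in CellType])

    @property
    def r0(self) -> np.ndarray:
        return np.array([self.cells[c].r0 for c in CellType])

    @property
    def ie(self) -> np.ndarray:
        return np.array([self.cells[c].ie for c in CellType])

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.cells[c].beta for c in CellType])

    @property
    def stim_vector(self) -> np.ndarray:
        return np.array([self.baseline_stim[c] for c in CellType])

    def with_weights(self, weights: WeightSet) -> "ModelParams":
        return replace(self, weights=weights)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cells": {c.name: {"alpha": self.cells[c].alpha,
                               "r0": self.cells[c].r0,
                               "ie": self.cells[c].ie,
                               "beta": self.cells[c].beta}
                      for c in CellType},
            "tau_ms": self.tau_ms,
            "weights": self.weights.to_dict(),
            "baseline_stim": {c.name: self.baseline_stim[c] for c in CellType},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelParams":
        cells = dict(DEFAULT_CELL_PARAMS)
        for name, fields_ in doc.get("cells", {}).items():
            c = CellType.from_name(name)
            base = cells[c]
            cells[c] = CellParams(
                alpha=float(fields_.get("alpha", base.alpha)),
                r0=float(fields_.get("r0", base.r0)),
                ie=float(fields_.get("ie", base.ie)),
                beta=float(fields_.get("beta", base.beta)),
            )
        weights = WeightSet(doc.get("weights", {}))
        stim = {CellType.from_name(k): float(v)
                for k, v in doc.get("baseline_stim", {}).items()}
        return cls(cells=cells, weights=weights,
                   tau_ms=float(doc.get("tau_ms", 5.0)), baseline_stim=stim)

    def fingerprint(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class DriveVector:
    """Per-cell total drive I_m and its synaptic+stimulus part Itilde_m.

    I_m - Itilde_m equals the cell's intrinsic excitability exactly.
    """

    I: np.ndarray
    I_syn: np.ndarray


def response(I, beta):
    """Firing-rate response function f(I) = 1 / (1 + exp(-beta * I)).

    Returns the saturating fraction of the maximal rate recruited by a
    total drive ``I`` (au) at gain ``beta``.  Numerically stable for
    |beta * I| up to ~1e3 (the exponential is evaluated on the negative
    half-line only).
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("drive I must be finite")
    if np.any(np.asarray(beta) <= 0):
        raise ValueError("beta must be positive")
    x = np.asarray(beta, dtype=float) * I
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def inverse_response(y, beta):
    """Inverse of :func:`response`: f^{-1}(y) = beta^{-1} ln(y / (1-y))."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly inside (0, 1)")
    if np.any(np.asarray(beta) <= 0):
        raise ValueError("beta must be positive")
    out = np.log(y / (1.0 - y)) / np.asarray(beta, dtype=float)
    return out if out.ndim else float(out)


def presynaptic_drive(params: ModelParams, delayed_rates, stim=None) -> DriveVector:
    """Assemble the per-cell drive from delayed rates and stimulation.

    ``delayed_rates`` are the population rates at time t - tau, in
    CellType order; ``stim`` is the instantaneous per-cell STIM (au).
    The synaptic part is Itilde_m = sum_n w_{n->m} r_n(t - tau) + STIM_m
    over the mask edges entering m; the total is I_m = ie_m + Itilde_m.
    """
    r = np.asarray(delayed_rates, dtype=float)
    if r.shape != (4,):
        raise ValueError("delayed_rates must have length 4 (CellType order)")
    r0 = params.r0
    if np.any(r < -1e-12) or np.any(r > r0 * (1 + 1e-12)):
        raise ValueError("rates must lie within [0, r0] for every cell")
    if stim is None:
        stim = params.stim_vector
    stim = np.asarray(stim, dtype=float)
    I_syn = params.weights.as_matrix() @ r + stim
    return DriveVector(I=params.ie + I_syn, I_syn=I_syn)


def drift(params: ModelParams, rates, delayed_rates, stim=None) -> np.ndarray:
    """Instantaneous right-hand side of the delayed rate equations, Hz/s.

    dr_m/dt = alpha_m * (-r_m + r0_m * f(I_m)) with I_m assembled by
    :func:`presynaptic_drive` from the delayed rates.
    """
    rates = np.asarray(rates, dtype=float)
    d = presynaptic_drive(params, delayed_rates, stim)
    return params.alpha * (-rates + params.r0 * response(d.I, params.beta))
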