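"""Linear stability analysis of the two-cell subsystems.

The four-population circuit decomposes into three independent two-cell
motifs: PYR+BiC (theta generator), PYR+PV and CCK+PV (gamma
generators).  For each motif (cells 1 and 2 with retained weights w11,
w12, w21, w22) the analysis

1. solves the delayed system's equilibrium (x1*, x2*),
2. linearizes around it; with s_i = x_i*(1 - x_i*/r_i) the dimensionless
   couplings are gamma_ij = beta * w_ij * s_i (delayed terms),
3. forms the characteristic equation of the linearization.  Writing
   lambda = i*omega and multiplying through by e^{lambda tau}, the real
   and imaginary parts become

       kappa1 cos(omega tau) + kappa2 sin(omega tau) + kappa3 = 0
       kappa4 cos(omega tau) + kappa5 sin(omega tau) + kappa6 = 0

   with
       kappa1 = -omega^2 + a1 a2 (1 + g11 g22 - g12 g21)
       kappa2 = -(a1 + a2) omega
       kappa3 = -a1 a2 (g11 + g22)
       kappa4 =  (a1 + a2) omega
       kappa5 = -omega^2 + a1 a2 (1 - g11 g22 + g12 g21)
       kappa6 = -omega (a1 g11 + a2 g22),

4. solves the pair for sin(omega tau) = G1(omega) and cos(omega tau) =
   G2(omega); the trigonometric identity G1^2 + G2^2 = 1 determines the
   Hopf frequency omega, and the critical delays follow as

       tau_k = (theta + 2 k pi) / omega,   theta = atan2(G1, G2) mod 2pi.

The smallest positive tau_k is the first Hopf bifurcation delay: below
it oscillations damp out, above it they are sustained.

The critical-delay relation also yields an approximate frequency-vs-
delay curve: sweeping omega continuously and plotting (tau_0(omega),
omega) along the branch through the Hopf root approximates the
oscillation frequency expressed at a given delay.  That curve is what
:func:`frequency_at_delay` inverts and what the delay sweep reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import CellType, ModelParams, response, inverse_response
from .simulate import SimConfig, StimProtocol, simulate
from .spectral import welch_psd

__all__ = ["SubsystemSpec", "StabilityResult", "SUBSYSTEMS",
           "find_equilibrium", "find_equilibria", "characteristic_coefficients",
           "oscillation_frequency", "bifurcation_delays", "frequency_at_delay",
           "sweep", "subsystem_params"]

# Numerical guard: the phase curve atan2(G1, G2) is meaningful only on
# the branch where the coupling terms are appreciable; below this norm
# the curve degenerates to the uncoupled system's phase and produces
# spurious crossings.
_MIN_G_NORM = 0.05


@dataclass(frozen=True)
class SubsystemSpec:
    """A two-cell motif with the edges retained from the full mask.

    w11: self-connection of cell 1; w12: cell2 -> cell1;
    w21: cell1 -> cell2; w22: self-connection of cell 2 (if any).
    """

    name: str
    cells: tuple
    zeroed_edges: tuple

    @property
    def cell1(self) -> CellType:
        return self.cells[0]

    @property
    def cell2(self) -> CellType:
        return self.cells[1]


SUBSYSTEMS = {
    "PYR+BiC": SubsystemSpec(
        "PYR+BiC", (CellType.PYR, CellType.BiC),
        zeroed_edges=((CellType.PV, CellType.PYR),)),
    "PYR+PV": SubsystemSpec(
        "PYR+PV", (CellType.PYR, CellType.PV),
        zeroed_edges=((CellType.BiC, CellType.PYR),
                      (CellType.CCK, CellType.PV))),
    "CCK+PV": SubsystemSpec(
        "CCK+PV", (CellType.CCK, CellType.PV),
        zeroed_edges=((CellType.PYR, CellType.PV),)),
}


def subsystem_params(spec: SubsystemSpec, params: ModelParams,
                     beta: float | None = None) -> dict:
    """Scalar parameters (a_i, r_i, ie_i, w_ij, beta) of one motif."""
    c1, c2 = spec.cells
    w = params.weights
    def get(src, tgt):
        edge = (src, tgt)
        from .model import MASK
        return w[edge] if edge in MASK else 0.0
    b = beta if beta is not None else params.cells[c1].beta
    return dict(
        a1=params.cells[c1].alpha, a2=params.cells[c2].alpha,
        r1=params.cells[c1].r0, r2=params.cells[c2].r0,
        ie1=params.cells[c1].ie, ie2=params.cells[c2].ie,
        w11=get(c1, c1), w12=get(c2, c1), w21=get(c1, c2), w22=get(c2, c2),
        beta=b)


def _f(x):
    return response(x, 1.0)


def _x2_given_x1(p: dict, x1: float) -> float:
    """Second cell's rate consistent with x1 (unique: w22 <= 0)."""
    b = p["beta"]
    if p["w22"] == 0.0:
        return p["r2"] * _f(b * (p["ie2"] + p["w21"] * x1))
    g = lambda x2: x2 - p["r2"] * _f(b * (p["ie2"] + p["w21"] * x1
                                          + p["w22"] * x2))
    return brentq(g, 0.0, p["r2"], xtol=1e-14)


def find_equilibria(spec: SubsystemSpec, params: ModelParams,
                    beta: float | None = None, ngrid: int = 801) -> list:
    """All equilibria (x1*, x2*) of the motif with STIM = 0.

    The second cell's nullcline is solved exactly for each x1 (unique
    because its self-coupling is non-positive), reducing the problem to
    a one-dimensional root scan in x1.
    """
    p = subsystem_params(spec, params, beta)
    h = lambda x1: x1 - p["r1"] * _f(p["beta"] * (
        p["ie1"] + p["w11"] * x1 + p["w12"] * _x2_given_x1(p, x1)))
    xs = np.linspace(0.0, p["r1"], ngrid)
    vals = np.array([h(x) for x in xs])
    sols = []
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            sols.append((xs[i], _x2_given_x1(p, xs[i])))
        elif vals[i] * vals[i + 1] < 0:
            x1 = brentq(h, xs[i], xs[i + 1], xtol=1e-14)
            sols.append((x1, _x2_given_x1(p, x1)))
    if vals[-1] == 0.0:
        sols.append((xs[-1], _x2_given_x1(p, xs[-1])))
    return sols


def find_equilibrium(spec: SubsystemSpec, params: ModelParams,
                     beta: float | None = None,
                     damping: float = 0.2, tol: float = 1e-11,
                     max_iter: int = 200_000) -> tuple:
    """One equilibrium by damped fixed-point iteration.

    Iterates x <- x + damping * (F(x) - x) from the decoupled fixed
    point x_i = r_i f(beta ie_i).  Residual below ``tol`` (Hz) on exit.
    Falls back to the root-scan solver if the iteration cycles.
    """
    p = subsystem_params(spec, params, beta)
    b = p["beta"]
    x1 = p["r1"] * _f(b * p["ie1"])
    x2 = p["r2"] * _f(b * p["ie2"])
    for _ in range(max_iter):
        n1 = p["r1"] * _f(b * (p["ie1"] + p["w11"] * x1 + p["w12"] * x2))
        n2 = p["r2"] * _f(b * (p["ie2"] + p["w21"] * x1 + p["w22"] * x2))
        res = max(abs(n1 - x1), abs(n2 - x2))
        x1 += damping * (n1 - x1)
        x2 += damping * (n2 - x2)
        if res < tol:
            return (x1, x2)
    sols = find_equilibria(spec, params, beta)
    if not sols:
        raise RuntimeError(
            f"no equilibrium found for subsystem {spec.name}; parameters "
            "may place both nullclines outside the admissible box")
    return min(sols, key=lambda s: abs(s[0] - x1))


def characteristic_coefficients(spec: SubsystemSpec, params: ModelParams,
                                equilibrium: tuple,
                                beta: float | None = None) -> dict:
    """Linearization couplings gamma_ij at an equilibrium.

    gamma_11 = beta w11 x1*(1 - x1*/r1), gamma_12 = beta w12 x1*(1 -
    x1*/r1), gamma_21 = beta w21 x2*(1 - x2*/r2) and, for motifs whose
    second cell has a self-connection, gamma_22 = beta w22 x2*(1 -
    x2*/r2) entering the diagonal exactly as gamma_11 does for cell 1.
    Returns the gammas together with the kappa coefficients as
    functions of omega.
    """
    p = subsystem_params(spec, params, beta)
    x1, x2 = equilibrium
    s1 = x1 * (1.0 - x1 / p["r1"])
    s2 = x2 * (1.0 - x2 / p["r2"])
    b = p["beta"]
    g = dict(g11=b * p["w11"] * s1, g12=b * p["w12"] * s1,
             g21=b * p["w21"] * s2, g22=b * p["w22"] * s2)
    a1, a2 = p["a1"], p["a2"]

    def kappas(omega):
        return (
            -omega**2 + a1 * a2 * (1 + g["g11"] * g["g22"]
                                   - g["g12"] * g["g21"]),   # kappa1
            -(a1 + a2) * omega,                              # kappa2
            -a1 * a2 * (g["g11"] + g["g22"]),                # kappa3
            (a1 + a2) * omega,                               # kappa4
            -omega**2 + a1 * a2 * (1 - g["g11"] * g["g22"]
                                   + g["g12"] * g["g21"]),   # kappa5
            -omega * (a1 * g["g11"] + a2 * g["g22"]),        # kappa6
        )

    return dict(p=p, gammas=g, kappas=kappas)


def _G12(coeffs, omega):
    """sin(omega tau) = G1 and cos(omega tau) = G2 at the critical point."""
    k1, k2, k3, k4, k5, k6 = coeffs["kappas"](omega)
    den = k1 * k5 - k2 * k4
    if den == 0.0:
        return np.nan, np.nan
    return (k3 * k4 - k1 * k6) / den, (k2 * k6 - k3 * k5) / den


def _char_residuals(coeffs, omega, tau):
    k1, k2, k3, k4, k5, k6 = coeffs["kappas"](omega)
    c, s = np.cos(omega * tau), np.sin(omega * tau)
    scale = max(abs(k1) + abs(k2) + abs(k3), abs(k4) + abs(k5) + abs(k6), 1.0)
    return (abs(k1 * c + k2 * s + k3) / scale,
            abs(k4 * c + k5 * s + k6) / scale)


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the Hopf analysis for one motif."""

    subsystem: str
    equilibrium: tuple
    gammas: dict
    omega: float                 # rad/s
    frequency: float             # Hz
    bifurcation_delays: list     # s, increasing
    residuals: tuple             # normalized |Re D|, |Im D| at the root
    G1: float = 0.0
    G2: float = 0.0
    coeffs: dict = field(default_factory=dict, repr=False)

    @property
    def first_bifurcation(self) -> float:
        return self.bifurcation_delays[0]

    def to_dict(self) -> dict:
        return {"subsystem": self.subsystem,
                "equilibrium": list(self.equilibrium),
                "gammas": self.gammas,
                "omega": self.omega, "frequency_hz": self.frequency,
                "bifurcation_delays_ms": [t * 1e3
                                          for t in self.bifurcation_delays],
                "residuals": list(self.residuals)}


def bifurcation_delays(omega: float, G1: float, G2: float,
                       n: int = 5) -> list:
    """Critical delays tau_k = (theta + 2 k pi) / omega, k = 0, 1, ...

    theta solves sin(theta) = G1 on the branch consistent with
    cos(theta) = G2; negative candidates are advanced by one period.
    Requires |G1| <= 1 (a genuine root of the critical equations).
    """
    if abs(G1) > 1 + 1e-9:
        raise ValueError(f"|G1| = {abs(G1):.6f} > 1: not a consistent root")
    theta = np.arctan2(G1, G2) % (2 * np.pi)
    out = [(theta + 2 * k * np.pi) / omega for k in range(n)]
    while out and out[0] <= 0:
        out = out[1:] + [out[-1] + 2 * np.pi / omega]
    return out


def oscillation_frequency(spec: SubsystemSpec, params: ModelParams,
                          beta: float | None = None,
                          f_max: float = 200.0,
                          n_scan: int = 4000) -> StabilityResult:
    """Hopf root of one motif: frequency, critical delays, residuals.

    Scans omega/2pi in (0, f_max] for sign changes of G1^2 + G2^2 - 1,
    refines each by bisection, and — considering every equilibrium of
    the motif — returns the root with the smallest positive first
    bifurcation delay.
    """
    best = None
    closest = np.inf
    for eq in find_equilibria(spec, params, beta):
        coeffs = characteristic_coefficients(spec, params, eq, beta)
        h = lambda om: _G12(coeffs, om)[0]**2 + _G12(coeffs, om)[1]**2 - 1.0
        oms = 2 * np.pi * np.geomspace(0.2, f_max, n_scan)
        vals = np.array([h(o) for o in oms])
        closest = min(closest, float(np.nanmin(np.abs(vals))))
        for i in range(len(oms) - 1):
            if not (np.isfinite(vals[i]) and np.isfinite(vals[i + 1])):
                continue
            if vals[i] * vals[i + 1] >= 0:
                continue
            omega = brentq(h, oms[i], oms[i + 1], xtol=1e-12, rtol=8.9e-16)
            G1, G2 = _G12(coeffs, omega)
            delays = bifurcation_delays(omega, np.clip(G1, -1, 1), G2)
            tau0 = delays[0]
            if tau0 <= 0:
                continue
            if best is None or tau0 < best.first_bifurcation:
                best = StabilityResult(
                    subsystem=spec.name, equilibrium=eq,
                    gammas=dict(coeffs["gammas"]),
                    omega=omega, frequency=omega / (2 * np.pi),
                    bifurcation_delays=delays,
                    residuals=_char_residuals(coeffs, omega, tau0),
                    G1=G1, G2=G2, coeffs=coeffs)
    if best is None:
        raise RuntimeError(
            f"no oscillation root found for {spec.name} with omega/2pi in "
            f"(0, {f_max}] Hz; min |G1^2+G2^2-1| on the scan was {closest:.3g}")
    return best


def frequency_at_delay(result: StabilityResult, tau: float,
                       f_max: float = 400.0, n_scan: int = 8000):
    """Approximate oscillation frequency expressed at delay ``tau``.

    Inverts the critical-delay curve tau_0(omega) along the continuous
    phase branch through the Hopf root.  Returns the frequency in Hz,
    or None if the branch does not reach ``tau``.
    """
    coeffs = result.coeffs
    oms = 2 * np.pi * np.geomspace(0.2, f_max, n_scan)
    G = np.array([_G12(coeffs, o) for o in oms])
    norm = np.hypot(G[:, 0], G[:, 1])
    theta = np.unwrap(np.arctan2(G[:, 0], G[:, 1]))
    i0 = int(np.searchsorted(oms, result.omega))
    i0 = min(max(i0, 0), len(oms) - 1)
    tau0 = result.first_bifurcation
    k = round((tau0 * result.omega - theta[i0]) / (2 * np.pi))
    taus = (theta + 2 * np.pi * k) / oms
    # restrict to the contiguous well-coupled window around the root
    valid = norm >= _MIN_G_NORM
    lo = i0
    while lo > 0 and valid[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(oms) - 1 and valid[hi + 1]:
        hi += 1
    d = taus[lo:hi + 1] - tau
    o = oms[lo:hi + 1]
    crossings = []
    for j in range(len(d) - 1):
        if np.isfinite(d[j]) and np.isfinite(d[j + 1]) and d[j] * d[j + 1] < 0:
            om = o[j] + (o[j + 1] - o[j]) * d[j] / (d[j] - d[j + 1])
            crossings.append(om / (2 * np.pi))
    if not crossings:
        return None
    f_star = result.frequency
    return min(crossings, key=lambda fr: abs(np.log(fr / f_star)))


def _dominant_cell(spec: SubsystemSpec, params: ModelParams, tau_s: float,
                   beta: float | None = None) -> CellType:
    """Cell with the larger post-transient amplitude range in simulation."""
    from dataclasses import replace as _replace
    sub = _subsystem_model(spec, params, beta)
    sub = _replace(sub, tau_ms=tau_s * 1e3)
    dt = tau_s / max(1, round(tau_s / 0.001))
    trace = simulate(sub, config=SimConfig(dt=dt, duration=4.0))
    post = trace.after(1.0)
    ranges = {c: float(np.ptp(post.cell(c))) for c in spec.cells}
    return max(ranges, key=ranges.get)


def _subsystem_model(spec: SubsystemSpec, params: ModelParams,
                     beta: float | None = None) -> ModelParams:
    """Full-model parameters with only the motif's edges retained."""
    from .model import MASK, WeightSet, CellParams
    keep = {(s, t) for (s, t) in params.weights.w
            if s in spec.cells and t in spec.cells
            and (s, t) not in spec.zeroed_edges}
    w = {e: v for e, v in params.weights.w.items() if e in keep}
    cells = params.cells
    if beta is not None:
        cells = {c: CellParams(cp.alpha, cp.r0, cp.ie, beta)
                 for c, cp in params.cells.items()}
    from dataclasses import replace as _replace
    return _replace(params, weights=WeightSet(w), cells=cells)


def sweep(spec: SubsystemSpec, params: ModelParams,
          beta_grid=None, tau_grid=None) -> dict:
    """Frequency curves vs beta (at the Hopf root) or vs delay.

    The beta sweep recomputes the Hopf root per beta; the tau sweep
    evaluates the frequency-at-delay curve of the root at the default
    beta.  The reported frequency is attributed to the motif's
    dominant (highest-amplitude) cell, determined by simulation.
    Per-point root failures are recorded as None, not raised.
    """
    if (beta_grid is None) == (tau_grid is None):
        raise ValueError("provide exactly one of beta_grid or tau_grid")
    out = {"subsystem": spec.name, "points": []}
    if beta_grid is not None:
        for b in beta_grid:
            try:
                res = oscillation_frequency(spec, params, beta=float(b))
                freq, tau0 = res.frequency, res.first_bifurcation
            except RuntimeError:
                freq = tau0 = None
            out["points"].append({"beta": float(b), "frequency_hz": freq,
                                  "tau0_ms": None if tau0 is None
                                  else tau0 * 1e3})
    else:
        res = oscillation_frequency(spec, params)
        for tau_s in tau_grid:
            freq = frequency_at_delay(res, float(tau_s))
            out["points"].append({"tau_ms": float(tau_s) * 1e3,
                                  "frequency_hz": freq,
                                  "tau0_ms": res.first_bifurcation * 1e3})
    try:
        tau_ref = (tau_grid[len(tau_grid) // 2] if tau_grid is not None
                   else params.tau_ms / 1e3)
        out["dominant_cell"] = _dominant_cell(spec, params, float(tau_ref)).name
    except Exception:
        out["dominant_cell"] = None
    return out
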